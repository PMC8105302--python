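"""Paired negative-binomial Wald differential expression.

Implements the three-way FACS population comparison as a paired NB GLM:
``log mu_gj = log s_j + mouse_j + population_j`` fitted per gene by IRLS,
with median-of-ratios size factors, empirical-Bayes dispersion estimation,
Wald tests on the population contrast, and Benjamini-Hochberg adjustment.
Every gene that is expressed receives a p-value: no outlier cut-off and no
independent filtering are applied.

Also houses the derived selections: the strict ``padj < 0.05 and |log2FC| > 1``
DE gene filter, the top-k lists by fold change at ``p < 0.01``, and the
``log2(x + 1)`` normalized marker-panel matrices used for heatmaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import _glm

LN2 = float(np.log(2.0))

DE_COLUMNS = ["gene_id", "base_mean", "log2fc", "se", "wald_stat", "p", "padj"]


@dataclass
class CountMatrix:
    """Integer gene-by-sample counts plus per-sample (mouse, population) labels."""

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise ValueError("sample metadata must match count columns in order")
        for col in ("mouse", "population"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta missing required column {col!r}")
            if self.sample_meta[col].isna().any():
                raise ValueError(f"sample_meta column {col!r} has missing values")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.sample_meta["population"]:
            if p not in seen:
                seen.append(p)
        return seen


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are those with strictly positive counts in every sample;
    each sample's factor is the median across reference genes of the ratio of
    its count to the gene's geometric mean.
    """
    K = cm.counts.to_numpy(dtype=float)
    all_pos = (K > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "size factors need at least one gene with strictly positive "
            "counts in all samples; none found"
        )
    ref = K[all_pos]
    log_geo = np.log(ref).mean(axis=1, keepdims=True)
    s = np.exp(np.median(np.log(ref) - log_geo, axis=0))
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=cm.counts.columns, name="size_factor")


def design_matrix(meta: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + mouse indicators + population indicators (treatment coding,
    first observed level of each factor as reference)."""
    mice = list(dict.fromkeys(meta["mouse"]))
    pops = list(dict.fromkeys(meta["population"]))
    n = len(meta)
    cols = ["intercept"] + [f"mouse[{m}]" for m in mice[1:]] + [
        f"population[{p}]" for p in pops[1:]
    ]
    X = np.zeros((n, len(cols)))
    X[:, 0] = 1.0
    for j, m in enumerate(mice[1:], start=1):
        X[(meta["mouse"] == m).to_numpy(), j] = 1.0
    off = 1 + len(mice) - 1
    for j, p in enumerate(pops[1:]):
        X[(meta["population"] == p).to_numpy(), off + j] = 1.0
    return X, cols


def estimate_dispersion(
    cm: CountMatrix,
    sf: pd.Series,
    method: str = "map",
    alpha_min: float = 1e-8,
) -> pd.DataFrame:
    """Per-gene NB dispersion on size-factor-normalized counts.

    ``method="map"`` (default) uses Cox-Reid adjusted profile likelihood with
    empirical-Bayes shrinkage toward a parametric mean-dispersion trend —
    the approach that keeps the downstream Wald test calibrated at a handful
    of samples. ``method="moment"`` is the transparent textbook alternative:
    within-population method of moments, ``max(0, (s2 - mean)/mean^2)``
    averaged over populations.

    Returns a frame with columns ``alpha`` and ``flagged`` (True for genes
    with zero mean, which receive ``alpha_min``).
    """
    K = cm.counts.to_numpy(dtype=float)
    norm = K / sf.to_numpy()[None, :]
    zero_mean = norm.mean(axis=1) <= 0

    if method == "moment":
        pops = cm.sample_meta["population"].to_numpy()
        ests = []
        for p in dict.fromkeys(pops):
            sub = norm[:, pops == p]
            m = sub.mean(axis=1)
            v = sub.var(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                a = np.where(m > 0, (v - m) / m**2, 0.0)
            ests.append(np.maximum(a, 0.0))
        alpha = np.mean(ests, axis=0)
    elif method == "map":
        X, _ = design_matrix(cm.sample_meta)
        offset = np.log(sf.to_numpy())
        alpha = np.full(K.shape[0], alpha_min)
        keep = ~zero_mean
        if keep.any():
            alpha[keep] = _glm.dispersion_map(K[keep], X, offset, floor=alpha_min)
    else:
        raise ValueError(f"unknown dispersion method {method!r}")

    alpha = np.maximum(alpha, alpha_min)
    alpha[zero_mean] = alpha_min
    return pd.DataFrame(
        {"alpha": alpha, "flagged": zero_mean}, index=cm.counts.index
    )


def fit_paired_nb_wald(
    cm: CountMatrix,
    sf: pd.Series,
    dispersions: pd.DataFrame | pd.Series,
    contrast: tuple[str, str],
    drop_all_zero: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Wald test of one population contrast under the paired NB GLM.

    ``contrast=(ref, alt)`` reports the ``alt`` vs ``ref`` log2 fold change.
    The model is fitted once on all samples with the full mouse + population
    design; the contrast is a linear combination of population coefficients.
    Non-converged genes are flagged and get a missing p-value; all-zero genes
    are excluded from testing when ``drop_all_zero`` (they appear with
    missing statistics otherwise).
    """
    ref, alt = contrast
    pops = cm.populations()
    for p in contrast:
        if p not in pops:
            raise ValueError(f"population {p!r} not present in the data")
    X, cols = design_matrix(cm.sample_meta)
    c = np.zeros(X.shape[1])
    for sign, p in ((-1.0, ref), (1.0, alt)):
        name = f"population[{p}]"
        if name in cols:
            c[cols.index(name)] = sign
    offset = np.log(sf.to_numpy())
    if isinstance(dispersions, pd.DataFrame):
        alpha = dispersions["alpha"].to_numpy(dtype=float)
    else:
        alpha = np.asarray(dispersions, dtype=float)

    K = cm.counts.to_numpy(dtype=float)
    norm = K / sf.to_numpy()[None, :]
    base_mean = norm.mean(axis=1)
    expressed = K.sum(axis=1) > 0

    G = K.shape[0]
    log2fc = np.full(G, np.nan)
    se = np.full(G, np.nan)
    wald = np.full(G, np.nan)
    pval = np.full(G, np.nan)
    converged = np.zeros(G, dtype=bool)

    idx = np.flatnonzero(expressed)
    if idx.size:
        fit = _glm.irls_nb(K[idx], X, alpha[idx], offset, max_iter=max_iter, tol=tol)
        est = fit.beta @ c
        var = np.einsum("p,gpq,q->g", c, fit.cov, c)
        sd = np.sqrt(np.maximum(var, 0.0))
        z = np.where(sd > 0, est / sd, 0.0)
        log2fc[idx] = est / LN2
        se[idx] = sd / LN2
        wald[idx] = z
        converged[idx] = fit.converged
        p_fit = 2.0 * stats.norm.sf(np.abs(z))
        p_fit[~fit.converged] = np.nan
        pval[idx] = p_fit

    out = pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_stat": wald,
            "p": pval,
            "converged": converged,
        }
    )
    if drop_all_zero:
        out = out[expressed].reset_index(drop=True)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out.attrs["contrast"] = (ref, alt)
    return out[DE_COLUMNS + ["converged"]]


def de_all_contrasts(
    cm: CountMatrix, sf=None, dispersions=None, **kwargs
) -> dict[tuple[str, str], pd.DataFrame]:
    """All three pairwise population contrasts from a single dispersion fit."""
    if sf is None:
        sf = size_factors(cm)
    if dispersions is None:
        dispersions = estimate_dispersion(cm, sf)
    pops = cm.populations()
    out = {}
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            contrast = (pops[i], pops[j])
            out[contrast] = fit_paired_nb_wald(cm, sf, dispersions, contrast, **kwargs)
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (missing p stay missing)."""
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def select_de(
    de: pd.DataFrame, padj_max: float = 0.05, lfc_min: float = 1.0
) -> pd.DataFrame:
    """Significant DE genes at strict thresholds: padj < padj_max AND |log2FC| > lfc_min."""
    mask = (de["padj"] < padj_max) & (de["log2fc"].abs() > lfc_min)
    return de[mask.fillna(False)].reset_index(drop=True)


def top_k_by_lfc(
    de: pd.DataFrame,
    k: int = 50,
    direction: str = "up",
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Top-``k`` genes by fold-change magnitude among genes with ``p < p_max``.

    ``direction`` selects up- ("up") or down-regulated ("down") genes; rows
    are sorted by |log2FC| descending with ties broken by smaller p then
    lexicographic gene id. If fewer than ``k`` genes qualify all are returned
    and ``attrs["truncated"]`` is set.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    eligible = de[de["p"] < p_max]
    if direction == "up":
        eligible = eligible[eligible["log2fc"] > 0]
    else:
        eligible = eligible[eligible["log2fc"] < 0]
    ordered = eligible.assign(_abs=eligible["log2fc"].abs()).sort_values(
        ["_abs", "p", "gene_id"], ascending=[False, True, True]
    )
    out = ordered.drop(columns="_abs").head(k).reset_index(drop=True)
    out.attrs["truncated"] = len(eligible) < k
    if len(eligible) < k:
        warnings.warn(
            f"only {len(eligible)} genes eligible for top-{k} ({direction})",
            stacklevel=2,
        )
    return out


def log2p1_panel(
    cm: CountMatrix,
    sf: pd.Series,
    marker_ids: list[str],
    errors: str = "raise",
) -> pd.DataFrame:
    """``log2(normalized count + 1)`` matrix for a marker panel.

    Rows follow ``marker_ids`` order. Missing markers raise (or warn and are
    dropped when ``errors="warn"``) — never silently ignored.
    """
    missing = [g for g in marker_ids if g not in cm.counts.index]
    if missing:
        msg = f"marker ids not in count matrix: {missing}"
        if errors == "raise":
            raise KeyError(msg)
        warnings.warn(msg, stacklevel=2)
    present = [g for g in marker_ids if g in cm.counts.index]
    norm = cm.counts.loc[present].to_numpy(dtype=float) / sf.to_numpy()[None, :]
    return pd.DataFrame(
        np.log2(norm + 1.0), index=pd.Index(present, name="gene_id"),
        columns=cm.counts.columns,
    )
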