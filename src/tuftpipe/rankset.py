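"""Signed-score Mann-Whitney-Wilcoxon geneset enrichment.

Each gene gets a signed score ``-log10(p) * sign(log2FC)`` from the DE
results; a geneset is tested by comparing the ranks of its members' scores
against the ranks of all other genes with a two-sided MWW test. Sets are
size-filtered (10-500 members within the measured universe by default) and
flagged significant at the Bonferroni threshold alpha / M over the M sets
actually tested. For plotting, each set receives volcano coordinates: x is
the members' mean log2 fold change weighted by ``-log10(p)``, y is
``-log10`` of the enrichment p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ENRICH_COLUMNS = [
    "set_name", "n_in", "u_stat", "z", "p_enrich",
    "bonferroni_significant", "x_volcano", "y_volcano", "bubble_size",
]


@dataclass
class GeneSetCollection:
    """Named gene-identifier sets (GMT semantics)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # dict keys are unique by construction; normalize members to frozensets
        self.sets = {name: frozenset(m) for name, m in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description, members."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (needs >= 3 fields): {line!r}")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate geneset name in GMT: {name!r}")
            sets[name] = frozenset(g for g in parts[2:] if g)
            desc[name] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def signed_scores(
    de: pd.DataFrame, use_adjusted: bool = False, p_floor: float = 1e-300
) -> pd.DataFrame:
    """Per-gene signed scores ``-log10(max(p, p_floor)) * sign(log2FC)``.

    Genes with a missing p-value are dropped (logged); raw DE p-values are
    used unless ``use_adjusted``.
    """
    pcol = "padj" if use_adjusted else "p"
    p = de[pcol].to_numpy(dtype=float)
    missing = np.isnan(p)
    if missing.any():
        logger.info("signed_scores: dropping %d genes with missing p", missing.sum())
    de = de[~missing]
    p = p[~missing]
    if (p > 1).any() or (p < 0).any():
        raise ValueError("p-values must lie in [0, 1]")
    lfc = de["log2fc"].to_numpy(dtype=float)
    score = -np.log10(np.maximum(p, p_floor)) * np.sign(lfc)
    return pd.DataFrame(
        {"gene_id": de["gene_id"].to_numpy(), "score": score, "lfc": lfc, "p": p}
    ).reset_index(drop=True)


def _mww(member_scores, other_scores, continuity, exact):
    """Two-sided MWW; returns (U of members, z, p)."""
    n1, n2 = len(member_scores), len(other_scores)
    combined = np.concatenate([member_scores, other_scores])
    ranks = stats.rankdata(combined)  # mid-ranks
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    has_ties = (counts > 1).any()
    N = n1 + n2
    tie_term = (counts**3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if sigma2 <= 0:  # all scores identical: no rank information
        return u1, 0.0, 1.0
    if exact and not has_ties:
        res = stats.mannwhitneyu(
            member_scores, other_scores, alternative="two-sided", method="exact"
        )
        p = float(res.pvalue)
    else:
        res = stats.mannwhitneyu(
            member_scores,
            other_scores,
            alternative="two-sided",
            method="asymptotic",
            use_continuity=continuity,
        )
        p = float(res.pvalue)
    mean_u = n1 * n2 / 2.0
    cc = 0.5 if continuity else 0.0
    num = u1 - mean_u
    z = (num - np.sign(num) * cc) / np.sqrt(sigma2)
    return u1, float(z), min(p, 1.0)


def enrich_collection(
    scores: pd.DataFrame,
    collection: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 500,
    alpha: float = 0.05,
    continuity: bool = True,
    exact_max_members: int = 10,
    exact_max_universe: int = 25,
) -> pd.DataFrame:
    """Test every geneset against the scored universe.

    Sets are intersected with the universe first, then size-filtered to
    ``[min_size, max_size]``. Small problems (``n_in <= exact_max_members``
    and universe ``<= exact_max_universe``, no tied scores) are tested by
    exact enumeration of the U distribution; otherwise the tie-corrected
    normal approximation (with continuity correction by default) is used.
    The Bonferroni flag uses ``alpha / M`` with M = sets tested in this call.
    """
    if len(scores) == 0:
        raise ValueError("empty score universe: no genes to rank")
    if len(collection) == 0:
        raise ValueError("empty geneset collection")
    universe = scores["gene_id"].to_numpy()
    uni_index = {g: i for i, g in enumerate(universe)}
    svals = scores["score"].to_numpy(dtype=float)

    surviving = []
    for name, members in collection:
        inter = [g for g in members if g in uni_index]
        if min_size <= len(inter) <= max_size:
            surviving.append((name, inter))
    if not surviving:
        raise ValueError(
            f"no genesets survived the [{min_size}, {max_size}] size filter "
            f"after intersecting with the {len(universe)}-gene universe"
        )
    M = len(surviving)
    exact_ok = len(universe) <= exact_max_universe

    rows = []
    for name, members in surviving:
        midx = np.array([uni_index[g] for g in members])
        mask = np.zeros(len(universe), dtype=bool)
        mask[midx] = True
        u, z, p = _mww(
            svals[mask],
            svals[~mask],
            continuity=continuity,
            exact=exact_ok and len(members) <= exact_max_members,
        )
        x = volcano_x(scores, members)
        rows.append(
            {
                "set_name": name,
                "n_in": len(members),
                "u_stat": u,
                "z": z,
                "p_enrich": p,
                "bonferroni_significant": p < alpha / M,
                "x_volcano": x,
                "y_volcano": -np.log10(max(p, 1e-300)),
                "bubble_size": len(members),
            }
        )
    out = pd.DataFrame(rows, columns=ENRICH_COLUMNS)
    out.attrs["n_tested"] = M
    out.attrs["alpha"] = alpha
    return out


def volcano_x(scores: pd.DataFrame, members, p_floor: float = 1e-300) -> float:
    """Weighted mean member log2FC, weights ``-log10(p)`` of each member gene.

    Returns NaN (logged) when every member has p = 1 so all weights vanish.
    """
    sub = scores[scores["gene_id"].isin(set(members))]
    w = -np.log10(np.maximum(sub["p"].to_numpy(dtype=float), p_floor))
    if w.sum() <= 0:
        logger.warning("volcano_x: all member weights are zero (all p = 1)")
        return float("nan")
    return float(np.average(sub["lfc"].to_numpy(dtype=float), weights=w))


def volcano_coordinates(
    scores: pd.DataFrame, p_enrich: float, members
) -> tuple[float, float]:
    """(x, y) volcano coordinates for one geneset."""
    return volcano_x(scores, members), float(-np.log10(max(p_enrich, 1e-300)))


def volcano_plot(result: pd.DataFrame, path, alpha: float = 0.05) -> None:
    """Bubble volcano of geneset enrichment (x: weighted mean log2FC,
    y: -log10 enrichment p, size: members; dotted Bonferroni line)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = result.attrs.get("n_tested", len(result))
    fig, ax = plt.subplots(figsize=(6, 5))
    up = result["x_volcano"] >= 0
    ax.scatter(
        result.loc[up, "x_volcano"], result.loc[up, "y_volcano"],
        s=result.loc[up, "bubble_size"], c="firebrick", alpha=0.5, lw=0,
    )
    ax.scatter(
        result.loc[~up, "x_volcano"], result.loc[~up, "y_volcano"],
        s=result.loc[~up, "bubble_size"], c="seagreen", alpha=0.5, lw=0,
    )
    ax.axhline(-np.log10(alpha / max(m, 1)), ls=":", c="gray")
    ax.axvline(0.0, ls="-", c="black", lw=0.5)
    ax.set_xlabel("weighted mean log2 fold change")
    ax.set_ylabel("-log10 enrichment p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
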