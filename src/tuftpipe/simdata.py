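"""Synthetic inputs for the tuft-cell maturation pipeline.

Every downstream stage consumes data in the shapes produced here: paired
negative-binomial RNA-seq counts from five mice and three FACS-sorted
populations (non-tuft background, young Trpm5-GFP-only tuft cells, mature
GFP/mCherry double-positive tuft cells), GMT geneset collections with planted
enriched sets, dual-reporter organoid time-lapse tracks sampled every 3 h for
up to 60 h, crypt/villus co-localization counts, and qPCR Ct tables.

Defaults reproduce the study conditions: 5 mice, dispersion 0.05, a 10.8 h
mean GFP-to-mCherry onset lag, 119-cell track cohorts split 58/33/25/3 into
transitioning / GFP-only / double-positive-throughout / mCherry-only, 98%
villus and 46% crypt double-positive fractions, and a ~1000-fold qPCR
enrichment of the top receptor. Ground truth is returned alongside every
simulated artifact so recovery tests downstream can score themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pairwise_de import CountMatrix
from .reporterdyn import CellTrack

POPULATIONS = ("background", "young_tuft", "mature_tuft")

#: Fig-4-style track category labels
CAT_TRANSITION = "transition"
CAT_GFP_ONLY = "GFP_only"
CAT_BOTH = "both_throughout"
CAT_MCHERRY_ONLY = "mCherry_only"


@dataclass(frozen=True)
class SimConfig:
    """Generative model for the paired three-population count matrix.

    Counts are NB2 with mean ``mu = base_g * exp(mouse_m) * lib_j * 2**lfc_gj``
    and variance ``mu + dispersion * mu**2``. The first ``n_de_genes`` genes
    carry a planted log2 fold change ``de_lfc`` in mature vs young tuft cells.
    """

    n_mice: int = 5
    n_genes: int = 2000
    populations: tuple[str, ...] = POPULATIONS
    library_size_mean: float = 5e5
    mouse_sd: float = 0.3
    dispersion: float = 0.05
    n_de_genes: int = 100
    de_lfc: float = 2.0
    seed: int = 0
    library_sd: float = 0.25       # log-normal spread of per-sample depth
    base_mean_range: tuple[float, float] = (2.0, 2000.0)

    def __post_init__(self) -> None:
        if self.n_mice < 2:
            raise ValueError("n_mice must be at least 2")
        if self.n_genes < 1 or self.library_size_mean <= 0:
            raise ValueError("n_genes and library_size_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.mouse_sd < 0 or self.library_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if tuple(self.populations) != POPULATIONS:
            raise ValueError(f"populations must be exactly {POPULATIONS}")
        if not 0 <= self.n_de_genes <= self.n_genes:
            raise ValueError("n_de_genes must lie in [0, n_genes]")


@dataclass(frozen=True)
class TrackSimConfig:
    """Dual-reporter time-lapse cohort model.

    Transitioning cells switch on GFP at a uniform time and mCherry after a
    lag drawn from a normal truncated at zero; onsets are then discretized to
    the imaging frame grid (a reporter is first seen "on" at the first frame
    at or after its continuous onset).
    """

    n_cells: int = 119
    frame_interval_h: float = 3.0
    horizon_h: float = 60.0
    lag_mean_h: float = 10.8
    lag_sd_h: float = 4.0
    fraction_transitioning: float = 58 / 119
    fraction_gfp_only: float = 33 / 119
    fraction_both_at_start: float = 25 / 119
    fraction_mcherry_only: float = 3 / 119
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if self.frame_interval_h <= 0 or self.horizon_h < self.frame_interval_h:
            raise ValueError("need horizon_h >= frame_interval_h > 0")
        if self.lag_mean_h < 0:
            raise ValueError("lag_mean_h must be nonnegative")
        if self.lag_sd_h < 0:
            raise ValueError("lag_sd_h must be nonnegative")
        fr = self.fractions
        if any(not 0 <= f <= 1 for f in fr):
            raise ValueError("category fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return (
            self.fraction_transitioning,
            self.fraction_gfp_only,
            self.fraction_both_at_start,
            self.fraction_mcherry_only,
        )

    @property
    def frame_times(self) -> np.ndarray:
        n_frames = int(math.floor(self.horizon_h / self.frame_interval_h)) + 1
        return np.arange(n_frames) * self.frame_interval_h

    def true_mean_lag(self) -> float:
        """Analytical mean of the zero-truncated normal lag distribution."""
        if self.lag_sd_h == 0:
            return self.lag_mean_h
        a = (0.0 - self.lag_mean_h) / self.lag_sd_h
        return float(
            stats.truncnorm.mean(a, np.inf, loc=self.lag_mean_h, scale=self.lag_sd_h)
        )


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw the paired count matrix plus its planted ground truth.

    Returns ``(count_matrix, truth)`` where ``truth`` has one row per gene
    with the planted mature-vs-young log2 fold change.
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    gene_ids = [f"gene_{i:05d}" for i in range(G)]

    lo, hi = cfg.base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), G))
    base *= cfg.library_size_mean / base.sum()

    # gene-specific mouse effects: a shared per-sample shift would be absorbed
    # by size factors; per-gene effects are what the paired GLM models
    mouse_eff = rng.normal(0.0, cfg.mouse_sd, (G, cfg.n_mice))
    lfc = np.zeros(G)
    lfc[: cfg.n_de_genes] = cfg.de_lfc

    samples, mice, pops, cols = [], [], [], []
    for m in range(cfg.n_mice):
        for popn in cfg.populations:
            sample = f"m{m + 1}_{popn}"
            lib = rng.lognormal(0.0, cfg.library_sd)
            mu = base * np.exp(mouse_eff[:, m]) * lib
            if popn == "mature_tuft":
                mu = mu * np.exp2(lfc)
            if cfg.dispersion < 1e-10:
                counts = rng.poisson(mu)
            else:
                shape = 1.0 / cfg.dispersion
                lam = rng.gamma(shape, mu / shape)
                counts = rng.poisson(lam)
            cols.append(counts)
            samples.append(sample)
            mice.append(f"mouse{m + 1}")
            pops.append(popn)

    counts = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(gene_ids, name="gene_id"),
        columns=samples,
    )
    meta = pd.DataFrame(
        {"mouse": mice, "population": pops}, index=pd.Index(samples, name="sample")
    )
    truth = pd.DataFrame(
        {"true_log2fc": lfc, "planted": lfc != 0.0},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return CountMatrix(counts=counts, sample_meta=meta), truth


def simulate_genesets(
    universe: list[str],
    n_sets: int,
    size_range: tuple[int, int] = (10, 500),
    n_planted: int = 0,
    de_genes: list[str] | None = None,
    seed: int = 0,
):
    """Random genesets over ``universe`` with optional planted enriched sets.

    Planted sets draw their members from ``de_genes`` (the planted-DE gene
    pool) so that rank-based enrichment has signal to find; the remaining
    sets are uniform draws without replacement from the whole universe.
    Returns ``(collection, planted_names)``.
    """
    from .rankset import GeneSetCollection

    lo, hi = size_range
    if lo < 2 or hi > len(universe) or lo > hi:
        raise ValueError(
            f"size_range {size_range} incompatible with universe of {len(universe)}"
        )
    if n_planted > 0 and not de_genes:
        raise ValueError("planted sets requested but no de_genes supplied")
    if n_planted > n_sets:
        raise ValueError("n_planted cannot exceed n_sets")

    rng = np.random.default_rng(seed)
    universe = list(universe)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    planted_names: list[str] = []

    for i in range(n_planted):
        name = f"planted_set_{i:03d}"
        size = int(rng.integers(lo, min(hi, len(de_genes)) + 1))
        members = list(rng.choice(de_genes, size=size, replace=False))
        sets[name] = frozenset(members)
        descriptions[name] = "planted enriched geneset"
        planted_names.append(name)
    for i in range(n_sets - n_planted):
        name = f"random_set_{i:03d}"
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(universe, size=size, replace=False))
        sets[name] = frozenset(members)
        descriptions[name] = "random geneset"
    return GeneSetCollection(sets=sets, descriptions=descriptions), planted_names


def simulate_tracks(cfg: TrackSimConfig) -> tuple[list[CellTrack], pd.DataFrame]:
    """Simulate a dual-reporter time-lapse cohort.

    Returns ``(tracks, truth)`` where ``truth`` records each cell's category
    and, for transitioning cells, the continuous (pre-discretization) GFP and
    mCherry onset times and lag.
    """
    rng = np.random.default_rng(cfg.seed)
    times = cfg.frame_times
    categories = (CAT_TRANSITION, CAT_GFP_ONLY, CAT_BOTH, CAT_MCHERRY_ONLY)
    assigned = rng.choice(4, size=cfg.n_cells, p=cfg.fractions)

    tracks: list[CellTrack] = []
    rows = []
    for i in range(cfg.n_cells):
        cat = categories[assigned[i]]
        gfp = np.zeros(times.size, dtype=bool)
        mch = np.zeros(times.size, dtype=bool)
        t_g = t_m = lag = np.nan
        if cat == CAT_TRANSITION:
            if cfg.lag_sd_h == 0:
                lag = cfg.lag_mean_h
            else:
                a = (0.0 - cfg.lag_mean_h) / cfg.lag_sd_h
                lag = float(
                    stats.truncnorm.rvs(
                        a, np.inf, loc=cfg.lag_mean_h, scale=cfg.lag_sd_h,
                        random_state=rng,
                    )
                )
            lag = min(lag, cfg.horizon_h)
            t_g = float(rng.uniform(0.0, cfg.horizon_h - lag))
            t_m = t_g + lag
            gfp = times >= t_g
            mch = times >= t_m
        elif cat == CAT_GFP_ONLY:
            t_g = float(rng.uniform(0.0, cfg.horizon_h))
            gfp = times >= t_g
        elif cat == CAT_BOTH:
            t_g = t_m = 0.0
            gfp[:] = True
            mch[:] = True
        else:  # mCherry only
            t_m = float(rng.uniform(0.0, cfg.horizon_h))
            mch = times >= t_m
        cell_id = f"cell_{i:04d}"
        organoid = f"organoid_{i % max(cfg.n_cells // 3, 1):03d}"
        tracks.append(
            CellTrack(
                cell_id=cell_id,
                organoid_id=organoid,
                times=times.copy(),
                gfp=gfp,
                mcherry=mch,
            )
        )
        rows.append(
            {
                "cell_id": cell_id,
                "category": cat,
                "true_t_gfp": t_g,
                "true_t_mcherry": t_m,
                "true_lag_h": lag,
            }
        )
    return tracks, pd.DataFrame(rows).set_index("cell_id")


def simulate_compartment_counts(
    n_animals: int = 3,
    per_region_cells: int = 350,
    p_double_villus: float = 0.98,
    p_double_crypt: float = 0.46,
    seed: int = 0,
    total_cells_factor: int = 20,
) -> pd.DataFrame:
    """Binomial crypt/villus co-localization counts, one row per animal/region.

    ``per_region_cells`` reporter-positive cells are scored per animal and
    region (>=300 by default, as in whole-mount quantification); each is
    double positive with the region's probability, otherwise GFP-only.
    ``n_total_cells`` is the total epithelial cell count of the scored area.
    """
    if not (0 <= p_double_villus <= 1 and 0 <= p_double_crypt <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if per_region_cells < 1 or n_animals < 1:
        raise ValueError("per_region_cells and n_animals must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        for region, p in (("crypt", p_double_crypt), ("villus", p_double_villus)):
            n_double = int(rng.binomial(per_region_cells, p))
            rows.append(
                {
                    "animal_id": f"animal_{a + 1}",
                    "region": region,
                    "n_double": n_double,
                    "n_gfp_only": per_region_cells - n_double,
                    "n_mcherry_only": 0,
                    "n_total_cells": per_region_cells * total_cells_factor,
                }
            )
    return pd.DataFrame(rows)


def simulate_ct(
    n_genes: int = 379,
    enriched_ids: list[str] | None = None,
    fold: float = 1000.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    housekeeping_ct: float = 18.0,
) -> pd.DataFrame:
    """qPCR Ct table for a receptor array sorted-vs-unsorted comparison.

    Enriched genes have their target-population Ct lowered by ``log2(fold)``
    cycles relative to the reference population; the housekeeping gene is
    constant. Gaussian Ct noise with ``noise_sd`` cycles is added to target
    Ct values.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    rng = np.random.default_rng(seed)
    enriched_ids = list(enriched_ids or [])
    other = [f"gpcr_{i:03d}" for i in range(n_genes - len(enriched_ids))]
    gene_ids = enriched_ids + other
    ct_neg = rng.uniform(24.0, 34.0, len(gene_ids))
    shift = np.zeros(len(gene_ids))
    shift[: len(enriched_ids)] = math.log2(fold)
    ct_pos = ct_neg - shift
    if noise_sd > 0:
        ct_pos = ct_pos + rng.normal(0.0, noise_sd, len(gene_ids))
        ct_neg = ct_neg + rng.normal(0.0, noise_sd, len(gene_ids))
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "ct_target_pos": ct_pos,
            "ct_target_neg": ct_neg,
            "ct_housekeeping_pos": housekeeping_ct,
            "ct_housekeeping_neg": housekeeping_ct,
            "detected_pos": True,
            "detected_neg": True,
        }
    )
    return df


# ---------------------------------------------------------------------------
# text-format round trips (simdata dialect)

def write_counts(cm: CountMatrix, counts_path, meta_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.sample_meta.to_csv(meta_path, sep="\t")


def read_counts(counts_path, meta_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, sample_meta=meta)


def write_tracks(tracks: list[CellTrack], path) -> None:
    rows = []
    for t in tracks:
        for time_h, g, m in zip(t.times, t.gfp, t.mcherry):
            rows.append(
                {
                    "cell_id": t.cell_id,
                    "organoid_id": t.organoid_id,
                    "time_h": time_h,
                    "gfp": int(g),
                    "mcherry": int(m),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks(path) -> list[CellTrack]:
    df = pd.read_csv(path)
    tracks = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("time_h")
        tracks.append(
            CellTrack(
                cell_id=str(cell_id),
                organoid_id=str(sub["organoid_id"].iloc[0]),
                times=sub["time_h"].to_numpy(float),
                gfp=sub["gfp"].to_numpy(bool),
                mcherry=sub["mcherry"].to_numpy(bool),
            )
        )
    return tracks
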