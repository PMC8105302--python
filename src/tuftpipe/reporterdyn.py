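"""Dual-reporter time-lapse dynamics and crypt/villus co-localization.

Classifies per-cell reporter tracks into the four observed categories
(GFP-only, GFP-then-mCherry transition, double-positive throughout,
mCherry-only), estimates the GFP-to-mCherry onset lag for transitioning
cells, and summarizes double-positive fractions per intestinal compartment.

Reporter states are booleans: intensity thresholding / segmentation is
upstream of this module. An onset is the first frame at which a reporter is
on and stays on for a configurable number of consecutive frames (guards
single-frame flicker). Cells already GFP-positive at the first frame are
left-censored: their onset, and hence their lag, is only partially observed,
and they are excluded from the lag mean by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("GFP_only", "transition", "both_throughout", "mCherry_only")


@dataclass
class CellTrack:
    """One cell's frame series of boolean reporter states."""

    cell_id: str
    organoid_id: str
    times: np.ndarray
    gfp: np.ndarray
    mcherry: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=bool)
        self.mcherry = np.asarray(self.mcherry, dtype=bool)
        if self.times.size < 2:
            raise ValueError(f"track {self.cell_id}: needs at least 2 frames")
        if not (np.diff(self.times) > 0).all():
            raise ValueError(f"track {self.cell_id}: times must strictly increase")
        if self.gfp.size != self.times.size or self.mcherry.size != self.times.size:
            raise ValueError(f"track {self.cell_id}: state/time length mismatch")


@dataclass
class TrackClassification:
    cell_id: str
    category: str | None
    t_gfp_first: float
    t_mcherry_first: float
    lag_h: float
    left_censored: bool

    def as_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "category": self.category,
            "t_gfp_first": self.t_gfp_first,
            "t_mcherry_first": self.t_mcherry_first,
            "lag_h": self.lag_h,
            "left_censored": self.left_censored,
        }


def _onset(states: np.ndarray, times: np.ndarray, persistence: int) -> float:
    """Time of the first frame where the reporter is on for ``persistence``
    consecutive frames; NaN when no such onset exists."""
    n = states.size
    for i in range(n):
        if i + persistence <= n and states[i : i + persistence].all():
            return float(times[i])
    return float("nan")


def classify_track(track: CellTrack, persistence_frames: int = 1) -> TrackClassification:
    """Assign a track to one of the four reporter categories.

    A cell seen GFP-on/mCherry-off at some frame that later becomes double
    positive is a ``transition`` (lag = mCherry onset - GFP onset); a cell
    double positive from its first fluorescent frame onward is
    ``both_throughout``. A track with no fluorescent frame gets category
    ``None`` with a warning.
    """
    if persistence_frames < 1:
        raise ValueError("persistence_frames must be >= 1")
    t_g = _onset(track.gfp, track.times, persistence_frames)
    t_m = _onset(track.mcherry, track.times, persistence_frames)
    left_censored = bool(track.gfp[0])
    lag = float("nan")
    if math.isnan(t_g) and math.isnan(t_m):
        warnings.warn(f"track {track.cell_id}: no fluorescent frame", stacklevel=2)
        category = None
    elif math.isnan(t_m):
        category = "GFP_only"
    elif math.isnan(t_g):
        category = "mCherry_only"
        left_censored = bool(track.mcherry[0])
    elif t_m > t_g:
        category = "transition"
        lag = t_m - t_g
    else:
        category = "both_throughout"
    return TrackClassification(
        cell_id=track.cell_id,
        category=category,
        t_gfp_first=t_g,
        t_mcherry_first=t_m,
        lag_h=lag,
        left_censored=left_censored,
    )


def classify_cohort(
    tracks: list[CellTrack], persistence_frames: int = 1
) -> pd.DataFrame:
    """Classify every track; one row per cell."""
    rows = [classify_track(t, persistence_frames).as_dict() for t in tracks]
    return pd.DataFrame(rows)


def category_counts(classes: pd.DataFrame) -> pd.Series:
    """Category tally over a cohort (fluorescent cells only)."""
    counted = classes[classes["category"].notna()]
    return counted["category"].value_counts().reindex(CATEGORIES, fill_value=0)


@dataclass
class LagSummary:
    mean_h: float
    sem_h: float
    n: int


def summarize_lags(
    classes: pd.DataFrame, include_censored: bool = False
) -> LagSummary:
    """Mean and SEM of the GFP-to-mCherry onset lag over transitioning cells.

    Left-censored transitioning cells (GFP already on at the first frame)
    are excluded unless ``include_censored``. SEM is sample SD / sqrt(n),
    reported missing at n = 1.
    """
    sub = classes[classes["category"] == "transition"]
    if not include_censored:
        sub = sub[~sub["left_censored"].astype(bool)]
    lags = sub["lag_h"].to_numpy(dtype=float)
    lags = lags[~np.isnan(lags)]
    if lags.size == 0:
        raise ValueError("no eligible transitioning cells for lag summary")
    mean = float(lags.mean())
    sem = float(lags.std(ddof=1) / math.sqrt(lags.size)) if lags.size > 1 else float("nan")
    return LagSummary(mean_h=mean, sem_h=sem, n=int(lags.size))


def colocalization_fractions(counts: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-animal and per-region double-positive fractions.

    For each animal and region computes the double-positive fraction of all
    detected reporter-positive cells and of the GFP-positive cells, then
    summarizes each region as mean +/- SEM across animals. Animal/region
    rows with a zero denominator are excluded with a warning.

    Returns ``{"per_animal": ..., "summary": ...}``.
    """
    rows = []
    for _, r in counts.iterrows():
        detected = r["n_double"] + r["n_gfp_only"] + r["n_mcherry_only"]
        gfp_pos = r["n_double"] + r["n_gfp_only"]
        if detected <= 0:
            warnings.warn(
                f"{r['animal_id']}/{r['region']}: no detected cells, excluded",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "animal_id": r["animal_id"],
                "region": r["region"],
                "fraction_double_of_detected": r["n_double"] / detected,
                "fraction_double_of_gfp": (
                    r["n_double"] / gfp_pos if gfp_pos > 0 else float("nan")
                ),
            }
        )
    per_animal = pd.DataFrame(rows)
    if per_animal.empty:
        raise ValueError("no animal/region rows with detected cells")

    summaries = []
    for region, sub in per_animal.groupby("region"):
        entry = {"region": region, "n_animals": len(sub)}
        for col in ("fraction_double_of_detected", "fraction_double_of_gfp"):
            vals = sub[col].dropna().to_numpy(dtype=float)
            entry[f"{col}_mean"] = float(vals.mean()) if vals.size else float("nan")
            entry[f"{col}_sem"] = (
                float(vals.std(ddof=1) / math.sqrt(vals.size))
                if vals.size > 1
                else float("nan")
            )
        summaries.append(entry)
    return {"per_animal": per_animal, "summary": pd.DataFrame(summaries)}


def write_classification(classes: pd.DataFrame, path) -> None:
    classes.to_csv(path, index=False)


def read_compartment_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {
        "animal_id", "region", "n_double", "n_gfp_only", "n_mcherry_only",
        "n_total_cells",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"compartment counts missing columns: {sorted(missing)}")
    num = df[["n_double", "n_gfp_only", "n_mcherry_only", "n_total_cells"]]
    if (num.to_numpy() < 0).any():
        raise ValueError("compartment counts must be nonnegative")
    detected = num["n_double"] + num["n_gfp_only"] + num["n_mcherry_only"]
    if (detected > num["n_total_cells"]).any():
        raise ValueError("detected cells exceed total cell count")
    return df
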