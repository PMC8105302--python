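"""Delta-delta-Ct relative quantification for qPCR receptor arrays.

Classic ddCt with amplification efficiency fixed at 2: for each gene,
``dCt = Ct_target - Ct_housekeeping`` within a population, relative
expression is ``2**(-dCt)``, and the sorted-vs-unsorted fold enrichment is
``2**(-(dCt_pos - dCt_neg))``. Undetected targets get relative expression 0
and are excluded from fold ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED = [
    "gene_id", "ct_target_pos", "ct_target_neg",
    "ct_housekeeping_pos", "ct_housekeeping_neg",
]


def ddct_relative_expression(ct: pd.DataFrame) -> pd.DataFrame:
    """Per-gene relative expression and fold enrichment by ddCt.

    Expects columns ``gene_id, ct_target_pos, ct_target_neg,
    ct_housekeeping_pos, ct_housekeeping_neg`` and optional boolean
    ``detected_pos`` / ``detected_neg`` flags (default: detected).
    """
    missing = [c for c in REQUIRED if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    for col in ("ct_housekeeping_pos", "ct_housekeeping_neg"):
        if ct[col].isna().any():
            raise ValueError(f"missing housekeeping Ct in column {col!r}")

    det_pos = ct.get("detected_pos", pd.Series(True, index=ct.index)).astype(bool)
    det_neg = ct.get("detected_neg", pd.Series(True, index=ct.index)).astype(bool)

    dct_pos = ct["ct_target_pos"] - ct["ct_housekeeping_pos"]
    dct_neg = ct["ct_target_neg"] - ct["ct_housekeeping_neg"]
    ddct = dct_pos - dct_neg

    rel_pos = np.where(det_pos, np.exp2(-dct_pos), 0.0)
    rel_neg = np.where(det_neg, np.exp2(-dct_neg), 0.0)
    both = (det_pos & det_neg).to_numpy()
    fold = np.where(both, np.exp2(-ddct), np.nan)

    return pd.DataFrame(
        {
            "gene_id": ct["gene_id"].to_numpy(),
            "dct_pos": dct_pos.to_numpy(dtype=float),
            "dct_neg": dct_neg.to_numpy(dtype=float),
            "ddct": np.where(both, ddct.to_numpy(dtype=float), np.nan),
            "rel_expr_pos": rel_pos,
            "rel_expr_neg": rel_neg,
            "fold_enrichment": fold,
            "detected": both,
        }
    )


def enrichment_scatter_table(
    rel: pd.DataFrame, label_top: int = 10, log_axes: bool = False
) -> pd.DataFrame:
    """Scatter table of positive vs negative population relative expression.

    One row per input gene; the ``annotate`` flag marks the ``label_top``
    genes by fold enrichment among detected genes. Ties at the cutoff fold
    are all flagged. ``log_axes`` adds log10 axis columns.
    """
    if rel.empty:
        raise ValueError("empty relative-expression table")
    out = rel[["gene_id", "rel_expr_neg", "rel_expr_pos", "fold_enrichment"]].copy()
    folds = out["fold_enrichment"].to_numpy(dtype=float)
    annotate = np.zeros(len(out), dtype=bool)
    ok = ~np.isnan(folds)
    if label_top > 0 and ok.any():
        ranked = np.sort(folds[ok])[::-1]
        cutoff = ranked[min(label_top, ranked.size) - 1]
        annotate = ok & (folds >= cutoff)  # ties at the cutoff all flagged
    out["annotate"] = annotate
    if log_axes:
        with np.errstate(divide="ignore"):
            out["log10_rel_expr_neg"] = np.log10(out["rel_expr_neg"])
            out["log10_rel_expr_pos"] = np.log10(out["rel_expr_pos"])
    return out
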