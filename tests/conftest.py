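import numpy as np
import pandas as pd
import pytest

from tuftpipe.pairwise_de import CountMatrix


@pytest.fixture
def tiny_cm() -> CountMatrix:
    """Hand-printed 4-gene, 6-sample paired matrix (2 mice x 3 populations)."""
    counts = pd.DataFrame(
        {
            "m1_background": [12, 40, 5, 210],
            "m1_young_tuft": [30, 35, 2, 190],
            "m1_mature_tuft": [95, 42, 1, 205],
            "m2_background": [18, 60, 8, 300],
            "m2_young_tuft": [41, 52, 4, 280],
            "m2_mature_tuft": [150, 66, 2, 310],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    meta = pd.DataFrame(
        {
            "mouse": ["mouse1"] * 3 + ["mouse2"] * 3,
            "population": ["background", "young_tuft", "mature_tuft"] * 2,
        },
        index=pd.Index(counts.columns, name="sample"),
    )
    return CountMatrix(counts=counts, sample_meta=meta)


@pytest.fixture
def toy_de() -> pd.DataFrame:
    """Six genes with stated (padj, log2fc) for hand-checkable selection."""
    return pd.DataFrame(
        {
            "gene_id": ["a", "b", "c", "d", "e", "f"],
            "base_mean": [10.0] * 6,
            "log2fc": [2.5, 1.0, -1.6, 0.4, -3.0, 1.2],
            "se": [0.2] * 6,
            "wald_stat": [5.0] * 6,
            "p": [0.001, 0.002, 0.004, 0.5, 0.0005, 0.03],
            "padj": [0.01, 0.01, 0.02, 0.6, 0.05, 0.049],
        }
    )


def make_cm(counts: np.ndarray, mice: list[str], pops: list[str]) -> CountMatrix:
    """Assemble a CountMatrix from a raw array and factor labels."""
    counts = np.asarray(counts)
    cols = [f"s{i}" for i in range(counts.shape[1])]
    df = pd.DataFrame(
        counts,
        index=pd.Index([f"g{i}" for i in range(counts.shape[0])], name="gene_id"),
        columns=cols,
    )
    meta = pd.DataFrame(
        {"mouse": mice, "population": pops}, index=pd.Index(cols, name="sample")
    )
    return CountMatrix(counts=df, sample_meta=meta)
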