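import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tuftpipe import pairwise_de, simdata
from tuftpipe.pairwise_de import (
    CountMatrix,
    bh_adjust,
    estimate_dispersion,
    fit_paired_nb_wald,
    log2p1_panel,
    select_de,
    size_factors,
    top_k_by_lfc,
)
from tuftpipe.simdata import SimConfig

from conftest import make_cm


class TestCountMatrix:
    def test_rejects_duplicates_negatives_and_mismatch(self):
        cm = make_cm([[1, 2], [3, 4]], ["m1", "m1"], ["a", "b"])
        bad = cm.counts.copy()
        bad.index = ["g0", "g0"]
        with pytest.raises(ValueError, match="duplicate"):
            CountMatrix(counts=bad, sample_meta=cm.sample_meta)
        with pytest.raises(ValueError, match="nonnegative"):
            make_cm([[1, -2]], ["m1", "m1"], ["a", "b"])
        with pytest.raises(ValueError, match="match"):
            CountMatrix(counts=cm.counts.iloc[:, ::-1], sample_meta=cm.sample_meta)


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        cm = make_cm([[5, 5], [9, 9], [2, 2]], ["m1", "m1"], ["a", "b"])
        assert np.allclose(size_factors(cm), [1.0, 1.0])

    def test_hand_median_of_ratios_doubling(self):
        # sample2 = 2x sample1: raw ratios (1, 2) -> geomean-rescaled (1/sqrt2, sqrt2)
        cm = make_cm([[10, 20], [30, 60], [7, 14]], ["m1", "m1"], ["a", "b"])
        s = size_factors(cm)
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_no_all_positive_gene_raises(self):
        cm = make_cm([[0, 5], [5, 0]], ["m1", "m1"], ["a", "b"])
        with pytest.raises(ValueError, match="strictly positive"):
            size_factors(cm)

    def test_scaling_equivariance(self):
        cfg = SimConfig(n_genes=300, seed=8, mouse_sd=0.0, library_sd=0.0)
        cm, _ = simdata.simulate_counts(cfg)
        s0 = size_factors(cm)
        scaled = cm.counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 4
        cm2 = CountMatrix(counts=scaled, sample_meta=cm.sample_meta)
        s1 = size_factors(cm2)
        ratio = (s1 / s0).iloc[0] / (s1 / s0).iloc[1:].mean()
        assert ratio == pytest.approx(4.0, rel=0.02)


class TestDispersion:
    def test_poisson_counts_give_tiny_moment_alpha(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(400.0, size=(300, 15))
        cm = make_cm(counts, [f"m{i//3}" for i in range(15)],
                     ["a", "b", "c"] * 5)
        sf = size_factors(cm)
        disp = estimate_dispersion(cm, sf, method="moment")
        assert np.median(disp["alpha"]) < 0.01

    def test_nb_moment_recovery(self):
        cfg = SimConfig(n_genes=2000, dispersion=0.2, mouse_sd=0.0,
                        library_sd=0.0, n_de_genes=0, seed=12,
                        base_mean_range=(100.0, 1000.0))
        cm, _ = simdata.simulate_counts(cfg)
        sf = size_factors(cm)
        disp = estimate_dispersion(cm, sf, method="moment")
        assert 0.1 <= np.median(disp["alpha"]) <= 0.3

    def test_all_zero_gene_flagged(self):
        counts = np.array([[0, 0, 0, 0, 0, 0], [10, 12, 9, 11, 10, 13]])
        cm = make_cm(counts, ["m1"] * 3 + ["m2"] * 3, ["a", "b", "c"] * 2)
        sf = size_factors(cm)
        disp = estimate_dispersion(cm, sf)
        assert bool(disp["flagged"].iloc[0])
        assert disp["alpha"].iloc[0] == pytest.approx(1e-8)


class TestWaldFit:
    def test_null_identity_contrast(self):
        # young and mature counts identical within each mouse -> lfc 0, p ~ 1
        rng = np.random.default_rng(3)
        base = rng.poisson(200.0, size=(20, 5))
        counts = np.empty((20, 15), dtype=int)
        mice, pops = [], []
        for m in range(5):
            counts[:, 3 * m] = rng.poisson(200.0, 20)
            counts[:, 3 * m + 1] = base[:, m]
            counts[:, 3 * m + 2] = base[:, m]
            mice += [f"mouse{m}"] * 3
            pops += ["background", "young_tuft", "mature_tuft"]
        cm = make_cm(counts, mice, pops)
        sf = size_factors(cm)
        disp = estimate_dispersion(cm, sf)
        de = fit_paired_nb_wald(cm, sf, disp, ("young_tuft", "mature_tuft"))
        assert np.allclose(de["log2fc"], 0.0, atol=1e-8)
        assert (de["p"] >= 0.99).all()

    def test_planted_lfc_recovered(self):
        cfg = SimConfig(n_genes=400, n_de_genes=40, de_lfc=2.0, seed=21)
        cm, truth = simdata.simulate_counts(cfg)
        sf = size_factors(cm)
        disp = estimate_dispersion(cm, sf)
        de = fit_paired_nb_wald(cm, sf, disp, ("young_tuft", "mature_tuft"))
        planted = de.set_index("gene_id").loc[truth.index[truth["planted"]]]
        assert planted["log2fc"].mean() == pytest.approx(2.0, abs=0.2)
        assert de["padj"].ge(de["p"] - 1e-15).all()

    def test_pairing_shrinks_standard_errors(self):
        cfg = SimConfig(n_genes=300, n_de_genes=0, mouse_sd=1.0, seed=30)
        cm, _ = simdata.simulate_counts(cfg)
        sf = size_factors(cm)
        disp = estimate_dispersion(cm, sf)
        paired = fit_paired_nb_wald(cm, sf, disp, ("young_tuft", "mature_tuft"))
        meta_unpaired = cm.sample_meta.copy()
        meta_unpaired["mouse"] = "pooled"
        cm_unpaired = CountMatrix(counts=cm.counts, sample_meta=meta_unpaired)
        disp_u = estimate_dispersion(cm_unpaired, sf)
        unpaired = fit_paired_nb_wald(
            cm_unpaired, sf, disp_u, ("young_tuft", "mature_tuft")
        )
        frac = (paired["se"].to_numpy() < unpaired["se"].to_numpy()).mean()
        assert frac >= 0.9

    def test_unknown_population_raises(self, tiny_cm):
        sf = size_factors(tiny_cm)
        disp = estimate_dispersion(tiny_cm, sf)
        with pytest.raises(ValueError, match="not present"):
            fit_paired_nb_wald(tiny_cm, sf, disp, ("young_tuft", "enterocyte"))


class TestBH:
    def test_single_p(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_example(self):
        padj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(padj, 0.04)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_monotone_in_p_rank(self, ps):
        p = np.array(ps)
        padj = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(padj[order]) >= -1e-12).all()
        assert (padj >= p - 1e-12).all() and (padj <= 1.0 + 1e-12).all()


class TestSelection:
    def test_strict_boundaries(self):
        de = pd.DataFrame(
            {
                "gene_id": ["x", "y"],
                "log2fc": [3.0, 1.0],
                "p": [0.001, 0.001],
                "padj": [0.05, 0.01],
            }
        )
        out = select_de(de)
        assert list(out["gene_id"]) == []  # padj=0.05 excluded, lfc=1.0 excluded

    def test_hand_filter_on_toy_table(self, toy_de):
        out = select_de(toy_de)
        # survivors need padj < 0.05 AND |lfc| > 1: a (0.01, 2.5), c (0.02, -1.6),
        # f (0.049, 1.2); b fails lfc, d fails both, e fails padj (= 0.05? no, 0.05>... e padj 0.05 not < 0.05)
        assert list(out["gene_id"]) == ["a", "c", "f"]

    def test_top_k_disjoint_directions(self, toy_de):
        up = top_k_by_lfc(toy_de, k=2, direction="up", p_max=0.01)
        down = top_k_by_lfc(toy_de, k=2, direction="down", p_max=0.01)
        assert set(up["gene_id"]).isdisjoint(down["gene_id"])
        assert list(up["gene_id"]) == ["a", "b"]
        assert list(down["gene_id"]) == ["e", "c"]

    def test_top_k_all_zero_lfc_empty(self):
        de = pd.DataFrame(
            {"gene_id": ["a", "b"], "log2fc": [0.0, 0.0], "p": [0.001, 0.002]}
        )
        with pytest.warns(UserWarning):
            up = top_k_by_lfc(de, k=5, direction="up")
        assert len(up) == 0

    def test_top_k_ordering_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        de = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(30)],
                "log2fc": rng.normal(0, 2, 30).round(1),
                "p": rng.uniform(0, 0.02, 30).round(4),
            }
        )
        got = top_k_by_lfc(de, k=8, direction="up", p_max=0.01)
        eligible = [
            r for r in de.itertuples() if r.p < 0.01 and r.log2fc > 0
        ]
        oracle = sorted(eligible, key=lambda r: (-abs(r.log2fc), r.p, r.gene_id))
        assert list(got["gene_id"]) == [r.gene_id for r in oracle[:8]]


class TestPanel:
    def test_values_and_order(self, tiny_cm):
        sf = pd.Series(1.0, index=tiny_cm.counts.columns)
        cm = tiny_cm
        cm.counts.loc["g3"] = [0, 7, 0, 7, 0, 7]
        panel = log2p1_panel(cm, sf, ["g3", "g1"])
        assert list(panel.index) == ["g3", "g1"]
        assert panel.loc["g3"].tolist() == [0.0, 3.0, 0.0, 3.0, 0.0, 3.0]

    def test_missing_marker_raises(self, tiny_cm):
        sf = pd.Series(1.0, index=tiny_cm.counts.columns)
        with pytest.raises(KeyError, match="nope"):
            log2p1_panel(tiny_cm, sf, ["g1", "nope"])
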