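import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tuftpipe import simdata
from tuftpipe.simdata import SimConfig, TrackSimConfig


class TestSimulateCounts:
    def test_paired_layout(self):
        cm, truth = simdata.simulate_counts(
            SimConfig(n_genes=50, n_de_genes=10, seed=3)
        )
        assert cm.counts.shape == (50, 15)
        # every sample pairs to exactly one mouse and one population
        assert cm.sample_meta.groupby("mouse").size().eq(3).all()
        assert cm.sample_meta.groupby("population").size().eq(5).all()
        vals = cm.counts.to_numpy()
        assert (vals >= 0).all() and np.issubdtype(vals.dtype, np.integer)
        assert len(truth) == 50

    def test_seeded_determinism(self):
        cfg = SimConfig(n_genes=100, seed=11)
        a, _ = simdata.simulate_counts(cfg)
        b, _ = simdata.simulate_counts(cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.sample_meta, b.sample_meta)

    def test_poisson_limit(self):
        cfg = SimConfig(
            n_genes=1000, de_lfc=0.0, n_de_genes=0, mouse_sd=0.0,
            library_sd=0.0, dispersion=1e-8, seed=5,
        )
        cm, _ = simdata.simulate_counts(cfg)
        vals = cm.counts.to_numpy(float)
        ratio = vals.var(axis=1, ddof=1) / vals.mean(axis=1)
        # per-gene variance ~ mean in the small-dispersion limit
        assert abs(np.mean(ratio) - 1.0) < 0.1

    def test_overdispersion_at_positive_alpha(self):
        cfg = SimConfig(
            n_genes=1500, de_lfc=0.0, n_de_genes=0, mouse_sd=0.0,
            library_sd=0.0, dispersion=0.2, seed=6,
        )
        cm, _ = simdata.simulate_counts(cfg)
        vals = cm.counts.to_numpy(float)
        excess = vals.var(axis=1, ddof=1) - vals.mean(axis=1)
        assert np.mean(excess) > 0

    def test_planted_truth_emitted(self):
        cfg = SimConfig(n_genes=40, n_de_genes=7, de_lfc=1.5, seed=0)
        _, truth = simdata.simulate_counts(cfg)
        assert truth["planted"].sum() == 7
        assert (truth.loc[truth["planted"], "true_log2fc"] == 1.5).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_mice": 1},
            {"n_genes": 0},
            {"dispersion": 0.0},
            {"populations": ("a", "b", "c")},
            {"library_size_mean": -1.0},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestSimulateGenesets:
    def test_sizes_within_bounds(self):
        universe = [f"g{i}" for i in range(1000)]
        coll, _ = simdata.simulate_genesets(
            universe, n_sets=30, size_range=(10, 500), seed=1
        )
        assert len(coll) == 30
        assert all(10 <= len(m) <= 500 for _, m in coll)

    def test_null_overlap_matches_hypergeometric(self):
        universe = [f"g{i}" for i in range(2000)]
        planted_pool = set(universe[:100])
        coll, _ = simdata.simulate_genesets(
            universe, n_sets=50, size_range=(50, 50), n_planted=0, seed=2
        )
        for _, members in coll:
            k = len(members & planted_pool)
            mean = 50 * 100 / 2000
            sd = np.sqrt(stats.hypergeom.var(2000, 100, 50))
            assert abs(k - mean) <= 3 * sd + 1e-9

    def test_planted_sets_drawn_from_de_pool(self):
        universe = [f"g{i}" for i in range(500)]
        de_genes = universe[:60]
        coll, planted = simdata.simulate_genesets(
            universe, n_sets=10, size_range=(10, 40), n_planted=3,
            de_genes=de_genes, seed=3,
        )
        assert len(planted) == 3
        for name in planted:
            assert coll.sets[name] <= set(de_genes)

    def test_size_range_exceeding_universe(self):
        with pytest.raises(ValueError):
            simdata.simulate_genesets([f"g{i}" for i in range(20)], 5, (10, 30))


class TestSimulateTracks:
    def test_frame_grid(self):
        tracks, _ = simdata.simulate_tracks(TrackSimConfig(n_cells=25, seed=0))
        for t in tracks:
            assert np.array_equal(t.times, np.arange(0.0, 61.0, 3.0))

    def test_zero_lag_coincident_onsets(self):
        cfg = TrackSimConfig(
            n_cells=40, lag_mean_h=0.0, lag_sd_h=0.0,
            fraction_transitioning=1.0, fraction_gfp_only=0.0,
            fraction_both_at_start=0.0, fraction_mcherry_only=0.0, seed=4,
        )
        tracks, _ = simdata.simulate_tracks(cfg)
        for t in tracks:
            assert np.array_equal(t.gfp, t.mcherry)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            TrackSimConfig(fraction_transitioning=0.9, fraction_gfp_only=0.9,
                           fraction_both_at_start=0.0, fraction_mcherry_only=0.0)

    def test_truth_categories_cover_cohort(self):
        tracks, truth = simdata.simulate_tracks(TrackSimConfig(n_cells=60, seed=9))
        assert len(tracks) == len(truth) == 60
        assert set(truth["category"]) <= {
            simdata.CAT_TRANSITION, simdata.CAT_GFP_ONLY,
            simdata.CAT_BOTH, simdata.CAT_MCHERRY_ONLY,
        }

    def test_round_trip_csv(self, tmp_path):
        tracks, _ = simdata.simulate_tracks(TrackSimConfig(n_cells=8, seed=2))
        path = tmp_path / "tracks.csv"
        simdata.write_tracks(tracks, path)
        back = simdata.read_tracks(path)
        assert len(back) == len(tracks)
        for a, b in zip(tracks, back):
            assert a.cell_id == b.cell_id
            assert np.array_equal(a.gfp, b.gfp)
            assert np.array_equal(a.mcherry, b.mcherry)


class TestCompartmentsAndCt:
    def test_villus_fraction_near_target(self):
        df = simdata.simulate_compartment_counts(
            n_animals=5, per_region_cells=400, seed=7
        )
        villus = df[df["region"] == "villus"]
        pooled = villus["n_double"].sum() / (
            villus[["n_double", "n_gfp_only", "n_mcherry_only"]].to_numpy().sum()
        )
        n = 5 * 400
        tol = 3 * np.sqrt(0.98 * 0.02 / n)
        assert abs(pooled - 0.98) <= tol

    def test_degenerate_probability_and_determinism(self):
        a = simdata.simulate_compartment_counts(p_double_crypt=0.0, seed=1)
        b = simdata.simulate_compartment_counts(p_double_crypt=0.0, seed=1)
        pd.testing.assert_frame_equal(a, b)
        assert (a.loc[a["region"] == "crypt", "n_double"] == 0).all()

    def test_ct_exact_folds(self):
        ct = simdata.simulate_ct(n_genes=10, enriched_ids=["Gpr64"], fold=8.0, seed=0)
        from tuftpipe.qpcr import ddct_relative_expression
        rel = ddct_relative_expression(ct)
        row = rel[rel["gene_id"] == "Gpr64"].iloc[0]
        assert row["ddct"] == pytest.approx(-3.0, abs=1e-12)
        assert row["fold_enrichment"] == pytest.approx(8.0, rel=1e-12)
        others = rel[rel["gene_id"] != "Gpr64"]
        assert np.allclose(others["fold_enrichment"], 1.0)
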