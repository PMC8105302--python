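# tuftpipe

Analysis pipeline for dual-reporter studies of intestinal tuft-cell
maturation. Tuft cells are rare chemosensory epithelial cells of the gut;
they are born in the crypts and mature as they migrate up the villus. In a
double-reporter mouse, a general tuft-cell promoter drives GFP (e.g. Trpm5)
and a maturation marker drives mCherry (e.g. Gpr64/Adgrg2), so young tuft
cells are GFP-only and mature ones are double positive. `tuftpipe` provides
the downstream statistics such a study needs, for transcriptomicists and
quantitative biologists working from count tables, geneset collections,
time-lapse track tables and qPCR Ct tables:

* **`pairwise_de`** — paired negative-binomial Wald differential expression
  for the three FACS-sorted populations (background, young tuft, mature
  tuft), with Benjamini–Hochberg control, strict DE selection, top-k
  fold-change lists and `log2(x+1)` marker-panel matrices.
* **`rankset`** — signed-score Mann–Whitney–Wilcoxon geneset enrichment
  with GMT I/O, Bonferroni control and volcano bubble coordinates.
* **`reporterdyn`** — classification of dual-reporter time-lapse tracks,
  GFP-to-mCherry onset-lag estimation with left-censoring handling, and
  crypt/villus co-localization fractions.
* **`qpcr`** — ΔΔCt relative quantification for receptor arrays.
* **`simdata`** — a seeded generator for every input above, with planted
  ground truth, so the full pipeline is testable without any external data.
* **`pipeline`** / `tuftpipe` CLI — seeded, manifest-logged orchestration.

## The statistics

**Differential expression.** Counts K_gj for gene g in sample j follow
NB(μ_gj, α_g) with Var = μ + αμ². The paired model is a log-link GLM

    log μ_gj = log s_j + β_g0 + mouse(j) + population(j)

with median-of-ratios size factors s_j (rescaled to geometric mean 1).
Dispersions α_g are estimated by Cox–Reid-adjusted profile likelihood,
moderated by empirical-Bayes shrinkage toward a mean–dispersion trend
α(μ) = a₀ + a₁/μ that is itself fitted by joint maximum likelihood. The
population contrast is tested by a Wald statistic β̂/SE(β̂) against a normal
reference; every expressed gene receives a p-value (no outlier cut-off, no
independent filtering). DE genes satisfy padj < 0.05 and |log2FC| > 1
(strict inequalities).

**Geneset enrichment.** Each gene gets a signed score
s_g = −log₁₀(p_g) · sign(log2FC_g) from the DE table. A geneset is tested by
a two-sided MWW rank test of member scores against all other scored genes
(mid-ranks, tie-corrected variance, continuity correction; exact enumeration
for tiny problems). Sets with fewer than 10 or more than 500 members in the
measured universe are skipped; significance uses the Bonferroni threshold
α/M over the M sets tested. Volcano coordinates per set:
x = Σ w_g·log2FC_g / Σ w_g with w_g = −log₁₀(p_g), and y = −log₁₀(p_enrich).

**Reporter dynamics.** A reporter's onset is the first frame at which it is
on (and stays on for a configurable persistence window). Cells seen
GFP-on/mCherry-off that later become double positive are "transitioning";
their lag is the difference of first-detection times, summarized as
mean ± SEM. Cells already fluorescent at the first frame are left-censored
and excluded from the lag mean by default.

**ΔΔCt.** ΔCt = Ct_target − Ct_housekeeping per population; relative
expression 2^(−ΔCt); fold enrichment 2^(−ΔΔCt) with amplification
efficiency fixed at 2.

## Worked example

```python
from tuftpipe import simdata, pairwise_de, rankset, reporterdyn

cfg = simdata.SimConfig(n_genes=2000, n_de_genes=100, de_lfc=2.0, seed=1)
cm, truth = simdata.simulate_counts(cfg)
sf = pairwise_de.size_factors(cm)
disp = pairwise_de.estimate_dispersion(cm, sf)
de = pairwise_de.fit_paired_nb_wald(cm, sf, disp, ("young_tuft", "mature_tuft"))
print(f"{len(pairwise_de.select_de(de))} genes significant "
      "at padj < 0.05 and |log2FC| > 1")

coll, planted = simdata.simulate_genesets(
    list(cm.counts.index), n_sets=100, size_range=(10, 50),
    n_planted=5, de_genes=list(truth.index[truth["planted"]]), seed=2)
res = rankset.enrich_collection(rankset.signed_scores(de), coll)
print(f"{res['bonferroni_significant'].sum()} of {len(res)} genesets "
      "Bonferroni-significant")

tracks, _ = simdata.simulate_tracks(simdata.TrackSimConfig(seed=1))
lag = reporterdyn.summarize_lags(reporterdyn.classify_cohort(tracks))
print(f"GFP-to-mCherry onset lag {lag.mean_h:.1f} h +/- {lag.sem_h:.1f} SEM "
      f"(n = {lag.n} transitioning cells)")
```

prints

```
98 genes significant at padj < 0.05 and |log2FC| > 1
5 of 100 genesets Bonferroni-significant
GFP-to-mCherry onset lag 11.3 h +/- 0.5 SEM (n = 57 transitioning cells)
```

The 98 selected genes are dominated by the 100 planted DE genes (recall
0.98 in this run), the five significant sets are exactly the five planted
enriched sets, and the lag estimate sits within half a frame interval of
the generator's 10.8 h target. A full run
(`tuftpipe run-all --config cfg.yaml`) additionally writes the DE tables,
enrichment volcano, marker panels, co-localization summaries, ΔΔCt tables
and a manifest with a checksum for every output.

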