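# Methods

## Paired negative-binomial differential expression

The count model is NB2: K_gj ~ NB(μ_gj, α_g), Var = μ + αμ², with a
log-link GLM per gene over an intercept, mouse indicators and population
indicators, plus a log size-factor offset. Fitting is IRLS vectorized
across genes (shared design matrix, per-gene weights), at most 100
iterations, stopping when the relative change in NB deviance falls below
1e-8; non-converged genes are flagged and their p-values withheld. A 1e-10
ridge on the weighted normal equations keeps near-degenerate genes
solvable, and linear predictors are clipped at ±30 to avoid overflow. The
population contrast is a linear combination of coefficients from a single
full-model fit; its Wald statistic is referred to a standard normal, and
natural-log coefficients are converted to log2 for reporting. All expressed
genes are tested — no outlier cut-off and no independent filtering — and
genes with zero counts in every sample are excluded from testing by
default (configurable).

**Size factors** are median-of-ratios over genes with strictly positive
counts in all samples, rescaled to geometric mean 1. If no such gene
exists the estimator fails loudly rather than guessing. A known property
worth keeping in mind: when a large fraction of genes changes in one
direction (≳10 % all up), the median ratio of the affected samples shifts
slightly and absorbs part of the fold change (measured ≈ −0.12 log2 units
at 10 % one-directional DE genes in the recovery simulations; negligible at
the ≤2 % DE fractions typical of genome-scale analyses).

**Dispersion** estimation follows the standard three-step empirical-Bayes
scheme for small-replicate RNA-seq:

1. *Gene-wise*: Cox–Reid-adjusted profile likelihood, evaluated on a log-α
   grid from 1e-6 to 10 with fitted means held fixed, maximized per gene.
2. *Trend*: α(μ) = a₀ + a₁/μ, fitted by maximizing the summed per-gene
   adjusted likelihoods over (a₀, a₁) (Nelder–Mead on log parameters).
   Fitting the trend by regression on gene-wise point estimates was
   rejected: those estimates are truncation- and skew-biased for weakly
   expressed genes, which inflated the fitted a₁ roughly threefold on
   constant-dispersion data and made low-count tests severely conservative.
   The joint-likelihood fit weights flat likelihoods correctly and has no
   truncation step.
3. *MAP*: a log-normal prior centred on the trend, prior variance
   estimated as MAD²(residual log dispersions) − trigamma((n − p)/2)
   (the expected sampling variance of a log dispersion estimate), floored
   at 1e-3; the posterior mode is located on a 121-point grid with
   quadratic interpolation.

With this scheme the pooled null type-I error at p < 0.05 over
50 × 2000-gene simulations is 0.0500; with a raw per-gene plug-in it was
0.074 (no inter-animal effects) to 0.006 (inter-animal effects leaking into
within-group moments). A transparent within-population method-of-moments
estimator (`method="moment"`) is retained for didactic use; it is not the
default precisely because of that miscalibration. Residual caveat: genes
with mean normalized counts below ~5 remain intrinsically conservative
(type-I ≈ 0.03–0.04 even at known dispersion) because the Wald normal
approximation degrades on near-discrete data.

**Multiple testing** is Benjamini–Hochberg (statsmodels implementation);
missing p-values stay missing and do not enter the adjustment. DE selection
uses strict inequalities (padj < 0.05 AND |log2FC| > 1), so boundary genes
are excluded. Top-k fold-change lists require p < 0.01, sort by |log2FC|
descending, and break ties by smaller p then lexicographic gene id (the
ordering must be total for reproducible panels). Marker panels report
log2(K/s + 1); requested markers absent from the matrix raise by default.

## Signed-score geneset enrichment

Gene scores are −log₁₀(p) · sign(log2FC), with raw DE p-values by default
(`use_adjusted` switches to BH-adjusted ones) and a 1e-300 floor on p
before the log to avoid overflow — extreme p-values do occur because no
independent filtering is applied upstream. Sets are intersected with the
scored universe *before* the 10–500 size filter, so the filter reflects
the testable sample space, and the Bonferroni denominator M counts only
sets actually tested in the run.

The test is a two-sided Mann–Whitney–Wilcoxon of member scores versus all
non-member scores: mid-ranks, tie-corrected variance, continuity correction
(on by default, switchable). When all scores are identical the rank
distribution carries no information and p = 1 is returned directly. For
small problems (≤10 members in a universe of ≤25, no ties) the exact
permutation distribution is used instead. Against full combinatorial
enumeration, exact-mode p-values agree to 1e-9; the normal approximation's
worst-case absolute error over the entire U distribution is 0.0086 at
10 members in a 20–25-gene universe, growing to 0.012 at 5 and 0.020 at 3
members — sizes the default filter never admits.

Volcano coordinates weight each member's log2FC by −log₁₀ of its own DE
p-value; if every member has p = 1 the x-coordinate is reported missing
rather than silently zero. Permutation-null calibration of the whole
path (500 sets × 20 rounds) rejects at 0.050 ± binomial noise.

## Reporter dynamics

Reporter states are booleans; intensity thresholding and segmentation are
upstream concerns. An onset is the first frame at which a reporter is on
for `persistence_frames` consecutive frames (default 1; raising it guards
against single-frame flicker at the cost of delaying detected onsets).
Categories: GFP-only, transitioning (GFP onset strictly before mCherry
onset), double-positive from first fluorescence, and mCherry-only; a track
with no fluorescent frame is classified missing with a warning. Cells
already GFP-positive at the first frame are left-censored: their true GFP
onset (and hence lag) is only bounded, so they are excluded from the lag
mean unless `include_censored` is set. Lags are summarized as mean ± SEM
(sample SD/√n; SEM missing at n = 1). On a regular frame grid every lag is
a nonnegative integer multiple of the frame interval; because both onsets
carry the same expected discretization delay, the delays largely cancel in
the lag and the estimated mean sits well within one frame interval of the
generative truth at cohort sizes of a few hundred cells.

Co-localization fractions are computed per animal and region —
double-positive over all detected reporter-positive cells, and over
GFP-positive cells — then summarized as mean ± SEM across animals.
Animal/region rows with no detected cells are excluded with a warning.
Inferential comparison of the fractions (the two-way ANOVA of the original
study design) is out of scope; this module is descriptive.

## ΔΔCt quantification

Classic ΔΔCt with amplification efficiency fixed at 2 (no
efficiency-corrected models, no multi-reference normalization). Undetected
targets get relative expression 0 and are excluded from fold ranking. The
scatter table flags the top-k genes by fold enrichment; ties at the cutoff
are all flagged, so the annotated set is deterministic.

## The synthetic-data generator

The generator emulates the study conditions end to end and returns planted
ground truth with every artifact:

* **Counts**: 5 mice × 3 populations (defaults). Gene base means are
  log-uniform over 2–2000 before scaling to the configured expected library
  size (5e5), giving a realistic low-count tail; per-sample depths are
  log-normal (σ = 0.25) to exercise size-factor estimation; NB dispersion
  defaults to α = 0.05, typical of sorted-cell bulk RNA-seq. Mouse effects
  are *gene-specific* log-normal (σ = 0.3): a mouse effect shared by all
  genes would be a pure depth shift that normalization removes, whereas
  gene-level inter-animal variability is exactly what the paired design
  exists to absorb. The first `n_de_genes` genes carry the planted log2FC
  in mature vs young tuft cells.
* **Genesets**: uniform draws from the gene universe, sizes in the
  configured range; planted sets draw members from the planted-DE pool so
  enrichment recovery is measurable.
* **Tracks**: 119 cells split 58/33/25/3 (transitioning / GFP-only /
  double-positive-throughout / mCherry-only) across categories, 3 h frames
  over 60 h. Transitioning cells get a uniform GFP onset and an mCherry
  onset after a lag drawn from a normal truncated at zero (mean 10.8 h,
  SD 4 h). The SD was set so the truncated distribution's mean stays at
  ≈10.8 h, the quantity the cohort is meant to reproduce; the much larger
  spread implied by the observed cohort's SEM would drag the truncated
  mean to ≈15 h and conflate location with dispersion. Continuous onsets
  are discretized to the frame grid ("first frame at or after onset"),
  matching detection-at-sampling semantics.
* **Compartments**: per animal and region, ≥300 scored reporter-positive
  cells, each double-positive with the region's probability (defaults
  0.98 villus, 0.46 crypt), remainder GFP-only.
* **Ct tables**: 379 receptors, constant housekeeping Ct, enriched genes
  shifted by log2(fold) cycles (default fold 1000), optional Gaussian Ct
  noise.

What the generator does **not** emulate: gene–gene correlation, GC/length
bias, mapping artifacts, FACS contamination between populations, intensity
noise or tracking errors in time-lapse data (reporter states are clean
booleans), cells leaving the field of view, or qPCR efficiency variation.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated model, not robustness to those real-data pathologies.

## Pipeline

Stages run in a fixed order (simulate → DE → enrichment → panels →
time-lapse → qPCR); a dynamic DAG engine was deliberately avoided for
auditability. Missing inputs for requested stages fail before anything
runs. The manifest records the package version, seed, a config hash, per-
table row counts and a SHA-256 checksum of every output file; table outputs
are byte-identical across reruns with the same config. Per-stage seeds are
derived from the run seed by fixed offsets.

## Problem sizes used in the test suite

Simulation-based checks use 2000-gene null replicates (×50, pooled) for
Wald calibration, 1000-gene replicates (×200, 2 % planted DE) for effect
recovery, 5000-gene replicates (×100) with a 50-gene planted set for
enrichment power, 500 sets × 20 permutation rounds for enrichment null
calibration, and 500-cell cohorts for lag accuracy. These sizes give the
binomial bands quoted above while keeping the default suite runtime under
ten minutes on a single CPU.
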