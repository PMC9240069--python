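# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that make results reproducible.

## Differential statistics

Metabolite and lipid intensities are treated as log-normal: all testing and
fold-change computation happens on the log2 scale, and raw matrices are
log2-transformed on entry to `differential_table`.  Two-group designs use
Welch's unequal-variance *t*-test with Satterthwaite degrees of freedom;
multi-level designs (e.g. a 0/48/72 h induction time course) use one-way
ANOVA for the p-value while the log2 fold change always comes from the named
contrast (comparison level minus reference level).  This keeps a single
p-value per feature per design while still reporting a directional effect
for the figure-level comparison of interest.

Missing values are handled by available-case analysis with a minimum of two
observations per compared group; features below the minimum keep their row
but carry missing statistics and are excluded from the Benjamini–Hochberg
adjustment (statsmodels' step-up implementation; verified against the
literal step-up definition in the test suite).  No imputation is performed.

Significance for the subpathway stages is the raw p ≤ 0.05 call, not FDR;
FDR enters only where a rule explicitly uses it (asterisks at adjusted
p < 0.25, lipid selection at FDR < 0.25).

Lipidomics normalization is log2 first, then per-feature median centering
and IQR scaling across samples.  Applying a median/IQR operation before the
log transform cannot yield centered values on the log scale, so the order
here is fixed as log2 → center/scale; zero-IQR features are centered only
and flagged.

## Subpathway scoring and enrichment

The DA score is `(n_up − n_down)/n_measured × 100` per subpathway.  Two
inclusion rules exist because the field uses both: the default requires at
least three *significantly altered* members in at least one comparison; the
alternative (behind `min_altered_rule="measured"`) requires only three
measured members.  Exclusion reasons are reported rather than rows dropped
silently.

ORA is the upper-tail hypergeometric test with universe = features carrying
a computed p-value; set members outside the universe are dropped (and
logged) before sizing.  BH runs across sets.  The asterisk ranking sorts by
star count, then mean |DA| across comparisons, then name — every tie-break
deterministic so two runs produce identical tables.

The GSEA variant permutes *metabolite sets*, not phenotypes: the null for a
set of size n is the ES distribution of random same-size subsets of the
ranked universe.  This matches the small-cohort setting the method targets
(phenotype permutation is degenerate at n = 4 per arm) but means the null
ignores inter-metabolite correlation; p-values are calibrated against
random sets, not against biology-preserving resampling, and the test suite
verifies exactly that calibration.  The running sum increments hits by
|metric|^w / Σ|metric in set|^w (w = 1 by default; w = 0 gives the classic
unweighted statistic) and decrements misses by 1/(N − n); the ES is the
extreme deviation, with magnitude ties (within 1e-12, to absorb summation
round-off) resolved to the extreme attained first along the list.  The
empirical p divides the add-one same-sign exceedance count by (number of
same-sign null scores + 1); dividing by the total permutation count instead
would bound p near 0.5 under the null and destroy uniformity, so the
same-sign denominator is used.  NES is ES over the mean |same-sign null
ES|; FDR is BH across sets — simpler than the original GSEA's pooled-null
FDR but exactly reproducible.

The signal-to-noise metric floors each group σ at max(0.2·|μ|, 1e-8),
the convention that keeps low-variance features from dominating the
ranking.

## Lipid analytics

Names parse as `CLASS(C:D/...)`; whether a single token is one explicit
chain or a sum composition is decided by class arity (TG = 3, DG/PC/… = 2,
lyso/CE = 1).  Ether/oxidized modifiers are rejected rather than guessed.
Chain composition counts every chain occurrence once (a per-species presence
mode is available) and excludes sum-notation species with a reported count —
the denominator choice is stated because published ">30% of chains"
statements rarely define it.  Selection thresholds (FDR < 0.25,
|log2FC| > x) are strict inequalities, matching how such rules are printed.

Tracer quantities are deliberately simple closed forms: uptake =
(labeled FA added − labeled FA remaining in medium)/mg protein, desaturase
activity = labeled monounsaturated / labeled saturated FA, and de novo
synthesis is reduced to a labeled fraction of the 16:0 pool.  Isotopomer
spectral analysis and natural-abundance correction are out of scope.
Calibration back-calculation inverts a least-squares linear response fit and
flags ratios outside the calibrated range as extrapolation.

## Signature activity and survival

Z-scores use the sample SD (n − 1); zero-variance genes become all-zero and
are flagged.  The activity score weights every signature gene equally
(sum of up-gene Z-scores minus down-gene Z-scores) — no effect-size
weighting, since the score is defined by its additive form.  Tertiles cut at
the empirical 1/3 and 2/3 quantiles with boundary ties assigned to the lower
stratum; the degenerate all-equal case is flagged rather than split
arbitrarily.

The two-group log-rank statistic is computed in-package from the
observed − expected decomposition over distinct event times with
hypergeometric variance, because the sign of O − E is needed to classify
whether the high- or low-expression tertile fares worse (red/blue/gray at
α = 0.05).  The implementation is cross-checked against lifelines'
`logrank_test` (including tied event times) and against a hand-tabulated
oracle on every small table; Kaplan–Meier curves come from lifelines'
product-limit fitter and can be skipped (`fit_curves=False`) in bulk
rankings.

Dependency scores aggregate per disease by mean (default) or median — both
are reported, with a flag when the two orderings disagree — and sort
ascending so the most dependent disease ranks first.

## Assay quantities

Inhibition = 100 − viability%, clipped to [0, 100] with a flag.  Bliss
scoring averages replicate viabilities per cell before scoring (per-replicate
scoring then averaging is available and agrees on complete grids); the
synergy/antagonism calls use strict >10 / <−10 with a 1e-9 epsilon so a
score exactly on the boundary is not tipped by floating-point round-off.
CTCF and 2^−ΔΔCt fold enrichment are direct formula implementations; the
ΔΔCt reference is a named negative-control region, which therefore scores
exactly 1.

## Synthetic generators

All generators draw from one `numpy.random.Generator` seeded per call — no
global state, identical seeds give identical output.

- **Metabolomics/lipidomics**: Gaussian log2 intensities around per-feature
  baselines (uniform on 10–20 log2 units) with σ = 1 log2 unit by default —
  a typical spread for platform data after normalization; planted
  subpathways/classes shift group 2 additively by the configured log2
  effect.  Missingness (default 0) left-censors below each feature's
  configured quantile, mimicking detection limits.  Default design: 10
  samples per group, 20 subpathways × 5 metabolites.  Not emulated:
  inter-metabolite correlation, heteroscedasticity across the intensity
  range, batch effects — so passing recovery tests demonstrate the
  statistics, not robustness to those artifacts.
- **Expression cohorts**: a latent activity N(0,1) drives up-genes with
  slope +effect and down-genes with −effect over unit noise; survival is
  exponential with hazard 0.1·exp(0.5·latent) by default and independent
  exponential censoring; the amplification label marks the top latent
  tertile with 5% label error.  Real cohorts have correlated genes and
  non-proportional hazards; none of that is modeled.
- **Dose grids**: Hill single-agent inhibition with EC50 defaulting to the
  largest dose (keeping single-agent inhibition ≤ 50%, so a planted Bliss
  excess of +15 points never clips at 100% inhibition); combination cells
  are the Bliss expectation ± the planted excess plus Gaussian viability
  noise; the untreated cell is exactly 100 by normalization.

## Problem sizes in the test suite

Recovery tests run at the defaults above (effect 2 log2 units, n = 10 per
group, 100 seeds for top-rank recovery; n = 500 patients for signature
recovery; 1000 simulations for null-uniformity checks; 999–10,000
permutations for GSEA).  These sizes make the Monte-Carlo assertions stable
across seeds while keeping the default suite run in a few minutes.

## Known limitations

- The set-permutation GSEA null ignores metabolite–metabolite correlation
  (see above).
- No moderated variance models; with n = 4 per arm the plain tests are
  noisy, which is faithful to the method being implemented rather than a
  recommendation.
- The lipid parser covers the slash-separated dialect with lyso./plasmenyl.
  prefixes only.
- Cohort-level reproduction of published numbers requires the external
  tables listed in the README; the package ships no downloader.
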