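# Methods

This note records the statistical model, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Model and procedure

Methylation is measured per probe as a beta value β ∈ [0, 1] and analysed
on the M scale, M = log₂(β / (1 − β)), where array measurement error is
closer to homoscedastic. Betas are clamped to [ε, 1 − ε] with ε = 10⁻³
before the logit so that values of exactly 0/1 stay finite; the inverse
transform 2ᴹ/(1 + 2ᴹ) is exact on the clamped range.

Per probe the model is an ordinary least-squares fit

    M_ij = α_i + δ_i·case_j + γ₁_i·sex_j + γ₂_i·(age_j − āge) + γ₃_i·(pmi_j − p̄mi) + ε_ij

and ΔM_i = δ̂_i is the covariate-adjusted case–control difference. A
covariate with any missing value, or a constant one, is dropped from the
design with a warning; a rank-deficient design (e.g. group perfectly
confounded with sex) is an error naming the dependent columns, because the
group effect is then not identifiable.

ΔM is smoothed with running medians within probe clusters (maximal runs of
same-chromosome probes with adjacent gaps ≤ maxgap). The window is k = 5
probes, truncated at cluster edges (index i uses the window
[i−2, i+2] ∩ cluster); clusters smaller than k are left unsmoothed. Medians
rather than means keep single outlier probes from manufacturing regions.

### Bootstrap empirical null

The null model omits the group column. Its fitted values F and residuals R
are formed per probe; each bootstrap draws n sample indices with
replacement and rebuilds M* = F + R[:, idx], then re-fits the full design
and smooths. Two numerical points:

* **Residual rescaling.** Raw OLS residuals under-estimate the error scale
  by a factor (n − p₀)/n in variance; residuals are multiplied by
  √(n/(n − p₀)) so the resampled data match the error scale. Without this
  the null is too narrow and region-level error rates run hot at small n.
* **Linear-estimator identity.** The group coefficient is linear in the
  response, so the bootstrap statistic equals f₀ + R·w_agg where w is the
  group row of the design pseudoinverse and w_agg aggregates w over the
  resampled indices. This is algebraically identical to re-fitting
  (verified against explicit re-fits in the tests) and turns the bootstrap
  into one matrix product per batch.

The region-calling cutoff is the empirical quantile (numpy's
linear-interpolation definition) of the pooled |smoothed| null statistics
across all bootstraps, at q = 0.95 by default (0.975 in sensitivity mode).
Pooling probe-level statistics — rather than null region areas — is what
ties the cutoff to the distribution of smoothed differences themselves.

### Regions and their uncertainty

Candidate regions are maximal within-cluster runs of probes with smoothed
ΔM strictly beyond ±cutoff (ties at the cutoff are excluded). The region
statistic is the area A = Σ|smoothed ΔM|, so long moderate regions and
short strong ones compete on one scale. With null regions re-scanned from
each bootstrap's smoothed profile at the same cutoff:

* P = (# null regions with area ≥ A) / (total # null regions), 0 when the
  null pool is empty. Using the pooled proportion rather than a
  per-bootstrap count lets P resolve below 1/B.
* FWER = (# bootstraps whose maximum null area ≥ A) / B, the resampling
  analogue of family-wise control over the whole scan.
* FDR = Benjamini–Hochberg over the candidate P-values. Both P and FDR are
  reported since either may be used as the per-cohort significance measure.

`min_probes_per_region` defaults to 1; single-probe candidates are kept and
left to the area ranking.

### Consensus

Significant regions (P < 0.05, strict) are intersected across cohorts,
stratified by direction. A consensus requires one region per cohort with a
common intersection of width ≥ 2 bp (1-based inclusive widths). When a
cohort offers several overlapping regions at a locus, all combinations are
evaluated and the largest-total-area valid combination is used, with a
warning — a locus therefore has a consensus if and only if an exhaustive
search over one-region-per-cohort combinations finds one (this equivalence
is tested against a triple-loop oracle). Cohort labels are processed in
sorted order, so file or argument order never changes the result.

Nearest-gene annotation uses the unstranded gap in bp between 1-based
inclusive intervals (0 when overlapping, 1 when adjacent); ties go to the
smaller gene start, then name. Strand is carried for upstream/downstream
phrasing only.

## Synthetic studies

The generator's defaults are the study conditions the package is exercised
under: three cohorts of 24/24, 20/23 and 18/15 cases/controls; 250 probe
clusters of 5–11 probes (≈2000 probes) with within-cluster gaps uniform on
20–400 bp and 5 kb between clusters (so cluster recovery is exact at maxgap
500 and clusters do not merge at 1000); baseline M drawn from a
−3 / 0 / +3 mixture with weights 0.45 / 0.10 / 0.45 (the bimodal marginal
beta distribution of real arrays); probe noise sd 0.5 M-units; 5 shared
hypermethylated and 2 shared hypomethylated DMRs of 4–10 probes planted at
|ΔM| = 0.7, plus 2 cohort-private DMRs per cohort; sex shift 0.2, age slope
0.01/year, PMI slope 0.005/hour on the M scale; and 1–2% of probes planted
to fail each filter stage (never on planted DMR probes, so the ground truth
survives filtering). Effects are planted additively in M-space because the
inference operates there; betas are the inverse logit. Baselines are drawn
per cohort, emulating between-cohort heterogeneity from differing
normalisation pipelines; a global `cohort_shift` batch offset is available
but defaults to 0.

What the generator does **not** emulate: Infinium I/II chemistry
differences, spatially varying probe density and CpG-island structure,
heteroscedastic beta-scale noise, correlated residuals between neighbouring
probes, cell-composition gradients, and realistic covariate distributions
per cohort. Passing tests therefore demonstrate correctness of the
algorithmic chain and calibration under the stated noise model — not
performance on real 450K data, where effect sizes are smaller, nulls are
heavier-tailed and filtering interacts with normalisation.

## Problem sizes and determinism

Tests and the acceptance script run the pipeline at the generator's default
scale (≈2000 probes, 100 bootstraps for recovery experiments; ≈500 probes,
200 bootstraps for null calibration, 50 replicates), sizes at which the
whole suite completes in well under a minute per experiment while leaving
the Monte-Carlo error of the measured rates small relative to the margins
tested. Every random draw descends from a single seed (numpy
`SeedSequence`), and the full pipeline is bit-for-bit reproducible under a
fixed seed.

## Known limitations

* Region end coordinates are the positions of the first and last probe in
  the run; no extension toward the midpoint of the flanking gaps.
* The bootstrap resamples samples unstratified by group; with very
  unbalanced cohorts a stratified scheme may be preferable.
* P = 0 is reportable when a region exceeds every null region; users
  needing strictly positive P should apply a +1 continuity correction
  downstream.
* The consensus multiplicity rule (largest total area) is a pragmatic
  choice; alternatives (longest intersection, best P) would differ only
  when a cohort tiles one locus with several significant regions.
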