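# Methods

## The measurement model

Droplet digital PCR partitions a restriction-digested DNA sample into
n ≈ 10⁴ droplets and end-point-reads each droplet as positive or negative
on two channels: a FAM-labelled assay for the copy-number-variable target
locus and a VIC-labelled reference assay (RNaseP), a locus carried at
exactly two copies per diploid genome. Template molecules distribute over
droplets approximately Poisson, so with positive fraction p̂ = k/n the mean
occupancy (copies per droplet) is

    λ̂ = −ln(1 − k/n),

the maximum-likelihood estimator under the Poisson partition model. Copies
per reaction is λ̂·n; for reaction sizing, one haploid human genome weighs
≈3.3 pg, so the ≈10,000 genome copies needed for an accurate reaction
correspond to 33 ng of input DNA.

Copy number per diploid genome is the reference-normalised ratio

    ĈN = 2·λ̂_target / λ̂_reference,

which cancels pipetting and input-mass variation (scale invariance:
multiplying both concentrations by a constant leaves ĈN unchanged). The
two channels are treated as independent given their rates; this matches
duplex end-point reading, where each channel is thresholded separately.

## Confidence intervals

*λ intervals.* In the bulk regime the delta method on the binomial
proportion gives Var(λ̂) = p̂ / (n(1−p̂)); the 95% interval is λ̂ ± 1.96·SE,
clipped below at 0. When fewer than 5 positive or 5 negative droplets are
observed the normal approximation is poor, so an exact binomial
(Clopper–Pearson) interval on p is transformed through −ln(1−p) instead.
The switch point (5) is the usual small-count rule; simulation at
λ ∈ {0.1, 0.5, 1.0} and n = 14,000 shows empirical coverage within 1.5
points of nominal (the acceptance script recomputes this).

*CN intervals.* The interval for ĈN is propagated by the delta method on
log(λ̂_t/λ̂_r): log-scale variances of the two channels are summed, the
interval back-transformed and doubled. On the Clopper–Pearson branch the
log-scale SE is recovered from the interval's log half-width. A target
concentration of exactly zero is reported as ĈN = 0 with a one-sided
interval from the target's upper bound (the reference uncertainty is
negligible against a zero numerator).

*Saturated wells* (k = n) have no finite estimate and are reported as a
distinct status, never as a number. A saturated or dead reference channel
makes the ratio meaningless and is reported as `failed_amplification`.

## Integer calling and the repeat protocol

A sample's genotype is assigned by CI containment: the 95% interval of the
measured CN must contain **exactly one** integer in the call universe
{1, 2, 3}. No integer inside → `no_integer` (consistent with mosaicism or
template degradation); two or more → `ambiguous` (only possible when the
interval is wider than 1 CN unit). The direction of the rule — interval of
the *measured* quantity containing the candidate integer, not the estimate
falling inside an interval centred on the integer — is chosen because only
the measured quantity has a defined sampling distribution. Copy numbers
above 3 fall outside the default universe and yield `no_integer`; the
universe is configurable (`max_cn`).

Repeats: wells sharing a replicate index are pooled at the droplet level
(Σk, Σn) before estimation — the merged-well MLE, whose interval narrows as
1/√m in the number of pooled wells. Each replicate index is one
measurement *attempt*. Attempts collapse per sample as follows: if at
least one attempt called an integer and all called attempts agree, the
sample resolves to that integer; discordant called attempts, or ≥2
attempts none of which called, mean the sample never resolved and is
`excluded`; a single non-called attempt is returned as-is, awaiting a
repeat. Exclusion percentages are reported against the full attempted
cohort, rounded to one decimal.

Because a 95% interval misses the true integer in ≈5% of single wells *by
construction*, per-sample accuracy is a property of the repeat protocol,
not of a lone well: with two independent attempts the probability that
neither resolves is ≈0.05² and a miscall requires the interval to contain
only a wrong integer (an error of a full copy unit, vanishingly rare above
10⁴ droplets). The recovery benchmark in the acceptance script therefore
simulates two attempts per sample — 500 samples per condition over
CN ∈ {1,2,3} × λ_ref ∈ {0.3, 0.55, 0.8} at 10,000 droplets — and observes
≥99% of samples resolving to the true integer.

## Extreme-phenotype design

Subjects on antihypertensive treatment have +10 mmHg added to SBP and
+5 mmHg to DBP before any selection, approximating their untreated
phenotype; the adjustment is tracked and cannot be applied twice. Extreme
groups are the empirical SBP deciles of the adjusted cohort: the lowest
⌊n·0.1⌋ and highest ⌊n·0.1⌋ subjects, ranked by (SBP, subject_id) so that
ties break deterministically and the groups are always disjoint (for
untied data this coincides with membership by the type-7 empirical
quantile thresholds, which `decile_thresholds` exposes).

The design's power is summarised by the standardized separation
D = (mean_high − mean_low)/SD_population and an effective sample size

    n_eff = (D²/4)·(n_high + n_low),

anchored so that two groups centred ±1 SD around the population mean
(D = 2) carry the information of a random sample of the same total size
(equal non-centrality of the two-group comparison). Other conventions
circulate in the power literature and can give substantially larger
equivalents; the formula is therefore explicit, configurable via a
callback, and reported as this package's convention rather than matched to
any external headline number. For the default design (D ≈ 4.71, N = 188)
it evaluates to ≈1041.

## Association testing

Genotypes enter as a carrier indicator (CN < 2 for deletion loci, CN > 2
for gain loci), mirroring how carrier status — not CN as a continuous
covariate — is analysed for rare CNVs. The group comparison is a logistic
regression of extreme-group membership (high = 1) on carrier status
adjusted for age, BMI and sex (male = 1), fit by Newton/IRLS with Wald
intervals exponentiated to the odds-ratio scale. With a single binary
predictor the MLE reproduces the analytic 2×2 cross-product odds ratio to
numerical precision (verified to 1e−6 in the tests). Complete or
quasi-complete separation — all carriers in one group — is detected (fit
exceptions, or |β̂| > 15 / SE > 50 after a formally converged fit) and
reported as status `separation` with no numeric estimate.

Within-group BP differences by genotype use the independent-sample
two-tailed Wilcoxon rank-sum test, unadjusted (the within-group carrier
counts are too small to support covariate adjustment). Midranks handle
ties. For pooled sizes n+m ≤ 12 the two-sided p is exact, by enumeration
of all C(n+m, n) group labelings of the midranks, rejecting on
|W − E[W]| ≥ observed; C(12,6) = 924 labelings make this instantaneous.
Larger samples use the normal approximation with tie-corrected variance
and continuity correction. Loci with a single observed copy-number class
are flagged monomorphic and skipped. No multiple-testing adjustment is
applied; the report carries the number of tests run so users can adjust
externally.

Comparison against reference-catalogue (DGV-style) loss/gain frequencies
is descriptive only — a side-by-side table with absolute differences — as
catalogue frequencies come from incompatible platforms and small panels.

## Genomic coordinates

Region coordinates are hg19, 1-based with both endpoints inclusive (UCSC
browser display style), so length = end − start + 1. The convention is
pinned by reproducing the two published segment lengths exactly from the
published coordinates (553,635 bp and 224,588 bp); the ≈3.5 Mb description
of the large chr1 segment is the rounding of the computed 3,584,238 bp.
BED export converts to 0-based half-open.

## What the simulator emulates — and what it does not

`synthetic_data` draws per-droplet Poisson occupancies per channel
(equivalent in distribution to a binomial draw of positives, and exactly
the model the estimator inverts), with optional per-droplet false-positive
/ false-negative rates as a stress knob (default 0: no rain model is
assumed). Defaults emulate wells of ~13,700 ± 1,300 droplets at
λ_ref = 0.5 — i.e. 5,000–8,000 template copies per reaction — with about
half the samples measured twice. Cohorts are drawn per group from normal
phenotype distributions truncated to the physiological region
(SBP > DBP > 0, age ≥ 0, BMI > 0); the truncation binds measurably only
for age in the younger group (≈1% of mass below zero, shifting its mean by
≈ +0.5 y), and the parameter-recovery tests assert the truncated-normal
moments accordingly. Sex, treatment (high group only) and carrier genotype
are Bernoulli.

Not modelled, hence not demonstrated by passing tests: fluorescence
amplitudes and rain thresholds, droplet-volume variability, partition-size
heterogeneity, assay-specific amplification bias, sample degradation or
mosaicism (non-integer CN is *generated* only via noise, never as a true
intermediate state), population structure, and relatedness. Passing the
recovery benchmark shows the estimator chain is correct under the Poisson
partition model at realistic droplet counts — not that real chemistry is
free of the effects above.

## Numerical choices and degenerate inputs

- Problem sizes: CI coverage uses 2,000 wells × 3 concentrations;
  recovery 500 samples × 9 conditions × 2 attempts; Wilcoxon null
  calibration 1,000 simulations; cohort recovery 20 replicate cohorts.
  These sizes put Monte-Carlo error well inside each asserted tolerance.
- Well seeds derive from SHA-256 of (master seed, sample, replicate) —
  stable across processes and platforms, unlike Python's salted `hash`.
- k = 0 gives λ̂ = 0 with CI lower bound exactly 0; k = n raises
  `SaturatedWellError`; malformed counts (k > n, n ≤ 0) raise
  `MalformedCountsError`.
- Rank-sum p-values are clipped to [0, 1]; an all-tied pooled sample
  returns p = 1 (zero rank variance carries no evidence).
- Percentages are rounded to one decimal at the reporting boundary only;
  all internal arithmetic is full precision. Droplet-count dispersion is
  summarised as SEM (not SD) in run reports.
- The pipeline repeats an unresolved single-attempt sample once (a fresh
  simulated well under a reserved replicate seed), mirroring bench
  practice of re-running failed samples before excluding them.

## Known limitations

- The CN interval is a delta-method approximation; at very low reference
  concentrations (λ_r < 0.05 with few positives) its coverage degrades
  and calling becomes conservative (more `no_integer`).
- The effective-sample-size convention is one of several; absolute values
  should not be compared across conventions.
- `replicate concordance` counts a non-called attempt as discordant, so
  under honest 95% intervals concordance plateaus near 0.85–0.90 for
  twice-measured samples even when every resolved call is correct.
- Logistic separation detection uses thresholds (|β̂| > 15, SE > 50) that
  flag quasi-separation conservatively; penalised (Firth) regression is
  out of scope.
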