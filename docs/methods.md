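# Methods

## Problem and model

`audsim` asks a treatment-coverage what-if question: in a fixed cohort of
2051 inpatients admitted for alcohol withdrawal (ICD-10 F10.x main
diagnosis), what would happen to four outcomes — number of hospitalisations
and days spent in hospital over 5 years, and abstinence and death within 28
months — if more patients received extended, "qualified" withdrawal
treatment (QWT, a ≥3-week programme combining detoxification with
psychosocial care) instead of short somatic detoxification (SWT)?

The model is deliberately simple. Each arm's outcome distribution is taken
from published per-arm summary statistics and the cohort is resampled under
alternative allocations:

- **Count outcomes** (hospitalisations, hospital days) are negative binomial
  per patient, NB(μ, k) with variance μ + μ²/k. Source studies publish mean
  and SD, so the size parameter is recovered by the method of moments,
  k = μ² / (σ² − μ). This requires overdispersion (σ² > μ); an arm violating
  it is rejected outright, because a Poisson fallback would silently
  understate sampling variance.
- **Binary outcomes** (abstinent, dead) are Bernoulli per patient with
  p = events/denominator as published.

A *scenario* is a split of the fixed cohort, (n_QWT, n_SWT) with
n_QWT + n_SWT = 2051. The baseline uses the observed head count (170 QWT);
hypothetical scenarios set the QWT share to 25% and 50%, rounding the QWT
count half-up (which reproduces the published splits 513/1538 and
1026/1025). For each scenario × outcome, 10,000 replicate cohort totals are
drawn; each is summarised by its mean and the empirical 2.5th/97.5th
percentiles (linear interpolation between order statistics).

## Aggregate sampling

The group total of n i.i.d. NB(μ, k) patients is exactly NB(nμ, nk) (sizes
add for independent negative binomials sharing a success probability), so
totals are drawn in one aggregate call per arm rather than per patient. The
choice is one of speed only: tests verify mean/variance agreement with a
brute-force per-patient summation oracle across all published arm settings.
Binary totals are Binomial(n, p) directly.

Outcomes are simulated independently of each other — no within-patient
coupling between hospitalisation counts and days, or between abstinence and
death (a replicate may have abstinent + dead exceeding the cohort). This
mirrors the outcome-by-outcome structure of the published model.

## Scenario comparison

Replicate *i* of a scenario is paired with replicate *i* of the baseline.
Absolute effects are the per-pair differences; relative effects are
100·(scenario − baseline)/baseline per pair. Both vectors are summarised by
mean and percentile CI. Pairs with a zero baseline value are excluded from
the relative summary and counted (with these parameters and cohort size the
count is always zero in practice). Summarising per-replicate ratios, rather
than taking the ratio of summary means, was a genuinely open choice; at
10,000 replicates and these effect sizes the two agree to well under one
percentage point, and the closed-form expectation ratio is checked against
the simulated value in tests. Binary outcomes are reported as proportions of
the full 2051-patient cohort.

## Parameter choices and data quirks

Defaults live in `src/audsim/data/default_config.yaml` and encode the
published parameter table bit-for-bit. Three quirks deserve note:

- **SWT mortality** is printed as "14.4% (13/92)", which is internally
  inconsistent (13/92 = 14.1%). The default uses 13/90, which matches both
  the printed percentage and the reported mortality reduction under the 50%
  scenario; 13/92 can be selected by editing the config.
- **QWT hospitalisation dispersion** is printed as 0.774, but the moment
  formula applied to the printed (rounded) mean 3.5 and SD 4.4 gives 0.772 —
  the printed value was presumably computed from unrounded source moments.
  The derived 0.772 is the default; the printed 0.774 may be supplied via a
  per-arm `dispersion:` override. This affects sampling variance only, never
  expected totals.
- **Baseline QWT count** is the printed 170, not 8% × 2051 = 164; the head
  count is authoritative.

## Randomness and reproducibility

Every (scenario label, outcome, arm) triple gets its own stream: the triple
is hashed (BLAKE2b) into four 32-bit words and mixed with the master seed in
a numpy `SeedSequence`. Streams are mutually independent, identical inputs
give bit-identical outputs, and adding a scenario or outcome never perturbs
existing streams. Each simulation run writes a manifest (config digest,
seed, replicate count, version) sufficient to reproduce it exactly.

## Synthetic cohort

No patient-level register data are published, so the `cohort` module
generates a synthetic stand-in carrying only the attributes the cohort
description reports: size, arm split (exact head count, randomised
membership), main-diagnosis mix (F10.3 53.5%, F10.2 38.6%, F10.0 5.5%,
F10.1 2.3% — printed shares sum to 99.9% and are renormalised), sex split
(26.2% female) and admission years 2016–2017. Patient-level outcome tables
realise the same NB/Bernoulli model per patient, enabling two end-to-end
checks: column sums agree in distribution with the aggregate engine, and
moment re-estimation from a 50,000-patient-per-arm table recovers the
generating means within 2% and dispersions within 10%. Dispersion recovery
uses the same moment formula as the pipeline (not maximum likelihood), so
the recovery test exercises the estimator actually used.

What the synthetic data do **not** emulate: covariate-dependent outcomes,
correlation between outcomes or between diagnosis and arm, per-hospital or
per-year structure, loss to follow-up (the published parameters already
absorb dropouts). Passing tests therefore demonstrate internal consistency
of the model and pipeline, not fidelity to any real register beyond the
reported marginals.

## Numerical choices

- CI method: empirical percentile, `numpy.quantile` linear interpolation.
- Half-up rounding for allocations and all printed integers/percentages,
  matching the published table's rendering.
- Count draws are int64; a zero-size arm contributes an all-zero vector
  (degenerate, not an error); `replicates = 1` yields point CIs.
- Problem sizes in tests: distributional-equivalence checks run at 2,000
  replicates and n = 50 patients per setting; parameter recovery at 50,000
  patients per arm; full-scale reproduction tests at the study's own
  10,000 replicates. The full suite runs in a few seconds.

## Limitations

The simulation propagates only sampling variability of the outcome
distributions at fixed parameter values; uncertainty in the published
parameters themselves (small source studies, n ≈ 80–100 per arm) is not
propagated, so intervals understate total uncertainty. Treatment-effect
transportability — assuming QWT's outcome distributions would hold for
patients currently receiving SWT — is an assumption of the design, not
something the model can test.
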