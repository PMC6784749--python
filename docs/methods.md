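# Methods

## The design problem

Infection-control and antimicrobial-stewardship interventions are usually
evaluated by randomizing intact units — wards, ICUs, or whole hospitals —
rather than patients, because the intervention acts at the unit level and
individual randomization invites contamination. Patients within a unit are
correlated (shared colonization pressure, hand-hygiene culture, case mix),
so the effective information per cluster saturates and the number of
clusters, not the number of patients, dominates power. `crtplan` provides
the three pieces a designer needs for incidence-rate outcomes: estimating
the between-cluster variation from count data, converting it into a cluster
requirement, and validating that requirement by simulation.

## Model

Cluster *i* has a latent true daily event rate λᵢ (events per patient-day
or device-day) and accumulates exposure dᵢ person-days. Observed counts are
cᵢ ~ Poisson(λᵢ·dᵢ). Heterogeneity of the λᵢ is summarized by the
coefficient of variation

    k = SD(λᵢ) / mean(λᵢ),

which together with the mean rate is all the sizing formula needs; no
distributional form is assumed for estimation or sizing. The ICC and the CV
both encode non-independence; the CV is the natural overdispersion input
for rate outcomes.

## Estimation (moment method)

With observed rates rᵢ = cᵢ/dᵢ and pooled rate r̄ = Σcᵢ/Σdᵢ:

* observed variance: s² = Σ(rᵢ − r̄)²/(H−1);
* expected Poisson floor: the average of the per-cluster sampling variances
  at a common rate, (r̄/H)·Σ(1/dᵢ) — even identical clusters would scatter
  this much;
* between-cluster variance: σ̂²_b = max(0, s² − floor), SD = σ̂_b,
  CV = σ̂_b / r̄.

The truncation at zero is the moment method's natural boundary: on data
with no true heterogeneity the excess is negative about half the time and
the estimate is exactly zero, slightly positive otherwise. No small-sample
bias correction is applied. The estimator is validated by parameter
recovery on synthetic gamma–Poisson data (bias < 0.05 at H = 5000 with
20 000 person-days per cluster, across true CV 0.3–0.7; the test suite
checks this directly) rather than against any external table, since the
raw hospital-level data behind published estimates are not redistributable.

The "mean rate" is the exposure-weighted mean of cluster rates, which is
identical to the pooled rate Σcᵢ/Σdᵢ; an unweighted per-cluster mean is
available (`unweighted_mean_rate`) for users who want every hospital to
count equally. The standard error of the CV uses a cluster bootstrap:
resample all H clusters with replacement B times (default B = 1000), recompute
the CV each time, and report the sample SD of the B values. Resamples whose
total count is zero have no defined CV and are skipped with a logged count.
The index stream is `default_rng(seed).integers(0, H, (B, H))`, making every
SE exactly reproducible from the seed.

`mean_cluster_size` converts total exposure to person-days per cluster per
day (total exposure / clusters / study days), the m that the sizing formula
pairs with follow-up time t to give person-time per cluster y = m·t.

## Sizing (Hayes–Bennett incidence formula)

For two arms of c clusters each, rates λ₁ (control) and λ₂ = (1−effect)·λ₁,
person-time y per cluster and CV k:

    c = 1 + (z₁₋α/2 + z_power)² · [ (λ₁+λ₂)/y + k²(λ₁²+λ₂²) ] / (λ₁−λ₂)²

The first bracket term is within-cluster Poisson noise and vanishes as y
grows; the k² term is irreducible between-cluster heterogeneity and puts a
floor under c no matter how large the clusters. The "+1" compensates for
estimating the between-cluster variance from the trial itself.
`power_given_clusters` inverts the formula algebraically for z_power and
round-trips with `clusters_required` to 10⁻⁶.

**Reporting convention.** The formula defines c per arm, but the published
scenario totals this package reproduces treat floor(c) as the *total*
cluster count for 1:1 allocation, split ceil/floor between arms
(c = 73.97 → 73 total, 37/36). Both readings are carried on every result:
`clusters_unrounded` is the raw per-arm c, `total_clusters` and the arm
fields follow the reporting convention. Users sizing a real trial should
note that the conservative standard reading is c clusters *per arm* — the
Monte-Carlo validator confirms nominal power at ⌈c⌉ per arm, not at ⌈c⌉
total. For allocation ratios other than 1 there is no published convention
to follow; the experimental arm receives c clusters and the control arm
AR·c, each rounded up independently.

Two of the reproduced CV inputs are the 2-decimal values quoted in running
text (e.g. 0.55, 0.44) rather than the 4-decimal table estimates; the
4-decimal values shift several totals by one cluster. Floor uses exact
floating-point comparison with no epsilon nudging; all reproduced values
sit ≥ 0.02 from an integer boundary.

**Known discrepancies.** Ten of the 24 printed scenario totals differ from
the recomputation by 1–8 clusters under every input-rounding and
floor/round/ceil convention tried (largest: MRSA acquisition at 10% effect,
printed 540 vs computed 548). `reproduce_results` prints computed and
printed values side by side and flags these as documented discrepancies;
the CLI `reproduce` command exits non-zero only if a mismatch appears
*outside* the documented set. The four printed balanced-arm splits all
reproduce.

## Synthetic data and power validation

`generate_cluster_table` draws λᵢ from a gamma distribution with shape
1/k² and scale mean·k² (exactly the requested mean and CV; gamma is
conjugate to Poisson and guarantees positivity), or lognormally with
matched moments as a robustness alternative; k = 0 degenerates to identical
rates. Exposure is fixed per cluster or derived from (m, t), optionally
with multiplicative gamma spread to mimic heterogeneous hospital sizes.
Each call owns a single `numpy` Generator seeded explicitly; no global RNG
state is touched.

`simulate_trial_power` runs repeated two-arm trials at a given per-arm size
and analyzes each with an unpaired pooled-variance t test on cluster-level
observed rates — the cluster-summary analysis this sizing formula is
calibrated to. Trials where the test is undefined (all rates identical,
possible when events are vanishingly rare) count as degenerate
non-rejections and are reported, never dropped. With `under_null=True` both
arms share the control rate, giving the empirical type-I error.

At the CDI 30% design (per-arm ⌈c⌉ = 32, 2000 simulations) the empirical
power is ≈ 0.83 against the nominal 0.80 — the closed form is approximate
and mildly conservative here — and the null rejection rate is within
Monte-Carlo noise of α = 0.05. The suite asserts power within [0.72, 0.90],
i.e. ±3 Monte-Carlo SEs plus a 0.03 allowance for formula approximation.

### What the generator does and does not emulate

It reproduces the structure the methods assume: gamma-heterogeneous true
rates, Poisson counts, independent clusters, optionally variable cluster
sizes. It does not emulate features of real hospital data outside that
model: secular trends and seasonality, two-level clustering (ICUs within
hospitals), informative cluster size, reporting artifacts, or
non-gamma-shaped rate distributions beyond the lognormal option. Passing
recovery and calibration tests therefore demonstrates internal consistency
of estimator, formula and analysis under the assumed model — not robustness
to those real-world departures, which the sizing formula itself does not
address either (cluster-size variation in particular is known to erode
power and is deliberately out of scope).

## Numerical and interface choices

* Rates are daily rates throughout; any per-1000 scaling is display-only.
* Normal quantiles come from `scipy.stats.norm.ppf` (|error| well below
  10⁻⁸); an erf-based inversion oracle in the tests cross-checks it.
* JSON output round-trips doubles at full precision; human-readable lines
  round for display only.
* Test and validation problem sizes (H = 5000 for recovery, 2000
  simulations for calibration) were chosen to make Monte-Carlo noise small
  relative to the asserted tolerances while keeping the default suite
  around ten seconds.
* Defaults: α = 0.05 two-tailed, power 0.80, allocation ratio 1,
  follow-up 365 days, B = 1000 bootstrap resamples — the conditions of the
  reproduced analyses.

## Limitations

Single-level clustering only; parallel two-arm designs only (no matched,
stratified, or crossover variants); no adjustment for cluster-size
variation; moment estimation only (no negative-binomial or mixed-model
likelihood for the CV); the excess-variance estimator's exact published
weighting was not available and the implemented unweighted form is
validated by recovery, so its point estimates need not coincide with any
specific published SD to the printed digit.
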