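# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical edge cases.

## Data model and time conventions

A recording is a set of `ChannelSeries`: per-minute beam-break counts
("activity scores") on a strict regular grid, one tube/individual per
monitor channel, 32 channels per monitor, with per-channel treatment
metadata (insemination status, meal, light regimen, control-tube flag).

The light schedule is LD 12:12 with one-hour linear twilight ramps: dusk
17:00→18:00 (lights off 18:00), dawn 05:00→06:00 (lights on 06:00).
Zeitgeber/circadian time is anchored at **lights-off** — 18:00 = ZT0/CT0,
06:00 = ZT12 — because that is the convention under which the endpoint
windows below are stated. Both conventions exist in the field, so
`LightSchedule(zt_anchor="lights_on")` flips the anchor. DD keeps the same
nominal clock anchors to define subjective dusk/dawn. Timestamps are naive
local clock times; no daylight-saving handling is attempted.

## QC rules

* **Day trimming.** The first and last recording days are discarded
  (transfer/handling artefacts; a 7-day run yields analysis days 2–6).
  Days are calendar days; when a recording starts mid-day the partial
  leading day is dropped together with the adjacent first full day (and
  symmetrically at the end), so retained data are always whole midnight
  aligned days, and day labels keep the original recording-day numbering.
* **Dead rule.** ≥ 24 h of continuous inactivity (1440 consecutive zero
  minutes) flags the individual dead. The rule is evaluated on the
  *untrimmed* series, so a death during the last day still removes the
  individual. Whether to evaluate it before or after trimming is a genuine
  design choice; pre-trim is the stricter reading of "24 h of continuous
  inactivity" with no day restriction.
* **Control tubes** are always removed before analysis; a control tube
  with nonzero counts is logged as a potential light-leak/vibration
  artifact. In inseminated arms with a recorded sperm-check outcome,
  failed checks are removed. All removals go to the QC log
  (individual, action, reason); the filter is idempotent.

## Chi-square periodogram

Counts are rebinned to 5-min bins (recording is per minute; 5 min is the
standard periodogram resolution and keeps the fold matrix well conditioned;
configurable). For each trial period *P* = *K* bins in the 5–32 h scan,
only the *N* = ⌊*T*/*K*⌋ complete cycles are used (the classical statistic
assumes complete fold rows; the trailing partial cycle is truncated), and

    Qp = N²·K · Σₕ (Mₕ − M̄)² / Σᵢ (xᵢ − M̄)²,

which is asymptotically χ²(*K*−1) under independent noise: the fold-column
means have variance σ²/N, so N·Σₕ(Mₕ−M̄)²/σ̂² with σ̂² = Σᵢ(xᵢ−M̄)²/(NK)
is the χ² quantity, and the N²K form above is the same expression
rearranged. Significance is Qp > χ²₁₋α(*K*−1).

**Multiplicity.** Every period in the grid (~325 trial periods at 5-min
bins) is tested, so the default applies Bonferroni across the grid
(α_eff = α/n_periods). The common chronobiology convention of uncorrected
α = 0.05 is available via `correction="none"`. On 500 simulated flat-noise
individuals the Bonferroni default calls < 1% rhythmic (the acceptance
suite bounds this at 7%).

**Peaks and classification.** Contiguous super-threshold runs contribute
one peak each (the run's maximal margin Qp − threshold; shorter period on
exact ties). Arrhythmic = no significant peak anywhere in the scanned
range — chosen over "no circadian peak" because arrhythmic individuals are
defined by the all-zero chronotype barcode, i.e. no significant period of
any length. The fundamental τ is the peak inside 23 ± 2 h with the largest
margin (margin, not raw Qp, because the threshold varies with K; shorter
period breaks ties). Individuals whose only circadian-range (18–30 h) peaks
fall outside the acceptance band are flagged atypical and excluded from τ
analyses rather than silently contributing an off-band period.

**Degenerate input.** A constant series has zero total variance; Qp is
defined as 0 everywhere and the periodogram carries a `degenerate` flag
(never significant).

## Chronotype barcodes and diversity

Peaks are mapped to the canonical secondary periods 6, 8, 12, 16, 18, 20,
30 h when within ±0.5 h (nearest assignment, one canonical period per peak,
equidistant ties to the shorter period). The barcode is those seven bits in
ascending period order plus an eighth bit for the circadian fundamental.

Shannon diversity is computed over the frequencies of **distinct barcode
combinations** within a group (not per-period marginals), in natural log
units: with group sizes of 14–36 the index then lives on the familiar
0–ln n ≈ 3.6 scale. A base switch is provided. Arrhythmic individuals are
included as the all-zero class — excluding them would understate the
homogeneity of groups dominated by arrhythmia.

## Activity endpoints

* **Nightly activity**: 16:00 → 07:00 next morning, summed into 180
  five-minute bins; nights cut by the series edge are omitted, not padded.
* **Onset**: first minute *m* in 17:00–19:30 with counts ≥ 1 at
  *m*, *m*+1, *m*+2. The window starts at the dusk-ramp start and extends
  90 min past lights-off because onset delays of ~15 min past 18:00 occur
  in delayed groups; both bounds are configurable.
* **Peak**: maximal 1-min count in 17:30–19:30 (LD) or 16:30–19:30 (DD),
  earliest minute on ties; all-zero windows yield a missing value.
  Windows are fixed clock windows; under DD free-run the dusk burst drifts
  earlier by (24 − τ) h per day, so late-day DD peaks can leave the window
  and go missing — a known limitation shared with fixed-window analyses of
  real recordings.
* Missing endpoints propagate as missing values (never zeros).
* A night is labelled by the day it starts.

## Group statistics

* **Williams-corrected G test**: G = 2 Σ O ln(O/E), 0·ln 0 ≡ 0, corrected
  by q = 1 + (n Σ 1/rᵢ − 1)(n Σ 1/cⱼ − 1)/(6n(r−1)(c−1)), referred to
  χ²((r−1)(c−1)).
* **Nightly rate ratio**: the estimand is the multiplicative difference in
  per-5-min count rates between two groups on one night. The point
  estimate comes from a log-link negative-binomial regression (ML
  dispersion, statsmodels; Poisson fallback when the dispersion estimate
  diverges — logged). With a group-only design the NB MLE of the rate
  ratio is exactly the ratio of group sample means, whatever the
  dispersion, so the cluster bootstrap (resampling individuals with
  replacement, default B = 1000, seeded) resamples precisely the model's
  point estimator; the 95% CI is percentile, and the p-value is the
  two-sided bootstrap tail probability of log RR crossing zero, floored at
  1/B. Repeated bins within an individual are handled by the clustering,
  not by random effects: this package deliberately replaces mixed-model
  machinery (random intercepts/slopes per individual, Tukey-adjusted
  marginal means) with the two-stage/cluster-bootstrap approximation —
  same estimands (RR, MD), far simpler numerics; every result row carries
  its method, seed, B and adjustment tags.
* **Period contrasts**: OLS on the meal × insemination cell means (LD and
  DD separately), pairwise mean differences with t-based CIs, Holm
  adjustment. With an empty cell the interaction is not estimable and
  observed cells are compared with a warning. When period estimates are
  degenerate (entrained cohorts pinned exactly to 24.0 h on the grid) the
  pipeline skips the contrasts rather than testing numerical zeros.
* **Onset contrasts**: two-stage — per-individual mean onset across days
  (missing days ignored), then difference of group means in minutes with a
  percentile cluster bootstrap over individuals; positive values mean the
  first group starts later.

## Synthetic actograms

Per-minute counts are negative-binomial with mean λ(t) and size parameter
k (`nb_dispersion`, default 5; variance = m + m²/k; NB because real
beam-break counts are overdispersed; k → ∞ recovers Poisson), with

    λ(t) = baseline · [1 + dusk_amp·exp(−Δt_dusk/decay)
                         + dawn_amp·1{LD}·exp(−Δt_dawn/decay)
                         + (plateau − 1)·1{night}] · suppression(t).

Δt_dusk/Δt_dawn are minutes since the most recent dusk/dawn anchor. Under
DD the anchors advance by (24 − τ) h per subjective day (free-run is
implemented by phase-advancing the anchors, not by time-warping the series
— simpler, and sufficient for periodogram and endpoint testing) and the
dawn term is off. The dusk anchor is shifted by the onset delay δ.
Arrhythmic individuals (probability `p_arrhythmic`) are flat at baseline.
Blood-fed individuals are multiplied by `blood_suppression` (default 0.3)
until `recovery_h` (default 72 h) and recover linearly over
`recovery_ramp_h` (default 24 h).

Default rates were fixed once as a realistic actogram shape: baseline
0.05 counts/min (near-quiescent photophase), dusk burst ×60 with a 30-min
decay constant (a dominant burst that visibly lasts 1–2 h), LD dawn burst
×30, night plateau ×8 (intermediate nocturnal activity), per-individual τ
spread 0.25 h around the group mean (clipped to 21–25 h). Amplitudes are
free parameters of the generator — published actograms give shapes, not
count units. The default study is the 2×2 factorial (virgin/inseminated ×
glucose/blood) under LD (n = 33/25/22/36) and DD (n = 15 each), with a
4-min onset delay for inseminated groups and an elevated arrhythmic
fraction (25%) for DD inseminated groups; each simulated monitor carries
two all-zero control tubes.

**What the generator does not emulate** — and hence what passing recovery
tests do *not* demonstrate about real data: startle responses to handling,
temperature coupling, gonotrophic-cycle progression beyond a single static
suppression factor, position-dependent beam sensitivity, slow amplitude
trends across days, within-day autocorrelation beyond NB overdispersion,
and mortality (death appears only as an all-zero series if configured).
Recovery results certify the estimators under the generator's assumptions,
not the biology.

## Problem sizes and determinism

The test suite runs parameter-recovery experiments at deliberately modest
sizes — 500 flat-noise individuals for calibration, 20 individuals for DD
period recovery, 25/group for onset recovery, 100 replicates × B = 200 for
rate-ratio coverage — chosen so the whole suite completes in well under a
minute while keeping Monte-Carlo error small relative to the tested
tolerances. All simulations and bootstraps take explicit seeds; pipeline
runs are bit-reproducible for a fixed config + seed, and every output
table carries the run's seed and options in `run_meta.json`.

## Known limitations

* The chi-square periodogram is applied to overdispersed counts; the χ²
  calibration assumes independence, and strong autocorrelation can inflate
  false positives (mitigated here by Bonferroni across the grid).
* Fixed clock windows for DD endpoints (see above).
* The cluster bootstrap is percentile-based; with very few individuals
  (< ~8/group) its CIs can undercover.
* Rhythm calls use a single fundamental per individual; split circadian
  peaks (e.g. bimodal τ) are resolved by margin, which may not match
  manual scoring.
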