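# circalam

Chronobiological analysis of beam-break locomotor activity data from tube
monitors (TriKinetics-style locomotor activity monitors, LAMs), built for
studies of spontaneous activity in female *Anopheles* mosquitoes under
light:dark (LD 12:12) and constant-darkness (DD) regimens — and, more
generally, for any insect actogram recorded as per-minute beam-break counts.

It is aimed at vector-behaviour and circadian-rhythm labs that need a
scripted, reproducible replacement for point-and-click actogram software:
parsing monitor files, applying standard QC rules, calling rhythmicity from
chi-square periodograms, summarising chronotype diversity, extracting dusk
activity endpoints, and testing group differences.

## What it computes

**Chi-square periodogram.** Counts are rebinned (default 5 min) and folded
at every trial period *P* = *K* bins over a 5–32 h scan. With *N* = ⌊*T*/*K*⌋
complete cycles, the statistic is

    Qp(P) = N²·K · Σₕ (Mₕ − M̄)² / Σᵢ (xᵢ − M̄)²

where *Mₕ* are the fold-column means and *M̄* the grand mean. Under
independent noise Qp ~ χ²(*K*−1), so a period is significant when Qp exceeds
the upper-α chi-square quantile (α Bonferroni-corrected across the period
grid by default). An individual with no significant peak anywhere is
**arrhythmic**. The **fundamental free-running period τ** is the significant
peak inside the circadian acceptance band τ = 23 ± 2 h with the largest
margin above threshold; rhythmic individuals whose circadian-range peaks all
fall outside that band are flagged atypical and excluded from period
analyses.

**Chronotype barcodes and Shannon diversity.** Each individual is reduced
to an 8-bit presence/absence barcode over the secondary periods
(6, 8, 12, 16, 18, 20, 30 h) plus the circadian fundamental; arrhythmic
individuals are the all-zero barcode. Per treatment group,
*H* = −Σ pₖ ln pₖ over the frequencies of distinct barcode combinations
measures chronotype heterogeneity.

**Activity endpoints.** Nightly activity (per-5-min counts, 16:00→07:00),
onset of sustained dusk activity (first minute of ≥1 count/min for 3
consecutive minutes in the 17:00–19:30 window) and dusk peak time (maximal
1-min count in 17:30–19:30 under LD, 16:30–19:30 under DD).

**Group statistics.** Williams-corrected G tests of independence for
rhythmicity tables; nightly-activity rate ratios (RR) from log-link
negative-binomial fits with cluster-bootstrap 95% CIs (resampling
individuals); period-length and onset mean differences (MD) with
Holm-adjusted pairwise contrasts.

**Synthetic actograms.** A negative-binomial count simulator with a dusk
burst (delayable by δ minutes), an LD-only dawn burst, a night plateau,
DD free-run at τ (anchors advance by 24 − τ h per subjective day),
~72 h blood-meal suppression, and an arrhythmic subpopulation — with ground
truth emitted for every individual, so the whole pipeline is testable by
parameter recovery.

## Worked example

Run the bundled synthetic study (2×2 factorial of insemination × meal under
LD and DD, group sizes 33/25/22/36 in LD and 15 each in DD):

```sh
circalam run --config config.yaml --out results/
```

with `config.yaml` containing:

```yaml
seed: 1
bootstrap_B: 1000
simulate:
  scale: 1.0
```

The run writes `qc_log.csv`, `rhythm_calls.csv`, `diversity.csv`,
`endpoints.csv`, `profiles.csv`, `stats.csv`, `run_meta.json` and a
plain-text `report.txt`, which for this seed prints (abridged):

```
Rhythmicity by regimen:
  DD: 60 individuals, 8 arrhythmic (13.3%)
  LD: 116 individuals, 2 arrhythmic (1.7%)

Shannon diversity of chronotype barcodes:
   inseminated  glucose   DD: H = 1.81 (n=15)
        virgin  glucose   LD: H = 0.74 (n=33)
  ...

Group contrasts:
  LD night 3: inseminated blood vs glucose: 0.328 [0.294, 0.351], p=0.001
  LD onset (glucose): inseminated - virgin: 3.82 min [3.44, 4.24], p=0.001
  ...
```

Read it as: arrhythmicity is concentrated in DD (13.3% vs 1.7% — the
simulator injects an elevated arrhythmic fraction among DD inseminated
females); chronotype diversity *H* is higher in DD groups than their LD
counterparts; blood-fed females move about a third as much as glucose-fed
ones on night 3 (RR ≈ 0.33, the injected ~72 h post-meal suppression), and
insemination delays activity onset by ≈ 4 min (the injected δ = 4 min,
recovered with a tight bootstrap CI).

The same pipeline runs on real monitor files:

```yaml
monitor_files: [Monitor01.txt, Monitor02.txt]
channel_meta: channel_meta.csv
```

where `channel_meta.csv` maps (monitor_id, channel) to individual id,
insemination, meal, regimen and control-tube status.

## Library surface

```python
from circalam import (
    read_monitor_file, trim_days, flag_dead, apply_cohort_filters,
    chi_square_periodogram, classify_rhythmicity, map_to_canonical,
    make_barcode, shannon_diversity, nightly_activity, onset_time,
    peak_time, williams_g_test, rate_ratio_nightly, compare_onset,
    simulate_cohort, default_study,
)
```

See `docs/methods.md` for the statistical model, the simulator's
assumptions, and the numerical choices.
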