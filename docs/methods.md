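# Methods and analysis conventions

This note records the measurement conventions, generator design choices, and
decision rules implemented in `cardiochron`, so results can be interpreted
without reading the source.

## Synthetic ECG generator

Each beat is a sum of Gaussian waves (P, Q, R, S, T), parameterized by
amplitude (mV), center offset from the R peak (ms), and width σ (ms).
Three leads are rendered with per-wave-group lead weights. The R-R sequence
draws each interval from the species' heart-rate distribution and modulates
it sinusoidally at the respiratory rate (3% depth). All randomness flows
from one `numpy.random.SeedSequence` split into independent substreams for
rhythm, events, and noise, so recordings are bit-reproducible and noise-free
and noisy runs of the same seed share identical beat times.

**Ground-truth convention.** A wave's onset/offset is its center ± 2σ
(≈ 95% of the deflection). Hence QRS duration = S offset − Q onset, PQ =
P onset → QRS onset, PR = P onset → R peak. These are the values reported
in the generator's `GroundTruth`.

**Species defaults.** Mouse: 550 ± 15 bpm, QRS ≈ 9.2 ms; NMR: 240 ± 8 bpm,
QRS ≈ 12 ms, longer PQ and a flatter, wider T. Waveform amplitudes and
widths were chosen once, analytically, for realistic rodent morphology *and*
so the fixed 5%-of-R fiducial rule (below) has geometric error < 1 ms under
the 2σ onset convention: for a Gaussian wave the 5% crossing sits at
σ·√(2 ln(a_wave/(0.05·a_R))) from the center, so the error versus the 2σ
truth is ≈ σ·(2 − √(2 ln(a_wave/(0.05·a_R)))), which constrains usable
amplitude/width pairs. They were not adjusted against test outcomes.

**Premature beats.** APB: P preserved, normal QRS, resetting pause. VPB: no
P, QRS widths ×2.5, fully compensatory pause (pre + post interval = 2 × mean
R-R). JPB: no P, normal QRS, resetting pause. Event coupling is uniform in
0.45–0.65 of the mean R-R. Total per-beat event probability is capped at
0.2 to keep template averaging valid; events are never consecutive.

**Signal-to-noise.** SNR is the standard power ratio versus the clean lead-I
trace: `noise_for_snr(params, snr_db)` returns the white-noise SD giving
`10·log10(P_signal/P_noise) = snr_db`.

## ECG analysis

- **R peaks.** Band-pass 15–300 Hz (2nd-order Butterworth, zero-phase),
  square, 5-ms boxcar smoothing; peaks above 0.15 × the 99.5th envelope
  percentile, with a refractory period of 0.4 × the running-median R-R,
  refined to the nearby extremum of the filtered signal.
- **Screening.** An interval is suspect when it is < 70% or > 130% of the
  mean of up to 11 neighbouring intervals centered on it (itself excluded,
  truncated at the edges). Consecutive suspect intervals sharing a beat are
  merged into one physical event. Screened heart rate excludes suspect
  intervals.
- **Averaging.** Up to 100 clean beats (neither adjacent interval suspect),
  aligned on R, window [−0.45, +0.55] × median R-R.
- **Fiducials.** Isoelectric baseline = median of the [−0.40, −0.30] × R-R
  segment before R. QRS onset/offset are the nearest points flanking R where
  |signal − baseline| falls below 5% of the R amplitude — floored at 2× the
  baseline-segment noise SD, since an averaged beat cannot resolve below its
  residual noise — and stays below for ≥ 1 ms. The P peak is the largest
  deflection in the pre-QRS window; P onset uses the same rule on the P
  amplitude. P is reported absent when its peak does not clear the expected
  noise maximum over the search window (noise_sd·√(2 ln n) plus a 3-SD
  margin); PQ/PR are then missing while QRS is still returned.
- **Classification.** For each suspect premature beat: QRS width measured on
  the single beat (at 25% of R amplitude after 1-ms smoothing — the 5% level
  is below single-beat noise — against the template's isoelectric baseline,
  since a premature beat's own pre-beat segment overlaps the previous T
  wave); width ratio vs the template > 1.5 → VPB. Otherwise a P-wave
  presence score decides APB (≥ 0.6) vs JPB: the normalized cross-correlation
  of the pre-QRS window against the template P wave, searched over ± half
  the physiologic PQ range, after subtracting the previous beat's template
  contribution (the previous T wave lies inside the window at premature
  coupling and mimics a P), and gated by the least-squares amplitude of the
  template match so that tiny but well-shaped residuals do not score as P
  waves. Events with only a long pause are left unclassified.

## Cardiac function and Doppler

- SV = EDV − ESV, EF = 100·SV/EDV, CO = SV·HR/1000 (ml/min), nCO = CO/BW.
  ESV > EDV is rejected as a segmentation error.
- Biplane area-length volume V = (8/3π)·A₁·A₂/L reproduces the ellipsoid
  volume (4/3)πabc exactly for orthogonal views; when each view has its own
  length, the shorter is used by default (configurable).
- E/A analysis segments the trace into cardiac cycles (known cycle starts,
  or an autocorrelation period estimate choosing the earliest near-maximal
  peak, since the E–A spacing also produces a smaller autocorrelation peak).
  A cycle is separable when it shows two peaks with prominence ≥ 20% of the
  larger and an inter-peak valley ≤ 80% of the smaller; E/A is reported only
  when ≥ 80% of cycles are separable — fused traces never yield a ratio.
- Stress deltas are percent change from the unstressed baseline per metric;
  dobutamine protocol constants (1.5 mg/kg, 6-min wait) are stored as
  metadata defaults.

## Cohort statistics

- **Age trends.** The outcome and age are sample-z-scored; candidate terms
  are age, age² (only after age), sex, and sex-specific slopes (only after
  sex and age). Forward selection keeps added terms when the nested F-test
  is significant at α = 0.05 (AIC available as an alternative). The strict
  hierarchy keeps the null age-selection rate at ≈ α. OLS uses
  `numpy.linalg.lstsq` with analytic t/F inference; the test suite verifies
  exact agreement with `statsmodels` OLS.
- **Wilcoxon.** Exact (full null distribution) for tie-free samples with
  min(n, m) ≤ 10, otherwise the normal approximation with tie and continuity
  corrections; verified against complete enumeration.
- **Prevalence.** Percent of animals with ≥ 1 event per class within each
  age bin; top bin edge inclusive, ages outside the bins rejected.
- **Minimal detectable change.** (z₁₋α/₂ + z_power)·CV·√(2/n) for a
  two-group comparison — e.g. CV 2.9% at n = 23 → ≈ 2.4%.

## Cohort generator

Outcomes follow `y_z = β_age·z + β_age²·z² + β_sex·male + interactions +
σ·ε` on the z scale (z = population-standardized uniform age), converted to
physical units by `mean + sd·y_z`. When σ is unspecified it is resolved so
the total z-scale variance is ≈ 1, which makes sample-standardized
regression recover `β_age`. Species defaults encode the study-sized designs
(mouse n = 132 over 0.25–2.5 y; NMR n = 120 over 2–34 y), the published
standardized effect sizes (e.g. mouse QRS β_age = 0.48, heart rate 0.46,
EF −0.44, E/A −0.64; flat or mildly quadratic NMR trends), rising Poisson
arrhythmia counts with age in the mouse, and a zero arrhythmia rate in the
NMR. Native-unit trajectory coefficients (body weight, g) are divided by
the outcome scale SD for the z-scale generator.

## Pipeline

`run_pipeline(RunConfig, outdir)` simulates both species' cohorts, renders
and analyzes one ECG per animal (morphology rescaled to the animal's QRS —
the whole Q,R,S group is scaled proportionally, as conduction slowing is
self-similar — and P shifted to its PR, capped so the P wave stays ≥ 1σ
clear of the fixed baseline segment at high heart rates), computes stress
deltas and Doppler E/A per animal, fits age trends, tabulates prevalence,
and writes per-animal CSVs plus a `summary.json` whose floats are rounded
and keys sorted so identical config + seed reproduce it byte-for-byte.
Per-animal failures are recorded and counted, never fatal.
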