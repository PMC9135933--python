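"""Ensemble-average 100 clean beats and measure QRS / PR / PQ against the
generator's ground truth."""

from cardiochron import (
    average_beats,
    detect_r_peaks,
    flag_irregular,
    measure_intervals,
    nmr_ecg_params,
    rr_series,
    simulate_ecg,
)
from cardiochron.simulate import noise_for_snr

params = nmr_ecg_params()
noise = noise_for_snr(params, 20.0)  # 20 dB signal-to-noise
rec, truth = simulate_ecg(params, duration=60.0, noise_sd=noise, seed=2)

r = detect_r_peaks(rec)
rr = rr_series(r)
flags = flag_irregular(rr)
avg = average_beats(rec, rr, flags, n=100)
fid = measure_intervals(avg)

print(f"averaged {avg.n_averaged} beats (median RR {avg.median_rr_ms:.1f} ms)")
for name, measured, true in (
    ("QRS", fid.qrs_ms, truth.intervals["qrs_ms"]),
    ("PQ", fid.pq_ms, truth.intervals["pq_ms"]),
    ("PR", fid.pr_ms, truth.intervals["pr_ms"]),
):
    print(f"{name:>3}: measured {measured:5.1f} ms, true {true:5.1f} ms "
          f"(error {measured - true:+.1f} ms)")
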