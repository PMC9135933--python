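"""Simulate a mouse ECG with premature beats, detect R peaks, and screen
the rhythm with the 70%/130% moving-average rule."""

from cardiochron import (
    ArrhythmiaSpec,
    detect_r_peaks,
    flag_irregular,
    mouse_ecg_params,
    rr_series,
    simulate_ecg,
    suspect_events,
)

params = mouse_ecg_params()
arr = ArrhythmiaSpec(apb_prob=0.02, vpb_prob=0.01)
rec, truth = simulate_ecg(params, arr, duration=120.0, noise_sd=0.02, seed=1)
print(f"simulated {truth.n_beats} beats "
      f"({sum(1 for l in truth.labels if l != 'normal')} premature)")

r = detect_r_peaks(rec)
rr = rr_series(r)
flags = flag_irregular(rr, low=0.70, high=1.30, window=11)
events = suspect_events(flags)
print(f"detected {rr.n_beats} R peaks; screened heart rate "
      f"{rr.heart_rate(flags):.0f} bpm")
print(f"{sum(f.suspect for f in flags)} suspect intervals "
      f"merged into {len(events)} events")
for ev in events[:5]:
    ratios = ", ".join(f"{f.rr_ratio:.2f}" for f in ev)
    print(f"  event at beat {ev[0].beat_index}: interval ratios {ratios}")
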