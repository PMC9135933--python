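"""Classify injected premature beats as atrial / ventricular / junctional
and compare against the generator labels."""

from cardiochron import (
    ArrhythmiaSpec,
    average_beats,
    classify_flagged,
    detect_r_peaks,
    flag_irregular,
    mouse_ecg_params,
    rr_series,
    simulate_ecg,
    suspect_events,
)
from cardiochron.simulate import noise_for_snr

params = mouse_ecg_params()
arr = ArrhythmiaSpec(apb_prob=0.02, vpb_prob=0.015, jpb_prob=0.015)
rec, truth = simulate_ecg(params, arr, duration=300.0,
                          noise_sd=noise_for_snr(params, 20.0), seed=3)

r = detect_r_peaks(rec)
rr = rr_series(r)
flags = flag_irregular(rr)
avg = average_beats(rec, rr, flags, n=100)
flags = classify_flagged(rec, rr, flags, avg)

true_events = [(t, lab) for t, lab in zip(truth.r_times, truth.labels)
               if lab != "normal"]
detected = []
for ev in suspect_events(flags):
    short = [f for f in ev if f.rr_ratio < 0.70]
    if short:
        detected.append((rr.r_times[short[0].beat_index],
                         short[0].beat_class))

correct = 0
for dt, dc in detected:
    for tt, tl in true_events:
        if abs(dt - tt) < 0.02:
            correct += dc == tl
            break
print(f"injected {len(true_events)} premature beats, "
      f"detected {len(detected)}, class correct {correct}")
counts = {}
for _, c in detected:
    counts[c] = counts.get(c, 0) + 1
print("detected class counts:", counts)
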