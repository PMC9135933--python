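"""Systolic function metrics, the biplane atrial volume, and dobutamine
stress-response deltas."""

from cardiochron import biplane_la_volume, function_metrics, stress_delta

# left-ventricular function from end-diastolic / end-systolic volumes
baseline = function_metrics(edv=55.0, esv=22.0, hr=234.0, body_weight=46.0)
print("baseline:", {k: round(v, 2) for k, v in baseline.as_dict().items()})

# after dobutamine: smaller end-systolic volume, faster rate
stressed = function_metrics(edv=55.0, esv=13.0, hr=270.0, body_weight=46.0)
d = stress_delta(baseline, stressed)
print("stress deltas (%):", {k: round(v, 1) for k, v in d.deltas.items()})

# biplane area-length left-atrial volume (areas mm^2, length mm -> ul)
v = biplane_la_volume(area_2ch=9.5, area_4ch=10.2, long_axis=4.8)
print(f"biplane LA volume: {v:.1f} ul")
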