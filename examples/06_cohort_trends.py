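"""Cross-sectional cohort statistics: age-trend model selection, between-
species Wilcoxon comparison, arrhythmia prevalence, and the minimal
detectable change."""

from cardiochron import (
    arrhythmia_prevalence,
    detectable_change,
    fit_trend,
    simulate_cohort,
    wilcoxon_test,
)
from cardiochron.simulate import default_mouse_design, default_nmr_design

mouse, _ = simulate_cohort(default_mouse_design(), seed=5)
nmr, _ = simulate_cohort(default_nmr_design(), seed=6)

for outcome in ("qrs_ms", "hr_bpm", "ea_ratio"):
    tm = fit_trend(mouse, outcome)
    form = "+".join(tm.terms) or "intercept"
    beta = tm.beta.get("age")
    print(f"mouse {outcome:8}: model [{form}], "
          f"standardized age slope {beta:+.2f}" if beta is not None
          else f"mouse {outcome:8}: model [{form}] (no age trend)")

w, p = wilcoxon_test(mouse["qrs_ms"].head(10), nmr["qrs_ms"].head(10))
print(f"mouse vs NMR QRS (n=10 each): rank sum {w:.0f}, p = {p:.4f}")

prev = arrhythmia_prevalence(mouse, bins=[0.0, 1.0, 1.7, 2.2, 3.0])
print("mouse arrhythmia prevalence by age bin (%):")
print(prev.table[["bin_lo", "bin_hi", "n", "APB_pct", "VPB_pct", "JPB_pct"]]
      .to_string(index=False))

mdc = detectable_change(cv=2.9, n_per_group=23)
print(f"assay CV 2.9% at n=23/group -> minimal detectable change {mdc:.1f}%")
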