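"""Generator-side tests: determinism, ground truth, event statistics."""

import numpy as np
import pytest
from scipy import stats

from cardiochron import simulate as sim


def test_simulate_ecg_deterministic(mouse_params):
    r1, g1 = sim.simulate_ecg(mouse_params, duration=5.0, noise_sd=0.02, seed=7)
    r2, g2 = sim.simulate_ecg(mouse_params, duration=5.0, noise_sd=0.02, seed=7)
    for lead in ("L1", "L2", "L3"):
        np.testing.assert_array_equal(r1.leads[lead], r2.leads[lead])
    np.testing.assert_array_equal(g1.r_times, g2.r_times)
    assert g1.labels == g2.labels


def test_simulate_ecg_seed_changes_output(mouse_params):
    r1, _ = sim.simulate_ecg(mouse_params, duration=5.0, noise_sd=0.02, seed=7)
    r2, _ = sim.simulate_ecg(mouse_params, duration=5.0, noise_sd=0.02, seed=8)
    assert not np.array_equal(r1.leads["L1"], r2.leads["L1"])


def test_seed_required(mouse_params):
    with pytest.raises(ValueError):
        sim.simulate_ecg(mouse_params, duration=5.0)
    with pytest.raises(ValueError):
        sim.simulate_cohort(sim.default_mouse_design())


def test_mean_rate_and_rr_spread(mouse_clean_60s, mouse_params):
    _, gt = mouse_clean_60s
    rr_s = np.diff(gt.r_times)
    hr = 60.0 / rr_s.mean()
    # hr_mean 550 with sd 15 and respiratory modulation: mean close to spec
    assert abs(hr - mouse_params.hr_mean) < 0.05 * mouse_params.hr_mean
    assert rr_s.std() > 0  # variability present


def test_ground_truth_intervals_match_wave_geometry(mouse_params):
    w = mouse_params.waves
    assert mouse_params.true_qrs_ms == pytest.approx(
        (w["S"].center + 2 * w["S"].sigma) - (w["Q"].center - 2 * w["Q"].sigma)
    )
    assert mouse_params.true_pq_ms == pytest.approx(
        (w["Q"].center - 2 * w["Q"].sigma) - (w["P"].center - 2 * w["P"].sigma)
    )
    assert mouse_params.true_pr_ms == pytest.approx(
        0.0 - (w["P"].center - 2 * w["P"].sigma)
    )


def test_scaled_qrs_params_hits_target_and_is_self_similar(mouse_params):
    for target in (6.0, 10.0, 14.0):
        p = sim.scaled_qrs_params(mouse_params, target)
        assert p.true_qrs_ms == pytest.approx(target)
        k = target / mouse_params.true_qrs_ms
        for nm in ("Q", "R", "S"):
            assert p.waves[nm].sigma == pytest.approx(
                k * mouse_params.waves[nm].sigma
            )


def test_r_peak_amplitude_at_r_times(mouse_clean_60s):
    rec, gt = mouse_clean_60s
    x = rec.leads["L1"]
    idx = np.round(gt.r_times * rec.fs).astype(int)
    # the R gaussian dominates at its center for every beat
    assert np.all(x[idx] > 0.6)


def test_vpb_wide_apb_normal_morphology(mouse_params):
    """Rendered VPBs are ~2.5x wider and P-free; JPB/APB per spec."""
    arr = sim.ArrhythmiaSpec(vpb_prob=0.05)
    rec, gt = sim.simulate_ecg(mouse_params, arr, duration=60.0, noise_sd=0.0, seed=11)
    labels = np.asarray(gt.labels)
    assert (labels == "VPB").sum() > 5
    fs = rec.fs
    x = rec.leads["L1"]
    for t, lab in zip(gt.r_times, gt.labels):
        if lab != "VPB":
            continue
        c = int(round(t * fs))
        # no P wave: segment around the (scaled) P location is near baseline
        p_c = c + int(round(2.5 * mouse_params.waves["P"].center / 1000 * fs))
        # VPB P suppressed entirely; check the normal P location too
        p_n = c + int(round(mouse_params.waves["P"].center / 1000 * fs))
        assert abs(x[p_n]) < 0.35  # would be >= 0.15 P amp + QRS tail otherwise
        break


def test_compensatory_pause_sums_to_two_mean_rr(mouse_params):
    arr = sim.ArrhythmiaSpec(vpb_prob=0.04)
    _, gt = sim.simulate_ecg(mouse_params, arr, duration=120.0, noise_sd=0.0, seed=3)
    mean_rr = 60.0 / mouse_params.hr_mean
    labels = gt.labels
    for i, lab in enumerate(labels):
        if lab == "VPB" and 1 <= i < len(labels) - 1:
            pre = gt.r_times[i] - gt.r_times[i - 1]
            post = gt.r_times[i + 1] - gt.r_times[i]
            assert pre + post == pytest.approx(2 * mean_rr, abs=1e-9)


def test_prematurity_range_respected(mouse_params):
    arr = sim.ArrhythmiaSpec(apb_prob=0.05, jpb_prob=0.05)
    _, gt = sim.simulate_ecg(mouse_params, arr, duration=120.0, noise_sd=0.0, seed=5)
    mean_rr = 60.0 / mouse_params.hr_mean
    n_ev = 0
    for i, lab in enumerate(gt.labels):
        if lab in ("APB", "JPB") and i >= 1:
            frac = (gt.r_times[i] - gt.r_times[i - 1]) / mean_rr
            assert 0.45 - 1e-9 <= frac <= 0.65 + 1e-9
            n_ev += 1
    assert n_ev > 10


def test_event_count_binomial_calibration(mouse_params):
    """Injected event counts are consistent with the per-beat probability."""
    arr = sim.ArrhythmiaSpec(apb_prob=0.03)
    total_beats = 0
    total_events = 0
    for seed in range(6):
        _, gt = sim.simulate_ecg(mouse_params, arr, duration=60.0,
                                 noise_sd=0.0, seed=1000 + seed)
        labels = np.asarray(gt.labels)
        total_events += int((labels == "APB").sum())
        # eligible beats: normal beats followed by another beat
        total_beats += int((labels == "normal").sum())
    # each event consumes the following slot; effective rate p/(1+2p)-ish.
    # Use a generous binomial band around the nominal rate.
    p_hat = total_events / total_beats
    lo, hi = stats.binom.interval(0.9999, total_beats, 0.03)
    assert lo / total_beats * 0.8 <= p_hat <= hi / total_beats * 1.1


def test_arrhythmia_spec_validation():
    with pytest.raises(ValueError):
        sim.ArrhythmiaSpec(apb_prob=-0.1)
    with pytest.raises(ValueError):
        sim.ArrhythmiaSpec(apb_prob=0.1, vpb_prob=0.1, jpb_prob=0.05)
    with pytest.raises(ValueError):
        sim.ArrhythmiaSpec(prematurity=(0.5, 0.9))


def test_noise_for_snr_power_ratio(mouse_params):
    sd = sim.noise_for_snr(mouse_params, 10.0)
    rec, _ = sim.simulate_ecg(mouse_params, duration=10.0, noise_sd=0.0,
                              fs=2000.0, seed=0)
    p_sig = float(np.mean(rec.leads["L1"] ** 2))
    assert 10 * np.log10(p_sig / sd**2) == pytest.approx(10.0, abs=1e-6)


def test_simulate_doppler_geometry():
    tr = sim.simulate_doppler(600.0, 300.0, 240.0, duration=3.0, seed=0)
    T = 60.0 / 240.0
    i_e = int(round(0.35 * T * tr.fs))
    assert tr.velocity[i_e] == pytest.approx(600.0, rel=0.02)
    assert len(tr.cycle_starts) == int(3.0 / T)


def test_simulate_cohort_shapes_and_determinism():
    design = sim.default_mouse_design(n_female=12, n_male=14)
    df1, truth1 = sim.simulate_cohort(design, seed=42)
    df2, _ = sim.simulate_cohort(design, seed=42)
    assert len(df1) == 26
    assert (df1["sex"] == "M").sum() == 14
    assert df1.equals(df2)
    assert set(design.outcomes) <= set(df1.columns)
    assert {"apb_count", "vpb_count", "jpb_count"} <= set(df1.columns)
    lo, hi = design.age_range
    assert df1["age_years"].between(lo, hi).all()
    assert "qrs_ms" in truth1["outcomes"]


def test_nmr_cohort_has_zero_arrhythmias():
    df, _ = sim.simulate_cohort(sim.default_nmr_design(), seed=9)
    assert int(df[["apb_count", "vpb_count", "jpb_count"]].to_numpy().sum()) == 0


def test_cohort_outcome_betas_recoverable_in_expectation():
    """Large-n sanity: sample-standardized OLS slope approximates beta_age."""
    design = sim.default_mouse_design(n_female=2000, n_male=2000)
    df, _ = sim.simulate_cohort(design, seed=77)
    y = df["qrs_ms"].to_numpy()
    a = df["age_years"].to_numpy()
    yz = (y - y.mean()) / y.std(ddof=1)
    az = (a - a.mean()) / a.std(ddof=1)
    slope = float(np.polyfit(az, yz, 1)[0])
    assert slope == pytest.approx(0.48, abs=0.05)
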