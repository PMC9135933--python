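"""ECG analysis unit tests: detection, screening, averaging, fiducials,
classification."""

import numpy as np
import pytest

from cardiochron import ecg as ea
from cardiochron import simulate as sim

from oracles import flag_oracle, match_events


# -- R-peak detection -------------------------------------------------------

def test_detect_r_peaks_clean_exact(mouse_clean_60s):
    rec, gt = mouse_clean_60s
    r = ea.detect_r_peaks(rec)
    assert len(r) == gt.n_beats
    assert np.max(np.abs(r - gt.r_times)) < 0.002  # within 2 ms


def test_detect_r_peaks_rejects_bad_input(mouse_params):
    rec, _ = sim.simulate_ecg(mouse_params, duration=5.0, noise_sd=0.0, seed=1)
    with pytest.raises(KeyError):
        ea.detect_r_peaks(rec, lead="L9")
    flat = ea.EcgRecording(fs=2000.0, leads={"L1": np.zeros(10000)})
    with pytest.warns(UserWarning):
        assert len(ea.detect_r_peaks(flat)) == 0
    short = ea.EcgRecording(fs=2000.0, leads={"L1": np.ones(1000)})
    with pytest.raises(ValueError):
        ea.detect_r_peaks(short)


def test_detect_r_peaks_low_fs_rejected(mouse_params):
    rec, _ = sim.simulate_ecg(mouse_params, duration=5.0, noise_sd=0.0, seed=1)
    rec2 = ea.EcgRecording(fs=400.0, leads={"L1": rec.leads["L1"]})
    with pytest.raises(ValueError):
        ea.detect_r_peaks(rec2)


def test_detect_r_peaks_other_lead(mouse_clean_60s):
    rec, gt = mouse_clean_60s
    r = ea.detect_r_peaks(rec, lead="L2")
    assert len(r) == gt.n_beats


# -- screening --------------------------------------------------------------

def test_flag_irregular_matches_oracle_random_series(rng):
    for _ in range(50):
        n = int(rng.integers(4, 200))
        intervals = rng.uniform(60.0, 200.0, size=n)
        times = np.concatenate([[0.0], np.cumsum(intervals)]) / 1000.0
        rr = ea.rr_series(times)
        flags = ea.flag_irregular(rr)
        ratios, suspect = flag_oracle(intervals)
        assert [f.suspect for f in flags] == suspect
        np.testing.assert_allclose([f.rr_ratio for f in flags], ratios, rtol=1e-12)


def test_flag_irregular_validation():
    rr = ea.rr_series([0.0, 0.1, 0.2])
    with pytest.raises(ValueError):
        ea.flag_irregular(rr)  # only 2 intervals
    rr = ea.rr_series([0.0, 0.1, 0.2, 0.3, 0.4])
    with pytest.raises(ValueError):
        ea.flag_irregular(rr, low=1.4, high=1.3)


def test_flag_known_premature_pattern():
    """One premature beat: short interval then long pause, both flagged."""
    rr_ms = [100.0] * 10 + [55.0, 145.0] + [100.0] * 10
    times = np.concatenate([[0.0], np.cumsum(rr_ms)]) / 1000.0
    flags = ea.flag_irregular(ea.rr_series(times))
    suspect_idx = [f.beat_index for f in flags if f.suspect]
    assert suspect_idx == [11, 12]
    events = ea.suspect_events(flags)
    assert len(events) == 1 and len(events[0]) == 2


def test_suspect_events_merges_only_consecutive():
    rr_ms = [100.0] * 8 + [55.0, 145.0] + [100.0] * 8 + [55.0, 145.0] + [100.0] * 8
    times = np.concatenate([[0.0], np.cumsum(rr_ms)]) / 1000.0
    flags = ea.flag_irregular(ea.rr_series(times))
    assert len(ea.suspect_events(flags)) == 2


def test_heart_rate_excludes_suspect_intervals():
    # resetting premature beat: one short interval, no compensatory pause
    rr_ms = [100.0] * 10 + [55.0] + [100.0] * 10
    times = np.concatenate([[0.0], np.cumsum(rr_ms)]) / 1000.0
    rr = ea.rr_series(times)
    flags = ea.flag_irregular(rr)
    assert rr.heart_rate(flags) == pytest.approx(600.0)
    # unscreened rate is biased high by the short interval
    assert rr.heart_rate() > 605.0


# -- averaging --------------------------------------------------------------

def test_average_beats_recovers_template(mouse_clean_60s):
    rec, gt = mouse_clean_60s
    r = ea.detect_r_peaks(rec)
    rr = ea.rr_series(r)
    flags = ea.flag_irregular(rr)
    avg = ea.average_beats(rec, rr, flags, n=100)
    assert avg.n_averaged == 100
    # R peak at t=0 with the configured amplitude
    i0 = int(np.argmin(np.abs(avg.time_ms)))
    assert avg.mean["L1"][i0] == pytest.approx(1.0, abs=0.05)
    # window as configured
    assert avg.time_ms[0] == pytest.approx(-0.45 * avg.median_rr_ms, abs=1.0)
    assert avg.time_ms[-1] == pytest.approx(0.55 * avg.median_rr_ms, abs=1.0)


def test_average_beats_uses_fewer_when_short(mouse_params):
    rec, _ = sim.simulate_ecg(mouse_params, duration=8.0, noise_sd=0.0, seed=2)
    r = ea.detect_r_peaks(rec)
    rr = ea.rr_series(r)
    flags = ea.flag_irregular(rr)
    avg = ea.average_beats(rec, rr, flags, n=100)
    assert 20 <= avg.n_averaged < 100


def test_average_beats_too_few_raises(mouse_params):
    rec, _ = sim.simulate_ecg(mouse_params, duration=3.0, noise_sd=0.0, seed=2)
    r = ea.detect_r_peaks(rec)
    rr = ea.rr_series(r)
    # 3 s at ~550 bpm gives ~27 beats; restrict to make it fail
    sub = ea.rr_series(r[:10])
    with pytest.raises(ValueError):
        ea.average_beats(rec, sub, None, n=100)


def test_averaging_noise_reduction_sqrt_n(mouse_params):
    """Residual RMS after averaging N beats scales ~ 1/sqrt(N)."""
    noise_sd = 0.05
    rec_n, _ = sim.simulate_ecg(mouse_params, duration=60.0,
                                noise_sd=noise_sd, seed=31)
    rec_c, _ = sim.simulate_ecg(mouse_params, duration=60.0,
                                noise_sd=0.0, seed=31)
    r = ea.detect_r_peaks(rec_c)
    rr = ea.rr_series(r)
    flags = ea.flag_irregular(rr)
    resid = {}
    for n in (25, 100):
        avg_n = ea.average_beats(rec_n, rr, flags, n=n)
        avg_c = ea.average_beats(rec_c, rr, flags, n=n)
        resid[n] = float(np.sqrt(np.mean(
            (avg_n.mean["L1"] - avg_c.mean["L1"]) ** 2
        )))
        # absolute level: noise_sd / sqrt(n) within 20%
        assert resid[n] == pytest.approx(noise_sd / np.sqrt(n), rel=0.2)
    assert resid[25] / resid[100] == pytest.approx(2.0, rel=0.2)


# -- fiducials --------------------------------------------------------------

def _measured_intervals(params, noise_sd, seed, duration=60.0):
    rec, gt = sim.simulate_ecg(params, duration=duration, noise_sd=noise_sd,
                               seed=seed)
    r = ea.detect_r_peaks(rec)
    rr = ea.rr_series(r)
    flags = ea.flag_irregular(rr)
    avg = ea.average_beats(rec, rr, flags, n=100)
    fid = ea.measure_intervals(avg)
    return fid, gt


def test_intervals_clean_mouse(mouse_params):
    fid, gt = _measured_intervals(mouse_params, 0.0, 41)
    assert fid.qrs_ms == pytest.approx(gt.intervals["qrs_ms"], abs=1.0)
    assert fid.pq_ms == pytest.approx(gt.intervals["pq_ms"], abs=2.0)
    assert fid.pr_ms == pytest.approx(gt.intervals["pr_ms"], abs=2.0)


def test_intervals_clean_nmr(nmr_params):
    fid, gt = _measured_intervals(nmr_params, 0.0, 42)
    assert fid.qrs_ms == pytest.approx(gt.intervals["qrs_ms"], abs=1.0)
    assert fid.pq_ms == pytest.approx(gt.intervals["pq_ms"], abs=2.0)
    assert fid.pr_ms == pytest.approx(gt.intervals["pr_ms"], abs=2.0)


def test_p_reported_absent_when_no_p_wave(mouse_params):
    waves = dict(mouse_params.waves)
    waves["P"] = sim.Wave(0.0001, waves["P"].center, waves["P"].sigma)
    p = sim.SpeciesEcgParams(
        species="mouse", hr_mean=mouse_params.hr_mean, hr_sd=mouse_params.hr_sd,
        waves=waves, resp_depth=mouse_params.resp_depth,
        resp_rate=mouse_params.resp_rate, lead_weights=mouse_params.lead_weights,
    )
    rec, _ = sim.simulate_ecg(p, duration=60.0, noise_sd=0.02, seed=8)
    r = ea.detect_r_peaks(rec)
    rr = ea.rr_series(r)
    flags = ea.flag_irregular(rr)
    avg = ea.average_beats(rec, rr, flags, n=100)
    fid = ea.measure_intervals(avg)
    assert fid.p_onset is None
    assert fid.pq_ms is None and fid.pr_ms is None


# -- classification ---------------------------------------------------------

def _classified_events(params, arr, seed, noise_sd, duration=120.0):
    rec, gt = sim.simulate_ecg(params, arr, duration=duration,
                               noise_sd=noise_sd, seed=seed)
    r = ea.detect_r_peaks(rec)
    rr = ea.rr_series(r)
    flags = ea.flag_irregular(rr)
    avg = ea.average_beats(rec, rr, flags, n=100)
    flags = ea.classify_flagged(rec, rr, flags, avg)
    det_t, det_c = [], []
    for ev in ea.suspect_events(flags):
        short = [f for f in ev if f.rr_ratio < 0.70]
        if short:
            det_t.append(rr.r_times[short[0].beat_index])
            det_c.append(short[0].beat_class)
    true_t = [t for t, lab in zip(gt.r_times, gt.labels) if lab != "normal"]
    true_l = [lab for lab in gt.labels if lab != "normal"]
    return det_t, det_c, true_t, true_l


def test_classify_each_class_clean(mouse_params):
    for cls, arr in [
        ("APB", sim.ArrhythmiaSpec(apb_prob=0.03)),
        ("VPB", sim.ArrhythmiaSpec(vpb_prob=0.03)),
        ("JPB", sim.ArrhythmiaSpec(jpb_prob=0.03)),
    ]:
        det_t, det_c, true_t, true_l = _classified_events(
            mouse_params, arr, seed=61, noise_sd=0.0
        )
        n_true, matched, correct, false, conf = match_events(
            det_t, det_c, true_t, true_l
        )
        assert n_true > 10
        assert matched / n_true >= 0.95
        assert false == 0
        assert correct / matched >= 0.95, (cls, conf)


def test_classify_without_template_unclassified(mouse_params):
    arr = sim.ArrhythmiaSpec(apb_prob=0.03)
    rec, _ = sim.simulate_ecg(mouse_params, arr, duration=30.0,
                              noise_sd=0.0, seed=62)
    r = ea.detect_r_peaks(rec)
    rr = ea.rr_series(r)
    flags = ea.flag_irregular(rr)
    flags = ea.classify_flagged(rec, rr, flags, None)
    classes = {f.beat_class for f in flags if f.suspect}
    assert classes <= {"unclassified"}
    assert "unclassified" in classes


def test_clean_regular_recording_has_no_flags(nmr_clean_60s):
    rec, _ = nmr_clean_60s
    r = ea.detect_r_peaks(rec)
    flags = ea.flag_irregular(ea.rr_series(r))
    assert sum(f.suspect for f in flags) == 0
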