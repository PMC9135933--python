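"""ECG rhythm and interval analysis for anesthetized rodents.

The pipeline mirrors a standard small-animal workflow: R peaks are found with
an energy detector, the R-R series is screened for irregular beats with a
moving-average ratio rule (suspect if an interval is < 70% or > 130% of the
local moving average), clean beats are ensemble-averaged, and conduction
intervals (QRS, PR, PQ) are measured on the averaged beat with a
baseline-threshold fiducial rule.  Suspect premature beats are classified as
atrial, ventricular, or junctional from single-beat QRS width and P-wave
presence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "EcgRecording",
    "RRSeries",
    "BeatFlag",
    "AveragedBeat",
    "FiducialSet",
    "detect_r_peaks",
    "rr_series",
    "flag_irregular",
    "suspect_events",
    "average_beats",
    "measure_intervals",
    "classify_flagged",
]

LEAD_NAMES = ("L1", "L2", "L3")


@dataclass
class EcgRecording:
    """Multi-lead sampled voltage series.

    Attributes
    ----------
    fs : float
        Sampling rate in Hz (>= 1 kHz recommended for rodent ECG).
    leads : dict
        Lead name -> voltage array in mV.  Standard names are L1, L2, L3.
    species : str or None
        Species tag ("mouse" or "nmr") when known.
    aux : dict
        Optional auxiliary channels (e.g. "breath", "temp_C").
    meta : dict
        Free-form provenance (generator seed, units, ...).
    """

    fs: float
    leads: dict[str, np.ndarray]
    species: str | None = None
    aux: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.leads:
            raise ValueError("recording must contain at least one lead")
        n = {len(v) for v in self.leads.values()}
        if len(n) != 1:
            raise ValueError("all leads must have equal length")
        self.leads = {k: np.asarray(v, dtype=float) for k, v in self.leads.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.leads.values())))

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        """Time axis in seconds (0-based sample times)."""
        return np.arange(self.n_samples) / self.fs


@dataclass
class RRSeries:
    """R-peak times and the derived inter-beat interval series."""

    r_times: np.ndarray  # s, strictly increasing

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        if self.r_times.ndim != 1:
            raise ValueError("r_times must be 1-D")
        if len(self.r_times) >= 2 and not np.all(np.diff(self.r_times) > 0):
            raise ValueError("r_times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return len(self.r_times)

    @property
    def rr_intervals(self) -> np.ndarray:
        """Inter-beat intervals in ms (length n_beats - 1)."""
        return np.diff(self.r_times) * 1000.0

    def heart_rate(self, flags: "list[BeatFlag] | None" = None) -> float:
        """Mean heart rate in bpm from non-suspect intervals.

        Rhythm-screened: intervals flagged as suspect are excluded so that
        premature beats and their pauses do not bias the rate estimate.
        """
        rr = self.rr_intervals
        if len(rr) == 0:
            return float("nan")
        if flags is not None:
            suspect_beats = {f.beat_index for f in flags if f.suspect}
            keep = np.array(
                [i + 1 not in suspect_beats for i in range(len(rr))], dtype=bool
            )
            if keep.any():
                rr = rr[keep]
        return 60000.0 / float(np.mean(rr))


@dataclass
class BeatFlag:
    """Screening verdict for one R-R interval / its terminating beat.

    ``beat_index`` is the index (into ``RRSeries.r_times``) of the beat that
    terminates the interval; ``rr_ratio`` is the interval divided by the
    moving average of its neighbours.
    """

    beat_index: int
    rr_ratio: float
    suspect: bool
    beat_class: str = "normal"  # normal | APB | VPB | JPB | unclassified


@dataclass
class AveragedBeat:
    """Ensemble average of clean beats, time axis centered at R (t = 0 ms)."""

    time_ms: np.ndarray
    mean: dict[str, np.ndarray]  # lead -> mV
    sd: dict[str, np.ndarray]
    n_averaged: int
    median_rr_ms: float
    fs: float

    def lead(self, name: str = "L1") -> np.ndarray:
        return self.mean[name]


@dataclass
class FiducialSet:
    """Landmark times (ms, relative to R) and conduction intervals.

    PQ is measured from P onset to QRS onset, PR from P onset to the R peak;
    both conventions are returned because published tables use either.
    PR/PQ are None when no P deflection is found.
    """

    p_onset: float | None
    p_peak: float | None
    qrs_onset: float
    r_peak: float
    qrs_offset: float

    @property
    def qrs_ms(self) -> float:
        return self.qrs_offset - self.qrs_onset

    @property
    def pq_ms(self) -> float | None:
        if self.p_onset is None:
            return None
        return self.qrs_onset - self.p_onset

    @property
    def pr_ms(self) -> float | None:
        if self.p_onset is None:
            return None
        return self.r_peak - self.p_onset


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(
    rec: EcgRecording,
    lead: str = "L1",
    min_rr_s: float = 0.02,
    refractory_frac: float = 0.4,
) -> np.ndarray:
    """Detect R-peak times with a band-pass/square/smooth energy detector.

    The chosen lead is band-pass filtered to the QRS energy band, squared and
    smoothed; peaks of the resulting envelope above an adaptive threshold are
    accepted subject to a refractory period of ``refractory_frac`` times the
    running median R-R interval, then each peak is refined to the local
    extremum of the filtered signal.

    Returns R times in seconds (possibly empty for flat input).
    """
    if rec.fs < 500:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for rodent ECG (need >= 500 Hz)"
        )
    if rec.duration < 2.0:
        raise ValueError("recording must be at least 2 s long")
    if lead not in rec.leads:
        raise KeyError(f"lead {lead!r} not in recording (has {list(rec.leads)})")
    x = rec.leads[lead]
    if np.ptp(x) == 0:
        warnings.warn("flat signal: no R peaks detected", stacklevel=2)
        return np.array([])

    fs = rec.fs
    hi = min(300.0, 0.45 * fs)
    sos = sps.butter(2, [15.0, hi], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, x)
    energy = band * band
    win = max(1, int(round(0.005 * fs)))  # 5 ms integration window
    energy = np.convolve(energy, np.ones(win) / win, mode="same")

    # Adaptive threshold: QRS complexes occupy a small duty cycle, so a high
    # percentile of the envelope tracks the R-peak energy level.
    thr = 0.15 * np.percentile(energy, 99.5)
    if thr <= 0:
        warnings.warn("degenerate signal: no R peaks detected", stacklevel=2)
        return np.array([])

    cand, _ = sps.find_peaks(energy, height=thr, distance=max(1, int(min_rr_s * fs)))
    if len(cand) < 2:
        return cand / fs

    # Refractory pass with a running median RR.
    accepted = [cand[0]]
    rr_hist: list[float] = []
    for c in cand[1:]:
        gap = c - accepted[-1]
        med = np.median(rr_hist[-11:]) if rr_hist else gap
        if gap < refractory_frac * med:
            # keep the larger of the competing envelope peaks
            if energy[c] > energy[accepted[-1]]:
                accepted[-1] = c
            continue
        rr_hist.append(gap)
        accepted.append(c)

    # Refine each detection to the extremum of |band| nearby (+-4 ms).
    half = max(1, int(round(0.004 * fs)))
    refined = []
    for c in accepted:
        lo, hi_ = max(0, c - half), min(len(band), c + half + 1)
        refined.append(lo + int(np.argmax(np.abs(band[lo:hi_]))))
    refined_arr = np.unique(np.asarray(refined))
    return refined_arr / fs


def rr_series(r_times: np.ndarray) -> RRSeries:
    """Convenience constructor for an :class:`RRSeries`."""
    return RRSeries(r_times=np.asarray(r_times, dtype=float))


# ---------------------------------------------------------------------------
# Irregular-beat screening
# ---------------------------------------------------------------------------

def flag_irregular(
    rr: RRSeries,
    low: float = 0.70,
    high: float = 1.30,
    window: int = 11,
) -> list[BeatFlag]:
    """Screen the R-R series for irregular beats.

    For each interval the moving average is the mean of up to ``window``
    neighbouring intervals centered on it, *excluding the interval itself*
    and truncated at the series edges.  An interval is suspect iff its ratio
    to that moving average is < ``low`` or > ``high``; the beat terminating
    the interval carries the flag.
    """
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    intervals = rr.rr_intervals
    if len(intervals) < 3:
        raise ValueError(f"need at least 3 R-R intervals, got {len(intervals)}")

    half = window // 2
    flags: list[BeatFlag] = []
    n = len(intervals)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        neigh = np.concatenate([intervals[lo:i], intervals[i + 1 : hi]])
        mavg = float(np.mean(neigh))
        ratio = float(intervals[i] / mavg)
        flags.append(
            BeatFlag(
                beat_index=i + 1,
                rr_ratio=ratio,
                suspect=(ratio < low or ratio > high),
            )
        )
    return flags


def suspect_events(flags: list[BeatFlag]) -> list[list[BeatFlag]]:
    """Group consecutive suspect intervals into single physical events.

    A premature beat produces one short interval and usually one long pause,
    i.e. two consecutive suspect intervals sharing a beat; these are merged
    so each event is counted once.
    """
    events: list[list[BeatFlag]] = []
    run: list[BeatFlag] = []
    for f in flags:
        if f.suspect:
            if run and f.beat_index != run[-1].beat_index + 1:
                events.append(run)
                run = []
            run.append(f)
        elif run:
            events.append(run)
            run = []
    if run:
        events.append(run)
    return events


# ---------------------------------------------------------------------------
# Ensemble averaging
# ---------------------------------------------------------------------------

def average_beats(
    rec: EcgRecording,
    rr: RRSeries,
    flags: list[BeatFlag] | None = None,
    n: int = 100,
    pre_frac: float = 0.45,
    post_frac: float = 0.55,
) -> AveragedBeat:
    """Ensemble-average up to ``n`` clean beats, aligned on R.

    The first ``n`` non-suspect beats are used (all available if fewer;
    ``n_averaged`` records the actual count).  The averaging window spans
    [-pre_frac, +post_frac] of the median R-R interval around each R peak.
    """
    if rr.n_beats < 3:
        raise ValueError("too few beats to average")
    rr_ms = rr.rr_intervals
    median_rr_ms = float(np.median(rr_ms))
    suspect_beats: set[int] = set()
    if flags is not None:
        suspect_beats = {f.beat_index for f in flags if f.suspect}

    fs = rec.fs
    pre = int(round(pre_frac * median_rr_ms / 1000.0 * fs))
    post = int(round(post_frac * median_rr_ms / 1000.0 * fs))
    n_samp = rec.n_samples

    usable: list[int] = []
    for b in range(1, rr.n_beats - 1):
        # a beat is clean when neither adjacent interval is suspect
        if b in suspect_beats or (b + 1) in suspect_beats:
            continue
        c = int(round(rr.r_times[b] * fs))
        if c - pre < 0 or c + post + 1 > n_samp:
            continue
        usable.append(b)
        if len(usable) >= n:
            break
    if len(usable) < 20:
        raise ValueError(
            f"only {len(usable)} usable beats; at least 20 required for averaging"
        )

    time_ms = (np.arange(-pre, post + 1) / fs) * 1000.0
    mean: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    for name, x in rec.leads.items():
        stack = np.empty((len(usable), pre + post + 1))
        for j, b in enumerate(usable):
            c = int(round(rr.r_times[b] * fs))
            stack[j] = x[c - pre : c + post + 1]
        mean[name] = stack.mean(axis=0)
        sd[name] = stack.std(axis=0, ddof=0)
    return AveragedBeat(
        time_ms=time_ms,
        mean=mean,
        sd=sd,
        n_averaged=len(usable),
        median_rr_ms=median_rr_ms,
        fs=fs,
    )


# ---------------------------------------------------------------------------
# Fiducial measurement
# ---------------------------------------------------------------------------

def _sustained_below(x: np.ndarray, idx: np.ndarray, min_run: int) -> np.ndarray:
    """Boolean mask of positions where ``x`` stays below threshold for
    ``min_run`` consecutive samples starting at each position (x is already
    thresholded to bool: True = below)."""
    if min_run <= 1:
        return x
    out = np.zeros_like(x)
    run = 0
    for i in range(len(x) - 1, -1, -1):
        run = run + 1 if x[i] else 0
        out[i] = run >= min_run
    return out


def measure_intervals(
    avg: AveragedBeat,
    lead: str = "L1",
    threshold_frac: float = 0.05,
    sustain_ms: float = 1.0,
    p_search_frac: float = 0.35,
    p_noise_mult: float = 3.0,
) -> FiducialSet:
    """Measure QRS, PR, and PQ on an averaged beat.

    The isoelectric baseline is the median of the segment [-0.40, -0.30] of
    the median R-R interval before R.  QRS onset/offset are the nearest
    points flanking R where ``|signal - baseline|`` falls below
    ``threshold_frac`` of the R amplitude and stays below for at least
    ``sustain_ms``.  The P peak is the largest absolute deflection in the
    pre-QRS search window; P onset uses the same threshold rule applied to
    the P amplitude.  When no P deflection clears the expected noise maximum
    over the search window (``noise_sd * sqrt(2 ln n)``) by ``p_noise_mult``
    baseline-noise SDs, PR and PQ are reported missing (QRS still returned).
    """
    t = avg.time_ms
    x = avg.mean[lead]
    if np.ptp(x) == 0:
        raise ValueError("flat averaged beat: no complex to measure")
    fs_ms = avg.fs / 1000.0  # samples per ms
    rrm = avg.median_rr_ms

    base_mask = (t >= -0.40 * rrm) & (t <= -0.30 * rrm)
    if not base_mask.any():
        raise ValueError("averaged-beat window too short for baseline segment")
    baseline = float(np.median(x[base_mask]))
    noise_sd = float(np.std(x[base_mask], ddof=0))

    r_idx = int(np.argmin(np.abs(t)))  # R is at t = 0 by construction
    r_amp = abs(x[r_idx] - baseline)
    if r_amp <= 0:
        raise ValueError("no R deflection at t = 0")
    dev = np.abs(x - baseline)
    # thresholds cannot resolve below the residual noise of the average
    noise_floor = 2.0 * noise_sd
    below = dev < max(threshold_frac * r_amp, noise_floor)
    min_run = max(1, int(round(sustain_ms * fs_ms)))

    # QRS offset: first sample after R where the signal stays below threshold.
    sust_fwd = _sustained_below(below, np.arange(len(x)), min_run)
    off_idx = None
    for i in range(r_idx + 1, len(x)):
        if sust_fwd[i]:
            off_idx = i
            break
    # QRS onset: first sample before R (scanning leftwards) with a sustained
    # below-threshold run ending at it.
    below_rev = below[::-1]
    sust_rev = _sustained_below(below_rev, np.arange(len(x)), min_run)[::-1]
    on_idx = None
    for i in range(r_idx - 1, -1, -1):
        if sust_rev[i]:
            on_idx = i
            break
    if on_idx is None or off_idx is None:
        raise ValueError("could not bracket the QRS complex")
    qrs_onset = float(t[on_idx])
    qrs_offset = float(t[off_idx])

    # P wave search window: before QRS onset, within the physiologic range.
    p_lo = qrs_onset - p_search_frac * rrm
    p_mask = (t >= p_lo) & (t <= qrs_onset - 2.0)
    p_onset = p_peak = None
    if p_mask.any():
        seg = dev[p_mask]
        k = int(np.argmax(seg))
        p_amp = float(seg[k])
        # the peak is a maximum over the window, so pure noise reaches
        # ~noise_sd * sqrt(2 ln n); require the configured margin above that
        n_win = max(int(p_mask.sum()), 2)
        p_thresh = (np.sqrt(2.0 * np.log(n_win)) + p_noise_mult) * max(noise_sd, 1e-12)
        if p_amp >= p_thresh:
            p_idx = np.flatnonzero(p_mask)[k]
            p_peak = float(t[p_idx])
            below_p = dev < max(threshold_frac * p_amp, noise_floor)
            sustp = _sustained_below(below_p[::-1], np.arange(len(x)), min_run)[::-1]
            for i in range(p_idx - 1, -1, -1):
                if sustp[i]:
                    p_onset = float(t[i])
                    break
    return FiducialSet(
        p_onset=p_onset,
        p_peak=p_peak,
        qrs_onset=qrs_onset,
        r_peak=0.0,
        qrs_offset=qrs_offset,
    )


# ---------------------------------------------------------------------------
# Premature-beat classification
# ---------------------------------------------------------------------------

def _single_beat_qrs_width(
    x: np.ndarray,
    fs: float,
    center_idx: int,
    baseline: float,
    half_window_ms: float,
    level_frac: float = 0.25,
) -> float:
    """Width (ms) of the QRS around ``center_idx`` at ``level_frac`` of the
    beat's own R amplitude, after 1 ms smoothing.  Robust at single-beat SNR
    (unlike the 5% rule used on noise-suppressed averaged beats)."""
    half = int(round(half_window_ms / 1000.0 * fs))
    lo, hi = max(0, center_idx - half), min(len(x), center_idx + half + 1)
    seg = x[lo:hi]
    k = max(1, int(round(0.001 * fs)))
    seg = np.convolve(seg, np.ones(k) / k, mode="same")
    dev = np.abs(seg - baseline)
    r_amp = dev.max()
    if r_amp <= 0:
        return 0.0
    above = np.flatnonzero(dev >= level_frac * r_amp)
    return (above[-1] - above[0]) / fs * 1000.0


def classify_flagged(
    rec: EcgRecording,
    rr: RRSeries,
    flags: list[BeatFlag],
    template: AveragedBeat | None,
    lead: str = "L1",
    width_ratio_thresh: float = 1.5,
    p_score_thresh: float = 0.6,
    low: float = 0.70,
    high: float = 1.30,
) -> list[BeatFlag]:
    """Classify suspect premature beats as APB, VPB, or JPB.

    For each merged suspect event containing a short interval, the premature
    beat's QRS width is measured on the single beat; a width ratio versus the
    template above ``width_ratio_thresh`` gives VPB.  Otherwise a P-wave
    presence score -- the maximum normalized cross-correlation of the
    pre-QRS window against the template P wave, searched over the physiologic
    PQ range -- at or above ``p_score_thresh`` gives APB, else JPB.  Events
    with only a long pause (no premature partner) are left unclassified.

    Returns the flag list with ``beat_class`` filled in (mutated in place and
    returned).  Without a template every suspect beat is unclassified.
    """
    events = suspect_events(flags)
    if not events:
        return flags
    if template is None or template.n_averaged < 20:
        for ev in events:
            for f in ev:
                f.beat_class = "unclassified"
        return flags

    fs = rec.fs
    x = rec.leads[lead]
    fid = measure_intervals(template, lead=lead)
    # the width window must cover a 2.5x-wide ectopic QRS yet exclude the T
    half_win_ms = 1.6 * fid.qrs_ms
    tm = template.time_ms
    tpl_base = float(
        np.median(
            template.mean[lead][
                (tm >= -0.40 * template.median_rr_ms)
                & (tm <= -0.30 * template.median_rr_ms)
            ]
        )
    )
    tpl_width = _single_beat_qrs_width(
        template.mean[lead],
        template.fs,
        int(np.argmin(np.abs(tm))),
        tpl_base,
        half_window_ms=half_win_ms,
    )

    # Template P segment (relative to R), for the presence score.
    have_p = fid.p_onset is not None
    if have_p:
        p_lo_ms = fid.p_onset - 2.0
        p_hi_ms = fid.qrs_onset - 1.0
        tm = template.time_ms
        p_mask = (tm >= p_lo_ms) & (tm <= p_hi_ms)
        tpl_p = template.mean[lead][p_mask]
        tpl_p = tpl_p - tpl_p.mean()
        tpl_norm = np.linalg.norm(tpl_p)

    rrm = template.median_rr_ms

    for ev in events:
        short = [f for f in ev if f.rr_ratio < low]
        if not short:
            for f in ev:
                f.beat_class = "unclassified"
            continue
        prem = short[0]  # beat terminating the short interval
        b = prem.beat_index
        c = int(round(rr.r_times[b] * fs))

        # A premature beat's own pre-beat segment often overlaps the previous
        # T wave, so the template's isoelectric level is the stable baseline
        # (the generator and short anesthetized recordings have no drift).
        width = _single_beat_qrs_width(
            x, fs, c, tpl_base, half_window_ms=half_win_ms
        )
        if tpl_width > 0 and width / tpl_width > width_ratio_thresh:
            cls = "VPB"
        elif have_p and tpl_norm > 0:
            # The pre-QRS window of a premature beat overlaps the previous
            # beat's T wave, which mimics a P deflection; subtract the
            # previous beat's template contribution before scoring.
            r_prev_s = rr.r_times[b - 1] if b >= 1 else None
            pq = fid.pq_ms if fid.pq_ms is not None else 0.3 * rrm
            best = -1.0
            seg_len = len(tpl_p)
            for lag_ms in np.arange(-0.5 * pq, 0.5 * pq + 0.25, 0.5):
                start = c + int(round((p_lo_ms + lag_ms) / 1000.0 * fs))
                stop = start + seg_len
                if start < 0 or stop > len(x):
                    continue
                w = x[start:stop].astype(float).copy()
                if r_prev_s is not None:
                    tau_ms = (np.arange(start, stop) / fs - r_prev_s) * 1000.0
                    prev = np.interp(
                        tau_ms, tm, template.mean[lead],
                        left=tpl_base, right=tpl_base,
                    )
                    w -= prev - tpl_base
                w -= w.mean()
                nw = np.linalg.norm(w)
                if nw == 0:
                    continue
                corr = float(np.dot(w, tpl_p) / (nw * tpl_norm))
                # scale-free correlation saturates on tiny residuals, so the
                # score is gated by the matched amplitude (least-squares
                # scale of the template P in the window, ~1 for a real P)
                alpha = float(np.dot(w, tpl_p) / (tpl_norm * tpl_norm))
                best = max(best, corr * min(1.0, max(alpha, 0.0)))
            cls = "APB" if best >= p_score_thresh else "JPB"
        else:
            cls = "JPB"
        for f in ev:
            f.beat_class = cls
    return flags
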