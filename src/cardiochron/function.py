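"""Systolic, diastolic, and stress-response cardiac metrics.

Covers the standard echocardiography/MRI-derived quantities: stroke volume,
ejection fraction, cardiac output (and body-weight-normalized output), the
biplane area-length atrial volume, transmitral E/A peak analysis with an
explicit separability verdict, and percent-change deltas for the dobutamine
stress test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "FunctionMetrics",
    "DopplerTrace",
    "DopplerResult",
    "StressDelta",
    "function_metrics",
    "biplane_la_volume",
    "la_volume_from_views",
    "ea_analysis",
    "stress_delta",
    "DOBUTAMINE_DOSE_MG_PER_KG",
    "DOBUTAMINE_WAIT_MIN",
]

# Stress-protocol configuration defaults (intraperitoneal dobutamine).
DOBUTAMINE_DOSE_MG_PER_KG = 1.5
DOBUTAMINE_WAIT_MIN = 6.0


@dataclass
class FunctionMetrics:
    """Left-ventricular function metrics with fixed units.

    edv/esv/sv in ul, ef in %, hr in bpm, co in ml/min, body weight in g,
    nco in ml/min/g.
    """

    edv: float
    esv: float
    sv: float
    ef: float
    hr: float
    co: float
    body_weight: float
    nco: float
    wall_thickness: float | None = None  # mm, optional

    def as_dict(self) -> dict[str, float]:
        d = {
            "edv_ul": self.edv,
            "esv_ul": self.esv,
            "sv_ul": self.sv,
            "ef_pct": self.ef,
            "hr_bpm": self.hr,
            "co_ml_min": self.co,
            "bw_g": self.body_weight,
            "nco_ml_min_g": self.nco,
        }
        if self.wall_thickness is not None:
            d["wall_thickness_mm"] = self.wall_thickness
        return d


def function_metrics(
    edv: float,
    esv: float,
    hr: float,
    body_weight: float,
    wall_thickness: float | None = None,
) -> FunctionMetrics:
    """Derive SV/EF/CO/nCO from end-diastolic and end-systolic volumes.

    sv = edv - esv (ul); ef = 100 * sv / edv (%); co = sv * hr / 1000
    (ml/min); nco = co / body_weight (ml/min/g).

    Raises ``ValueError`` on nonpositive inputs or esv > edv (the latter is
    the signature of a segmentation error upstream).
    """
    if edv <= 0:
        raise ValueError(f"edv must be positive, got {edv}")
    if esv < 0:
        raise ValueError(f"esv must be non-negative, got {esv}")
    if esv > edv:
        raise ValueError(
            f"esv ({esv}) > edv ({edv}): likely segmentation error, rejected"
        )
    if hr <= 0:
        raise ValueError(f"hr must be positive, got {hr}")
    if body_weight <= 0:
        raise ValueError(f"body_weight must be positive, got {body_weight}")
    sv = edv - esv
    ef = 100.0 * sv / edv
    co = sv * hr / 1000.0
    return FunctionMetrics(
        edv=edv, esv=esv, sv=sv, ef=ef, hr=hr, co=co,
        body_weight=body_weight, nco=co / body_weight,
        wall_thickness=wall_thickness,
    )


def biplane_la_volume(area_2ch: float, area_4ch: float, long_axis: float) -> float:
    """Biplane area-length atrial volume, in ul.

    V = (8 / 3 pi) * A_2ch * A_4ch / L with areas in mm^2 and the long-axis
    length in mm (1 mm^3 = 1 ul).  For a true ellipsoid this reproduces
    (4/3) pi a b c exactly.
    """
    if area_2ch <= 0 or area_4ch <= 0:
        raise ValueError("chamber areas must be positive")
    if long_axis <= 0:
        raise ValueError("long-axis length must be positive")
    return (8.0 / (3.0 * np.pi)) * area_2ch * area_4ch / long_axis


def la_volume_from_views(
    area_2ch: float,
    area_4ch: float,
    length_2ch: float,
    length_4ch: float,
    length_strategy: str = "min",
) -> float:
    """Biplane volume when each view provides its own long-axis length.

    ``length_strategy`` picks the length used: "min" (default), "max", or
    "mean" of the two view lengths.
    """
    if length_strategy == "min":
        L = min(length_2ch, length_4ch)
    elif length_strategy == "max":
        L = max(length_2ch, length_4ch)
    elif length_strategy == "mean":
        L = 0.5 * (length_2ch + length_4ch)
    else:
        raise ValueError(f"unknown length_strategy {length_strategy!r}")
    return biplane_la_volume(area_2ch, area_4ch, L)


@dataclass
class DopplerTrace:
    """Sampled transmitral velocity trace (mm/s vs s)."""

    time: np.ndarray
    velocity: np.ndarray
    hr: float | None = None  # bpm, if known
    cycle_starts: np.ndarray | None = None  # s, if known
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.time.shape != self.velocity.shape:
            raise ValueError("time and velocity must have equal length")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass
class DopplerResult:
    """E/A analysis outcome.  ``ea_ratio`` is present iff ``separable``."""

    e_peak: float | None
    a_peak: float | None
    separable: bool
    n_cycles: int
    n_separable: int

    @property
    def ea_ratio(self) -> float | None:
        if not self.separable or not self.a_peak:
            return None
        return self.e_peak / self.a_peak


def _estimate_period(v: np.ndarray, fs: float) -> float:
    """Cycle length (s) from the autocorrelation of the velocity trace."""
    x = v - v.mean()
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
    min_lag = max(2, int(0.05 * fs))
    peaks, _ = sps.find_peaks(ac[min_lag:])
    if len(peaks) == 0:
        raise ValueError("could not estimate a cardiac period from the trace")
    # the E-A spacing also produces an autocorrelation peak, but only the
    # full cycle aligns every pulse; take the earliest near-maximal peak
    vals = ac[min_lag:][peaks]
    best = peaks[vals >= 0.9 * vals.max()][0]
    return (min_lag + best) / fs


def ea_analysis(
    trace: DopplerTrace,
    prominence_frac: float = 0.20,
    valley_frac: float = 0.80,
    min_separable_frac: float = 0.80,
) -> DopplerResult:
    """Measure E and A inflow peaks with a separability verdict.

    Cycles are segmented (using known cycle starts / heart rate when the
    trace carries them, otherwise an autocorrelation period estimate with
    boundaries placed at the low-velocity systolic phase).  A cycle is
    *separable* when it shows two peaks, each with prominence at least
    ``prominence_frac`` of the larger peak, and the valley between them no
    higher than ``valley_frac`` of the smaller peak.  E/A is only reported
    when at least ``min_separable_frac`` of cycles are separable, mirroring
    the practice of quantifying E/A only for clearly separable inflow peaks.
    """
    v = trace.velocity
    if len(v) == 0 or np.all(v == 0):
        raise ValueError("empty or all-zero Doppler trace")
    fs = trace.fs

    if trace.cycle_starts is not None and len(trace.cycle_starts) >= 3:
        bounds = np.round(np.asarray(trace.cycle_starts) * fs).astype(int)
        bounds = bounds[(bounds >= 0) & (bounds < len(v))]
        segments = [
            (bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
        ]
    else:
        T = 60.0 / trace.hr if trace.hr else _estimate_period(v, fs)
        per = int(round(T * fs))
        if per < 4:
            raise ValueError("cardiac period too short for the sampling rate")
        # phase the boundaries into the low-velocity (systolic) stretch
        n_cyc = len(v) // per
        if n_cyc < 3:
            raise ValueError("need at least 3 cardiac cycles in the trace")
        folded = v[: n_cyc * per].reshape(n_cyc, per).mean(axis=0)
        phase = int(np.argmin(np.convolve(folded, np.ones(3) / 3, mode="same")))
        segments = [
            (phase + i * per, phase + (i + 1) * per)
            for i in range(n_cyc)
            if phase + (i + 1) * per <= len(v)
        ]
    if len(segments) < 3:
        raise ValueError("need at least 3 cardiac cycles in the trace")

    e_vals, a_vals = [], []
    n_sep = 0
    for lo, hi in segments:
        seg = v[lo:hi]
        vmax = seg.max()
        if vmax <= 0:
            continue
        peaks, props = sps.find_peaks(seg, prominence=1e-9)
        if len(peaks) < 2:
            continue
        order = np.argsort(props["prominences"])[::-1][:2]
        two = np.sort(peaks[order])
        pk1, pk2 = seg[two[0]], seg[two[1]]
        larger, smaller = max(pk1, pk2), min(pk1, pk2)
        prom = props["prominences"][order]
        if prom.min() < prominence_frac * larger:
            continue
        valley = seg[two[0] : two[1] + 1].min()
        if valley > valley_frac * smaller:
            continue
        n_sep += 1
        e_vals.append(pk1)  # earlier peak = early (E) filling
        a_vals.append(pk2)  # later peak = atrial (A) filling

    n_cycles = len(segments)
    separable = n_sep >= min_separable_frac * n_cycles and n_sep > 0
    if not separable:
        return DopplerResult(
            e_peak=None, a_peak=None, separable=False,
            n_cycles=n_cycles, n_separable=n_sep,
        )
    return DopplerResult(
        e_peak=float(np.mean(e_vals)),
        a_peak=float(np.mean(a_vals)),
        separable=True,
        n_cycles=n_cycles,
        n_separable=n_sep,
    )


@dataclass
class StressDelta:
    """Percent change of each metric from unstressed baseline."""

    baseline: FunctionMetrics
    stressed: FunctionMetrics
    deltas: dict[str, float]  # metric name -> % change


def stress_delta(baseline: FunctionMetrics, stressed: FunctionMetrics) -> StressDelta:
    """Percent change from baseline for every strictly positive baseline
    metric: delta = 100 * (stressed - baseline) / baseline.

    Metrics with a zero baseline are omitted with a warning.
    """
    deltas: dict[str, float] = {}
    b, s = baseline.as_dict(), stressed.as_dict()
    for key in b:
        if key not in s:
            continue
        if b[key] == 0:
            warnings.warn(
                f"baseline {key} is zero; delta omitted", stacklevel=2
            )
            continue
        deltas[key] = 100.0 * (s[key] - b[key]) / b[key]
    return StressDelta(baseline=baseline, stressed=stressed, deltas=deltas)
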