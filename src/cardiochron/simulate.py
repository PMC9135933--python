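"""Synthetic ground-truth generators: ECG, transmitral Doppler, cohorts.

Every analysis stage in the package can be exercised against known truth:

* :func:`simulate_ecg` renders multi-lead rodent ECG as a sum of Gaussian
  waves (P, Q, R, S, T) per beat on a stochastic R-R process, with injectable
  atrial/ventricular/junctional premature beats and full ground-truth
  annotations (beat times, class labels, template fiducials).
* :func:`simulate_doppler` renders transmitral inflow as two Gaussian
  velocity pulses (E then A) per cardiac cycle whose separation shrinks as
  heart rate grows, reproducing E/A fusion at high rates.
* :func:`simulate_cohort` draws cross-sectional cohort tables from a
  standardized (z-scale) linear age/sex model, mapped back to physical
  units, plus Poisson arrhythmia counts.

All generators are deterministic given a seed: one user seed is split into
independent substreams per component (R-R process, event placement, noise),
so e.g. adding noise never perturbs beat placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ecg import EcgRecording
from .function import DopplerTrace

__all__ = [
    "Wave",
    "SpeciesEcgParams",
    "ArrhythmiaSpec",
    "GroundTruth",
    "OutcomeSpec",
    "CountModel",
    "CohortDesign",
    "mouse_ecg_params",
    "nmr_ecg_params",
    "default_mouse_design",
    "default_nmr_design",
    "scaled_qrs_params",
    "noise_for_snr",
    "simulate_ecg",
    "simulate_doppler",
    "simulate_cohort",
]


@dataclass
class Wave:
    """One Gaussian wave component: ``amp * exp(-(t-center)^2 / 2 sigma^2)``.

    ``center`` is the offset from the R peak in ms, ``sigma`` the Gaussian
    width in ms, ``amp`` the amplitude in mV.
    """

    amp: float
    center: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"wave sigma must be positive, got {self.sigma}")


@dataclass
class SpeciesEcgParams:
    """Species-specific ECG morphology and rhythm parameters.

    Wave onset/offset ground truth uses the center +- 2 sigma convention;
    QRS onset = Q onset and QRS offset = S offset.  ``lead_weights`` projects
    each wave group (P, QRS, T) onto the three leads.
    """

    species: str
    hr_mean: float  # bpm
    hr_sd: float  # bpm, beat-to-beat
    waves: dict[str, Wave]  # keys P, Q, R, S, T
    resp_depth: float = 0.03  # fractional R-R modulation
    resp_rate: float = 60.0  # breaths/min
    lead_weights: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "P": (1.0, 0.8, 0.6),
            "QRS": (1.0, 0.9, 0.5),
            "T": (1.0, 0.7, 0.8),
        }
    )

    def __post_init__(self) -> None:
        if self.hr_mean <= 0:
            raise ValueError("hr_mean must be positive")
        if self.hr_sd < 0:
            raise ValueError("hr_sd must be non-negative")
        missing = {"P", "Q", "R", "S", "T"} - set(self.waves)
        if missing:
            raise ValueError(f"missing waves: {sorted(missing)}")
        w = self.waves
        order = [w["P"].center, w["Q"].center, w["R"].center, w["S"].center, w["T"].center]
        if not (order[0] < order[1] < order[2] == 0.0 < order[3] < order[4]):
            raise ValueError(
                "wave centers must satisfy P < Q < 0 = R < S < T (ms from R)"
            )

    # -- ground-truth template fiducials (ms relative to R) ---------------
    @property
    def true_p_onset(self) -> float:
        return self.waves["P"].center - 2 * self.waves["P"].sigma

    @property
    def true_qrs_onset(self) -> float:
        return self.waves["Q"].center - 2 * self.waves["Q"].sigma

    @property
    def true_qrs_offset(self) -> float:
        return self.waves["S"].center + 2 * self.waves["S"].sigma

    @property
    def true_qrs_ms(self) -> float:
        return self.true_qrs_offset - self.true_qrs_onset

    @property
    def true_pq_ms(self) -> float:
        return self.true_qrs_onset - self.true_p_onset

    @property
    def true_pr_ms(self) -> float:
        return 0.0 - self.true_p_onset


def mouse_ecg_params(**overrides) -> SpeciesEcgParams:
    """Anesthetized-mouse defaults: heart rate ~550 bpm, QRS ~9 ms."""
    kw = dict(
        species="mouse",
        hr_mean=550.0,
        hr_sd=15.0,
        waves={
            "P": Wave(0.15, -30.0, 2.5),
            "Q": Wave(-0.20, -3.2, 0.7),
            "R": Wave(1.00, 0.0, 1.0),
            "S": Wave(-0.30, 3.2, 0.7),
            "T": Wave(0.25, 25.0, 6.0),
        },
        resp_depth=0.03,
        resp_rate=65.0,
    )
    kw.update(overrides)
    return SpeciesEcgParams(**kw)


def nmr_ecg_params(**overrides) -> SpeciesEcgParams:
    """Anesthetized naked mole-rat defaults: heart rate ~240 bpm, QRS ~12 ms."""
    kw = dict(
        species="nmr",
        hr_mean=240.0,
        hr_sd=8.0,
        waves={
            "P": Wave(0.12, -45.0, 3.0),
            "Q": Wave(-0.25, -4.0, 1.0),
            "R": Wave(0.90, 0.0, 1.2),
            "S": Wave(-0.28, 4.0, 1.0),
            "T": Wave(0.20, 60.0, 12.0),
        },
        resp_depth=0.03,
        resp_rate=45.0,
    )
    kw.update(overrides)
    return SpeciesEcgParams(**kw)


def scaled_qrs_params(base: SpeciesEcgParams, qrs_ms: float) -> SpeciesEcgParams:
    """Return params with the QRS complex rescaled to a target true duration.

    Conduction slowing widens the whole complex, so Q, R, and S centers and
    widths are scaled together (self-similar shape); P and T are untouched.
    The ground-truth QRS (S offset - Q onset, center +- 2 sigma convention)
    of the result equals ``qrs_ms``.
    """
    if qrs_ms <= 0:
        raise ValueError("target QRS duration must be positive")
    scale = qrs_ms / base.true_qrs_ms
    waves = {k: Wave(v.amp, v.center, v.sigma) for k, v in base.waves.items()}
    for nm in ("Q", "R", "S"):
        w = waves[nm]
        waves[nm] = Wave(w.amp, w.center * scale, w.sigma * scale)
    return SpeciesEcgParams(
        species=base.species,
        hr_mean=base.hr_mean,
        hr_sd=base.hr_sd,
        waves=waves,
        resp_depth=base.resp_depth,
        resp_rate=base.resp_rate,
        lead_weights=base.lead_weights,
    )


@dataclass
class ArrhythmiaSpec:
    """Premature-beat injection model.

    Per-beat event probabilities per class; the coupling (prematurity) of an
    injected beat is drawn uniformly from ``prematurity`` as a fraction of
    the mean R-R interval.  VPBs are rendered with all QRS widths (and Q/S
    offsets) scaled by ``vpb_width_mult`` and no P wave, followed by a fully
    compensatory pause; APBs keep their P wave and normal QRS; JPBs lack the
    P wave with a normal QRS; APB/JPB reset the rhythm.
    """

    apb_prob: float = 0.0
    vpb_prob: float = 0.0
    jpb_prob: float = 0.0
    prematurity: tuple[float, float] = (0.45, 0.65)
    vpb_width_mult: float = 2.5
    pause: dict[str, str] = field(
        default_factory=lambda: {
            "APB": "resetting",
            "VPB": "compensatory",
            "JPB": "resetting",
        }
    )

    def __post_init__(self) -> None:
        probs = (self.apb_prob, self.vpb_prob, self.jpb_prob)
        if any(p < 0 for p in probs):
            raise ValueError("event probabilities must be non-negative")
        if sum(probs) > 0.2:
            raise ValueError(
                "total event probability > 0.2 breaks the template-averaging "
                f"assumption (got {sum(probs):.3f})"
            )
        lo, hi = self.prematurity
        if not (0 < lo <= hi <= 0.7):
            raise ValueError("prematurity range must lie within (0, 0.7]")

    @property
    def total_prob(self) -> float:
        return self.apb_prob + self.vpb_prob + self.jpb_prob


@dataclass
class GroundTruth:
    """Generator-side truth for one simulated recording."""

    r_times: np.ndarray  # s
    labels: list[str]  # per beat: normal | APB | VPB | JPB
    fiducials: dict[str, float]  # template landmarks, ms relative to R
    intervals: dict[str, float]  # qrs_ms, pr_ms, pq_ms

    @property
    def n_beats(self) -> int:
        return len(self.r_times)

    def to_jsonable(self) -> dict:
        return {
            "r_times_s": [float(t) for t in self.r_times],
            "labels": list(self.labels),
            "fiducials_ms": {k: float(v) for k, v in self.fiducials.items()},
            "intervals_ms": {k: float(v) for k, v in self.intervals.items()},
        }


def noise_for_snr(params: SpeciesEcgParams, snr_db: float, fs: float = 2000.0) -> float:
    """Noise SD (mV) that yields a given signal-to-noise ratio.

    SNR is the standard power ratio: ``10 log10(P_signal / P_noise)`` with
    ``P_signal`` the mean squared voltage of the clean lead-I trace
    (estimated from a short noise-free simulation).
    """
    rec, _ = simulate_ecg(params, duration=10.0, noise_sd=0.0, fs=fs, seed=0)
    rms = float(np.sqrt(np.mean(rec.leads["L1"] ** 2)))
    return rms / 10 ** (snr_db / 20.0)


def _render_beat(
    out: np.ndarray,
    time_s: np.ndarray,
    fs: float,
    t_beat: float,
    params: SpeciesEcgParams,
    label: str,
    vpb_width_mult: float,
) -> None:
    """Add one beat's waves into ``out`` (shape: n_samples x 3 leads)."""
    groups = {"P": ("P",), "QRS": ("Q", "R", "S"), "T": ("T",)}
    for group, names in groups.items():
        if group == "P" and label in ("VPB", "JPB"):
            continue  # ectopic/junctional beats have no (visible) P wave
        wts = params.lead_weights[group]
        for nm in names:
            w = params.waves[nm]
            center = w.center
            sigma = w.sigma
            if group == "QRS" and label == "VPB":
                center *= vpb_width_mult
                sigma *= vpb_width_mult
            c_s = t_beat + center / 1000.0
            half_s = 4.0 * sigma / 1000.0
            lo = max(0, int(math.floor((c_s - half_s) * fs)))
            hi = min(len(out), int(math.ceil((c_s + half_s) * fs)) + 1)
            if lo >= hi:
                continue
            tt = time_s[lo:hi]
            # computed in ms to keep sigma units transparent
            g = w.amp * np.exp(-(((tt - c_s) * 1000.0) ** 2) / (2 * sigma**2))
            for li in range(3):
                out[lo:hi, li] += wts[li] * g


def simulate_ecg(
    params: SpeciesEcgParams,
    arr: ArrhythmiaSpec | None = None,
    duration: float = 300.0,
    noise_sd: float = 0.0,
    fs: float = 2000.0,
    seed: int | None = None,
) -> tuple[EcgRecording, GroundTruth]:
    """Simulate a multi-lead ECG recording with ground truth.

    Parameters
    ----------
    params
        Species morphology/rhythm parameters.
    arr
        Premature-beat injection spec (default: no events).
    duration
        Recording length in seconds.
    noise_sd
        White Gaussian noise SD per sample per lead, in mV.
    fs
        Sampling rate in Hz (>= 1 kHz).
    seed
        Required RNG seed; equal seeds give bit-identical output.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs < 1000:
        raise ValueError("sampling rate must be >= 1 kHz for rodent ECG")
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    if arr is None:
        arr = ArrhythmiaSpec()

    ss = np.random.SeedSequence(seed)
    rng_rr, rng_ev, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    mean_rr = 60.0 / params.hr_mean  # s
    f_resp = params.resp_rate / 60.0  # Hz

    def next_rr(t_now: float) -> float:
        hr = params.hr_mean + params.hr_sd * rng_rr.standard_normal()
        hr = max(hr, 0.3 * params.hr_mean)
        rr = 60.0 / hr
        return rr * (1.0 + params.resp_depth * math.sin(2 * math.pi * f_resp * t_now))

    # margin keeps every beat's full wave window inside the recording
    margin = (params.waves["T"].center + 4 * params.waves["T"].sigma) / 1000.0 + 0.02
    beats: list[tuple[float, str]] = [(max(mean_rr, 0.06), "normal")]
    probs = (arr.apb_prob, arr.vpb_prob, arr.jpb_prob)
    while True:
        t_cur, label_cur = beats[-1]
        if t_cur >= duration - margin:
            beats.pop()
            break
        # decide the class of the next beat (no consecutive events)
        nxt = "normal"
        if label_cur == "normal" and len(beats) >= 2 and arr.total_prob > 0:
            u = rng_ev.random()
            if u < probs[0]:
                nxt = "APB"
            elif u < probs[0] + probs[1]:
                nxt = "VPB"
            elif u < probs[0] + probs[1] + probs[2]:
                nxt = "JPB"
        if nxt == "normal":
            beats.append((t_cur + next_rr(t_cur), "normal"))
        else:
            frac = rng_ev.uniform(*arr.prematurity)
            t_ev = t_cur + frac * mean_rr
            beats.append((t_ev, nxt))
            if arr.pause.get(nxt, "resetting") == "compensatory":
                t_post = t_cur + 2.0 * mean_rr  # RR_pre + RR_post = 2 * mean RR
            else:
                t_post = t_ev + next_rr(t_ev)
            beats.append((t_post, "normal"))

    n = int(round(duration * fs))
    time_s = np.arange(n) / fs
    voltages = np.zeros((n, 3))
    for t_beat, label in beats:
        _render_beat(voltages, time_s, fs, t_beat, params, label, arr.vpb_width_mult)
    if noise_sd > 0:
        voltages = voltages + rng_noise.normal(0.0, noise_sd, size=voltages.shape)

    breath = 0.5 * np.sin(2 * math.pi * f_resp * time_s)
    temp = np.full(n, 37.0 if params.species == "mouse" else 34.0)

    rec = EcgRecording(
        fs=fs,
        leads={"L1": voltages[:, 0], "L2": voltages[:, 1], "L3": voltages[:, 2]},
        species=params.species,
        aux={"breath": breath, "temp_C": temp},
        meta={"seed": int(seed), "noise_sd_mV": float(noise_sd)},
    )
    gt = GroundTruth(
        r_times=np.array([b[0] for b in beats]),
        labels=[b[1] for b in beats],
        fiducials={
            "p_onset": params.true_p_onset,
            "p_peak": params.waves["P"].center,
            "qrs_onset": params.true_qrs_onset,
            "r_peak": 0.0,
            "qrs_offset": params.true_qrs_offset,
        },
        intervals={
            "qrs_ms": params.true_qrs_ms,
            "pr_ms": params.true_pr_ms,
            "pq_ms": params.true_pq_ms,
        },
    )
    return rec, gt


# ---------------------------------------------------------------------------
# Doppler inflow
# ---------------------------------------------------------------------------

def simulate_doppler(
    e_peak: float,
    a_peak: float,
    hr: float,
    noise_sd: float = 0.0,
    duration: float = 5.0,
    fs: float = 1000.0,
    e_frac: float = 0.35,
    a_offset_s: float = 0.035,
    sigma_e_s: float = 0.014,
    sigma_a_s: float = 0.010,
    seed: int | None = None,
) -> DopplerTrace:
    """Simulate a transmitral Doppler velocity trace.

    Per cardiac cycle of length ``T = 60/hr`` two Gaussian pulses are placed:
    E at ``e_frac * T`` after the cycle start and A at ``T - a_offset_s``
    before the next cycle, so their separation ``(1 - e_frac) * T -
    a_offset_s`` shrinks as heart rate grows and the peaks fuse above a
    geometric threshold (roughly when the separation drops below the summed
    pulse widths).
    """
    if e_peak < 0 or a_peak < 0:
        raise ValueError("peak velocities must be non-negative")
    if hr <= 0:
        raise ValueError("heart rate must be positive")
    if seed is None:
        seed = 0
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    T = 60.0 / hr
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    v = np.zeros(n)
    starts = []
    k = 0
    while (k + 1) * T <= duration:
        s = k * T
        starts.append(s)
        ce = s + e_frac * T
        ca = s + T - a_offset_s
        v += e_peak * np.exp(-((t - ce) ** 2) / (2 * sigma_e_s**2))
        v += a_peak * np.exp(-((t - ca) ** 2) / (2 * sigma_a_s**2))
        k += 1
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)
    return DopplerTrace(
        time=t,
        velocity=v,
        hr=hr,
        cycle_starts=np.asarray(starts),
        meta={
            "e_peak": float(e_peak),
            "a_peak": float(a_peak),
            "e_frac": e_frac,
            "a_offset_s": a_offset_s,
            "sigma_e_s": sigma_e_s,
            "sigma_a_s": sigma_a_s,
            "seed": int(seed),
        },
    )


# ---------------------------------------------------------------------------
# Cross-sectional cohorts
# ---------------------------------------------------------------------------

@dataclass
class OutcomeSpec:
    """Generative model for one outcome, on the standardized (z) scale.

    ``y_z = beta_age * z + beta_age2 * z^2 + beta_sex * male
    + beta_age_sex * z * male + beta_age2_sex * z^2 * male + sigma * eps``
    with ``z`` the population-standardized age and ``male`` coded 0/1
    (female = 0); the physical value is ``mean + sd * y_z``.  When ``sigma``
    is None it is chosen so the total z-scale variance is ~1 (floored at
    0.2), which makes sample-standardized regression recover ``beta_age``.
    """

    mean: float
    sd: float
    beta_age: float = 0.0
    beta_age2: float = 0.0
    beta_sex: float = 0.0
    beta_age_sex: float = 0.0
    beta_age2_sex: float = 0.0
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("outcome scale sd must be positive")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("residual sigma must be positive")

    def resolved_sigma(self) -> float:
        if self.sigma is not None:
            return self.sigma
        # uniform-z: Var(z)=1, Var(z^2)=0.8, Var(male)=0.25 (balanced-ish)
        ba = self.beta_age + 0.5 * self.beta_age_sex
        ba2 = self.beta_age2 + 0.5 * self.beta_age2_sex
        explained = ba**2 + 0.8 * ba2**2 + 0.25 * self.beta_sex**2
        return math.sqrt(max(1.0 - explained, 0.04))


@dataclass
class CountModel:
    """Poisson event-count model: ``lambda = exp(log_base + beta_age * z +
    beta_sex * male)`` expected events per recording."""

    log_base: float
    beta_age: float = 0.0
    beta_sex: float = 0.0

    def rate(self, age_z: np.ndarray, male: np.ndarray) -> np.ndarray:
        return np.exp(self.log_base + self.beta_age * age_z + self.beta_sex * male)


@dataclass
class CohortDesign:
    """Design of one species' cross-sectional cohort."""

    species: str
    n_female: int
    n_male: int
    age_range: tuple[float, float]  # years
    outcomes: dict[str, OutcomeSpec]
    arrhythmia: dict[str, CountModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_female < 1 or self.n_male < 1:
            raise ValueError("need at least one animal per sex group")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")


def default_mouse_design(**overrides) -> CohortDesign:
    """Mouse cohort defaults: study-sized groups, published effect sizes.

    Standardized betas follow the published cross-sectional trends (e.g.
    QRS duration beta_age = 0.48; heart rate 0.46; EF -0.44; E/A -0.64;
    quadratic body-weight/fat trajectories).  Arrhythmia counts rise with
    age, atrial premature beats most prevalent.
    """
    kw = dict(
        species="mouse",
        n_female=62,
        n_male=70,
        age_range=(0.25, 2.5),
        outcomes={
            # body-weight trajectory coefficients are native-unit (g);
            # divide by the 5 g scale sd for the z-scale generator
            "body_weight_g": OutcomeSpec(30.0, 5.0, beta_age=0.62, beta_age2=-0.478,
                                         beta_age_sex=-0.106, beta_age2_sex=0.092,
                                         beta_sex=0.16),
            "hr_bpm": OutcomeSpec(520.0, 60.0, beta_age=0.46),
            "qrs_ms": OutcomeSpec(9.5, 1.3, beta_age=0.48),
            "pr_ms": OutcomeSpec(38.0, 4.0, beta_age=0.53, beta_age_sex=0.06),
            "pq_ms": OutcomeSpec(33.0, 4.0, beta_age=0.48, beta_age_sex=0.04),
            "edv_ul": OutcomeSpec(60.0, 10.0, beta_age=0.57),
            "esv_ul": OutcomeSpec(25.0, 7.0, beta_age=0.53),
            "ef_pct": OutcomeSpec(58.0, 7.0, beta_age=-0.44),
            "ea_ratio": OutcomeSpec(1.25, 0.2, beta_age=-0.64),
            "e_peak_mm_s": OutcomeSpec(700.0, 120.0, beta_age=-0.45),
            "hr_stress_bpm": OutcomeSpec(597.0, 30.0, beta_age=-0.37),
            "ef_stress_pct": OutcomeSpec(70.0, 6.0, beta_age=-0.14),
        },
        arrhythmia={
            "APB": CountModel(-2.5, 0.9, 0.2),
            "VPB": CountModel(-3.2, 0.8, 0.2),
            "JPB": CountModel(-3.5, 0.8, 0.2),
        },
    )
    kw.update(overrides)
    return CohortDesign(**kw)


def default_nmr_design(**overrides) -> CohortDesign:
    """Naked mole-rat cohort defaults: flat or mildly quadratic age trends,
    zero arrhythmia rate (none were ever observed in this species)."""
    kw = dict(
        species="nmr",
        n_female=48,
        n_male=72,
        age_range=(2.0, 34.0),
        outcomes={
            "body_weight_g": OutcomeSpec(46.0, 10.0, beta_age=0.87, beta_age2=-0.85),
            "hr_bpm": OutcomeSpec(238.0, 22.0, beta_age=-1.16, beta_age2=1.02),
            "qrs_ms": OutcomeSpec(12.0, 1.5, beta_age=0.08),
            "pr_ms": OutcomeSpec(52.0, 5.0, beta_age=0.89, beta_age2=-0.71),
            "pq_ms": OutcomeSpec(46.0, 5.0, beta_age=0.93, beta_age2=-0.76),
            "edv_ul": OutcomeSpec(55.0, 9.0, beta_age=-0.0044),
            "esv_ul": OutcomeSpec(22.0, 6.0, beta_age=-0.03),
            "ef_pct": OutcomeSpec(60.0, 6.0, beta_age=0.11),
            "ea_ratio": OutcomeSpec(1.5, 0.3, beta_age=-0.1),
            "e_peak_mm_s": OutcomeSpec(500.0, 90.0, beta_age=0.05),
            "hr_stress_bpm": OutcomeSpec(270.0, 29.0, beta_age=-1.58, beta_age2=1.45),
            "ef_stress_pct": OutcomeSpec(70.0, 6.0, beta_age=0.01),
        },
        arrhythmia={},  # no arrhythmias in this species
    )
    kw.update(overrides)
    return CohortDesign(**kw)


def simulate_cohort(
    design: CohortDesign, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Draw a cross-sectional cohort table from ``design``.

    Returns the table (one row per animal: animal_id, species, sex,
    age_years, outcome columns, per-class arrhythmia counts) and a record of
    the true generating parameters.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    ss = np.random.SeedSequence(seed)
    rng_age, rng_out, rng_ev = (np.random.default_rng(s) for s in ss.spawn(3))

    n = design.n_female + design.n_male
    male = np.concatenate([np.zeros(design.n_female), np.ones(design.n_male)])
    lo, hi = design.age_range
    ages = rng_age.uniform(lo, hi, size=n)
    # population standardization of the uniform age distribution
    age_z = (ages - (lo + hi) / 2.0) / ((hi - lo) / math.sqrt(12.0))

    df = pd.DataFrame(
        {
            "animal_id": [f"{design.species}_{i:04d}" for i in range(n)],
            "species": design.species,
            "sex": np.where(male == 1, "M", "F"),
            "age_years": ages,
        }
    )
    truth: dict = {"species": design.species, "outcomes": {}, "arrhythmia": {}}
    for name, spec in design.outcomes.items():
        sig = spec.resolved_sigma()
        eta = (
            spec.beta_age * age_z
            + spec.beta_age2 * age_z**2
            + spec.beta_sex * male
            + spec.beta_age_sex * age_z * male
            + spec.beta_age2_sex * age_z**2 * male
        )
        y_z = eta + sig * rng_out.standard_normal(n)
        df[name] = spec.mean + spec.sd * y_z
        truth["outcomes"][name] = {**asdict(spec), "sigma_resolved": sig}
    for cls, cm in design.arrhythmia.items():
        lam = cm.rate(age_z, male)
        df[f"{cls.lower()}_count"] = rng_ev.poisson(lam)
        truth["arrhythmia"][cls] = asdict(cm)
    for cls in ("APB", "VPB", "JPB"):
        col = f"{cls.lower()}_count"
        if col not in df.columns:
            df[col] = 0
    return df, truth
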