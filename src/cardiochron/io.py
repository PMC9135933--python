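"""File I/O: ECG CSV + JSON sidecar, Doppler and cohort tables.

CSV dialect is fixed (comma, header row, UTF-8, '.' decimal); floats are
written with ``repr`` so that read/write round-trips are bit-exact.  Each
ECG CSV has a JSON sidecar carrying the sampling rate, species, units, and
(for simulated recordings) the ground-truth annotations.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .ecg import EcgRecording, LEAD_NAMES
from .function import DopplerTrace
from .simulate import GroundTruth

__all__ = [
    "write_recording",
    "load_recording",
    "write_doppler",
    "load_doppler",
    "write_cohort",
    "load_cohort",
]


def _write_csv(path: Path, header: list[str], columns: list[np.ndarray]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(header) + "\n")
        for row in zip(*columns):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def write_recording(
    rec: EcgRecording,
    basepath: str | Path,
    ground_truth: GroundTruth | None = None,
) -> tuple[Path, Path]:
    """Write a recording as ``<base>.csv`` + ``<base>.json`` sidecar.

    CSV columns: time_s, L1_mV, L2_mV, L3_mV (present leads only), then any
    auxiliary channels.  Returns (csv_path, json_path).
    """
    base = Path(basepath)
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")

    header = ["time_s"]
    cols: list[np.ndarray] = [rec.time]
    for name in LEAD_NAMES:
        if name in rec.leads:
            header.append(f"{name}_mV")
            cols.append(rec.leads[name])
    for name, x in rec.aux.items():
        header.append(name)
        cols.append(np.asarray(x, dtype=float))
    _write_csv(csv_path, header, cols)

    sidecar = {
        "sampling_rate_hz": rec.fs,
        "species": rec.species,
        "units": {"leads": "mV", "time": "s"},
        "meta": rec.meta,
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth.to_jsonable()
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return csv_path, json_path


def load_recording(
    path: str | Path, jitter_ppm: float = 1.0
) -> tuple[EcgRecording, GroundTruth | None]:
    """Load an ECG recording written by :func:`write_recording`.

    Validates strictly monotone time and uniform sampling (max deviation of
    any interval from the nominal period below ``jitter_ppm`` parts per
    million); a recording with a time gap is rejected.  Missing leads load
    with a warning, restricting analysis to the present leads.
    """
    path = Path(path)
    csv_path = path if path.suffix == ".csv" else path.with_suffix(".csv")
    json_path = csv_path.with_suffix(".json")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError("recording CSV must contain a time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("recording too short")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time axis must be strictly increasing")
    period = np.median(dt)
    jitter = np.max(np.abs(dt - period)) / period
    if jitter > jitter_ppm * 1e-6:
        raise ValueError(
            f"nonuniform sampling: max jitter {jitter * 1e6:.2f} ppm "
            f"exceeds {jitter_ppm} ppm (time gap?)"
        )
    fs = 1.0 / period

    leads = {}
    for name in LEAD_NAMES:
        col = f"{name}_mV"
        if col in df.columns:
            leads[name] = df[col].to_numpy(dtype=float)
    if not leads:
        raise ValueError("no ECG leads found in recording CSV")
    missing = [n for n in LEAD_NAMES if n not in leads]
    if missing:
        warnings.warn(
            f"leads {missing} missing; analysis restricted to {sorted(leads)}",
            stacklevel=2,
        )
    aux = {
        c: df[c].to_numpy(dtype=float)
        for c in df.columns
        if c != "time_s" and not c.endswith("_mV")
    }

    species = None
    meta: dict = {}
    gt = None
    if json_path.exists():
        sidecar = json.loads(json_path.read_text())
        fs = float(sidecar.get("sampling_rate_hz", fs))
        species = sidecar.get("species")
        meta = sidecar.get("meta", {})
        if "ground_truth" in sidecar:
            g = sidecar["ground_truth"]
            gt = GroundTruth(
                r_times=np.asarray(g["r_times_s"], dtype=float),
                labels=list(g["labels"]),
                fiducials=g["fiducials_ms"],
                intervals=g["intervals_ms"],
            )
    rec = EcgRecording(fs=fs, leads=leads, species=species, aux=aux, meta=meta)
    return rec, gt


def write_doppler(trace: DopplerTrace, path: str | Path) -> Path:
    """Write a Doppler trace as CSV (time_s, velocity_mm_s) + JSON sidecar."""
    path = Path(path).with_suffix(".csv")
    _write_csv(path, ["time_s", "velocity_mm_s"], [trace.time, trace.velocity])
    sidecar = {"hr_bpm": trace.hr, "meta": trace.meta}
    if trace.cycle_starts is not None:
        sidecar["cycle_starts_s"] = [float(s) for s in trace.cycle_starts]
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def load_doppler(path: str | Path) -> DopplerTrace:
    path = Path(path)
    csv_path = path if path.suffix == ".csv" else path.with_suffix(".csv")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    hr = None
    starts = None
    meta: dict = {}
    json_path = csv_path.with_suffix(".json")
    if json_path.exists():
        sidecar = json.loads(json_path.read_text())
        hr = sidecar.get("hr_bpm")
        meta = sidecar.get("meta", {})
        if "cycle_starts_s" in sidecar:
            starts = np.asarray(sidecar["cycle_starts_s"], dtype=float)
    return DopplerTrace(
        time=df["time_s"].to_numpy(float),
        velocity=df["velocity_mm_s"].to_numpy(float),
        hr=hr,
        cycle_starts=starts,
        meta=meta,
    )


def write_cohort(df: pd.DataFrame, path: str | Path, truth: dict | None = None) -> Path:
    """Write a cohort table as CSV; the generating config (if given) goes to
    a JSON sidecar."""
    path = Path(path).with_suffix(".csv")
    df.to_csv(path, index=False)
    if truth is not None:
        path.with_suffix(".json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return path


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), float_precision="round_trip")
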