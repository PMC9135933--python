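"""End-to-end reproducible pipeline: simulate -> analyze -> summarize.

One seeded configuration drives per-animal ECG simulation and analysis,
function and stress metrics, Doppler E/A analysis, cohort trend fits, and
arrhythmia prevalence tables, writing per-animal results and a
machine-readable summary JSON.  Identical config + seed yields byte-identical
summaries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cs
from . import ecg as ea
from . import function as fn
from . import simulate as sim
from .io import write_cohort

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Serializable configuration for one pipeline run.

    Analysis thresholds default to the screening constants used throughout
    the package (suspect interval outside 70-130% of the moving average,
    100-beat ensemble average).
    """

    seed: int = 0
    n_mice_female: int = 10
    n_mice_male: int = 10
    n_nmr_female: int = 10
    n_nmr_male: int = 10
    ecg_duration_s: float = 60.0
    ecg_noise_sd_mv: float = 0.02
    ecg_fs_hz: float = 2000.0
    rr_low: float = 0.70
    rr_high: float = 1.30
    rr_window: int = 11
    n_avg: int = 100
    lead: str = "L1"
    selection_alpha: float = 0.05
    doppler_duration_s: float = 4.0
    mouse_age_bins: tuple[float, ...] = (0.0, 1.0, 1.7, 2.2, 3.0)
    nmr_age_bins: tuple[float, ...] = (0.0, 10.0, 20.0, 35.0)
    trend_outcomes: tuple[str, ...] = ("qrs_ms", "pr_ms", "hr_bpm", "ef_pct", "ea_ratio")
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        for k in ("mouse_age_bins", "nmr_age_bins", "trend_outcomes"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _morphed_params(base: sim.SpeciesEcgParams, hr: float, qrs_ms: float,
                    pr_ms: float) -> sim.SpeciesEcgParams:
    """Per-animal morphology: rescale the QRS group to the animal's QRS
    duration and shift the P wave to its PR interval."""
    hr = float(np.clip(hr, 100.0, 900.0))
    qrs_ms = float(np.clip(qrs_ms, 5.0, 25.0))
    w = dict(sim.scaled_qrs_params(base, qrs_ms).waves)
    sp = w["P"].sigma
    min_pr = (0.0 - w["Q"].center) + 2 * w["Q"].sigma + 4 * sp + 4.0
    # cap PR so the P peak stays >= 1 sigma clear of the isoelectric
    # baseline segment (which ends at -0.30 * RR before R); PR shortens
    # with rate physiologically, so fast hearts get proportionally less
    rr_ms = 60000.0 / hr
    pr_ms = float(np.clip(pr_ms, min_pr, 0.30 * rr_ms + sp))
    w["P"] = sim.Wave(w["P"].amp, -(pr_ms - 2 * sp), sp)
    return sim.SpeciesEcgParams(
        species=base.species, hr_mean=hr, hr_sd=base.hr_sd, waves=w,
        resp_depth=base.resp_depth, resp_rate=base.resp_rate,
        lead_weights=base.lead_weights,
    )


def _analyze_animal(rec: ea.EcgRecording, cfg: RunConfig) -> dict:
    """Run the full ECG analysis chain on one recording."""
    out: dict = {"status": "ok"}
    r = ea.detect_r_peaks(rec, lead=cfg.lead)
    rr = ea.rr_series(r)
    flags = ea.flag_irregular(rr, low=cfg.rr_low, high=cfg.rr_high, window=cfg.rr_window)
    avg = ea.average_beats(rec, rr, flags, n=cfg.n_avg)
    fid = ea.measure_intervals(avg, lead=cfg.lead)
    flags = ea.classify_flagged(rec, rr, flags, avg, lead=cfg.lead,
                                low=cfg.rr_low, high=cfg.rr_high)
    events = ea.suspect_events(flags)
    counts = {"APB": 0, "VPB": 0, "JPB": 0, "unclassified": 0}
    for ev in events:
        cls = ev[0].beat_class
        counts[cls if cls in counts else "unclassified"] += 1
    out.update(
        n_beats=rr.n_beats,
        hr_bpm=rr.heart_rate(flags),
        qrs_ms=fid.qrs_ms,
        pr_ms=fid.pr_ms,
        pq_ms=fid.pq_ms,
        n_averaged=avg.n_averaged,
        apb_count=counts["APB"],
        vpb_count=counts["VPB"],
        jpb_count=counts["JPB"],
        unclassified_count=counts["unclassified"],
    )
    return out


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full pipeline and write results under ``outdir``.

    Per-animal failures are recorded (status column) without aborting the
    run; the summary JSON notes the failure count.  Returns the summary
    dict (also written to ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json())

    ss = np.random.SeedSequence(config.seed)
    s_mouse, s_nmr, s_ecg = ss.spawn(3)

    designs = {
        "mouse": sim.default_mouse_design(
            n_female=config.n_mice_female, n_male=config.n_mice_male
        ),
        "nmr": sim.default_nmr_design(
            n_female=config.n_nmr_female, n_male=config.n_nmr_male
        ),
    }
    cohort_seeds = {"mouse": s_mouse, "nmr": s_nmr}
    base_params = {"mouse": sim.mouse_ecg_params(), "nmr": sim.nmr_ecg_params()}
    bins = {"mouse": config.mouse_age_bins, "nmr": config.nmr_age_bins}

    summary: dict = {"config_seed": config.seed, "species": {}}
    ecg_seed_root = s_ecg

    for species, design in designs.items():
        cohort_df, truth = sim.simulate_cohort(
            design, seed=int(cohort_seeds[species].generate_state(1)[0] % (2**31))
        )
        write_cohort(cohort_df, outdir / f"cohort_{species}.csv", truth)

        exp_beats = config.ecg_duration_s * cohort_df["hr_bpm"].clip(100, 900) / 60.0
        animal_rows = []
        child_seeds = ecg_seed_root.spawn(len(cohort_df) + 1)
        n_failed = 0
        for i, row in cohort_df.iterrows():
            probs = {}
            for cls in ("APB", "VPB", "JPB"):
                probs[cls] = min(0.06, row[f"{cls.lower()}_count"] / exp_beats[i])
            try:
                arr = sim.ArrhythmiaSpec(
                    apb_prob=probs["APB"], vpb_prob=probs["VPB"], jpb_prob=probs["JPB"]
                )
                params = _morphed_params(
                    base_params[species], row["hr_bpm"], row["qrs_ms"], row["pr_ms"]
                )
                rec, gt = sim.simulate_ecg(
                    params,
                    arr,
                    duration=config.ecg_duration_s,
                    noise_sd=config.ecg_noise_sd_mv,
                    fs=config.ecg_fs_hz,
                    seed=int(child_seeds[i].generate_state(1)[0] % (2**31)),
                )
                res = _analyze_animal(rec, config)
                res["true_events"] = sum(
                    1 for lab in gt.labels if lab in ("APB", "VPB", "JPB")
                )
            except Exception as exc:  # per-animal failure: record and continue
                res = {"status": f"failed: {exc}"}
                n_failed += 1
            res["animal_id"] = row["animal_id"]
            res["age_years"] = row["age_years"]
            res["sex"] = row["sex"]
            animal_rows.append(res)
        ecg_df = pd.DataFrame(animal_rows)
        ecg_df.to_csv(outdir / f"ecg_results_{species}.csv", index=False)

        # function + stress metrics from the cohort table
        deltas = []
        for _, row in cohort_df.iterrows():
            try:
                base = fn.function_metrics(
                    row["edv_ul"], min(row["esv_ul"], row["edv_ul"] - 1e-9),
                    row["hr_bpm"], row["body_weight_g"],
                )
                ef_s = float(np.clip(row["ef_stress_pct"], 1.0, 99.0))
                esv_s = row["edv_ul"] * (1 - ef_s / 100.0)
                stressed = fn.function_metrics(
                    row["edv_ul"], esv_s, row["hr_stress_bpm"], row["body_weight_g"]
                )
                d = fn.stress_delta(base, stressed)
                deltas.append(d.deltas)
            except ValueError:
                n_failed += 1
                deltas.append({})
        hr_deltas = [d.get("hr_bpm") for d in deltas if d.get("hr_bpm") is not None]
        co_deltas = [d.get("nco_ml_min_g") for d in deltas if "nco_ml_min_g" in d]

        # Doppler E/A per animal
        ea_meas = []
        n_fused = 0
        for i, row in cohort_df.iterrows():
            e = max(row["e_peak_mm_s"], 1.0)
            ratio = max(row["ea_ratio"], 0.2)
            tr = sim.simulate_doppler(
                e, e / ratio, float(np.clip(row["hr_bpm"], 100, 900)),
                noise_sd=5.0, duration=config.doppler_duration_s,
                seed=int(child_seeds[-1].generate_state(1)[0] % (2**31)) + i,
            )
            res = fn.ea_analysis(tr)
            if res.separable:
                ea_meas.append(res.ea_ratio)
            else:
                n_fused += 1

        # cohort statistics on the simulated measurement table
        trends = {}
        for outcome in config.trend_outcomes:
            if outcome not in cohort_df.columns:
                continue
            try:
                tm = cs.fit_trend(cohort_df, outcome, alpha=config.selection_alpha)
                trends[outcome] = {
                    "form": "+".join(tm.terms) or "intercept",
                    "beta": tm.beta,
                    "model_p": tm.model_p,
                    "n": tm.n,
                }
            except ValueError as exc:
                trends[outcome] = {"error": str(exc)}

        ok = ecg_df[ecg_df["status"] == "ok"] if "status" in ecg_df else ecg_df
        counts_df = ok[["age_years", "apb_count", "vpb_count", "jpb_count"]].copy()
        prev = cs.arrhythmia_prevalence(counts_df, bins[species])
        prev.table.to_csv(outdir / f"prevalence_{species}.csv", index=False)

        summary["species"][species] = {
            "n_animals": len(cohort_df),
            "n_failed_stages": n_failed,
            "ecg": {
                "mean_hr_bpm": float(ok["hr_bpm"].mean()) if len(ok) else None,
                "mean_qrs_ms": float(ok["qrs_ms"].mean()) if len(ok) else None,
                "total_events": {
                    "APB": int(ok["apb_count"].sum()),
                    "VPB": int(ok["vpb_count"].sum()),
                    "JPB": int(ok["jpb_count"].sum()),
                },
            },
            "stress": {
                "mean_hr_delta_pct": float(np.mean(hr_deltas)) if hr_deltas else None,
                "mean_nco_delta_pct": float(np.mean(co_deltas)) if co_deltas else None,
            },
            "doppler": {
                "mean_ea_ratio": float(np.mean(ea_meas)) if ea_meas else None,
                "n_fused": n_fused,
            },
            "trends": trends,
            "prevalence_pct": {
                cls: [float(v) for v in prev.table[f"{cls}_pct"]]
                for cls in ("APB", "VPB", "JPB")
            },
        }

    n_failed_total = sum(
        s["n_failed_stages"] for s in summary["species"].values()
    )
    summary["n_failed_stages"] = n_failed_total
    summary = _round_floats(summary)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    return summary
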