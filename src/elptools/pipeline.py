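"""Stage orchestration behind the ``elp`` command line interface.

Each stage reads the standard containers written by the simulators (or by
real acquisition-export converters), runs one analysis module, and writes
CSV/JSON outputs under a run directory with a fixed layout::

    run_dir/
      mea/        per-channel summary CSV + slice JSON
      calcium/    per-neuron call CSV + population summary CSV
      icage/      feature matrix, repetitiveness and time-course CSVs
      lipids/     volcano CSV
      manifest.json

A single global seed is fanned out to per-stage child seeds by a fixed
derivation so stages are independently reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import calcium as ca
from . import icage, io, lipids, simulate

__all__ = ["DEMO_CONFIG", "child_seeds", "run_pipeline", "run_stage"]

#: Analysis defaults: the acquisition-rule parameters of the emulated study
#: (5xSD threshold, 100 spikes / 5 min, 200 Hz order-2 highpass, 10%/20%
#: 5-sample run rules, 60 s IVI, 12 h bins, 1000 shuffles).
ANALYSIS_DEFAULTS = {
    "mea": {
        "threshold_multiple": 5.0,
        "cutoff": 200.0,
        "order": 2,
        "dead_time": 0.001,
        "min_spikes": 100,
        "reference_duration": 300.0,
        "channels": None,
    },
    "calcium": {"caps_threshold": 1.10, "kcl_threshold": 1.20, "min_run": 5},
    "icage": {"ivi_threshold": 60.0, "n_shuffles": 1000, "bin_width_h": 12.0},
    "lipids": {"reference": "control", "log_transform": True},
}

#: Bundled demo scale: small enough for an end-to-end smoke run while
#: exercising every stage (simulation sizes only; analysis rules unchanged).
DEMO_CONFIG = {
    "seed": 7,
    "simulate": {
        "mea": {"n_channels": 6, "duration": 20.0, "spike_rate": 8.0},
        "calcium": {"n_neurons": 24},
        "icage": {
            "n_animals_per_group": {"control": 3, "elp": 3},
            "task_schedule": [["FA", 2], ["NP3c", 2], ["PPL", 2], ["PPLrev", 2]],
        },
        "lipids": {"n_samples_per_group": [6, 6], "n_species": 24,
                   "affected_species": [0, 1, 2, 3]},
    },
    "analysis": {},
}


def child_seeds(seed: int, n: int) -> list[int]:
    """Fixed fan-out of one global seed into n independent child seeds."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def _merged(defaults: dict, override: dict | None) -> dict:
    out = dict(defaults)
    out.update(override or {})
    return out


def _simulate_stage(config: dict, out: Path, seeds: list[int]) -> dict[str, str]:
    sim_cfg = config.get("simulate", {})
    outputs: dict[str, str] = {}
    out.mkdir(parents=True, exist_ok=True)

    mea_cfg = simulate.MEASimConfig(**_merged({"seed": seeds[0]}, sim_cfg.get("mea")))
    rec, truth = simulate.simulate_mea_recording(mea_cfg)
    io.save_mea_h5(out / "mea_recording.h5", rec)
    np.savez(out / "mea_truth.npz", **{f"ch{i}": t for i, t in enumerate(truth)})
    outputs["mea_recording"] = str(out / "mea_recording.h5")

    ca_kwargs = _merged({"seed": seeds[1]}, sim_cfg.get("calcium"))
    traces, ca_truth = simulate.simulate_calcium_traces(simulate.CaSimConfig(**ca_kwargs))
    io.write_calcium_csv(out / "calcium_traces.csv", traces)
    ca_truth.to_csv(out / "calcium_truth.csv", index=False)
    outputs["calcium_traces"] = str(out / "calcium_traces.csv")

    ic_kwargs = _merged({"seed": seeds[2]}, sim_cfg.get("icage"))
    if "task_schedule" in ic_kwargs:
        ic_kwargs["task_schedule"] = tuple(
            (str(t), int(d)) for t, d in ic_kwargs["task_schedule"]
        )
    if "groups" in ic_kwargs:
        ic_kwargs["groups"] = {
            k: simulate.GroupBehavior(**v) for k, v in ic_kwargs["groups"].items()
        }
    visits, schedule, ic_truth = simulate.simulate_intellicage(
        simulate.ICSimConfig(**ic_kwargs)
    )
    io.write_visits_csv(out / "visits.csv", visits)
    io.write_schedule_csv(out / "schedule.csv", out / "assignments.csv", schedule)
    (out / "icage_truth.json").write_text(json.dumps(ic_truth, indent=2))
    outputs["visits"] = str(out / "visits.csv")
    outputs["schedule"] = str(out / "schedule.csv")
    outputs["assignments"] = str(out / "assignments.csv")

    lp_kwargs = _merged({"seed": seeds[3]}, sim_cfg.get("lipids"))
    for key in ("n_samples_per_group", "affected_species", "group_labels"):
        if key in lp_kwargs:
            lp_kwargs[key] = tuple(lp_kwargs[key])
    table, groups, lp_truth = simulate.simulate_lipid_table(
        simulate.LipidSimConfig(**lp_kwargs)
    )
    io.write_lipid_csv(out / "lipids.csv", table, groups)
    (out / "lipid_truth.json").write_text(json.dumps(lp_truth, indent=2))
    outputs["lipids"] = str(out / "lipids.csv")
    return outputs


def _mea_stage(input_path: str, params: dict, out: Path) -> dict[str, str]:
    from .mea import summarize_slice

    out.mkdir(parents=True, exist_ok=True)
    rec = io.load_mea_h5(input_path)
    summary = summarize_slice(rec, **params)
    summary.to_frame().to_csv(out / "channel_summary.csv", index=False)
    (out / "slice_summary.json").write_text(
        json.dumps(
            {
                "slice_id": summary.slice_id,
                "group": summary.group,
                "active_channels": summary.active_count,
                "mean_active_mua_hz": float(summary.active_mua_hz.mean())
                if summary.active_count
                else None,
            },
            indent=2,
        )
    )
    return {
        "channel_summary": str(out / "channel_summary.csv"),
        "slice_summary": str(out / "slice_summary.json"),
    }


def _calcium_stage(input_path: str, params: dict, out: Path) -> dict[str, str]:
    out.mkdir(parents=True, exist_ok=True)
    traces = io.read_calcium_csv(input_path)
    windows = ca.StimulusWindows()
    rows = []
    for tr in traces:
        fold = ca.normalize_to_baseline(tr, windows.baseline)
        for call in (
            ca.call_capsaicin_peak(
                fold, tr.times, windows, params["caps_threshold"], params["min_run"]
            ),
            ca.call_kcl_peak(
                fold, tr.times, windows, params["kcl_threshold"], params["min_run"]
            ),
        ):
            rows.append(
                {
                    "neuron_id": tr.neuron_id,
                    "animal_id": tr.animal_id,
                    "group": tr.group,
                    "rule": call.rule,
                    "detected": call.detected,
                    "peak_fold": call.peak_fold,
                    "time_to_peak_s": call.time_to_peak,
                    "auc": call.auc,
                }
            )
    calls = pd.DataFrame(rows)
    calls.to_csv(out / "peak_calls.csv", index=False)
    ca.summarize_population(calls).to_csv(out / "population_summary.csv", index=False)
    return {
        "peak_calls": str(out / "peak_calls.csv"),
        "population_summary": str(out / "population_summary.csv"),
    }


def _icage_stage(
    visits_path: str,
    schedule_path: str,
    assignments_path: str,
    params: dict,
    seed: int,
    out: Path,
) -> dict[str, str]:
    out.mkdir(parents=True, exist_ok=True)
    schedule = icage.load_schedule(schedule_path, assignments_path)
    visits = icage.load_visits(visits_path, schedule)
    tc = icage.bin_timecourse(
        visits, params["bin_width_h"], anchor_s=schedule.lights_on_s,
        total_duration_s=schedule.end_s,
    )
    tc.to_csv(out / "timecourse.csv", index=False)
    rep = icage.repetitiveness(
        visits, params["ivi_threshold"], params["n_shuffles"], seed=seed
    )
    rep.to_csv(out / "repetitiveness.csv", index=False)
    fm = icage.task_feature_matrix(
        visits, schedule, params["ivi_threshold"], seed=seed
    )
    fm.to_csv(out / "feature_matrix.csv")
    long = fm.stack(["parameter", "task"], future_stack=True).rename("value").reset_index()
    long.to_csv(out / "feature_long.csv", index=False)
    return {
        "timecourse": str(out / "timecourse.csv"),
        "repetitiveness": str(out / "repetitiveness.csv"),
        "feature_matrix": str(out / "feature_matrix.csv"),
        "feature_long": str(out / "feature_long.csv"),
    }


def _lipids_stage(input_path: str, params: dict, out: Path) -> dict[str, str]:
    out.mkdir(parents=True, exist_ok=True)
    table, groups = io.read_lipid_csv(input_path)
    volcano = lipids.volcano_table(
        table, groups, params["reference"], params["log_transform"]
    )
    volcano.to_csv(out / "volcano.csv", index=False)
    return {"volcano": str(out / "volcano.csv")}


def run_stage(stage: str, config: dict, out_dir) -> dict[str, str]:
    """Run one named stage of the pipeline; see :func:`run_pipeline`."""
    out_dir = Path(out_dir)
    seed = int(config.get("seed", 0))
    seeds = child_seeds(seed, 5)
    analysis = config.get("analysis", {})
    sim_dir = out_dir / "sim"
    if stage == "simulate":
        return _simulate_stage(config, sim_dir, seeds)
    if stage == "mea":
        params = _merged(ANALYSIS_DEFAULTS["mea"], analysis.get("mea"))
        path = config.get("inputs", {}).get("mea", sim_dir / "mea_recording.h5")
        return _mea_stage(str(path), params, out_dir / "mea")
    if stage == "calcium":
        params = _merged(ANALYSIS_DEFAULTS["calcium"], analysis.get("calcium"))
        path = config.get("inputs", {}).get("calcium", sim_dir / "calcium_traces.csv")
        return _calcium_stage(str(path), params, out_dir / "calcium")
    if stage == "icage":
        params = _merged(ANALYSIS_DEFAULTS["icage"], analysis.get("icage"))
        inputs = config.get("inputs", {})
        return _icage_stage(
            str(inputs.get("visits", sim_dir / "visits.csv")),
            str(inputs.get("schedule", sim_dir / "schedule.csv")),
            str(inputs.get("assignments", sim_dir / "assignments.csv")),
            params,
            seeds[4],
            out_dir / "icage",
        )
    if stage == "lipids":
        params = _merged(ANALYSIS_DEFAULTS["lipids"], analysis.get("lipids"))
        path = config.get("inputs", {}).get("lipids", sim_dir / "lipids.csv")
        return _lipids_stage(str(path), params, out_dir / "lipids")
    raise ValueError(f"unknown stage {stage!r}")


def run_pipeline(config: dict, out_dir) -> dict[str, str]:
    """simulate -> mea -> calcium -> icage -> lipids, with a manifest."""
    out_dir = Path(out_dir)
    outputs: dict[str, str] = {}
    for stage in ("simulate", "mea", "calcium", "icage", "lipids"):
        outputs.update(run_stage(stage, config, out_dir))
    io.write_manifest(out_dir / "manifest.json", config, int(config.get("seed", 0)), outputs)
    outputs["manifest"] = str(out_dir / "manifest.json")
    return outputs
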