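"""End-to-end orchestration over a cohort of recordings.

Given a cohort bundle (in memory from :func:`nvp.synthetic.gen_cohort` or
loaded from its on-disk layout), the pipeline runs every vessel through
trial segmentation, locomotion gating, normalization and response metrics;
computes per-vessel responsiveness, mean-response metrics and vasomotion;
classifies each mouse's calcium responses and computes per-vessel NVCi;
and emits tidy per-vessel and per-group tables plus a run manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

import nvp
from nvp.core import DiameterTrace
from nvp.neuro import cell_trial_means, classify_cells, nvci
from nvp.synthetic import CohortBundle
from nvp.trials import (
    gate_locomotion,
    mean_response,
    response_metrics,
    responsiveness,
    segment_trials,
    trial_metrics,
)
from nvp.vasomotion import vasomotion_power

log = logging.getLogger(__name__)


def analyze_vessel(vessel, schedule, locomotion, speed_eps: float = 0.0) -> dict:
    """Full per-vessel readout: responsiveness, mean-trace metrics, and
    vasomotion relative power (from the same recording's diameter trace)."""
    tset = segment_trials(vessel.diameter, vessel.frame_rate, schedule)
    tset = gate_locomotion(tset, locomotion, speed_eps=speed_eps)
    per_trial = trial_metrics(tset)
    resp = responsiveness(per_trial)
    mean_tr = mean_response(tset)
    mean_m = response_metrics(mean_tr, vessel.frame_rate,
                              tset.baseline_span, tset.stim_dur)
    dtrace = DiameterTrace(values=vessel.diameter, frame_rate=vessel.frame_rate)
    try:
        _, rel_power = vasomotion_power(dtrace)
    except ValueError:
        rel_power = np.nan
    peaks = [m.max_peak for m in per_trial if m.valid and m.responsive]
    return {
        "mouse": vessel.mouse, "group": vessel.group,
        "genotype": vessel.genotype, "exercise": vessel.exercise,
        "timepoint": vessel.timepoint, "vessel_id": vessel.vessel_id,
        "baseline_diameter_um": vessel.baseline_diameter,
        "n_trials": tset.n_trials,
        "n_retained": int(tset.retained.sum()),
        "responsiveness_pct": resp,
        "mean_peak_pct": float(np.mean(peaks)) if peaks else np.nan,
        "mean_trace_peak_pct": mean_m.max_peak,
        "mean_trace_auc": mean_m.auc,
        "mean_trace_ttp_s": mean_m.time_to_peak,
        "vasomotion_rel_power": rel_power,
    }


def analyze_mouse_calcium(mouse, speed_eps: float = 0.0) -> dict | None:
    """Trial-average each cell, classify ON/OFF/BOTH, and return the mean
    stimulus AUC used as the neuronal denominator of the NVCi."""
    if mouse.calcium is None:
        return None
    ts = segment_trials(mouse.calcium.dff[0], mouse.calcium.sample_rate,
                        mouse.schedule)
    gated = gate_locomotion(ts, mouse.locomotion, speed_eps=speed_eps)
    means = cell_trial_means(mouse.calcium, mouse.schedule,
                             retained=gated.retained)
    cls = classify_cells(means, mouse.calcium.sample_rate,
                         stim_dur=mouse.schedule.stim_dur)
    return {"labels": cls.labels, "stim_auc_mean": cls.stim_auc_mean,
            "on_auc": cls.on_auc}


def run_cohort(bundle: CohortBundle, speed_eps: float = 0.0,
               nvci_grouping: str = "genotype") -> dict:
    """Analyze every vessel and mouse in a cohort.

    NVCi denominators are pooled per ``nvci_grouping`` ("genotype", the
    default because calcium data may not exist for every mouse, or
    "group" for genotype x exercise).  Returns {"vessels": per-vessel
    DataFrame, "neuro": per-mouse DataFrame}.
    """
    vrows, nrows = [], []
    neuro_by_mouse = {}
    for mouse in bundle.mice:
        res = analyze_mouse_calcium(mouse, speed_eps=speed_eps)
        if res is not None:
            key = (mouse.mouse, mouse.timepoint)
            neuro_by_mouse[key] = res
            nrows.append({
                "mouse": mouse.mouse, "group": mouse.group,
                "genotype": mouse.genotype, "exercise": mouse.exercise,
                "timepoint": mouse.timepoint,
                "stim_auc_mean": res["stim_auc_mean"],
                "n_on": sum(1 for l in res["labels"] if l == "ON"),
                "n_off": sum(1 for l in res["labels"] if l == "OFF"),
                "n_both": sum(1 for l in res["labels"] if l == "BOTH"),
                "n_none": sum(1 for l in res["labels"] if l == "NONE"),
            })
        for vessel in mouse.vessels:
            vrows.append(analyze_vessel(vessel, mouse.schedule,
                                        mouse.locomotion, speed_eps))
    vessels = pd.DataFrame(vrows)
    neuro = pd.DataFrame(nrows)

    # NVCi: vessel AUC / mean neuronal AUC of the vessel's group
    if not neuro.empty:
        keycol = "genotype" if nvci_grouping == "genotype" else "group"
        denom = neuro.groupby([keycol, "timepoint"])["stim_auc_mean"].mean()
        nvcis = []
        for _, row in vessels.iterrows():
            key = (row[keycol], row["timepoint"])
            if key in denom.index and denom[key] > 0:
                nvcis.append(nvci(row["mean_trace_auc"], [denom[key]],
                                  vessel_id=row["vessel_id"],
                                  group=str(key)).value)
            else:
                nvcis.append(np.nan)
        vessels["nvci"] = nvcis
    return {"vessels": vessels, "neuro": neuro}


def group_summary(vessels: pd.DataFrame,
                  metrics=("responsiveness_pct", "mean_peak_pct",
                           "mean_trace_auc", "nvci",
                           "vasomotion_rel_power")) -> pd.DataFrame:
    """Group means (and SEM) of the per-vessel metrics."""
    cols = [m for m in metrics if m in vessels.columns]
    g = vessels.groupby(["group", "timepoint"])[list(cols)]
    out = g.agg(["mean", "sem"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()


def run_pipeline(config: dict, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Config-driven end-to-end run: synthetic cohort -> per-vessel and
    per-group tables -> manifest.  Deterministic for a fixed config + seed.

    Recognized config sections: "cohort" (kwargs of gen_cohort),
    "analysis" ({"speed_eps", "nvci_grouping"}).  Unknown keys are
    rejected so typos cannot silently change a run.
    """
    from nvp.synthetic import gen_cohort, write_bundle

    known = {"cohort", "analysis"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    cohort_cfg = dict(config.get("cohort", {}))
    if seed is not None:
        cohort_cfg["seed"] = seed
    analysis_cfg = dict(config.get("analysis", {}))
    bad = set(analysis_cfg) - {"speed_eps", "nvci_grouping"}
    if bad:
        raise ValueError(f"unknown analysis keys: {sorted(bad)}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = gen_cohort(**cohort_cfg)
    write_bundle(bundle, out / "bundle")
    res = run_cohort(bundle, **analysis_cfg)
    res["vessels"].to_csv(out / "vessels.csv", index=False)
    res["neuro"].to_csv(out / "neuro.csv", index=False)
    summary = group_summary(res["vessels"])
    summary.to_csv(out / "group_summary.csv", index=False)
    manifest = {
        "nvp_version": nvp.__version__,
        "config": {"cohort": cohort_cfg, "analysis": analysis_cfg},
        "seed": cohort_cfg.get("seed"),
        "rows": {"vessels": len(res["vessels"]), "neuro": len(res["neuro"]),
                 "group_summary": len(summary)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("pipeline run complete: %s", out)
    return out
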