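"""Neuronal calcium analysis and the neurovascular coupling index.

Baseline (no-stimulus) recordings yield per-cell event statistics within
rest periods; stimulus recordings yield ON/OFF/BOTH classification of
trial-averaged responses; and the neurovascular coupling index (NVCi)
relates each vessel's response AUC to the mean neuronal AUC of its group,
so that a reduced NVCi indicates a smaller vascular response for the same
neuronal drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nvp.core import CalciumTraces, LocomotionTrace, StimulusSchedule
from nvp.hemo import rest_periods
from nvp.trials import response_metrics


@dataclass
class CalciumBaselineStats:
    peaks_per_minute: np.ndarray   # per cell
    mean_peak_size: np.ndarray     # per cell, dF/F units
    n_rest_periods: int
    total_rest_s: float
    threshold_k: float


def baseline_calcium_stats(traces: CalciumTraces, locomotion: LocomotionTrace,
                           min_rest: float = 10.0, k: float = 3.0,
                           speed_eps: float = 0.0,
                           min_separation: float = 1.0) -> CalciumBaselineStats:
    """Per-cell calcium event rate and size within rest periods.

    Within each rest period of at least ``min_rest`` s, peaks are local
    maxima exceeding median + k robust standard deviations (1.4826*MAD) of
    that rest period's trace, with a prominence of at least the same margin
    and a minimum separation of
    ``min_separation`` seconds (so noise riding a transient's decay is not
    counted repeatedly).  The rate (peaks/min) and mean peak size are
    averaged across rest periods weighted by period duration.
    """
    from scipy.signal import find_peaks

    if abs(locomotion.sample_rate - traces.sample_rate) > 1e-9:
        t_cal = np.arange(traces.dff.shape[1]) / traces.sample_rate
        t_loc = np.arange(len(locomotion.speed)) / locomotion.sample_rate
        speed = np.interp(t_cal, t_loc, locomotion.speed)
        locomotion = LocomotionTrace(speed=speed, sample_rate=traces.sample_rate)
    spans = rest_periods(locomotion, min_rest=min_rest, speed_eps=speed_eps)
    if not spans:
        raise ValueError("no qualifying rest period; baseline stats undefined")

    n_cells = traces.n_cells
    rates = np.zeros(n_cells)
    sizes = np.zeros(n_cells)
    total = 0.0
    sum_size_weights = np.zeros(n_cells)
    for i0, i1 in spans:
        i1 = min(i1, traces.dff.shape[1])
        dur_min = (i1 - i0) / traces.sample_rate / 60.0
        total += dur_min * 60.0
        for c in range(n_cells):
            seg = traces.dff[c, i0:i1]
            med = np.median(seg)
            robust_sd = 1.4826 * np.median(np.abs(seg - med))
            margin = k * max(robust_sd, 1e-12)
            pk, props = find_peaks(
                seg, height=med + margin, prominence=margin,
                distance=max(int(min_separation * traces.sample_rate), 1))
            rates[c] += len(pk)  # accumulate counts; divide by total later
            if len(pk):
                sizes[c] += props["peak_heights"].sum()
                sum_size_weights[c] += len(pk)
    rates = rates / (total / 60.0)
    with np.errstate(invalid="ignore"):
        mean_size = np.where(sum_size_weights > 0,
                             sizes / np.maximum(sum_size_weights, 1), 0.0)
    return CalciumBaselineStats(peaks_per_minute=rates,
                                mean_peak_size=mean_size,
                                n_rest_periods=len(spans),
                                total_rest_s=total, threshold_k=k)


@dataclass
class CellClassification:
    labels: list                  # ON / OFF / BOTH / NONE per cell
    on_flags: np.ndarray
    off_flags: np.ndarray
    on_auc: np.ndarray            # AUC over the stimulus window per cell
    stim_auc_mean: float          # mean stimulus-window AUC across cells


def classify_cells(trial_means: np.ndarray, sample_rate: float,
                   baseline_span: float = 5.0, stim_dur: float = 5.0,
                   off_window: float = 5.0) -> CellClassification:
    """Classify trial-averaged, baseline-normalized cell traces.

    on-flag: peak in the stimulus window exceeds 2x the SD of the 5 s
    baseline.  off-flag: the signal *increase* after the stimulus — peak in
    the ``off_window`` seconds after offset minus the value at offset —
    exceeds the same threshold (measuring the rise rather than the absolute
    level keeps the decaying tail of an ON response from counting as an
    OFF response).  BOTH requires both flags, NONE neither.
    """
    trial_means = np.atleast_2d(np.asarray(trial_means, dtype=float))
    n_cells = trial_means.shape[0]
    on = np.zeros(n_cells, dtype=bool)
    off = np.zeros(n_cells, dtype=bool)
    aucs = np.zeros(n_cells)
    onset = int(round(baseline_span * sample_rate))
    offset = int(round((baseline_span + stim_dur) * sample_rate))
    off_end = int(round((baseline_span + stim_dur + off_window) * sample_rate))
    for c in range(n_cells):
        y = trial_means[c]
        m = response_metrics(y, sample_rate, baseline_span, stim_dur)
        on[c] = m.valid and m.responsive
        aucs[c] = m.auc if m.valid else np.nan
        sd = y[:onset].std(ddof=0)
        seg = y[offset:min(off_end, len(y))]
        off[c] = len(seg) > 0 and float(seg.max() - seg[0]) > 2.0 * sd
    labels = []
    for o, f in zip(on, off):
        labels.append("BOTH" if (o and f) else "ON" if o else
                      "OFF" if f else "NONE")
    return CellClassification(labels=labels, on_flags=on, off_flags=off,
                              on_auc=aucs,
                              stim_auc_mean=float(np.nanmean(aucs)))


def cell_trial_means(traces: CalciumTraces, schedule: StimulusSchedule,
                     retained: np.ndarray | None = None,
                     baseline_span: float = 5.0,
                     post_span: float = 20.0) -> np.ndarray:
    """Trial-averaged, baseline-subtracted trace per cell.

    dF/F is already a fractional change, so trials are baseline-subtracted
    (mean of the final 1 s of baseline) rather than ratio-normalized.
    """
    from nvp.trials import segment_trials

    out = []
    for c in range(traces.n_cells):
        ts = segment_trials(traces.dff[c], traces.sample_rate, schedule,
                            baseline_span=baseline_span, post_span=post_span)
        keep = ts.retained if retained is None else (ts.retained & retained[:ts.n_trials])
        rows = []
        onset = ts.onset_index
        n1 = int(round(1.0 * traces.sample_rate))
        for k in range(ts.n_trials):
            if not keep[k]:
                continue
            tr = ts.trials[k]
            rows.append(tr - tr[onset - n1:onset].mean())
        out.append(np.mean(rows, axis=0))
    return np.array(out)


@dataclass
class NVCIndex:
    value: float
    vessel_id: str
    group: str
    n_neuronal: int


def nvci(vessel_auc: float, neuronal_aucs, vessel_id: str = "",
         group: str = "") -> NVCIndex:
    """Neurovascular coupling index: vessel AUC / mean neuronal AUC.

    Homogeneous of degree -1 in the neuronal AUCs and linear in the vessel
    AUC.  Raises if the neuronal mean is non-positive (index undefined).
    """
    arr = np.asarray(list(neuronal_aucs), dtype=float)
    if arr.size == 0:
        raise ValueError("neuronal AUC list is empty")
    mean_n = float(np.nanmean(arr))
    if not np.isfinite(mean_n) or mean_n <= 0:
        raise ValueError("mean neuronal AUC non-positive; NVCi undefined")
    return NVCIndex(value=float(vessel_auc) / mean_n, vessel_id=vessel_id,
                    group=group, n_neuronal=int(np.isfinite(arr).sum()))
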