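"""Stimulus-locked trial analysis.

Cuts any time series into 30 s trials (5 s baseline, 5 s stimulus, 20 s
post), gates trials by locomotion in the 2 s before and during the
stimulus, normalizes each trial to the final 1 s of its baseline, and
computes response metrics: max peak (% change), AUC over the stimulus
window, time to peak, and the 2-SD responsiveness flag, aggregated to a
per-vessel % responsiveness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from nvp.core import LocomotionTrace, StimulusSchedule, TrialSet

log = logging.getLogger(__name__)


@dataclass
class ResponseMetrics:
    """Per-trial response metrics on a normalized (% change) trial."""

    max_peak: float          # % change from baseline
    auc: float               # %.s over the stimulus window
    time_to_peak: float      # s from stimulus onset
    baseline_sd: float       # SD of the normalized 5 s baseline
    responsive: bool
    valid: bool = True
    reason: str | None = None

    @classmethod
    def invalid(cls, reason: str) -> "ResponseMetrics":
        return cls(max_peak=float("nan"), auc=float("nan"),
                   time_to_peak=float("nan"), baseline_sd=float("nan"),
                   responsive=False, valid=False, reason=reason)


def segment_trials(trace: np.ndarray, sample_rate: float,
                   schedule: StimulusSchedule, baseline_span: float = 5.0,
                   post_span: float = 20.0) -> TrialSet:
    """Cut a trace into stimulus-locked trials.

    One row per stimulus onset; onsets whose trial window (baseline before,
    stimulus + post after) does not fit inside the recording are dropped
    with a logged reason.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    pre = int(round(baseline_span * sample_rate))
    post = int(round((schedule.stim_dur + post_span) * sample_rate))
    rows, kept_onsets = [], []
    for onset in schedule.onsets:
        i = int(round(onset * sample_rate))
        if i - pre < 0 or i + post > n:
            log.info("dropping partial trial at onset %.2f s (out of range)",
                     onset)
            continue
        rows.append(trace[i - pre:i + post])
        kept_onsets.append(onset)
    if not rows:
        raise ValueError("no complete trial fits inside the recording")
    return TrialSet(trials=np.array(rows), sample_rate=sample_rate,
                    stim_dur=schedule.stim_dur, baseline_span=baseline_span,
                    post_span=post_span, onset_times=np.array(kept_onsets))


def gate_locomotion(tset: TrialSet, locomotion: LocomotionTrace,
                    pre_window: float = 2.0,
                    speed_eps: float = 0.0) -> TrialSet:
    """Exclude trials during which the mouse ran.

    A trial is excluded (retained=False, reason "locomotion") if speed
    exceeds ``speed_eps`` anywhere in [onset - pre_window, onset +
    stim_dur].  Idempotent: re-gating an already gated set is a no-op.
    """
    if tset.onset_times is None:
        raise ValueError("trial set lacks onset times; segment first")
    retained = tset.retained.copy()
    reasons = list(tset.exclusion_reasons)
    for k, onset in enumerate(tset.onset_times):
        i0 = max(int(np.floor((onset - pre_window) * locomotion.sample_rate)), 0)
        i1 = min(int(np.ceil((onset + tset.stim_dur) * locomotion.sample_rate)),
                 len(locomotion.speed))
        if np.any(locomotion.speed[i0:i1] > speed_eps):
            retained[k] = False
            reasons[k] = "locomotion"
    return TrialSet(trials=tset.trials, sample_rate=tset.sample_rate,
                    stim_dur=tset.stim_dur, baseline_span=tset.baseline_span,
                    post_span=tset.post_span, retained=retained,
                    exclusion_reasons=reasons, onset_times=tset.onset_times)


def normalize_trial(trial: np.ndarray, sample_rate: float,
                    baseline_span: float = 5.0,
                    norm_window: float = 1.0) -> np.ndarray:
    """Normalize a trial to % change from the final ``norm_window`` seconds
    of its pre-stimulus baseline.

    Returns trial / mean(last 1 s before onset) * 100 - 100.  Scale
    invariant: doubling the raw units leaves the output unchanged.  Raises
    if the baseline mean is non-positive (normalization undefined).
    """
    trial = np.asarray(trial, dtype=float)
    onset = int(round(baseline_span * sample_rate))
    n_norm = int(round(norm_window * sample_rate))
    if n_norm < 1 or onset - n_norm < 0:
        raise ValueError("trial has less than 1 s of baseline")
    base = trial[onset - n_norm:onset].mean()
    if base <= 0:
        raise ValueError("baseline mean is non-positive; cannot normalize")
    return trial / base * 100.0 - 100.0


def response_metrics(trial_norm: np.ndarray, sample_rate: float,
                     baseline_span: float = 5.0,
                     stim_dur: float = 5.0) -> ResponseMetrics:
    """Metrics of a normalized trial.

    baseline_sd is the SD of the full 5 s baseline of the normalized trace
    (while normalization itself used only its final 1 s); max_peak and the
    trapezoidal AUC are taken over the stimulus window; a trial is
    responsive when max_peak > 2 * baseline_sd.
    """
    y = np.asarray(trial_norm, dtype=float)
    if not np.all(np.isfinite(y)):
        return ResponseMetrics.invalid("non-finite normalized trial")
    onset = int(round(baseline_span * sample_rate))
    offset = int(round((baseline_span + stim_dur) * sample_rate))
    if offset > len(y) or onset < 1:
        return ResponseMetrics.invalid("trial too short for stimulus window")
    baseline_sd = float(y[:onset].std(ddof=0))
    stim = y[onset:offset]
    ipk = int(np.argmax(stim))
    max_peak = float(stim[ipk])
    auc = float(np.trapezoid(stim, dx=1.0 / sample_rate))
    ttp = ipk / sample_rate
    return ResponseMetrics(max_peak=max_peak, auc=auc, time_to_peak=ttp,
                           baseline_sd=baseline_sd,
                           responsive=bool(max_peak > 2.0 * baseline_sd))


def trial_metrics(tset: TrialSet) -> list[ResponseMetrics]:
    """Normalize and score every retained trial of a TrialSet.

    Excluded trials get an invalid placeholder carrying their exclusion
    reason, so indices stay aligned with the trial matrix.
    """
    out = []
    for k in range(tset.n_trials):
        if not tset.retained[k]:
            out.append(ResponseMetrics.invalid(
                tset.exclusion_reasons[k] or "excluded"))
            continue
        try:
            norm = normalize_trial(tset.trials[k], tset.sample_rate,
                                   tset.baseline_span)
        except ValueError as err:
            out.append(ResponseMetrics.invalid(str(err)))
            continue
        out.append(response_metrics(norm, tset.sample_rate,
                                    tset.baseline_span, tset.stim_dur))
    return out


def responsiveness(metrics: list[ResponseMetrics]) -> float:
    """% of retained (valid) trials classified responsive.

    Excluded/invalid trials do not enter the denominator.  Raises if no
    trial was retained.
    """
    usable = [m for m in metrics if m.valid]
    if not usable:
        raise ValueError("no retained trials; responsiveness undefined")
    return 100.0 * sum(m.responsive for m in usable) / len(usable)


def mean_response(tset: TrialSet) -> np.ndarray:
    """Mean normalized trace over retained trials (the per-vessel average
    response used for group time-course figures).  Metrics of this mean
    trace are exposed separately from per-trial metrics."""
    rows = []
    for k in range(tset.n_trials):
        if not tset.retained[k]:
            continue
        try:
            rows.append(normalize_trial(tset.trials[k], tset.sample_rate,
                                        tset.baseline_span))
        except ValueError:
            continue
    if not rows:
        raise ValueError("no retained trials to average")
    return np.mean(rows, axis=0)
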