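"""Net haemodynamics: CMRO2, rest-period baselines and reference-group
normalization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nvp.core import HEMO_CHANNELS, HemoRecording, LocomotionTrace


def cmro2(cbf, hbd, hbt):
    """Cerebral metabolic rate of oxygen: CMRO2 = CBF * Hbd / Hbt.

    Works elementwise on arrays or scalars.  Samples with Hbt <= 0 are
    flagged invalid (NaN).  The ratio is invariant to common rescaling of
    Hbd and Hbt, and the result is linear in CBF.
    """
    cbf = np.asarray(cbf, dtype=float)
    hbd = np.asarray(hbd, dtype=float)
    hbt = np.asarray(hbt, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(hbt > 0, cbf * hbd / np.where(hbt > 0, hbt, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def rest_periods(locomotion: LocomotionTrace, min_rest: float = 10.0,
                 speed_eps: float = 0.0) -> list[tuple[int, int]]:
    """Contiguous index spans [i0, i1) with speed <= speed_eps lasting at
    least ``min_rest`` seconds."""
    still = locomotion.speed <= speed_eps
    spans = []
    i = 0
    n = len(still)
    while i < n:
        if still[i]:
            j = i
            while j < n and still[j]:
                j += 1
            if (j - i) / locomotion.sample_rate >= min_rest:
                spans.append((i, j))
            i = j
        else:
            i += 1
    return spans


@dataclass
class RestBaseline:
    means: dict                 # per-channel mean over rest samples
    n_periods: int
    total_rest_s: float


def rest_baseline(rec: HemoRecording, locomotion: LocomotionTrace,
                  min_rest: float = 10.0,
                  speed_eps: float = 0.0) -> RestBaseline:
    """Per-channel baseline: mean over the union of all rest periods of at
    least ``min_rest`` seconds.

    Pooling all qualifying rest samples makes the result a duration-weighted
    mean of per-period means, invariant to period order and to concatenation
    of qualifying periods.  Raises if no period qualifies.
    """
    if abs(locomotion.sample_rate - rec.sample_rate) > 1e-9:
        # resample locomotion gate onto the recording clock
        t_rec = rec.times
        t_loc = np.arange(len(locomotion.speed)) / locomotion.sample_rate
        speed = np.interp(t_rec, t_loc, locomotion.speed)
        locomotion = LocomotionTrace(speed=speed, sample_rate=rec.sample_rate)
    spans = rest_periods(locomotion, min_rest=min_rest, speed_eps=speed_eps)
    if not spans:
        raise ValueError(f"no rest period of >= {min_rest} s found; "
                         "baseline undefined")
    idx = np.concatenate([np.arange(i0, min(i1, len(rec))) for i0, i1 in spans])
    means = {ch: float(rec.channels[ch].to_numpy()[idx].mean())
             for ch in HEMO_CHANNELS}
    total = len(idx) / rec.sample_rate
    return RestBaseline(means=means, n_periods=len(spans), total_rest_s=total)


def normalize_to_reference(values: pd.DataFrame, reference_group: str,
                           group_col: str = "group",
                           timepoint_col: str = "timepoint",
                           value_cols: list | None = None) -> pd.DataFrame:
    """Normalize per-mouse means to the reference group, within timepoint.

    Each value is divided by the mean of the reference group's values at
    the same timepoint, per column independently, so the reference-group
    mean maps to 1 by construction.  Raises if the reference group is empty
    or has a non-positive mean at any timepoint.
    """
    df = values.copy()
    if value_cols is None:
        value_cols = [c for c in df.columns
                      if c not in (group_col, timepoint_col)
                      and np.issubdtype(df[c].dtype, np.number)]
    for tp, sub in df.groupby(timepoint_col):
        ref = sub[sub[group_col] == reference_group]
        if ref.empty:
            raise ValueError(f"reference group '{reference_group}' empty at "
                             f"timepoint {tp}")
        for col in value_cols:
            ref_mean = ref[col].mean()
            if not np.isfinite(ref_mean) or ref_mean <= 0:
                raise ValueError(
                    f"reference mean for '{col}' non-positive at timepoint {tp}")
            df.loc[sub.index, col] = sub[col] / ref_mean
    return df
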