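"""Trial segmentation, locomotion gating, normalization and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nvp.core import LocomotionTrace, StimulusSchedule
from nvp.synthetic import gen_locomotion
from nvp.trials import (
    gate_locomotion,
    normalize_trial,
    response_metrics,
    responsiveness,
    segment_trials,
    trial_metrics,
)

FS = 7.63


def make_trace(schedule, level=10.0, fs=FS):
    duration = schedule.onsets[-1] + schedule.stim_dur + schedule.isi
    return np.full(int(round(duration * fs)), level)


def test_segment_full_coverage_yields_all_trials(default_schedule):
    trace = make_trace(default_schedule)
    tset = segment_trials(trace, FS, default_schedule)
    assert tset.n_trials == 20


def test_segment_drops_partial_first_trial():
    sched = StimulusSchedule.default(n_stims=5, first_onset=3.0)
    trace = np.full(int(200 * FS), 10.0)
    tset = segment_trials(trace, FS, sched)
    assert tset.n_trials == 4  # first onset has only 3 s of baseline


def test_segment_constant_trace_rows_constant(default_schedule):
    tset = segment_trials(make_trace(default_schedule), FS, default_schedule)
    assert np.ptp(tset.trials) == 0


@pytest.mark.parametrize("bout, excluded", [
    ((9.95, 10.5, 1.0), True),     # spans the 2 s pre-window of onset 12...
    ((5.0, 9.0, 1.0), False),      # ends 3 s before a 12 s onset
    ((22.0, 23.0, 1.0), False),    # post-stimulus only (onset+10 s)
])
def test_gating_layouts(bout, excluded):
    """Hand-enumerated bout/stimulus layouts, onset at 12 s."""
    sched = StimulusSchedule(onsets=np.array([12.0]))
    trace = np.full(int(60 * FS), 10.0)
    tset = segment_trials(trace, FS, sched)
    loco = gen_locomotion([bout], duration=60.0, sample_rate=FS)
    gated = gate_locomotion(tset, loco)
    assert bool(~gated.retained[0]) == excluded
    if excluded:
        assert gated.exclusion_reasons[0] == "locomotion"


def test_gating_boundary_two_seconds_before_onset():
    # bout ending exactly 2.5 s before onset is retained; one ending 1.5 s
    # before (inside the pre-window) is excluded
    sched = StimulusSchedule(onsets=np.array([12.0]))
    trace = np.full(int(60 * FS), 10.0)
    tset = segment_trials(trace, FS, sched)
    keep = gate_locomotion(tset, gen_locomotion([(8.0, 9.5, 1.0)], 60.0, FS))
    drop = gate_locomotion(tset, gen_locomotion([(8.0, 10.5, 1.0)], 60.0, FS))
    assert keep.retained[0]
    assert not drop.retained[0]


def test_gating_idempotent(default_schedule):
    trace = make_trace(default_schedule)
    tset = segment_trials(trace, FS, default_schedule)
    duration = default_schedule.onsets[-1] + 30
    loco = gen_locomotion([(10.0, 40.0, 2.0)], duration, FS)
    once = gate_locomotion(tset, loco)
    twice = gate_locomotion(once, loco)
    np.testing.assert_array_equal(once.retained, twice.retained)


def test_no_bouts_all_retained(default_schedule):
    trace = make_trace(default_schedule)
    tset = segment_trials(trace, FS, default_schedule)
    duration = default_schedule.onsets[-1] + 30
    gated = gate_locomotion(tset, gen_locomotion([], duration, FS))
    assert gated.retained.all()


def test_normalize_constant_trial_is_zero():
    trial = np.full(int(30 * FS), 7.5)
    norm = normalize_trial(trial, FS)
    np.testing.assert_allclose(norm, 0.0, atol=1e-12)


def test_normalize_plateau_percentage():
    fs = 10.0
    trial = np.full(300, 10.0)
    trial[50:100] = 11.0  # stimulus window plateau
    norm = normalize_trial(trial, fs)
    assert norm[60] == pytest.approx(10.0)


@given(scale=st.floats(0.5, 100.0))
@settings(max_examples=20, deadline=None)
def test_normalize_scale_invariance(scale):
    rng = np.random.default_rng(0)
    trial = 10.0 + rng.normal(0, 0.5, int(30 * FS))
    np.testing.assert_allclose(normalize_trial(trial, FS),
                               normalize_trial(trial * scale, FS),
                               atol=1e-9)


def test_normalize_rejects_nonpositive_baseline():
    trial = np.zeros(int(30 * FS))
    with pytest.raises(ValueError, match="non-positive"):
        normalize_trial(trial, FS)


@pytest.mark.parametrize("peak, responsive", [(2.5, True), (1.9, False)])
def test_two_sd_rule(peak, responsive):
    fs = 10.0
    rng = np.random.default_rng(1)
    trial = rng.normal(0, 1.0, 300)
    trial[:50] = rng.standard_normal(50)      # baseline sd ~1
    trial = trial - trial[:50].mean()
    trial[:50] = trial[:50] / trial[:50].std()  # exactly sd 1
    trial[50:100] = 0.0
    trial[60] = peak
    m = response_metrics(trial, fs)
    assert m.baseline_sd == pytest.approx(1.0)
    assert m.responsive == responsive
    assert m.max_peak == pytest.approx(peak)
    assert 0.0 <= m.time_to_peak <= 5.0


def test_metrics_auc_of_plateau():
    fs = 10.0
    trial = np.zeros(300)
    trial[50:100] = 10.0
    m = response_metrics(trial, fs)
    # trapezoid over 5 s of a 10% plateau (edges ramp over one sample)
    assert m.auc == pytest.approx(10.0 * 4.9, rel=0.05)


def test_responsiveness_arithmetic():
    from nvp.trials import ResponseMetrics

    def mk(resp):
        return ResponseMetrics(max_peak=1.0, auc=1.0, time_to_peak=1.0,
                               baseline_sd=0.1, responsive=resp)
    ms = [mk(True), mk(True), mk(True), mk(False)]
    assert responsiveness(ms) == pytest.approx(75.0)
    assert responsiveness([mk(True)] * 5) == pytest.approx(100.0)
    excl = ms + [ResponseMetrics.invalid("locomotion")]
    assert responsiveness(excl) == pytest.approx(75.0)  # excluded not counted


def test_responsiveness_permutation_invariant(rng):
    from nvp.trials import ResponseMetrics

    ms = [ResponseMetrics(1, 1, 1, 0.1, bool(rng.random() < 0.5))
          for _ in range(10)]
    base = responsiveness(ms)
    for _ in range(5):
        perm = [ms[i] for i in rng.permutation(len(ms))]
        assert responsiveness(perm) == base
    assert 0.0 <= base <= 100.0


def test_responsiveness_undefined_without_retained_trials():
    from nvp.trials import ResponseMetrics

    with pytest.raises(ValueError, match="undefined"):
        responsiveness([ResponseMetrics.invalid("locomotion")])


def test_null_trials_match_monte_carlo_oracle(rng):
    """On white-noise null trials the fraction classified responsive matches
    an independent brute-force simulation of the same event (max of the
    stimulus-window samples vs 2x the baseline SD) within its 95% CI."""
    fs = FS
    n_trials = 4000
    level, noise = 100.0, 1.0
    n_samp = int(round(30 * fs))
    onset = int(round(5 * fs))
    offset = int(round(10 * fs))
    n1 = int(round(1 * fs))

    # pipeline path
    hits = 0
    for _ in range(n_trials):
        raw = level + rng.normal(0, noise, n_samp)
        norm = normalize_trial(raw, fs)
        hits += response_metrics(norm, fs).responsive
    pipeline_frac = hits / n_trials

    # independent oracle: replicate the event definition with plain numpy
    oracle_rng = np.random.default_rng(999)
    o_hits = 0
    n_oracle = 10000
    for _ in range(n_oracle):
        raw = level + oracle_rng.normal(0, noise, n_samp)
        y = raw / raw[onset - n1:onset].mean() * 100.0 - 100.0
        o_hits += y[onset:offset].max() > 2.0 * y[:onset].std()
    p = o_hits / n_oracle
    ci = 1.96 * np.sqrt(p * (1 - p) / n_oracle + p * (1 - p) / n_trials)
    assert abs(pipeline_frac - p) <= ci + 0.0


def test_time_reversed_null_same_peak_distribution(rng):
    """Stationarity check: reversing null trials leaves the max-peak
    distribution unchanged (KS test far from rejection)."""
    from scipy.stats import ks_2samp

    fs = FS
    peaks_f, peaks_r = [], []
    for _ in range(400):
        raw = 100.0 + rng.normal(0, 1.0, int(30 * fs))
        peaks_f.append(response_metrics(normalize_trial(raw, fs), fs).max_peak)
        rev = raw[::-1]
        peaks_r.append(response_metrics(normalize_trial(rev, fs), fs).max_peak)
    assert ks_2samp(peaks_f, peaks_r).pvalue > 0.01
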