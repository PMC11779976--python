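"""Generator contracts: determinism, construction invariants, error cases."""

import numpy as np
import pandas as pd
import pytest

from nvp.core import StimulusSchedule
from nvp.synthetic import (
    box_gauss_fwhm,
    gen_anatomy_stack,
    gen_calcium,
    gen_cohort,
    gen_hemo_and_stim,
    gen_kymograph,
    gen_locomotion,
    gen_tracking,
    gen_vessel_movie,
    write_bundle,
)


@pytest.mark.parametrize("gen, kwargs", [
    (gen_vessel_movie, dict(width_fn=10.0, n_frames=3, noise_sd=2.0)),
    (gen_kymograph, dict(velocity_fn=2.0, n_lines=512, noise_sd=0.05)),
    (gen_hemo_and_stim, dict(noise_sd=1.0, stim_n=3)),
    (gen_calcium, dict(classes=["ON", "OFF"], noise_sd=0.1)),
])
def test_same_seed_bit_identical(gen, kwargs):
    a = gen(seed=7, **kwargs)
    b = gen(seed=7, **kwargs)
    first_a, first_b = a[0], b[0]
    for attr in ("data", "dff"):
        if hasattr(first_a, attr):
            np.testing.assert_array_equal(getattr(first_a, attr),
                                          getattr(first_b, attr))
            return
    pd.testing.assert_frame_equal(first_a.channels, first_b.channels)


def test_vessel_movie_rejects_unresolvable_width():
    with pytest.raises(ValueError, match="resolvable limit"):
        gen_vessel_movie(width_fn=0.3, pixel_size=0.23, n_frames=2)


def test_vessel_movie_ground_truth_fwhm_close_to_width():
    # for a PSF much narrower than the vessel, blurring barely widens it
    assert box_gauss_fwhm(10.0, 0.3) == pytest.approx(10.0, rel=0.01)


def test_kymograph_rejects_subpixel_total_displacement():
    with pytest.raises(ValueError, match="pixel displacement"):
        gen_kymograph(velocity_fn=0.0001, n_lines=128, line_rate=1092.0,
                      pixel_size=0.2)


def test_hemo_additivity_and_schedule(default_schedule):
    rec, sched, _ = gen_hemo_and_stim(noise_sd=0.0, seed=0)
    np.testing.assert_allclose(rec.channels["Hbt"],
                               rec.channels["Hbo"] + rec.channels["Hbd"])
    assert sched.n_stims == 20
    spacing = np.diff(sched.onsets)
    np.testing.assert_allclose(spacing, 30.0)  # 5 s stim + 25 s grey


def test_hemo_noiseless_peak_equals_amplitude():
    rec, sched, _ = gen_hemo_and_stim(response_amps={"Flux": 10.0},
                                      noise_sd=0.0, seed=0)
    flux = rec.channels["Flux"].to_numpy()
    base = flux[0]
    i0 = int(sched.onsets[0] * rec.sample_rate)
    i1 = int((sched.onsets[0] + sched.stim_dur) * rec.sample_rate)
    peak_pct = (flux[i0:i1].max() / base - 1.0) * 100.0
    assert peak_pct == pytest.approx(10.0, abs=0.05)


def test_locomotion_speed_nonzero_exactly_in_bouts():
    tr = gen_locomotion([(2.0, 4.0, 3.0)], duration=10.0, sample_rate=10.0)
    t = np.arange(len(tr.speed)) / tr.sample_rate
    inside = (t >= 2.0) & (t < 4.0)
    assert np.all(tr.speed[inside] == 3.0)
    assert np.all(tr.speed[~inside] == 0.0)


def test_locomotion_rejects_overlapping_bouts():
    with pytest.raises(ValueError, match="overlapping"):
        gen_locomotion([(0.0, 5.0, 1.0), (4.0, 8.0, 1.0)], duration=10.0)


def test_anatomy_rejects_degenerate_segment():
    with pytest.raises(ValueError, match="zero-length"):
        gen_anatomy_stack([((5, 5, 5), (5, 5, 5), 3.0)])


def test_anatomy_ground_truth_length():
    _, _, gt = gen_anatomy_stack(
        [((10.0, 20.0, 5.0), (10.0, 20.0, 105.0), 3.0)],
        shape=(20, 90, 250), seed=0)
    assert gt.true_network_length == pytest.approx(100.0)


def test_tracking_dropout_fraction_and_path_length():
    table, gt = gen_tracking([(0, 0), (100, 0)], fps=30, duration=120,
                             dropout_rate=0.1, seed=3)
    assert gt.true_path_length == pytest.approx(100.0)
    frac = (table["likelihood"] < 1).groupby(table["frame"]).first().mean()
    assert frac == pytest.approx(0.1, abs=0.02)


def test_tracking_stationary_mouse_moving_wheel():
    table, _ = gen_tracking([(50, 50), (50, 50)], wheel_rotations=3.0,
                            fps=30, duration=30, seed=0)
    mouse = table[table["label"] == "head"]
    assert mouse["x"].std() == 0 and mouse["y"].std() == 0
    wheel = table[table["label"] == "wheel_outer"]
    assert wheel["x"].std() > 0


def test_cohort_monotone_responsiveness_in_multiplier():
    """Raising the responsiveness multiplier never lowers the recovered
    group-mean responsiveness (3 levels, fixed seeds)."""
    from nvp.pipeline import run_cohort

    means = []
    for mult in (0.5, 0.75, 1.0):
        table = {
            "REF": {"resp_prob": 1.0, "resp_amp": 1.0, "neuro_amp": 1.0},
            "VAR": {"resp_prob": mult, "resp_amp": 1.0, "neuro_amp": 1.0},
        }
        b = gen_cohort(effect_table=table, n_mice_per_group=2,
                       vessels_per_mouse=4, n_stims=10, seed=11)
        res = run_cohort(b)
        v = res["vessels"]
        means.append(v[v.group == "VAR"]["responsiveness_pct"].mean())
    assert means[0] <= means[1] <= means[2]


def test_cohort_bundle_roundtrip(tmp_path):
    b = gen_cohort(n_mice_per_group=1, vessels_per_mouse=2, n_stims=5,
                   seed=2, out_dir=tmp_path)
    assert (tmp_path / "ground_truth.json").exists()
    meta = pd.read_csv(tmp_path / "cohort.csv")
    assert len(meta) == 4 * 1 * 2  # groups x mice x vessels
    first = b.mice[0]
    d = tmp_path / f"{first.mouse}_tp{first.timepoint}"
    from nvp.io import read_locomotion_csv, read_trace_csv

    values, rate = read_trace_csv(d / f"{first.vessels[0].vessel_id}.csv")
    np.testing.assert_allclose(values, first.vessels[0].diameter)
    loco = read_locomotion_csv(d / "locomotion.csv")
    np.testing.assert_allclose(loco.speed, first.locomotion.speed)


def test_cohort_fixed_seed_identical_bundle(tmp_path):
    b1 = gen_cohort(n_mice_per_group=1, vessels_per_mouse=1, n_stims=3, seed=5)
    b2 = gen_cohort(n_mice_per_group=1, vessels_per_mouse=1, n_stims=3, seed=5)
    for m1, m2 in zip(b1.mice, b2.mice):
        np.testing.assert_array_equal(m1.vessels[0].diameter,
                                      m2.vessels[0].diameter)
        np.testing.assert_array_equal(m1.calcium.dff, m2.calcium.dff)
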