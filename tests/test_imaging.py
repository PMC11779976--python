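"""Diametry and velocimetry against constructions with known truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nvp.core import Kymograph, VesselMovie
from nvp.imaging import (
    classify_vessel,
    diameter_trace,
    fwhm,
    rbcv_radon,
    skeletonize_2d,
)
from nvp.synthetic import gen_kymograph, gen_vessel_movie


def gaussian_profile(sigma_px: float, n: int = 61, center=None):
    x = np.arange(n, dtype=float)
    c = (n - 1) / 2 if center is None else center
    return np.exp(-0.5 * ((x - c) / sigma_px) ** 2)


GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@pytest.mark.parametrize("sigma", [1, 2, 3, 4, 5, 6])
def test_fwhm_gaussian_closed_form(sigma):
    n = max(12 * sigma + 1, 41)
    width = fwhm(gaussian_profile(sigma, n), pixel_size=0.5)
    assert width == pytest.approx(GAUSS_FWHM * sigma * 0.5, rel=0.01)


def test_fwhm_rectangular_profile():
    prof = np.zeros(30)
    prof[10:20] = 1.0
    assert fwhm(prof, pixel_size=1.0) == pytest.approx(10.0, abs=1.0)


def test_fwhm_noise_robustness(rng):
    """Monte-Carlo: 5% peak noise changes the mean estimate by < 2%."""
    clean = gaussian_profile(4.0, 61)
    truth = fwhm(clean, 1.0)
    est = []
    for _ in range(100):
        est.append(fwhm(clean + rng.normal(0, 0.05, clean.shape), 1.0))
    assert np.mean(est) == pytest.approx(truth, rel=0.02)


@given(scale=st.floats(0.1, 50.0), offset=st.floats(-5.0, 5.0))
@settings(max_examples=25, deadline=None)
def test_fwhm_scale_and_offset_invariance(scale, offset):
    prof = gaussian_profile(3.0, 41)
    base = fwhm(prof, 1.0)
    assert fwhm(prof * scale, 1.0) == pytest.approx(base, rel=1e-6)
    assert fwhm(prof + offset, 1.0) == pytest.approx(base, rel=1e-3)


def test_fwhm_clipped_profile_flagged():
    # peak at the very edge: no left crossing
    prof = np.exp(-0.5 * (np.arange(20) / 3.0) ** 2)
    assert np.isnan(fwhm(prof, 1.0))


@pytest.mark.parametrize("orientation, expected", [
    # tangents are (y, x) row-major: a horizontal ridge runs along x
    (0.0, (0.0, 1.0)),
    (45.0, (np.sqrt(2) / 2, np.sqrt(2) / 2)),
])
def test_skeleton_tangents_follow_ridge(orientation, expected):
    movie, _ = gen_vessel_movie(8.0, n_frames=1, orientation=orientation,
                                noise_sd=0.0, seed=0)
    skel = skeletonize_2d(movie.mean_image(), movie.pixel_size)
    # ignore the few endpoint tangents
    t = skel.tangents[5:-5]
    dots = np.abs(t @ np.asarray(expected))
    assert np.median(dots) > 0.99


def test_skeleton_keeps_largest_of_two_ridges():
    yy, xx = np.mgrid[0:100, 0:100].astype(float)
    big = np.exp(-0.5 * ((yy - 30) / 3) ** 2)       # full-width ridge
    small = np.where(xx < 20, np.exp(-0.5 * ((yy - 70) / 3) ** 2), 0.0)
    skel = skeletonize_2d(big + small, pixel_size=0.5)
    assert np.all(np.abs(skel.points[:, 0] - 30) < 5)


def test_skeleton_error_on_blank_image():
    with pytest.raises(ValueError):
        skeletonize_2d(np.zeros((50, 50)), pixel_size=0.5)


def test_diameter_trace_constant_width():
    movie, gt = gen_vessel_movie(10.0, n_frames=10, noise_sd=0.0, seed=0)
    skel = skeletonize_2d(movie.mean_image(), movie.pixel_size)
    trace = diameter_trace(movie, skel)
    np.testing.assert_allclose(trace.values, gt.true_fwhm_trace[0], rtol=0.02)


def test_diameter_trace_step_dilation():
    step_frame = 10
    wf = lambda t: np.where(np.arange(len(t)) < step_frame, 10.0, 12.0)
    movie, _ = gen_vessel_movie(wf, n_frames=20, noise_sd=0.0, seed=0)
    skel = skeletonize_2d(movie.mean_image(), movie.pixel_size)
    trace = diameter_trace(movie, skel)
    assert np.all(trace.values[:step_frame] < 11.0)
    assert np.all(trace.values[step_frame:] > 11.0)


def test_diameter_trace_rotation_consistency():
    movie, _ = gen_vessel_movie(10.0, n_frames=5, noise_sd=1.0, seed=4)
    rot = VesselMovie(data=np.rot90(movie.data, axes=(1, 2)).copy(),
                      pixel_size=movie.pixel_size, frame_rate=movie.frame_rate)
    t1 = diameter_trace(movie, skeletonize_2d(movie.mean_image(),
                                              movie.pixel_size))
    t2 = diameter_trace(rot, skeletonize_2d(rot.mean_image(),
                                            rot.pixel_size))
    np.testing.assert_allclose(t1.values, t2.values, rtol=0.01)


@pytest.mark.parametrize("velocity", [0.5, 2.0, -2.0, 5.0])
def test_rbcv_recovers_constant_velocity(velocity):
    kymo, _ = gen_kymograph(velocity, n_lines=1024, noise_sd=0.05,
                            seed=int(abs(velocity) * 10))
    trace = rbcv_radon(kymo)
    assert trace.valid.mean() > 0.9
    got = np.nanmean(trace.values)
    assert got == pytest.approx(velocity, rel=0.05)


def test_rbcv_pure_noise_all_flagged(rng):
    kymo = Kymograph(data=rng.normal(1.0, 0.2, (1024, 128)),
                     line_rate=1092.0, pixel_size=0.2)
    trace = rbcv_radon(kymo)
    assert not trace.valid.any()
    assert np.all(np.isnan(trace.values))


def test_rbcv_blank_window_flagged_not_fatal():
    kymo = Kymograph(data=np.ones((256, 128)), line_rate=1092.0,
                     pixel_size=0.2)
    trace = rbcv_radon(kymo)
    assert not trace.valid.any()


@pytest.mark.parametrize("diameter, superficial, expected", [
    (6.0, False, "capillary"),
    (6.9, True, "capillary"),
    (7.0, False, "intermediate"),     # boundary -> intermediate
    (10.0, True, "intermediate"),
    (12.0, True, "intermediate"),     # boundary -> intermediate
    (13.0, True, "pial"),
    (13.0, False, "intermediate"),    # deep large vessel, warned
])
def test_classify_vessel(diameter, superficial, expected):
    assert classify_vessel(diameter, superficial) == expected
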