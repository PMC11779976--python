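"""Ex vivo morphometry on tube phantoms with known geometry."""

import numpy as np
import pytest

from nvp import anatomy as an
from nvp.core import PericyteSet
from nvp.synthetic import gen_anatomy_stack

VOX = (1.0, 0.45, 0.45)


@pytest.fixture(scope="module")
def straight_tube():
    """500 um straight tube, radius 3 um."""
    stack, somata, gt = gen_anatomy_stack(
        segments=[((15.0, 25.0, 10.0), (15.0, 25.0, 510.0), 3.0)],
        voxel_size=VOX, shape=(30, 110, 1160), noise_sd=5.0, seed=1)
    mask, method = an.threshold_stack(stack)
    skel = an.skeleton_3d(mask, VOX)
    return stack, mask, method, skel, gt


def test_threshold_separates_two_level_phantom(straight_tube):
    stack, mask, method, _, _ = straight_tube
    # IoU against the noiseless construction
    truth = stack.data > 100.0  # amplitude 200 over background 10
    inter = np.logical_and(mask, truth).sum()
    union = np.logical_or(mask, truth).sum()
    assert inter / union >= 0.9
    assert method in ("Default", "Huang", "Huang2", "Li")


def test_threshold_choice_deterministic(straight_tube):
    stack, mask, method, _, _ = straight_tube
    mask2, method2 = an.threshold_stack(stack)
    assert method2 == method
    np.testing.assert_array_equal(mask, mask2)


def test_threshold_warns_on_inverted_contrast():
    stack, _, _ = gen_anatomy_stack(
        segments=[((10.0, 22.0, 5.0), (10.0, 22.0, 95.0), 3.0)],
        voxel_size=VOX, shape=(20, 100, 230), noise_sd=2.0, seed=2)
    stack.data = stack.data.max() - stack.data  # dark vessels
    with pytest.warns(UserWarning, match="polarity"):
        an.threshold_stack(stack)


def test_skeleton_length_straight_tube(straight_tube):
    _, _, _, skel, gt = straight_tube
    assert skel.total_length_um == pytest.approx(gt.true_network_length,
                                                 rel=0.05)


def test_skeleton_length_rotation_invariant():
    """A 45-degree in-plane tube of the same length is recovered within 5%."""
    L = 300.0
    d = L / np.sqrt(2.0)
    stack, _, _ = gen_anatomy_stack(
        segments=[((12.0, 15.0, 15.0), (12.0, 15.0 + d, 15.0 + d), 3.0)],
        voxel_size=VOX, shape=(24, 530, 530), noise_sd=2.0, seed=3)
    mask, _ = an.threshold_stack(stack)
    skel = an.skeleton_3d(mask, VOX)
    assert skel.total_length_um == pytest.approx(L, rel=0.05)


def test_y_junction_single_branch_cluster():
    stack, _, _ = gen_anatomy_stack(
        segments=[
            ((12.0, 25.0, 5.0), (12.0, 25.0, 100.0), 3.0),
            ((12.0, 25.0, 100.0), (12.0, 70.0, 180.0), 3.0),
            ((12.0, 25.0, 100.0), (12.0, 25.0, 195.0), 3.0),
        ],
        voxel_size=VOX, shape=(24, 180, 460), noise_sd=2.0, seed=4)
    mask, _ = an.threshold_stack(stack)
    skel = an.skeleton_3d(mask, VOX)
    assert an.branch_point_clusters(skel) == 1


def test_radii_from_distance_map(straight_tube):
    _, mask, _, skel, _ = straight_tube
    radii = an.radii_from_distance_map(mask, skel, VOX)
    assert np.nanmedian(radii) == pytest.approx(3.0, abs=max(VOX))


def test_radius_scales_with_phantom_radius():
    med = {}
    for r in (2.0, 4.0):
        stack, _, _ = gen_anatomy_stack(
            segments=[((12.0, 25.0, 5.0), (12.0, 25.0, 155.0), r)],
            voxel_size=VOX, shape=(24, 110, 360), noise_sd=2.0, seed=5)
        mask, _ = an.threshold_stack(stack)
        skel = an.skeleton_3d(mask, VOX)
        med[r] = np.nanmedian(an.radii_from_distance_map(mask, skel, VOX))
    assert med[4.0] == pytest.approx(2 * med[2.0], abs=max(VOX))


def test_vessel_density_arithmetic_and_filter(straight_tube):
    stack, mask, _, skel, gt = straight_tube
    dens = an.vessel_density(skel, stack.volume_mm3)
    expected = (gt.true_network_length / 1000.0) / stack.volume_mm3
    assert dens == pytest.approx(expected, rel=0.05)
    radii = an.radii_from_distance_map(mask, skel, VOX)
    # the tube is 6 um in diameter: counted under a 7 um filter,
    # excluded under a 5 um filter
    under7 = an.vessel_density(skel, stack.volume_mm3, radii_um=radii,
                               max_diameter_um=7.0)
    under5 = an.vessel_density(skel, stack.volume_mm3, radii_um=radii,
                               max_diameter_um=5.0)
    assert under7 == pytest.approx(dens, rel=0.10)
    assert under5 < 0.2 * dens


def test_vessel_density_rejects_zero_volume(straight_tube):
    _, _, _, skel, _ = straight_tube
    with pytest.raises(ValueError):
        an.vessel_density(skel, 0.0)


def test_pericyte_density_counts_and_capture(straight_tube):
    stack, _, _, skel, _ = straight_tube
    on_vessel = np.array([[15.0, 25.0, 100.0], [15.0, 25.0, 300.0]])
    far_away = np.array([[15.0, 48.0, 200.0]])  # > 20 um off the axis
    somata = PericyteSet(positions_um=np.vstack([on_vessel, far_away]))
    snapped = an.snap_somata(somata, skel, VOX)
    dens = an.pericyte_density(snapped, skel, stack.volume_mm3, VOX)
    assert dens.n_counted == 2
    assert dens.n_excluded == 1
    assert dens.per_mm_vessel == pytest.approx(
        2.0 / (skel.total_length_um / 1000.0))


def test_constriction_profile_minimum_at_soma():
    """20% constriction at the soma with 10 um extent: profile minimum in
    bin 0, recovering ~0.8x the far-field diameter."""
    stack, somata, _ = gen_anatomy_stack(
        segments=[((15.0, 25.0, 10.0), (15.0, 25.0, 410.0), 3.0)],
        pericytes=[(0, 0.5, 0.2, 10.0)],
        voxel_size=VOX, shape=(30, 110, 940), noise_sd=2.0, seed=6)
    mask, _ = an.threshold_stack(stack)
    skel = an.skeleton_3d(mask, VOX)
    radii = an.radii_from_distance_map(mask, skel, VOX)
    snapped = an.snap_somata(somata, skel, VOX)
    prof = an.diameter_vs_soma_distance(skel, radii, snapped, VOX,
                                        bin_width_um=2.0, max_dist_um=50.0)
    d = prof["mean_diameter_um"].to_numpy()
    assert np.nanargmin(d) == 0
    far = np.nanmean(d[-5:])
    assert d[0] == pytest.approx(0.8 * far, rel=0.05)


def test_no_constriction_flat_profile(straight_tube):
    stack, mask, _, skel, _ = straight_tube
    radii = an.radii_from_distance_map(mask, skel, VOX)
    somata = PericyteSet(positions_um=np.array([[15.0, 25.0, 250.0]]))
    snapped = an.snap_somata(somata, skel, VOX)
    prof = an.diameter_vs_soma_distance(skel, radii, snapped, VOX)
    d = prof["mean_diameter_um"].dropna().to_numpy()
    assert np.ptp(d) < 0.15 * d.mean()


def test_two_somata_nearest_path_assignment(straight_tube):
    _, _, _, skel, _ = straight_tube
    somata = PericyteSet(positions_um=np.array([[15.0, 25.0, 100.0],
                                                [15.0, 25.0, 300.0]]))
    snapped = an.snap_somata(somata, skel, VOX)
    assign = an.soma_assignment(skel, snapped, VOX, max_dist_um=90.0)
    pts_um = skel.points * np.asarray(VOX)
    x = pts_um[:, 2]
    covered = assign >= 0
    # points nearer soma 0 along the tube axis are assigned to soma 0
    assert np.all(assign[covered & (x < 190)] == 0)
    assert np.all(assign[covered & (x > 210)] == 1)


def test_empty_mask_rejected():
    with pytest.raises(ValueError):
        an.skeleton_3d(np.zeros((5, 5, 5), dtype=bool), VOX)
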