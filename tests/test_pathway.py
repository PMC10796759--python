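"""Canal estimation: difference image, segmentation, PCA axis, endpoints,
cylinder mask and profile extraction."""

import numpy as np
import pytest

from drillct.core import CTVolume, DrillPath
from drillct.pathway import (
    VoxelCloud,
    cylinder_mask,
    difference_volume,
    estimate_axis_pca,
    extract_profile,
    refine_endpoints,
    segment_canal,
)


def _uniform_volume(value=500.0, n=40, spacing=1.0):
    return CTVolume(np.full((n, n, n), value), (spacing,) * 3, (0.0, 0.0, 0.0))


# ---------------------------------------------------------------------------
# difference_volume


def test_difference_of_identical_volumes_is_zero(aligned_phantom):
    pre, _ = aligned_phantom
    diff = difference_volume(pre, pre)
    assert np.all(diff.data == 0)


def test_difference_is_offset_invariant(aligned_pair_volumes):
    pre, post, _ = aligned_pair_volumes
    d1 = difference_volume(pre, post)
    pre2 = CTVolume(pre.data + 37.0, pre.spacing, pre.origin)
    post2 = CTVolume(post.data + 37.0, post.spacing, post.origin)
    d2 = difference_volume(pre2, post2)
    assert np.allclose(d1.data, d2.data)


def test_difference_grid_mismatch_errors(aligned_phantom):
    pre, _ = aligned_phantom
    other = CTVolume(np.zeros((32, 32, 32)), pre.spacing, pre.origin)
    with pytest.raises(ValueError, match="same grid"):
        difference_volume(pre, other)


# ---------------------------------------------------------------------------
# segment_canal


def test_segment_finds_component_containing_true_axis(aligned_pair_volumes):
    pre, post, truth = aligned_pair_volumes
    diff = difference_volume(pre, post)
    cloud = segment_canal(diff)
    mid = truth.path.point_at(truth.path.length / 2)
    d = np.linalg.norm(cloud.points - mid, axis=1)
    assert d.min() <= np.max(diff.spacing)  # a cloud voxel adjoins the midpoint


def test_segment_threshold_above_max_errors(aligned_pair_volumes):
    pre, post, _ = aligned_pair_volumes
    diff = difference_volume(pre, post)
    with pytest.raises(ValueError, match="canal not detected"):
        segment_canal(diff, threshold_hu=float(diff.data.max()) + 1)


def test_segment_keeps_larger_of_two_blobs():
    data = np.zeros((40, 40, 40))
    data[5:8, 5:8, 5:30] = 1500.0  # large elongated blob: 3*3*25 voxels
    data[30:33, 30:33, 30:33] = 1500.0  # small artifact blob: 27 voxels
    diff = CTVolume(data, (1, 1, 1), (0, 0, 0))
    cloud = segment_canal(diff, threshold_hu=400)
    assert len(cloud) == 3 * 3 * 25
    assert cloud.points[:, 2].max() < 30.0


# ---------------------------------------------------------------------------
# estimate_axis_pca


def test_pca_exact_line_along_z():
    pts = np.array([[10.0, 10.0, float(k)] for k in range(21)])
    cloud = VoxelCloud(pts, np.ones(21), np.zeros(3), np.full(3, 40.0))
    path = estimate_axis_pca(cloud)
    assert np.allclose(np.abs(path.direction), [0, 0, 1], atol=1e-12)
    ends = sorted([path.start[2], path.end[2]])
    assert np.allclose(ends, [0.0, 20.0], atol=1e-9)
    # entry side: z = 0 end is nearer the volume boundary
    assert path.start[2] < path.end[2]


def test_pca_recovers_oblique_phantom_axis(aligned_pair_volumes):
    pre, post, truth = aligned_pair_volumes
    diff = difference_volume(pre, post)
    path = estimate_axis_pca(segment_canal(diff), truth.path.radius)
    cosang = abs(path.direction @ truth.path.direction)
    assert np.degrees(np.arccos(min(1.0, cosang))) <= 2.0


def test_pca_isotropic_blob_has_no_dominant_axis():
    rng = np.random.default_rng(4)
    pts = rng.normal(20, 2.0, size=(500, 3))
    cloud = VoxelCloud(pts, np.ones(500), np.zeros(3), np.full(3, 40.0))
    with pytest.raises(ValueError, match="no dominant axis"):
        estimate_axis_pca(cloud)


def test_pca_needs_enough_voxels():
    pts = np.zeros((5, 3))
    with pytest.raises(ValueError, match="voxels"):
        estimate_axis_pca(VoxelCloud(pts, np.ones(5), np.zeros(3), np.ones(3)))


# ---------------------------------------------------------------------------
# refine_endpoints


def test_refine_endpoints_close_to_truth(aligned_pair_volumes):
    pre, post, truth = aligned_pair_volumes
    diff = difference_volume(pre, post)
    path = refine_endpoints(diff, estimate_axis_pca(segment_canal(diff),
                                                    truth.path.radius))
    tol = 0.5 * float(np.max(pre.spacing))
    assert np.linalg.norm(path.start - truth.path.start) <= tol
    assert np.linalg.norm(path.end - truth.path.end) <= tol


def test_refine_of_true_path_is_stable(aligned_pair_volumes):
    pre, post, truth = aligned_pair_volumes
    diff = difference_volume(pre, post)
    refined = refine_endpoints(diff, truth.path)
    assert abs(refined.length - truth.path.length) < 0.2


def test_refine_keeps_provisional_when_no_crossing():
    diff = _uniform_volume(value=1000.0)  # uniformly high difference
    path = DrillPath((20.0, 20.0, 5.0), (20.0, 20.0, 35.0), 1.5)
    with pytest.warns(UserWarning, match="provisional"):
        refined = refine_endpoints(diff, path)
    assert np.allclose(refined.start, path.start)
    assert np.allclose(refined.end, path.end)


# ---------------------------------------------------------------------------
# cylinder_mask


def test_cylinder_mask_disk_membership_by_hand():
    # axis along z through voxel centres, radius = 1.6 * in-plane spacing:
    # per slice the disk holds centre + 4-neighbours + 4 diagonals = 9
    vol = _uniform_volume(n=15)
    path = DrillPath((7.0, 7.0, 2.0), (7.0, 7.0, 12.0), radius=1.6)
    mask = cylinder_mask(vol, path)
    per_slice = mask.sum(axis=(0, 1))
    assert per_slice[7] == 9
    assert mask[7, 7, 7] and mask[6, 7, 7] and mask[6, 6, 7]
    assert not mask[5, 7, 7]  # distance 2 > 1.6
    assert per_slice[:2].sum() == 0 and per_slice[13:].sum() == 0


def test_cylinder_mask_volume_matches_analytic():
    vol = _uniform_volume(n=64, spacing=0.5)
    path = DrillPath((16.0, 16.0, 6.0), (16.0, 16.0, 26.0), radius=3.0)
    mask = cylinder_mask(vol, path)
    analytic = np.pi * path.radius**2 * path.length
    measured = mask.sum() * 0.5**3
    assert abs(measured - analytic) / analytic < 0.15


def test_cylinder_mask_reversal_invariant(aligned_pair_volumes):
    pre, _, truth = aligned_pair_volumes
    m1 = cylinder_mask(pre, truth.path)
    m2 = cylinder_mask(pre, truth.path.reversed())
    assert np.array_equal(m1, m2)


def test_cylinder_mask_empty_for_tiny_radius():
    vol = _uniform_volume(n=20)
    path = DrillPath((7.25, 7.25, 2.0), (7.25, 7.25, 12.0), radius=0.01)
    with pytest.raises(ValueError, match="empty mask"):
        cylinder_mask(vol, path)


# ---------------------------------------------------------------------------
# extract_profile


def test_profile_homogeneous_volume_constant():
    vol = _uniform_volume(value=500.0)
    path = DrillPath((20.0, 20.0, 5.0), (20.0, 20.0, 25.0), 1.5)
    prof = extract_profile(vol, path)
    # constant up to trilinear float rounding
    assert np.allclose(prof.mean, 500.0, atol=1e-9)
    assert np.allclose(prof.min, 500.0, atol=1e-9)
    assert np.allclose(prof.max, 500.0, atol=1e-9)


def test_profile_two_layer_boundary_location():
    n = 40
    data = np.full((n, n, n), 200.0)
    data[:, :, 20:] = 1000.0  # boundary between voxel centres z=19 and z=20
    vol = CTVolume(data, (1, 1, 1), (0, 0, 0))
    path = DrillPath((20.0, 20.0, 5.0), (20.0, 20.0, 35.0), 1.5)
    prof = extract_profile(vol, path)  # s measured from z=5
    ds = 0.1
    boundary_s = 19.5 - 5.0
    lo = prof.s[prof.mean <= 250.0].max()
    hi = prof.s[prof.mean >= 950.0].min()
    tol = 2 * ds + 1.0  # two steps + one voxel
    assert boundary_s - tol <= lo <= hi <= boundary_s + tol


def test_profile_step_count_for_published_length():
    # a 29.9 mm pathway sampled at 0.1 mm gives exactly 300 positions
    vol = _uniform_volume(value=300.0, n=40)
    path = DrillPath((20.0, 20.0, 4.0), (20.0, 20.0, 33.9), 1.5)
    prof = extract_profile(vol, path, ds=0.1)
    assert len(prof) == 300


def test_profile_commutes_with_hu_offset(aligned_pair_volumes):
    pre, _, truth = aligned_pair_volumes
    shifted = CTVolume(pre.data + 55.0, pre.spacing, pre.origin)
    p1 = extract_profile(pre, truth.path)
    p2 = extract_profile(shifted, truth.path)
    assert np.allclose(p2.mean, p1.mean + 55.0, atol=1e-9)
    assert np.allclose(p2.min, p1.min + 55.0, atol=1e-9)
    assert np.allclose(p2.max, p1.max + 55.0, atol=1e-9)


def test_profile_reversal_reverses_channels():
    rng = np.random.default_rng(9)
    vol = CTVolume(rng.normal(500, 100, (40, 40, 40)), (1, 1, 1), (0, 0, 0))
    path = DrillPath((20.0, 20.0, 5.0), (20.0, 20.0, 25.0), 1.5)  # L = 20 = k*ds
    fwd = extract_profile(vol, path)
    rev = extract_profile(vol, path.reversed())
    assert np.allclose(rev.mean, fwd.mean[::-1], atol=1e-9)
    assert np.allclose(rev.max, fwd.max[::-1], atol=1e-9)


def test_profile_stencil_outside_volume_names_position():
    vol = _uniform_volume(n=20)
    path = DrillPath((18.0, 18.0, 2.0), (18.0, 18.0, 18.0), radius=3.0)
    with pytest.raises(ValueError, match="s = "):
        extract_profile(vol, path)
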