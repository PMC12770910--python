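"""Tangent-normal skull thickness: contours, sampling, chords, aggregation."""

import numpy as np
import pytest

import craniomorph as cm
from craniomorph.thickness import (
    DegenerateSliceError,
    SliceBandError,
    measure_slice,
    sample_points,
    slice_boundaries,
)
from oracles import ellipse_normal_chord


def annulus_slice(shape=(100, 100), center=(50, 50), r_out=40, r_in=35):
    x, y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    r = np.hypot(x - center[0], y - center[1])
    return ((r <= r_out) & (r > r_in)).astype(np.uint8)


# ---------------------------------------------------------------------------
# CT reference mask
# ---------------------------------------------------------------------------

def test_ct_threshold_recovers_phantom_bone(sphere_phantom):
    labels, _, ct, _ = sphere_phantom
    mask = cm.ct_skull_mask(ct, 471.0)
    np.testing.assert_array_equal(mask.data, (labels.data == 2).astype(np.uint8))


def test_ct_threshold_above_bone_warns_empty(sphere_phantom):
    _, _, ct, _ = sphere_phantom
    with pytest.warns(UserWarning, match="empty"):
        mask = cm.ct_skull_mask(ct, 1500.0)
    assert mask.count() == 0


def test_ct_threshold_below_air_rejected(sphere_phantom):
    _, _, ct, _ = sphere_phantom
    with pytest.raises(ValueError, match="-1000"):
        cm.ct_skull_mask(ct, -1500.0)


def test_ct_mask_volume_monotone_in_threshold(two_density_phantom):
    _, _, ct, _ = two_density_phantom
    volumes = [cm.ct_skull_mask(ct, hu).count() for hu in (300, 400, 500, 800)]
    assert all(a >= b for a, b in zip(volumes, volumes[1:]))
    # the cancellous sub-shell (450 HU) drops out between 400 and 500
    assert volumes[1] > volumes[2]


# ---------------------------------------------------------------------------
# measurement band
# ---------------------------------------------------------------------------

def test_select_slices_stated_constants():
    assert cm.select_slices(50, 1.0, 200) == (60, 76)


def test_select_slices_physical_extent_rule():
    z_start, z_end = cm.select_slices(50, 0.95, 200)
    count = z_end - z_start
    assert count == round(16 / 0.95)
    assert count * 0.95 >= 16.0 - 0.95 / 2  # covers ~16 mm of physical extent


def test_select_slices_extent_error_reports_fit():
    with pytest.raises(SliceBandError, match="only 6 of 16"):
        cm.select_slices(50, 1.0, 66)


# ---------------------------------------------------------------------------
# contours and sampling
# ---------------------------------------------------------------------------

def test_annulus_contour_radii():
    sl = annulus_slice(r_out=40, r_in=35)
    outer, inner, _, _ = slice_boundaries(sl)
    r_outer = np.hypot(outer[:, 0] - 50, outer[:, 1] - 50)
    r_inner = np.hypot(inner[:, 0] - 50, inner[:, 1] - 50)
    assert abs(r_outer.mean() - 40) <= 1.0
    assert abs(r_inner.mean() - 35) <= 1.0


def test_solid_disk_is_degenerate():
    sl = annulus_slice(r_out=40, r_in=-1)
    with pytest.raises(DegenerateSliceError):
        slice_boundaries(sl)
    assert measure_slice(sl, 0, (1.0, 1.0)) == []


def test_annulus_with_pocket_still_has_closed_contours():
    sl = annulus_slice(r_out=40, r_in=35)
    sl[88, 50] = 0  # 1-voxel sinus-like pocket inside the wall
    outer, inner, _, cavity = slice_boundaries(sl)
    assert np.allclose(outer[0], outer[-1])
    assert np.allclose(inner[0], inner[-1])
    assert not cavity[88, 50]  # the pocket is not the cranial cavity


def test_sample_points_uniform_on_circle():
    t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    circle = np.stack([50 + 40 * np.cos(t), 50 + 40 * np.sin(t)], axis=1)
    circle = np.vstack([circle, circle[:1]])
    pts = sample_points(circle, n=100)
    assert len(pts) == 100
    # starts at the most anterior vertex
    assert pts[0, 0] == pytest.approx(circle[:, 0].max(), abs=1e-9)
    gaps = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    total = np.sum(np.linalg.norm(np.diff(circle, axis=0), axis=1))
    assert np.all(np.abs(gaps - total / 100) < 0.01 * total / 100 + 1e-6)


def test_sample_points_start_on_voxelized_contour():
    sl = annulus_slice(r_out=40, r_in=-1)
    from craniomorph.thickness import _longest_closed_contour
    contour = _longest_closed_contour(sl.astype(bool))
    pts = sample_points(contour, n=100)
    assert pts[0, 0] == pytest.approx(contour[:, 0].max(), abs=1e-9)


def test_sample_points_square_quarters():
    square = np.array(
        [[0.0, 0.0], [0.0, 10.0], [10.0, 10.0], [10.0, 0.0], [0.0, 0.0]]
    )
    pts = sample_points(square, n=4)
    gaps = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    np.testing.assert_allclose(gaps, 10.0)


def test_sample_points_open_contour_rejected():
    open_c = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
    with pytest.raises(ValueError, match="closed"):
        sample_points(open_c)


@pytest.mark.parametrize("seed", range(4))
def test_sample_points_random_smooth_curves(seed):
    """Arc-length gaps agree with an independent cumulative-length check."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    r = 30 + sum(
        rng.uniform(0.5, 2.0) * np.sin(k * t + rng.uniform(0, 2 * np.pi))
        for k in range(2, 5)
    )
    curve = np.stack([50 + r * np.cos(t), 50 + r * np.sin(t)], axis=1)
    curve = np.vstack([curve, curve[:1]])
    pts = sample_points(curve, n=64)
    gaps = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    total = np.sum(np.linalg.norm(np.diff(curve, axis=0), axis=1))
    assert np.all(np.abs(gaps - total / 64) <= 0.01 * total / 64)


# ---------------------------------------------------------------------------
# normal-chord thickness
# ---------------------------------------------------------------------------

def test_annulus_thickness_within_one_voxel():
    sl = annulus_slice(shape=(100, 100), r_out=20, r_in=15)
    samples = measure_slice(sl, 0, (1.0, 1.0))
    values = [s.thickness_mm for s in samples if s.thickness_mm is not None]
    assert len(values) >= 95
    assert np.all(np.abs(np.array(values) - 5.0) <= 1.0)


def test_ellipse_shell_matches_analytic_normal_chords():
    a_out, b_out, a_in, b_in = 40.0, 32.0, 33.0, 25.0
    x, y = np.meshgrid(np.arange(110), np.arange(110), indexing="ij")
    outer = ((x - 55) / a_out) ** 2 + ((y - 55) / b_out) ** 2 <= 1
    inner = ((x - 55) / a_in) ** 2 + ((y - 55) / b_in) ** 2 <= 1
    sl = (outer & ~inner).astype(np.uint8)
    samples = measure_slice(sl, 0, (1.0, 1.0))
    checked = 0
    for s in samples:
        if s.thickness_mm is None:
            continue
        dx, dy = s.point[0] - 55, s.point[1] - 55
        theta = np.arctan2(dy / b_out, dx / a_out)
        expected = ellipse_normal_chord(a_out, b_out, a_in, b_in, theta)
        assert abs(s.thickness_mm - expected) <= 1.0
        checked += 1
    assert checked >= 90


def test_pocket_spanning_wall_gives_missing_sample():
    sl = annulus_slice(r_out=20, r_in=15)
    # sinus-like air pocket enclosed inside the wall, spanning nearly its
    # full thickness: anterior rays exit into it instead of the cavity
    sl[67:70, 47:54] = 0
    samples = measure_slice(sl, 0, (1.0, 1.0))
    assert len(samples) > 0
    assert any(s.thickness_mm is None for s in samples)


# ---------------------------------------------------------------------------
# band aggregation
# ---------------------------------------------------------------------------

def test_spherical_shell_median_recovery(shell_5mm):
    labels, _, _, truth = shell_5mm
    skull = cm.binarize(labels, "skull")
    z0 = truth["center_voxel"][2] - 18  # band straddles the equator
    result = cm.median_skull_thickness(skull, z0)
    assert abs(result.median_thickness_mm - 5.0) <= 0.5
    assert result.slice_band == (z0 + 10, z0 + 26)
    assert result.n_samples_kept <= result.n_samples_total
    # trimming keeps at least 95% of the pool (minus percentile edge effects)
    assert result.n_samples_kept >= 0.95 * result.n_samples_total - 2


def test_wall_ordering_strict():
    medians = []
    for wall in (4.0, 7.0):
        labels, _, _, truth = cm.make_phantom(cm.shell_spec(wall))
        skull = cm.binarize(labels, "skull")
        result = cm.median_skull_thickness(skull, truth["center_voxel"][2] - 18)
        medians.append(result.median_thickness_mm)
    assert medians[0] < medians[1]


def test_trim_of_near_constant_data_stable(shell_5mm):
    labels, _, _, truth = shell_5mm
    skull = cm.binarize(labels, "skull")
    z0 = truth["center_voxel"][2] - 18
    trimmed = cm.median_skull_thickness(skull, z0)
    untrimmed = cm.median_skull_thickness(skull, z0, trim_pct=100.0)
    assert abs(trimmed.median_thickness_mm - untrimmed.median_thickness_mm) <= 1.0


def test_per_slice_trim_close_to_pooled(shell_5mm):
    labels, _, _, truth = shell_5mm
    skull = cm.binarize(labels, "skull")
    z0 = truth["center_voxel"][2] - 18
    pooled = cm.median_skull_thickness(skull, z0)
    per_slice = cm.median_skull_thickness(skull, z0, per_slice_trim=True)
    assert abs(pooled.median_thickness_mm - per_slice.median_thickness_mm) <= 1.0


def test_insufficient_samples_raises():
    data = np.zeros((40, 40, 80), dtype=np.uint8)
    data[18:22, 18:22, 40:56] = 1  # solid block: every slice degenerate
    with pytest.raises(cm.InsufficientDataError):
        cm.median_skull_thickness(cm.BinaryMask(data=data), 30)


def test_coarse_inplane_spacing_rejected(shell_5mm):
    labels = shell_5mm[0]
    skull = cm.binarize(labels, "skull")
    coarse = cm.BinaryMask(data=skull.data, spacing=(2.0, 2.0, 1.0))
    with pytest.raises(cm.GeometryError, match="in-plane"):
        cm.median_skull_thickness(coarse, 30)


def test_thickness_invariant_to_lateral_flip(shell_5mm):
    labels, _, _, truth = shell_5mm
    skull = cm.binarize(labels, "skull")
    z0 = truth["center_voxel"][2] - 18
    flipped = cm.BinaryMask(data=skull.data[:, ::-1, :].copy(), spacing=skull.spacing)
    a = cm.median_skull_thickness(skull, z0).median_thickness_mm
    b = cm.median_skull_thickness(flipped, z0).median_thickness_mm
    assert a == pytest.approx(b, abs=1e-9)


def test_mri_vs_ct_mask_same_geometry(shell_5mm):
    """Label-derived and HU-thresholded masks of one shell agree to 1 voxel."""
    labels, _, ct, truth = shell_5mm
    z0 = truth["center_voxel"][2] - 18
    mri = cm.median_skull_thickness(cm.binarize(labels, "skull"), z0)
    ct_mask = cm.ct_skull_mask(ct, 471.0)
    ct_res = cm.median_skull_thickness(ct_mask, z0)
    assert abs(mri.median_thickness_mm - ct_res.median_thickness_mm) <= 1.0


# ---------------------------------------------------------------------------
# cross-tool comparison table
# ---------------------------------------------------------------------------

def test_compare_thickness_table():
    results = {
        "ct": [5.60, 6.10, 5.90],
        "mri": [5.46, 6.10, 5.90],
        "identical": [5.60, 6.10, 5.90],
    }
    table = cm.compare_thickness(results, "ct").set_index("tool")
    assert table.loc["identical", "mean_abs_diff_mm"] == pytest.approx(0.0)
    assert table.loc["mri", "mean_abs_diff_mm"] == pytest.approx(0.14 / 3)
    assert table.loc["ct", "is_reference"]


def test_compare_thickness_single_subject_difference():
    table = cm.compare_thickness({"ct": [5.60], "tool": [5.46]}, "ct")
    row = table.set_index("tool").loc["tool"]
    assert row["mean_abs_diff_mm"] == pytest.approx(0.14)


def test_compare_thickness_missing_reference():
    with pytest.raises(KeyError):
        cm.compare_thickness({"a": [1.0], "b": [2.0]}, "zzz")
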