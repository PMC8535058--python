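"""Centerline length, subregion partition, and insertion-box placement."""

import numpy as np
import pytest

from pclt2.geometry import (
    Centerline,
    GeometryError,
    InsertionSite,
    central_pcl_slice,
    compute_centerline,
    measure_length,
    partition_subregions,
    place_insertion_box,
)
from pclt2.relaxometry import summarize_roi

from .conftest import SPACING, curved_tube, straight_tube


def test_polyline_length_three_four_five():
    cl = Centerline(points=np.array([[0.0, 0, 0], [0.0, 3, 4]]),
                    cumulative_arclength=np.zeros(2))
    assert measure_length(cl) == pytest.approx(5.0)


def test_degenerate_one_point_line_rejected():
    with pytest.raises(GeometryError):
        Centerline(points=np.array([[0.0, 0, 0]]), cumulative_arclength=np.zeros(1))


def test_straight_tube_length_exact():
    mask = straight_tube(length=40.0)
    cl = compute_centerline(mask, SPACING)
    assert measure_length(cl) == pytest.approx(40.0, abs=0.5)


def test_quarter_circle_arc_length():
    th = np.linspace(0, np.pi / 2, 2000)
    zc = 4 * 3.2
    curve = np.column_stack([np.full_like(th, zc),
                             6 + 30 * np.sin(th), 6 + 30 * (1 - np.cos(th))])
    mask = curved_tube(curve)
    L = measure_length(compute_centerline(mask, SPACING))
    assert L == pytest.approx(np.pi * 30 / 2, rel=0.02)


def test_length_invariant_under_inplane_rotation():
    zc = 4 * 3.2
    lengths = []
    for ang in (0.0, 30.0):
        a = np.deg2rad(ang)
        t = np.linspace(0, 40.0, 1500)
        curve = np.column_stack([np.full_like(t, zc),
                                 6 + t * np.sin(a), 6 + t * np.cos(a)])
        mask = curved_tube(curve, shape=(9, 140, 140))
        lengths.append(measure_length(compute_centerline(mask, SPACING)))
    assert lengths[1] == pytest.approx(lengths[0], rel=0.01)


def test_slab_count_convergence():
    mask = straight_tube(length=40.0)
    l20 = measure_length(compute_centerline(mask, SPACING, n_slabs=20))
    l40 = measure_length(compute_centerline(mask, SPACING, n_slabs=40))
    assert l40 == pytest.approx(l20, rel=0.01)


def test_disconnected_mask_rejected():
    mask = straight_tube(length=15.0) | straight_tube(length=15.0, x_start=30.0)
    with pytest.raises(GeometryError, match="components"):
        compute_centerline(mask, SPACING)


def test_subregion_partition_covers_and_splits_25_50_25():
    mask = straight_tube(length=40.0)
    cl = compute_centerline(mask, SPACING)
    part = partition_subregions(mask, cl, SPACING)
    n = mask.sum()
    assert (part.assignment > 0).sum() == n          # coverage
    fracs = [(part.assignment == k).sum() / n for k in (1, 2, 3)]
    assert fracs[0] == pytest.approx(0.25, abs=0.05)
    assert fracs[1] == pytest.approx(0.50, abs=0.05)
    assert fracs[2] == pytest.approx(0.25, abs=0.05)


def test_entire_mean_equals_weighted_subregion_mean(fitted_noisy_d0):
    """Algebraic identity: the entire-ligament mean is the n_valid-weighted
    mean of the three subregion means."""
    t2map, mask, _gt = fitted_noisy_d0
    pcl = mask.mask_for("PCL")
    cl = compute_centerline(pcl, SPACING)
    part = partition_subregions(pcl, cl, SPACING)
    whole = summarize_roi(t2map, pcl)
    parts = [summarize_roi(t2map, part.mask_for(n)) for n in ("PR", "CR", "DR")]
    weighted = sum(p.mean * p.n_valid for p in parts) / sum(p.n_valid for p in parts)
    assert whole.mean == pytest.approx(weighted, abs=1e-9)
    assert whole.n_valid == sum(p.n_valid for p in parts)


def test_loading_stretch_scales_length(noiseless_d0, noiseless_d1):
    _, m0, g0 = noiseless_d0
    _, m1, g1 = noiseless_d1
    l0 = measure_length(compute_centerline(m0.mask_for("PCL"), SPACING))
    l1 = measure_length(compute_centerline(m1.mask_for("PCL"), SPACING))
    assert l1 / l0 == pytest.approx(g1.length / g0.length, rel=0.02)


def _interface_scene(angle_deg=0.0, shape=(3, 120, 120)):
    """Bone half-plane below a (possibly tilted) line, ligament above."""
    dz, dy, dx = SPACING
    nz, ny, nx = shape
    yy, xx = np.meshgrid(np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij")
    a = np.deg2rad(angle_deg)
    n_hat = np.array([np.cos(a), -np.sin(a)])      # normal of the interface
    d = (yy - 20.0) * n_hat[0] + (xx - 24.0) * n_hat[1]
    bone2d = d < 0
    lig2d = (d >= 0) & (d <= 12.0) & (np.abs((xx - 24.0)) <= 8.0)
    pcl = np.zeros(shape, bool)
    bone = np.zeros(shape, bool)
    pcl[1] = lig2d
    bone[1] = bone2d
    return pcl, bone


@pytest.mark.parametrize("angle", [0.0, 30.0])
def test_insertion_box_orientation_tracks_interface(angle):
    pcl, bone = _interface_scene(angle)
    box = place_insertion_box(pcl, bone, InsertionSite.FEMORAL, SPACING, slice_index=1)
    measured = abs(box.angle_deg) % 180
    expected = angle % 180
    tol = 1.0 if angle == 0.0 else 5.0
    assert min(measured - expected, 180 - abs(measured - expected)) == pytest.approx(0.0, abs=tol)


def test_insertion_box_bone_fraction_and_area():
    pcl, bone = _interface_scene(0.0)
    box = place_insertion_box(pcl, bone, InsertionSite.FEMORAL, SPACING, slice_index=1)
    enclosed = box.enclosed_mask(pcl.shape, SPACING)
    area = enclosed.sum() * 0.4 * 0.4
    pixel_row = 10.0 * 0.4  # one row of the 10 mm width
    assert area == pytest.approx(50.0, abs=pixel_row + 0.5)
    frac_bone = (enclosed & bone).sum() / enclosed.sum()
    assert frac_bone == pytest.approx(0.25, abs=0.05)


def test_insertion_box_requires_nearby_bone():
    pcl, bone = _interface_scene(0.0)
    bone[:] = False
    bone[1, -2:, -2:] = True  # far corner only
    with pytest.raises(GeometryError):
        place_insertion_box(pcl, bone, InsertionSite.FEMORAL, SPACING, slice_index=1)


def test_central_slice_is_largest_cross_section():
    mask = np.zeros((5, 10, 10), bool)
    mask[1, :2, :2] = True
    mask[2, :5, :5] = True
    mask[3, :2, :2] = True
    assert central_pcl_slice(mask) == 2
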