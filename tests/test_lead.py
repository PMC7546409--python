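"""Directional-lead geometry, rasterization and GPi targeting."""

import numpy as np
import pytest

from pallisteer import anatomy as an
from pallisteer.anatomy import GeometryError
from pallisteer.lead import (
    CONTACT_IDS,
    PlacementError,
    build_lead,
    contact_label,
    place_at_target,
    rasterize_lead,
    rasterize_on_points,
)


@pytest.mark.parametrize(
    "spacing, expected", [(1.5, 3.0), (0.5, 2.0)]
)
def test_row_center_distance_is_height_plus_spacing(spacing, expected):
    lead = build_lead(spacing)
    d = np.linalg.norm(lead.row_center_mm(3) - lead.row_center_mm(2))
    assert d == pytest.approx(expected)


def test_zero_angles_give_vertical_shaft():
    lead = build_lead(1.5, sagittal_angle_deg=0.0, coronal_angle_deg=0.0)
    assert np.allclose(lead.shaft_direction, [0.0, 0.0, 1.0])


def test_contact_layout_tip_to_shaft():
    lead = build_lead(1.5)
    assert tuple(c.id for c in lead.contacts) == CONTACT_IDS
    intervals = sorted(c.axial_extent_mm for c in lead.contacts)
    for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
        assert hi1 <= lo2 + 1e-12 or lo1 == lo2  # same row shares the interval
    kinds = [c.kind for c in lead.contacts]
    assert kinds == ["ring"] + ["segment"] * 6 + ["ring"]


def test_lead_length_increases_with_spacing():
    lengths = [build_lead(s).active_length_mm for s in (0.5, 1.0, 1.5)]
    assert lengths == sorted(lengths)
    assert lengths[0] < lengths[-1]


def test_degenerate_azimuth_rejected():
    with pytest.raises(GeometryError):
        build_lead(1.5, segment_A_azimuth=(0.0, 0.0, 0.0))
    lead = build_lead(1.5)
    with pytest.raises(GeometryError):
        build_lead(1.5, segment_A_azimuth=lead.shaft_direction)


def _grid_around(lead, h=0.1, half=3.0):
    c = lead.row_center_mm(2)
    axes = [np.arange(c[a] - half, c[a] + half, h) for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.stack([xx, yy, zz], axis=-1)


def test_segment_rotation_maps_2a_onto_2b():
    """Rotating the azimuth reference by 120 deg permutes the segments."""
    lead = build_lead(1.5, sagittal_angle_deg=0.0, coronal_angle_deg=0.0)
    pts = _grid_around(lead)
    labels = rasterize_on_points(lead, pts, 0.1)
    e1, e2, _ = lead.frame()
    rotated = build_lead(
        1.5,
        sagittal_angle_deg=0.0,
        coronal_angle_deg=0.0,
        segment_A_azimuth=np.cos(np.deg2rad(120)) * e1 + np.sin(np.deg2rad(120)) * e2,
    )
    labels_rot = rasterize_on_points(rotated, pts, 0.1)
    set_2b = labels == contact_label("2B")
    set_2a_rot = labels_rot == contact_label("2A")
    # 2A of the rotated lead occupies 2B's voxels of the original
    assert np.array_equal(set_2b, set_2a_rot)


def test_rasterization_idempotent_and_encapsulated(phantom, placed_lead):
    once = rasterize_lead(placed_lead, phantom)
    twice = rasterize_lead(placed_lead, once)
    assert np.array_equal(once.label_grid, twice.label_grid)
    assert np.count_nonzero(once.label_grid == an.ENCAPSULATION) > 0
    for cid in CONTACT_IDS:
        assert np.count_nonzero(once.label_grid == contact_label(cid)) > 0


def test_zero_encapsulation_thickness(phantom, placed_lead):
    from dataclasses import replace

    bare = replace(placed_lead, encapsulation_thickness_mm=0.0)
    model = rasterize_lead(bare, phantom)
    assert np.count_nonzero(model.label_grid == an.ENCAPSULATION) == 0


def test_placement_hits_requested_offsets(phantom, placed_lead):
    rep = placed_lead.placement_report
    h = phantom.voxel_size_mm
    assert abs(rep["achieved_lateral_mm"] - 2.25) <= h
    assert abs(rep["achieved_posterior_mm"] - 2.3) <= h
    # ventral posterolateral octant of the GPi
    gpi = np.argwhere(phantom.label_grid == an.GPI)
    centroid = phantom.origin_mm + (gpi.mean(axis=0) + 0.5) * h
    r2 = placed_lead.row_center_mm(2)
    assert r2[0] > centroid[0] and r2[1] < centroid[1] and r2[2] < centroid[2]


def test_placement_zero_offsets_touch_borders(phantom):
    lead = place_at_target(build_lead(1.5), phantom, target_offsets=(0.0, 0.0))
    rep = lead.placement_report
    h = phantom.voxel_size_mm
    assert abs(rep["achieved_lateral_mm"]) <= h
    assert abs(rep["achieved_posterior_mm"]) <= h


def test_placement_requires_gpi(phantom):
    import copy

    model = phantom.copy()
    model.label_grid[model.label_grid == an.GPI] = an.GPE
    with pytest.raises(PlacementError):
        place_at_target(build_lead(1.5), model)
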