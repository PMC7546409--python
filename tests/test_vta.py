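"""API bounding, voxelization, partition and comparison metrics."""

import numpy as np
import pytest

from pallisteer import anatomy as an
from pallisteer.anatomy import ConsistencyError, TissueModel
from pallisteer.vta import (
    build_vta,
    compare_vtas,
    export_vta,
    flag_side_effect_overlap,
    partition_vta,
    read_vta_mask,
)


def cube_corners(edge=1.0):
    g = np.array([0.0, edge])
    return np.array([[x, y, z] for x in g for y in g for z in g])


def dense_ball(r=1.2, spacing=0.25, center=(0, 0, 0)):
    g = np.arange(-r, r + 1e-9, spacing)
    pts = np.array([[x, y, z] for x in g for y in g for z in g])
    pts = pts[np.linalg.norm(pts, axis=1) <= r]
    return pts + np.asarray(center)


def test_unit_cube_hull_volume():
    """Hull of the 8 corners of a unit cube voxelizes to ~1 mm^3."""
    vta = build_vta(cube_corners(), voxel_size_mm=0.05, mode="hull")
    assert vta.total_volume_mm3 == pytest.approx(1.0, rel=0.05)


def test_empty_and_degenerate_point_sets():
    empty = build_vta(np.zeros((0, 3)), 0.25)
    assert empty.total_volume_mm3 == 0.0 and empty.degenerate
    coplanar = build_vta(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]]), 0.25)
    assert coplanar.degenerate or coplanar.total_volume_mm3 < 0.25**3 * 8


def test_api_sites_contained_in_mask():
    pts = dense_ball()
    vta = build_vta(pts, 0.25, mode="alpha", plane_spacing_mm=0.5)
    idx = np.floor((pts - vta.origin_mm) / vta.voxel_size_mm).astype(int)
    assert np.all(vta.mask[idx[:, 0], idx[:, 1], idx[:, 2]])


def test_alpha_volume_below_hull_volume():
    rng = np.random.default_rng(11)
    pts = np.vstack([dense_ball(center=(0, 0, 0)), dense_ball(center=(4.0, 0, 0))])
    hull = build_vta(pts, 0.2, mode="hull")
    alpha = build_vta(pts, 0.2, mode="alpha", plane_spacing_mm=0.5)
    # the dumbbell's waist is excluded by the alpha criterion
    assert alpha.total_volume_mm3 < hull.total_volume_mm3


def test_superset_points_never_shrink_hull_volume():
    pts = dense_ball(r=1.0)
    more = np.vstack([pts, dense_ball(r=1.5)])
    v1 = build_vta(pts, 0.2, mode="hull").total_volume_mm3
    v2 = build_vta(more, 0.2, mode="hull").total_volume_mm3
    assert v2 >= v1


def _planar_model(h=0.1, n=60):
    """GPi for x < 0, GPe for x >= 0; origin centered on the interface."""
    labels = np.full((n, n, n), an.GPE, dtype=np.int16)
    labels[: n // 2] = an.GPI
    origin = np.array([-n * h / 2, -n * h / 2, -n * h / 2])
    table = dict(an.DEFAULT_SIGMA)
    return TissueModel(labels, h, origin, table)


def test_partition_conservation_and_straddle():
    model = _planar_model()
    # a cube of API sites centered on the GPi|GPe interface
    g = np.arange(-1.0, 1.0 + 1e-9, 0.25)
    pts = np.array([[x, y, z] for x in g for y in g for z in g])
    vta = build_vta(pts, 0.1, mode="hull", grid_origin_mm=model.origin_mm)
    vta = partition_vta(vta, model)
    total = sum(vta.sub_volumes_mm3.values())
    assert total == pytest.approx(vta.total_volume_mm3, abs=1e-9)
    assert sum(vta.percentages.values()) == pytest.approx(100.0, abs=0.1)
    assert vta.percentages["in_GPi"] == pytest.approx(50.0, abs=2.0)
    assert vta.percentages["in_GPe"] == pytest.approx(50.0, abs=2.0)


def test_partition_wholly_inside_gpi():
    model = _planar_model()
    pts = dense_ball(r=0.8, center=(-1.5, 0, 0))
    vta = partition_vta(
        build_vta(pts, 0.1, mode="hull", grid_origin_mm=model.origin_mm), model
    )
    assert vta.percentages["in_GPi"] == pytest.approx(100.0, abs=0.01)


def test_compare_identity_disjoint_and_ratio():
    a = build_vta(dense_ball(r=1.0), 0.2, mode="hull")
    cmp_self = compare_vtas(a, a)
    assert cmp_self.dice == pytest.approx(1.0)
    assert cmp_self.percent_difference == pytest.approx(0.0)
    b = build_vta(dense_ball(r=1.0, center=(10.0, 0, 0)), 0.2, mode="hull")
    assert compare_vtas(a, b).dice == pytest.approx(0.0)
    # 42.9% enlargement is pure arithmetic on the voxel volumes
    from dataclasses import replace as drep

    bigger = build_vta(dense_ball(r=1.0), 0.2, mode="hull")
    bigger.total_volume_mm3 = a.total_volume_mm3 * 1.429
    assert compare_vtas(bigger, a).percent_difference == pytest.approx(42.9, abs=1e-9)
    with pytest.raises(ArithmeticError):
        compare_vtas(a, build_vta(np.zeros((0, 3)), 0.2))


def test_side_effect_overlap_bounds():
    model = _planar_model()
    model.label_grid[-5:] = an.OPTIC_TRACT
    vta = build_vta(
        dense_ball(r=0.8, center=(-1.5, 0, 0)), 0.1, mode="hull",
        grid_origin_mm=model.origin_mm,
    )
    vta = partition_vta(vta, model)
    ov = flag_side_effect_overlap(vta, model, [an.OPTIC_TRACT])
    assert ov == 0.0  # disjoint
    assert ov <= vta.total_volume_mm3
    with pytest.raises(ConsistencyError):
        flag_side_effect_overlap(vta, model, [an.CSF + 50])


def test_export_round_trip(tmp_path):
    vta = build_vta(dense_ball(), 0.25, mode="hull")
    export_vta(vta, tmp_path / "v.nii.gz", tmp_path / "v.stl")
    back = read_vta_mask(tmp_path / "v.nii.gz")
    assert np.count_nonzero(back.mask) == np.count_nonzero(vta.mask)
    assert (tmp_path / "v.stl").stat().st_size > 0
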