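"""Volume of tissue activated: direct bounding of API sites and partition.

The VTA is the 3D volume bounding the action-potential initiation sites of
the activated axon population ("direct bounding", in contrast to center-node
remapping).  Default bounding surface is the 3D alpha-shape of the API point
set with alpha = 2 x the axon-plane spacing (concavity at the scale the
sampling supports); a convex-hull mode is available.  The interior is
voxelized and partitioned four ways against the anatomy: inside GPi, in the
medial medullary lamina (between GPi and GPe), inside GPe, and outside the
globus pallidus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .anatomy import GPE, GPI, LAMINA, TissueModel, GeometryError, ConsistencyError

REGION_KEYS = ("in_GPi", "lamina", "in_GPe", "outside_GP")


class AlignmentError(ValueError):
    """VTA grid does not sit inside the tissue-model domain."""


@dataclass
class VTAResult:
    mask: np.ndarray  # boolean voxel grid
    origin_mm: np.ndarray
    voxel_size_mm: float
    total_volume_mm3: float
    sub_volumes_mm3: dict[str, float] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)
    mode: str = "alpha"
    degenerate: bool = False
    api_sites_mm: np.ndarray | None = None

    def voxel_centers(self) -> np.ndarray:
        idx = np.argwhere(self.mask)
        return self.origin_mm + (idx + 0.5) * self.voxel_size_mm


@dataclass(frozen=True)
class VTAComparison:
    volume_ratio: float
    percent_difference: float
    dice: float
    asymmetry_index: float | None = None


def _tet_circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron (vectorized)."""
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]] - a
    c = points[simplices[:, 2]] - a
    d = points[simplices[:, 3]] - a
    bb = np.einsum("ij,ij->i", b, b)
    cc = np.einsum("ij,ij->i", c, c)
    dd = np.einsum("ij,ij->i", d, d)
    cross_cd = np.cross(c, d)
    cross_db = np.cross(d, b)
    cross_bc = np.cross(b, c)
    denom = 2.0 * np.einsum("ij,ij->i", b, cross_cd)
    num = (
        bb[:, None] * cross_cd + cc[:, None] * cross_db + dd[:, None] * cross_bc
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        center = num / denom[:, None]
    r = np.linalg.norm(center, axis=1)
    r[~np.isfinite(r)] = np.inf  # degenerate tetrahedra never pass the alpha test
    return r


def build_vta(
    activation,
    voxel_size_mm: float = 0.25,
    mode: str = "alpha",
    alpha_mm: float | None = None,
    plane_spacing_mm: float = 0.5,
    grid_origin_mm: np.ndarray | None = None,
) -> VTAResult:
    """Bound the API sites into a voxelized 3D volume.

    ``activation`` is an :class:`~pallisteer.axons.ActivationResult` or a raw
    (n, 3) array of API coordinates.  ``alpha_mm`` defaults to twice the axon
    plane spacing.  The voxel grid is aligned to ``grid_origin_mm`` (so it can
    match a TissueModel grid for exact partition); voxels containing an API
    site are always inside the mask.
    """
    pts = activation if isinstance(activation, np.ndarray) else activation.api_sites()
    pts = np.asarray(pts, dtype=float).reshape(-1, 3)
    if mode not in ("alpha", "hull"):
        raise ValueError("mode must be 'alpha' or 'hull'")
    h = float(voxel_size_mm)

    def _empty() -> VTAResult:
        return VTAResult(
            np.zeros((0, 0, 0), dtype=bool),
            np.zeros(3),
            h,
            0.0,
            mode=mode,
            degenerate=True,
            api_sites_mm=pts,
        )

    if pts.shape[0] < 4:
        return _empty()
    # API sites sit on a regular lattice; the exactly degenerate (cospherical)
    # triangulation makes point location pathologically slow.  A deterministic
    # sub-nanometre jitter breaks the ties without moving any geometry.
    jitter = 1e-6 * np.random.default_rng(0).standard_normal(pts.shape)
    try:
        tri = Delaunay(pts + jitter)
    except QhullError:
        return _empty()  # coplanar/collinear point set: zero volume, flagged
    keep = None
    if mode == "alpha":
        alpha = 2.0 * plane_spacing_mm if alpha_mm is None else float(alpha_mm)
        radii = _tet_circumradii(pts, tri.simplices)
        keep = radii <= alpha
        if not np.any(keep):
            return _empty()

    lo = pts.min(axis=0) - h
    hi = pts.max(axis=0) + h
    if grid_origin_mm is None:
        origin = lo
    else:
        base = np.asarray(grid_origin_mm, dtype=float)
        origin = base + np.floor((lo - base) / h) * h
    n = np.maximum(np.ceil((hi - origin) / h).astype(int), 1)
    axes = [origin[a] + (np.arange(n[a]) + 0.5) * h for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
    simplex = tri.find_simplex(centers)
    inside = simplex >= 0
    if keep is not None:
        inside &= np.where(simplex >= 0, keep[np.clip(simplex, 0, None)], False)
    mask = inside.reshape(tuple(n))
    # containment contract: the voxel of every API site is inside
    idx = np.floor((pts - origin) / h).astype(int)
    idx = np.clip(idx, 0, np.asarray(n) - 1)
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    total = float(np.count_nonzero(mask)) * h**3
    return VTAResult(mask, origin, h, total, mode=mode, api_sites_mm=pts)


def partition_vta(vta: VTAResult, model: TissueModel) -> VTAResult:
    """Fill the four-way sub-volume breakdown by voxel label counting."""
    if vta.degenerate or vta.total_volume_mm3 == 0:
        vta.sub_volumes_mm3 = {k: 0.0 for k in REGION_KEYS}
        vta.percentages = {k: 0.0 for k in REGION_KEYS}
        return vta
    centers = vta.voxel_centers()
    try:
        labels = model.sample_labels(centers)
    except GeometryError as err:
        raise AlignmentError(f"VTA grid leaves the tissue model domain: {err}")
    vv = vta.voxel_size_mm**3
    sub = {
        "in_GPi": float(np.count_nonzero(labels == GPI)) * vv,
        "lamina": float(np.count_nonzero(labels == LAMINA)) * vv,
        "in_GPe": float(np.count_nonzero(labels == GPE)) * vv,
    }
    sub["outside_GP"] = vta.total_volume_mm3 - sum(sub.values())
    vta.sub_volumes_mm3 = sub
    vta.percentages = {
        k: round(100.0 * v / vta.total_volume_mm3, 2) for k, v in sub.items()
    }
    return vta


def asymmetry_index(
    vta: VTAResult, axis_point_mm, axis_direction, azimuth_direction
) -> float:
    """Fraction of VTA volume in the half-space toward the active segment.

    The half-space is bounded by the plane containing the lead axis and
    normal to the (axis-orthogonalized) azimuth direction; 0.5 = axially
    symmetric, 1.0 = entirely on the segment side.
    """
    if vta.total_volume_mm3 == 0:
        return float("nan")
    d = np.asarray(axis_direction, float)
    d = d / np.linalg.norm(d)
    az = np.asarray(azimuth_direction, float)
    az = az - (az @ d) * d
    az = az / np.linalg.norm(az)
    centers = vta.voxel_centers()
    side = (centers - np.asarray(axis_point_mm, float)) @ az
    return float(np.count_nonzero(side > 0) / side.size)


def compare_vtas(
    a: VTAResult, b: VTAResult, azimuth: dict | None = None
) -> VTAComparison:
    """Volume ratio, percent difference 100*(Va-Vb)/Vb, Dice overlap, and
    (optionally) the asymmetry index of ``a`` given a lead axis + azimuth."""
    if b.total_volume_mm3 == 0:
        raise ArithmeticError("reference VTA has zero volume")
    ratio = a.total_volume_mm3 / b.total_volume_mm3
    pct = 100.0 * (a.total_volume_mm3 - b.total_volume_mm3) / b.total_volume_mm3
    dice = _dice(a, b)
    asym = None
    if azimuth is not None:
        asym = asymmetry_index(
            a, azimuth["axis_point_mm"], azimuth["axis_direction"], azimuth["azimuth"]
        )
    return VTAComparison(ratio, pct, dice, asym)


def _dice(a: VTAResult, b: VTAResult) -> float:
    na = int(np.count_nonzero(a.mask)) if a.mask.size else 0
    nb = int(np.count_nonzero(b.mask)) if b.mask.size else 0
    if na + nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    if a.voxel_size_mm != b.voxel_size_mm:
        raise AlignmentError("VTAs must share a voxel size for Dice")
    # voxel sets on the common lattice defined by each grid's origin
    ia = np.argwhere(a.mask) + np.round(a.origin_mm / a.voxel_size_mm).astype(int)
    ib = np.argwhere(b.mask) + np.round(b.origin_mm / b.voxel_size_mm).astype(int)
    if not (
        np.allclose(a.origin_mm / a.voxel_size_mm, np.round(a.origin_mm / a.voxel_size_mm), atol=1e-6)
        and np.allclose(b.origin_mm / b.voxel_size_mm, np.round(b.origin_mm / b.voxel_size_mm), atol=1e-6)
    ):
        raise AlignmentError("VTA grids are not on a common lattice")
    sa = set(map(tuple, ia))
    sb = set(map(tuple, ib))
    inter = len(sa & sb)
    return 2.0 * inter / (len(sa) + len(sb))


def flag_side_effect_overlap(
    vta: VTAResult, model: TissueModel, labels: list[int]
) -> float:
    """VTA volume (mm3) intersecting the named side-effect structure labels."""
    present = set(int(v) for v in np.unique(model.label_grid))
    unknown = [l for l in labels if l not in present]
    if unknown:
        raise ConsistencyError(f"labels absent from the model: {unknown}")
    if vta.total_volume_mm3 == 0:
        return 0.0
    sampled = model.sample_labels(vta.voxel_centers())
    return float(np.count_nonzero(np.isin(sampled, labels))) * vta.voxel_size_mm**3


def export_vta(vta: VTAResult, mask_path: str | Path, surface_path: str | Path | None = None) -> None:
    """Write the mask as NIfTI and (optionally) the surface as STL."""
    import nibabel as nib

    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = vta.voxel_size_mm
    affine[:3, 3] = vta.origin_mm + vta.voxel_size_mm / 2.0
    nib.save(nib.Nifti1Image(vta.mask.astype(np.uint8), affine), str(mask_path))
    if surface_path is not None and vta.total_volume_mm3 > 0:
        from skimage import measure
        import trimesh

        padded = np.pad(vta.mask.astype(np.uint8), 1)
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
        verts = (verts - 0.5) * vta.voxel_size_mm + vta.origin_mm  # unpad + world
        trimesh.Trimesh(vertices=verts, faces=faces, process=False).export(
            str(surface_path)
        )


def read_vta_mask(mask_path: str | Path) -> VTAResult:
    """Re-read an exported mask (round-trip helper)."""
    import nibabel as nib

    img = nib.load(str(mask_path))
    data = np.asanyarray(img.dataobj) > 0
    h = float(img.affine[0, 0])
    origin = img.affine[:3, 3] - h / 2.0
    total = float(np.count_nonzero(data)) * h**3
    return VTAResult(data, origin, h, total)
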