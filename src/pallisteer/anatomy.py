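"""Synthetic pallidal anatomy: a voxelized phantom of the globus pallidus region.

The phantom emulates a heterogeneous head-model neighbourhood of the globus
pallidus at desk scale: an external segment (GPe) ellipsoid containing an
internal segment (GPi) separated by a thin medial medullary lamina shell,
flanked by an internal-capsule slab and an optic-tract cylinder, embedded in
grey/white/CSF background with an outermost "case" shell that stands in for
the epidermis return surface of monopolar stimulation.

Coordinate convention (shared by every module): millimetres, right-handed,
+x lateral, +y anterior, +z dorsal.  Voxel centers sit at
``origin_mm + (index + 0.5) * voxel_size_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import nibabel as nib


class GeometryError(ValueError):
    """A structure does not fit the phantom domain."""


class ConsistencyError(ValueError):
    """Labels and conductivity table disagree."""


# ---------------------------------------------------------------------------
# Label enumeration.  0 is reserved for exterior/air; 20..27 for contact metal.
# ---------------------------------------------------------------------------
EXTERIOR = 0
GREY = 1
WHITE = 2
CSF = 3
GPE = 4
GPI = 5
LAMINA = 6
INTERNAL_CAPSULE = 7
OPTIC_TRACT = 8
CASE = 9
ENCAPSULATION = 10
INSULATION = 11
CONTACT_BASE = 20  # contact k (0..7) rasterizes as CONTACT_BASE + k

LABEL_NAMES: dict[int, str] = {
    EXTERIOR: "exterior",
    GREY: "grey_matter",
    WHITE: "white_matter",
    CSF: "csf",
    GPE: "gpe",
    GPI: "gpi",
    LAMINA: "medial_medullary_lamina",
    INTERNAL_CAPSULE: "internal_capsule",
    OPTIC_TRACT: "optic_tract",
    CASE: "case",
    ENCAPSULATION: "encapsulation",
    INSULATION: "insulation",
}
LABEL_NAMES.update({CONTACT_BASE + k: f"contact_{k}" for k in range(8)})

CONTACT_LABELS = frozenset(CONTACT_BASE + k for k in range(8))
LEAD_LABELS = frozenset({ENCAPSULATION, INSULATION}) | CONTACT_LABELS

#: Labels allowed to carry zero conductivity (perfect insulators: the solver
#: excludes them from the discrete operator).
ZERO_SIGMA_LABELS = frozenset({EXTERIOR, INSULATION})

#: Labels never touched by :func:`homogenize` (electrode hardware + exterior).
NON_TISSUE_LABELS = frozenset({EXTERIOR, INSULATION}) | CONTACT_LABELS

# Default conductivities in S/m.  Grey/white/CSF follow the low-frequency
# values commonly used for DBS volume-conductor models; lamina, capsule and
# optic tract are treated as white matter; encapsulation is fibrous scar at
# 0.1 S/m.  All overridable per model.
DEFAULT_SIGMA: dict[int, float] = {
    EXTERIOR: 0.0,
    GREY: 0.275,
    WHITE: 0.126,
    CSF: 1.654,
    GPE: 0.275,
    GPI: 0.275,
    LAMINA: 0.126,
    INTERNAL_CAPSULE: 0.126,
    OPTIC_TRACT: 0.126,
    CASE: 0.10,
    ENCAPSULATION: 0.10,
    INSULATION: 0.0,
}
DEFAULT_SIGMA.update({lab: 9.4e6 for lab in CONTACT_LABELS})  # Pt/Ir; see solver

DEFAULT_EPS_R: dict[int, float] = {lab: 1.0e5 for lab in DEFAULT_SIGMA}


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned-by-default ellipsoid; ``euler_deg`` rotates it (z, y, x)."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def rotation(self) -> np.ndarray:
        az, ay, ax = np.deg2rad(self.euler_deg)
        cz, sz = np.cos(az), np.sin(az)
        cy, sy = np.cos(ay), np.sin(ay)
        cx, sx = np.cos(ax), np.sin(ax)
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
        ry = np.array([[cy, 0, sy], [0, 1.0, 0], [-sy, 0, cy]])
        rx = np.array([[1.0, 0, 0], [0, cx, -sx], [0, sx, cx]])
        return rz @ ry @ rx

    def inside(self, points: np.ndarray, grow_mm: float = 0.0) -> np.ndarray:
        """Boolean mask of ``points`` (N, 3) inside the (grown) ellipsoid."""
        local = (points - np.asarray(self.center_mm)) @ self.rotation()
        semi = np.asarray(self.semi_axes_mm) + grow_mm
        return np.sum((local / semi) ** 2, axis=-1) <= 1.0


@dataclass(frozen=True)
class Slab:
    """Infinite slab: points p with |(p - point) . normal| <= thickness/2."""

    point_mm: tuple[float, float, float]
    normal: tuple[float, float, float]
    thickness_mm: float

    def inside(self, points: np.ndarray) -> np.ndarray:
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        s = (points - np.asarray(self.point_mm)) @ n
        return np.abs(s) <= self.thickness_mm / 2.0


@dataclass(frozen=True)
class Cylinder:
    """Infinite circular cylinder around an axis line."""

    point_mm: tuple[float, float, float]
    axis: tuple[float, float, float]
    radius_mm: float

    def inside(self, points: np.ndarray) -> np.ndarray:
        a = np.asarray(self.axis, dtype=float)
        a = a / np.linalg.norm(a)
        w = points - np.asarray(self.point_mm)
        t = w @ a
        radial = w - t[..., None] * a
        return np.einsum("...i,...i", radial, radial) <= self.radius_mm**2


_GP_CENTER = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric recipe for the pallidal phantom.

    Defaults reflect human pallidal scale: outer GP envelope ~1.3 cm3 of
    tissue split into GPe (~750 mm3), a ~1 mm lamina shell, and a GPi of
    ~350 mm3, with the internal capsule posteromedial and the optic tract
    directly ventral to the GPi.
    """

    domain_size_mm: tuple[float, float, float] = (48.0, 48.0, 48.0)
    voxel_size_mm: float = 0.4
    origin_mm: tuple[float, float, float] = (-24.0, -24.0, -24.0)
    gpe_ellipsoid: Ellipsoid = Ellipsoid(_GP_CENTER, (10.5, 6.0, 5.0))
    gpi_ellipsoid: Ellipsoid = Ellipsoid((0.5, -0.5, -0.3), (7.5, 4.0, 3.5))
    lamina_thickness_mm: float = 1.0
    ic_slab: Slab = Slab(
        point_mm=(-7.64, -7.64, 0.0), normal=(-1.0, -1.0, 0.0), thickness_mm=3.0
    )
    optic_tract_cylinder: Cylinder = Cylinder(
        point_mm=(0.5, 0.0, -5.85), axis=(0.0, 1.0, 0.0), radius_mm=1.25
    )
    csf_rim_mm: float = 2.4
    case_thickness_mm: float = 0.45
    background_labels: tuple[str, ...] = ("grey_matter",)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.lamina_thickness_mm < 0:
            raise ValueError("lamina_thickness_mm must be >= 0")
        lo = np.asarray(self.origin_mm)
        hi = lo + np.asarray(self.domain_size_mm)
        inner_lo = lo + self.csf_rim_mm + self.case_thickness_mm
        inner_hi = hi - self.csf_rim_mm - self.case_thickness_mm
        for name, ell in (("gpe", self.gpe_ellipsoid), ("gpi", self.gpi_ellipsoid)):
            c = np.asarray(ell.center_mm)
            r = float(np.max(ell.semi_axes_mm))
            if np.any(c - r < inner_lo) or np.any(c + r > inner_hi):
                raise GeometryError(f"{name} ellipsoid exceeds the phantom domain")
        # GPi plus lamina must sit strictly inside the GPe envelope: sample the
        # grown GPi surface and require containment.
        u = np.linspace(0, np.pi, 24)
        v = np.linspace(0, 2 * np.pi, 48)
        uu, vv = np.meshgrid(u, v)
        semi = np.asarray(self.gpi_ellipsoid.semi_axes_mm) + self.lamina_thickness_mm
        pts = np.stack(
            [
                semi[0] * np.sin(uu) * np.cos(vv),
                semi[1] * np.sin(uu) * np.sin(vv),
                semi[2] * np.cos(uu),
            ],
            axis=-1,
        ).reshape(-1, 3)
        pts = pts @ self.gpi_ellipsoid.rotation().T + np.asarray(
            self.gpi_ellipsoid.center_mm
        )
        if not np.all(self.gpe_ellipsoid.inside(pts)):
            raise GeometryError(
                "gpi ellipsoid (plus lamina) is not strictly interior to the gpe"
            )


@dataclass
class TissueModel:
    """Voxel label grid plus per-label electrical properties.

    ``label_grid`` is indexed ``[i, j, k]`` for (x, y, z); the conductivity
    table maps every occurring label to sigma in S/m (zero only for the
    documented perfect-insulator labels).
    """

    label_grid: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray
    conductivity_table: dict[int, float]
    permittivity_table: dict[int, float] | None = None
    label_names: dict[int, str] = field(default_factory=lambda: dict(LABEL_NAMES))

    def validate(self) -> None:
        if self.label_grid.ndim != 3 or min(self.label_grid.shape) < 2:
            raise ValueError("label grid must be 3D with >= 2 voxels per axis")
        if not np.issubdtype(self.label_grid.dtype, np.integer):
            raise ConsistencyError("label grid must be an integer volume")
        present = set(int(v) for v in np.unique(self.label_grid))
        missing = sorted(present - set(self.conductivity_table))
        if missing:
            raise ConsistencyError(
                f"labels present in grid but missing from table: {missing}"
            )
        bad = [
            lab
            for lab in present
            if self.conductivity_table[lab] <= 0 and lab not in ZERO_SIGMA_LABELS
        ]
        if bad:
            raise ConsistencyError(f"non-insulator labels with sigma <= 0: {bad}")

    # -- geometry helpers ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_grid.shape  # type: ignore[return-value]

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h = self.voxel_size_mm
        return tuple(
            self.origin_mm[ax] + (np.arange(self.shape[ax]) + 0.5) * h
            for ax in range(3)
        )

    def sample_labels(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel label lookup at world coordinates (N, 3)."""
        idx = np.floor((points - self.origin_mm) / self.voxel_size_mm).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise GeometryError("sample points fall outside the model domain")
        return self.label_grid[idx[..., 0], idx[..., 1], idx[..., 2]]

    def volumes_mm3(self) -> dict[int, float]:
        labels, counts = np.unique(self.label_grid, return_counts=True)
        vv = self.voxel_size_mm**3
        return {int(l): float(c) * vv for l, c in zip(labels, counts)}

    def copy(self) -> "TissueModel":
        return TissueModel(
            self.label_grid.copy(),
            self.voxel_size_mm,
            self.origin_mm.copy(),
            dict(self.conductivity_table),
            None if self.permittivity_table is None else dict(self.permittivity_table),
            dict(self.label_names),
        )


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------
_BACKGROUND_BY_NAME = {"grey_matter": GREY, "white_matter": WHITE}


def label_points(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Analytic label lookup at arbitrary world points (N, 3).

    This is the single source of truth for phantom geometry: the voxel grid
    is this function evaluated at voxel centers, so the phantom can be
    re-rasterized consistently at any resolution (used by the two-level
    field solve).
    """
    pts = np.asarray(points, dtype=float)
    flat = pts.reshape(-1, 3)
    labels = np.full(flat.shape[0], _BACKGROUND_BY_NAME.get(
        spec.background_labels[0] if spec.background_labels else "grey_matter", GREY
    ), dtype=np.int16)

    lo = np.asarray(spec.origin_mm)
    hi = lo + np.asarray(spec.domain_size_mm)
    # Distance to the nearest domain face decides case shell and CSF rim.
    dmin = np.minimum(flat - lo, hi - flat).min(axis=1)
    labels[dmin <= spec.case_thickness_mm + spec.csf_rim_mm] = CSF
    labels[dmin <= spec.case_thickness_mm] = CASE
    labels[dmin < 0] = EXTERIOR

    interior = labels == labels  # all; structural labels only overwrite background
    bg = (labels != CASE) & (labels != CSF) & (labels != EXTERIOR) & interior
    labels[bg & spec.ic_slab.inside(flat) & ~spec.gpe_ellipsoid.inside(flat)] = (
        INTERNAL_CAPSULE
    )
    labels[bg & spec.optic_tract_cylinder.inside(flat)] = OPTIC_TRACT
    gpe_in = spec.gpe_ellipsoid.inside(flat)
    labels[bg & gpe_in] = GPE
    if spec.lamina_thickness_mm > 0:
        lam = spec.gpi_ellipsoid.inside(flat, grow_mm=spec.lamina_thickness_mm)
        labels[bg & gpe_in & lam] = LAMINA
    labels[bg & spec.gpi_ellipsoid.inside(flat)] = GPI
    return labels.reshape(pts.shape[:-1])


def build_pallidum_phantom(spec: PhantomSpec) -> TissueModel:
    """Rasterize the phantom recipe into a :class:`TissueModel`.

    Deterministic for a fixed spec (the seed is carried for provenance; the
    default geometry is purely analytic).
    """
    spec.validate()
    h = spec.voxel_size_mm
    n = np.round(np.asarray(spec.domain_size_mm) / h).astype(int)
    axes = [spec.origin_mm[a] + (np.arange(n[a]) + 0.5) * h for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1)
    labels = label_points(spec, pts).astype(np.int16)
    model = TissueModel(
        labels,
        h,
        np.asarray(spec.origin_mm, dtype=float),
        dict(DEFAULT_SIGMA),
        dict(DEFAULT_EPS_R),
    )
    model.validate()
    return model


def homogenize(model: TissueModel, sigma: float) -> TissueModel:
    """Replace every internal tissue conductivity with ``sigma``.

    Geometry and labels are untouched; electrode metal and insulation (and
    exterior air) keep their entries.  Mirrors the paper-style homogeneous
    control model (0.3 S/m).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = model.copy()
    for lab in out.conductivity_table:
        if lab not in NON_TISSUE_LABELS:
            out.conductivity_table[lab] = float(sigma)
    return out


# ---------------------------------------------------------------------------
# I/O: NIfTI label volume + TSV conductivity table
# ---------------------------------------------------------------------------
def write_tissue_model(
    model: TissueModel, label_volume_path: str | Path, table_path: str | Path
) -> None:
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = model.voxel_size_mm
    affine[:3, 3] = model.origin_mm + model.voxel_size_mm / 2.0
    img = nib.Nifti1Image(model.label_grid.astype(np.int16), affine)
    nib.save(img, str(label_volume_path))

    rows = []
    eps = model.permittivity_table or {}
    for lab in sorted(model.conductivity_table):
        rows.append(
            {
                "label": lab,
                "name": model.label_names.get(lab, f"label_{lab}"),
                "sigma_S_per_m": model.conductivity_table[lab],
                "eps_r": eps.get(lab, np.nan),
            }
        )
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)


def read_tissue_model(
    label_volume_path: str | Path, table_path: str | Path
) -> TissueModel:
    img = nib.load(str(label_volume_path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ConsistencyError("label volume is not an integer NIfTI")
        data = np.round(data).astype(np.int16)
    affine = img.affine
    diag = np.diag(affine)[:3]
    if not np.allclose(affine[:3, :3], np.diag(diag)) or not np.allclose(
        diag, diag[0]
    ):
        raise ConsistencyError("label volume must be axis-aligned and isotropic")
    h = float(diag[0])
    origin = affine[:3, 3] - h / 2.0

    table = pd.read_csv(table_path, sep="\t")
    required = {"label", "name", "sigma_S_per_m"}
    if not required.issubset(table.columns):
        raise ConsistencyError(
            f"conductivity table must have columns {sorted(required)}"
        )
    sigma = {int(r.label): float(r.sigma_S_per_m) for r in table.itertuples()}
    names = {int(r.label): str(r.name) for r in table.itertuples()}
    eps = None
    if "eps_r" in table.columns:
        eps = {
            int(r.label): float(r.eps_r)
            for r in table.itertuples()
            if np.isfinite(r.eps_r)
        }
    model = TissueModel(data.astype(np.int16), h, origin, sigma, eps, names)
    model.validate()
    return model
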