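"""Parametric directional 8-contact DBS lead (1-3-3-1 layout).

Geometry follows the common segmented-lead family: a 1.27 mm diameter shaft
with a ring contact near the tip (row 1), two segmented rows of three 90
degree segments separated by 30 degree insulation gaps (rows 2 and 3, A/B/C),
and a ring contact on top (row 4).  Rows are separated edge-to-edge by the
"vertical spacing" (0.5 or 1.5 mm); the two lead variants differ only in that
gap.  The A segments face the ``azimuth_reference`` direction.

Contact dimensions are configurable assumptions (the clinical lead's exact
segment extents are proprietary), defaulting to 1.5 mm contact height and a
0.5 mm encapsulation shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anatomy import (
    CASE,
    CONTACT_BASE,
    CSF,
    DEFAULT_SIGMA,
    ENCAPSULATION,
    EXTERIOR,
    GPI,
    GeometryError,
    INSULATION,
    TissueModel,
)


class PlacementError(ValueError):
    """Requested target offsets cannot be realized inside the GPi."""


#: canonical contact ids, tip to shaft
CONTACT_IDS = ("1", "2A", "2B", "2C", "3A", "3B", "3C", "4")

_SEGMENT_CENTER_DEG = {"A": 0.0, "B": 120.0, "C": 240.0}


@dataclass(frozen=True)
class ContactSpec:
    id: str
    kind: str  # "ring" | "segment"
    row: int
    axial_extent_mm: tuple[float, float]
    angular_extent_deg: tuple[float, float] | None = None  # segments only


@dataclass(frozen=True)
class LeadGeometry:
    tip_position_mm: np.ndarray
    shaft_direction: np.ndarray
    azimuth_reference: np.ndarray
    diameter_mm: float = 1.27
    contact_height_mm: float = 1.5
    vertical_spacing_mm: float = 1.5
    encapsulation_thickness_mm: float = 0.5
    contact_thickness_mm: float = 0.3
    tip_length_mm: float = 1.0
    segment_span_deg: float = 90.0
    shaft_length_mm: float = 60.0
    contacts: tuple[ContactSpec, ...] = ()
    placement_report: dict = field(default_factory=dict, compare=False)

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    def row_axial_interval(self, row: int) -> tuple[float, float]:
        """Axial extent of a contact row, measured from the tip along the shaft."""
        bottom = self.tip_length_mm + (row - 1) * (
            self.contact_height_mm + self.vertical_spacing_mm
        )
        return bottom, bottom + self.contact_height_mm

    def row_center_t(self, row: int) -> float:
        lo, hi = self.row_axial_interval(row)
        return 0.5 * (lo + hi)

    def row_center_mm(self, row: int) -> np.ndarray:
        return self.tip_position_mm + self.row_center_t(row) * self.shaft_direction

    @property
    def active_length_mm(self) -> float:
        """Tip to the top edge of row 4 (strictly increasing in spacing)."""
        return self.row_axial_interval(4)[1]

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(e1, e2, d): e1 = azimuth reference, e2 = e1 x d, d = shaft axis.

        Segment angles increase from the reference (anterior, segment A)
        toward e2; with the default implant pose in the left hemisphere e2
        points laterally, so segment B (120 deg) faces posterolateral and C
        (240 deg) posteromedial, matching the clinical orientation.
        """
        d = self.shaft_direction
        e1 = self.azimuth_reference
        e2 = np.cross(e1, d)
        return e1, e2, d

    def segment_direction(self, contact_id: str) -> np.ndarray:
        """Unit outward direction of a segment's center (rings: reference)."""
        e1, e2, _ = self.frame()
        if len(contact_id) == 1:
            return e1
        c = np.deg2rad(_SEGMENT_CENTER_DEG[contact_id[1]])
        return np.cos(c) * e1 + np.sin(c) * e2

    def cylindrical(self, points: np.ndarray):
        """World points (N, 3) -> (t along shaft, radial distance, angle deg)."""
        e1, e2, d = self.frame()
        w = np.asarray(points, dtype=float) - self.tip_position_mm
        t = w @ d
        radial = w - t[..., None] * d
        r = np.linalg.norm(radial, axis=-1)
        theta = np.degrees(np.arctan2(radial @ e2, radial @ e1)) % 360.0
        return t, r, theta

    def translated(self, delta_mm: np.ndarray) -> "LeadGeometry":
        return replace(self, tip_position_mm=self.tip_position_mm + np.asarray(delta_mm))


def _build_contacts(lead: LeadGeometry) -> tuple[ContactSpec, ...]:
    half = lead.segment_span_deg / 2.0
    contacts = []
    for cid in CONTACT_IDS:
        row = int(cid[0])
        interval = lead.row_axial_interval(row)
        if len(cid) == 1:
            contacts.append(ContactSpec(cid, "ring", row, interval))
        else:
            c = _SEGMENT_CENTER_DEG[cid[1]]
            contacts.append(
                ContactSpec(cid, "segment", row, interval, ((c - half) % 360.0, (c + half) % 360.0))
            )
    return tuple(contacts)


def shaft_direction_from_angles(
    sagittal_angle_deg: float, coronal_angle_deg: float
) -> np.ndarray:
    """Shaft axis from vertical, tilted toward +y (anterior) in the sagittal
    plane and toward +x (lateral) in the coronal plane."""
    sag = np.deg2rad(sagittal_angle_deg)
    cor = np.deg2rad(coronal_angle_deg)
    v = np.array([0.0, np.sin(sag), np.cos(sag)])  # sagittal tilt about x
    d = np.array([v[2] * np.sin(cor), v[1], v[2] * np.cos(cor)])  # coronal tilt
    return d / np.linalg.norm(d)


def build_lead(
    spacing_mm: float,
    tip_mm=(0.0, 0.0, 0.0),
    sagittal_angle_deg: float = 23.0,
    coronal_angle_deg: float = 11.0,
    segment_A_azimuth=(0.0, 1.0, 0.0),
    **overrides,
) -> LeadGeometry:
    """Construct the eight-contact directional lead.

    Default orientation matches the modelled implant trajectory: 23 degrees
    anterior in the sagittal plane, 11 degrees lateral in the coronal plane,
    with the A segments facing anterior.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    d = shaft_direction_from_angles(sagittal_angle_deg, coronal_angle_deg)
    a = np.asarray(segment_A_azimuth, dtype=float)
    if np.linalg.norm(a) < 1e-12 or np.linalg.norm(np.cross(d, a)) < 1e-9:
        raise GeometryError("degenerate segment_A_azimuth direction")
    a = a - (a @ d) * d  # project to the plane normal to the shaft
    a = a / np.linalg.norm(a)
    lead = LeadGeometry(
        tip_position_mm=np.asarray(tip_mm, dtype=float),
        shaft_direction=d,
        azimuth_reference=a,
        vertical_spacing_mm=float(spacing_mm),
        **overrides,
    )
    return replace(lead, contacts=_build_contacts(lead))


def contact_label(cid: str) -> int:
    return CONTACT_BASE + CONTACT_IDS.index(cid)


def _angular_inside(theta: np.ndarray, extent: tuple[float, float]) -> np.ndarray:
    lo, hi = extent
    if lo <= hi:
        return (theta >= lo) & (theta <= hi)
    return (theta >= lo) | (theta <= hi)


def rasterize_on_points(
    lead: LeadGeometry, points: np.ndarray, voxel_size_mm: float
) -> np.ndarray:
    """Lead label at world points; 0 where the point is outside the lead body.

    Precedence metal > insulation > encapsulation.  The metal shell is widened
    to at least ~one voxel so contacts stay present on coarse grids.
    """
    t, r, theta = lead.cylindrical(points)
    out = np.zeros(t.shape, dtype=np.int16)
    R = lead.radius_mm
    in_shaft_t = (t >= 0.0) & (t <= lead.shaft_length_mm)
    enc = lead.encapsulation_thickness_mm
    if enc > 0:
        out[(r <= R + enc) & (t >= -enc) & (t <= lead.shaft_length_mm + enc)] = (
            ENCAPSULATION
        )
    out[in_shaft_t & (r <= R)] = INSULATION
    shell = max(lead.contact_thickness_mm, 1.05 * voxel_size_mm)
    metal_r = (r <= R) & (r >= R - shell)
    for contact in lead.contacts:
        lo, hi = contact.axial_extent_mm
        m = metal_r & (t >= lo) & (t <= hi)
        if contact.kind == "segment":
            m &= _angular_inside(theta, contact.angular_extent_deg)
        out[m] = contact_label(contact.id)
    return out


def rasterize_lead(lead: LeadGeometry, model: TissueModel) -> TissueModel:
    """Burn metal, insulation and encapsulation labels into a tissue model."""
    xs, ys, zs = model.voxel_centers_1d()
    xx, yy, zz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1)
    lead_labels = rasterize_on_points(lead, pts, model.voxel_size_mm)
    if not np.any(lead_labels >= CONTACT_BASE):
        raise GeometryError("lead contacts fall outside the model domain")
    out = model.copy()
    mask = lead_labels > 0
    # lead never overwrites the case shell or exterior air
    keep = (out.label_grid == CASE) | (out.label_grid == EXTERIOR)
    mask &= ~keep
    out.label_grid[mask] = lead_labels[mask]
    for lab in (ENCAPSULATION, INSULATION, *[contact_label(c) for c in CONTACT_IDS]):
        out.conductivity_table.setdefault(lab, DEFAULT_SIGMA[lab])
    return out


# ---------------------------------------------------------------------------
# Placement at the ventral posterolateral GPi
# ---------------------------------------------------------------------------
def _border_distance(model: TissueModel, start: np.ndarray, direction: np.ndarray,
                     inside_label: int, max_mm: float = 20.0) -> float:
    """March from ``start`` along ``direction`` to the first non-``inside_label``
    voxel; returns the travelled distance in mm."""
    step = model.voxel_size_mm / 2.0
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    n = int(max_mm / step)
    pts = start + np.outer(np.arange(1, n) * step, d)
    lo = model.origin_mm
    hi = model.origin_mm + np.asarray(model.shape) * model.voxel_size_mm
    inside = np.all((pts >= lo) & (pts < hi), axis=1)
    pts = pts[inside]  # structures are interior, so the border precedes the box
    if pts.shape[0] == 0:
        raise PlacementError("probe ray leaves the domain immediately")
    labs = model.sample_labels(pts)
    hits = np.nonzero(labs != inside_label)[0]
    if hits.size == 0:
        raise PlacementError("no border found along the probe direction")
    return float((hits[0] + 1) * step)


def place_at_target(
    lead: LeadGeometry,
    model: TissueModel,
    target_offsets=(2.25, 2.3),
    ventral_fraction: float = 0.30,
) -> LeadGeometry:
    """Translate the lead so the row-2 contact surface sits at the requested
    distances from the lateral (+x) and posterior (-y) GPi borders, with row 2
    in the ventral part of the GPi.

    ``ventral_fraction`` picks the row-2 height as a quantile of the GPi
    z-extent (0.30 = ventral third).  Returns a new lead carrying a
    ``placement_report`` with achieved distances.
    """
    lat_off, post_off = target_offsets
    gpi = np.argwhere(model.label_grid == GPI)
    if gpi.size == 0:
        raise PlacementError("model contains no GPi label")
    h = model.voxel_size_mm
    centers = model.origin_mm + (gpi + 0.5) * h
    z_t = float(np.quantile(centers[:, 2], ventral_fraction))
    # initial in-plane guess: GPi centroid at that height
    slab = centers[np.abs(centers[:, 2] - z_t) <= max(h, 0.5)]
    if slab.size == 0:
        raise PlacementError("GPi too small at the requested ventral level")
    x_t, y_t = float(np.mean(slab[:, 0])), float(np.mean(slab[:, 1]))
    R = lead.radius_mm
    target = np.array([x_t, y_t, z_t])
    for _ in range(12):  # damped fixed-point iteration on the border distances
        d_lat = _border_distance(model, target, (1.0, 0.0, 0.0), GPI)
        d_post = _border_distance(model, target, (0.0, -1.0, 0.0), GPI)
        delta = np.array([d_lat - (lat_off + R), -(d_post - (post_off + R)), 0.0])
        # backtrack if the joint step would overshoot the curved border
        for _try in range(8):
            if model.sample_labels((target + delta)[None])[0] == GPI:
                break
            delta *= 0.5
        else:
            raise PlacementError(
                f"GPi too small to satisfy offsets {target_offsets}; achieved "
                f"(lateral {d_lat - R:.2f}, posterior {d_post - R:.2f}) mm at "
                f"{np.round(target, 2).tolist()}"
            )
        target += delta
        if np.linalg.norm(delta) < model.voxel_size_mm / 4:
            break
    new_lead = lead.translated(target - lead.row_center_mm(2))
    ach_lat = _border_distance(model, new_lead.row_center_mm(2), (1, 0, 0), GPI) - R
    ach_post = _border_distance(model, new_lead.row_center_mm(2), (0, -1, 0), GPI) - R
    report = {
        "requested_lateral_mm": float(lat_off),
        "requested_posterior_mm": float(post_off),
        "achieved_lateral_mm": float(ach_lat),
        "achieved_posterior_mm": float(ach_post),
        "row2_center_mm": new_lead.row_center_mm(2).tolist(),
    }
    if abs(ach_lat - lat_off) > 2 * h or abs(ach_post - post_off) > 2 * h:
        raise PlacementError(f"placement did not converge: {report}")
    return replace(new_lead, placement_report=report)
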