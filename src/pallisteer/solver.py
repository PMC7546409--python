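"""Quasi-static volume-conductor solve on the heterogeneous voxel grid.

The potential obeys the ohmic quasi-static equation div(sigma grad phi) = 0,
discretized with cell-centered finite volumes on a rectilinear grid and
harmonic averaging of sigma across faces (the standard treatment for
discontinuous coefficients).  Active contacts are Dirichlet surfaces
(cathodes at -V0, anodes and the case shell at 0 V); the outer box is a
natural zero-normal-current (Neumann) boundary; cells with sigma = 0
(air, polyurethane insulation) are excluded as perfect insulators; inactive
metal contacts are merged into floating equipotential super-nodes.

Graded resolution is approximated by a two-level composite solve: a coarse
solve over the whole phantom provides Dirichlet values on the boundary of a
finely resolved region of interest (ROI) around the contacts.  From the fine
solution the cathode current flux, the electrode-tissue-interface (ETI)
impedance V/I, and the equivalent delivered current are computed; linearity
of the operator makes rescaling to a target current exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .anatomy import (
    CASE,
    CONTACT_LABELS,
    ConsistencyError,
    LEAD_LABELS,
    TissueModel,
    ENCAPSULATION,
)
from .lead import CONTACT_IDS, LeadGeometry, contact_label, rasterize_on_points


class SolverError(RuntimeError):
    """Iterative solve failed to converge."""


@dataclass(frozen=True)
class SolverSettings:
    """Tolerances and grid resolutions for the two-level solve.

    Defaults follow the convergence criteria of the reference workflow
    (relative 1e-8, absolute 1e-10); grid resolutions are desk-scale choices
    (the 0.04 mm electrode-edge resolution of a production mesh is available
    via ``roi_resolution_mm`` but is not the default).
    """

    relative_tolerance: float = 1e-8
    absolute_tolerance: float = 1e-10
    max_iterations: int = 40000
    roi_bounds_mm: tuple | None = None  # ((xlo,ylo,zlo),(xhi,yhi,zhi)) or auto
    roi_margin_mm: float = 8.0
    roi_resolution_mm: float = 0.25
    electrode_resolution_mm: float = 0.25
    coarse_resolution_mm: float = 1.2
    frequency_hz: float = 130.0  # carried; the implemented operator is resistive

    def validate(self) -> None:
        if self.relative_tolerance <= 0 or self.absolute_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if not (
            self.electrode_resolution_mm
            <= self.roi_resolution_mm
            <= self.coarse_resolution_mm
        ):
            raise ValueError(
                "require electrode_resolution <= roi_resolution <= coarse_resolution"
            )


@dataclass(frozen=True)
class StimConfiguration:
    """Cathode/anode contact sets plus the pulse parameters.

    ``anodes`` is either a tuple of contact ids or the string ``"CASE"`` for
    a monopolar return through the outer case shell.  Co-activated contacts
    are tied to one potential (hardware parallel connection).
    """

    name: str
    cathodes: tuple[str, ...]
    anodes: tuple[str, ...] | str
    amplitude_mA: float = 1.0
    pulse_width_us: float = 60.0
    frequency_hz: float = 130.0
    waveform: str = "biphasic-passive-discharge"
    coactivated: bool = True

    def validate(self) -> None:
        if not self.cathodes:
            raise ValueError("cathodes must be nonempty")
        if self.amplitude_mA <= 0:
            raise ValueError("amplitude_mA must be positive")
        for cid in self.cathodes:
            if cid not in CONTACT_IDS:
                raise ConsistencyError(f"unknown cathode contact id {cid!r}")
        if self.anodes != "CASE":
            for cid in self.anodes:
                if cid not in CONTACT_IDS:
                    raise ConsistencyError(f"unknown anode contact id {cid!r}")
            if set(self.anodes) & set(self.cathodes):
                raise ValueError("cathode and anode sets overlap")

    @property
    def case_return(self) -> bool:
        return self.anodes == "CASE"


@dataclass
class GridField:
    """A scalar field on a uniform cell-centered grid."""

    values: np.ndarray
    origin_mm: np.ndarray
    voxel_size_mm: float

    def sample(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        coords = (pts - self.origin_mm) / self.voxel_size_mm - 0.5
        return ndimage.map_coordinates(
            self.values, coords.reshape(-1, 3).T, order=1, mode="nearest"
        ).reshape(pts.shape[:-1])

    def contains(self, points: np.ndarray, margin_vox: float = 1.0) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        coords = (pts - self.origin_mm) / self.voxel_size_mm - 0.5
        n = np.asarray(self.values.shape)
        return np.all(
            (coords >= margin_vox - 1) & (coords <= n - margin_vox), axis=-1
        )


@dataclass
class PotentialField:
    """Solved potential (volts) with flux / impedance / current metadata."""

    fine: GridField
    coarse: GridField
    applied_voltage_V: float
    cathode_flux_A: float
    eti_impedance_ohm: float
    equivalent_current_mA: float
    info: dict = field(default_factory=dict)
    # internal grids retained so the flux is recomputable after rescaling
    _fine_sigma: np.ndarray | None = None
    _cathode_mask: np.ndarray | None = None
    _anode_mask: np.ndarray | None = None

    def sample(self, points: np.ndarray) -> np.ndarray:
        """phi at world points: fine grid inside the ROI, coarse outside."""
        pts = np.asarray(points, dtype=float)
        shape = pts.shape[:-1]
        flat = pts.reshape(-1, 3)
        vals = self.coarse.sample(flat)
        inside = self.fine.contains(flat)
        if np.any(inside):
            vals[inside] = self.fine.sample(flat[inside])
        return vals.reshape(shape)


# ---------------------------------------------------------------------------
# Low-level uniform-grid solve
# ---------------------------------------------------------------------------
_CONDUCTOR_SIGMA = 1.0e12  # stand-in for a perfect conductor in face averages


def _face_conductance(sa: np.ndarray, sb: np.ndarray, h: float) -> np.ndarray:
    """Conductance (S) of the face between adjacent cells with sigma sa, sb."""
    num = 2.0 * sa * sb
    den = sa + sb
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(den > 0, num / den, 0.0)
    return g * h


def solve_on_grid(
    sigma: np.ndarray,
    voxel_size_mm: float,
    dirichlet_mask: np.ndarray,
    dirichlet_values: np.ndarray,
    settings: SolverSettings = SolverSettings(),
    source_A: np.ndarray | None = None,
    merge_groups: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Solve div(sigma grad phi) = -source on one uniform grid.

    sigma = 0 marks excluded (perfectly insulating) cells; ``merge_groups``
    (int, -1 = none) collapses floating equipotential conductors into single
    unknowns.  Returns phi (volts, excluded cells filled from their nearest
    solved neighbour so interpolation stays finite) and solver diagnostics.
    """
    h = voxel_size_mm * 1e-3  # face conductance wants metres
    shape = sigma.shape
    n = sigma.size
    sig = sigma.reshape(-1)
    dmask = dirichlet_mask.reshape(-1)
    dvals = dirichlet_values.reshape(-1)
    groups = (
        np.full(n, -1, dtype=np.int64)
        if merge_groups is None
        else merge_groups.reshape(-1).astype(np.int64)
    )

    excluded = (sig <= 0) & ~dmask
    unknown = ~excluded & ~dmask
    uid = np.full(n, -1, dtype=np.int64)
    plain = unknown & (groups < 0)
    uid[plain] = np.arange(np.count_nonzero(plain))
    n_plain = int(np.count_nonzero(plain))
    group_ids = np.unique(groups[unknown & (groups >= 0)])
    for gi, g in enumerate(group_ids):
        uid[unknown & (groups == g)] = n_plain + gi
    n_unknown = n_plain + len(group_ids)
    if n_unknown == 0:
        raise ValueError("no unknown cells to solve for")

    conductor = dmask | (groups >= 0)
    sig_eff = np.where(conductor & (sig > 0), _CONDUCTOR_SIGMA, sig)

    idx = np.arange(n).reshape(shape)
    rows, cols, vals = [], [], []
    b = np.zeros(n_unknown)

    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        ia = idx[tuple(sl_a)].reshape(-1)
        ib = idx[tuple(sl_b)].reshape(-1)
        g = _face_conductance(sig_eff[ia], sig_eff[ib], h)
        live = g > 0
        # same merged conductor: interior face, no resistance to model
        same = (uid[ia] >= 0) & (uid[ia] == uid[ib])
        live &= ~same
        # distinct conductors rasterized into face contact are an artifact of
        # voxelizing the inter-contact insulation gap: keep them insulated
        live &= ~(conductor[ia] & conductor[ib])
        ia, ib, g = ia[live], ib[live], g[live]
        ua, ub = uid[ia], uid[ib]
        both = (ua >= 0) & (ub >= 0)
        rows += [ua[both], ub[both], ua[both], ub[both]]
        cols += [ub[both], ua[both], ua[both], ub[both]]
        vals += [-g[both], -g[both], g[both], g[both]]
        for u, other in ((ua, ib), (ub, ia)):
            bd = (u >= 0) & dmask[other]
            rows.append(u[bd])
            cols.append(u[bd])
            vals.append(g[bd])
            np.add.at(b, u[bd], g[bd] * dvals[other[bd]])

    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unknown, n_unknown),
    ).tocsr()
    if source_A is not None:
        src = source_A.reshape(-1)
        nz = np.nonzero(src)[0]
        np.add.at(b, uid[nz][uid[nz] >= 0], src[nz][uid[nz] >= 0])

    diag = A.diagonal()
    diag = np.where(diag > 0, diag, 1.0)
    M = spla.LinearOperator(A.shape, matvec=lambda x: x / diag)
    iters = [0]

    def _count(_):
        iters[0] += 1

    x, code = spla.cg(
        A,
        b,
        rtol=settings.relative_tolerance,
        atol=settings.absolute_tolerance,
        maxiter=settings.max_iterations,
        M=M,
        callback=_count,
    )
    resid = float(np.linalg.norm(A @ x - b))
    bnorm = float(np.linalg.norm(b))
    if code != 0:
        raise SolverError(
            f"CG did not converge in {settings.max_iterations} iterations "
            f"(|r| = {resid:.3e}, |r|/|b| = {resid / max(bnorm, 1e-300):.3e})"
        )

    phi = np.zeros(n)
    phi[dmask] = dvals[dmask]
    phi[uid >= 0] = x[uid[uid >= 0]]
    solved = ~excluded
    if np.any(excluded):
        # fill insulators from nearest solved cell so interpolation is finite
        _, (ix, iy, iz) = ndimage.distance_transform_edt(
            ~solved.reshape(shape), return_indices=True
        )
        phi = phi.reshape(shape)[ix, iy, iz].reshape(-1)
    info = {
        "iterations": iters[0],
        "residual": resid,
        "rhs_norm": bnorm,
        "n_unknowns": n_unknown,
    }
    return phi.reshape(shape), info


def boundary_current_A(
    phi: np.ndarray, sigma: np.ndarray, voxel_size_mm: float, mask: np.ndarray
) -> float:
    """Net current (A) flowing out of the fixed-potential cell set ``mask``.

    Sums the face currents g * (phi_mask - phi_neighbour) over the boundary of
    the set, treating mask cells as perfect conductors (half-cell face
    conductance of the tissue side only).
    """
    h = voxel_size_mm * 1e-3
    total = 0.0
    for axis in range(3):
        for side in (1, -1):
            nb = np.roll(mask, side, axis=axis)
            edge = [slice(None)] * 3
            edge[axis] = slice(0, 1) if side == 1 else slice(-1, None)
            nb[tuple(edge)] = False  # roll wrap-around is not adjacency
            face = nb & ~mask & (sigma > 0)
            if not np.any(face):
                continue
            phi_mask = np.roll(phi, side, axis=axis)[face]
            g = 2.0 * sigma[face] * h
            total += float(np.sum(g * (phi_mask - phi[face])))
    return total


# ---------------------------------------------------------------------------
# Two-level composite solve on a TissueModel + lead
# ---------------------------------------------------------------------------
def _sigma_lookup(model: TissueModel) -> np.ndarray:
    table = np.zeros(max(model.conductivity_table) + 1)
    for lab, s in model.conductivity_table.items():
        table[lab] = s
    return table


def _coarse_level(model, config, cathode_labels, anode_labels, factor):
    labels = model.label_grid
    shape = np.asarray(labels.shape)
    crop = (shape // factor) * factor
    labels = labels[: crop[0], : crop[1], : crop[2]]
    blocks = labels.reshape(
        crop[0] // factor, factor, crop[1] // factor, factor, crop[2] // factor, factor
    )
    center = factor // 2
    coarse_labels = blocks[:, center, :, center, :, center]
    is_cath = np.isin(blocks, list(cathode_labels)).any(axis=(1, 3, 5))
    if config.case_return:
        is_an = (blocks == CASE).any(axis=(1, 3, 5))
    else:
        is_an = np.isin(blocks, list(anode_labels)).any(axis=(1, 3, 5))
    conflict = is_cath & is_an
    is_cath &= ~conflict
    is_an &= ~conflict
    sigma = _sigma_lookup(model)[np.clip(coarse_labels, 0, None)]
    # inactive metal at coarse scale: small and surrounded by insulation; treat
    # as ordinary moderate conductor to keep the far-field well-posed
    inactive = np.isin(coarse_labels, list(CONTACT_LABELS)) & ~is_cath & ~is_an
    sigma = np.where(inactive, 1.0, sigma)
    return coarse_labels, sigma, is_cath, is_an


def _auto_roi(lead: LeadGeometry, model: TissueModel, settings: SolverSettings):
    if settings.roi_bounds_mm is not None:
        lo = np.asarray(settings.roi_bounds_mm[0], dtype=float)
        hi = np.asarray(settings.roi_bounds_mm[1], dtype=float)
    else:
        centers = np.array([lead.row_center_mm(r) for r in (1, 2, 3, 4)])
        m = settings.roi_margin_mm
        lo = centers.min(axis=0) - m
        hi = centers.max(axis=0) + m
    dom_lo = model.origin_mm + model.voxel_size_mm
    dom_hi = model.origin_mm + np.asarray(model.shape) * model.voxel_size_mm - model.voxel_size_mm
    lo = np.maximum(lo, dom_lo)
    hi = np.minimum(hi, dom_hi)
    hf = settings.roi_resolution_mm
    lo = model.origin_mm + np.floor((lo - model.origin_mm) / hf) * hf
    n = np.ceil((hi - lo) / hf).astype(int)
    return lo, n


def solve_potential(
    model: TissueModel,
    lead: LeadGeometry,
    config: StimConfiguration,
    settings: SolverSettings = SolverSettings(),
    applied_voltage_V: float = 1.0,
) -> PotentialField:
    """Two-level voltage-controlled solve for one contact configuration.

    Cathode contacts are fixed at -applied_voltage (co-activated cathodes
    share the potential), anodes (or the case shell) at 0 V.  The returned
    field carries the cathode flux, ETI impedance and equivalent current of
    the unit solve; use :func:`scale_to_current` for a target amplitude.
    """
    settings.validate()
    config.validate()
    present = set(int(v) for v in np.unique(model.label_grid))
    cathode_labels = {contact_label(c) for c in config.cathodes}
    anode_labels = (
        set() if config.case_return else {contact_label(a) for a in config.anodes}
    )
    missing = sorted(
        cid
        for cid in (set(config.cathodes) | (set() if config.case_return else set(config.anodes)))
        if contact_label(cid) not in present
    )
    if missing:
        raise ConsistencyError(
            f"configuration references contacts absent from the grid: {missing}"
        )
    if config.case_return and CASE not in present:
        raise ConsistencyError("monopolar configuration requires a case label")

    v0 = float(applied_voltage_V)
    factor = max(1, int(round(settings.coarse_resolution_mm / model.voxel_size_mm)))

    # --- coarse level over the whole phantom -------------------------------
    _, sig_c, cath_c, an_c, = _coarse_level(
        model, config, cathode_labels, anode_labels, factor
    )
    dmask_c = cath_c | an_c
    dvals_c = np.where(cath_c, -v0, 0.0)
    hc = model.voxel_size_mm * factor
    phi_c, info_c = solve_on_grid(sig_c, hc, dmask_c, dvals_c, settings)
    coarse = GridField(phi_c, model.origin_mm.copy(), hc)

    # --- fine ROI level ----------------------------------------------------
    hf = settings.roi_resolution_mm
    lo, nf = _auto_roi(lead, model, settings)
    axes = [lo[a] + (np.arange(nf[a]) + 0.5) * hf for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1)
    fine_labels = model.sample_labels(pts.reshape(-1, 3)).reshape(tuple(nf)).copy()
    lead_lab = rasterize_on_points(lead, pts, hf)
    stale = np.isin(fine_labels, list(LEAD_LABELS)) & (lead_lab == 0)
    fine_labels[stale] = ENCAPSULATION  # staircase shadow of the coarse raster
    fine_labels[lead_lab > 0] = lead_lab[lead_lab > 0]

    sig_f = _sigma_lookup(model)[np.clip(fine_labels, 0, None)]
    cath_f = np.isin(fine_labels, list(cathode_labels))
    if config.case_return:
        an_f = fine_labels == CASE
    else:
        an_f = np.isin(fine_labels, list(anode_labels))
    if not np.any(cath_f):
        raise ConsistencyError("no cathode voxels inside the fine ROI")

    boundary = np.zeros(tuple(nf), dtype=bool)
    for axis in range(3):
        sl = [slice(None)] * 3
        sl[axis] = slice(0, 1)
        boundary[tuple(sl)] = True
        sl[axis] = slice(-1, None)
        boundary[tuple(sl)] = True
    dvals_f = np.zeros(tuple(nf))
    if config.case_return:
        # monopolar: the return current exits the ROI toward the case, carried
        # by Dirichlet boundary values interpolated from the coarse solve
        dmask_f = cath_f | an_f | boundary
        dvals_f[boundary] = coarse.sample(pts[boundary])
    else:
        # bipolar: the current loop closes between the contact rows; the ROI
        # boundary is a natural zero-flux surface, which keeps cathode and
        # anode fluxes conservative on the fine grid
        dmask_f = cath_f | an_f
    dvals_f[an_f] = 0.0
    dvals_f[cath_f] = -v0

    groups = np.full(tuple(nf), -1, dtype=np.int64)
    for lab in CONTACT_LABELS - cathode_labels - anode_labels:
        groups[fine_labels == lab] = lab
    phi_f, info_f = solve_on_grid(sig_f, hf, dmask_f, dvals_f, settings, merge_groups=groups)
    if not config.case_return:
        # align the coarse far field with the fine Neumann solve: a bipole in
        # an insulated box is defined up to the constant its boundaries pin,
        # so match the levels on the ROI skin (a constant shift carries no
        # current and no transmembrane drive)
        skin = boundary & (sig_f > 0)
        offset = float(np.mean(phi_f[skin] - coarse.sample(pts[skin])))
        coarse = GridField(coarse.values + offset, coarse.origin_mm, coarse.voxel_size_mm)
    fine = GridField(phi_f, lo, hf)

    # flux counts tissue faces only: metal-metal contact faces are rasterization
    # artifacts of the insulation gaps and carry no physical current
    sig_flux = np.where(np.isin(fine_labels, list(CONTACT_LABELS)), 0.0, sig_f)
    flux = abs(boundary_current_A(phi_f, sig_flux, hf, cath_f))
    if flux <= 0:
        raise SolverError("zero cathode flux after solve")
    field = PotentialField(
        fine=fine,
        coarse=coarse,
        applied_voltage_V=v0,
        cathode_flux_A=flux,
        eti_impedance_ohm=v0 / flux,
        equivalent_current_mA=flux * 1e3,
        info={
            "coarse": info_c,
            "fine": info_f,
            "config": config.name,
            "roi_origin_mm": lo.tolist(),
            "roi_shape": [int(v) for v in nf],
        },
        _fine_sigma=sig_flux,
        _cathode_mask=cath_f,
        _anode_mask=an_f,
    )
    return field


def compute_cathode_flux(field: PotentialField, *_ignored) -> float:
    """Total current (A, magnitude) over the cathode boundary, recomputed
    from the stored fine grid."""
    if field._fine_sigma is None or field._cathode_mask is None:
        raise RuntimeError("field does not carry its solve grids (unsolved state)")
    return abs(
        boundary_current_A(
            field.fine.values,
            field._fine_sigma,
            field.fine.voxel_size_mm,
            field._cathode_mask,
        )
    )


def compute_anode_flux(field: PotentialField) -> float:
    if field._fine_sigma is None or field._anode_mask is None:
        raise RuntimeError("field does not carry its solve grids (unsolved state)")
    if not np.any(field._anode_mask):
        raise RuntimeError("anode is not inside the fine ROI (case return)")
    return boundary_current_A(
        field.fine.values,
        field._fine_sigma,
        field.fine.voxel_size_mm,
        field._anode_mask,
    )


def compute_eti_impedance(field: PotentialField) -> float:
    """Electrode-tissue-interface impedance: applied voltage over cathode flux."""
    if field.cathode_flux_A == 0:
        raise ArithmeticError("cathode flux is zero; impedance undefined")
    return field.applied_voltage_V / field.cathode_flux_A


def _scaled(field: PotentialField, factor: float) -> PotentialField:
    return replace(
        field,
        fine=GridField(field.fine.values * factor, field.fine.origin_mm, field.fine.voxel_size_mm),
        coarse=GridField(
            field.coarse.values * factor, field.coarse.origin_mm, field.coarse.voxel_size_mm
        ),
        applied_voltage_V=field.applied_voltage_V * factor,
        cathode_flux_A=field.cathode_flux_A * factor,
        equivalent_current_mA=field.equivalent_current_mA * factor,
    )


def scale_to_current(field: PotentialField, target_mA: float) -> PotentialField:
    """Rescale the linear solution so the delivered current equals target_mA."""
    if field.cathode_flux_A == 0:
        raise ArithmeticError("cannot rescale a field with zero cathode flux")
    return _scaled(field, target_mA / (1000.0 * field.cathode_flux_A))


def scale_to_voltage(field: PotentialField, target_V: float) -> PotentialField:
    """Rescale the linear solution to a target applied voltage."""
    if field.applied_voltage_V == 0:
        raise ArithmeticError("cannot rescale a field solved at zero voltage")
    return _scaled(field, target_V / field.applied_voltage_V)


def export_field(field: PotentialField, path: str | Path) -> None:
    """HDF5 export: fine and coarse phi grids with their placement metadata."""
    import h5py

    with h5py.File(path, "w") as f:
        for name, grid in (("fine", field.fine), ("coarse", field.coarse)):
            g = f.create_group(name)
            g.create_dataset("phi_V", data=grid.values, compression="gzip")
            g.attrs["origin_mm"] = grid.origin_mm
            g.attrs["voxel_size_mm"] = grid.voxel_size_mm
        f.attrs["applied_voltage_V"] = field.applied_voltage_V
        f.attrs["cathode_flux_A"] = field.cathode_flux_A
        f.attrs["eti_impedance_ohm"] = field.eti_impedance_ohm
        f.attrs["equivalent_current_mA"] = field.equivalent_current_mA
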