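"""Orchestration of the configuration / spacing / amplitude / tissue sweep.

One :class:`SweepSpec` drives the full study grid: six named contact
configurations on the 1.5 mm-spaced lead, the vertical configurations
repeated on the 0.5 mm-spaced lead, both repeated at 1 and 2 mA, plus one
homogeneous-tissue control cell for configuration 4.  Each cell runs
solve -> current scaling -> population activation -> VTA bounding ->
four-way partition, and lands as one row of the breakdown CSV.

The homogeneous control is voltage-matched to its heterogeneous counterpart
(same applied voltage; the delivered equivalent current is reported in the
row): replacing the low-conductivity encapsulation sheath with bulk tissue
is what enlarges the activation volume, and that effect appears at matched
voltage, not matched current.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import anatomy
from .anatomy import PhantomSpec, TissueModel, build_pallidum_phantom, homogenize
from .axons import (
    ActivationResult,
    AxonGridSpec,
    MembraneParameters,
    StimulusWaveform,
    evaluate_population,
    generate_axon_grid,
)
from .lead import LeadGeometry, build_lead, place_at_target, rasterize_lead
from .solver import (
    PotentialField,
    SolverSettings,
    StimConfiguration,
    scale_to_current,
    scale_to_voltage,
    solve_potential,
)
from .vta import (
    VTAResult,
    asymmetry_index,
    build_vta,
    export_vta,
    flag_side_effect_overlap,
    partition_vta,
)

#: contact sets of the six named configurations
_NAMED = {
    "1": (("2B",), "CASE"),
    "2a": (("2A", "2B"), "CASE"),
    "2b": (("2B", "3B"), "CASE"),
    "3": (("2A", "2B", "2C"), "CASE"),
    "4": (("2B",), ("3A", "3B", "3C")),
    "5": (("2A", "2B", "2C"), ("3A", "3B", "3C")),
}

#: configurations engaging vertically separated contacts (repeated at 0.5 mm)
VERTICAL_CONFIGS = ("2b", "4", "5")


def _cathode_azimuth(lead: LeadGeometry, config: StimConfiguration) -> np.ndarray:
    """Mean outward direction of the cathode segments; falls back to the
    active-row reference when the cathode set is rotationally symmetric."""
    dirs = [lead.segment_direction(c) for c in config.cathodes if len(c) > 1]
    if dirs:
        mean = np.sum(dirs, axis=0)
        if np.linalg.norm(mean) > 1e-6:
            return mean / np.linalg.norm(mean)
    return lead.segment_direction("2B")


def named_configuration(name: str, amplitude_mA: float = 1.0) -> StimConfiguration:
    """The six canonical contact configurations (co-activated cathodes).

    1 = single-segment monopole, 2a = row two-segment monopole, 2b =
    vertically stacked two-segment monopole, 3 = ring monopole, 4 =
    one-cathode-ring-anode bipole, 5 = ring-cathode-ring-anode bipole.
    """
    key = str(name).lower()
    if key not in _NAMED:
        raise KeyError(
            f"unknown configuration {name!r}; valid names: {sorted(_NAMED)}"
        )
    cathodes, anodes = _NAMED[key]
    return StimConfiguration(
        name=key, cathodes=cathodes, anodes=anodes, amplitude_mA=amplitude_mA
    )


@dataclass(frozen=True)
class SweepSpec:
    """Full sweep description; defaults reproduce the study grid."""

    phantom: PhantomSpec = PhantomSpec()
    spacings_mm: tuple[float, ...] = (1.5, 0.5)
    configurations: tuple[str, ...] = ("1", "2a", "2b", "3", "4", "5")
    amplitudes_mA: tuple[float, ...] = (1.0, 2.0)
    homogeneous_sigma: float = 0.3
    homogeneous_cells: tuple[tuple[str, float, float], ...] = (("4", 1.5, 1.0),)
    target_offsets_mm: tuple[float, float] = (2.25, 2.3)
    solver: SolverSettings = SolverSettings(
        roi_resolution_mm=0.3, electrode_resolution_mm=0.3
    )
    axon: AxonGridSpec = AxonGridSpec()
    membrane: MembraneParameters = MembraneParameters()
    waveform: StimulusWaveform = StimulusWaveform()
    vta_mode: str = "alpha"
    vta_voxel_mm: float = 0.25
    write_artifacts: bool = False
    seed: int = 0

    def cells(self) -> list[dict]:
        """Enumerate sweep cells: (config, spacing, amplitude, tissue_mode)."""
        out = []
        for spacing in self.spacings_mm:
            for name in self.configurations:
                if spacing != max(self.spacings_mm) and name not in VERTICAL_CONFIGS:
                    continue  # non-vertical configs are spacing-invariant
                for amp in self.amplitudes_mA:
                    out.append(
                        {
                            "config": name,
                            "spacing_mm": spacing,
                            "amplitude_mA": amp,
                            "tissue_mode": "heterogeneous",
                        }
                    )
        for name, spacing, amp in self.homogeneous_cells:
            out.append(
                {
                    "config": name,
                    "spacing_mm": spacing,
                    "amplitude_mA": amp,
                    "tissue_mode": "homogeneous",
                }
            )
        return out


CSV_NAME = "vta_breakdown.csv"

_CSV_COLUMNS = [
    "config",
    "spacing_mm",
    "amplitude_mA",
    "tissue_mode",
    "applied_voltage_V",
    "eti_impedance_ohm",
    "equivalent_current_mA",
    "n_axons",
    "n_activated",
    "total_mm3",
    "in_GPi_mm3",
    "lamina_mm3",
    "in_GPe_mm3",
    "outside_mm3",
    "pct_in_GPi",
    "pct_lamina",
    "pct_in_GPe",
    "pct_outside",
    "asymmetry_index",
    "optic_tract_mm3",
    "internal_capsule_mm3",
]


def run_sweep(spec: SweepSpec, output_dir: str | Path) -> pd.DataFrame:
    """Run every sweep cell; write the breakdown CSV, summary and manifest.

    Unique (config, spacing, tissue_mode) combinations are solved once at
    unit voltage and rescaled per amplitude (exact by linearity).  Failures
    are recorded per cell and the sweep continues.
    """
    out_dir = Path(output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    phantom = build_pallidum_phantom(spec.phantom)

    leads: dict[float, LeadGeometry] = {}
    models: dict[tuple[float, str], TissueModel] = {}
    axon_grids: dict[float, list] = {}
    for spacing in spec.spacings_mm:
        lead = build_lead(spacing)
        lead = place_at_target(lead, phantom, spec.target_offsets_mm)
        leads[spacing] = lead
        models[(spacing, "heterogeneous")] = rasterize_lead(lead, phantom)
        models[(spacing, "homogeneous")] = homogenize(
            models[(spacing, "heterogeneous")], spec.homogeneous_sigma
        )
        axon_grids[spacing] = generate_axon_grid(lead, spec.axon, spec.membrane)

    fields: dict[tuple[str, float, str], PotentialField] = {}
    failures: list[dict] = []
    rows: list[dict] = []
    timings: dict[str, float] = {}

    def unit_field(name: str, spacing: float, mode: str) -> PotentialField:
        key = (name, spacing, mode)
        if key not in fields:
            t0 = time.time()
            fields[key] = solve_potential(
                models[(spacing, mode)],
                leads[spacing],
                named_configuration(name),
                spec.solver,
            )
            timings[f"solve_{name}_{spacing}_{mode}"] = time.time() - t0
        return fields[key]

    for cell in spec.cells():
        name, spacing, amp, mode = (
            cell["config"],
            cell["spacing_mm"],
            cell["amplitude_mA"],
            cell["tissue_mode"],
        )
        try:
            t0 = time.time()
            if mode == "heterogeneous":
                scaled = scale_to_current(unit_field(name, spacing, mode), amp)
            else:
                het = scale_to_current(unit_field(name, spacing, "heterogeneous"), amp)
                scaled = scale_to_voltage(
                    unit_field(name, spacing, mode), het.applied_voltage_V
                )
            lead = leads[spacing]
            waveform = replace(
                spec.waveform, pulse_width_us=named_configuration(name).pulse_width_us
            )
            activation = evaluate_population(
                scaled, axon_grids[spacing], waveform, spec.membrane
            )
            vta = build_vta(
                activation,
                spec.vta_voxel_mm,
                mode=spec.vta_mode,
                plane_spacing_mm=spec.axon.plane_spacing_mm,
                grid_origin_mm=phantom.origin_mm,
            )
            vta = partition_vta(vta, phantom)
            asym = asymmetry_index(
                vta,
                lead.tip_position_mm,
                lead.shaft_direction,
                _cathode_azimuth(lead, named_configuration(name)),
            )
            ot = flag_side_effect_overlap(vta, phantom, [anatomy.OPTIC_TRACT])
            ic = flag_side_effect_overlap(vta, phantom, [anatomy.INTERNAL_CAPSULE])
            sub = vta.sub_volumes_mm3
            pct = vta.percentages
            rows.append(
                {
                    "config": name,
                    "spacing_mm": spacing,
                    "amplitude_mA": amp,
                    "tissue_mode": mode,
                    "applied_voltage_V": scaled.applied_voltage_V,
                    "eti_impedance_ohm": scaled.eti_impedance_ohm,
                    "equivalent_current_mA": scaled.equivalent_current_mA,
                    "n_axons": len(axon_grids[spacing]),
                    "n_activated": activation.n_activated,
                    "total_mm3": vta.total_volume_mm3,
                    "in_GPi_mm3": sub["in_GPi"],
                    "lamina_mm3": sub["lamina"],
                    "in_GPe_mm3": sub["in_GPe"],
                    "outside_mm3": sub["outside_GP"],
                    "pct_in_GPi": pct["in_GPi"],
                    "pct_lamina": pct["lamina"],
                    "pct_in_GPe": pct["in_GPe"],
                    "pct_outside": pct["outside_GP"],
                    "asymmetry_index": asym,
                    "optic_tract_mm3": ot,
                    "internal_capsule_mm3": ic,
                }
            )
            timings[f"cell_{name}_{spacing}_{amp}_{mode}"] = time.time() - t0
            if spec.write_artifacts:
                stem = f"vta_{name}_{spacing}mm_{amp}mA_{mode}"
                export_vta(
                    vta, out_dir / f"{stem}.nii.gz", out_dir / f"{stem}.stl"
                )
        except Exception as err:  # per-cell failure; sweep continues
            failures.append({**cell, "error": f"{type(err).__name__}: {err}"})

    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    csv_path = out_dir / CSV_NAME
    # 17 significant digits round-trip float64 exactly, so the summary is a
    # pure function of the CSV and reruns are byte-identical
    df.to_csv(csv_path, index=False, float_format="%.17g", lineterminator="\n")

    manifest = {
        "seed": spec.seed,
        "n_cells": len(spec.cells()),
        "n_rows": len(rows),
        "failures": failures,
        "spec_sha256": hashlib.sha256(
            json.dumps(_spec_digest(spec), sort_keys=True).encode()
        ).hexdigest(),
        "placement": {
            str(s): leads[s].placement_report for s in spec.spacings_mm
        },
        "solver_info": {
            f"{k[0]}_{k[1]}_{k[2]}": fields[k].info for k in sorted(fields)
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "wall_time_s": round(time.time() - t_start, 3),
    }
    if failures:
        manifest["failure_summary"] = "; ".join(
            f"{f['config']}/{f['spacing_mm']}mm/{f['amplitude_mA']}mA/{f['tissue_mode']}: {f['error']}"
            for f in failures
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    summary = summarize(df)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return df


def _spec_digest(spec: SweepSpec) -> dict:
    def conv(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: conv(v) for k, v in asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [conv(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    return conv(spec)


def summarize(df: pd.DataFrame) -> dict:
    """Derived sweep statistics: mean %-in-GPi of the vertical configurations
    per spacing/amplitude, configuration 4 -> 5 shifts, the homogeneous vs
    heterogeneous volume difference, and side-effect structure volumes."""
    df = df.assign(config=df.config.astype(str))  # CSV may infer integers
    het = df[df.tissue_mode == "heterogeneous"]
    out: dict = {"missing_cells": []}

    def cell(config, spacing, amp, mode="heterogeneous"):
        sel = df[
            (df.config == config)
            & (df.spacing_mm == spacing)
            & (df.amplitude_mA == amp)
            & (df.tissue_mode == mode)
        ]
        if sel.empty:
            out["missing_cells"].append(f"{config}/{spacing}/{amp}/{mode}")
            return None
        return sel.iloc[0]

    mean_gpi: dict[str, float] = {}
    for spacing in sorted(het.spacing_mm.unique()):
        for amp in sorted(het.amplitude_mA.unique()):
            sel = het[
                (het.spacing_mm == spacing)
                & (het.amplitude_mA == amp)
                & het.config.isin(VERTICAL_CONFIGS)
            ]
            if len(sel):
                mean_gpi[f"{spacing:g}mm_{amp:g}mA"] = round(
                    float(sel.pct_in_GPi.mean()), 2
                )
    out["mean_pct_in_gpi_vertical_configs"] = mean_gpi

    shifts: dict[str, dict] = {}
    for spacing in sorted(het.spacing_mm.unique()):
        for amp in sorted(het.amplitude_mA.unique()):
            c4, c5 = cell("4", spacing, amp), cell("5", spacing, amp)
            if c4 is None or c5 is None or c4.total_mm3 == 0:
                continue
            shifts[f"{spacing:g}mm_{amp:g}mA"] = {
                "volume_change_pct": round(
                    float(100.0 * (c5.total_mm3 - c4.total_mm3) / c4.total_mm3), 2
                ),
                "pct_in_gpi_from": round(float(c4.pct_in_GPi), 2),
                "pct_in_gpi_to": round(float(c5.pct_in_GPi), 2),
            }
    out["config_4_to_5"] = shifts

    homog = df[df.tissue_mode == "homogeneous"]
    homo_stats = {}
    for _, hrow in homog.iterrows():
        match = cell(hrow.config, hrow.spacing_mm, hrow.amplitude_mA)
        if match is not None and match.total_mm3 > 0:
            key = f"{hrow.config}/{hrow.spacing_mm:g}mm/{hrow.amplitude_mA:g}mA"
            homo_stats[key] = {
                "homogeneous_mm3": round(float(hrow.total_mm3), 4),
                "heterogeneous_mm3": round(float(match.total_mm3), 4),
                "percent_difference": round(
                    float(100.0 * (hrow.total_mm3 - match.total_mm3) / match.total_mm3),
                    2,
                ),
            }
    out["homogeneous_vs_heterogeneous"] = homo_stats

    out["side_effect_mm3"] = {
        f"{r.config}/{r.spacing_mm:g}mm/{r.amplitude_mA:g}mA/{r.tissue_mode}": {
            "optic_tract": round(float(r.optic_tract_mm3), 4),
            "internal_capsule": round(float(r.internal_capsule_mm3), 4),
        }
        for _, r in df.iterrows()
    }
    out["asymmetry_index"] = {
        f"{r.config}/{r.spacing_mm:g}mm/{r.amplitude_mA:g}mA": round(
            float(r.asymmetry_index), 6
        )
        for _, r in het.iterrows()
        if np.isfinite(r.asymmetry_index)
    }
    return out
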