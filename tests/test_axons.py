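"""Axon-population layout and double-cable membrane dynamics."""

import numpy as np
import pytest
from dataclasses import replace

from conftest import point_source_profile, straight_axon

from pallisteer.axons import (
    AxonGridSpec,
    BracketError,
    MembraneParameters,
    StimulusWaveform,
    evaluate_population,
    find_threshold,
    generate_axon_grid,
    interpolate_potentials,
    simulate_axon,
)
from pallisteer.lead import build_lead
from pallisteer.solver import GridField, PotentialField

PARAMS = MembraneParameters()
WAVE = StimulusWaveform()


def test_node_count_from_length_and_internode():
    """20 mm fiber at 0.5 mm internodal length carries 41 nodes."""
    ax = straight_axon()
    assert ax.n_nodes == 41
    # first/last compartments are nodes; equidistant nodes
    assert ax.compartment_kinds[0] == 0 and ax.compartment_kinds[-1] == 0
    nodes = ax.compartment_positions_mm[ax.node_indices]
    gaps = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    assert np.allclose(gaps, 0.5, atol=1e-9)


def test_grid_orientations_and_exclusion():
    lead = build_lead(1.5)
    spec = AxonGridSpec(plane_extent_mm=6.0)
    axons = generate_axon_grid(lead, spec)
    orientations = {a.orientation_index for a in axons}
    assert orientations == set(range(6))  # 0..150 degrees
    r_excl = lead.radius_mm + lead.encapsulation_thickness_mm
    for a in axons[:200]:
        # line-to-axis distance never dips into the lead body
        w = a.compartment_positions_mm - lead.tip_position_mm
        t = w @ lead.shaft_direction
        radial = w - t[:, None] * lead.shaft_direction
        assert np.min(np.linalg.norm(radial, axis=1)) >= r_excl - 1e-9


def _uniform_gradient_field(c=0.01):
    """phi = c * x volts on a coarse grid (fine grid empty box elsewhere)."""
    n, h = 40, 1.0
    origin = np.array([-20.0, -20.0, -20.0])
    xs = origin[0] + (np.arange(n) + 0.5) * h
    phi = np.broadcast_to(c * xs[:, None, None], (n, n, n)).copy()
    grid = GridField(phi, origin, h)
    return PotentialField(
        fine=grid, coarse=grid, applied_voltage_V=1.0, cathode_flux_A=1.0,
        eti_impedance_ohm=1.0, equivalent_current_mA=1.0,
    )


def test_interpolation_exact_on_affine_field():
    field = _uniform_gradient_field(0.01)
    ax = straight_axon(direction=(1, 0, 0))
    prof = interpolate_potentials(field, ax)
    x = ax.compartment_positions_mm[:, 0]
    assert np.allclose(prof, 0.01 * x, atol=1e-12)
    zero = _uniform_gradient_field(0.0)
    assert np.allclose(interpolate_potentials(zero, ax), 0.0)


def test_point_source_profile_peaks_at_nearest_compartment():
    ax = straight_axon()
    prof = point_source_profile(ax, (0.3, 1.0, 0.0))
    nearest = np.argmin(
        np.linalg.norm(ax.compartment_positions_mm - np.array([0.3, 1.0, 0.0]), axis=1)
    )
    assert np.argmin(prof) == nearest  # cathodal: most negative closest


def test_rest_is_stable_without_input():
    ax = straight_axon()
    rec = simulate_axon(ax, np.zeros(ax.compartment_positions_mm.shape[0]),
                        replace(WAVE, total_time_ms=10.0), PARAMS)
    assert not rec["activated"]
    assert abs(rec["vmax_mV"] - PARAMS.vrest_mV) < 1.0


def test_cathodal_api_at_nearest_node():
    ax = straight_axon()
    prof = point_source_profile(ax, (0.0, 0.5, 0.0))  # above the center node
    rec = simulate_axon(ax, prof, WAVE, PARAMS)
    assert rec["activated"]
    center = (ax.n_nodes - 1) // 2
    assert abs(rec["api_node"] - center) <= 1


def test_threshold_monotonic_in_distance():
    ax = straight_axon()
    thr = [
        find_threshold(ax, point_source_profile(ax, (0.0, d, 0.0)), WAVE, PARAMS)
        for d in (1.0, 2.0)
    ]
    assert thr[0] < thr[1]


def test_threshold_monotonic_in_pulse_width():
    """Strength-duration: longer pulses need less current."""
    ax = straight_axon()
    prof = point_source_profile(ax, (0.0, 1.5, 0.0))
    t60 = find_threshold(ax, prof, replace(WAVE, pulse_width_us=60.0), PARAMS)
    t200 = find_threshold(ax, prof, replace(WAVE, pulse_width_us=200.0), PARAMS)
    assert t200 < t60


def test_threshold_monotonic_in_fiber_diameter():
    prof_args = ((0.0, 1.5, 0.0),)
    thr = {}
    for dia in (5.7, 8.7):
        ax = straight_axon(diameter_um=dia)
        thr[dia] = find_threshold(ax, point_source_profile(ax, *prof_args), WAVE, PARAMS)
    assert thr[8.7] < thr[5.7]


def test_bisection_contract():
    ax = straight_axon()
    prof = point_source_profile(ax, (0.0, 1.0, 0.0))
    thr = find_threshold(ax, prof, WAVE, PARAMS)
    assert simulate_axon(ax, prof * thr, WAVE, PARAMS)["activated"]
    assert not simulate_axon(ax, prof * 0.98 * thr, WAVE, PARAMS)["activated"]
    with pytest.raises(BracketError):
        find_threshold(ax, prof, WAVE, PARAMS, bracket=(1e-6, 2e-6))


def test_dt_refinement_stability():
    """Halving both time steps moves the threshold by < 2%."""
    ax = straight_axon()
    prof = point_source_profile(ax, (0.0, 2.0, 0.0))
    fine = replace(WAVE, dt_us=WAVE.dt_us / 2, dt_coarse_us=WAVE.dt_coarse_us / 2)
    t_ref = find_threshold(ax, prof, WAVE, PARAMS, rel_tol=0.003)
    t_fine = find_threshold(ax, prof, fine, PARAMS, rel_tol=0.003)
    assert abs(t_fine - t_ref) / t_ref < 0.02


def test_population_null_field_and_order_independence():
    lead = build_lead(1.5)
    spec = AxonGridSpec(plane_extent_mm=3.0, axial_extent_mm=(2.0, 4.0))
    axons = generate_axon_grid(lead, spec)
    field = _uniform_gradient_field(0.0)
    res = evaluate_population(field, axons, WAVE, PARAMS)
    assert res.n_activated == 0
    # order independence: reversed population gives the mirrored flags
    res_rev = evaluate_population(field, axons[::-1], WAVE, PARAMS)
    assert np.array_equal(res.activated[::-1], res_rev.activated)


def test_activation_table_round_trip(tmp_path):
    from pallisteer.axons import activation_table

    lead = build_lead(1.5)
    spec = AxonGridSpec(plane_extent_mm=3.0, axial_extent_mm=(2.0, 4.0))
    axons = generate_axon_grid(lead, spec)
    res = evaluate_population(_uniform_gradient_field(0.0), axons, WAVE, PARAMS)
    df = activation_table(res)
    assert len(df) == len(axons)
    df.to_csv(tmp_path / "act.csv", index=False)
    import pandas as pd

    back = pd.read_csv(tmp_path / "act.csv")
    assert back.activated.sum() == res.n_activated


def test_profile_length_mismatch_rejected():
    ax = straight_axon()
    with pytest.raises(ValueError):
        simulate_axon(ax, np.zeros(3), WAVE, PARAMS)
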