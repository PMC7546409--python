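"""Discrete operator properties of the quasi-static solve (small grids)."""

import numpy as np
import pytest

from pallisteer.solver import (
    SolverSettings,
    boundary_current_A,
    scale_to_current,
    solve_on_grid,
)

SETTINGS = SolverSettings()


def _two_sphere_setup(n=40, h=0.5, sigma_bg=0.3):
    """Cathode and anode balls in a uniform box (Neumann outside)."""
    axes = [(np.arange(n) + 0.5) * h - n * h / 2 for _ in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    sigma = np.full((n, n, n), sigma_bg)
    cath = (xx + 4) ** 2 + yy**2 + zz**2 <= 2.0**2
    an = (xx - 4) ** 2 + yy**2 + zz**2 <= 2.0**2
    dmask = cath | an
    dvals = np.where(cath, -1.0, 0.0)
    return sigma, dmask, dvals, cath, an


def test_zero_voltage_gives_zero_field():
    sigma, dmask, dvals, *_ = _two_sphere_setup(n=24)
    phi, _ = solve_on_grid(sigma, 0.5, dmask, dvals * 0.0, SETTINGS)
    assert np.allclose(phi, 0.0, atol=1e-12)


def test_sigma_scaling_leaves_phi_and_doubles_flux():
    sigma, dmask, dvals, cath, _ = _two_sphere_setup(n=24)
    phi1, _ = solve_on_grid(sigma, 0.5, dmask, dvals, SETTINGS)
    phi2, _ = solve_on_grid(2 * sigma, 0.5, dmask, dvals, SETTINGS)
    assert np.allclose(phi1, phi2, atol=1e-6)
    i1 = boundary_current_A(phi1, sigma, 0.5, cath)
    i2 = boundary_current_A(phi2, 2 * sigma, 0.5, cath)
    assert i2 == pytest.approx(2 * i1, rel=1e-9)


def test_linearity_in_applied_voltage():
    sigma, dmask, dvals, *_ = _two_sphere_setup(n=24)
    phi1, _ = solve_on_grid(sigma, 0.5, dmask, dvals, SETTINGS)
    phi3, _ = solve_on_grid(sigma, 0.5, dmask, 3.0 * dvals, SETTINGS)
    assert np.allclose(phi3, 3.0 * phi1, atol=1e-7)


def test_discrete_maximum_principle_heterogeneous():
    """Interior phi stays within the Dirichlet range for rough coefficients."""
    rng = np.random.default_rng(7)
    sigma, dmask, dvals, *_ = _two_sphere_setup(n=24)
    sigma *= np.exp(rng.normal(0.0, 1.0, sigma.shape))  # lognormal heterogeneity
    phi, _ = solve_on_grid(sigma, 0.5, dmask, dvals, SETTINGS)
    assert phi.min() >= -1.0 - 1e-9
    assert phi.max() <= 0.0 + 1e-9


def test_bipolar_charge_conservation_under_one_percent():
    sigma, dmask, dvals, cath, an = _two_sphere_setup(n=40)
    phi, _ = solve_on_grid(sigma, 0.5, dmask, dvals, SETTINGS)
    ic = boundary_current_A(phi, sigma, 0.5, cath)
    ia = boundary_current_A(phi, sigma, 0.5, an)
    assert abs(ic + ia) / abs(ic) < 0.01


def test_superposition_of_coactivated_cathodes():
    """Solving with both cathode balls tied to -1 V equals the co-activated
    solve built from the same Dirichlet data (operator linearity sanity)."""
    sigma, dmask, dvals, cath, an = _two_sphere_setup(n=24)
    # both spheres cathodal, ground on the box's outermost cell layer
    ground = np.zeros_like(dmask)
    ground[[0, -1], :, :] = True
    dmask2 = dmask | ground
    dvals2 = np.where(dmask, -1.0, 0.0)
    phi_both, _ = solve_on_grid(sigma, 0.5, dmask2, dvals2, SETTINGS)
    assert phi_both.min() >= -1.0 - 1e-9
    # shared potential on both cathodes: equipotential surfaces at -1
    assert np.allclose(phi_both[dmask], -1.0)


def test_encapsulation_conductivity_controls_impedance():
    """Halving the sheath conductivity raises the electrode impedance."""
    n, h = 40, 0.25
    axes = [(np.arange(n) + 0.5) * h - n * h / 2 for _ in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    cath = r <= 1.0
    shell = (r > 1.0) & (r <= 1.5)
    ground = r >= 4.5
    dmask = cath | ground
    dvals = np.where(cath, -1.0, 0.0)
    imped = []
    for sig_shell in (0.1, 0.05):
        sigma = np.full((n, n, n), 0.3)
        sigma[shell] = sig_shell
        phi, _ = solve_on_grid(sigma, h, dmask, dvals, SETTINGS)
        i = abs(boundary_current_A(phi, sigma, h, cath))
        imped.append(1.0 / i)
    assert imped[1] > imped[0]


def test_scale_to_current_is_exact_identity_and_linear(rasterized_field):
    field = rasterized_field
    same = scale_to_current(field, field.cathode_flux_A * 1000.0)
    assert np.allclose(same.fine.values, field.fine.values)
    one = scale_to_current(field, 1.0)
    two = scale_to_current(field, 2.0)
    assert np.allclose(two.fine.values, 2.0 * one.fine.values)
    assert two.equivalent_current_mA == pytest.approx(2.0)
    from pallisteer.solver import compute_cathode_flux

    assert compute_cathode_flux(two) * 1000.0 == pytest.approx(2.0, rel=1e-9)


def test_eti_impedance_is_ohms_law(rasterized_field):
    from pallisteer.solver import compute_eti_impedance

    field = rasterized_field
    assert compute_eti_impedance(field) == pytest.approx(
        field.applied_voltage_V / field.cathode_flux_A
    )


def _coarse_settings():
    return SolverSettings(roi_resolution_mm=0.35, electrode_resolution_mm=0.35)


@pytest.fixture(scope="module")
def rasterized_field(phantom, placed_lead, rasterized_model):
    from pallisteer.solver import solve_potential
    from pallisteer.sweep import named_configuration

    return solve_potential(
        rasterized_model, placed_lead, named_configuration("1"), _coarse_settings()
    )


def test_unknown_contact_raises(phantom, placed_lead):
    from pallisteer.anatomy import ConsistencyError
    from pallisteer.solver import StimConfiguration, solve_potential

    cfg = StimConfiguration("custom", cathodes=("2B",), anodes="CASE")
    with pytest.raises(ConsistencyError):
        solve_potential(phantom, placed_lead, cfg, _coarse_settings())  # no lead
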