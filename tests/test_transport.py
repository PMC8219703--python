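"""Forward solver: oracle agreement, conservation properties, moments."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from hyporeact.transport import (
    BoundarySeries,
    BreakthroughCurve,
    PecletWarning,
    SpatialGrid,
    TransportParameters,
    analytic_constant_bc,
    interpolate_boundary,
    solve_ade,
    temporal_moment,
    triangular_pulse_boundary,
)


def test_parameter_invariants_rejected():
    with pytest.raises(ValueError):
        TransportParameters(k=-0.1, R=1.0, v=0.004, L=0.05, D=1e-4)
    with pytest.raises(ValueError):
        TransportParameters(k=0.0, R=0.5, v=0.004, L=0.05, D=1e-4)
    with pytest.raises(ValueError):
        TransportParameters(k=0.0, R=1.0, v=-0.004, L=0.05, D=1e-4)
    with pytest.raises(ValueError):
        TransportParameters(k=0.0, R=1.0, v=0.004, L=0.05, D=0.0)


@pytest.mark.parametrize(
    "times, concs, t, expected",
    [
        ([0.0, 24.0], [11.5, 9.0], 0.0, 11.5),
        ([0.0, 24.0], [10.0, 10.0], 12.0, 10.0),
        ([0.0, 24.0], [10.0, 0.0], 12.0, 5.0),
    ],
)
def test_boundary_interpolation(times, concs, t, expected):
    series = BoundarySeries(np.array(times), np.array(concs))
    assert interpolate_boundary(series, t) == pytest.approx(expected)


def test_boundary_extrapolation_rejected():
    series = BoundarySeries(np.array([0.0, 24.0]), np.array([10.0, 9.0]))
    with pytest.raises(ValueError, match="extrapolation"):
        series(25.0)
    with pytest.raises(ValueError, match="extrapolation"):
        series(-1.0)


def test_zero_boundary_gives_zero_curve(coarse_grid):
    params = TransportParameters(k=0.1, R=2.0, v=0.004, L=0.05, D=1e-4)
    curve = solve_ade(params, BoundarySeries.constant(0.0, 504.0), coarse_grid)
    assert np.all(curve.concentrations == 0.0)


def test_decay_free_steady_state_is_uniform(constant_boundary):
    params = TransportParameters(k=0.0, R=1.0, v=0.004, L=0.05, D=1e-4)
    curve = solve_ade(params, BoundarySeries.constant(10.0, 504.0))
    assert curve.concentrations[-1] == pytest.approx(10.0, rel=1e-6)


def test_numeric_matches_analytic_oracle(constant_boundary):
    params = TransportParameters(k=0.05, R=1.0, v=0.004, L=0.05, D=1e-4)
    curve = solve_ade(params, constant_boundary)
    t_check = np.array([6.0, 12.0, 24.0, 48.0, 96.0])
    numeric = curve.at(t_check)
    analytic = analytic_constant_bc(params, 11.5, t_check)
    assert np.max(np.abs(numeric - analytic)) / 11.5 < 1e-2
    # refinement improves agreement by at least 2x (first order or better)
    fine = solve_ade(params, constant_boundary, SpatialGrid().refined(2))
    err_coarse = np.max(np.abs(numeric - analytic))
    err_fine = np.max(np.abs(fine.at(t_check) - analytic))
    assert err_fine < err_coarse / 2.0


def test_analytic_steady_state_limit():
    params = TransportParameters(k=0.05, R=1.3, v=0.004, L=0.05, D=1e-4)
    c_inf = analytic_constant_bc(params, 11.5, 1e7)
    u = np.sqrt(params.v**2 + 4 * params.k * params.D)
    expected = 11.5 * np.exp(params.L * (params.v - u) / (2 * params.D))
    assert c_inf == pytest.approx(expected, rel=1e-9)


def test_analytic_edge_cases():
    params = TransportParameters(k=0.0, R=1.0, v=0.004, L=0.05, D=1e-4)
    assert analytic_constant_bc(params, 11.5, 1e7) == pytest.approx(11.5, rel=1e-9)
    assert analytic_constant_bc(params, 0.0, 10.0) == 0.0
    with pytest.raises(ValueError):
        analytic_constant_bc(params, 11.5, 0.0)


def test_monotone_in_removal_rate(constant_boundary, coarse_grid):
    base = dict(R=1.2, v=0.004, L=0.05, D=1e-4)
    prev = solve_ade(TransportParameters(k=0.0, **base), constant_boundary,
                     coarse_grid).concentrations
    for k in (0.01, 0.05, 0.2):
        cur = solve_ade(TransportParameters(k=k, **base), constant_boundary,
                        coarse_grid).concentrations
        assert np.all(cur <= prev + 1e-9 * 11.5)
        prev = cur


def test_linearity_in_boundary(coarse_grid):
    params = TransportParameters(k=0.02, R=1.5, v=0.004, L=0.08, D=1e-4)
    t = np.array([0.0, 48.0, 504.0])
    base = BoundarySeries(t, np.array([11.5, 5.0, 1.0]))
    scaled = BoundarySeries(t, 3.0 * base.concentrations)
    c1 = solve_ade(params, base, coarse_grid).concentrations
    c3 = solve_ade(params, scaled, coarse_grid).concentrations
    np.testing.assert_allclose(c3, 3.0 * c1, rtol=1e-10, atol=1e-12)


def test_non_negativity(coarse_grid):
    import contextlib

    pulse = triangular_pulse_boundary(2.0, 2.0, 11.5, 504.0)
    for D in (1e-6, 1e-4):  # high- and low-Peclet regimes
        params = TransportParameters(k=0.0, R=1.0, v=0.005, L=0.1, D=D)
        ctx = (pytest.warns(PecletWarning) if D == 1e-6
               else contextlib.nullcontext())
        with ctx:
            curve = solve_ade(params, pulse, coarse_grid)
        assert curve.concentrations.min() >= -1e-9 * 11.5


def test_peclet_fallback_warns_and_stays_finite():
    params = TransportParameters(k=0.0, R=1.0, v=0.01, L=0.05, D=1e-6)
    with pytest.warns(PecletWarning):
        curve = solve_ade(params, BoundarySeries.constant(10.0, 504.0),
                          SpatialGrid.for_inference())
    assert np.isfinite(curve.concentrations).all()
    assert curve.concentrations[-1] == pytest.approx(10.0, rel=1e-3)


def test_first_moment_of_symmetric_pulse():
    t = np.linspace(0.0, 20.0, 401)
    c = np.maximum(0.0, 1.0 - np.abs(t - 10.0) / 3.0)
    assert temporal_moment(BreakthroughCurve(t, c)) == pytest.approx(10.0, rel=1e-9)


def test_moment_undefined_for_zero_curve():
    t = np.linspace(0.0, 10.0, 11)
    with pytest.raises(ValueError, match="undefined"):
        temporal_moment(BreakthroughCurve(t, np.zeros_like(t)))


@pytest.mark.parametrize("retardation, factor", [(1.0, 1.0), (2.0, 2.0), (4.0, 4.0)])
def test_retardation_scales_pulse_delay(retardation, factor):
    """First-moment delay of a conservative pulse is R * L / v."""
    geom_tau = 11.5
    L = 0.05
    params = TransportParameters(k=0.0, R=retardation, v=L / geom_tau, L=L, D=1e-6)
    pulse = triangular_pulse_boundary(1.0, 1.0, 11.5, 504.0)
    grid = SpatialGrid()
    with pytest.warns(PecletWarning):
        out = solve_ade(params, pulse, grid)
    inlet = BreakthroughCurve(grid.times, pulse(grid.times))
    delay = temporal_moment(out) - temporal_moment(inlet)
    assert delay == pytest.approx(factor * geom_tau, rel=0.02)


@hyp_settings(max_examples=20, deadline=None, derandomize=True)
@given(
    k=st.floats(0.0, 0.5),
    R=st.floats(1.0, 10.0),
    v=st.floats(1e-3, 8e-3),
    L=st.floats(0.02, 0.2),
)
def test_solution_bounded_by_inlet(k, R, v, L):
    """c(L, t) never exceeds the largest inlet concentration (max principle)."""
    params = TransportParameters(k=k, R=R, v=v, L=L, D=2e-4)
    curve = solve_ade(params, BoundarySeries.constant(11.5, 504.0),
                      SpatialGrid.for_inference())
    assert curve.concentrations.max() <= 11.5 * (1 + 1e-9)
    assert curve.concentrations.min() >= -1e-9 * 11.5
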