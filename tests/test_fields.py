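"""Closed-form fields: EDL potential, ionic densities, D_p, u, s_xy, Psi."""

import numpy as np
import pytest

from peritrap import (
    DomainError,
    FlowParameters,
    PlugState,
    Region,
    WavyChannel,
    axial_velocity,
    edl_potential,
    field_grid,
    ionic_densities,
    pressure_gradient,
    shear_stress,
    stream_function,
)
from peritrap.fields import psi_on_grid, yield_stress


@pytest.fixture(scope="module")
def channel():
    return WavyChannel.from_rule(0.034, 5)


# ---------------------------------------------------------------------------
# EDL potential and ionic densities
# ---------------------------------------------------------------------------


def test_edl_wall_value(channel):
    p = FlowParameters(q=-0.2, Dl=2.0)
    for x in (0.0, 0.3, 0.8):
        h = float(channel.height(x))
        assert edl_potential(h, x, channel, p) == pytest.approx(1.0, abs=1e-14)


def test_edl_centerline_value():
    ch = WavyChannel((0.2,))
    p = FlowParameters(q=-0.2, Dl=1.0)
    # h(0) = 1
    assert edl_potential(0.0, 0.0, ch, p) == pytest.approx(1.0 / np.cosh(1.0), abs=1e-14)


def test_edl_satisfies_linearized_equation(channel):
    p = FlowParameters(q=-0.2, Dl=3.0)
    x = 0.37
    h = float(channel.height(x))
    # the second-difference truncation error is ~Dl^4 d^2 / 12; 12001 points
    # push it safely below the tolerance
    y = np.linspace(-h, h, 12001)
    th = edl_potential(y, x, channel, p)
    d = y[1] - y[0]
    lap = (th[2:] - 2 * th[1:-1] + th[:-2]) / d**2
    assert np.max(np.abs(lap - p.Dl**2 * th[1:-1])) < 1e-6
    # symmetry boundary condition at the centerline
    dth0 = (edl_potential(1e-6, x, channel, p) - edl_potential(-1e-6, x, channel, p)) / 2e-6
    assert abs(dth0) < 1e-8


def test_edl_outside_channel_rejected(channel):
    p = FlowParameters(q=-0.2)
    with pytest.raises(DomainError):
        edl_potential(2.0, 0.0, channel, p)


def test_ionic_densities_identities():
    n_plus, n_minus = ionic_densities(0.0)
    assert (n_plus, n_minus) == (1.0, 1.0)
    n_plus, n_minus = ionic_densities(1.0)
    assert n_plus == pytest.approx(np.exp(-1.0))
    assert n_minus == pytest.approx(np.exp(1.0))
    rng = np.random.default_rng(7)
    theta = rng.uniform(-2, 2, 100)
    n_plus, n_minus = ionic_densities(theta)
    assert np.allclose(n_plus * n_minus, 1.0, atol=1e-14)


# ---------------------------------------------------------------------------
# Pressure gradient
# ---------------------------------------------------------------------------


def test_pressure_gradient_peristaltic_values():
    ch = WavyChannel((0.2,))  # h(0) = 1
    assert pressure_gradient(0.0, ch, FlowParameters(q=-1.0)) == pytest.approx(0.0, abs=1e-12)
    assert pressure_gradient(0.0, ch, FlowParameters(q=0.0)) == pytest.approx(-3.0, abs=1e-12)


def test_pressure_gradient_plug_reaches_wall():
    ch = WavyChannel((0.2,))
    with pytest.raises(DomainError):
        pressure_gradient(0.75, ch, FlowParameters(q=-0.2, h_pl=0.9))  # h(0.75) = 0.8


def test_pressure_gradient_thin_debye_layer_limit():
    ch = WavyChannel((0.2,))
    base = pressure_gradient(0.1, ch, FlowParameters(q=-0.2, ue=0.0, Dl=1.0))
    gaps = []
    for Dl in (2e-4, 1e-4):
        full = pressure_gradient(0.1, ch, FlowParameters(q=-0.2, ue=1.0, Dl=Dl))
        gaps.append(abs(full - base))
    # halving Dl quarters the electroosmotic correction: O(Dl^2)
    assert gaps[0] / gaps[1] == pytest.approx(4.0, rel=1e-2)


# ---------------------------------------------------------------------------
# Velocity and shear stress
# ---------------------------------------------------------------------------


def test_velocity_no_slip_at_wall(channel):
    p = FlowParameters(q=-0.18366, ue=1.0, Dl=1.0, h_pl=0.1)
    for x in (0.05, 0.3, 0.62, 0.9):
        h = float(channel.height(x))
        assert abs(axial_velocity(h, x, channel, p)) < 1e-12


def test_velocity_plug_speed_peristaltic():
    ch = WavyChannel((0.2,))  # h(0) = 1
    p = FlowParameters(q=-0.123, h_pl=0.3)
    expected = 1.5 * (p.q + 0.7) / 0.7
    assert axial_velocity(p.h_pl, 0.0, ch, p) == pytest.approx(expected, abs=1e-12)
    # the plug translates rigidly at that speed
    assert axial_velocity(0.1, 0.0, ch, p) == pytest.approx(expected, abs=1e-12)
    st = PlugState.at(0.0, ch, p)
    assert st.c == pytest.approx(expected - 1.0, abs=1e-12)


def test_velocity_outside_channel_rejected(channel):
    with pytest.raises(DomainError):
        axial_velocity(1.5, 0.0, channel, FlowParameters(q=-0.2))


def test_shear_stress_centerline_and_yield(channel):
    p = FlowParameters(q=-0.18366, ue=1.0, Dl=1.0, h_pl=0.1)
    assert shear_stress(0.0, 0.3, channel, p) == 0.0
    p0 = FlowParameters(q=-0.123, h_pl=0.3)
    x = 0.2
    dp = pressure_gradient(x, channel, p0)
    assert yield_stress(x, channel, p0) == pytest.approx(dp * 0.3, abs=1e-12)


def test_shear_stress_derivative_matches_momentum_balance(channel):
    p = FlowParameters(q=-0.18366, ue=1.0, Dl=1.0, h_pl=0.1)
    x = 0.41
    h = float(channel.height(x))
    y = np.linspace(0.2, h - 0.05, 50)
    d = 1e-6
    ds = (shear_stress(y + d, x, channel, p) - shear_stress(y - d, x, channel, p)) / (2 * d)
    rhs = pressure_gradient(x, channel, p) - p.ue * p.Dl**2 * np.cosh(p.Dl * y) / np.cosh(p.Dl * h)
    assert np.max(np.abs(ds - rhs)) < 1e-8


# ---------------------------------------------------------------------------
# Stream function
# ---------------------------------------------------------------------------


def test_stream_function_wall_level_is_q(channel):
    for p in (FlowParameters(q=-0.18366, ue=0.0, Dl=1.0, h_pl=0.1),
              FlowParameters(q=-0.18366, ue=3.0, Dl=2.0, h_pl=0.1)):
        for x in (0.1, 0.5, 0.77):
            h = float(channel.height(x))
            psi, region = stream_function(x, h, channel, p)
            assert region is Region.SIGMA1
            assert psi == pytest.approx(p.q, abs=1e-12)


def test_stream_function_yield_surface_level_is_zero(channel):
    p = FlowParameters(q=-0.18366, ue=1.0, Dl=1.0, h_pl=0.3)
    for x in (0.15, 0.55, 0.95):
        psi, region = stream_function(x, p.h_pl, channel, p)
        assert region is Region.SIGMA1
        assert abs(psi) < 1e-12


def test_stream_function_lower_wall_contract_at_zero_plug(channel):
    p = FlowParameters(q=-0.18366, ue=1.0, Dl=1.0, h_pl=0.0)
    for x in (0.2, 0.6):
        h = float(channel.height(x))
        psi, region = stream_function(x, -h, channel, p)
        assert region is Region.SIGMA3
        assert psi == pytest.approx(-p.q, abs=1e-12)
        # wave-frame no-slip: dPsi/dy = u - 1 = -1 at the lower wall
        d = 1e-7
        dpsi = (stream_function(x, -h + d, channel, p)[0] - psi) / d
        assert dpsi == pytest.approx(-1.0, abs=1e-6)


def test_stream_function_zones_coincide_at_zero_plug(channel):
    p = FlowParameters(q=-0.18366, ue=1.0, Dl=1.0, h_pl=0.0)
    x = 0.33
    h = float(channel.height(x))
    for y in np.linspace(0.0, h, 17):
        up, _ = stream_function(x, y, channel, p)
        lo, _ = stream_function(x, -y, channel, p) if y > 0 else (up, None)
        # antisymmetric piecewise form: the lower zone mirrors the upper one
        assert lo == pytest.approx(-up if y > 0 else up, abs=1e-12)


def test_stream_function_outside_channel_rejected(channel):
    with pytest.raises(DomainError):
        stream_function(0.0, 1.7, channel, FlowParameters(q=-0.2))


# ---------------------------------------------------------------------------
# Grid export
# ---------------------------------------------------------------------------


def test_field_grid_regions_and_mask(channel):
    p = FlowParameters(q=-0.18366, ue=1.0, Dl=1.0, h_pl=0.2)
    grid = field_grid(channel, p, nx=81, ny=81)
    assert set(np.unique(grid.region)) == {0, 1, 2, 3}
    outside = grid.region == 0
    assert np.all(np.isnan(grid.psi[outside]))
    assert np.all(np.isfinite(grid.u[~outside]))
    frame = grid.to_frame()
    assert list(frame.columns) == ["x", "y", "region", "psi", "u", "s_xy"]
    assert len(frame) == 81 * 81


def test_psi_on_grid_matches_pointwise(channel):
    p = FlowParameters(q=-0.18366, ue=1.0, Dl=1.0, h_pl=0.1)
    x = np.array([[0.2, 0.7]])
    y = np.array([[0.5, -0.4]])
    grid_vals = psi_on_grid(x, y, channel, p)
    for k in range(2):
        psi, _ = stream_function(x[0, k], y[0, k], channel, p)
        assert grid_vals[0, k] == pytest.approx(psi, abs=1e-14)


def test_flow_parameter_validation(channel):
    with pytest.raises(ValueError):
        FlowParameters(q=-0.2, Dl=0.0)
    with pytest.raises(ValueError):
        FlowParameters(q=-0.2, h_pl=-0.1)
    with pytest.raises(ValueError, match="plug"):
        FlowParameters(q=-0.2, h_pl=0.9).validate_with(channel)
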