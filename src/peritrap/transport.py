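"""Temperature and solute-concentration closed forms.

The lubrication-limit energy balance in a yielded zone reads

    theta'' = -G - Br * S',      S' = s_xy * du/dy,

with Joule heating G, Brinkman number Br, and viscous dissipation S'
(in the yielded zone du/dy = s_xy - s0, the Bingham law).  Boundary
conditions: theta = 1 at the wall, dtheta/dy = 0 at the yield surface.
The solution implemented here is the exact double integral of the right-hand
side (a quartic in y plus electroosmotic sinh/cosh corrections); it
reproduces the coefficient structure of the quartic closed form and is
verified in the test suite against a numerical two-point BVP solve, which is
treated as authoritative.

The solute concentration obeys  phi'' = alpha1*phi + alpha2  with
alpha1 = k_r*Sc and alpha2 = k_r*Sc*N_d, phi(h_pl) = 1, phi(h) = 0, solved
by a sinh combination (requires alpha1 > 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .channel import WavyChannel
from .fields import DomainError, FlowParameters, _dp_of_h

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThermoSoluteParameters:
    """Dimensionless heat/mass-transfer groups.

    Br : Brinkman number (viscous dissipation vs conduction).
    G  : Joule-heating parameter (electrical heating source).
    Sc : Schmidt number; kr : first-order reaction rate;
    Nd : concentration-difference parameter.
    """

    Br: float = 0.0
    G: float = 0.0
    Sc: float = 1.0
    kr: float = 1.0
    Nd: float = 0.0

    @property
    def alpha1(self) -> float:
        return self.kr * self.Sc

    @property
    def alpha2(self) -> float:
        return self.kr * self.Sc * self.Nd


@dataclass(frozen=True)
class ScalarProfile:
    """Sampled transverse profile of a scalar field at fixed abscissa."""

    x: float
    y_grid: np.ndarray
    values: np.ndarray
    kind: str  # "temperature" | "concentration"

    def __post_init__(self) -> None:
        y = np.asarray(self.y_grid, dtype=float)
        if y.ndim != 1 or np.any(np.diff(y) <= 0):
            raise ValueError("y_grid must be strictly increasing and 1-D")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"y": self.y_grid, self.kind: self.values}).to_csv(
            path, index=False, float_format="%.12g"
        )


# ---------------------------------------------------------------------------
# Temperature
# ---------------------------------------------------------------------------


def _heat_antiderivatives(y, h, flow: FlowParameters, thermo: ThermoSoluteParameters, hpl: float):
    """(J, J') where J'' = -G - Br*s_xy*(s_xy - s0), integration constants zero.

    Expansion of the dissipation with s = P*y - E*sinh(a*y), a = Dl,
    E = ue*Dl/cosh(Dl*h):

        s*(s - s0) = P^2 y^2 - 2 P E y sinh(ay) + E^2 sinh^2(ay)
                     - s0 P y + s0 E sinh(ay)
    """
    a = flow.Dl
    P = _dp_of_h(h, flow, hpl)
    E = flow.ue * a / np.cosh(a * h)
    s0 = P * hpl - E * np.sinh(a * hpl)
    G, Br = thermo.G, thermo.Br

    sh, ch = np.sinh(a * y), np.cosh(a * y)
    sh2, ch2 = np.sinh(2.0 * a * y), np.cosh(2.0 * a * y)

    J1 = -G * y - Br * (
        P**2 * y**3 / 3.0
        - 2.0 * P * E * (y * ch / a - sh / a**2)
        + E**2 * (sh2 / (4.0 * a) - y / 2.0)
        - s0 * P * y**2 / 2.0
        + s0 * E * ch / a
    )
    J0 = -G * y**2 / 2.0 - Br * (
        P**2 * y**4 / 12.0
        - 2.0 * P * E * (y * sh / a**2 - 2.0 * ch / a**3)
        + E**2 * (ch2 / (8.0 * a**2) - y**2 / 4.0)
        - s0 * P * y**3 / 6.0
        + s0 * E * sh / a**2
    )
    return J0, J1


def _theta_zone(y, h, flow, thermo, hpl: float, wall: float):
    """Temperature in one yielded zone: theta(wall) = 1, theta'(hpl-side) = 0."""
    J0, _ = _heat_antiderivatives(y, h, flow, thermo, hpl)
    _, J1_at_plug = _heat_antiderivatives(hpl, h, flow, thermo, hpl)
    J0_at_wall, _ = _heat_antiderivatives(wall, h, flow, thermo, hpl)
    slope = -J1_at_plug
    const = 1.0 - J0_at_wall - slope * wall
    return J0 + slope * y + const


def temperature_profile(x, y, channel: WavyChannel, flow: FlowParameters,
                        thermo: ThermoSoluteParameters):
    """Temperature theta(y) at abscissa x.

    Upper zone (y >= h_pl): theta(h) = 1, theta'(h_pl) = 0.  Lower zone
    (y < 0): the zero-plug variant mirrored onto [-h, 0] with theta(-h) = 1,
    theta'(0) = 0.  Inside the plug the upper-zone form is continued smoothly.
    """
    h = float(channel.height(x))
    y = np.asarray(y, dtype=float)
    if np.any(np.abs(y) > h + 1e-12):
        raise DomainError("temperature requested outside the channel")
    scalar = not y.shape
    y = np.atleast_1d(y)
    out = np.empty_like(y)
    up = y >= 0.0
    if np.any(up):
        out[up] = _theta_zone(y[up], h, flow, thermo, flow.h_pl, wall=h)
    if np.any(~up):
        # lower zone: integrate with plug thickness 0, wall at y = -h.
        # theta'(0) = 0 and theta(-h) = 1.
        J0, _ = _heat_antiderivatives(y[~up], h, flow, thermo, 0.0)
        _, J1_at_0 = _heat_antiderivatives(0.0, h, flow, thermo, 0.0)
        J0_wall, _ = _heat_antiderivatives(-h, h, flow, thermo, 0.0)
        slope = -J1_at_0
        const = 1.0 - J0_wall + slope * h
        out[~up] = J0 + slope * y[~up] + const
    return float(out[0]) if scalar else out


def temperature_samples(x, channel, flow, thermo, n: int = 201) -> ScalarProfile:
    """Upper-zone temperature profile sampled on [h_pl, h(x)]."""
    h = float(channel.height(x))
    y = np.linspace(flow.h_pl, h, n)
    return ScalarProfile(
        x=float(x), y_grid=y,
        values=temperature_profile(x, y, channel, flow, thermo),
        kind="temperature",
    )


def temperature_field_grid(
    channel: WavyChannel,
    flow: FlowParameters,
    thermo: ThermoSoluteParameters,
    *,
    nx: int = 201,
    ny: int = 201,
):
    """Temperature over one periodic cell for contouring (NaN outside walls).

    Returns (x, y, theta) with theta shaped (ny, nx); periodic in x.
    """
    flow.validate_with(channel)
    x = np.linspace(0.0, 1.0, nx)
    hmax = channel.max_height
    yv = np.linspace(-hmax, hmax, ny)
    X, Y = np.meshgrid(x, yv)
    H = np.asarray(channel.height(X), dtype=float)
    theta = np.full(X.shape, np.nan)
    up = (Y >= 0.0) & (Y <= H)
    lo = (Y < 0.0) & (Y >= -H)
    if np.any(up):
        theta[up] = _theta_zone(Y[up], H[up], flow, thermo, flow.h_pl, wall=H[up])
    if np.any(lo):
        J0, _ = _heat_antiderivatives(Y[lo], H[lo], flow, thermo, 0.0)
        _, J1_at_0 = _heat_antiderivatives(np.zeros_like(H[lo]), H[lo], flow, thermo, 0.0)
        J0_wall, _ = _heat_antiderivatives(-H[lo], H[lo], flow, thermo, 0.0)
        slope = -J1_at_0
        const = 1.0 - J0_wall + slope * H[lo]
        theta[lo] = J0 + slope * Y[lo] + const
    return x, yv, theta


# ---------------------------------------------------------------------------
# Concentration
# ---------------------------------------------------------------------------


def concentration_profile(x, y, channel: WavyChannel, flow: FlowParameters,
                          thermo: ThermoSoluteParameters):
    """Solute concentration phi(y) in the upper yielded zone.

    phi = [ -a2 sinh(r(h - h_pl)) + (a1 + a2) sinh(r(h - y))
            + a2 sinh(r(y - h_pl)) ] / (a1 sinh(r(h - h_pl))),  r = sqrt(a1),

    with phi(h_pl) = 1, phi(h) = 0 and residual phi'' - a1 phi - a2 = 0
    identically.  Requires a1 = k_r*Sc > 0.
    """
    a1, a2 = thermo.alpha1, thermo.alpha2
    if not a1 > 0.0:
        raise ValueError(f"sinh-form concentration requires alpha1 = kr*Sc > 0, got {a1}")
    h = float(channel.height(x))
    y = np.asarray(y, dtype=float)
    if np.any((y < flow.h_pl - 1e-12) | (y > h + 1e-12)):
        raise DomainError("concentration is defined on the upper yielded zone [h_pl, h]")
    r = np.sqrt(a1)
    S = np.sinh(r * (h - flow.h_pl))
    out = (
        -a2 * S + (a1 + a2) * np.sinh(r * (h - y)) + a2 * np.sinh(r * (y - flow.h_pl))
    ) / (a1 * S)
    out = np.asarray(out)
    return out if out.shape else float(out[()])


def concentration_samples(x, channel, flow, thermo, n: int = 201) -> ScalarProfile:
    """Concentration profile on [h_pl, h(x)]; warns if a profile that should
    be monotone (alpha2 >= 0) is not."""
    h = float(channel.height(x))
    y = np.linspace(flow.h_pl, h, n)
    vals = concentration_profile(x, y, channel, flow, thermo)
    if thermo.alpha2 >= 0.0 and np.any(np.diff(vals) > 1e-12):
        logger.warning("concentration profile at x=%g is not monotone decreasing", x)
    return ScalarProfile(x=float(x), y_grid=y, values=vals, kind="concentration")
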