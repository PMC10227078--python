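"""Closed-form electro-hydrodynamic fields.

Lubrication-limit solutions for electroosmotic peristaltic transport of a
Bingham fluid: the Debye-Hueckel electric-double-layer potential, the ionic
number densities, the axial pressure gradient (with its electroosmotic
correction), the axial velocity, the shear stress, and the piecewise stream
function of the wave-frame particle motion.

Zone convention (wave frame, one periodic cell):

* ``SIGMA1`` -- upper yielded zone, ``h_pl <= y <= h(x)``;
* ``SIGMA2`` -- rigid plug, ``0 <= y < h_pl`` (empty when ``h_pl = 0``);
* ``SIGMA3`` -- lower yielded zone, ``-h(x) <= y < 0``, obtained from the
  upper-zone formulas with the plug thickness set to zero (mirror-wall
  construction).

The stream function in each yielded zone, for any Helmholtz-Smoluchowski
velocity ``u_e``, is

    Psi = D_p (h - y)^2 (2h + y - 3 h_pl) / 6 + h - y + q + u_e * A(y)

with ``A`` the electroosmotic quadrature term and ``D_p`` the full pressure
gradient.  This form satisfies Psi(h) = q, Psi(h_pl) = 0 and
dPsi/dy = u - 1 exactly for every ``u_e`` (the zero-plug variant serves the
lower zone).  All evaluators are numpy-vectorized and complex-step safe in
``h``, which the dynamics module exploits to get machine-precision
x-derivatives.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from .channel import WavyChannel

logger = logging.getLogger(__name__)

#: classification band for points sitting numerically on a switching line
BOUNDARY_TOL = 1e-8


class DomainError(ValueError):
    """Evaluation requested outside the zone where a closed form is valid."""


class Region(enum.Enum):
    """Flow zones of the switched system (plus the exterior)."""

    SIGMA1 = "sigma1"
    SIGMA2 = "sigma2"
    SIGMA3 = "sigma3"
    OUTSIDE = "outside"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class FlowParameters:
    """Dimensionless hydrodynamic and electrokinetic parameters.

    Parameters
    ----------
    q
        Wave-frame flow rate through the upper half-channel.
    ue
        Helmholtz-Smoluchowski velocity (electroosmotic slip scale); sign
        selects the direction of the applied axial electric field.
    Dl
        Debye parameter (inverse dimensionless double-layer thickness), > 0.
    h_pl
        Plug (un-yielded core) half-thickness, >= 0.
    """

    q: float
    ue: float = 0.0
    Dl: float = 1.0
    h_pl: float = 0.0

    def __post_init__(self) -> None:
        if not self.Dl > 0.0:
            raise ValueError(f"Debye parameter must be positive, got Dl={self.Dl}")
        if self.h_pl < 0.0:
            raise ValueError(f"plug half-thickness must be >= 0, got h_pl={self.h_pl}")

    def validate_with(self, channel: WavyChannel) -> None:
        """Check the plug surface stays strictly below the wall everywhere."""
        if self.h_pl >= channel.min_height:
            raise ValueError(
                f"plug half-thickness h_pl={self.h_pl} reaches the wall "
                f"(min_x h = {channel.min_height:.6g})"
            )


# ---------------------------------------------------------------------------
# EDL potential and ionic densities
# ---------------------------------------------------------------------------


def edl_potential(y, x, channel: WavyChannel, params: FlowParameters):
    """Linearized (Debye-Hueckel) double-layer potential Theta.

    Theta = cosh(Dl*y)/cosh(Dl*h), the solution of Theta'' = Dl^2 Theta with
    Theta'(0) = 0 and Theta(h) = 1.
    """
    h = channel.height(x)
    y = np.asarray(y, dtype=float)
    if np.any(np.abs(y) > np.asarray(h) + BOUNDARY_TOL):
        raise DomainError("EDL potential requested outside the channel (|y| > h)")
    out = np.cosh(params.Dl * y) / np.cosh(params.Dl * h)
    return out if out.shape else out[()]


def ionic_densities(theta):
    """Boltzmann ionic number densities ``(n_plus, n_minus) = exp(-/+ Theta)``."""
    theta = np.asarray(theta, dtype=float)
    n_plus = np.exp(-theta)
    n_minus = np.exp(theta)
    if theta.shape:
        return n_plus, n_minus
    return n_plus[()], n_minus[()]


# ---------------------------------------------------------------------------
# Pressure gradient, velocity, shear stress  (core h-parameterized kernels)
# ---------------------------------------------------------------------------


def _dp_of_h(h, params: FlowParameters, hpl: float):
    """Full axial pressure gradient D_p as a function of local wall height.

    D_p = dp_c/dx + electroosmotic correction;  dp_c/dx is the Bingham
    Poiseuille gradient -3(q + h - h_pl)/(h - h_pl)^3.  Complex-safe in h.
    """
    q, ue, Dl = params.q, params.ue, params.Dl
    H = h - hpl
    dpc = -3.0 * (q + H) / H**3
    if ue == 0.0:
        return dpc
    Sp = np.sinh(Dl * hpl)
    Ch = np.cosh(Dl * h)
    Sh = np.sinh(Dl * h)
    M = (2.0 - (H * Dl) ** 2) * Sp + 2.0 * Dl * H * Ch - 2.0 * Sh
    return dpc + 1.5 * ue * M / (Dl * Ch * H**3)


def _ddp_dh(h, params: FlowParameters, hpl: float):
    """Analytic d(D_p)/dh (used by the exact stream-function gradient)."""
    q, ue, Dl = params.q, params.ue, params.Dl
    H = h - hpl
    out = -3.0 / H**3 + 9.0 * (q + H) / H**4
    if ue == 0.0:
        return out
    Sp = np.sinh(Dl * hpl)
    Ch = np.cosh(Dl * h)
    Sh = np.sinh(Dl * h)
    M = (2.0 - (H * Dl) ** 2) * Sp + 2.0 * Dl * H * Ch - 2.0 * Sh
    M_h = 2.0 * Dl**2 * H * (Sh - Sp)
    return out + 1.5 * ue * (
        M_h / (Dl * Ch * H**3) - M * Sh / (Ch**2 * H**3) - 3.0 * M / (Dl * Ch * H**4)
    )


def _lambda1(y, h, params: FlowParameters, hpl: float):
    """Electroosmotic part of the axial velocity (and of dPsi/dy)."""
    Dl = params.Dl
    Ch = np.cosh(Dl * h)
    return (Dl * (y - h) * np.sinh(Dl * hpl) + Ch - np.cosh(Dl * y)) / Ch


def _u_of_h(y, h, params: FlowParameters, hpl: float):
    """Lab-frame axial velocity in a yielded zone, as a function of (y, h)."""
    Dp = _dp_of_h(h, params, hpl)
    u = 0.5 * Dp * (y**2 - h**2) - hpl * Dp * (y - h)
    if params.ue != 0.0:
        u = u + params.ue * _lambda1(y, h, params, hpl)
    return u


def _psi_of_h(y, h, params: FlowParameters, hpl: float):
    """Stream function in a yielded zone as a function of (y, h); complex-safe."""
    q, ue, Dl = params.q, params.ue, params.Dl
    Dp = _dp_of_h(h, params, hpl)
    psi = Dp * (h - y) ** 2 * (2.0 * h + y - 3.0 * hpl) / 6.0 + h - y + q
    if ue != 0.0:
        Ch = np.cosh(Dl * h)
        A = (
            0.5 * Dl**2 * (h - y) ** 2 * np.sinh(Dl * hpl)
            - Dl * (h - y) * Ch
            + np.sinh(Dl * h)
            - np.sinh(Dl * y)
        ) / (Dl * Ch)
        psi = psi + ue * A
    return psi


def _dpsi_dh(y, h, params: FlowParameters, hpl: float):
    """Analytic partial dPsi/dh at fixed y (all x-dependence enters through h)."""
    ue, Dl = params.ue, params.Dl
    Dp = _dp_of_h(h, params, hpl)
    Dp_h = _ddp_dh(h, params, hpl)
    B = (h - y) ** 2 * (2.0 * h + y - 3.0 * hpl)
    out = Dp_h * B / 6.0 + Dp * (h - y) * (h - hpl) + 1.0
    if ue != 0.0:
        Sp = np.sinh(Dl * hpl)
        Ch = np.cosh(Dl * h)
        Sh = np.sinh(Dl * h)
        N = 0.5 * Dl**2 * (h - y) ** 2 * Sp - Dl * (h - y) * Ch + Sh - np.sinh(Dl * y)
        A_h = Dl * (h - y) * (Sp - Sh) / Ch - N * Sh / Ch**2
        out = out + ue * A_h
    return out


def _sxy_of_h(y, h, params: FlowParameters, hpl: float):
    """Shear stress s_xy = D_p*y - ue*Dl*sinh(Dl*y)/cosh(Dl*h)."""
    Dp = _dp_of_h(h, params, hpl)
    s = Dp * y
    if params.ue != 0.0:
        s = s - params.ue * params.Dl * np.sinh(params.Dl * y) / np.cosh(params.Dl * h)
    return s


# ---------------------------------------------------------------------------
# Region classification (shared with the dynamics module)
# ---------------------------------------------------------------------------


def classify_region(x, y, channel: WavyChannel, params: FlowParameters) -> Region:
    """Zone of a single point; switching lines follow the half-open convention
    (y = h_pl belongs to SIGMA1, y = 0 to SIGMA2 -- or to SIGMA1 if the plug
    is absent)."""
    h = float(channel.height(x))
    y = float(y)
    if y > h or y < -h:
        return Region.OUTSIDE
    if y >= params.h_pl:
        return Region.SIGMA1
    if y >= 0.0:
        return Region.SIGMA2
    return Region.SIGMA3


def _hpl_eff(region: Region, params: FlowParameters) -> float:
    return params.h_pl if region is Region.SIGMA1 else 0.0


# ---------------------------------------------------------------------------
# Public pointwise evaluators
# ---------------------------------------------------------------------------


def pressure_gradient(x, channel: WavyChannel, params: FlowParameters, *, lower: bool = False):
    """Full axial pressure gradient D_p(x).

    Reduces to the Bingham Poiseuille gradient dp_c/dx when ``ue = 0`` and is
    continuous in ``ue`` (the electroosmotic correction is O(ue) and, for
    thin double layers, O(Dl^2) relative to dp_c/dx as Dl -> 0).  With
    ``lower=True`` the lower-zone variant (plug thickness zero) is returned.
    """
    h = channel.height(x)
    hpl = 0.0 if lower else params.h_pl
    if np.any(np.asarray(h) <= hpl):
        raise DomainError("wall height h <= h_pl: plug fills the channel at this x")
    out = _dp_of_h(np.asarray(h, dtype=float), params, hpl)
    out = np.asarray(out)
    return out if out.shape else out[()]


def axial_velocity(y, x, channel: WavyChannel, params: FlowParameters):
    """Lab-frame axial velocity u(y) at abscissa x.

    Upper yielded zone uses the plug-thickness form; the lower zone uses its
    zero-plug variant; inside the plug the rigid-body speed u(h_pl) is
    returned (velocity is continuous across the yield surface).
    """
    h = float(channel.height(x))
    y = float(y)
    if y > h + BOUNDARY_TOL or y < -h - BOUNDARY_TOL:
        raise DomainError(f"y={y} outside the channel (|y| > h={h})")
    if y >= params.h_pl:
        return float(_u_of_h(y, h, params, params.h_pl))
    if y >= 0.0:
        return float(_u_of_h(params.h_pl, h, params, params.h_pl))
    return float(_u_of_h(y, h, params, 0.0))


def shear_stress(y, x, channel: WavyChannel, params: FlowParameters):
    """Shear stress s_xy(y); s_xy(0) = 0, and s_xy(h_pl) is the yield stress."""
    h = channel.height(x)
    y = np.asarray(y, dtype=float)
    if np.any(np.abs(y) > np.asarray(h) + BOUNDARY_TOL):
        raise DomainError("shear stress requested outside the channel")
    out = np.asarray(_sxy_of_h(y, np.asarray(h, dtype=float), params, params.h_pl))
    return out if out.shape else out[()]


def yield_stress(x, channel: WavyChannel, params: FlowParameters) -> float:
    """Implied yield stress s0 = s_xy(h_pl)."""
    return float(shear_stress(params.h_pl, x, channel, params))


@dataclass(frozen=True)
class PlugState:
    """Wave-frame rigid-plug translational speed at a given abscissa.

    ``c = u(h_pl) - 1``: velocity continuity across the yield surface fixes
    the plug speed to the yielded-zone velocity evaluated at y = h_pl.
    """

    c: float
    x: float

    @classmethod
    def at(cls, x: float, channel: WavyChannel, params: FlowParameters) -> "PlugState":
        c = axial_velocity(params.h_pl, x, channel, params) - 1.0
        # continuity check against the upper-zone closed form
        h = float(channel.height(x))
        u_zone = float(_u_of_h(params.h_pl, h, params, params.h_pl))
        if abs((c + 1.0) - u_zone) > 1e-12 * max(1.0, abs(u_zone)):
            raise AssertionError("plug speed violates velocity continuity")  # pragma: no cover
        return cls(c=float(c), x=float(x))


def stream_function(
    x, y, channel: WavyChannel, params: FlowParameters
) -> tuple[float, Region]:
    """Piecewise stream function Psi with its region tag.

    Per-region constants: Psi(h) = q and Psi(h_pl) = 0 in SIGMA1 for every
    ue; the plug carries the linear form c*y; SIGMA3 reuses the upper-zone
    formula with zero plug thickness (so Psi(-h) = -q when h_pl = 0).  Psi is
    *not* required to be continuous across y = h_pl: streamlines are level
    sets within each zone.
    """
    region = classify_region(x, y, channel, params)
    if region is Region.OUTSIDE:
        raise DomainError(f"point (x={x}, y={y}) lies outside the channel")
    h = float(channel.height(x))
    if region is Region.SIGMA2:
        c = PlugState.at(x, channel, params).c
        return float(c * y), region
    return float(_psi_of_h(float(y), h, params, _hpl_eff(region, params))), region


# ---------------------------------------------------------------------------
# Grid evaluation / export
# ---------------------------------------------------------------------------

_REGION_CODE = {Region.SIGMA1: 1, Region.SIGMA2: 2, Region.SIGMA3: 3, Region.OUTSIDE: 0}


@dataclass(frozen=True)
class FieldGrid:
    """Fields sampled on a rectangular (x, y) grid over one periodic cell.

    Points above the upper wall or below the mirror wall are NaN-masked and
    carry region code 0 (1/2/3 encode the three flow zones).
    """

    x: np.ndarray  # (nx,)
    y: np.ndarray  # (ny,)
    psi: np.ndarray  # (ny, nx)
    u: np.ndarray  # (ny, nx)
    sxy: np.ndarray  # (ny, nx)
    region: np.ndarray  # (ny, nx) int codes

    def to_frame(self):
        import pandas as pd

        X, Y = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {
                "x": X.ravel(),
                "y": Y.ravel(),
                "region": self.region.ravel(),
                "psi": self.psi.ravel(),
                "u": self.u.ravel(),
                "s_xy": self.sxy.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    def contour_png(self, path, *, levels: int = 40) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        ax.contour(self.x, self.y, self.psi, levels=levels, linewidths=0.7)
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        fig.savefig(path, dpi=150)
        plt.close(fig)


def psi_on_grid(x2d: np.ndarray, y2d: np.ndarray, channel: WavyChannel, params: FlowParameters):
    """Vectorized piecewise Psi over coordinate arrays; NaN outside the channel.

    The plug zone (if any) carries NaN as well -- its linear c*y form is not a
    level-set continuation of the yielded-zone stream function.
    """
    h = np.asarray(channel.height(x2d), dtype=float)
    psi = np.full(np.broadcast(x2d, y2d).shape, np.nan)
    up = (y2d >= params.h_pl) & (y2d <= h)
    lo = (y2d < 0.0) & (y2d >= -h)
    if np.any(up):
        psi[up] = _psi_of_h(y2d[up], h[up], params, params.h_pl)
    if np.any(lo):
        psi[lo] = _psi_of_h(y2d[lo], h[lo], params, 0.0)
    return psi


def field_grid(
    channel: WavyChannel,
    params: FlowParameters,
    *,
    nx: int = 201,
    ny: int = 201,
) -> FieldGrid:
    """Sample psi, u and s_xy over one periodic cell."""
    params.validate_with(channel)
    x = np.linspace(0.0, 1.0, nx)
    hmax = channel.max_height
    y = np.linspace(-hmax, hmax, ny)
    X, Y = np.meshgrid(x, y)
    h = np.asarray(channel.height(X), dtype=float)
    psi = psi_on_grid(X, Y, channel, params)
    u = np.full_like(psi, np.nan)
    sxy = np.full_like(psi, np.nan)
    region = np.zeros(psi.shape, dtype=int)

    up = (Y >= params.h_pl) & (Y <= h)
    plug = (Y >= 0.0) & (Y < params.h_pl) & (Y <= h)
    lo = (Y < 0.0) & (Y >= -h)
    region[up], region[plug], region[lo] = 1, 2, 3
    u[up] = _u_of_h(Y[up], h[up], params, params.h_pl)
    u[lo] = _u_of_h(Y[lo], h[lo], params, 0.0)
    if np.any(plug):
        u[plug] = _u_of_h(params.h_pl, h[plug], params, params.h_pl)
        c = u[plug] - 1.0
        psi[plug] = c * Y[plug]
    upper = region > 0
    upper &= Y >= 0.0  # the upper-zone stress formula extends across the plug
    sxy[upper] = _sxy_of_h(Y[upper], h[upper], params, params.h_pl)
    sxy[lo] = _sxy_of_h(Y[lo], h[lo], params, 0.0)
    return FieldGrid(x=x, y=y, psi=psi, u=u, sxy=sxy, region=region)
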