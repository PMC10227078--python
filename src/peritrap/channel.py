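"""Complex wavy channel geometry.

The upper wall of the microchannel, in wavelength-normalized wave-frame
coordinates, is the multi-harmonic profile

    h(x, t) = 1 + sum_{i=1..m} eps_i * sin(2*pi*i*(x - t)),

with the closure constraint ``sum(eps_i) <= 1`` so the channel never pinches
shut.  All downstream analysis works in the wave frame at t = 0, where the
flow is steady and the particle-motion system is autonomous; ``x`` lives on
the periodic cell [0, 1).

Besides the wall height and slope, this module locates the critical
abscissae -- the roots of dh/dx = 0 within one period -- which are exactly
the abscissae where stagnation points of the wave-frame flow can sit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: grid used to verify the channel stays open at construction time
_OPENNESS_GRID = 2048

#: default scan density (points per period) for critical-abscissa bracketing;
#: resolves channels with up to ~50 harmonics
DEFAULT_ROOT_GRID = 10_000

#: two critical abscissae closer than this are considered duplicates
ROOT_DEDUP_TOL = 1e-9


class FlatChannelError(ValueError):
    """All wave amplitudes vanish: dh/dx == 0 identically, every x is critical."""


@dataclass(frozen=True)
class WavyChannel:
    """Multi-harmonic peristaltic wall shape.

    Parameters
    ----------
    amplitudes
        Dimensionless wave amplitudes ``eps_1 .. eps_m`` (wall-height units);
        harmonic ``i`` contributes ``eps_i * sin(2*pi*i*(x - t))``.
    """

    amplitudes: tuple[float, ...]
    harmonic_count: int = field(init=False)

    def __post_init__(self) -> None:
        amps = tuple(float(a) for a in np.atleast_1d(np.asarray(self.amplitudes, dtype=float)))
        if len(amps) < 1:
            raise ValueError("at least one harmonic amplitude is required")
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "harmonic_count", len(amps))
        if sum(amps) > 1.0 + 1e-12:
            raise ValueError(
                f"sum of amplitudes {sum(amps):.6g} exceeds 1; the wall law requires sum(eps_i) <= 1"
            )
        x = np.linspace(0.0, 1.0, _OPENNESS_GRID, endpoint=False)
        hmin = float(np.min(self.height(x)))
        if hmin <= 0.0:
            raise ValueError(f"channel closes: min_x h(x, 0) = {hmin:.6g} <= 0")

    @classmethod
    def from_rule(cls, coefficient: float, count: int) -> "WavyChannel":
        """Amplitude shorthand ``eps_j = coefficient * j`` for ``j = 1..count``."""
        return cls(tuple(coefficient * j for j in range(1, count + 1)))

    # -- wall shape ---------------------------------------------------------

    def height(self, x, t: float = 0.0):
        """Wall height ``h(x, t)``; accepts scalars or arrays (complex-safe)."""
        x = np.asarray(x)
        phase = x - t
        h = 1.0 + sum(
            a * np.sin(2.0 * np.pi * (i + 1) * phase) for i, a in enumerate(self.amplitudes)
        )
        return h if h.shape else h[()]

    def slope(self, x, t: float = 0.0):
        """Wall slope ``dh/dx = sum 2*pi*i*eps_i*cos(2*pi*i*(x - t))``."""
        x = np.asarray(x)
        phase = x - t
        s = sum(
            2.0 * np.pi * (i + 1) * a * np.cos(2.0 * np.pi * (i + 1) * phase)
            for i, a in enumerate(self.amplitudes)
        )
        s = s + np.zeros_like(np.asarray(phase, dtype=float))
        return s if s.shape else s[()]

    def curvature(self, x, t: float = 0.0):
        """Second derivative ``d2h/dx2``."""
        x = np.asarray(x)
        phase = x - t
        c = sum(
            -((2.0 * np.pi * (i + 1)) ** 2) * a * np.sin(2.0 * np.pi * (i + 1) * phase)
            for i, a in enumerate(self.amplitudes)
        )
        c = c + np.zeros_like(np.asarray(phase, dtype=float))
        return c if c.shape else c[()]

    @property
    def max_height(self) -> float:
        x = np.linspace(0.0, 1.0, _OPENNESS_GRID, endpoint=False)
        return float(np.max(self.height(x)))

    @property
    def min_height(self) -> float:
        x = np.linspace(0.0, 1.0, _OPENNESS_GRID, endpoint=False)
        return float(np.min(self.height(x)))

    # -- critical abscissae -------------------------------------------------

    def critical_abscissae(self, t: float = 0.0, grid: int = DEFAULT_ROOT_GRID) -> np.ndarray:
        """All roots of ``dh/dx = 0`` in one period, ascending in [0, 1).

        Roots are bracketed by sign changes of the slope on a ``grid``-point
        scan and polished by Newton iteration on dh/dx; near-duplicates are
        merged at ``ROOT_DEDUP_TOL``.

        Raises
        ------
        FlatChannelError
            if every amplitude is zero (the slope vanishes identically).
        """
        if all(a == 0.0 for a in self.amplitudes):
            raise FlatChannelError("flat channel: dh/dx == 0 for every x")
        xs = np.linspace(0.0, 1.0, grid, endpoint=False)
        s = self.slope(xs, t)
        s_next = np.roll(s, -1)
        roots: list[float] = []
        for i in np.nonzero(np.sign(s) != np.sign(s_next))[0]:
            a = xs[i]
            b = xs[i] + 1.0 / grid
            if s[i] == 0.0:
                x0 = a
            else:
                # bisection-seeded Newton polish
                x0 = a + (b - a) * abs(s[i]) / (abs(s[i]) + abs(s_next[i]))
            for _ in range(60):
                f = self.slope(x0, t)
                fp = self.curvature(x0, t)
                if fp == 0.0:
                    break
                step = f / fp
                x0 -= step
                if abs(step) < 1e-15:
                    break
            x0 %= 1.0
            roots.append(float(x0))
        roots.sort()
        out: list[float] = []
        for r in roots:
            if not out or (r - out[-1] > ROOT_DEDUP_TOL and (out[0] + 1.0) - r > ROOT_DEDUP_TOL):
                out.append(r)
        logger.debug("critical abscissae (m=%d): %s", self.harmonic_count, out)
        return np.asarray(out)


def wall_height(x, t, channel: WavyChannel):
    """Functional alias for :meth:`WavyChannel.height`."""
    return channel.height(x, t)


def wall_slope(x, t, channel: WavyChannel):
    """Functional alias for :meth:`WavyChannel.slope`."""
    return channel.slope(x, t)


def critical_abscissae(channel: WavyChannel, t: float = 0.0, grid: int = DEFAULT_ROOT_GRID):
    """Functional alias for :meth:`WavyChannel.critical_abscissae`."""
    return channel.critical_abscissae(t, grid)


def m2_closed_form_root(eps1: float, eps2: float) -> float:
    """Smallest positive root of ``eps1*cos(2 pi x) + 2*eps2*cos(4 pi x) = 0``.

    Closed form for the two-harmonic wall: with c = cos(2 pi x),
    ``4*eps2*c**2 + eps1*c - 2*eps2 = 0`` gives
    ``c = (-eps1 + sqrt(eps1**2 + 32*eps2**2)) / (8*eps2)``.
    """
    if eps2 == 0.0:
        raise ValueError("closed form requires eps2 != 0")
    c = (-eps1 + np.sqrt(eps1**2 + 32.0 * eps2**2)) / (8.0 * eps2)
    return float(np.arccos(c) / (2.0 * np.pi))
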