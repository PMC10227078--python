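"""Three-zone switched Hamiltonian dynamics of fluid-particle motion.

In the wave frame, particle paths obey  xdot = dPsi/dy,  ydot = -dPsi/dx
inside each yielded zone, while the rigid plug (SIGMA2) is advected
horizontally at the constant plug speed c: the switched system

    zdot = f1(z)   in SIGMA1,
    zdot = (c, 0)  in SIGMA2,
    zdot = f3(z) = f1(z)|_{h_pl=0}  in SIGMA3.

``f1`` is evaluated from exact analytic partial derivatives of the stream
function (all x-dependence enters through the wall height h(x), so
dPsi/dx = dPsi/dh * dh/dx); no finite differencing is involved in the
vector field itself, which keeps the Hamiltonian structure to machine
precision.

Streamline *figures* should be produced from per-zone level sets of Psi
(see :mod:`peritrap.topology`); trajectory integration here exists to verify
the dynamics (conservation of Psi along orbits, closure of center orbits,
mirror symmetry).  A trajectory entering the plug is advected horizontally
and never re-enters a yielded zone, implementing the literal switched
definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .channel import WavyChannel
from .fields import (
    DomainError,
    FlowParameters,
    PlugState,
    Region,
    _dp_of_h,
    _dpsi_dh,
    _lambda1,
    _psi_of_h,
    classify_region,
)

logger = logging.getLogger(__name__)

#: default integrator tolerances (separatrix work needs tight conservation)
RTOL = 1e-9
ATOL = 1e-11
#: orbit closure detection radius
CLOSURE_TOL = 1e-6
#: minimum escape distance before closure detection activates
CLOSURE_ESCAPE = 5e-2
#: vector-field norm below which integration is declared stalled
STALL_NORM = 1e-10


@dataclass(frozen=True)
class PhasePoint:
    """A point of the periodic phase cylinder with its zone label."""

    x: float
    y: float
    region: Region

    @classmethod
    def at(cls, x: float, y: float, channel: WavyChannel, params: FlowParameters):
        return cls(float(x), float(y), classify_region(x, y, channel, params))


def region_of(x, y, channel: WavyChannel, params: FlowParameters) -> Region:
    """Zone classification; y = h_pl belongs to SIGMA1 and y = 0 to SIGMA2
    (to SIGMA1 when the plug is absent)."""
    return classify_region(x, y, channel, params)


# ---------------------------------------------------------------------------
# Vector field
# ---------------------------------------------------------------------------


def zone_vector_field(x, y, channel: WavyChannel, params: FlowParameters, hpl: float):
    """Vectorized yielded-zone field (f1 for hpl = h_pl, f3 for hpl = 0).

    xdot = dPsi/dy = -(1/2) D_p (h - y)(h - 2 h_pl + y) - 1 + ue * Lambda1
    ydot = -dPsi/dx = -(dPsi/dh) * dh/dx          (exact analytic partials)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    h = np.asarray(channel.height(x), dtype=float)
    hx = np.asarray(channel.slope(x), dtype=float)
    Dp = _dp_of_h(h, params, hpl)
    xdot = -0.5 * Dp * (h - y) * (h - 2.0 * hpl + y) - 1.0
    if params.ue != 0.0:
        xdot = xdot + params.ue * _lambda1(y, h, params, hpl)
    ydot = -hx * _dpsi_dh(y, h, params, hpl)
    return xdot, ydot


def vector_field(point: PhasePoint, channel: WavyChannel, params: FlowParameters):
    """Switched vector field at a phase point.

    Raises :class:`~peritrap.fields.DomainError` outside the channel.
    """
    if point.region is Region.OUTSIDE:
        raise DomainError(f"({point.x}, {point.y}) lies outside the channel")
    if point.region is Region.SIGMA2:
        return PlugState.at(point.x, channel, params).c, 0.0
    hpl = params.h_pl if point.region is Region.SIGMA1 else 0.0
    xd, yd = zone_vector_field(point.x, point.y, channel, params, hpl)
    return float(xd), float(yd)


# ---------------------------------------------------------------------------
# Orbits
# ---------------------------------------------------------------------------


@dataclass
class Orbit:
    """Polyline trajectory with per-segment zone labels and Psi levels.

    ``status`` is one of ``closed``, ``wall``, ``plug_entry``, ``budget``,
    ``stalled``.
    """

    points: np.ndarray  # (n, 2)
    segments: list[tuple[slice, Region, float]] = field(default_factory=list)
    status: str = "budget"

    @property
    def arc_length(self) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def to_frame(self):
        import pandas as pd

        region = np.empty(len(self.points), dtype=object)
        for sl, reg, _lvl in self.segments:
            region[sl] = reg.value
        return pd.DataFrame(
            {"x": self.points[:, 0], "y": self.points[:, 1], "region": region}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


class StalledOrbitError(RuntimeError):
    """Step-size collapse near a degenerate point; carries the last state."""

    def __init__(self, state):
        super().__init__(f"orbit stalled at {state}")
        self.state = state


def _cyl_dist(p, seed):
    """Distance on the periodic cylinder (x identified mod 1)."""
    dx = (p[0] - seed[0] + 0.5) % 1.0 - 0.5
    return float(np.hypot(dx, p[1] - seed[1]))


def integrate_streamline(
    seed: PhasePoint,
    channel: WavyChannel,
    params: FlowParameters,
    *,
    arc_budget: float = 10.0,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Orbit:
    """Integrate the switched system from a seed, parametrized by arc length.

    Terminates at wall contact, on entry into the plug zone (after appending
    the horizontal plug segment), on closure (return to within
    ``CLOSURE_TOL`` of the seed after escaping it), or when the arc budget is
    spent.  Raises :class:`StalledOrbitError` on step-size collapse near a
    degenerate point.
    """
    region = seed.region
    if region is Region.OUTSIDE:
        raise DomainError("seed lies outside the channel")

    if region is Region.SIGMA2:
        c = PlugState.at(seed.x, channel, params).c
        xs = seed.x + np.sign(c or 1.0) * np.linspace(0.0, arc_budget, 64)
        pts = np.column_stack([xs, np.full_like(xs, seed.y)])
        psi = float(c * seed.y)
        return Orbit(points=pts, segments=[(slice(0, len(pts)), region, psi)], status="budget")

    pts_all: list[np.ndarray] = []
    segments: list[tuple[slice, Region, float]] = []
    status = "budget"
    z = np.array([seed.x, seed.y], dtype=float)
    seed_xy = z.copy()
    spent = 0.0
    escaped = False

    while spent < arc_budget:
        hpl = params.h_pl if region is Region.SIGMA1 else 0.0

        def rhs(_s, zz):
            xd, yd = zone_vector_field(zz[0], zz[1], channel, params, hpl)
            n = np.hypot(xd, yd)
            if n < STALL_NORM:
                return np.zeros(2)
            return np.array([xd, yd]) / n

        def ev_upper(_s, zz):
            return float(channel.height(zz[0])) - zz[1]

        def ev_lower(_s, zz):
            return zz[1] + float(channel.height(zz[0]))

        def ev_plug_top(_s, zz):
            return zz[1] - params.h_pl

        def ev_axis(_s, zz):
            return zz[1]

        def ev_stall(_s, zz):
            xd, yd = zone_vector_field(zz[0], zz[1], channel, params, hpl)
            return float(np.hypot(xd, yd)) - STALL_NORM

        for ev in (ev_upper, ev_lower, ev_plug_top, ev_axis, ev_stall):
            ev.terminal = True  # type: ignore[attr-defined]
        events = [ev_upper, ev_lower, ev_stall]
        if params.h_pl > 0.0:
            events.append(ev_plug_top if region is Region.SIGMA1 else ev_axis)
        elif region is Region.SIGMA1:
            pass  # h_pl = 0: zones meet at y = 0, field is continuous there
        chunk = min(arc_budget - spent, 2.0)
        sol = solve_ivp(
            rhs, (0.0, chunk), z, rtol=rtol, atol=atol, dense_output=True,
            events=events, max_step=0.05,
        )
        s_grid = np.linspace(0.0, sol.t[-1], max(8, int(sol.t[-1] / 2e-3)))
        chunk_pts = sol.sol(s_grid).T

        # closure detection against the seed (periodic in x)
        d = np.array([_cyl_dist(p, seed_xy) for p in chunk_pts])
        if not escaped and np.any(d > CLOSURE_ESCAPE):
            escaped = True
        close_idx = None
        if escaped:
            cand = np.nonzero(d < 10 * CLOSURE_TOL)[0]
            if cand.size:
                # refine the closest approach on the dense output
                from scipy.optimize import minimize_scalar

                i = cand[np.argmin(d[cand])]
                lo = s_grid[max(i - 1, 0)]
                hi = s_grid[min(i + 1, len(s_grid) - 1)]
                res = minimize_scalar(
                    lambda s: _cyl_dist(sol.sol(s), seed_xy), bounds=(lo, hi),
                    method="bounded", options={"xatol": 1e-12},
                )
                if res.fun < CLOSURE_TOL:
                    close_idx = i
                    chunk_pts = np.vstack([chunk_pts[: i + 1], sol.sol(res.x)])

        start = sum(len(p) for p in pts_all)
        pts_all.append(chunk_pts)
        psi_level = float(_psi_of_h(seed_xy[1], channel.height(seed_xy[0]), params, hpl)) \
            if region is not Region.SIGMA2 else 0.0
        segments.append((slice(start, start + len(chunk_pts)), region, psi_level))
        d_arc = np.diff(chunk_pts, axis=0)
        spent += float(np.sum(np.hypot(d_arc[:, 0], d_arc[:, 1])))
        z = chunk_pts[-1].copy()

        if close_idx is not None:
            status = "closed"
            break
        if sol.status == 1:  # a terminal event fired
            fired = [k for k, te in enumerate(sol.t_events) if len(te)]
            which = events[fired[0]]
            if which in (ev_upper, ev_lower):
                status = "wall"
                break
            if which is ev_stall:
                raise StalledOrbitError(tuple(z))
            # plug entry (from SIGMA1 at y=h_pl going down, or SIGMA3 at y=0 going up)
            c = PlugState.at(z[0], channel, params).c
            rem = arc_budget - spent
            xs = z[0] + np.sign(c or 1.0) * np.linspace(0.0, rem, 32)
            tail = np.column_stack([xs, np.full_like(xs, z[1])])
            start = sum(len(p) for p in pts_all)
            pts_all.append(tail)
            segments.append((slice(start, start + len(tail)), Region.SIGMA2, float(c * z[1])))
            status = "plug_entry"
            break
        if sol.status == 0 and spent >= arc_budget - 1e-12:
            status = "budget"
            break
        # h_pl = 0 crossing of y=0 is seamless; just reclassify and continue
        region = classify_region(z[0] % 1.0, z[1], channel, params)
        if region is Region.OUTSIDE:
            status = "wall"
            break

    points = np.vstack(pts_all) if pts_all else np.array([[seed.x, seed.y]])
    return Orbit(points=points, segments=segments, status=status)


def psi_drift(orbit: Orbit, channel: WavyChannel, params: FlowParameters) -> float:
    """Max |Psi - Psi(segment start)| over the orbit's yielded-zone segments."""
    worst = 0.0
    for sl, reg, _lvl in orbit.segments:
        if reg is Region.SIGMA2:
            continue
        hpl = params.h_pl if reg is Region.SIGMA1 else 0.0
        p = orbit.points[sl]
        if len(p) == 0:
            continue
        vals = _psi_of_h(p[:, 1], np.asarray(channel.height(p[:, 0]), dtype=float), params, hpl)
        worst = max(worst, float(np.max(np.abs(vals - vals[0]))))
    return worst
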