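"""Stagnation points: analytic formulas, batched Newton search, and sweeps.

Stagnation (equilibrium) points of the wave-frame particle motion satisfy
f_i(x, y) = 0 for the yielded-zone fields.  Because the transverse velocity
is proportional to the wall slope, equilibria sit on the critical abscissae
xbar where dh/dx = 0; in the purely peristaltic case (u_e = 0) the
transverse positions are closed-form:

    ybar = h_pl +/- (H/sqrt(3)) * sqrt((3q + H)/(q + H)),  H = h(xbar) - h_pl

for the upper zone, and the same with h_pl = 0 for the lower zone.  The
general (electroosmotic) case is handled by a damped Newton iteration run in
parallel from a deterministic seed lattice over the sector decomposition of
each zone's extended rectangle.

Every root is classified twice: by *admissibility* (does the root of f_i lie
inside Sigma_i? Exactly on a switching line?) and by *linear type* via the
Jacobian of the Hamiltonian linearization (trace J = 0; saddle iff
det J < 0, center iff det J > 0, degenerate at zero).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .channel import WavyChannel
from .fields import FlowParameters, Region, _psi_of_h
from .dynamics import zone_vector_field

logger = logging.getLogger(__name__)

#: |det J| below this is degenerate
DET_TOL = 1e-9
#: switching-line band for admissibility classification
BOUNDARY_BAND = 1e-8
#: residual norm required of a converged root
ROOT_RESIDUAL = 1e-11
#: two roots closer than this are duplicates
DEDUP_TOL = 1e-6
#: central-difference step for the Jacobian
JAC_STEP = 1e-6

ADMISSIBLE = "admissible"
VIRTUAL = "virtual"
BOUNDARY = "boundary"

SADDLE = "saddle"
CENTER = "center"
DEGENERATE = "degenerate"


class SingularFlowRateError(ValueError):
    """q + H = 0 at a critical abscissa: the closed-form position blows up."""


@dataclass(frozen=True)
class Equilibrium:
    """A classified stagnation point."""

    x: float
    y: float
    region_claimed: Region  # zone whose vector field vanishes here
    admissibility: str
    linear_type: str
    detJ: float
    trace: float = 0.0

    @property
    def is_saddle(self) -> bool:
        return self.linear_type == SADDLE

    @property
    def is_center(self) -> bool:
        return self.linear_type == CENTER

    def psi_level(self, channel: WavyChannel, params: FlowParameters) -> float:
        hpl = params.h_pl if self.region_claimed is Region.SIGMA1 else 0.0
        return float(_psi_of_h(self.y, float(channel.height(self.x)), params, hpl))

    def as_dict(self) -> dict:
        return {
            "x": self.x,
            "y": self.y,
            "region_claimed": self.region_claimed.value,
            "admissibility": self.admissibility,
            "linear_type": self.linear_type,
            "detJ": self.detJ,
        }


def _hpl_of(region: Region, params: FlowParameters) -> float:
    return params.h_pl if region is Region.SIGMA1 else 0.0


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_admissibility(
    x: float, y: float, region_claimed: Region, channel: WavyChannel, params: FlowParameters
) -> str:
    """Definition-style classification of a converged root of f1 or f3.

    boundary: the root sits on its zone's switching line (y = h_pl for f1
    roots, y = 0 for f3 roots) within ``BOUNDARY_BAND``; admissible: it lies
    inside its zone; virtual: anywhere else.
    """
    h = float(channel.height(x))
    if region_claimed is Region.SIGMA1:
        if abs(y - params.h_pl) < BOUNDARY_BAND:
            return BOUNDARY
        return ADMISSIBLE if params.h_pl <= y <= h else VIRTUAL
    if abs(y) < BOUNDARY_BAND:
        return BOUNDARY
    return ADMISSIBLE if -h <= y < 0.0 else VIRTUAL


def linearize(
    x: float, y: float, region_claimed: Region, channel: WavyChannel, params: FlowParameters
) -> tuple[np.ndarray, str]:
    """Jacobian (central differences of the zone field, step 1e-6) and type.

    The Hamiltonian structure J = [[Psi_xy, Psi_yy], [-Psi_xx, -Psi_xy]] is
    imposed exactly: J = [[a, b], [c, -a]] with a = dfx/dx, b = dfx/dy,
    c = dfy/dx, so trace J = 0 by construction and det J = -a^2 - b*c.
    """
    hpl = _hpl_of(region_claimed, params)
    d = JAC_STEP

    def f(xx, yy):
        xd, yd = zone_vector_field(xx, yy, channel, params, hpl)
        return float(xd), float(yd)

    fxp, fyp = f(x + d, y)
    fxm, fym = f(x - d, y)
    fxp_y, _ = f(x, y + d)
    fxm_y, _ = f(x, y - d)
    a = (fxp - fxm) / (2 * d)
    c = (fyp - fym) / (2 * d)
    b = (fxp_y - fxm_y) / (2 * d)
    J = np.array([[a, b], [c, -a]])
    det = float(-a * a - b * c)
    if det < -DET_TOL:
        kind = SADDLE
    elif det > DET_TOL:
        kind = CENTER
    else:
        kind = DEGENERATE
    return J, kind


def _make_equilibrium(
    x: float, y: float, region_claimed: Region, channel: WavyChannel, params: FlowParameters
) -> Equilibrium:
    J, kind = linearize(x, y, region_claimed, channel, params)
    return Equilibrium(
        x=float(x % 1.0),
        y=float(y),
        region_claimed=region_claimed,
        admissibility=classify_admissibility(x % 1.0, y, region_claimed, channel, params),
        linear_type=kind,
        detJ=float(np.linalg.det(J)),
        trace=float(np.trace(J)),
    )


# ---------------------------------------------------------------------------
# Analytic equilibria (u_e = 0)
# ---------------------------------------------------------------------------


def analytic_equilibria(
    channel: WavyChannel, params: FlowParameters
) -> list[Equilibrium]:
    """Closed-form stagnation points for the purely peristaltic flow (u_e = 0).

    For each critical abscissa and each zone: real transverse roots where the
    radicand (3q + H)/(q + H) is non-negative; a vanishing radicand gives a
    single boundary point on the switching line.  Abscissae with q + H = 0
    are logged and skipped (singular flow-rate configuration).
    """
    if params.ue != 0.0:
        raise ValueError("analytic equilibria are derived for ue = 0")
    out: list[Equilibrium] = []
    for xbar in channel.critical_abscissae():
        hbar = float(channel.height(xbar))
        for region in (Region.SIGMA1, Region.SIGMA3):
            hpl = _hpl_of(region, params)
            H = hbar - hpl
            if abs(params.q + H) < 1e-14:
                logger.warning(
                    "singular flow rate at xbar=%.6f (%s): q + H = 0", xbar, region.value
                )
                continue
            radicand = (3.0 * params.q + H) / (params.q + H)
            if radicand < -1e-12:
                continue
            # vanishing radicand: the pair collapses onto the switching line
            offsets = [0.0] if radicand < 1e-12 else [1.0, -1.0]
            radicand = max(radicand, 0.0)
            for sgn in offsets:
                ybar = hpl + sgn * (H / np.sqrt(3.0)) * np.sqrt(radicand)
                if region is Region.SIGMA3:
                    ybar = sgn * (hbar / np.sqrt(3.0)) * np.sqrt(radicand)
                out.append(_make_equilibrium(xbar, ybar, region, channel, params))
    return out


# ---------------------------------------------------------------------------
# Numeric equilibria (batched damped Newton)
# ---------------------------------------------------------------------------


def _newton_batch(
    x0: np.ndarray,
    y0: np.ndarray,
    channel: WavyChannel,
    params: FlowParameters,
    hpl: float,
    *,
    itmax: int = 80,
    step_cap: float = 0.2,
    fd: float = 1e-7,
):
    """Damped Newton iteration on the zone field, vectorized over all seeds."""
    x = x0.astype(float).copy()
    y = y0.astype(float).copy()

    def F(xx, yy):
        return zone_vector_field(xx, yy, channel, params, hpl)

    for _ in range(itmax):
        fx, fy = F(x, y)
        res = np.hypot(fx, fy)
        active = res > ROOT_RESIDUAL / 10
        if not np.any(active):
            break
        fxp, fyp = F(x + fd, y)
        fxm, fym = F(x - fd, y)
        a = (fxp - fxm) / (2 * fd)
        c = (fyp - fym) / (2 * fd)
        fxp2, fyp2 = F(x, y + fd)
        fxm2, fym2 = F(x, y - fd)
        b = (fxp2 - fxm2) / (2 * fd)
        dcoef = (fyp2 - fym2) / (2 * fd)
        det = a * dcoef - b * c
        ok = np.abs(det) > 1e-14
        dx = np.where(ok, (dcoef * fx - b * fy) / np.where(ok, det, 1.0), 0.0)
        dy = np.where(ok, (-c * fx + a * fy) / np.where(ok, det, 1.0), 0.0)
        # damping: cap the step norm (singular-Jacobian seeds take no step)
        n = np.hypot(dx, dy)
        scale = np.where(n > step_cap, step_cap / np.where(n > 0, n, 1.0), 1.0)
        x = np.where(active, x - dx * scale, x)
        y = np.where(active, y - dy * scale, y)
    fx, fy = F(x, y)
    res = np.hypot(fx, fy)
    return x, y, res


def _switching_line_roots(
    channel: WavyChannel, params: FlowParameters, region: Region, n: int = 4001
) -> list[float]:
    """Abscissae of equilibria on the zone's switching line.

    Each zone's switching line (y = h_pl for the upper field, y = 0 for the
    lower one) is invariant: the stream function vanishes identically along
    it, so the transverse velocity is zero there and equilibria sit exactly
    where the horizontal velocity c(x) crosses zero.  Those points are always
    saddles (the Jacobian is triangular with eigenvalues +/- c'(x)) and they
    all share the stream-function level 0, which makes them the endpoints of
    heteroclinic connections.  A 2-D seed lattice can step over them, so they
    are located by a dedicated 1-D sign-change scan plus bisection.
    """
    from scipy.optimize import brentq

    hpl = _hpl_of(region, params)
    yline = params.h_pl if region is Region.SIGMA1 else 0.0
    xs = np.linspace(0.0, 1.0, n)
    fx, _ = zone_vector_field(xs, np.full_like(xs, yline), channel, params, hpl)

    def cx(x):
        gx, _ = zone_vector_field(np.array([x]), np.array([yline]), channel, params, hpl)
        return float(gx[0])

    roots: list[float] = []
    for i in range(n - 1):
        if fx[i] == 0.0:
            roots.append(float(xs[i]))
        elif fx[i] * fx[i + 1] < 0.0:
            roots.append(float(brentq(cx, xs[i], xs[i + 1], xtol=1e-14)))
    return roots


def numeric_equilibria(
    channel: WavyChannel,
    params: FlowParameters,
    *,
    x_bounds: tuple[float, float] = (0.0, 1.0),
    nx: int = 200,
    ny: int = 100,
) -> list[Equilibrium]:
    """All stagnation points of f1 and f3, found by lattice-seeded Newton.

    Seeds form an ``nx x ny`` lattice per zone over the sector decomposition
    Pi = Pi1 (upper-zone rectangle) union Pi2 (lower-zone rectangle);
    converged roots (residual < 1e-11) are deduplicated at 1e-6 and
    classified.  Equilibria on the switching lines (boundary saddles) are
    located by a dedicated 1-D scan of each line.  A flat channel supports
    no isolated equilibria (the transverse velocity vanishes identically)
    and returns an empty list.
    """
    if all(a == 0.0 for a in channel.amplitudes):
        logger.warning("flat channel: degenerate line of zeros; no isolated equilibria")
        return []
    ymax = channel.max_height
    a, b = x_bounds
    xs = np.linspace(a, b, nx, endpoint=False)
    out: list[Equilibrium] = []
    for region in (Region.SIGMA1, Region.SIGMA3):
        hpl = _hpl_of(region, params)
        # seed each zone field over the full extended rectangle: virtual
        # roots (including mirrored ones on the far side of the channel)
        # are part of the classification and must be found too
        ys = np.linspace(-ymax + 1e-3, ymax - 1e-3, ny)
        X, Y = np.meshgrid(xs, ys)
        rx, ry, res = _newton_batch(X.ravel(), Y.ravel(), channel, params, hpl)
        good = (res < ROOT_RESIDUAL) & (np.abs(ry) < 2.0 * ymax) & np.isfinite(rx)
        n_fail = int(np.sum(~good))
        if n_fail:
            logger.debug("%s: %d of %d seeds did not converge", region.value, n_fail, rx.size)
        rx, ry = rx[good] % 1.0, ry[good]
        # equilibria on the zone's switching line (always saddles, level 0)
        yline = params.h_pl if region is Region.SIGMA1 else 0.0
        line_roots = _switching_line_roots(channel, params, region)
        rx = np.concatenate([rx, np.asarray(line_roots)])
        ry = np.concatenate([ry, np.full(len(line_roots), yline)])
        # deduplicate on the periodic cylinder (line roots take precedence:
        # a lattice root that converged next to the line is the same point)
        order = np.concatenate(
            [np.arange(len(rx) - len(line_roots), len(rx)),
             np.lexsort((ry[: len(rx) - len(line_roots)],
                         rx[: len(rx) - len(line_roots)]))]
        )
        kept: list[tuple[float, float]] = []
        for i in order:
            if not any(
                min(abs(rx[i] - kx), 1.0 - abs(rx[i] - kx)) < DEDUP_TOL
                and abs(ry[i] - ky) < DEDUP_TOL
                for kx, ky in kept
            ):
                kept.append((float(rx[i]), float(ry[i])))
        for kx, ky in kept:
            out.append(_make_equilibrium(kx, ky, region, channel, params))
    out.sort(key=lambda e: (e.region_claimed.value, e.x, e.y))
    return out


def equilibria_to_frame(eqs: Sequence[Equilibrium]):
    import pandas as pd

    return pd.DataFrame([e.as_dict() for e in eqs])


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------


@dataclass
class BranchEvent:
    kind: str  # "appear" | "vanish" | "admissibility_change" | "boundary"
    parameter: str
    between: tuple[float, float]
    detail: str


@dataclass
class Branch:
    """Equilibrium sets along a swept parameter, with transition events."""

    parameter: str
    values: list[float]
    equilibria: list[list[Equilibrium]]
    events: list[BranchEvent]

    def admissible_counts(self, linear_type: str | None = None, region: Region | None = None):
        counts = []
        for eqs in self.equilibria:
            n = 0
            for e in eqs:
                if e.admissibility != ADMISSIBLE:
                    continue
                if linear_type and e.linear_type != linear_type:
                    continue
                if region and e.region_claimed is not region:
                    continue
                n += 1
            counts.append(n)
        return counts

    def to_json(self, path) -> None:
        payload = {
            "parameter": self.parameter,
            "values": self.values,
            "equilibria": [[e.as_dict() for e in eqs] for eqs in self.equilibria],
            "events": [
                {"kind": ev.kind, "parameter": ev.parameter,
                 "between": list(ev.between), "detail": ev.detail}
                for ev in self.events
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _match(prev: list[Equilibrium], curr: list[Equilibrium]):
    """Nearest-neighbor continuation between two equilibrium sets.

    The matching radius is half the smallest inter-root distance of the
    denser set (falling back to 0.2 for singletons).
    """

    def dist(e1, e2):
        dx = min(abs(e1.x - e2.x), 1.0 - abs(e1.x - e2.x))
        return np.hypot(dx, e1.y - e2.y)

    pool = prev if len(prev) >= len(curr) else curr
    radius = 0.2
    if len(pool) >= 2:
        dmin = min(dist(a, b) for i, a in enumerate(pool) for b in pool[i + 1:])
        radius = max(dmin / 2.0, 1e-6)
    pairs = []
    used = set()
    for i, e in enumerate(prev):
        best, bestd = None, radius
        for j, f in enumerate(curr):
            if j in used or f.region_claimed is not e.region_claimed:
                continue
            d = dist(e, f)
            if d < bestd:
                best, bestd = j, d
        if best is not None:
            used.add(best)
            pairs.append((i, best))
    unmatched_prev = [i for i in range(len(prev)) if i not in {p for p, _ in pairs}]
    unmatched_curr = [j for j in range(len(curr)) if j not in used]
    return pairs, unmatched_prev, unmatched_curr


def sweep(
    channel: WavyChannel,
    params: FlowParameters,
    parameter: str,
    values: Sequence[float],
    *,
    nx: int = 200,
    ny: int = 100,
    refine_depth: int = 2,
) -> Branch:
    """Track equilibria along a monotone parameter sequence.

    Events (appearance, vanishing, admissibility change, boundary collision)
    are localized between adjacent values by bisection up to ``refine_depth``
    halvings when the equilibrium count changes.
    """
    vals = [float(v) for v in values]
    if len(vals) >= 2:
        d = np.diff(vals)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("sweep values must be monotone")

    def solve(v):
        return numeric_equilibria(
            channel, replace(params, **{parameter: v}), nx=nx, ny=ny
        )

    sets = [solve(v) for v in vals]
    events: list[BranchEvent] = []
    for k in range(len(vals) - 1):
        prev, curr = sets[k], sets[k + 1]
        pairs, gone, born = _match(prev, curr)
        lo, hi = vals[k], vals[k + 1]
        if (gone or born) and refine_depth > 0:
            a, b = lo, hi
            na, _nb = len(prev), len(curr)
            for _ in range(refine_depth):
                mid = 0.5 * (a + b)
                nm = len(solve(mid))
                if nm == na:
                    a = mid
                else:
                    b = mid
            lo_ev, hi_ev = a, b
        else:
            lo_ev, hi_ev = lo, hi
        for i in gone:
            events.append(BranchEvent("vanish", parameter, (lo_ev, hi_ev),
                                      f"{prev[i].region_claimed.value} root near "
                                      f"({prev[i].x:.4f}, {prev[i].y:.4f})"))
        for j in born:
            events.append(BranchEvent("appear", parameter, (lo_ev, hi_ev),
                                      f"{curr[j].region_claimed.value} root near "
                                      f"({curr[j].x:.4f}, {curr[j].y:.4f})"))
        for i, j in pairs:
            if prev[i].admissibility != curr[j].admissibility:
                kind = "boundary" if BOUNDARY in (prev[i].admissibility,
                                                  curr[j].admissibility) else \
                    "admissibility_change"
                events.append(BranchEvent(kind, parameter, (lo, hi),
                                          f"{prev[i].admissibility} -> {curr[j].admissibility} "
                                          f"near ({curr[j].x:.4f}, {curr[j].y:.4f})"))
    return Branch(parameter=parameter, values=vals, equilibria=sets, events=events)
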