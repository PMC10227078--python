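"""Global streamline topology: heteroclinic connections, trapping zones, boluses.

In each yielded zone the particle motion is Hamiltonian with the stream
function Psi as invariant, so a separatrix joining two saddle stagnation
points lies exactly on a shared Psi level.  The level structure is special:

* Each zone's switching line (y = h_pl for the upper zone, y = 0 for the
  lower zone) is invariant with Psi identically 0 along it.  Equilibria on
  the line -- the boundary saddles, where the plug speed crosses zero -- all
  share the exact level 0, and the level-0 contour arcs that leave them into
  the zone are the heteroclinic connections that bound trapping zones.
* Interior admissible saddles carry generically pairwise-distinct levels
  (each level depends on the local wall height), so they bound individual
  boluses rather than joining one another.

Connections are therefore detected by shared-level contour connectivity: for
every non-virtual saddle pair whose levels agree within ``level_tol``,
extract the Psi = level contour of each zone over two channel periods (so
that connections to periodic saddle images are seen), polish the polylines
onto the exact level set by gradient projection, and accept the pair when a
component passes within ``delta`` of both saddles.  At zero plug thickness
the two zones share their boundary saddles, and a pair joined by components
from both zones forms a cross-region connection; a finite plug separates the
switching lines and severs it.  The invariant line itself (a trivial union
of connecting orbits) is excluded by starting the contour grid a small
offset above the line.

The closed regions bounded by connection components are the trapping zones
("the flow is completely trapped between the connection orbits"): two
components joining the same pair chain into a lens, a single arc closes
through the interface chord between its endpoints, and a zone must enclose
at least one admissible center (the recirculating boluses it transports).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .channel import WavyChannel
from .dynamics import zone_vector_field
from .equilibria import ADMISSIBLE, BOUNDARY, CENTER, SADDLE, Equilibrium
from .fields import FlowParameters, Region, _psi_of_h

logger = logging.getLogger(__name__)

#: two saddles "share" a level when their Psi values agree within this
LEVEL_TOL = 1e-6
#: a contour component must pass within this distance of both saddles
SADDLE_DELTA = 1e-3
#: default contour grid, per region per periodic cell
CONTOUR_NX = 800
CONTOUR_NY = 400
#: number of periods contoured (to catch connections to periodic images)
SPAN_PERIODS = 2
#: contour grids start this far above the switching line: the line itself is
#: a trivial invariant orbit at level 0, and contouring a row where Psi ~ 0
#: identically is numerically meaningless.  Connection arcs leave boundary
#: saddles transversally, so truncation moves their endpoints O(EDGE_OFFSET)
#: -- well inside SADDLE_DELTA.
EDGE_OFFSET = 1e-4


@dataclass(frozen=True)
class HeteroclinicConnection:
    """Saddle-to-saddle separatrix on a shared stream-function level."""

    saddle_a: Equilibrium
    saddle_b: Equilibrium
    shift: int  # periods separating the two saddle images along x
    level: float
    span: str  # "within-sigma1" | "within-sigma3" | "cross-region"
    extent: float  # Euclidean distance between the two saddle images
    components: tuple = field(default_factory=tuple, compare=False, repr=False)

    def as_dict(self) -> dict:
        return {
            "saddle_a": self.saddle_a.as_dict(),
            "saddle_b": self.saddle_b.as_dict(),
            "shift": self.shift,
            "level": self.level,
            "span": self.span,
            "extent": self.extent,
            "n_components": len(self.components),
        }


@dataclass(frozen=True)
class TrappingZone:
    """Closed region bounded by connection contour(s) on the periodic cell."""

    connection: HeteroclinicConnection
    polygon: np.ndarray  # (n, 2) boundary in the covering space
    enclosed_centers: tuple  # Equilibria
    area: float
    closed_over_period: bool = False

    @property
    def extent(self) -> float:
        return self.connection.extent

    def as_dict(self) -> dict:
        return {
            "level": self.connection.level,
            "span": self.connection.span,
            "extent": self.extent,
            "area": self.area,
            "closed_over_period": self.closed_over_period,
            "enclosed_centers": [c.as_dict() for c in self.enclosed_centers],
        }


# ---------------------------------------------------------------------------
# Level-set machinery
# ---------------------------------------------------------------------------


def _zone_grid(channel, params, region: Region, nx: int, ny: int):
    """(X, Y, Psi, hpl) over SPAN_PERIODS periods for one zone (NaN outside).

    The transverse range starts EDGE_OFFSET inside the zone so the invariant
    switching line is excluded from every contour.
    """
    ymax = channel.max_height
    x = np.linspace(0.0, float(SPAN_PERIODS), SPAN_PERIODS * nx)
    if region is Region.SIGMA1:
        y = np.linspace(params.h_pl + EDGE_OFFSET, ymax, ny)
        hpl = params.h_pl
    else:
        y = np.linspace(-ymax, -EDGE_OFFSET, ny)
        hpl = 0.0
    X, Y = np.meshgrid(x, y)
    H = np.asarray(channel.height(X), dtype=float)
    psi = np.full(X.shape, np.nan)
    inside = (Y <= H) & (Y >= -H)
    psi[inside] = _psi_of_h(Y[inside], H[inside], params, hpl)
    return X, Y, psi, hpl


def _contour_components(X, Y, psi, level):
    """Polyline components of the psi = level contour (masked NaN regions)."""
    import contourpy

    gen = contourpy.contour_generator(
        X, Y, np.ma.masked_invalid(psi), line_type=contourpy.LineType.SeparateCode
    )
    lines, _codes = gen.lines(level)
    return [np.asarray(seg) for seg in lines if len(seg) >= 2]


def _project_to_level(poly, level, channel, params, hpl, iters: int = 4, cap: float = 0.02):
    """Newton-project polyline vertices onto the exact Psi = level set.

    Moves each vertex along grad(Psi); steps are capped so near-saddle points
    (where the gradient degenerates) stay put rather than overshoot.
    """
    p = poly.copy()
    for _ in range(iters):
        xd, yd = zone_vector_field(p[:, 0], p[:, 1], channel, params, hpl)
        gx, gy = -np.asarray(yd), np.asarray(xd)  # grad Psi = (-ydot, xdot)
        g2 = gx * gx + gy * gy
        h = np.asarray(channel.height(p[:, 0]), dtype=float)
        val = _psi_of_h(p[:, 1], h, params, hpl) - level
        ok = g2 > 1e-24
        step = np.where(ok, val / np.where(ok, g2, 1.0), 0.0)
        dx, dy = -step * gx, -step * gy
        n = np.hypot(dx, dy)
        scale = np.where(n > cap, cap / np.where(n > 0, n, 1.0), 1.0)
        p[:, 0] += dx * scale
        p[:, 1] += dy * scale
    return p


def _point_polyline_distance(point, poly) -> float:
    """Min distance from a point to a polyline (segment-wise, vectorized)."""
    p = np.asarray(point, dtype=float)
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    ap = p - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.divide(np.einsum("ij,ij->i", ap, ab), np.where(denom > 0, denom, 1.0)), 0, 1)
    proj = a + ab * t[:, None]
    d = np.hypot(proj[:, 0] - p[0], proj[:, 1] - p[1])
    return float(np.min(d)) if len(d) else float("inf")


def _psi_level(eq: Equilibrium, channel, params) -> float:
    return eq.psi_level(channel, params)


# ---------------------------------------------------------------------------
# Connection detection
# ---------------------------------------------------------------------------


def _endpoint_saddles(equilibria) -> list[Equilibrium]:
    """Connection endpoint candidates: non-virtual saddles, unique positions.

    Boundary saddles are included: they lie on the invariant switching line
    at exact level 0 and are precisely the saddles the connections join.  At
    zero plug thickness the two zone fields coincide on the line and report
    the same boundary saddle twice; positions are collapsed.
    """
    sads = [
        e for e in equilibria
        if e.linear_type == SADDLE and e.admissibility in (ADMISSIBLE, BOUNDARY)
    ]
    unique: list[Equilibrium] = []
    for s in sorted(sads, key=lambda e: (e.x, e.y, e.region_claimed.value)):
        if not any(
            min(abs(s.x - u.x), 1.0 - abs(s.x - u.x)) < 1e-6 and abs(s.y - u.y) < 1e-6
            for u in unique
        ):
            unique.append(s)
    return unique


def detect_connections(
    equilibria: list[Equilibrium],
    channel: WavyChannel,
    params: FlowParameters,
    *,
    level_tol: float = LEVEL_TOL,
    delta: float = SADDLE_DELTA,
    nx: int = CONTOUR_NX,
    ny: int = CONTOUR_NY,
) -> list[HeteroclinicConnection]:
    """Find saddle-to-saddle separatrices by shared-level contour connectivity.

    Periodic images of a saddle count as distinct endpoints; connections are
    reported up to the period-1 translation in x (the invariant of a pair is
    the image shift between its endpoints).  A connection stores every
    contour component joining its pair; components from both zones appear
    when the pair sits on the shared line of a plugless channel, making the
    connection cross-region.
    """
    saddles = _endpoint_saddles(equilibria)
    if not saddles:
        return []
    levels = [_psi_level(s, channel, params) for s in saddles]

    grids = {
        Region.SIGMA1: _zone_grid(channel, params, Region.SIGMA1, nx, ny),
        Region.SIGMA3: _zone_grid(channel, params, Region.SIGMA3, nx, ny),
    }
    cache: dict[tuple, list] = {}

    def components_at(region: Region, level: float):
        key = (region, round(level, 12))
        if key not in cache:
            X, Y, psi, hpl = grids[region]
            raw = _contour_components(X, Y, psi, level)
            # drop pure second-period duplicates of first-period components
            raw = [c for c in raw if c[:, 0].min() < 1.0]
            cache[key] = [_project_to_level(c, level, channel, params, hpl) for c in raw]
        return cache[key]

    found: list[HeteroclinicConnection] = []
    n = len(saddles)
    for i in range(n):
        for j in range(i, n):
            # pairs are canonical up to period translation: endpoint b may sit
            # shift periods right (+1), left (-1), or in the same cell (0)
            for shift in (0, 1, -1):
                if j == i and shift != 1:
                    continue  # a point pairs with itself only via its image
                if abs(levels[i] - levels[j]) > level_tol:
                    continue
                level = 0.5 * (levels[i] + levels[j])
                comps = []
                comp_regions = set()
                # the contoured window is [0, SPAN_PERIODS]; a pair whose
                # joining arc straddles x = 1 is seen under one of these
                # global translations of both endpoints
                for m in (0, 1):
                    pa = np.array([saddles[i].x + m, saddles[i].y])
                    pb = np.array([saddles[j].x + shift + m, saddles[j].y])
                    for reg in (Region.SIGMA1, Region.SIGMA3):
                        for comp in components_at(reg, level):
                            da = _point_polyline_distance(pa, comp)
                            db = _point_polyline_distance(pb, comp)
                            if da < delta and db < delta:
                                comps.append(comp)
                                comp_regions.add(reg)
                    if comps:
                        break
                if not comps:
                    continue
                if len(comp_regions) == 2:
                    span = "cross-region"
                else:
                    span = f"within-{comp_regions.pop().value}"
                found.append(
                    HeteroclinicConnection(
                        saddle_a=saddles[i],
                        saddle_b=saddles[j],
                        shift=shift,
                        level=float(level),
                        span=span,
                        extent=float(np.hypot(pb[0] - pa[0], pb[1] - pa[1])),
                        components=tuple(comps),
                    )
                )
    out = sorted(found, key=lambda c: (c.span, c.level, c.saddle_a.x, c.shift))
    logger.info("detected %d heteroclinic connection(s)", len(out))
    return out


# ---------------------------------------------------------------------------
# Trapping zones and boluses
# ---------------------------------------------------------------------------


def _polygon_area(poly) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _centers_inside(polygon, equilibria):
    from matplotlib.path import Path

    centers = [e for e in equilibria
               if e.admissibility == ADMISSIBLE and e.linear_type == CENTER]
    if not centers:
        return ()
    path = Path(polygon)
    hits = []
    for c in centers:
        for k in range(SPAN_PERIODS + 1):
            if path.contains_point((c.x + k, c.y)):
                hits.append(c)
                break
    return tuple(hits)


def trapping_zones(
    connections: list[HeteroclinicConnection],
    equilibria: list[Equilibrium],
    channel: WavyChannel,
    params: FlowParameters,
) -> list[TrappingZone]:
    """Close connection contours into bounded regions and list trapped centers.

    Two separatrix components joining the same saddle pair chain into a
    lens-shaped zone (at zero plug thickness the upper and lower arcs bound
    the maximal trapping zone together).  A single component closes through
    the chord along the switching line between its endpoints -- the line is
    itself a union of connecting orbits.  A region qualifies as a trapping
    zone only when it encloses at least one admissible center, i.e. fluid
    recirculates inside it; the zone extent is the bounding connection's
    saddle-saddle distance.
    """
    zones: list[TrappingZone] = []
    for conn in connections:
        comps = sorted(conn.components, key=len, reverse=True)
        if len(comps) >= 2:
            c1, c2 = comps[0], comps[1]
            # chain c1 with whichever orientation of c2 matches its end
            if np.hypot(*(c1[-1] - c2[0])) > np.hypot(*(c1[-1] - c2[-1])):
                c2 = c2[::-1]
            polygon = np.vstack([c1, c2])
        else:
            # single arc; the shoelace/point-in-polygon closure supplies the
            # interface chord between its endpoints
            polygon = comps[0]
        if len(polygon) < 3:
            continue
        centers = _centers_inside(polygon, equilibria)
        if not centers:
            continue
        zones.append(
            TrappingZone(
                connection=conn,
                polygon=polygon,
                enclosed_centers=centers,
                area=_polygon_area(polygon),
                closed_over_period=bool(conn.shift),
            )
        )
    return zones


def _morse_enclosed(center: Equilibrium, channel, params, radius: float = 5e-3) -> bool:
    """True when Psi - Psi(center) has a definite sign on a small circle,
    i.e. nearby level sets are closed loops around the center."""
    hpl = params.h_pl if center.region_claimed is Region.SIGMA1 else 0.0
    t = np.linspace(0.0, 2 * np.pi, 24, endpoint=False)
    xs = center.x + radius * np.cos(t)
    ys = center.y + radius * np.sin(t)
    h = np.asarray(channel.height(xs), dtype=float)
    vals = _psi_of_h(ys, h, params, hpl) - _psi_of_h(
        center.y, float(channel.height(center.x)), params, hpl
    )
    return bool(np.all(vals > 0) or np.all(vals < 0))


def count_boluses(
    equilibria: list[Equilibrium],
    channel: WavyChannel,
    params: FlowParameters,
    region: Region | None = None,
) -> int:
    """Number of admissible centers (optionally restricted to one zone)
    enclosed by closed streamline loops."""
    n = 0
    for e in equilibria:
        if e.admissibility != ADMISSIBLE or e.linear_type != CENTER:
            continue
        if region is not None and e.region_claimed is not region:
            continue
        if _morse_enclosed(e, channel, params):
            n += 1
    return n


def bolus_areas(
    equilibria: list[Equilibrium],
    channel: WavyChannel,
    params: FlowParameters,
    *,
    nx: int = CONTOUR_NX,
    ny: int = CONTOUR_NY,
) -> list[float]:
    """Area of the recirculating bolus around each admissible center.

    The bolus is delimited by the closed level loop just inside the nearest
    saddle level (boundary saddles included, at level 0); the loop is
    extracted by contouring and its area taken by the shoelace formula.
    Centers whose loops cannot be closed report 0.
    """
    saddles = _endpoint_saddles(equilibria)
    centers = [e for e in equilibria
               if e.admissibility == ADMISSIBLE and e.linear_type == CENTER]
    if not centers:
        return []
    grids = {
        Region.SIGMA1: _zone_grid(channel, params, Region.SIGMA1, nx, ny),
        Region.SIGMA3: _zone_grid(channel, params, Region.SIGMA3, nx, ny),
    }
    from matplotlib.path import Path

    areas = []
    slevels = [_psi_level(s, channel, params) for s in saddles]
    for c in centers:
        lc = _psi_level(c, channel, params)
        if not slevels:
            areas.append(0.0)
            continue
        ls = min(slevels, key=lambda v: abs(v - lc))
        X, Y, psi, _hpl = grids[c.region_claimed]
        area = 0.0
        for frac in (0.98, 0.9, 0.75, 0.5):
            level = lc + frac * (ls - lc)
            for comp in _contour_components(X, Y, psi, level):
                if np.hypot(*(comp[-1] - comp[0])) > 0.02:
                    continue
                path = Path(comp)
                if any(path.contains_point((c.x + k, c.y)) for k in range(SPAN_PERIODS + 1)):
                    area = _polygon_area(comp)
                    break
            if area > 0.0:
                break
        areas.append(area)
    return areas


def connections_to_json(connections, zones, path) -> None:
    payload = {
        "connections": [c.as_dict() for c in connections],
        "trapping_zones": [z.as_dict() for z in zones],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
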