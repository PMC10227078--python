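"""Stagnation points: analytic formulas, Newton search, classification, sweeps."""

import numpy as np
import pytest

from peritrap import (
    FlowParameters,
    Region,
    WavyChannel,
    analytic_equilibria,
    classify_admissibility,
    linearize,
    numeric_equilibria,
    sweep,
)
from peritrap.dynamics import zone_vector_field
from peritrap.equilibria import ADMISSIBLE, BOUNDARY, CENTER, SADDLE, VIRTUAL


@pytest.fixture(scope="module")
def channel():
    return WavyChannel((0.2,))  # critical abscissae 0.25 (h=1.2) and 0.75 (h=0.8)


# ---------------------------------------------------------------------------
# Analytic (purely peristaltic) equilibria
# ---------------------------------------------------------------------------


def test_analytic_positions_match_closed_form(channel):
    p = FlowParameters(q=-0.2, h_pl=0.0)
    eqs = analytic_equilibria(channel, p)
    # at xbar = 0.25, H = 1.2: ybar = (H/sqrt(3))*sqrt((3q+H)/(q+H))
    H = 1.2
    expected = (H / np.sqrt(3.0)) * np.sqrt((3 * p.q + H) / (p.q + H))
    got = sorted(e.y for e in eqs if abs(e.x - 0.25) < 1e-9 and e.region_claimed is Region.SIGMA1)
    assert got == pytest.approx([-expected, expected], abs=1e-12)


def test_analytic_negative_radicand_gives_no_roots(channel):
    # q = -0.5: (3q+H)/(q+H) < 0 at both abscissae for both zones
    eqs = analytic_equilibria(channel, FlowParameters(q=-0.5, h_pl=0.0))
    assert eqs == []


def test_analytic_boundary_case_on_yield_surface(channel):
    # 3q + H = 0 at xbar = 0.25 puts a single boundary point at y = h_pl
    h_pl = 0.1
    H = 1.2 - h_pl
    p = FlowParameters(q=-H / 3.0, h_pl=h_pl)
    eqs = analytic_equilibria(channel, p)
    hits = [e for e in eqs if abs(e.x - 0.25) < 1e-9 and e.region_claimed is Region.SIGMA1]
    assert len(hits) == 1
    assert hits[0].y == pytest.approx(h_pl, abs=1e-12)
    assert hits[0].admissibility == BOUNDARY


def test_analytic_degenerate_case_is_knife_edge(channel):
    # perturbing q by 1e-4 around 3q+H=0 flips between a real pair and nothing
    H = 1.2
    q0 = -H / 3.0
    upper_025 = lambda eqs: [e for e in eqs if abs(e.x - 0.25) < 1e-9
                             and e.region_claimed is Region.SIGMA1]
    pair = upper_025(analytic_equilibria(channel, FlowParameters(q=q0 + 1e-4)))
    none = upper_025(analytic_equilibria(channel, FlowParameters(q=q0 - 1e-4)))
    assert len(pair) == 2
    assert none == []


def test_analytic_requires_zero_ue(channel):
    with pytest.raises(ValueError):
        analytic_equilibria(channel, FlowParameters(q=-0.2, ue=1.0))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def test_admissibility_rules(channel):
    p = FlowParameters(q=-0.2, h_pl=0.1)
    assert classify_admissibility(0.25, 0.5, Region.SIGMA1, channel, p) == ADMISSIBLE
    assert classify_admissibility(0.25, 1.3, Region.SIGMA1, channel, p) == VIRTUAL
    assert classify_admissibility(0.25, 0.05, Region.SIGMA1, channel, p) == VIRTUAL
    assert classify_admissibility(0.25, p.h_pl, Region.SIGMA1, channel, p) == BOUNDARY
    assert classify_admissibility(0.25, -0.5, Region.SIGMA3, channel, p) == ADMISSIBLE
    assert classify_admissibility(0.25, 0.0, Region.SIGMA3, channel, p) == BOUNDARY
    assert classify_admissibility(0.25, 0.5, Region.SIGMA3, channel, p) == VIRTUAL


def test_linearization_trace_and_types(channel):
    p = FlowParameters(q=-0.2, h_pl=0.0)
    for e in analytic_equilibria(channel, p):
        J, kind = linearize(e.x, e.y, e.region_claimed, channel, p)
        assert abs(np.trace(J)) < 1e-9
        det = float(np.linalg.det(J))
        if kind == SADDLE:
            assert det < -1e-9
            lam = np.linalg.eigvals(J)
            assert np.all(np.abs(lam.imag) < 1e-12)
            assert lam.real.min() < 0 < lam.real.max()
        elif kind == CENTER:
            assert det > 1e-9
            lam = np.linalg.eigvals(J)
            assert np.all(np.abs(lam.real) < 1e-9)


# ---------------------------------------------------------------------------
# Numeric equilibria
# ---------------------------------------------------------------------------


def test_numeric_matches_analytic_on_single_harmonic(channel):
    p = FlowParameters(q=-0.2, h_pl=0.1)
    analytic = analytic_equilibria(channel, p)
    numeric = numeric_equilibria(channel, p, nx=120, ny=60)
    for a in analytic:
        d = min(
            np.hypot(min(abs(a.x - n.x), 1 - abs(a.x - n.x)), a.y - n.y)
            for n in numeric if n.region_claimed is a.region_claimed
        )
        assert d < 1e-8


def test_numeric_roots_have_tiny_residuals(channel):
    p = FlowParameters(q=-0.2, ue=1.0, Dl=1.0, h_pl=0.1)
    for e in numeric_equilibria(channel, p, nx=120, ny=60):
        hpl = p.h_pl if e.region_claimed is Region.SIGMA1 else 0.0
        fx, fy = zone_vector_field(np.array([e.x]), np.array([e.y]), channel, p, hpl)
        assert np.hypot(fx[0], fy[0]) < 1e-10


def test_numeric_stable_under_seed_refinement(channel):
    p = FlowParameters(q=-0.2, ue=1.0, Dl=1.0, h_pl=0.1)
    coarse = numeric_equilibria(channel, p, nx=100, ny=50)
    fine = numeric_equilibria(channel, p, nx=200, ny=100)
    assert len(coarse) == len(fine)
    for c in coarse:
        d = min(
            np.hypot(min(abs(c.x - f.x), 1 - abs(c.x - f.x)), c.y - f.y)
            for f in fine if f.region_claimed is c.region_claimed
        )
        assert d < 1e-8


def test_flat_channel_has_no_isolated_equilibria():
    ch = WavyChannel((0.0,))
    assert numeric_equilibria(ch, FlowParameters(q=-0.2)) == []


def test_switching_line_saddles_are_level_zero(channel):
    # equilibria on the invariant lines y = h_pl and y = 0 are saddles with
    # stream-function level exactly 0.  With q = -0.3 the line speed
    # -1 + 1.5 (q + H) / H vanishes where H = -3q = 0.9, i.e. where the wall
    # passes through h = 1.0 (upper line) or h = 0.9 (lower line) -- both
    # heights attained by this channel's range [0.8, 1.2].
    p = FlowParameters(q=-0.3, h_pl=0.1)
    eqs = numeric_equilibria(channel, p, nx=120, ny=60)
    line = [e for e in eqs if e.admissibility == BOUNDARY]
    assert len(line) >= 2  # the line speed changes sign along each line
    for e in line:
        assert e.linear_type == SADDLE
        assert abs(e.psi_level(channel, p)) < 1e-12


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------


def test_sweep_requires_monotone_values(channel):
    p = FlowParameters(q=-0.2, h_pl=0.0)
    with pytest.raises(ValueError):
        sweep(channel, p, "h_pl", [0.0, 0.2, 0.1], nx=60, ny=30)


def test_sweep_reversibility(channel):
    p = FlowParameters(q=-0.2, h_pl=0.0)
    values = [0.0, 0.05, 0.1]
    fwd = sweep(channel, p, "h_pl", values, nx=60, ny=30, refine_depth=0)
    rev = sweep(channel, p, "h_pl", values[::-1], nx=60, ny=30, refine_depth=0)
    for eq_f, eq_r in zip(fwd.equilibria, rev.equilibria[::-1]):
        assert len(eq_f) == len(eq_r)
        for a, b in zip(eq_f, eq_r):
            assert a.x == pytest.approx(b.x, abs=1e-9)
            assert a.y == pytest.approx(b.y, abs=1e-9)


def test_sweep_detects_vanishing_roots(channel):
    # driving q toward the no-root regime must emit vanish events
    p = FlowParameters(q=-0.2, h_pl=0.0)
    branch = sweep(channel, p, "q", [-0.2, -0.35, -0.6], nx=60, ny=30, refine_depth=1)
    assert any(ev.kind == "vanish" for ev in branch.events)
    counts = [len(eqs) for eqs in branch.equilibria]
    assert counts[0] > counts[-1]


def test_sweep_admissible_count_helper(channel):
    p = FlowParameters(q=-0.2, h_pl=0.0)
    branch = sweep(channel, p, "h_pl", [0.0, 0.05], nx=60, ny=30, refine_depth=0)
    counts = branch.admissible_counts(linear_type=CENTER, region=Region.SIGMA1)
    assert len(counts) == 2
    assert all(c >= 0 for c in counts)
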