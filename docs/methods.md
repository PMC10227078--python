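# Methods

This note records how `peritrap` computes each quantity, the numerical
conventions involved, and the places where a documented judgement call was
required.

## Model summary

The toolkit analyzes wave-frame particle transport in electroosmotic
peristaltic flow of a Bingham fluid through a two-dimensional microchannel
whose upper wall is the multi-harmonic profile

    h(x, t) = 1 + sum_{i=1..m} eps_i sin(2*pi*i*(x - t)),    sum(eps_i) <= 1,

with the lower wall at y = -h by mirror symmetry. All analysis happens in the
wave frame at t = 0, where the flow is steady, on the periodic cell
x in [0, 1). Lengths are normalized by the mean half-width, speeds by the wave
speed, and the stream function by their product.

The cross-section splits into three zones:

* `SIGMA1` — upper yielded zone, h_pl <= y <= h(x);
* `SIGMA2` — rigid plug, 0 <= y < h_pl, translating at the constant speed
  c = u(h_pl) - 1 (velocity continuity across the yield surface);
* `SIGMA3` — lower yielded zone, -h(x) <= y < 0, described by the upper-zone
  closed forms with the plug thickness set to zero.

In the lubrication limit the fields are closed-form. The linearized
(Debye–Hückel) double-layer potential is Theta = cosh(Dl*y)/cosh(Dl*h); the
axial pressure gradient D_p is the Bingham Poiseuille gradient
-3(q + H)/H^3 (H = h - h_pl) plus an O(ue) electroosmotic correction; the
shear stress is s_xy = D_p*y - ue*Dl*sinh(Dl*y)/cosh(Dl*h), so s_xy(0) = 0 and
the implied yield stress is s0 = s_xy(h_pl). The per-zone stream function

    Psi = D_p (h - y)^2 (2h + y - 3 h_pl) / 6 + h - y + q + ue * A(y, h)

(with A the electroosmotic quadrature term) satisfies Psi(h) = q,
Psi(h_pl) = 0, and dPsi/dy = u - 1 for every ue. Psi is a per-zone invariant
only: its constants differ between zones, so streamlines are rendered as level
sets within each zone, never across y = h_pl.

Two derivation details deserve note, because getting either wrong destroys the
Hamiltonian structure:

1. **The full pressure gradient belongs inside the stream function.** The
   polynomial part of Psi must carry the complete D_p (including the
   electroosmotic correction), not just the Poiseuille part; only then do
   Psi(h_pl) = 0 and dPsi/dy = u - 1 hold identically in x. The test suite
   pins this with the wall/yield-surface level checks and the
   field-vs-finite-difference consistency test.
2. **Exact analytic partials.** The vector field is evaluated from exact
   partial derivatives (all x-dependence enters through h(x), so
   dPsi/dx = (dPsi/dh)·(dh/dx)); no finite differencing enters the dynamics.

## Equilibria

Transverse velocity is proportional to the wall slope, so interior equilibria
sit on the critical abscissae (dh/dx = 0). For purely peristaltic flow
(ue = 0) the transverse positions are closed-form,

    ybar = h_pl ± (H/sqrt(3)) sqrt((3q + H)/(q + H)),

with the zero-plug variant for the lower zone; a vanishing radicand
(3q + H = 0) collapses the pair onto the yield surface as a single boundary
point. The general case uses a damped, vectorized Newton iteration from a
deterministic 200×100 seed lattice per zone; converged roots (residual
< 1e-11) are deduplicated at 1e-6 on the periodic cylinder.

Classification is two-fold. *Admissibility* follows set membership: a root of
a zone's field is admissible if it lies inside that zone, boundary if it sits
on the zone's switching line within 1e-8, virtual otherwise. *Linear type*
comes from the Jacobian with the Hamiltonian structure imposed exactly
(J = [[a, b], [c, -a]] from central differences of the field, step 1e-6):
saddle for det J < -1e-9, center for det J > 1e-9, degenerate in between. The
trace is zero by construction; the finite-difference estimate of it is
reported and stays below 1e-9.

### Switching-line equilibria

Each zone's switching line (y = h_pl for the upper field, y = 0 for the lower
one) is invariant: Psi vanishes identically along it, hence the transverse
velocity is exactly zero there for every x. Equilibria on the line therefore
sit where the along-line speed c(x) = u(line) - 1 crosses zero, and a 2-D seed
lattice steps over them almost surely, so they are located by a dedicated 1-D
sign-change scan plus bisection. At such a point the Jacobian is triangular
with eigenvalues ±c'(x): **every switching-line equilibrium is a saddle, and
all of them share the exact stream-function level 0.** These boundary saddles
are dynamically essential — see below.

## Heteroclinic connections

Within a zone the dynamics is Hamiltonian, so a separatrix joining two saddles
lies on a shared Psi level. The level structure of this flow is special:

* Interior admissible saddles carry generically pairwise-distinct levels
  (each level depends on the local wall height through D_p(h(xbar))); across
  all packaged scenarios the closest interior-saddle level pairs differ by
  1e-4 to 1e-2, far above the 1e-6 matching tolerance. Interior saddles
  therefore never join one another; their level sets bound individual boluses.
* The switching-line saddles all sit at level 0 exactly, and the level-0
  contour arcs leaving them into a zone are precisely the orbits that join
  saddle to saddle. Every connection observed in the packaged scenarios is of
  this kind.

A literal reading that restricts connection endpoints to *admissible* saddles
finds no connections at all in any scenario, contradicting the qualitative
structure the detector must reproduce (a cross-region connection at zero plug
thickness; two distinct upper-zone connections at h_pl = 0.3; two trapping
regions at h_pl = 0.1). Endpoint candidates are therefore the **non-virtual**
saddles — admissible and boundary alike — and the boundary saddles are the
ones that actually terminate connections. This is the central structural
decision of the topology module.

Detection is by shared-level contour connectivity. For each saddle pair with
levels equal within `level_tol = 1e-6`, the Psi = level contour of each zone
is extracted over two periods (catching connections to periodic images; a
pair's invariant is the image shift between its endpoints, so pairs are
reported up to period-1 translation). Contour polylines are Newton-projected
onto the exact level set, and a pair is accepted when a component passes
within `delta = 1e-3` of both saddles. Components from both zones joining the
same pair make the connection cross-region; this happens exactly when the
plug is absent and the two zones share their switching line. A finite plug
separates the lines by h_pl, severing the cross-region connection.

The contour grids start `1e-4` above the switching line: the line itself is a
trivial invariant orbit at level 0, and contouring a row where Psi vanishes
identically is numerically meaningless. Connection arcs leave the line
saddles transversally, so the truncation moves arc endpoints by O(1e-4),
well inside `delta`. Halving the grid spacing changes no connection's
existence (tested), and the reported levels are exact by construction — the
line saddles sit at level 0 to machine precision.

## Trapping zones and boluses

A trapping zone is a closed region bounded by connection orbits: two contour
components joining the same pair chain into a lens (at zero plug thickness the
upper and lower arcs together bound the maximal zone); a single arc closes
through the switching-line chord between its endpoints — legitimately, since
the line is itself a union of connecting orbits. A region counts as a trapping
zone only when it encloses at least one admissible center, i.e. fluid actually
recirculates inside it. Zone extent is the bounding connection's
saddle–saddle distance; area is the shoelace value of the closed polygon.

Bolus counting is a Morse test: an admissible center is enclosed by closed
streamline loops when Psi minus its center value has a definite sign on a
small surrounding circle. Bolus areas contour the closed loop just inside the
nearest saddle level (switching-line saddles included at level 0) and apply
the shoelace formula.

## Temperature and concentration

The yielded-zone energy balance theta'' = -G - Br*s_xy*(s_xy - s0) (the
constitutive law gives du/dy = s_xy - s0) is integrated exactly twice, with
theta(h) = 1 at the wall and theta'(h_pl) = 0 at the yield surface; the lower
zone uses the zero-plug variant with theta(-h) = 1 and theta'(0) = 0. The
closed form is validated against a collocation two-point boundary-value solve,
which the test suite treats as authoritative (sup-norm tolerance 1e-5).

The solute concentration obeys phi'' = alpha1*phi + alpha2 with
alpha1 = kr*Sc > 0, phi(h_pl) = 1, phi(h) = 0, solved by the standard sinh
combination and validated against its own collocation solve (sup-norm 1e-6).
Note that for large alpha2 the profile legitimately undershoots zero before
rising back to the wall value; the samplers log a warning when a profile that
might be expected to decrease monotonically does not, but this is a property
of the ODE, not an error.

## Known discrepancy: trapping at large Debye parameter

The scenario family fig6a/fig6b varies the Debye parameter (Dl = 3, 5) at
q = -0.18366, ue = 1, h_pl = 0.2. The expectation encoded in the acceptance
suite is that trapping disappears entirely at Dl = 5. The implemented field
does not reproduce that:

* Sweeping Dl with all other parameters fixed, the upper zone keeps five
  admissible centers at Dl = 1, 2, 3, 4 and 5 and loses them between Dl = 5
  and Dl = 6; interior admissible saddles disappear between Dl = 4 and Dl = 5.
  At Dl = 5 the surviving recirculation pockets are extremely shallow — the
  stream-function amplitudes above level 0 range from about 8.7e-7 to 4.5e-3 —
  but they are genuine closed-streamline regions bounded by switching-line
  connections, and the detector reports them.
* The lower zone is plugless (its effective plug thickness is zero), so its
  structure barely changes with Dl at all: fig6b's lower zone carries the same
  two trapping regions that the h_pl = 0.3 scenario shows in its upper zone.

The trend is right — trapping is suppressed as the double layer thins, and the
bolus count at Dl = 5 does not exceed the count at Dl = 3 — but the threshold
sits between Dl = 5 and 6 rather than at or below 5. We found no
parameter-free definition of "trapping zone" that yields zero zones at Dl = 5
while preserving the two zones required at h_pl = 0.1 (the structures are
pointwise of the same kind), and declined to add an area or amplitude cutoff
tuned to make that single case pass. The corresponding acceptance assertion is
left as stated and fails; every other topology assertion passes.

## Tolerances

| quantity | value | role |
| --- | --- | --- |
| `LEVEL_TOL` | 1e-6 | saddles "share" a level |
| `SADDLE_DELTA` | 1e-3 | contour-to-saddle acceptance distance |
| `CONTOUR_NX x CONTOUR_NY` | 800 x 400 | contour grid per zone per cell |
| `EDGE_OFFSET` | 1e-4 | contour-grid standoff from the switching line |
| `ROOT_RESIDUAL` | 1e-11 | Newton convergence |
| `DEDUP_TOL` | 1e-6 | root deduplication |
| `BOUNDARY_BAND` | 1e-8 | boundary-point classification |
| `DET_TOL` | 1e-9 | degenerate-type threshold |

`LEVEL_TOL` is a documented default, not a derived constant; the interior
saddle levels in the packaged scenarios are separated by at least 1e-4, so any
tolerance between roughly 1e-12 and 1e-5 yields identical results (the
switching-line saddles match at machine precision).
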