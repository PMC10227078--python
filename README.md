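# peritrap

Streamline topology of electroosmotic peristaltic flow of a Bingham fluid in
a complex wavy microchannel.

## The problem

A two-dimensional microchannel is bounded by mirror-symmetric walls at
`y = ±h(x, t)`, where

    h(x, t) = 1 + Σᵢ εᵢ sin(2πi(x − t)),        Σᵢ εᵢ ≤ 1,

is a travelling multi-harmonic wave (lengths scaled by the mean half-width,
speeds by the wave speed). The channel carries a Bingham plastic — a fluid
with a yield stress — driven both peristaltically by the wall wave and
electroosmotically by an axial field acting on the charged double layer at
the walls. In the frame moving with the wave the flow is steady, and in the
lubrication limit every field is closed-form: the Debye–Hückel double-layer
potential, the axial pressure gradient (Poiseuille part plus an
electroosmotic correction), the velocity, the shear stress, and a per-zone
stream function `Ψ`.

Because the stress vanishes on the centerline, the cross-section splits into
three zones: an unyielded plug `0 ≤ y < h_pl` translating rigidly, and two
yielded zones above and below it. Wave-frame particle paths follow a
*switched Hamiltonian* system — within each yielded zone the motion is
Hamiltonian with `Ψ` as the Hamiltonian, and trajectories change rules at the
yield surface. The physical question is **trapping**: for which flow rates
`q`, electroosmotic velocities `ue`, Debye parameters `Dl`, and plug
thicknesses `h_pl` does a parcel of fluid recirculate inside a closed bolus
and travel with the wave instead of slipping backwards through it?

`peritrap` answers this computationally:

* closed-form fields and their exact analytic derivatives (`peritrap.fields`);
* the three-zone piecewise vector field and orbit integration
  (`peritrap.dynamics`);
* equilibrium location (analytic where available, lattice-seeded Newton in
  general), classification into admissible / boundary / virtual and
  saddle / center (`peritrap.equilibria`);
* heteroclinic-connection detection, trapping-zone extraction and bolus
  counting (`peritrap.topology`);
* temperature and solute-concentration profiles (`peritrap.transport`);
* packaged scenario fixtures and a command-line interface
  (`peritrap.scenarios`, `peritrap.cli`).

The mechanism that organizes the whole phase portrait: each zone's switching
line is invariant with `Ψ ≡ 0`, equilibria on it are always saddles, and all
of them share the exact level 0 — so these line saddles, not the interior
ones, are the endpoints of the heteroclinic connections that bound trapping
zones. See `docs/methods.md` for the details and the numerical conventions.

## Worked example

The packaged scenario `fig5a` (five-harmonic wall with amplitudes
0.034·(1..5), `q = −0.18366`, `ue = 1`, `Dl = 1`, `h_pl = 0.1`):

```python
from peritrap import (FIXTURES, numeric_equilibria, detect_connections,
                      trapping_zones)
from peritrap.topology import count_boluses

sc = FIXTURES["fig5a"]
eqs = numeric_equilibria(sc.channel, sc.flow)
adm = [e for e in eqs if e.admissibility == "admissible"]
print(f"{len(eqs)} equilibria, {len(adm)} admissible")

conns = detect_connections(eqs, sc.channel, sc.flow)
for c in conns:
    print(f"{c.span}: level={c.level:.3e} extent={c.extent:.4f} shift={c.shift:+d}")

zones = trapping_zones(conns, eqs, sc.channel, sc.flow)
for z in zones:
    print(f"{z.connection.span}: area={z.area:.4f} centers={len(z.enclosed_centers)}")
print("boluses:", count_boluses(eqs, sc.channel, sc.flow))
```

prints

```
40 equilibria, 18 admissible
within-sigma1: level=-5.898e-17 extent=0.9454 shift=-1
within-sigma3: level=4.163e-17 extent=0.9960 shift=-1
within-sigma1: area=0.6111 centers=5
within-sigma3: area=0.7287 centers=5
boluses: 10
```

Both connections run between switching-line saddles at level 0 (machine
zero, as the theory demands) and wrap once around the periodic cell
(`shift = -1`), each trapping a chain of five recirculation boluses. The
plug (`h_pl = 0.1`) separates the two zones' switching lines, so there is no
cross-region connection here — set `h_pl = 0` (scenario `fig4`) and the two
zones share the line `y = 0` and join into a single maximal trapping zone.

The same analysis from the shell:

```
$ peritrap portrait fig5a
40 equilibria, 2 connections, 2 zones -> peritrap_out/
$ peritrap equilibria fig5a
40 equilibria -> peritrap_out/equilibria.csv
$ head -4 peritrap_out/equilibria.csv
x,y,region_claimed,admissibility,linear_type,detJ
0.0607159204882,0.746419775991,sigma1,admissible,center,41.8192642233
0.0607159204882,-0.55117153514,sigma1,virtual,center,41.701970783
0.172903745839,0.331910761324,sigma1,admissible,saddle,-28.2048984127
```

`peritrap portrait` also renders the phase portrait (streamlines, equilibria,
connections, zone fill) to `peritrap_out/portrait.png`. Other subcommands:
`list` (the packaged scenarios), `fields` (grid samples of `Ψ`, `u`,
`s_xy`), `transport` (temperature/concentration profiles), `sweep`
(parameter continuation of equilibrium branches with vanish/collision
events), and `scenario` (run a fixture or a YAML config end to end, writing
CSV/JSON plus a manifest).

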