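"""Packaged parameter scenarios and the report-bundle runner.

Each fixture bundles the dimensionless parameters of one figure-style study:
the five-harmonic wall (eps_j = 0.034*j unless noted), flow rate, plug
thickness, Debye parameter and Helmholtz-Smoluchowski velocity, plus thermal/
solute groups where relevant.  Scenarios round-trip losslessly through a
flat YAML config (with the ``epsilon_rule`` shorthand for eps_j =
coefficient * j), and ``run`` writes a deterministic report bundle: CSV
tables, JSON topology records, PNG contours and a manifest of every
parameter, tolerance and library version (the pipeline is seed-free).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import topology
from .channel import WavyChannel
from .equilibria import equilibria_to_frame, numeric_equilibria
from .fields import FlowParameters, field_grid
from .topology import connections_to_json, detect_connections, trapping_zones
from .transport import (
    ScalarProfile,
    ThermoSoluteParameters,
    concentration_samples,
    temperature_field_grid,
    temperature_samples,
)

logger = logging.getLogger(__name__)

ANALYSES = ("fields", "equilibria", "portrait", "transport")


@dataclass(frozen=True)
class Scenario:
    """A named, fully validated parameter set with requested analyses."""

    name: str
    channel: WavyChannel
    flow: FlowParameters
    thermo: ThermoSoluteParameters | None = None
    analyses: tuple[str, ...] = ("equilibria", "portrait")
    transport_variants: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.flow.validate_with(self.channel)
        bad = set(self.analyses) - set(ANALYSES)
        if bad:
            raise ValueError(f"unknown analyses {sorted(bad)}; choose from {ANALYSES}")

    # -- config round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "name": self.name,
            "amplitudes": list(self.channel.amplitudes),
            "flow": asdict(self.flow),
            "analyses": list(self.analyses),
        }
        if self.thermo is not None:
            d["thermo"] = asdict(self.thermo)
        if self.transport_variants:
            d["transport_variants"] = {k: list(v) for k, v in self.transport_variants.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        if "epsilon_rule" in d:
            rule = d["epsilon_rule"]
            channel = WavyChannel.from_rule(float(rule["coefficient"]), int(rule["count"]))
        else:
            channel = WavyChannel(tuple(d["amplitudes"]))
        thermo = ThermoSoluteParameters(**d["thermo"]) if "thermo" in d else None
        return cls(
            name=str(d.get("name", "custom")),
            channel=channel,
            flow=FlowParameters(**d["flow"]),
            thermo=thermo,
            analyses=tuple(d.get("analyses", ("equilibria", "portrait"))),
            transport_variants=dict(d.get("transport_variants", {})),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _fixtures() -> dict[str, Scenario]:
    eps34 = WavyChannel.from_rule(0.034, 5)
    eps40 = WavyChannel.from_rule(0.04, 5)
    f: dict[str, Scenario] = {}

    f["fig3"] = Scenario("fig3", eps40,
                         FlowParameters(q=-0.123, ue=0.0, Dl=1.0, h_pl=0.3))
    f["fig4"] = Scenario("fig4", eps34,
                         FlowParameters(q=-0.18366, ue=1.0, Dl=1.0, h_pl=0.0))
    f["fig5a"] = Scenario("fig5a", eps34,
                          FlowParameters(q=-0.18366, ue=1.0, Dl=1.0, h_pl=0.1))
    f["fig5b"] = Scenario("fig5b", eps34,
                          FlowParameters(q=-0.18366, ue=1.0, Dl=1.0, h_pl=0.3))
    f["fig6a"] = Scenario("fig6a", eps34,
                          FlowParameters(q=-0.18366, ue=1.0, Dl=3.0, h_pl=0.2))
    f["fig6b"] = Scenario("fig6b", eps34,
                          FlowParameters(q=-0.18366, ue=1.0, Dl=5.0, h_pl=0.2))
    f["fig7a"] = Scenario("fig7a", eps34,
                          FlowParameters(q=-0.25, ue=-5.0, Dl=1.1, h_pl=0.0))
    f["fig7b"] = Scenario("fig7b", eps34,
                          FlowParameters(q=-0.25, ue=5.0, Dl=1.1, h_pl=0.0))
    f["fig7c"] = Scenario("fig7c", eps34,
                          FlowParameters(q=-0.25, ue=-5.0, Dl=1.1, h_pl=0.2))
    f["fig7d"] = Scenario("fig7d", eps34,
                          FlowParameters(q=-0.25, ue=5.0, Dl=1.1, h_pl=0.2))

    flow8 = FlowParameters(q=-0.18366, ue=1.0, Dl=1.0, h_pl=0.1)
    for tag, Br, G in (("a", 1.0, -1.0), ("b", 1.0, 0.0), ("c", 1.0, 1.0), ("d", 0.5, 1.0)):
        f[f"fig8{tag}"] = Scenario(
            f"fig8{tag}", eps34, flow8,
            thermo=ThermoSoluteParameters(Br=Br, G=G, Sc=1.25, kr=2.7, Nd=1.1),
            analyses=("transport",),
        )
    # the results discussion reads the temperature study with h_pl = 0.2;
    # both readings ship, neither is canonical
    f["fig8alt"] = Scenario(
        "fig8alt", eps34, FlowParameters(q=-0.18366, ue=1.0, Dl=1.0, h_pl=0.2),
        thermo=ThermoSoluteParameters(Br=1.0, G=1.0, Sc=1.25, kr=2.7, Nd=1.1),
        analyses=("transport",),
    )
    f["fig9"] = Scenario(
        "fig9", eps34, flow8,
        thermo=ThermoSoluteParameters(Br=1.0, G=1.0, Sc=1.25, kr=2.7, Nd=1.1),
        analyses=("transport",),
        transport_variants={"Sc": [0.5, 1.25, 2.5], "kr": [1.2, 2.7, 2.9],
                            "Nd": [0.1, 1.1, 2.1]},
    )
    return f


FIXTURES = _fixtures()


def load_scenario(name_or_path: str) -> Scenario:
    """A packaged fixture by name, or a scenario read from a YAML config."""
    if name_or_path in FIXTURES:
        return FIXTURES[name_or_path]
    p = Path(name_or_path)
    if p.exists():
        with open(p) as fh:
            return Scenario.from_dict(yaml.safe_load(fh))
    raise KeyError(
        f"unknown scenario {name_or_path!r}; packaged fixtures: {sorted(FIXTURES)}"
    )


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------


def _versions() -> dict:
    import matplotlib
    import numpy
    import pandas
    import scipy

    from . import __version__

    return {
        "peritrap": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "matplotlib": matplotlib.__version__,
    }


def run(scenario: Scenario, outdir) -> dict:
    """Execute the scenario's analyses and write the report bundle.

    Fully deterministic: repeated runs produce byte-identical CSV/JSON.
    Returns the manifest dictionary.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "scenario": scenario.to_dict(),
        "tolerances": {
            "level_tol": topology.LEVEL_TOL,
            "saddle_delta": topology.SADDLE_DELTA,
            "contour_grid": [topology.CONTOUR_NX, topology.CONTOUR_NY],
        },
        "stochastic_seeds": [],  # the pipeline contains no randomness
        "versions": _versions(),
        "outputs": [],
    }

    def emit(name):
        manifest["outputs"].append(name)
        return out / name

    eqs = None
    if {"equilibria", "portrait"} & set(scenario.analyses):
        logger.info("[%s] computing equilibria", scenario.name)
        eqs = numeric_equilibria(scenario.channel, scenario.flow)
        equilibria_to_frame(eqs).to_csv(
            emit("equilibria.csv"), index=False, float_format="%.12g"
        )
    if "portrait" in scenario.analyses:
        logger.info("[%s] detecting connections and zones", scenario.name)
        conns = detect_connections(eqs, scenario.channel, scenario.flow)
        zones = trapping_zones(conns, eqs, scenario.channel, scenario.flow)
        connections_to_json(conns, zones, emit("topology.json"))
        _portrait_png(scenario, eqs, conns, emit("portrait.png"))
    if "fields" in scenario.analyses:
        logger.info("[%s] sampling field grid", scenario.name)
        grid = field_grid(scenario.channel, scenario.flow)
        grid.to_csv(emit("fields.csv"))
        grid.contour_png(emit("streamlines.png"))
    if "transport" in scenario.analyses:
        thermo = scenario.thermo or ThermoSoluteParameters()
        x0 = 0.25
        temperature_samples(x0, scenario.channel, scenario.flow, thermo).to_csv(
            emit("temperature_profile.csv")
        )
        if thermo.alpha1 > 0:
            _concentration_csvs(scenario, thermo, x0, emit)
        x, y, theta = temperature_field_grid(scenario.channel, scenario.flow, thermo)
        _theta_png(x, y, theta, emit("temperature_field.png"))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _concentration_csvs(scenario, thermo, x0, emit):
    from dataclasses import replace

    concentration_samples(x0, scenario.channel, scenario.flow, thermo).to_csv(
        emit("concentration_profile.csv")
    )
    for pname, values in scenario.transport_variants.items():
        for v in values:
            t = replace(thermo, **{pname: float(v)})
            prof: ScalarProfile = concentration_samples(
                x0, scenario.channel, scenario.flow, t
            )
            prof.to_csv(emit(f"concentration_{pname}_{v}.csv"))


def _portrait_png(scenario, eqs, conns, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    from .fields import psi_on_grid

    ch, fl = scenario.channel, scenario.flow
    x = np.linspace(0.0, 1.0, 400)
    ymax = ch.max_height
    yv = np.linspace(-ymax, ymax, 400)
    X, Y = np.meshgrid(x, yv)
    psi = psi_on_grid(X, Y, ch, fl)
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.contour(X, Y, psi, levels=41, linewidths=0.5, colors="steelblue")
    ax.plot(x, ch.height(x), "k", lw=1.5)
    ax.plot(x, -np.asarray(ch.height(x)), "k", lw=1.5)
    for e in eqs:
        marker = "*" if e.admissibility == "admissible" else "o"
        color = "crimson" if e.linear_type == "saddle" else "seagreen"
        ax.plot(e.x, e.y, marker, color=color, ms=8, mfc="none" if marker == "o" else color)
    for c in conns:
        for comp in c.components:
            m = (comp[:, 0] >= 0) & (comp[:, 0] <= 1)
            if m.any():
                ax.plot(comp[m, 0], comp[m, 1], "darkorange", lw=1.4)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title(scenario.name)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _theta_png(x, y, theta, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    cs = ax.contourf(x, y, theta, levels=30)
    fig.colorbar(cs, ax=ax, label="theta")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.savefig(path, dpi=150)
    plt.close(fig)
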