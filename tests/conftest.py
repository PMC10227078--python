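"""Shared fixtures: packaged scenarios with cached analysis results.

Equilibrium finding and connection detection are the expensive stages, and
several test modules interrogate the same packaged scenarios; a session-scoped
cache computes each stage once per scenario and hands out the results.
"""

from __future__ import annotations

import pytest

from peritrap import (
    FIXTURES,
    WavyChannel,
    detect_connections,
    numeric_equilibria,
    trapping_zones,
)


class _ScenarioCache:
    """Lazily computed (equilibria, connections, zones) per packaged scenario."""

    def __init__(self) -> None:
        self._eqs: dict[str, list] = {}
        self._topo: dict[str, tuple] = {}

    def scenario(self, name: str):
        return FIXTURES[name]

    def equilibria(self, name: str):
        if name not in self._eqs:
            sc = FIXTURES[name]
            self._eqs[name] = numeric_equilibria(sc.channel, sc.flow)
        return self._eqs[name]

    def topology(self, name: str):
        """(equilibria, connections, zones) for one packaged scenario."""
        if name not in self._topo:
            sc = FIXTURES[name]
            eqs = self.equilibria(name)
            conns = detect_connections(eqs, sc.channel, sc.flow)
            zones = trapping_zones(conns, eqs, sc.channel, sc.flow)
            self._topo[name] = (eqs, conns, zones)
        return self._topo[name]


@pytest.fixture(scope="session")
def cache() -> _ScenarioCache:
    return _ScenarioCache()


@pytest.fixture(scope="session")
def single_wave() -> WavyChannel:
    """One-harmonic channel used by the cheap unit tests."""
    return WavyChannel((0.2,))
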