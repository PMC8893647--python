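"""Parameter fixtures: shipped organism tables and custom YAML files."""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import yaml

from .model import CellState, GrowthMode, KineticParameters

__all__ = ["OrganismFixture", "load_organism", "load_fixture_file", "ORGANISMS"]

ORGANISMS = ("yeast", "mammalian")


@dataclass(frozen=True)
class OrganismFixture:
    """A shipped (or user-provided) parameter set for one cell type."""

    organism: str
    initial_state: CellState
    parameters: KineticParameters
    poor_mode: GrowthMode
    quiescent_mode: GrowthMode
    quiescent_horizon: float

    def mode(self, regime: str) -> GrowthMode:
        if regime == "rich":
            return GrowthMode.rich()
        if regime == "poor":
            return self.poor_mode
        if regime == "quiescent":
            return self.quiescent_mode
        raise ValueError(f"unknown regime {regime!r}")


def _from_mapping(doc: dict, name: str) -> OrganismFixture:
    state = CellState(**{k: float(v) for k, v in doc["initial_state"].items()})
    params = KineticParameters.from_dict(doc["parameters"])
    params.validate()
    state.validate()
    modes = doc.get("modes", {})
    poor = GrowthMode.poor(float(modes["poor"]["t1_bar_const"]))
    q = modes["quiescent"]
    quiescent = GrowthMode.quiescent(
        t1_bar_const=float(q["t1_bar_const"]),
        d_quiescent=float(q["d_quiescent"]),
        s3_override=float(q["s3_override"]),
    )
    horizon = float(doc.get("horizons", {}).get("quiescent", 200.0))
    return OrganismFixture(doc.get("organism", name), state, params,
                           poor, quiescent, horizon)


def load_organism(organism: str) -> OrganismFixture:
    """Load a shipped fixture (``yeast`` or ``mammalian``)."""
    if organism not in ORGANISMS:
        raise ValueError(
            f"unknown organism {organism!r}; choose from {ORGANISMS} "
            "or load a custom file with load_fixture_file()")
    ref = importlib.resources.files("cngrowth.data") / f"{organism}.yaml"
    doc = yaml.safe_load(ref.read_text())
    return _from_mapping(doc, organism)


def load_fixture_file(path: str | Path) -> OrganismFixture:
    """Load a custom fixture from a YAML file with the shipped schema."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    return _from_mapping(doc, path.stem)
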