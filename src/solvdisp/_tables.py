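"""Loaders for the packaged parameter tables (plain CSV under data/).

The tables are data, not code: solvent optical/ionization parameters,
per-state damping parameters and ionization potentials for the three
carbonyl solutes, and small discrete-level model systems used by the
perturbation-theory oracles.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("solvdisp.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=None)
def solvent_table() -> pd.DataFrame:
    return _read("solvents.csv").set_index("name")


@lru_cache(maxsize=None)
def solute_state_table() -> pd.DataFrame:
    return _read("solute_states.csv")


@lru_cache(maxsize=None)
def transition_system_table() -> pd.DataFrame:
    return _read("transition_systems.csv")
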