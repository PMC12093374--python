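"""Parameter registry: YAML-backed constants, organisms, minerals, scenarios.

Every default the simulations use lives in ``phswing/data/*.yaml`` with a
source comment; the loaders below turn those files into the typed objects
of the kinetic modules.  ``overrides`` dictionaries are deep-merged onto
the file contents so scenarios and tests can perturb single values without
copying files.
"""

from __future__ import annotations

import copy
from importlib import resources

import yaml

from .chemistry import EquilibriumConstantSet
from .microbes import OxidizerParams, ReducerParams
from .minerals import MineralPhase


def _read_yaml(name):
    ref = resources.files("phswing.data").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def deep_merge(base, overrides):
    """Recursively merge ``overrides`` into a copy of ``base``."""
    out = copy.deepcopy(base)
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_constants(overrides=None):
    """Equilibrium/Henry constants from the registry."""
    raw = deep_merge(_read_yaml("constants.yaml"), overrides)
    eq = raw["equilibria"]
    return EquilibriumConstantSet(
        k1_carbonate=eq["k1_carbonate"], k2_carbonate=eq["k2_carbonate"],
        kw=eq["kw"], ka1_h2s=eq["ka1_h2s"], ka2_h2s=eq["ka2_h2s"],
        ksp_mgco3=eq["ksp_mgco3"], ksp_caso4=eq["ksp_caso4"],
        ksp_calcite=eq["ksp_calcite"], ksp_dolomite=eq["ksp_dolomite"],
        ksp_brucite=eq["ksp_brucite"], henry=dict(raw["henry"]),
        temperature=raw["temperature"],
    )


def load_organism(block="oxidizer", overrides=None):
    """One organism parameter block ('oxidizer', 'reducer', or the
    'validation_oxidizer' variant)."""
    raw = deep_merge(_read_yaml("organisms.yaml"), overrides)
    params = dict(raw[block])
    params.pop("version", None)
    if "mu_max_s" in params:
        return ReducerParams(**params)
    return OxidizerParams(**params)


def load_mineral(name, overrides=None):
    raw = deep_merge(_read_yaml("minerals.yaml"), overrides)
    if name not in raw:
        raise KeyError(f"unknown mineral phase {name!r}; known: {sorted(raw)}")
    entry = dict(raw[name])
    return MineralPhase(name=name, **entry)


def load_mineral_db(overrides=None):
    raw = deep_merge(_read_yaml("minerals.yaml"), overrides)
    return {name: MineralPhase(name=name, **dict(entry))
            for name, entry in raw.items()}


def load_scenario(name, overrides=None):
    """Raw scenario configuration dict ('h2s_cycle', 's2o3_cycle',
    'validation'), deep-merged with ``overrides``."""
    ref = resources.files("phswing.data").joinpath(f"scenarios/{name}.yaml")
    with ref.open("r") as fh:
        raw = yaml.safe_load(fh)
    return deep_merge(raw, overrides)


__all__ = ["load_constants", "load_organism", "load_mineral",
           "load_mineral_db", "load_scenario", "deep_merge"]
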