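"""Reconstruction of models and graph fixtures from serialised specs.

A model spec is a small mapping ``{"type": ..., "params": {...}, ...}``
written by :func:`neuroblankets.io.write_model_spec`.  Rebuilding from the
spec and hashing the result is the round-trip contract the CLI relies on:
``build`` then re-read gives an identical model hash.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from . import fixtures, models
from .graph import DependencyGraph


def _split_noise(spec: Mapping) -> tuple[dict, object]:
    """Constructor params and noise; noise may sit in params or top-level."""
    params = dict(spec.get("params", {}))
    noise = params.pop("noise", spec.get("noise", 0.0))
    return params, noise


def _hh(spec: Mapping, ctor):
    params, noise = _split_noise(spec)
    return ctor(models.HHParams(**params), noise=noise)


def _fhn(spec: Mapping):
    params, noise = _split_noise(spec)
    return models.fitzhugh_nagumo(models.FHNParams(**params), noise=noise)


def _ml(spec: Mapping):
    params, noise = _split_noise(spec)
    return models.morris_lecar(models.MLParams(**params), noise=noise)


_MODEL_BUILDERS = {
    "hodgkin_huxley": lambda s: _hh(s, models.hodgkin_huxley),
    "hodgkin_huxley_classic": lambda s: _hh(s, models.hodgkin_huxley_classic),
    "fitzhugh_nagumo": _fhn,
    "morris_lecar": _ml,
}


def _neural_mass_pair(spec: Mapping):
    params, noise = _split_noise(spec)
    return models.neural_mass_pair(**params, noise=noise)


def _neural_mass_network(spec: Mapping):
    params, noise = _split_noise(spec)
    W = np.asarray(params.pop("W"))
    return models.neural_mass_network(
        W, roles=spec.get("roles"), noise=noise, **params)


def _cmc_chain(spec: Mapping):
    params, noise = _split_noise(spec)
    intrinsic = params.pop("intrinsic", None)
    if intrinsic is not None:
        intrinsic = {tuple(key.split("->")): w for key, w in intrinsic.items()}
    return models.cmc_chain(intrinsic=intrinsic, noise=noise, **params)


def _spring_chain(spec: Mapping):
    params, noise = _split_noise(spec)
    return fixtures.spring_chain(**params, noise=noise)


_MODEL_BUILDERS.update({
    "neural_mass_pair": _neural_mass_pair,
    "neural_mass_network": _neural_mass_network,
    "cmc_chain": _cmc_chain,
    "random_blanket_system":
        lambda s: fixtures.random_blanket_system(**s.get("params", {})),
    "spring_chain": _spring_chain,
})

_GRAPH_BUILDERS = {
    "random_dag": lambda s: fixtures.random_dag(**s.get("params", {})),
    "network_of_networks": lambda s: fixtures.network_of_networks(),
}

KNOWN_TYPES = sorted(set(_MODEL_BUILDERS) | set(_GRAPH_BUILDERS))


def build_from_spec(spec: Mapping):
    """Build the model (or static graph) a spec describes."""
    kind = spec.get("type")
    if kind in _MODEL_BUILDERS:
        return _MODEL_BUILDERS[kind](spec)
    if kind in _GRAPH_BUILDERS:
        return _GRAPH_BUILDERS[kind](spec)
    raise ValueError(
        f"unknown model type {kind!r}; known types: {KNOWN_TYPES}")


def is_model(obj) -> bool:
    return isinstance(obj, models.DynamicalModel)


def is_graph(obj) -> bool:
    return isinstance(obj, DependencyGraph)
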