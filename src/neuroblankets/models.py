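"""Conductance-based and neural-mass models with declared dependency sparsity.

Each constructor returns a :class:`DynamicalModel` bundling the flow
function, its parameters, per-state noise amplitudes and a *declared*
dependency graph — the "who influences whose flow" structure the blanket
machinery operates on.  The declared graph is a contract: the finite
difference probe :func:`structural_graph` must never find an edge the
declaration does not contain.

The zoo covers the classic single-neuron models (a Hodgkin–Huxley variant
with one gate per channel, FitzHugh–Nagumo, Morris–Lecar), first-order
voltage/conductance neural-mass units coupled through sigmoid firing rates,
and chains of four-population canonical-microcircuit (CMC) cortical columns
with laminar-specific forward and backward connections.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .graph import (
    BlanketPartition,
    DependencyGraph,
    StateNode,
)
from .io import model_spec_hash

__all__ = [
    "DynamicalModel",
    "ModelParameterError",
    "HHParams",
    "FHNParams",
    "MLParams",
    "hodgkin_huxley",
    "hodgkin_huxley_classic",
    "fitzhugh_nagumo",
    "morris_lecar",
    "neural_mass_pair",
    "neural_mass_network",
    "cmc_chain",
    "cmc_roles",
    "CMC_POPULATIONS",
    "structural_graph",
    "random_probe_points",
]


class ModelParameterError(ValueError):
    """A model constructor was handed invalid parameters."""


@dataclass
class DynamicalModel:
    """A flow ``dx/dt = f(x, u, params)`` with declared dependency sparsity.

    Attributes
    ----------
    state_labels, input_labels
        Ordered names; flow output matches ``state_labels`` order.
    flow
        Callable ``(x, u, params) -> dx/dt`` (vectors as 1-D arrays).
    declared_edges
        Dependency graph over states and inputs (self-loops implicit).
    noise
        Per-state diffusion amplitude, state units per sqrt(time).
    roles
        Documented role per node (the model's canonical blanket reading),
        or None when no canonical assignment exists.
    state_ranges, input_ranges
        Physically plausible (lo, hi) per label, used to draw probe points.
    spec
        Serialisable construction record (type + numeric parameters).
    """

    name: str
    state_labels: tuple[str, ...]
    input_labels: tuple[str, ...]
    flow: Callable[[np.ndarray, np.ndarray, Mapping], np.ndarray]
    declared_edges: DependencyGraph
    noise: np.ndarray
    parameters: dict = field(default_factory=dict)
    roles: dict[str, str] | None = None
    state_ranges: tuple[tuple[float, float], ...] = ()
    input_ranges: tuple[tuple[float, float], ...] = ()
    default_dt: float = 0.01
    spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.noise = np.asarray(self.noise, dtype=float)
        if self.noise.shape != (len(self.state_labels),):
            raise ModelParameterError(
                f"noise must have one amplitude per state "
                f"({len(self.state_labels)}), got shape {self.noise.shape}"
            )
        declared = self.declared_edges.node_ids
        expected = set(self.state_labels) | set(self.input_labels)
        if not declared <= expected:
            raise ModelParameterError(
                f"declared_edges mentions undeclared nodes: {sorted(declared - expected)}"
            )

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def n_inputs(self) -> int:
        return len(self.input_labels)

    def flow_at(self, x: np.ndarray, u: np.ndarray | None = None) -> np.ndarray:
        if u is None:
            u = np.zeros(self.n_inputs)
        out = np.asarray(self.flow(np.asarray(x, float), np.asarray(u, float),
                                   self.parameters), dtype=float)
        if out.shape != (self.n_states,):
            raise ModelParameterError(
                f"flow returned shape {out.shape}, expected ({self.n_states},)"
            )
        return out

    def index(self, label: str) -> int:
        return self.state_labels.index(label)

    def partition(self) -> BlanketPartition:
        """The documented role assignment as a partition (states + inputs)."""
        if self.roles is None:
            raise ModelParameterError(f"model {self.name!r} has no documented roles")
        p: dict[str, set[str]] = {r: set() for r in
                                  ("internal", "sensory", "active", "external")}
        for node_id, role in self.roles.items():
            p[role].add(node_id)
        return BlanketPartition(**p)

    def model_hash(self) -> str:
        return model_spec_hash(self.spec) if self.spec else ""

    def with_noise(self, noise) -> "DynamicalModel":
        out = _copy.copy(self)
        amp = np.asarray(noise, dtype=float)
        if amp.ndim == 0:
            amp = np.full(self.n_states, float(amp))
        out.noise = amp
        out.spec = _copy.deepcopy(self.spec)
        if "noise" in out.spec:
            out.spec["noise"] = amp.tolist()
        return out

    def copy(self) -> "DynamicalModel":
        out = _copy.copy(self)
        out.declared_edges = self.declared_edges.copy()
        out.noise = self.noise.copy()
        out.parameters = _copy.deepcopy(self.parameters)
        out.roles = dict(self.roles) if self.roles is not None else None
        out.spec = _copy.deepcopy(self.spec)
        return out


def _build_graph(
    states: Sequence[str],
    inputs: Sequence[str],
    edges: Iterable[tuple[str, str]],
    roles: Mapping[str, str] | None = None,
    signs: Mapping[tuple[str, str], str] | None = None,
) -> DependencyGraph:
    g = DependencyGraph()
    for label in list(states) + list(inputs):
        role = (roles or {}).get(label, "unassigned")
        g.add_node(StateNode(label, role=role))
    for u, v in edges:
        g.add_edge(u, v, sign=(signs or {}).get((u, v), "unsigned"))
    return g


# -------------------------------------------------------------------------
# Hodgkin–Huxley (single gate per channel, gated leak) and classic variant
# -------------------------------------------------------------------------

def _alpha_n(v):
    return 0.01 * (v + 55.0) / -np.expm1(-(v + 55.0) / 10.0)


def _beta_n(v):
    return 0.125 * np.exp(-(v + 65.0) / 80.0)


def _alpha_m(v):
    return 0.1 * (v + 40.0) / -np.expm1(-(v + 40.0) / 10.0)


def _beta_m(v):
    return 4.0 * np.exp(-(v + 65.0) / 18.0)


def _alpha_h(v):
    return 0.07 * np.exp(-(v + 65.0) / 20.0)


def _beta_h(v):
    return 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))


@dataclass
class HHParams:
    """Hodgkin–Huxley constants (mV, ms, mS/cm^2, uF/cm^2).

    The rate functions default to the classic voltage-dependent forms for
    the Na and K gates and to voltage-independent constants for the leak
    gate (alpha_l = beta_l keeps the leak gate near 1/2); all overridable.
    """

    C: float = 1.0
    g_K: float = 36.0
    g_Na: float = 120.0
    g_l: float = 0.3
    v_K: float = -77.0
    v_Na: float = 50.0
    v_l: float = -54.4
    alpha: dict[str, Callable] = field(default_factory=lambda: {
        "Na": _alpha_m, "K": _alpha_n, "l": (lambda v: 0.1 + 0.0 * v)})
    beta: dict[str, Callable] = field(default_factory=lambda: {
        "Na": _beta_m, "K": _beta_n, "l": (lambda v: 0.1 + 0.0 * v)})

    def validate(self) -> None:
        if self.C <= 0:
            raise ModelParameterError(f"capacitance must be positive, got {self.C}")
        for name, g in (("g_K", self.g_K), ("g_Na", self.g_Na), ("g_l", self.g_l)):
            if g < 0:
                raise ModelParameterError(f"{name} must be non-negative, got {g}")

    def numeric(self) -> dict:
        return {k: getattr(self, k)
                for k in ("C", "g_K", "g_Na", "g_l", "v_K", "v_Na", "v_l")}


def hodgkin_huxley(params: HHParams | None = None,
                   noise: float | Sequence[float] = 0.0) -> DynamicalModel:
    """Hodgkin–Huxley with one gating state per channel and a gated leak.

    States: membrane potential ``v`` (active), gates ``mNa``, ``nK``, ``mL``
    (internal); input: injected current ``I`` (sensory)::

        C dv/dt = I - g_K nK^4 (v - v_K) - g_Na mNa^3 (v - v_Na)
                    - g_l mL (v - v_l)
        dmu_i/dt = alpha_i(v) (1 - mu_i) - beta_i(v) mu_i

    Note the deliberate departures from the classic 1952 model: the sodium
    channel has a single (cubed) activation gate with no inactivation, and
    the leak carries a gating state of its own.  The classic ``m^3 h``
    formulation is available as :func:`hodgkin_huxley_classic`.
    """
    params = params or HHParams()
    params.validate()
    p = {"params": params}

    def flow(x, u, p):
        prm: HHParams = p["params"]
        v, m_na, n_k, m_l = x
        i_inj = u[0]
        dv = (i_inj
              - prm.g_K * n_k ** 4 * (v - prm.v_K)
              - prm.g_Na * m_na ** 3 * (v - prm.v_Na)
              - prm.g_l * m_l * (v - prm.v_l)) / prm.C
        dm_na = prm.alpha["Na"](v) * (1 - m_na) - prm.beta["Na"](v) * m_na
        dn_k = prm.alpha["K"](v) * (1 - n_k) - prm.beta["K"](v) * n_k
        dm_l = prm.alpha["l"](v) * (1 - m_l) - prm.beta["l"](v) * m_l
        return np.array([dv, dm_na, dn_k, dm_l])

    states = ("v", "mNa", "nK", "mL")
    roles = {"v": "active", "mNa": "internal", "nK": "internal",
             "mL": "internal", "I": "sensory"}
    edges = [("I", "v"), ("mNa", "v"), ("nK", "v"), ("mL", "v"),
             ("v", "mNa"), ("v", "nK")]
    # the default leak-gate rates are voltage-independent constants, so the
    # leak gate only depends on voltage when custom rates make it so
    probe = (-70.0, 0.0)
    if not (np.isclose(*map(params.alpha["l"], probe))
            and np.isclose(*map(params.beta["l"], probe))):
        edges.append(("v", "mL"))
    amp = np.broadcast_to(np.asarray(noise, float), (4,)).copy()
    return DynamicalModel(
        name="hodgkin_huxley",
        state_labels=states,
        input_labels=("I",),
        flow=flow,
        declared_edges=_build_graph(states, ("I",), edges, roles),
        noise=amp,
        parameters=p,
        roles=roles,
        state_ranges=((-80.0, 40.0), (0.05, 0.95), (0.05, 0.95), (0.05, 0.95)),
        input_ranges=((-5.0, 20.0),),
        default_dt=0.01,
        spec={"type": "hodgkin_huxley", "params": params.numeric(),
              "noise": amp.tolist()},
    )


def hodgkin_huxley_classic(params: HHParams | None = None,
                           noise: float | Sequence[float] = 0.0) -> DynamicalModel:
    """Classic 1952 formulation: m^3 h sodium kinetics, ungated leak."""
    params = params or HHParams()
    params.validate()
    p = {"params": params}

    def flow(x, u, p):
        prm: HHParams = p["params"]
        v, m, h, n = x
        i_inj = u[0]
        dv = (i_inj
              - prm.g_K * n ** 4 * (v - prm.v_K)
              - prm.g_Na * m ** 3 * h * (v - prm.v_Na)
              - prm.g_l * (v - prm.v_l)) / prm.C
        dm = _alpha_m(v) * (1 - m) - _beta_m(v) * m
        dh = _alpha_h(v) * (1 - h) - _beta_h(v) * h
        dn = _alpha_n(v) * (1 - n) - _beta_n(v) * n
        return np.array([dv, dm, dh, dn])

    states = ("v", "m", "h", "n")
    roles = {"v": "active", "m": "internal", "h": "internal",
             "n": "internal", "I": "sensory"}
    edges = [("I", "v"), ("m", "v"), ("h", "v"), ("n", "v"),
             ("v", "m"), ("v", "h"), ("v", "n")]
    amp = np.broadcast_to(np.asarray(noise, float), (4,)).copy()
    return DynamicalModel(
        name="hodgkin_huxley_classic",
        state_labels=states,
        input_labels=("I",),
        flow=flow,
        declared_edges=_build_graph(states, ("I",), edges, roles),
        noise=amp,
        parameters=p,
        roles=roles,
        state_ranges=((-80.0, 40.0), (0.05, 0.95), (0.05, 0.95), (0.05, 0.95)),
        input_ranges=((-5.0, 20.0),),
        default_dt=0.01,
        spec={"type": "hodgkin_huxley_classic", "params": params.numeric(),
              "noise": amp.tolist()},
    )


# -------------------------------------------------------------------------
# FitzHugh–Nagumo
# -------------------------------------------------------------------------

@dataclass
class FHNParams:
    """FitzHugh–Nagumo constants (dimensionless time)."""

    tau: float = 12.5
    alpha: float = 0.7
    beta: float = 0.8

    def validate(self) -> None:
        if self.tau <= 0:
            raise ModelParameterError(f"tau must be positive, got {self.tau}")

    def numeric(self) -> dict:
        return {"tau": self.tau, "alpha": self.alpha, "beta": self.beta}


def fitzhugh_nagumo(params: FHNParams | None = None,
                    noise: float | Sequence[float] = 0.0) -> DynamicalModel:
    """FitzHugh–Nagumo: fast voltage ``v`` (active) and slow recovery ``w``
    (internal), driven by injected current ``I`` (sensory)::

        dv/dt = v - v^3/3 - w + I
        dw/dt = (v + alpha - beta w) / tau
    """
    params = params or FHNParams()
    params.validate()

    def flow(x, u, p):
        prm: FHNParams = p["params"]
        v, w = x
        return np.array([
            v - v ** 3 / 3.0 - w + u[0],
            (v + prm.alpha - prm.beta * w) / prm.tau,
        ])

    states = ("v", "w")
    roles = {"v": "active", "w": "internal", "I": "sensory"}
    edges = [("I", "v"), ("w", "v"), ("v", "w")]
    amp = np.broadcast_to(np.asarray(noise, float), (2,)).copy()
    return DynamicalModel(
        name="fitzhugh_nagumo",
        state_labels=states,
        input_labels=("I",),
        flow=flow,
        declared_edges=_build_graph(states, ("I",), edges, roles),
        noise=amp,
        parameters={"params": params},
        roles=roles,
        state_ranges=((-2.5, 2.5), (-1.5, 2.5)),
        input_ranges=((-1.0, 1.5),),
        default_dt=0.001,
        spec={"type": "fitzhugh_nagumo", "params": params.numeric(),
              "noise": amp.tolist()},
    )


# -------------------------------------------------------------------------
# Morris–Lecar
# -------------------------------------------------------------------------

@dataclass
class MLParams:
    """Morris–Lecar constants, standard Hopf-regime set (mV, ms, uF, mS)."""

    C: float = 20.0
    g_L: float = 2.0
    g_Ca: float = 4.4
    g_K: float = 8.0
    v_L: float = -60.0
    v_Ca: float = 120.0
    v_K: float = -84.0
    V1: float = -1.2   # Ca activation midpoint (mV)
    V2: float = 18.0   # Ca activation steepness (mV)
    V3: float = 2.0    # K activation midpoint (mV)
    V4: float = 30.0   # K activation steepness (mV)
    phi: float = 0.04  # K gating rate (1/ms)

    def validate(self) -> None:
        if self.C <= 0:
            raise ModelParameterError(f"capacitance must be positive, got {self.C}")
        for name in ("g_L", "g_Ca", "g_K"):
            if getattr(self, name) < 0:
                raise ModelParameterError(f"{name} must be non-negative")
        if self.phi <= 0 or self.V2 <= 0 or self.V4 <= 0:
            raise ModelParameterError("phi, V2 and V4 must be positive")

    def m_inf(self, v):
        return 0.5 * (1.0 + np.tanh((v - self.V1) / self.V2))

    def w_inf(self, v):
        return 0.5 * (1.0 + np.tanh((v - self.V3) / self.V4))

    def tau_w(self, v):
        return 1.0 / (self.phi * np.cosh((v - self.V3) / (2.0 * self.V4)))

    def numeric(self) -> dict:
        return {k: getattr(self, k) for k in
                ("C", "g_L", "g_Ca", "g_K", "v_L", "v_Ca", "v_K",
                 "V1", "V2", "V3", "V4", "phi")}


def morris_lecar(params: MLParams | None = None,
                 noise: float | Sequence[float] = 0.0) -> DynamicalModel:
    """Morris–Lecar: voltage ``v`` (active) with instantaneous calcium
    activation, one potassium gating state ``w`` (internal), injected
    current ``I`` (sensory)::

        C dv/dt = I - g_L (v - v_L) - g_Ca m_inf(v) (v - v_Ca)
                    - g_K w (v - v_K)
        dw/dt   = (w_inf(v) - w) / tau_w(v)
    """
    params = params or MLParams()
    params.validate()

    def flow(x, u, p):
        prm: MLParams = p["params"]
        v, w = x
        dv = (u[0]
              - prm.g_L * (v - prm.v_L)
              - prm.g_Ca * prm.m_inf(v) * (v - prm.v_Ca)
              - prm.g_K * w * (v - prm.v_K)) / prm.C
        dw = (prm.w_inf(v) - w) / prm.tau_w(v)
        return np.array([dv, dw])

    states = ("v", "w")
    roles = {"v": "active", "w": "internal", "I": "sensory"}
    edges = [("I", "v"), ("w", "v"), ("v", "w")]
    amp = np.broadcast_to(np.asarray(noise, float), (2,)).copy()
    return DynamicalModel(
        name="morris_lecar",
        state_labels=states,
        input_labels=("I",),
        flow=flow,
        declared_edges=_build_graph(states, ("I",), edges, roles),
        noise=amp,
        parameters={"params": params},
        roles=roles,
        state_ranges=((-70.0, 40.0), (0.05, 0.95)),
        input_ranges=((0.0, 120.0),),
        default_dt=0.01,
        spec={"type": "morris_lecar", "params": params.numeric(),
              "noise": amp.tolist()},
    )


# -------------------------------------------------------------------------
# Neural-mass units: first-order voltage + conductance per population
# -------------------------------------------------------------------------

def logistic_rate(v, slope: float = 0.56, threshold: float = 0.0):
    """Sigmoid converting potentials (mV) to normalised firing rates."""
    return 1.0 / (1.0 + np.exp(-slope * (v - threshold)))


def neural_mass_network(
    W: np.ndarray,
    slope: float = 0.56,
    threshold: float = 0.0,
    kappa_v: float = 1.0,
    kappa_g: float = 0.5,
    unit_names: Sequence[str] | None = None,
    roles: Mapping[str, str] | None = None,
    signs: Mapping[tuple[int, int], str] | None = None,
    noise: float | Sequence[float] = 0.0,
    name: str = "neural_mass_network",
) -> DynamicalModel:
    """``n`` voltage/conductance units coupled through sigmoid firing rates.

    ``W[i, j]`` is the connection gain from the voltage of unit ``j`` onto
    the conductance of unit ``i``.  Per unit::

        dv_i/dt = g_i - kappa_v v_i
        dg_i/dt = sum_j W[i,j] sigma(v_j) - kappa_g g_i

    so a unit's voltage depends only on its own conductance (and itself),
    while its conductance collects presynaptic voltages — the asymmetry that
    makes voltages blanket states and conductances internal/external states.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ModelParameterError(f"W must be square, got shape {W.shape}")
    n = W.shape[0]
    if unit_names is None:
        unit_names = [f"u{i + 1}" for i in range(n)]
    if len(unit_names) != n:
        raise ModelParameterError(
            f"{len(unit_names)} unit names for {n} units")
    v_labels = [f"{u}.v" for u in unit_names]
    g_labels = [f"{u}.g" for u in unit_names]
    states = tuple(v_labels + g_labels)
    prm = {"W": W, "slope": slope, "threshold": threshold,
           "kappa_v": kappa_v, "kappa_g": kappa_g}

    def flow(x, u, p):
        v = x[:n]
        g = x[n:]
        dv = g - p["kappa_v"] * v
        dg = p["W"] @ logistic_rate(v, p["slope"], p["threshold"]) - p["kappa_g"] * g
        return np.concatenate([dv, dg])

    edges: list[tuple[str, str]] = [(g_labels[i], v_labels[i]) for i in range(n)]
    edge_signs: dict[tuple[str, str], str] = {}
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] != 0.0:
                e = (v_labels[j], g_labels[i])
                edges.append(e)
                edge_signs[e] = "excitatory" if W[i, j] > 0 else "inhibitory"
            if (signs or {}).get((i, j)):
                edge_signs[(v_labels[j], g_labels[i])] = signs[(i, j)]
    amp = np.broadcast_to(np.asarray(noise, float), (2 * n,)).copy()
    return DynamicalModel(
        name=name,
        state_labels=states,
        input_labels=(),
        flow=flow,
        declared_edges=_build_graph(states, (), edges, roles, edge_signs),
        noise=amp,
        parameters=prm,
        roles=dict(roles) if roles else None,
        state_ranges=tuple([(-2.0, 2.0)] * n + [(-1.0, 1.0)] * n),
        input_ranges=(),
        default_dt=0.01,
        spec={"type": name if name != "neural_mass_network" else "neural_mass_network",
              "params": {"W": W.tolist(), "slope": slope, "threshold": threshold,
                         "kappa_v": kappa_v, "kappa_g": kappa_g,
                         "unit_names": list(unit_names)},
              "roles": dict(roles) if roles else None,
              "noise": amp.tolist()},
    )


def neural_mass_pair(
    A_mu: float = 0.5,
    A_eta: float = 0.5,
    **kwargs,
) -> DynamicalModel:
    """Two coupled neural-mass units with the canonical two-neuron blanket.

    ``A_eta`` couples the voltage (active state) of unit 1 onto the
    conductance (external state) of unit 2; ``A_mu`` couples the voltage
    (sensory state) of unit 2 back onto the conductance (internal state) of
    unit 1.  Documented roles: ``u1.g`` internal, ``u1.v`` active, ``u2.v``
    sensory, ``u2.g`` external.
    """
    W = np.array([[0.0, A_mu], [A_eta, 0.0]])
    roles = {"u1.g": "internal", "u1.v": "active",
             "u2.v": "sensory", "u2.g": "external"}
    model = neural_mass_network(W, roles=roles, name="neural_mass_pair", **kwargs)
    model.spec["type"] = "neural_mass_pair"
    model.spec["params"] = {"A_mu": A_mu, "A_eta": A_eta,
                            **{k: v for k, v in model.spec["params"].items()
                               if k not in ("W", "unit_names")}}
    return model


# -------------------------------------------------------------------------
# Canonical microcircuit columns
# -------------------------------------------------------------------------

CMC_POPULATIONS = ("SS", "SP", "II", "DP")

# Intrinsic connectivity (source population -> target population, gain).
# Sources are voltages, targets conductances; II is inhibitory.  The default
# follows the canonical-microcircuit convention used in effective-connectivity
# modelling and is fully overridable.  Intrinsic edges never cross columns.
DEFAULT_INTRINSIC: dict[tuple[str, str], float] = {
    ("SS", "SP"): 0.8,
    ("SS", "II"): 0.4,
    ("SP", "II"): 0.4,
    ("SP", "DP"): 0.6,
    ("II", "SS"): -0.8,
    ("II", "SP"): -0.6,
    ("II", "DP"): -0.4,
    ("DP", "II"): 0.2,
}


def cmc_roles(L: int) -> dict[str, str]:
    """Documented role assignment for a chain of L columns.

    L = 1: spiny stellates and interneurons internal, pyramidal cells
    active (a column on its own has no outside).  L = 2: column 1 SS/II
    internal, column 2 SS/II external, column-1 pyramidal cells active and
    column-2 pyramidal cells sensory.  L = 4: whole columns take the roles
    internal / active / sensory / external left to right, the middle two
    columns insulating the ends.
    """
    roles: dict[str, str] = {}

    def assign(col: int, pops: Iterable[str], role: str) -> None:
        for pop in pops:
            for suffix in ("v", "g"):
                roles[f"c{col}.{pop}.{suffix}"] = role

    if L == 1:
        assign(1, ("SS", "II"), "internal")
        assign(1, ("SP", "DP"), "active")
    elif L == 2:
        assign(1, ("SS", "II"), "internal")
        assign(2, ("SS", "II"), "external")
        assign(1, ("SP", "DP"), "active")
        assign(2, ("SP", "DP"), "sensory")
    elif L == 4:
        for col, role in zip(range(1, 5),
                             ("internal", "active", "sensory", "external")):
            assign(col, CMC_POPULATIONS, role)
    else:
        raise ModelParameterError(
            f"no documented role assignment for a {L}-column chain")
    return roles


def cmc_chain(
    L: int,
    intrinsic: Mapping[tuple[str, str], float] | None = None,
    forward_gain: float = 0.5,
    backward_gain: float = 0.3,
    forward_to_dp: bool = False,
    noise: float | Sequence[float] = 0.0,
    **unit_kwargs,
) -> DynamicalModel:
    """A chain of L canonical-microcircuit columns.

    Each column holds four neural-mass populations (spiny stellate SS,
    superficial pyramidal SP, inhibitory interneurons II, deep pyramidal
    DP).  Forward (ascending) connections originate at SP of column i and
    terminate on SS and II of column i+1 (optionally also DP); backward
    (descending) connections originate at DP of column i+1 and terminate on
    SP and II of column i.  SS and II never project outside their column,
    which is what makes them internal/external states while the pyramidal
    populations form the blanket.
    """
    if L < 1:
        raise ModelParameterError(f"need at least one column, got L={L}")
    intrinsic = dict(DEFAULT_INTRINSIC if intrinsic is None else intrinsic)
    for (src, dst) in intrinsic:
        if src not in CMC_POPULATIONS or dst not in CMC_POPULATIONS:
            raise ModelParameterError(f"unknown population in intrinsic edge {(src, dst)}")
    unit_names = [f"c{col}.{pop}" for col in range(1, L + 1)
                  for pop in CMC_POPULATIONS]
    idx = {u: i for i, u in enumerate(unit_names)}
    n = len(unit_names)
    W = np.zeros((n, n))
    for col in range(1, L + 1):
        for (src, dst), w in intrinsic.items():
            W[idx[f"c{col}.{dst}"], idx[f"c{col}.{src}"]] = w
    for col in range(1, L):
        targets = ["SS", "II"] + (["DP"] if forward_to_dp else [])
        for t in targets:
            W[idx[f"c{col + 1}.{t}"], idx[f"c{col}.SP"]] = forward_gain
        for t in ("SP", "II"):
            W[idx[f"c{col}.{t}"], idx[f"c{col + 1}.DP"]] = backward_gain
    try:
        roles = cmc_roles(L)
    except ModelParameterError:
        roles = None
    model = neural_mass_network(
        W, unit_names=unit_names, roles=roles, noise=noise,
        name=f"cmc_chain_L{L}", **unit_kwargs)
    model.spec = {
        "type": "cmc_chain",
        "params": {"L": L,
                   "intrinsic": {f"{s}->{d}": w for (s, d), w in intrinsic.items()},
                   "forward_gain": forward_gain,
                   "backward_gain": backward_gain,
                   "forward_to_dp": forward_to_dp,
                   **{k: unit_kwargs[k] for k in
                      ("slope", "threshold", "kappa_v", "kappa_g")
                      if k in unit_kwargs}},
        "roles": roles,
        "noise": model.noise.tolist(),
    }
    return model


# -------------------------------------------------------------------------
# Structural probing
# -------------------------------------------------------------------------

def random_probe_points(
    model: DynamicalModel, n: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw n probe states (and inputs) uniformly within the model's ranges."""
    if not model.state_ranges:
        raise ModelParameterError(f"model {model.name!r} declares no state ranges")
    lo = np.array([r[0] for r in model.state_ranges])
    hi = np.array([r[1] for r in model.state_ranges])
    ulo = np.array([r[0] for r in model.input_ranges]) if model.input_ranges else np.zeros(0)
    uhi = np.array([r[1] for r in model.input_ranges]) if model.input_ranges else np.zeros(0)
    return [
        (rng.uniform(lo, hi), rng.uniform(ulo, uhi) if len(ulo) else np.zeros(0))
        for _ in range(n)
    ]


def structural_graph(
    model: DynamicalModel,
    probe_points: Sequence[tuple[np.ndarray, np.ndarray]] | Sequence[np.ndarray],
    tol: float = 1e-8,
    eps: float = 1e-5,
) -> DependencyGraph:
    """Dependency graph recovered by finite-difference probing of the flow.

    An edge ``j -> i`` is recorded when ``|df_i/dx_j|`` (central difference,
    step ``eps``) exceeds ``tol`` at *any* probe point.  Probing can miss
    edges whose derivative vanishes at every probe point; it never invents
    edges beyond ``tol``, so the result must be a subgraph of the declared
    dependency graph for a correctly declared model.
    """
    if len(probe_points) < 1:
        raise ModelParameterError("need at least one probe point")
    labels = list(model.state_labels) + list(model.input_labels)
    present = np.zeros((model.n_states, len(labels)), dtype=bool)
    for point in probe_points:
        if isinstance(point, tuple):
            x0, u0 = point
        else:
            x0, u0 = point, np.zeros(model.n_inputs)
        x0 = np.asarray(x0, float)
        u0 = np.asarray(u0, float)
        f0 = model.flow_at(x0, u0)
        if not np.all(np.isfinite(f0)):
            raise ModelParameterError(
                f"flow is non-finite at probe point {x0.tolist()}")
        for j in range(model.n_states):
            xp, xm = x0.copy(), x0.copy()
            xp[j] += eps
            xm[j] -= eps
            deriv = (model.flow_at(xp, u0) - model.flow_at(xm, u0)) / (2 * eps)
            if not np.all(np.isfinite(deriv)):
                raise ModelParameterError(
                    f"non-finite derivative wrt {labels[j]!r} at {x0.tolist()}")
            present[:, j] |= np.abs(deriv) > tol
        for j in range(model.n_inputs):
            up, um = u0.copy(), u0.copy()
            up[j] += eps
            um[j] -= eps
            deriv = (model.flow_at(x0, up) - model.flow_at(x0, um)) / (2 * eps)
            present[:, model.n_states + j] |= np.abs(deriv) > tol
    roles = model.roles or {}
    g = _build_graph(model.state_labels, model.input_labels, (), roles)
    for i, dst in enumerate(model.state_labels):
        for j, src in enumerate(labels):
            if present[i, j] and src != dst:
                g.add_edge(src, dst)
    return g
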