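"""Seeded synthetic-system generators.

These supply every test input: random DAGs for the blanket-extraction
oracle, random stable linear systems whose Jacobian sparsity is exactly the
four-role flow template (the calibration substrate for the statistical
verifier), single-edge perturbations for edge-gain negative controls, the
Newtonian spring–mass chain that instantiates the same blanket template as
the neural models, and the static brain-wide network graph.

Every generator is deterministic given its seed and parameters.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .graph import (
    DependencyGraph,
    GraphError,
    StateNode,
)
from .models import DynamicalModel, ModelParameterError, _build_graph

__all__ = [
    "random_dag",
    "random_blanket_system",
    "blanket_template_ok",
    "perturb_add_edge",
    "spring_chain",
    "spring_roles",
    "spring_energy",
    "network_of_networks",
]


def random_dag(n: int, p: float, seed: int | None = None) -> DependencyGraph:
    """Random DAG: edges respect a randomly drawn topological order.

    Each of the n(n-1)/2 order-respecting pairs becomes an edge with
    probability ``p``.  Node ids are ``x0 .. x{n-1}``.
    """
    if n < 1:
        raise GraphError(f"need at least one node, got n={n}")
    if not 0.0 <= p <= 1.0:
        raise GraphError(f"edge probability must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    labels = [f"x{i}" for i in range(n)]
    order = rng.permutation(n)
    g = DependencyGraph(nodes=labels)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(labels[order[i]], labels[order[j]])
    return g


# Allowed flow dependencies of the four-role template: row = whose flow,
# column = who may appear in it (self-dependence implicit).
_TEMPLATE_ALLOWED: dict[str, tuple[str, ...]] = {
    "internal": ("internal", "sensory", "active"),
    "active": ("internal", "sensory", "active"),
    "sensory": ("external", "sensory", "active"),
    "external": ("external", "sensory", "active"),
}


def blanket_template_ok(role_of_parent: str, role_of_child: str) -> bool:
    """Whether a dependency from one role onto another's flow is allowed."""
    return role_of_parent in _TEMPLATE_ALLOWED[role_of_child]


def random_blanket_system(
    n_mu: int = 3,
    n_s: int = 2,
    n_a: int = 2,
    n_eta: int = 4,
    stability_margin: float = 0.1,
    coupling_scale: float = 0.5,
    self_decay: float = 2.0,
    noise_amp: float = 1.0,
    seed: int | None = None,
    max_attempts: int = 20,
) -> DynamicalModel:
    """Random stable linear system with exact four-role Jacobian sparsity.

    The drift ``J`` has Gaussian off-diagonal entries (sd
    ``coupling_scale``) within the blocks the template allows and is
    identically zero in the four forbidden blocks (internal->sensory,
    internal->external, external->active, external->internal).  Each state
    carries an explicit self-decay ``-self_decay`` on the diagonal; draws
    whose eigenvalues do not all have real part <= -``stability_margin``
    are rejected and redrawn (bounded attempts).  The decay keeps every
    mode — including oscillatory ones — well damped, so trajectories of a
    few thousand steps actually mix; merely pinning the largest real part
    at the margin would leave slowly rotating, barely damped modes whose
    autocorrelation spans most of such a trajectory.  Diffusion is
    additive, diagonal, amplitude ``noise_amp`` per state.  The documented
    roles validate with zero violations by construction.
    """
    for size, name in ((n_mu, "n_mu"), (n_s, "n_s"), (n_a, "n_a"), (n_eta, "n_eta")):
        if size < 1:
            raise ModelParameterError(f"{name} must be >= 1, got {size}")
    rng = np.random.default_rng(seed)
    labels: list[str] = (
        [f"mu{i + 1}" for i in range(n_mu)]
        + [f"s{i + 1}" for i in range(n_s)]
        + [f"a{i + 1}" for i in range(n_a)]
        + [f"eta{i + 1}" for i in range(n_eta)]
    )
    roles = {lab: role for lab, role in zip(
        labels,
        ["internal"] * n_mu + ["sensory"] * n_s + ["active"] * n_a
        + ["external"] * n_eta)}
    n = len(labels)

    J = None
    for _ in range(max_attempts):
        cand = rng.normal(scale=coupling_scale, size=(n, n))
        for i, child in enumerate(labels):
            for j, parent in enumerate(labels):
                if i != j and not blanket_template_ok(roles[parent], roles[child]):
                    cand[i, j] = 0.0
        np.fill_diagonal(cand, -self_decay)
        eig = np.linalg.eigvals(cand)
        if np.all(np.isfinite(eig)) and eig.real.max() <= -stability_margin:
            J = cand
            break
    if J is None:
        raise ModelParameterError(
            "failed to draw a drift with stability margin "
            f"{stability_margin} in {max_attempts} attempts; try another seed")

    def flow(x, u, p):
        return p["J"] @ x

    edges = [(labels[j], labels[i])
             for i in range(n) for j in range(n)
             if i != j and J[i, j] != 0.0]
    graph = _build_graph(labels, (), edges, roles)
    return DynamicalModel(
        name="random_blanket_system",
        state_labels=tuple(labels),
        input_labels=(),
        flow=flow,
        declared_edges=graph,
        noise=np.full(n, float(noise_amp)),
        parameters={"J": J},
        roles=roles,
        state_ranges=tuple([(-3.0, 3.0)] * n),
        input_ranges=(),
        default_dt=0.1,
        spec={"type": "random_blanket_system",
              "params": {"n_mu": n_mu, "n_s": n_s, "n_a": n_a, "n_eta": n_eta,
                         "stability_margin": stability_margin,
                         "coupling_scale": coupling_scale,
                         "noise_amp": noise_amp, "seed": seed}},
    )


def perturb_add_edge(
    target: DynamicalModel | DependencyGraph,
    from_role: str,
    to_role: str,
    weight: float = 0.5,
    seed: int | None = None,
    restabilize: bool = True,
    stability_margin: float = 0.1,
):
    """Copy of a model or graph with exactly one gained edge between roles.

    The source is a random node of ``from_role`` and the destination a
    random node of ``to_role`` (seeded).  For a model the flow of the
    destination state gains a linear term ``weight * x_source`` (linear
    models get it written straight into their drift matrix) and the edge is
    added to the declared graph.  The original is untouched.

    A gained edge can tip a linear system past its stability margin, in
    which case trajectories diverge along one eigendirection and carry no
    stationary information.  With ``restabilize`` (default) the perturbed
    drift's diagonal is shifted back so all eigenvalues keep real part
    <= -``stability_margin``; the shift touches only the implicit
    self-dependence, never the cross-state structure under test.
    """
    rng = np.random.default_rng(seed)
    if isinstance(target, DependencyGraph):
        roles = target.roles()
        pool_from = sorted(i for i, r in roles.items() if r == from_role)
        pool_to = sorted(i for i, r in roles.items() if r == to_role)
        if not pool_from or not pool_to:
            raise GraphError(
                f"no nodes with role {from_role if not pool_from else to_role!r}")
        src = pool_from[rng.integers(len(pool_from))]
        dst = pool_to[rng.integers(len(pool_to))]
        out = target.copy()
        out.add_edge(src, dst)
        return out

    model = target
    if model.roles is None:
        raise ModelParameterError(f"model {model.name!r} has no documented roles")
    states = set(model.state_labels)
    pool_from = sorted(l for l, r in model.roles.items()
                       if r == from_role and l in states)
    pool_to = sorted(l for l, r in model.roles.items()
                     if r == to_role and l in states)
    if not pool_from or not pool_to:
        raise ModelParameterError(
            f"no state with role {from_role if not pool_from else to_role!r}")
    src = pool_from[rng.integers(len(pool_from))]
    dst = pool_to[rng.integers(len(pool_to))]
    src_i, dst_i = model.index(src), model.index(dst)

    out = model.copy()
    out.name = f"{model.name}+{from_role}->{to_role}"
    if "J" in out.parameters and out.parameters.get("J") is not None \
            and model.name.startswith("random_blanket_system"):
        J = np.array(out.parameters["J"], dtype=float, copy=True)
        J[dst_i, src_i] += weight
        if restabilize:
            max_re = np.linalg.eigvals(J).real.max()
            if max_re > -stability_margin:
                J -= (max_re + stability_margin) * np.eye(len(J))

        def flow(x, u, p):
            return p["J"] @ x

        out.parameters = {"J": J}
        out.flow = flow
    else:
        base_flow = model.flow
        base_params = out.parameters

        def flow(x, u, p, _f=base_flow, _s=src_i, _d=dst_i, _w=weight):
            dx = np.array(_f(x, u, p), dtype=float, copy=True)
            dx[_d] += _w * x[_s]
            return dx

        out.flow = flow
        out.parameters = base_params
    if not out.declared_edges.has_edge(src, dst) and src != dst:
        out.declared_edges.add_edge(src, dst)
    out.spec = dict(out.spec)
    out.spec["perturbation"] = {"from": src, "to": dst, "weight": weight,
                                "from_role": from_role, "to_role": to_role}
    return out


# -------------------------------------------------------------------------
# Newtonian spring–mass chain
# -------------------------------------------------------------------------

def spring_roles(n: int, focus: int) -> dict[str, str]:
    """Blanket roles from the perspective of particle ``focus`` (1-based).

    The particle's momentum is internal, its position active, the
    neighbouring positions sensory, and everything else external — the
    Newtonian mirror of the neuronal voltage/conductance asymmetry.
    """
    if not 1 <= focus <= n:
        raise ModelParameterError(f"focus {focus} outside chain of {n} particles")
    roles: dict[str, str] = {}
    for i in range(1, n + 1):
        roles[f"q{i}"] = "external"
        roles[f"p{i}"] = "external"
    roles[f"p{focus}"] = "internal"
    roles[f"q{focus}"] = "active"
    for nb in (focus - 1, focus + 1):
        if 1 <= nb <= n:
            roles[f"q{nb}"] = "sensory"
    return roles


def spring_chain(
    n: int,
    masses: float | Sequence[float] = 1.0,
    k: float | Sequence[float] = 1.0,
    anchored: bool = False,
    focus: int | None = None,
    noise: float = 0.0,
    seed: int | None = None,
) -> DynamicalModel:
    """1-D chain of point masses coupled by linear springs.

    States: positions ``q1..qn`` (m) and momenta ``p1..pn`` (kg m/s)::

        dq_i/dt = p_i / m_i
        dp_i/dt = k_i (q_{i+1} - q_i) - k_{i-1} (q_i - q_{i-1})

    with free ends by default (``anchored=True`` ties the end springs to
    rigid walls at the origin).  A position's flow depends only on the
    particle's own momentum; a momentum's flow depends on the neighbouring
    positions — the same asymmetric template as the neural models.
    Documented roles are taken from the middle particle's perspective
    (override with ``focus``).
    """
    if n < 2:
        raise ModelParameterError(f"need at least two particles, got n={n}")
    m = np.broadcast_to(np.asarray(masses, float), (n,)).copy()
    if np.any(m <= 0):
        raise ModelParameterError("all masses must be positive")
    n_springs = n + 1 if anchored else n - 1
    ks = np.broadcast_to(np.asarray(k, float), (n_springs,)).copy()
    if np.any(ks < 0):
        raise ModelParameterError("spring constants must be non-negative")
    focus = focus or (n + 1) // 2

    prm = {"m": m, "k": ks, "anchored": anchored}

    def flow(x, u, p):
        q = x[:n]
        pm = x[n:]
        dq = pm / p["m"]
        if p["anchored"]:
            ext = np.concatenate([[0.0], q, [0.0]])
            kfull = p["k"]
        else:
            ext = np.concatenate([[q[0]], q, [q[-1]]])  # phantom = free end
            kfull = np.concatenate([[0.0], p["k"], [0.0]])
        dp = kfull[1:] * (ext[2:] - ext[1:-1]) - kfull[:-1] * (ext[1:-1] - ext[:-2])
        return np.concatenate([dq, dp])

    q_labels = [f"q{i}" for i in range(1, n + 1)]
    p_labels = [f"p{i}" for i in range(1, n + 1)]
    states = tuple(q_labels + p_labels)
    roles = spring_roles(n, focus)
    edges = [(p_labels[i], q_labels[i]) for i in range(n)]
    # force on particle i depends on its own position and both neighbours
    for i in range(n):
        for nb in (i - 1, i, i + 1):
            if 0 <= nb < n:
                edges.append((q_labels[nb], p_labels[i]))
    return DynamicalModel(
        name="spring_chain",
        state_labels=states,
        input_labels=(),
        flow=flow,
        declared_edges=_build_graph(states, (), edges, roles),
        noise=np.full(2 * n, float(noise)),
        parameters=prm,
        roles=roles,
        state_ranges=tuple([(-1.0, 1.0)] * (2 * n)),
        input_ranges=(),
        default_dt=0.001,
        spec={"type": "spring_chain",
              "params": {"n": n, "masses": m.tolist(), "k": ks.tolist(),
                         "anchored": anchored, "focus": focus},
              "noise": float(noise)},
    )


def spring_energy(model: DynamicalModel, states: np.ndarray) -> np.ndarray:
    """Total mechanical energy along a trajectory of :func:`spring_chain`."""
    n = len(model.state_labels) // 2
    q = states[..., :n]
    p = states[..., n:]
    m = model.parameters["m"]
    ks = model.parameters["k"]
    kinetic = 0.5 * np.sum(p ** 2 / m, axis=-1)
    if model.parameters["anchored"]:
        ext = np.concatenate(
            [np.zeros(q.shape[:-1] + (1,)), q, np.zeros(q.shape[:-1] + (1,))],
            axis=-1)
        stretch = np.diff(ext, axis=-1)
    else:
        stretch = np.diff(q, axis=-1)
    potential = 0.5 * np.sum(ks * stretch ** 2, axis=-1)
    return kinetic + potential


# -------------------------------------------------------------------------
# Static brain-wide network graph
# -------------------------------------------------------------------------

def network_of_networks() -> DependencyGraph:
    """Static macro graph of resting-state-style brain networks.

    Two visual networks (internal) reciprocally influence the dorsal and
    ventral attention networks (active); the default-mode network (sensory)
    mediates the influence of the sensorimotor network (external) back onto
    the visual networks.  Ships as a fixed graph — a sketch of large-scale
    organisation, not an anatomical claim — with no network-level dynamics.
    The assignment is equally valid with internal and external reversed.
    """
    g = DependencyGraph()
    nodes = {
        "Vis1": "internal", "Vis2": "internal",
        "DAN": "active", "VAN": "active",
        "DMN": "sensory", "SMN": "external",
    }
    for name, role in nodes.items():
        g.add_node(StateNode(name, role=role, scale=3))
    for edge in [
        ("Vis1", "Vis2"), ("Vis2", "Vis1"),
        ("Vis1", "DAN"), ("DAN", "Vis1"),
        ("Vis1", "VAN"), ("VAN", "Vis1"),
        ("Vis2", "DAN"), ("DAN", "Vis2"),
        ("Vis2", "VAN"), ("VAN", "Vis2"),
        ("DAN", "SMN"), ("VAN", "SMN"),
        ("SMN", "DMN"),
        ("DMN", "Vis1"), ("DMN", "Vis2"),
        ("DMN", "DAN"), ("DAN", "DMN"),
        ("DMN", "VAN"), ("VAN", "DMN"),
    ]:
        g.add_edge(*edge)
    return g
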