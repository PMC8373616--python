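"""Statistical verification of blanket conditional-independence structure.

The flow constraints of a valid partition say the increment of the internal
states, given the current internal and blanket states, carries no extra
information about the external states.  Under linear dynamics, Gaussian
noise and an Euler–Maruyama trajectory this is a nested ordinary
least-squares comparison with an exact F null per internal component;
independent per-component p-values (the noise is diagonal) are combined by
Fisher's method.  A mirror test swaps the roles of internal and external.

The stationary partial correlation between internal and external states
given the blanket is also computed — as a *diagnostic* only: Jacobian
sparsity does not in general imply stationary-density independence, so no
verdict is attached to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .graph import (
    BlanketPartition,
    classify_blanket,
    validate_partition,
)
from .models import DynamicalModel
from .simulate import Trajectory, integrate, linearize, stationary_covariance

__all__ = [
    "CITestResult",
    "DegenerateDesignError",
    "dynamic_ci_test",
    "stationary_partial_correlation",
    "blanket_report",
]


class DegenerateDesignError(ValueError):
    """The regression design matrix is rank deficient."""


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one nested-regression conditional-independence test.

    ``statistic`` is the single-equation F statistic when one state is
    predicted, or Fisher's combined chi-square across equations otherwise;
    ``dof`` is the corresponding degree-of-freedom pair.  ``verdict`` is
    ``"reject"`` iff ``p_value < alpha`` (rejection = evidence of a
    dependency the partition forbids).
    """

    statistic: float
    dof: tuple[float, float]
    p_value: float
    alpha: float
    verdict: str
    predicted: tuple[str, ...]
    added: tuple[str, ...]
    conditioning: tuple[str, ...]
    n_samples: int
    per_equation: tuple[dict, ...] = ()

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "dof": list(self.dof),
            "p_value": self.p_value,
            "alpha": self.alpha,
            "verdict": self.verdict,
            "predicted": list(self.predicted),
            "added": list(self.added),
            "conditioning": list(self.conditioning),
            "n_samples": self.n_samples,
        }


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _columns(traj: Trajectory, labels: list[str]) -> np.ndarray:
    idx = [traj.state_labels.index(l) for l in labels]
    return traj.states[:, idx]


def dynamic_ci_test(
    traj: Trajectory,
    partition: BlanketPartition,
    alpha: float = 0.05,
    direction: str = "internal",
) -> CITestResult:
    """Test whether the far side of the blanket predicts this side's increment.

    ``direction="internal"`` regresses the internal increments on the
    current internal + blanket states and asks (F-test on residual sums of
    squares) whether adding the external states reduces the residual;
    ``direction="external"`` is the mirror test.  An empty far side
    degenerates to an accept with p = 1.
    """
    if direction not in ("internal", "external"):
        raise ValueError(f"direction must be 'internal' or 'external', got {direction!r}")
    state_set = set(traj.state_labels)
    near_role, far_role = (("internal", "external") if direction == "internal"
                           else ("external", "internal"))
    near = sorted(getattr(partition, near_role) & state_set)
    far = sorted(getattr(partition, far_role) & state_set)
    blanket = sorted(partition.blanket & state_set)
    conditioning = near + blanket
    n_total = len(state_set)
    n_samples = len(traj) - 1

    if not far or not near:
        return CITestResult(
            statistic=0.0, dof=(0.0, float(n_samples)), p_value=1.0,
            alpha=alpha, verdict="accept", predicted=tuple(near),
            added=tuple(far), conditioning=tuple(conditioning),
            n_samples=n_samples)

    if n_samples < 10 * n_total:
        raise ValueError(
            f"trajectory too short: {n_samples} transitions for "
            f"{n_total} states (need at least {10 * n_total})")
    if traj.model is not None:
        mu_idx = [traj.state_labels.index(l) for l in near]
        if np.any(np.asarray(traj.model.noise)[mu_idx] == 0.0):
            raise ValueError(
                f"diffusion amplitude is zero on predicted states {near}; "
                "the regression noise model does not apply")

    Y = np.diff(_columns(traj, near), axis=0)
    X_cond = _columns(traj, conditioning)[:-1]
    X_add = _columns(traj, far)[:-1]
    ones = np.ones((n_samples, 1))
    X0 = np.hstack([ones, X_cond])
    X1 = np.hstack([X0, X_add])

    # rank check on the column-normalised design so wildly different state
    # magnitudes (e.g. an unstable negative control) cannot mask columns
    norms = np.linalg.norm(X1, axis=0)
    sd = X1[:, 1:].std(axis=0)
    flat = [lab for lab, s in zip(conditioning + far, sd) if s < 1e-12]
    if flat:
        raise DegenerateDesignError(f"constant states in design: {flat}")
    rank = np.linalg.matrix_rank(X1 / np.where(norms == 0, 1.0, norms))
    if rank < X1.shape[1]:
        raise DegenerateDesignError(
            f"design matrix is rank deficient ({rank} < {X1.shape[1]}); "
            "some states are collinear")

    q = X1.shape[1] - X0.shape[1]
    dof2 = n_samples - X1.shape[1]
    per_eq = []
    pvals = []
    for i, lab in enumerate(near):
        rss0 = _ols_rss(X0, Y[:, i])
        rss1 = _ols_rss(X1, Y[:, i])
        F = ((rss0 - rss1) / q) / (rss1 / dof2)
        p = float(stats.f.sf(F, q, dof2))
        per_eq.append({"state": lab, "F": float(F), "p": p})
        pvals.append(p)

    if len(pvals) == 1:
        statistic, p_value = per_eq[0]["F"], pvals[0]
        dof = (float(q), float(dof2))
    else:
        statistic = float(-2.0 * np.sum(np.log(np.maximum(pvals, 1e-300))))
        dof = (2.0 * len(pvals), float("inf"))
        p_value = float(stats.chi2.sf(statistic, 2 * len(pvals)))

    return CITestResult(
        statistic=statistic, dof=dof, p_value=p_value, alpha=alpha,
        verdict="reject" if p_value < alpha else "accept",
        predicted=tuple(near), added=tuple(far),
        conditioning=tuple(conditioning), n_samples=n_samples,
        per_equation=tuple(per_eq))


def stationary_partial_correlation(
    Sigma: np.ndarray,
    partition: BlanketPartition,
    labels: list[str],
) -> pd.DataFrame:
    """Partial correlation of each (internal, external) pair given the blanket.

    Computed from the precision of the covariance restricted to the pair
    plus the blanket states.  Reported as a diagnostic: a valid partition
    constrains the flow, not the stationary density, so these values need
    not vanish.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.shape != (len(labels), len(labels)):
        raise ValueError("covariance shape does not match labels")
    if np.any(np.linalg.eigvalsh((Sigma + Sigma.T) / 2) <= 0):
        raise ValueError("covariance must be positive definite")
    pos = {lab: i for i, lab in enumerate(labels)}
    mu = sorted(partition.internal & set(labels))
    eta = sorted(partition.external & set(labels))
    b_idx = [pos[l] for l in sorted(partition.blanket & set(labels))]
    out = np.zeros((len(mu), len(eta)))
    for i, m in enumerate(mu):
        for j, e in enumerate(eta):
            idx = [pos[m], pos[e]] + b_idx
            P = np.linalg.inv(Sigma[np.ix_(idx, idx)])
            out[i, j] = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
    return pd.DataFrame(out, index=mu, columns=eta)


def blanket_report(
    model: DynamicalModel,
    partition: BlanketPartition,
    t_end: float = 100.0,
    dt: float | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    init: np.ndarray | None = None,
    negative_control: bool = True,
    control_weight: float = 0.5,
) -> dict:
    """One machine-readable verdict bundle for a proposed partition.

    Contains the structural violation list, the sensory/active/ambiguous
    classification, both one-step conditional-independence verdicts
    (Bonferroni-corrected across the two directions), the stationary
    partial-correlation diagnostic from the linearised dynamics, and — when
    requested — a negative control in which one forbidden external->internal
    edge is gained and the test is expected to flip to reject.
    """
    from .fixtures import perturb_add_edge  # local import avoids a cycle

    graph = model.declared_edges
    report: dict = {
        "model": model.name,
        "model_hash": model.model_hash(),
        "partition": partition.to_dict(),
        "alpha": alpha,
        "seed": seed,
    }
    violations = validate_partition(graph, partition)
    report["violations"] = [v.to_dict() for v in violations]

    sensory, active, ambiguous, cls_violations = classify_blanket(
        graph, partition.internal & graph.node_ids,
        partition.external & graph.node_ids,
        graph.node_ids - partition.internal - partition.external)
    report["classification"] = {
        "sensory": sorted(sensory), "active": sorted(active),
        "ambiguous": sorted(ambiguous),
        "violations": [v.to_dict() for v in cls_violations],
    }

    if init is None:
        init = np.zeros(model.n_states)
    n_steps = int(round(t_end / (dt or model.default_dt)))
    if n_steps < 1:
        report["ci_tests"] = {"status": "skipped",
                              "reason": "zero-length simulation"}
        return report

    dt = dt or model.default_dt
    sim_model = model if np.any(model.noise != 0.0) else model.with_noise(0.1)
    traj = integrate(sim_model, init, t_end, dt, seed=seed)
    # Bonferroni across the two tested directions
    alpha_dir = alpha / 2.0
    report["ci_tests"] = {
        "status": "done",
        "dt": dt,
        "t_end": t_end,
        "internal": dynamic_ci_test(traj, partition, alpha_dir, "internal").to_dict(),
        "external": dynamic_ci_test(traj, partition, alpha_dir, "external").to_dict(),
    }

    try:
        J, _ = linearize(model, init)
        eig = np.linalg.eigvals(J)
        report["operating_point"] = {
            "max_real_eigenvalue": float(eig.real.max()),
            "linearization_governs": bool(eig.real.max() < 0),
        }
        if eig.real.max() < 0:
            Q = np.diag(np.asarray(sim_model.noise, float) ** 2)
            Sigma = stationary_covariance(J, Q)
            pc = stationary_partial_correlation(
                Sigma, partition, list(model.state_labels))
            report["stationary_partial_correlation"] = {
                "note": "diagnostic only; flow sparsity does not bound it",
                "max_abs": float(np.abs(pc.to_numpy()).max()) if pc.size else 0.0,
                "values": pc.round(6).to_dict(),
            }
    except ValueError as err:
        report["operating_point"] = {"error": str(err)}

    if negative_control and partition.external & set(model.state_labels) \
            and partition.internal & set(model.state_labels):
        perturbed = perturb_add_edge(model, "external", "internal",
                                     weight=control_weight, seed=seed)
        pert_traj = integrate(
            perturbed if np.any(perturbed.noise != 0.0) else perturbed.with_noise(0.1),
            init, t_end, dt, seed=seed + 1)
        control = dynamic_ci_test(pert_traj, partition, alpha_dir, "internal")
        report["negative_control"] = {
            "gained_edge_rule": "eta->mu",
            "weight": control_weight,
            "violations": [v.to_dict() for v in
                           validate_partition(perturbed.declared_edges, partition)],
            "ci": control.to_dict(),
        }
    return report
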