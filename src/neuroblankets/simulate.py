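"""Seeded integration of dynamical models and linear-algebra oracles.

Deterministic models are integrated with classic fixed-step RK4; models
with any nonzero diffusion amplitude use Euler–Maruyama, whose one-step
dependency structure is exactly what the statistical verifier assumes.
Identical (model, init, dt, seed) always reproduces a bit-identical
trajectory: noise is drawn as standard-normal blocks of shape
(steps, n_states), consumed row by row in state-label order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import scipy.linalg

from .models import DynamicalModel

__all__ = [
    "Trajectory",
    "IntegrationError",
    "UnstableSystemError",
    "integrate",
    "linearize",
    "stationary_covariance",
]

_NOISE_CHUNK = 65536  # steps of pre-drawn noise per block (keeps memory flat)


class IntegrationError(RuntimeError):
    """Integration produced a non-finite state."""


class UnstableSystemError(ValueError):
    """A Lyapunov solve was requested for a non-Hurwitz matrix."""


@dataclass
class Trajectory:
    """Time-stamped simulation output.

    ``states`` is indexed (time, state) in the model's label order and
    includes the initial condition as its first row.
    """

    times: np.ndarray
    states: np.ndarray
    inputs: np.ndarray
    seed: int | None
    dt: float
    integrator: str
    state_labels: tuple[str, ...]
    input_labels: tuple[str, ...]
    model_name: str = ""
    model_hash: str = ""
    model: DynamicalModel | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times}
        for i, lab in enumerate(self.state_labels):
            data[lab] = self.states[:, i]
        for i, lab in enumerate(self.input_labels):
            data[lab] = self.inputs[:, i]
        return pd.DataFrame(data)

    def column(self, label: str) -> np.ndarray:
        return self.states[:, self.state_labels.index(label)]

    def __len__(self) -> int:
        return len(self.times)


def _check_stability_bound(model: DynamicalModel, dt: float) -> None:
    J = model.parameters.get("J")
    if J is None:
        return
    radius = np.max(np.abs(np.linalg.eigvals(np.asarray(J, float))))
    if dt * radius >= 2.0:
        warnings.warn(
            f"dt={dt} exceeds the explicit-Euler stability bound "
            f"2/rho(J)={2.0 / radius:.4g} for this linear system",
            stacklevel=3,
        )


def integrate(
    model: DynamicalModel,
    init: np.ndarray,
    t_end: float,
    dt: float,
    input_fn: Callable[[float], np.ndarray] | None = None,
    seed: int | None = 0,
) -> Trajectory:
    """Integrate ``model`` from ``init`` to ``t_end`` with fixed step ``dt``.

    RK4 when every diffusion amplitude is zero, Euler–Maruyama otherwise.
    ``input_fn(t)`` supplies the exogenous drive (zeros by default).
    Raises :class:`IntegrationError` naming the first bad time and state
    label if the state leaves the finite range.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if t_end < dt:
        raise ValueError(f"t_end={t_end} must be at least dt={dt}")
    x = np.asarray(init, dtype=float).copy()
    if x.shape != (model.n_states,):
        raise ValueError(
            f"init has shape {x.shape}, model has {model.n_states} states")
    n_steps = int(round(t_end / dt))
    _check_stability_bound(model, dt)

    if input_fn is None:
        u_const = np.zeros(model.n_inputs)
        input_fn = lambda t: u_const  # noqa: E731

    stochastic = bool(np.any(model.noise != 0.0))
    times = np.arange(n_steps + 1) * dt
    states = np.empty((n_steps + 1, model.n_states))
    inputs = np.empty((n_steps + 1, model.n_inputs))
    states[0] = x

    def fail_if_bad(row: np.ndarray, t: float) -> None:
        if not np.all(np.isfinite(row)):
            bad = model.state_labels[int(np.argmax(~np.isfinite(row)))]
            raise IntegrationError(
                f"non-finite state {bad!r} at t={t:.6g} "
                f"(integrator {'euler-maruyama' if stochastic else 'rk4'})")

    if stochastic:
        rng = np.random.default_rng(seed)
        amp = model.noise
        sqrt_dt = np.sqrt(dt)
        noise_block = np.empty((0, model.n_states))
        offset = 0
        for k in range(n_steps):
            if offset >= len(noise_block):
                noise_block = rng.standard_normal(
                    (min(_NOISE_CHUNK, n_steps - k), model.n_states))
                offset = 0
            t = times[k]
            u = np.asarray(input_fn(t), dtype=float)
            inputs[k] = u
            x = x + model.flow(x, u, model.parameters) * dt \
                + amp * sqrt_dt * noise_block[offset]
            offset += 1
            fail_if_bad(x, times[k + 1])
            states[k + 1] = x
        integrator = "euler-maruyama"
    else:
        for k in range(n_steps):
            t = times[k]
            u = np.asarray(input_fn(t), dtype=float)
            inputs[k] = u
            p = model.parameters
            k1 = model.flow(x, u, p)
            u_mid = np.asarray(input_fn(t + dt / 2), dtype=float)
            k2 = model.flow(x + dt / 2 * k1, u_mid, p)
            k3 = model.flow(x + dt / 2 * k2, u_mid, p)
            k4 = model.flow(x + dt * k3,
                            np.asarray(input_fn(t + dt), dtype=float), p)
            x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            fail_if_bad(x, times[k + 1])
            states[k + 1] = x
        integrator = "rk4"
    inputs[n_steps] = np.asarray(input_fn(times[n_steps]), dtype=float)

    return Trajectory(
        times=times,
        states=states,
        inputs=inputs,
        seed=seed,
        dt=dt,
        integrator=integrator,
        state_labels=tuple(model.state_labels),
        input_labels=tuple(model.input_labels),
        model_name=model.name,
        model_hash=model.model_hash(),
        model=model,
    )


def linearize(
    model: DynamicalModel,
    point: np.ndarray,
    u: np.ndarray | None = None,
    eps: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference Jacobian and affine offset of the flow at a point.

    Returns ``(J, f0)`` with ``f(x) ~= f0 + J (x - point)``.  The Jacobian's
    off-diagonal sparsity is a subset of the declared dependency graph for a
    correctly declared model.
    """
    point = np.asarray(point, dtype=float)
    u = np.zeros(model.n_inputs) if u is None else np.asarray(u, dtype=float)
    f0 = model.flow_at(point, u)
    if not np.all(np.isfinite(f0)):
        raise ValueError(f"flow is non-finite at {point.tolist()}")
    n = model.n_states
    J = np.empty((n, n))
    for j in range(n):
        xp, xm = point.copy(), point.copy()
        xp[j] += eps
        xm[j] -= eps
        col = (model.flow_at(xp, u) - model.flow_at(xm, u)) / (2 * eps)
        if not np.all(np.isfinite(col)):
            raise ValueError(
                f"non-finite derivative wrt {model.state_labels[j]!r}")
        J[:, j] = col
    return J, f0


def stationary_covariance(J: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Stationary covariance of ``dx = J x dt + dW`` with diffusion ``Q``.

    Solves the continuous Lyapunov equation ``J S + S J' + Q = 0``.  ``J``
    must be Hurwitz (all eigenvalues in the open left half-plane); the
    result is symmetrised and positive semi-definite.
    """
    J = np.asarray(J, dtype=float)
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    eig = np.linalg.eigvals(J)
    bad = eig[eig.real >= 0]
    if len(bad):
        raise UnstableSystemError(
            "stationary covariance requires a stable drift matrix; "
            f"eigenvalues with non-negative real part: {bad.tolist()}")
    S = scipy.linalg.solve_continuous_lyapunov(J, -Q)
    return (S + S.T) / 2.0
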