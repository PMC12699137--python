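"""Episodic rollouts of kinetic models under piecewise-constant control.

A kinetic model becomes a Markov decision process by holding the input
constant over each interval of an equidistant :class:`ControlGrid` and
integrating the ODE system across the interval.  Per-episode domain
randomization perturbs named initial conditions and parameters with
zero-mean Gaussians whose standard deviation is a fraction (the
"uncertainty level") of the nominal value; the draw is fixed for the
whole episode.

For speed, a whole batch of episodes is integrated as one stacked ODE
system (block-diagonal in the episodes), so adaptive error control and
the LSODA stiff path are shared across the batch.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import KineticModel
from .objectives import ObjectiveSpec, step_rewards

__all__ = [
    "ControlGrid",
    "RandomizationSpec",
    "Trajectory",
    "EpisodeBatch",
    "IntegrationError",
    "integrate_interval",
    "sample_disturbance",
    "rollout",
    "rollout_batch",
    "write_trajectory",
]

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9


class IntegrationError(RuntimeError):
    """ODE solver failed to converge over a control interval."""


@dataclass(frozen=True)
class ControlGrid:
    """Equidistant control grid: ``n_intervals`` intervals on [t0, t_end]."""

    t_end: float
    n_intervals: int
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.t_end <= self.t0:
            raise ValueError("t_end must exceed t0")
        if self.n_intervals < 1:
            raise ValueError("need at least one control interval")

    @property
    def dt(self) -> float:
        return (self.t_end - self.t0) / self.n_intervals

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_intervals + 1)


@dataclass(frozen=True)
class RandomizationSpec:
    """Disturbance law for domain randomization.

    ``level`` is the relative uncertainty: each named target q is
    perturbed as q + N(0, (level*q)^2), independently per episode, with
    negative draws clamped to zero.  ``initials``/``parameters`` default
    to the model's own randomization targets; ``level=0`` reproduces the
    deterministic system exactly.
    """

    level: float = 0.0
    initials: tuple[str, ...] | None = None
    parameters: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("uncertainty level must be non-negative")
        for attr in ("initials", "parameters"):
            v = getattr(self, attr)
            if v is not None:
                object.__setattr__(self, attr, tuple(v))

    def resolve(self, model: KineticModel) -> tuple[tuple[str, ...], tuple[str, ...]]:
        initials = self.initials if self.initials is not None else model.randomizable_initials
        params = self.parameters if self.parameters is not None else model.randomizable_params
        for name in initials:
            if name not in model.state_names:
                raise KeyError(f"unknown initial-condition target {name!r} for {model.name}")
        for name in params:
            if name not in model.params.__dataclass_fields__:
                raise KeyError(f"unknown parameter target {name!r} for {model.name}")
        return tuple(initials), tuple(params)


def sample_disturbance(
    spec: RandomizationSpec,
    model: KineticModel,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw per-episode initial conditions and parameters.

    Returns ``(x0, params)`` where ``x0`` has shape (n_states,) or
    (size, n_states) and ``params`` is a parameter dataclass whose
    perturbed fields are scalars or arrays of length ``size``.  Targets
    with nominal value zero are left at zero under the relative-sigma
    law.  Nominal-state couplings (e.g. the fatty-acid tie S0 = 1 - X0*)
    enter only through the nominal ``model.x0``; each targeted initial
    condition is perturbed independently around its nominal value.
    """
    initials, param_names = spec.resolve(model)
    k = 1 if size is None else size

    x0 = np.tile(model.x0, (k, 1))
    for name in initials:
        i = model.state_index(name)
        sigma = spec.level * model.x0[i]
        x0[:, i] = np.maximum(model.x0[i] + rng.normal(0.0, sigma, size=k), 0.0)

    updates = {}
    for name in param_names:
        nominal = getattr(model.params, name)
        draw = np.maximum(nominal + rng.normal(0.0, spec.level * nominal, size=k), 0.0)
        updates[name] = float(draw[0]) if size is None else draw
    params = dataclasses.replace(model.params, **updates) if updates else model.params

    return (x0[0] if size is None else x0), params


def integrate_interval(
    model: KineticModel,
    x: np.ndarray,
    u,
    dt: float,
    params=None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str | None = None,
) -> np.ndarray:
    """Advance state(s) ``x`` by ``dt`` hours with the input held constant.

    ``x`` may be a single state (n_states,) or a batch (k, n_states)
    with per-episode inputs/parameters; the batch is integrated as one
    block-diagonal system.  The returned state is clamped non-negative
    (the dynamics cannot cross zero except by integration noise).
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    x = np.asarray(x, dtype=float)
    if dt == 0:
        return x.copy()
    single = x.ndim == 1
    xb = x[None, :] if single else x
    k, n = xb.shape
    p = model.params if params is None else params
    u = np.asarray(u, dtype=float)

    def f(_t, y):
        return model.rhs(y.reshape(k, n), u, p).ravel()

    method = method or model.solver
    options = {}
    if method in ("LSODA", "BDF", "Radau"):
        # the batch system is block-diagonal with n x n blocks
        if method == "LSODA":
            options = {"lband": n - 1, "uband": n - 1}
    sol = solve_ivp(f, (0.0, dt), xb.ravel(), method=method, rtol=rtol, atol=atol, **options)
    if not sol.success:
        raise IntegrationError(
            f"{method} failed over dt={dt} for model {model.name}: {sol.message}"
        )
    out = np.maximum(sol.y[:, -1].reshape(k, n), 0.0)
    return out[0] if single else out


@dataclass
class Trajectory:
    """One episode: states on the grid nodes, applied inputs and rewards.

    ``states`` has shape (N+1, n_states); ``inputs``, ``rewards`` and the
    policy records (features, raw pre-clip inputs, Gaussian moments and
    log-densities of the sampled actions) have length N.  ``params`` and
    ``x0`` record the realized disturbance draw.
    """

    model: KineticModel
    times: np.ndarray
    states: np.ndarray
    inputs: np.ndarray
    rewards: np.ndarray
    params: object
    features: np.ndarray | None = None
    raw_inputs: np.ndarray | None = None
    means: np.ndarray | None = None
    sigmas: np.ndarray | None = None
    log_pdfs: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.inputs)
        if len(self.states) != n + 1 or len(self.rewards) != n:
            raise ValueError("inconsistent trajectory lengths")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def total_return(self) -> float:
        return float(self.rewards.sum())

    @property
    def final_titer(self) -> float:
        return float(self.model.titer(self.states[-1], self.params))


@dataclass
class EpisodeBatch:
    """A batch of N_MC episodes rolled out under one policy (one epoch)."""

    model: KineticModel
    times: np.ndarray
    states: np.ndarray      # (k, N+1, n_states)
    inputs: np.ndarray      # (k, N)
    rewards: np.ndarray     # (k, N)
    x0: np.ndarray          # (k, n_states)
    params: object          # fields scalar or (k,)
    features: np.ndarray | None = None   # (k, N, n_features)
    raw_inputs: np.ndarray | None = None
    means: np.ndarray | None = None
    sigmas: np.ndarray | None = None
    log_pdfs: np.ndarray | None = None

    @property
    def n_episodes(self) -> int:
        return self.states.shape[0]

    @property
    def returns(self) -> np.ndarray:
        return self.rewards.sum(axis=1)

    def final_titers(self) -> np.ndarray:
        return np.asarray(self.model.titer(self.states[:, -1, :], self.params))

    def episode(self, i: int) -> Trajectory:
        p = self.params
        fields = {
            name: np.asarray(getattr(p, name))[i]
            if np.ndim(getattr(p, name)) > 0
            else getattr(p, name)
            for name in p.__dataclass_fields__
        }
        take = lambda a: None if a is None else a[i]
        return Trajectory(
            model=self.model,
            times=self.times,
            states=self.states[i],
            inputs=self.inputs[i],
            rewards=self.rewards[i],
            params=dataclasses.replace(p, **fields),
            features=take(self.features),
            raw_inputs=take(self.raw_inputs),
            means=take(self.means),
            sigmas=take(self.sigmas),
            log_pdfs=take(self.log_pdfs),
        )


def rollout_batch(
    policy,
    model: KineticModel,
    grid: ControlGrid,
    spec: RandomizationSpec,
    objective: ObjectiveSpec,
    rng: np.random.Generator,
    n_episodes: int,
    deterministic_actions: bool = False,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> EpisodeBatch:
    """Roll out ``n_episodes`` episodes in lockstep under one policy.

    Each episode draws its own disturbance once, then alternates feature
    construction, action sampling and interval integration over the
    grid.  With ``deterministic_actions`` the policy's mean action is
    applied instead of sampling.
    """
    objective.check_grid(grid.n_intervals)
    k, n_int = n_episodes, grid.n_intervals
    x0, params = sample_disturbance(spec, model, rng, size=k)

    states = np.empty((k, n_int + 1, model.n_states))
    states[:, 0] = x0
    inputs = np.empty((k, n_int))
    needs_features = getattr(policy, "needs_features", False)
    feats = np.empty((k, n_int, policy.n_features)) if needs_features else None
    raws = np.empty((k, n_int))
    means = np.empty((k, n_int))
    sigmas = np.empty((k, n_int))
    lps = np.empty((k, n_int))

    prev_x = x0
    prev_u = np.zeros(k)
    prev2_u = np.zeros(k)
    for t in range(n_int):
        x_t = states[:, t]
        if needs_features:
            s_t = policy.features(x_t, prev_x, prev_u, prev2_u, t, grid)
            feats[:, t] = s_t
        else:
            s_t = None
        u_applied, u_raw, m_t, sig_t, lp = policy.act(
            s_t, rng, n=k, deterministic=deterministic_actions
        )
        inputs[:, t] = u_applied
        raws[:, t] = u_raw
        means[:, t] = m_t
        sigmas[:, t] = sig_t
        lps[:, t] = lp

        states[:, t + 1] = integrate_interval(
            model, x_t, u_applied, grid.dt, params=params, rtol=rtol, atol=atol
        )
        prev_x, prev2_u, prev_u = x_t, prev_u, u_applied

    rewards = step_rewards(states, model, objective, params)
    return EpisodeBatch(
        model=model,
        times=grid.times(),
        states=states,
        inputs=inputs,
        rewards=rewards,
        x0=x0,
        params=params,
        features=feats,
        raw_inputs=raws,
        means=means,
        sigmas=sigmas,
        log_pdfs=lps,
    )


def rollout(
    policy,
    model: KineticModel,
    grid: ControlGrid,
    spec: RandomizationSpec,
    objective: ObjectiveSpec,
    rng: np.random.Generator,
    deterministic_actions: bool = False,
    **solver_opts,
) -> Trajectory:
    """Roll out a single episode (batch of one)."""
    batch = rollout_batch(
        policy, model, grid, spec, objective, rng, n_episodes=1,
        deterministic_actions=deterministic_actions, **solver_opts,
    )
    return batch.episode(0)


def write_trajectory(traj: Trajectory, path: str | Path, episode: int = 0,
                     sidecar: dict | None = None) -> None:
    """Write a trajectory as tidy CSV plus a JSON sidecar with the realized draw.

    The CSV holds one row per grid node with state columns named after
    the model states; input and reward are attached to the interval
    *starting* at the row's time (blank on the final node).
    """
    path = Path(path)
    n = len(traj.inputs)
    frame = pd.DataFrame({"episode": episode, "step": np.arange(n + 1), "time_h": traj.times})
    for i, name in enumerate(traj.model.state_names):
        frame[name] = traj.states[:, i]
    frame["input"] = np.append(traj.inputs, np.nan)
    frame["reward"] = np.append(traj.rewards, np.nan)
    frame.to_csv(path, index=False)

    record = {
        "model": traj.model.name,
        "x0": traj.states[0].tolist(),
        "params": {
            k: float(np.asarray(getattr(traj.params, k)))
            for k in traj.params.__dataclass_fields__
        },
    }
    if sidecar:
        record.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(record, indent=2))
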