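"""Return functions for the control objectives.

Two objectives are supported:

* ``terminal_titer`` — maximize the final product concentration (g/L);
  the economic objective.  All reward mass is assigned to the last
  control interval, so the trajectory return equals the final titer.
* ``reference_tracking`` — follow a predefined "golden-batch" enzyme
  trajectory; the per-step reward is the negative squared deviation of
  the enzyme level from its reference, so the (non-positive) return is
  the negative summed squared tracking error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ObjectiveSpec", "step_rewards", "compute_return"]

KINDS = ("terminal_titer", "reference_tracking")


@dataclass(frozen=True)
class ObjectiveSpec:
    """Which scalar return a trajectory is scored by.

    For ``reference_tracking`` the reference sequence holds the target
    enzyme levels E_r at the ends of control intervals 1..N_x, and
    ``tracked_state`` names the state being tracked.
    """

    kind: str
    reference: np.ndarray | None = None
    tracked_state: str = "E"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"objective kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == "reference_tracking":
            if self.reference is None:
                raise ValueError("reference_tracking requires a reference sequence")
            object.__setattr__(self, "reference", np.asarray(self.reference, dtype=float))

    def check_grid(self, n_intervals: int) -> None:
        if self.kind == "reference_tracking" and len(self.reference) != n_intervals:
            raise ValueError(
                f"reference length {len(self.reference)} does not match "
                f"{n_intervals} control intervals"
            )


def step_rewards(states: np.ndarray, model, objective: ObjectiveSpec, params=None) -> np.ndarray:
    """Per-interval rewards R_1..R_N for a (batch of) state path(s).

    ``states`` has shape (..., N+1, n_states); the result has shape
    (..., N).
    """
    states = np.asarray(states, dtype=float)
    n = states.shape[-2] - 1
    objective.check_grid(n)
    rewards = np.zeros(states.shape[:-2] + (n,))
    if objective.kind == "terminal_titer":
        rewards[..., -1] = model.titer(states[..., -1, :], params)
    else:
        idx = model.state_index(objective.tracked_state)
        err = states[..., 1:, idx] - objective.reference
        rewards[...] = -(err**2)
    return rewards


def compute_return(trajectory, objective: ObjectiveSpec, model=None) -> float:
    """Scalar return J(tau) of a completed trajectory.

    Recomputed from the stored states (not from the cached rewards), so
    it can serve as an independent check on the rollout bookkeeping.
    """
    from .episodes import Trajectory  # circular-safe, typing only

    assert isinstance(trajectory, Trajectory)
    model = model if model is not None else trajectory.model
    return float(
        step_rewards(trajectory.states, model, objective, trajectory.params).sum()
    )
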