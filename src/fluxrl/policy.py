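"""Stochastic Gaussian control policies.

The policy maps a featurized process state to the mean and standard
deviation of a Gaussian over the scalar control input.  Features are the
two most recent state-input pairs plus a linear process-time embedding,
affinely normalized to [-1, 1].  The network outputs are squashed with a
logistic map so that, for *any* weights, the mean lies inside the input
bounds and the standard deviation inside (0, sigma_cap] with
sigma_cap = 0.25 * input range — bound satisfaction by construction,
never by clipping the distribution.

Sampling draws from the unclipped Gaussian; the applied input is clipped
to the bounds but the stored log-density is evaluated at the pre-clip
sample, keeping the score-function estimator consistent with the
distribution the agent actually sampled from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .episodes import ControlGrid, RandomizationSpec, rollout_batch
from .kinetics import ControlBounds, KineticModel
from .nn import MLP
from .objectives import ObjectiveSpec

__all__ = [
    "FeatureScales",
    "build_features",
    "GaussianMLPPolicy",
    "StaticPolicy",
    "default_feature_scales",
]

LOG_2PI = float(np.log(2.0 * np.pi))
HIDDEN_LAYERS = (20, 20, 20, 20)
SIGMA_CAP_FRACTION = 0.25
# relative floor of the sigma squash: keeps sigma strictly positive even
# when the logistic underflows at saturated network outputs
SIGMA_FLOOR = 1e-9
LEAKY_SLOPE = 0.01
# the output layer starts downscaled so every fresh policy begins near the
# mid-range mean and half-cap sigma instead of a randomly saturated head;
# this removes an initialization-dependent failure mode of the ascent
OUTPUT_INIT_SCALE = 0.1


@dataclass(frozen=True)
class FeatureScales:
    """Per-state normalization ranges [0, smax] used for featurization."""

    state_max: np.ndarray

    def __post_init__(self) -> None:
        sm = np.asarray(self.state_max, dtype=float)
        if np.any(sm <= 0):
            raise ValueError("feature scale ranges must be strictly positive")
        object.__setattr__(self, "state_max", sm)


def default_feature_scales(
    model: KineticModel,
    grid: ControlGrid,
    u_const: float | None = None,
    margin: float = 1.5,
    floor: float = 1e-6,
) -> FeatureScales:
    """Feature scales from a deterministic static-control rollout.

    Each state's range is [0, margin * max over the rollout], floored to
    keep identically-zero states well-defined.
    """
    pol = StaticPolicy(model.static_input if u_const is None else u_const, model.bounds)
    batch = rollout_batch(
        pol, model, grid, RandomizationSpec(0.0),
        ObjectiveSpec("terminal_titer"), np.random.default_rng(0), n_episodes=1,
    )
    smax = margin * batch.states[0].max(axis=0)
    return FeatureScales(np.maximum(smax, floor))


def build_features(
    x_t: np.ndarray,
    x_prev: np.ndarray,
    u_prev: np.ndarray,
    u_prev2: np.ndarray,
    t: int,
    grid: ControlGrid,
    scales: FeatureScales,
    bounds: ControlBounds,
) -> np.ndarray:
    """Featurize the two most recent state-input pairs plus a time embedding.

    Layout: [x_t, u_{t-1}, x_{t-1}, u_{t-2}, time], every entry affinely
    mapped to [-1, 1] and clipped; length 2*(n_states+1)+1.  At t=0 the
    missing earlier pair repeats the initial state with a zero input.
    """
    if not 0 <= t < grid.n_intervals:
        raise ValueError(f"step {t} outside grid with {grid.n_intervals} intervals")
    x_t = np.atleast_2d(x_t)
    x_prev = np.atleast_2d(x_prev)

    def scale_x(x):
        return np.clip(2.0 * x / scales.state_max - 1.0, -1.0, 1.0)

    def scale_u(u):
        return np.clip(2.0 * (np.asarray(u) - bounds.lower) / bounds.width - 1.0, -1.0, 1.0)

    k = x_t.shape[0]
    u1 = np.broadcast_to(np.atleast_1d(scale_u(u_prev)), (k,))
    u2 = np.broadcast_to(np.atleast_1d(scale_u(u_prev2)), (k,))
    denom = max(grid.n_intervals - 1, 1)
    t_embed = np.full(k, 2.0 * t / denom - 1.0)
    return np.concatenate(
        [scale_x(x_t), u1[:, None], scale_x(x_prev), u2[:, None], t_embed[:, None]],
        axis=1,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def gaussian_log_pdf(u: np.ndarray, m: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    z = (u - m) / sigma
    return -0.5 * z**2 - np.log(sigma) - 0.5 * LOG_2PI


class GaussianMLPPolicy:
    """Gaussian policy with a 4x20 leaky-rectifier network head.

    The two network outputs are squashed: mean = lb + range*logistic(a),
    sigma = sigma_cap*logistic(b).
    """

    needs_features = True

    def __init__(
        self,
        model: KineticModel,
        grid: ControlGrid,
        scales: FeatureScales | None = None,
        hidden: tuple[int, ...] = HIDDEN_LAYERS,
        sigma_cap_fraction: float = SIGMA_CAP_FRACTION,
        rng: np.random.Generator | int | None = None,
    ) -> None:
        self.bounds = model.bounds
        self.grid = grid
        self.scales = scales if scales is not None else default_feature_scales(model, grid)
        if len(self.scales.state_max) != model.n_states:
            raise ValueError("feature scales do not match the model state dimension")
        self.sigma_cap = sigma_cap_fraction * self.bounds.width
        self.n_features = 2 * (model.n_states + 1) + 1
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.mlp = MLP([self.n_features, *hidden, 2], rng, negative_slope=LEAKY_SLOPE)
        self.mlp.params[-2] *= OUTPUT_INIT_SCALE
        self._meta = {
            "model": model.name,
            "hidden": list(hidden),
            "sigma_cap_fraction": sigma_cap_fraction,
        }
        self._model = model

    # -- distribution -------------------------------------------------------

    def features(self, x_t, x_prev, u_prev, u_prev2, t, grid) -> np.ndarray:
        return build_features(x_t, x_prev, u_prev, u_prev2, t, grid, self.scales, self.bounds)

    def action_distribution(self, feats: np.ndarray, cache: list | None = None):
        """Map features (n, n_features) to Gaussian moments (m, sigma)."""
        feats = np.atleast_2d(feats)
        if feats.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {feats.shape[1]} != network input {self.n_features}"
            )
        raw = self.mlp.forward(feats, cache=cache)
        m = self.bounds.lower + self.bounds.width * _sigmoid(raw[:, 0])
        sigma = self.sigma_cap * (SIGMA_FLOOR + (1.0 - SIGMA_FLOOR) * _sigmoid(raw[:, 1]))
        return m, sigma

    def act(self, feats, rng: np.random.Generator, n: int | None = None,
            deterministic: bool = False):
        """Sample an action per feature row.

        Returns (u_applied, u_raw, mean, sigma, log_pdf); ``u_applied``
        is the raw Gaussian sample clipped to the bounds, while the
        log-density refers to the unclipped sample.
        """
        m, sigma = self.action_distribution(feats)
        if deterministic:
            u_raw = m.copy()
        else:
            u_raw = rng.normal(m, sigma)
        u_applied = np.clip(u_raw, self.bounds.lower, self.bounds.upper)
        return u_applied, u_raw, m, sigma, gaussian_log_pdf(u_raw, m, sigma)

    # -- gradients ----------------------------------------------------------

    def grad_log_policy(
        self,
        feats: np.ndarray,
        u_raw: np.ndarray,
        sample_weights: np.ndarray | None = None,
    ) -> list[np.ndarray]:
        """Gradient of sum_i w_i * log pi(u_i | s_i) w.r.t. the network weights.

        ``feats`` (n, n_features) and ``u_raw`` (n,) are the stored
        per-step records; with unit weights this is the exact gradient
        of the summed log-densities, as verified against finite
        differences.
        """
        feats = np.atleast_2d(feats)
        u_raw = np.asarray(u_raw, dtype=float)
        if feats.shape[0] != u_raw.shape[0]:
            raise ValueError("mismatched feature/action records")
        if u_raw.size == 0:
            return [np.zeros_like(p) for p in self.mlp.params]
        w = np.ones_like(u_raw) if sample_weights is None else np.asarray(sample_weights)

        cache: list = []
        raw = self.mlp.forward(feats, cache=cache)
        sa = _sigmoid(raw[:, 0])
        sb = _sigmoid(raw[:, 1])
        m = self.bounds.lower + self.bounds.width * sa
        sigma = self.sigma_cap * (SIGMA_FLOOR + (1.0 - SIGMA_FLOOR) * sb)
        z = (u_raw - m) / sigma

        d_m = z / sigma                      # d log pi / d m
        d_sigma = (z**2 - 1.0) / sigma       # d log pi / d sigma
        d_raw = np.stack(
            [
                w * d_m * self.bounds.width * sa * (1.0 - sa),
                w * d_sigma * self.sigma_cap * (1.0 - SIGMA_FLOOR) * sb * (1.0 - sb),
            ],
            axis=1,
        )
        return self.mlp.backward(cache, d_raw)

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a lossless JSON checkpoint (weights + metadata)."""
        doc = {
            "format": "fluxrl-policy-v1",
            **self._meta,
            "bounds": [self.bounds.lower, self.bounds.upper],
            "grid": {"t_end": self.grid.t_end, "n_intervals": self.grid.n_intervals,
                     "t0": self.grid.t0},
            "feature_scales": self.scales.state_max.tolist(),
            "weights": self.mlp.get_flat().tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path, model: KineticModel) -> "GaussianMLPPolicy":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "fluxrl-policy-v1":
            raise ValueError(f"{path} is not a policy checkpoint")
        if doc["model"] != model.name:
            raise ValueError(f"checkpoint was trained on {doc['model']!r}, not {model.name!r}")
        grid = ControlGrid(**doc["grid"])
        pol = cls(
            model,
            grid,
            scales=FeatureScales(np.array(doc["feature_scales"])),
            hidden=tuple(doc["hidden"]),
            sigma_cap_fraction=doc["sigma_cap_fraction"],
            rng=0,
        )
        pol.mlp.set_flat(np.array(doc["weights"]))
        return pol


class StaticPolicy:
    """Degenerate policy emitting one constant input with zero variance."""

    needs_features = False

    def __init__(self, u_const: float, bounds: ControlBounds) -> None:
        if not bounds.lower <= u_const <= bounds.upper:
            raise ValueError(
                f"constant input {u_const} outside bounds [{bounds.lower}, {bounds.upper}]"
            )
        self.u_const = float(u_const)
        self.bounds = bounds

    def act(self, feats, rng, n: int | None = None, deterministic: bool = False):
        k = 1 if n is None else n
        u = np.full(k, self.u_const)
        return u, u.copy(), u.copy(), np.zeros(k), np.zeros(k)
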