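"""Kinetic batch-fermentation models used as surrogate control environments.

Two fully parameterized *E. coli* case studies are shipped:

* :class:`FattyAcidModel` — fatty-acid biosynthesis with inducible
  acetyl-CoA carboxylase (ACC).  ACC converts acetyl-CoA to malonyl-CoA,
  the fatty-acid precursor, but accumulating ACC is cytotoxic: Hill-type
  toxicity factors reduce both growth (``TX``) and, above a threshold
  ``Etox``, product formation (``TP``).  All dynamic states are
  normalized dimensionless variables; ``HX``/``HP`` convert biomass and
  product to relative OD600 units and g/L.

* :class:`LactateModel` — anaerobic lactate fermentation with
  light-inducible F1-ATPase expression.  ATP hydrolysis ("ATP wasting")
  raises glucose uptake and lactate flux while suppressing growth,
  giving a tunable growth/production trade-off.

Every rate function here is pure, deterministic and vectorized over
leading array dimensions, so a whole batch of randomized episodes can be
integrated as one stacked ODE system.  Parameter fields may therefore be
scalars or arrays of per-episode values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Any

import numpy as np
import yaml

__all__ = [
    "ControlBounds",
    "FattyAcidParams",
    "LactateParams",
    "KineticModel",
    "FattyAcidModel",
    "LactateModel",
    "fa_toxicity",
    "fa_growth_rate",
    "fa_rhs",
    "fa_observables",
    "lac_rates",
    "lac_rhs",
    "fatty_acid_model",
    "lactate_model",
    "load_parameter_file",
]


def _pos(x: np.ndarray) -> np.ndarray:
    """Clamp to the physical (non-negative) domain before rate evaluation."""
    return np.maximum(x, 0.0)


def hill(x, K, n):
    """Hill activation x^n / (K^n + x^n), with the continuous extension 0 at x=0.

    ``0**n`` is 0 for any n > 0 under numpy, which matches the
    continuous-extension convention used for the near-zero Hill
    exponents of the lactate model (e.g. n1 = 0.01).
    """
    with np.errstate(over="ignore", invalid="ignore"):
        xn = np.power(_pos(x), n)
        out = xn / (np.power(K, n) + xn)
    # x^n overflows to inf for extreme x: the saturated limit is 1
    return np.where(np.isinf(xn), 1.0, out)


@dataclass(frozen=True)
class ControlBounds:
    """Admissible range of the scalar control input."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower < self.upper):
            raise ValueError(f"require 0 <= lower < upper, got [{self.lower}, {self.upper}]")

    @property
    def width(self) -> float:
        return self.upper - self.lower


# ---------------------------------------------------------------------------
# fatty-acid / ACC model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FattyAcidParams:
    """Constant parameter vector of the fatty-acid/ACC model.

    Units: rate constants in 1/h, ``KI`` in uM inducer, ``HP`` in g/L per
    dimensionless product unit; everything else dimensionless.
    """

    kX: float
    kE: float
    kM: float
    kP: float
    kR1: float
    mu_d: float
    TXmax: float
    Etox: float
    dE: float
    dR: float
    KTX: float
    KTP: float
    KR0: float
    KI: float
    KSP: float
    nTX: float
    nTP: float
    nR: float
    nI: float
    HX: float
    HP: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"parameter {name} must be non-negative")
        if np.any(np.asarray(self.TXmax) > 1):
            raise ValueError("TXmax must lie in [0, 1]")
        for name in ("Etox", "HX", "HP", "nTX", "nTP", "nR", "nI"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"parameter {name} must be positive")


def fa_toxicity(E, p: FattyAcidParams):
    """Toxicity factors (TX, TP) of intracellular ACC level ``E``.

    TX is Hill-type growth toxicity saturating at ``TXmax``; TP is the
    piecewise product-formation toxicity, zero below the threshold
    ``Etox`` and Hill-activated in the excess ``E - Etox`` above it
    (continuous at the threshold).
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("enzyme level E must be non-negative")
    TX = p.TXmax * hill(E, p.KTX, p.nTX)
    TP = hill(_pos(E - p.Etox), p.KTP, p.nTP)
    return TX, TP


def fa_growth_rate(S, E, p: FattyAcidParams):
    """Specific growth rate mu = kX * S * (1 - TX(E))  [1/h]."""
    TX, _ = fa_toxicity(E, p)
    return p.kX * _pos(S) * (1.0 - TX)


def fa_rhs(x, u, p: FattyAcidParams):
    """Right-hand side of the fatty-acid/ACC ODE system.

    State order: (S, X*, E, M, R, P*) — glucose, biomass, ACC,
    malonyl-CoA, LacI and fatty acid, all dimensionless.  ``u`` is the
    inducer level (uM IPTG-equivalent); inducer binding releases LacI
    repression of ACC expression via the factor R / (1 + (u/KI)^nI).
    Vectorized over leading dimensions of ``x`` (shape (..., 6)).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state passed to fa_rhs")
    S, Xb, E, M, R, _P = (_pos(x[..., i]) for i in range(6))
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("control input must be non-negative")

    TX, TP = fa_toxicity(E, p)
    mu = p.kX * S * (1.0 - TX)
    R_free = R / (1.0 + np.power(u / p.KI, p.nI))

    dS = -mu * Xb
    dXb = mu * Xb - p.mu_d * Xb
    # repression Hill in free LacI: KR0^nR / (KR0^nR + R_free^nR)
    dE = p.kE * (1.0 - hill(R_free, p.KR0, p.nR)) - (p.dE + mu) * E
    dM = p.kM * E - p.kP * M - mu * M
    dR = p.kR1 - (p.dR + mu) * R
    dP = p.kP * M * Xb * S / (p.KSP + S) * (1.0 - TP)
    return np.stack([dS, dXb, dE, dM, dR, dP], axis=-1)


def fa_observables(x, p: FattyAcidParams):
    """Map dimensionless (X*, P*) to measured units: X = HX*X* (relative
    OD600), P = HP*P* (g/L)."""
    x = np.asarray(x, dtype=float)
    return p.HX * x[..., 1], p.HP * x[..., 5]


# ---------------------------------------------------------------------------
# lactate / ATPase model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LactateParams:
    """Constant parameter vector of the lactate/ATPase model.

    ``S``, ``X``, ``L`` are carried in g/L and the ATPase level ``E`` in
    virtual units per gram biomass (VU/g); see the shipped parameter
    file for per-field units.
    """

    qSmax: float
    kS: float
    kSV: float
    n1: float
    mS: float
    kXV: float
    n2: float
    YXS: float
    YLX: float
    mL: float
    kLS: float
    kLV: float
    n3: float
    qE0: float
    qEmax: float
    kl: float
    n4: float
    kd: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"parameter {name} must be non-negative")
        for name in ("kd", "n1", "n2", "n3", "n4"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"parameter {name} must be positive")


def lac_rates(x, u, p: LactateParams):
    """Specific rates (qS, mu, qL, qE) of the lactate/ATPase model.

    qS — glucose uptake, boosted up to two-fold by ATPase (ATP wasting);
    mu — growth, suppressed by ATPase; qL — lactate synthesis
    (growth-associated plus ATPase-boosted maintenance term, gated off
    at substrate exhaustion); qE — light-driven ATPase expression.
    """
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(x < 0) or np.any(u < 0):
        raise ValueError("states and input of the lactate model must be non-negative")
    S, _X, _L, E = (x[..., i] for i in range(4))

    qS = p.qSmax * S / (S + p.kS) * (1.0 + hill(E, p.kSV, p.n1))
    mu = p.YXS * (qS - p.mS) * (1.0 - hill(E, p.kXV, p.n2))
    qL = p.YLX * mu + p.mL * S / (S + p.kLS) * (1.0 + hill(E, p.kLV, p.n3))
    qE = p.qE0 + p.qEmax * hill(u, p.kl, p.n4)
    return qS, mu, qL, qE


def lac_rhs(x, u, p: LactateParams):
    """Right-hand side of the lactate/ATPase ODE system.

    State order: (S, X, L, E).  ``u`` is the green-light photon flux in
    umol m^-2 s^-1.  Vectorized over leading dimensions of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state passed to lac_rhs")
    xc = _pos(x)
    qS, mu, qL, qE = lac_rates(xc, u, p)
    X = xc[..., 1]
    return np.stack([-qS * X, mu * X, qL * X, qE - p.kd * xc[..., 3]], axis=-1)


# ---------------------------------------------------------------------------
# model wrapper
# ---------------------------------------------------------------------------

@dataclass
class KineticModel:
    """A kinetic environment: RHS, nominal parameters/initial state and metadata.

    ``randomizable_initials`` / ``randomizable_params`` are the default
    disturbance targets of the case study; ``static_input`` is the
    constant-induction baseline the dynamic policies are benchmarked
    against.
    """

    name: str
    state_names: tuple[str, ...]
    params: Any
    x0: np.ndarray
    bounds: ControlBounds
    static_input: float
    randomizable_initials: tuple[str, ...]
    randomizable_params: tuple[str, ...]
    solver: str = "RK45"
    input_unit: str = ""

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def state_index(self, name: str) -> int:
        try:
            return self.state_names.index(name)
        except ValueError:
            raise KeyError(f"unknown state {name!r} for model {self.name}") from None

    def rhs(self, x, u, params=None):
        raise NotImplementedError

    def titer(self, x, params=None) -> np.ndarray:
        """Final-product concentration in g/L for state(s) ``x``."""
        raise NotImplementedError

    def apply_couplings(self, x0: np.ndarray, params=None) -> np.ndarray:
        """Re-impose algebraic ties between initial conditions (default: none)."""
        return x0

    def with_params(self, **updates) -> Any:
        return dataclasses.replace(self.params, **updates)


class FattyAcidModel(KineticModel):
    def rhs(self, x, u, params=None):
        return fa_rhs(x, u, self.params if params is None else params)

    def titer(self, x, params=None):
        p = self.params if params is None else params
        return np.asarray(x, dtype=float)[..., 5] * p.HP

    def apply_couplings(self, x0, params=None):
        # initial glucose is tied to initial biomass: S0 = 1 - X0*
        x0 = np.array(x0, dtype=float, copy=True)
        x0[..., 0] = np.maximum(1.0 - x0[..., 1], 0.0)
        return x0


class LactateModel(KineticModel):
    def rhs(self, x, u, params=None):
        return lac_rhs(x, u, self.params if params is None else params)

    def titer(self, x, params=None):
        return np.asarray(x, dtype=float)[..., 2]


# ---------------------------------------------------------------------------
# parameter-file loading
# ---------------------------------------------------------------------------

def load_parameter_file(name: str) -> dict:
    """Load one of the shipped parameter files (``fatty_acid`` or ``lactate``)."""
    ref = resources.files("fluxrl.data").joinpath(f"{name}.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def _values(doc: dict) -> dict:
    return {k: float(v["value"]) for k, v in doc["parameters"].items()}


def fatty_acid_model() -> FattyAcidModel:
    """Fatty-acid/ACC case study with nominal (shipped) parameters."""
    doc = load_parameter_file("fatty_acid")
    params = FattyAcidParams(**_values(doc))
    names = ("S", "X*", "E", "M", "R", "P*")
    ic = doc["initial_conditions"]
    x0 = np.array([0.0] + [float(ic[n]) for n in names[1:]])
    model = FattyAcidModel(
        name="fatty_acid",
        state_names=names,
        params=params,
        x0=x0,
        bounds=ControlBounds(float(doc["input"]["lower"]), float(doc["input"]["upper"])),
        static_input=float(doc["input"]["static_baseline"]),
        randomizable_initials=tuple(doc["randomization_defaults"]["initials"]),
        randomizable_params=tuple(doc["randomization_defaults"]["parameters"]),
        solver=doc["solver"],
        input_unit=doc["input"]["unit"],
    )
    model.x0 = model.apply_couplings(model.x0)
    return model


def lactate_model() -> LactateModel:
    """Lactate/ATPase case study with nominal (shipped) parameters."""
    doc = load_parameter_file("lactate")
    params = LactateParams(**_values(doc))
    names = ("S", "X", "L", "E")
    ic = doc["initial_conditions"]
    x0 = np.array([float(ic[n]) for n in names])
    return LactateModel(
        name="lactate",
        state_names=names,
        params=params,
        x0=x0,
        bounds=ControlBounds(float(doc["input"]["lower"]), float(doc["input"]["upper"])),
        static_input=float(doc["input"]["static_baseline"]),
        randomizable_initials=tuple(doc["randomization_defaults"]["initials"]),
        randomizable_params=tuple(doc["randomization_defaults"]["parameters"]),
        solver=doc["solver"],
        input_unit=doc["input"]["unit"],
    )


_MODELS = {"fatty_acid": fatty_acid_model, "lactate": lactate_model}


def get_model(name: str) -> KineticModel:
    try:
        return _MODELS[name]()
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {sorted(_MODELS)}") from None
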