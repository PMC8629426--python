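"""Closed-form tumor-burden trajectory under immune checkpoint inhibition.

The model describes the normalized tumor burden rho'(t) (total indexed-lesion
volume divided by its value at the first dose, so rho'(0) = 1) of a solid tumor
treated with a PD-1/PD-L1 checkpoint inhibitor. Three parameters govern the
trajectory:

* ``alpha`` -- intrinsic tumor proliferation rate (1/day); the growth rate the
  tumor would have with no immune kill. Doubling time = ln 2 / alpha.
* ``lam`` (Lambda) -- dimensionless anti-tumor immune state, combining
  intratumoral effector-cell abundance and per-cell kill ability; lam >= 0.
* ``mu`` -- immunotherapy-mediated amplification of immune kill (1/day); may be
  negative when therapy is ineffective and the pretreatment trend dominates.

The trajectory is the solution of the logistic-type ODE
``drho/dt = k * rho * (1 - rho / rho_inf)`` with

    k       = alpha - mu + mu * lam
    rho_inf = 1 + (alpha - mu) / (mu * lam)

giving the closed form

    rho'(t) = rho_inf / (1 - (1 - rho_inf) * exp(-k * t)),   rho'(0) = 1.

The sign of (alpha - mu) sets the direction of long-term response: progressive
disease for alpha > mu, regression for alpha < mu. When |mu * lam| is below a
small epsilon the finite carrying capacity disappears and the trajectory is the
pure exponential exp(k * t) (= exp(alpha * t) when mu = 0), the analytic limit
of the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EXPONENTIAL_LIMIT_EPS",
    "SINGULARITY_TOL",
    "ModelParameters",
    "TrajectoryModel",
    "ExponentialLimitError",
    "SingularTrajectoryError",
    "UndefinedDoublingTimeError",
    "effective_rate",
    "long_term_burden",
    "predict_burden",
    "singularity_time",
    "doubling_time",
    "diameter_to_volume",
]

#: Below this |mu * lam| the model is treated as its exponential limit.
EXPONENTIAL_LIMIT_EPS = 1e-12

#: |denominator| below this raises :class:`SingularTrajectoryError`.
SINGULARITY_TOL = 1e-9


class ExponentialLimitError(ValueError):
    """No finite long-term burden exists (|mu * lam| below epsilon)."""


class SingularTrajectoryError(ArithmeticError):
    """The trajectory denominator vanishes at a requested time.

    Happens for nonphysical parameter/time combinations (finite-time blow-up,
    possible when mu < 0).
    """


class UndefinedDoublingTimeError(ValueError):
    """Doubling time requested for a non-growing tumor (alpha <= 0)."""


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ModelParameters:
    """The (alpha, lam, mu) triplet for one patient.

    alpha : tumor proliferation rate, 1/day
    lam   : anti-tumor immune state Lambda, dimensionless, >= 0
    mu    : immunotherapy effect, 1/day (negative values allowed)
    """

    alpha: float
    lam: float
    mu: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", _check_finite("alpha", self.alpha))
        object.__setattr__(self, "lam", _check_finite("lam", self.lam))
        object.__setattr__(self, "mu", _check_finite("mu", self.mu))
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")


def effective_rate(params: ModelParameters) -> float:
    """Net exponential coefficient k = alpha - mu + mu * lam (1/day)."""
    return params.alpha - params.mu + params.mu * params.lam


@dataclass(frozen=True)
class TrajectoryModel:
    """Parameters plus the derived trajectory constants k and rho_inf.

    In the exponential-limit regime (|mu * lam| <= epsilon) ``rho_inf`` is NaN
    and ``exponential_limit`` is True; the trajectory is exp(k * t).
    """

    params: ModelParameters
    k: float = field(init=False)
    rho_inf: float = field(init=False)
    exponential_limit: bool = field(init=False)

    def __post_init__(self) -> None:
        p = self.params
        k = effective_rate(p)
        ml = p.mu * p.lam
        if abs(ml) <= EXPONENTIAL_LIMIT_EPS:
            object.__setattr__(self, "exponential_limit", True)
            object.__setattr__(self, "rho_inf", math.nan)
        else:
            object.__setattr__(self, "exponential_limit", False)
            object.__setattr__(self, "rho_inf", 1.0 + (p.alpha - p.mu) / ml)
        object.__setattr__(self, "k", k)

    @classmethod
    def from_values(cls, alpha: float, lam: float, mu: float) -> "TrajectoryModel":
        return cls(ModelParameters(alpha=alpha, lam=lam, mu=mu))


def _as_trajectory(model: TrajectoryModel | ModelParameters) -> TrajectoryModel:
    if isinstance(model, ModelParameters):
        return TrajectoryModel(model)
    return model


def long_term_burden(params: ModelParameters | TrajectoryModel) -> float:
    """Long-term normalized burden rho_inf = 1 + (alpha - mu)/(mu * lam).

    Raises :class:`ExponentialLimitError` when |mu * lam| is below epsilon
    (the burden grows or decays exponentially forever; no finite plateau).
    A negative return value signals the complete-regression regime, where the
    trajectory decays through zero burden; callers that report physical burden
    should clamp at 0.
    """
    model = _as_trajectory(params)
    if model.exponential_limit:
        raise ExponentialLimitError(
            "no finite long-term burden: |mu * lam| <= "
            f"{EXPONENTIAL_LIMIT_EPS} (exponential-limit regime)"
        )
    return model.rho_inf


def predict_burden(
    model: TrajectoryModel | ModelParameters,
    t: float | np.ndarray,
) -> float | np.ndarray:
    """Normalized tumor burden rho'(t) at time(s) ``t`` (days since first dose).

    rho'(t) = rho_inf / (1 - (1 - rho_inf) * exp(-k t)); exp(k t) in the
    exponential-limit regime. rho'(0) = 1 exactly in all regimes.

    Raises
    ------
    ValueError
        If any t < 0.
    SingularTrajectoryError
        If the denominator is within :data:`SINGULARITY_TOL` of zero at a
        requested time.
    """
    model = _as_trajectory(model)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0 (days since first dose)")
    scalar = t_arr.ndim == 0
    tt = np.atleast_1d(t_arr)
    if model.exponential_limit:
        out = np.exp(model.k * tt)
    else:
        with np.errstate(over="ignore"):
            denom = 1.0 - (1.0 - model.rho_inf) * np.exp(-model.k * tt)
            out = model.rho_inf / denom
        if np.any(np.abs(denom) < SINGULARITY_TOL):
            raise SingularTrajectoryError(
                f"trajectory denominator vanishes (k={model.k:.6g}, "
                f"rho_inf={model.rho_inf:.6g})"
            )
    # enforce the exact normalization at treatment start
    out = np.where(tt == 0.0, 1.0, out)
    return float(out[0]) if scalar else out


def predict_burden_clamped(
    model: TrajectoryModel | ModelParameters,
    t: float | np.ndarray,
) -> float | np.ndarray:
    """Like :func:`predict_burden` but clamped at 0 (physical burden).

    Negative analytic values arise in the complete-regression regime once the
    trajectory crosses zero; reported burden is nonnegative.
    """
    out = predict_burden(model, t)
    return np.maximum(out, 0.0) if isinstance(out, np.ndarray) else max(out, 0.0)


def singularity_time(model: TrajectoryModel | ModelParameters) -> float | None:
    """Time t* > 0 at which the trajectory denominator vanishes, or None.

    The denominator 1 - (1 - rho_inf) exp(-k t) has a positive root iff
    1 - rho_inf > 0 and ln(1 - rho_inf) / k > 0 (finite-time blow-up).
    """
    m = _as_trajectory(model)
    if m.exponential_limit:
        return None
    q = 1.0 - m.rho_inf
    if q <= 0.0 or m.k == 0.0:
        return None
    t_star = math.log(q) / m.k
    return t_star if t_star > 0.0 else None


def doubling_time(alpha: float) -> float:
    """Tumor volume doubling time ln(2)/alpha in days, for alpha > 0."""
    alpha = _check_finite("alpha", alpha)
    if alpha <= 0:
        raise UndefinedDoublingTimeError(
            f"doubling time undefined for alpha <= 0 (got {alpha})"
        )
    return math.log(2.0) / alpha


def diameter_to_volume(d: float) -> float:
    """Volume of a sphere of diameter ``d`` (mm): V = (4/3) pi (d/2)^3 mm^3."""
    d = _check_finite("d", d)
    if d < 0:
        raise ValueError(f"diameter must be >= 0, got {d}")
    return (4.0 / 3.0) * math.pi * (d / 2.0) ** 3
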