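"""Two-step parameter estimation from normalized burden series.

Step 1 estimates the proliferation rate alpha, either cohort-wide from the
fastest-progressing patient (exponential fit, as when no pretreatment imaging
exists) or per patient from a single pretreatment scan. Step 2 fixes alpha and
fits (Lambda, mu) to each patient's trajectory by bounded nonlinear least
squares against the closed-form model, using a deterministic multi-start grid.

Identifiability at fixed alpha follows from the invertible map between
(Lambda, mu) and the trajectory constants (k, rho_inf):
mu * Lambda = k / rho_inf and mu = alpha - k (rho_inf - 1) / rho_inf.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .cohort import Cohort, PatientSeries
from .model import (
    SINGULARITY_TOL,
    EXPONENTIAL_LIMIT_EPS,
    ModelParameters,
    TrajectoryModel,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "fit_exponential_rate",
    "cohort_alpha",
    "pretreatment_alpha",
    "fit_patient",
    "fit_cohort",
    "resolve_alpha",
]

# residual value substituted where the trajectory denominator vanishes, to
# steer the optimizer away from finite-time blow-up regions
_PENALTY = 1e6


@dataclass(frozen=True)
class FitConfig:
    """Bounds, multi-start grid, and tolerances for the (Lambda, mu) fit.

    Bounds span all reported cohort-level values with wide margin; the start
    grid is fixed (no RNG) so repeated fits are bitwise identical.
    """

    lam_bounds: tuple[float, float] = (0.0, 100.0)
    mu_bounds: tuple[float, float] = (-1.0, 1.0)
    lam_starts: tuple[float, ...] = (0.01, 0.1, 1.0, 5.0)
    mu_starts: tuple[float, ...] = (-0.01, 0.001, 0.01, 0.05, 0.2)
    ftol: float = 1e-10
    xtol: float = 1e-12
    max_iter: int = 500
    #: also start from a moment-style estimate inverted from the data
    #: (k from the first post-baseline point, rho_inf from the last);
    #: deterministic, and essential when the plateau lies far outside the
    #: fixed grid (e.g. near-exponential-limit patients)
    data_driven_start: bool = True

    def start_grid(self) -> list[tuple[float, float]]:
        lam_lo, lam_hi = self.lam_bounds
        mu_lo, mu_hi = self.mu_bounds
        return [
            (min(max(l, lam_lo), lam_hi), min(max(m, mu_lo), mu_hi))
            for l, m in itertools.product(self.lam_starts, self.mu_starts)
        ]


@dataclass(frozen=True)
class FitResult:
    """Per-patient fit: fixed alpha, fitted (Lambda, mu), and diagnostics."""

    patient_id: str
    alpha: float
    lam: float
    mu: float
    rho_inf: float  # NaN in the exponential-limit regime
    rmse: float
    n_points: int
    converged: bool
    truncation_window: float | str = "all"

    @property
    def params(self) -> ModelParameters:
        return ModelParameters(alpha=self.alpha, lam=self.lam, mu=self.mu)

    @property
    def trajectory(self) -> TrajectoryModel:
        return TrajectoryModel(self.params)


def fit_exponential_rate(series: PatientSeries) -> float:
    """Exponential growth rate alpha from the on-treatment series.

    Fits rho(t) = e^(alpha t) by linear regression of ln(burden) on time
    (exact and convex for positive burdens). Requires >= 2 on-treatment
    points with burden > 0.
    """
    t = series.times
    b = series.burdens
    if t.size < 2:
        raise ValueError(
            f"patient {series.patient_id!r}: need >= 2 on-treatment points"
        )
    if np.any(b <= 0):
        raise ValueError(
            f"patient {series.patient_id!r}: exponential fit needs burdens > 0"
        )
    slope = np.polyfit(t, np.log(b), 1)[0]
    return float(slope)


def cohort_alpha(cohort: Cohort) -> float:
    """Alpha of the fastest-progressing patient in the cohort.

    The fastest progressor is the patient with the maximal fitted exponential
    rate; ties break toward the first patient in patient_id order.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    best_rate = -math.inf
    skipped = []
    for p in sorted(cohort, key=lambda p: p.patient_id):
        try:
            rate = fit_exponential_rate(p)
        except ValueError:
            # a zero burden (complete response) cannot be exponential-fit and
            # cannot be the fastest progressor either
            skipped.append(p.patient_id)
            continue
        if rate > best_rate:
            best_rate = rate
    if not math.isfinite(best_rate):
        raise ValueError("no patient admits an exponential fit")
    if skipped:
        warnings.warn(
            f"{len(skipped)} patient(s) skipped in fastest-progressor search "
            f"(non-positive or too few burdens)",
            stacklevel=2,
        )
    return best_rate


def pretreatment_alpha(series: PatientSeries) -> float:
    """Per-patient alpha from the pretreatment scan.

    With rho(t) ~ e^(alpha t) between the pretreatment scan (t_pre < 0,
    normalized burden rho_pre) and baseline, alpha = ln(rho_pre) / t_pre.
    Negative alpha indicates a tumor already shrinking before therapy.
    """
    if series.pretreatment is None:
        raise ValueError(f"patient {series.patient_id!r}: no pretreatment scan")
    t_pre, b_pre = series.pretreatment
    if b_pre <= 0:
        raise ValueError(f"patient {series.patient_id!r}: pretreatment burden <= 0")
    return math.log(b_pre) / t_pre


def _residuals(theta: np.ndarray, alpha: float, t: np.ndarray, obs: np.ndarray) -> np.ndarray:
    lam, mu = theta
    k = alpha - mu + mu * lam
    ml = mu * lam
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if abs(ml) <= EXPONENTIAL_LIMIT_EPS:
            pred = np.exp(np.clip(k * t, -500.0, 500.0))
        else:
            rho_inf = 1.0 + (alpha - mu) / ml
            denom = 1.0 - (1.0 - rho_inf) * np.exp(np.clip(-k * t, -500.0, 500.0))
            # past a finite-time singularity the denominator flips sign
            # relative to rho_inf (wrong branch): penalize, don't evaluate
            bad = (np.abs(denom) < SINGULARITY_TOL) | (
                np.sign(denom) != np.sign(rho_inf)
            )
            denom = np.where(bad, 1.0, denom)
            pred = np.where(bad, _PENALTY, rho_inf / denom)
        pred = np.where(t == 0.0, 1.0, pred)
        res = pred - obs
    return np.clip(
        np.nan_to_num(res, nan=_PENALTY, posinf=_PENALTY, neginf=-_PENALTY),
        -_PENALTY,
        _PENALTY,
    )


def _jacobian(theta: np.ndarray, alpha: float, t: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the burden residuals wrt (lam, mu).

    Rows are zeroed at the pinned baseline (t = 0) and wherever the model is
    in a penalty region (vanishing denominator), matching the flat residual.
    """
    lam, mu = theta
    k = alpha - mu + mu * lam
    ml = mu * lam
    jac = np.zeros((t.size, 2))
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if abs(ml) <= EXPONENTIAL_LIMIT_EPS:
            kt = np.clip(k * t, -500.0, 500.0)
            pred = np.exp(kt)
            jac[:, 0] = t * mu * pred
            jac[:, 1] = t * (lam - 1.0) * pred
        else:
            rho_inf = 1.0 + (alpha - mu) / ml
            e = np.exp(np.clip(-k * t, -500.0, 500.0))
            denom = 1.0 - (1.0 - rho_inf) * e
            bad = (np.abs(denom) < SINGULARITY_TOL) | (
                np.sign(denom) != np.sign(rho_inf)
            )
            denom = np.where(bad, 1.0, denom)
            r_lam = -(rho_inf - 1.0) / lam if lam != 0 else 0.0
            r_mu = -alpha / (mu * mu * lam) if mu != 0 and lam != 0 else 0.0
            for col, (r_th, k_th) in enumerate(((r_lam, mu), (r_mu, lam - 1.0))):
                d_th = r_th * e + (1.0 - rho_inf) * e * t * k_th
                jac[:, col] = np.where(
                    bad, 0.0, r_th / denom - rho_inf * d_th / denom**2
                )
        jac[t == 0.0, :] = 0.0
    return np.nan_to_num(jac, nan=0.0, posinf=1e12, neginf=-1e12)


def _moment_start(t: np.ndarray, obs: np.ndarray, alpha: float) -> tuple[float, float] | None:
    """Invert a crude (k, rho_inf) estimate to a (lam, mu) starting point.

    k is read from the first positive post-baseline burden (exponential
    approximation), rho_inf from the last observation (plateau approximation);
    the exact inversion mu*lam = k/rho_inf, mu = alpha - k (rho_inf - 1)/rho_inf
    then gives the start. Returns None when the data admit no such estimate.
    """
    post = (t > 0) & (obs > 0)
    if post.sum() < 2:
        return None
    t1 = t[post][0]
    k0 = math.log(obs[post][0]) / t1
    r0 = float(obs[post][-1])
    if not (math.isfinite(k0) and r0 > 0) or abs(r0 - 1.0) < 1e-6:
        return None
    mu0 = alpha - k0 * (r0 - 1.0) / r0
    if abs(mu0) < 1e-12:
        return None
    lam0 = (k0 / r0) / mu0
    if not (math.isfinite(lam0) and lam0 >= 0):
        return None
    return lam0, mu0


def fit_patient(
    series: PatientSeries,
    alpha: float,
    config: FitConfig | None = None,
    truncation_window: float | str = "all",
) -> FitResult:
    """Fit (Lambda, mu) to one patient's burden series at fixed alpha.

    Minimizes the sum of squared burden residuals over all on-treatment points
    (the baseline (0, 1) is included; the model satisfies it exactly). Each
    point of the deterministic start grid is polished with bounded
    trust-region least squares; the best final SSR wins, ties going to the
    earliest grid point. ``converged`` is False only if no start converged.
    """
    config = config or FitConfig()
    t = series.times
    obs = series.burdens
    lo = np.array([config.lam_bounds[0], config.mu_bounds[0]])
    hi = np.array([config.lam_bounds[1], config.mu_bounds[1]])

    best = None
    best_ssr = math.inf
    any_converged = False
    grid = list(config.start_grid())
    if config.data_driven_start:
        extra = _moment_start(t, obs, alpha)
        if extra is not None:
            grid.append(extra)
    starts = [np.clip(np.asarray(s, dtype=float), lo, hi) for s in grid]
    # a start with penalized residuals sits in a finite-time blow-up region
    # (trajectory singular before the last scan): nonphysical for these data,
    # and polishing from it cannot reach a valid basin smoothly -- skip it
    usable = [
        x0 for x0 in starts
        if np.max(np.abs(_residuals(x0, alpha, t, obs))) < 0.99 * _PENALTY
    ]
    if not usable:
        usable = starts[:1]
    for x0 in usable:
        with np.errstate(all="ignore"):
            sol = least_squares(
                _residuals,
                x0,
                jac=_jacobian,
                bounds=(lo, hi),
                args=(alpha, t, obs),
                method="trf",
                ftol=config.ftol,
                xtol=config.xtol,
                gtol=None,
                max_nfev=config.max_iter,
            )
        ssr = 2.0 * sol.cost
        if sol.status > 0:
            any_converged = True
        if ssr < best_ssr:
            best_ssr = ssr
            best = sol

    lam, mu = (float(v) for v in best.x)
    traj = TrajectoryModel.from_values(alpha, lam, mu)
    return FitResult(
        patient_id=series.patient_id,
        alpha=float(alpha),
        lam=lam,
        mu=mu,
        rho_inf=traj.rho_inf,
        rmse=math.sqrt(best_ssr / t.size),
        n_points=int(t.size),
        converged=any_converged,
        truncation_window=truncation_window,
    )


def resolve_alpha(
    cohort: Cohort,
    mode: str = "fastest-progressor",
    fixed: float | None = None,
) -> dict[str, float]:
    """Map patient_id -> alpha under the chosen estimation mode.

    Modes: ``fastest-progressor`` (one cohort-wide alpha from the maximal
    exponential rate), ``per-patient-pretreatment`` (each patient's
    pretreatment scan), or ``fixed`` (a supplied value, e.g. a reported
    histology-specific rate).
    """
    if mode == "fastest-progressor":
        a = cohort_alpha(cohort)
        return {p.patient_id: a for p in cohort}
    if mode == "per-patient-pretreatment":
        return {p.patient_id: pretreatment_alpha(p) for p in cohort}
    if mode == "fixed":
        if fixed is None:
            raise ValueError("alpha mode 'fixed' requires a value")
        return {p.patient_id: float(fixed) for p in cohort}
    raise ValueError(f"unknown alpha mode {mode!r}")


def fit_cohort(
    cohort: Cohort,
    alpha: float | Mapping[str, float],
    config: FitConfig | None = None,
    truncation_window: float | str = "all",
) -> list[FitResult]:
    """Fit every patient; ``alpha`` may be one rate or a per-patient map."""
    if isinstance(alpha, Mapping):
        return [
            fit_patient(p, alpha[p.patient_id], config, truncation_window)
            for p in cohort
        ]
    return [fit_patient(p, float(alpha), config, truncation_window) for p in cohort]


def fits_to_frame(fits: Sequence[FitResult]):
    """FitResults as a DataFrame (one row per patient, fixed column order)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "patient_id": f.patient_id,
                "alpha": f.alpha,
                "lam": f.lam,
                "mu": f.mu,
                "rho_inf": f.rho_inf,
                "rmse": f.rmse,
                "n_points": f.n_points,
                "converged": f.converged,
                "truncation_window": f.truncation_window,
            }
            for f in fits
        ]
    )
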