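"""Life-table quantities from a fitted multistate transition model.

Given age-dependent per-step transition probabilities this module computes

* the stable (period) prevalence — the within-alive distribution over the
  two living states to which the age-inhomogeneous chain converges after a
  long burn-in, independent of the starting state;
* state-conditional expectancies e^{ij}(x) — expected years spent in living
  state j after age x given state i at x, as step sums of occupancy
  probabilities with a trapezoid end-correction of h/2 on the diagonal;
* population-based LE / HLE / HLE-ratio — conditional rows mixed by the
  stable prevalence, with e^{..} = e^{.1} + e^{.2} holding exactly;
* parametric-bootstrap confidence intervals over the coefficient sampling
  distribution;
* a Kannisto logistic old-age hazard fit mu(x) = a e^{b(x-x0)} /
  (1 + a e^{b(x-x0)}) as a mortality-pattern check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .markov import (
    ModelError,
    StepParams,
    TransitionCoefficients,
    _nearest_psd,
    _rates_from_eta,
)

__all__ = [
    "PrevalenceVector",
    "ExpectancyResult",
    "KannistoFit",
    "KannistoHazard",
    "stable_prevalence",
    "conditional_expectancies",
    "population_expectancies",
    "confidence_intervals",
    "kannisto_fit",
    "exposure_deaths_by_band",
]


@dataclass(frozen=True)
class PrevalenceVector:
    """Stable within-alive state distribution at age ``x``."""

    age: float
    w1: float
    w2: float
    burn_in: float
    converged: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.w1 <= 1 and 0 <= self.w2 <= 1):
            raise ModelError("prevalence components must lie in [0, 1]")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ModelError("w1 + w2 must equal 1")


@dataclass
class ExpectancyResult:
    """Per starting age: conditional and population-based expectancies (years)."""

    age: float
    profile: dict[str, float]
    e_cond: np.ndarray  # (2, 2): e^{ij}
    w2: float
    hle: float  # e^{.1}
    ule: float  # e^{.2}
    le: float  # e^{..} = e^{.1} + e^{.2}
    hle_pct: float  # 100 * hle / le
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_draws: int = 0
    seed: int | None = None


@dataclass(frozen=True)
class KannistoFit:
    """Logistic old-age hazard parameters mu(x) = a e^{b(x-x0)}/(1+a e^{b(x-x0)})."""

    a: float
    b: float
    x0: float
    deviance: float
    age_range: tuple[float, float]

    def hazard(self, age: np.ndarray | float) -> np.ndarray | float:
        z = self.a * np.exp(self.b * (np.asarray(age, dtype=float) - self.x0))
        return z / (1.0 + z)


# ---------------------------------------------------------------------------
# batched chain engine (vectorized over coefficient draws)


def _as_batch(coeffs: TransitionCoefficients, theta: np.ndarray | None) -> np.ndarray:
    """Coefficient draws (B, 4, q); B=1 holds the point estimate."""
    if theta is None:
        return coeffs.coef[None, :, :]
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 1:
        theta = theta[None, :]
    return theta.reshape(theta.shape[0], *coeffs.coef.shape)


def _z(coeffs: TransitionCoefficients, age: float, x: np.ndarray) -> np.ndarray:
    cols = [1.0]
    if coeffs.age_slope:
        cols.append(age - coeffs.step.age_origin)
    return np.concatenate([np.asarray(cols), x])


def _rates_at(batch: np.ndarray, coeffs: TransitionCoefficients, age: float, x: np.ndarray):
    eta = batch @ _z(coeffs, age, x)  # (B, 4)
    return _rates_from_eta(eta)


def _stable_w(
    batch: np.ndarray,
    coeffs: TransitionCoefficients,
    age: float,
    x: np.ndarray,
    burn_in: float,
    tol: float,
) -> tuple[np.ndarray, float, bool]:
    """Start-state prevalence rows w^{i.} (B, 2, 2) plus burn-in used.

    Growing the burn-in prepends earlier-age matrices to the front of the
    living-state product; convergence requires both successive-t stability
    and independence of the starting state i.  ``burn_in`` caps the window;
    the product stops extending as soon as both checks pass, so the typical
    window is 30-60 years and only slow-mixing parameter draws use more.
    """
    h = coeffs.step.h
    block = max(int(round(5.0 / h)), 1)  # extend burn-in in 5-year blocks
    max_steps = int(round(burn_in / h))
    S = np.broadcast_to(np.eye(2), (batch.shape[0], 2, 2)).copy()
    w_prev = None
    k = 0
    converged = False
    while k < max_steps:
        upto = min(k + block, max_steps)
        while k < upto:
            k += 1
            Q, _ = _rates_at(batch, coeffs, age - k * h, x)
            S = Q @ S
        alive = S.sum(axis=2, keepdims=True)
        w = S / np.maximum(alive, 1e-300)
        start_dep = np.abs(w[:, 0, :] - w[:, 1, :]).max()
        if w_prev is not None and np.abs(w - w_prev).max() < tol and start_dep < tol:
            converged = True
            break
        w_prev = w
    if not converged:
        warnings.warn(
            f"stable prevalence at age {age} not converged within burn-in "
            f"{burn_in} y (last change check failed); using last iterate",
            stacklevel=2,
        )
    return w, k * h, converged


def stable_prevalence(
    coeffs: TransitionCoefficients,
    age: float,
    profile: Mapping[str, float] | None = None,
    burn_in: float = 150.0,
    tol: float = 1e-6,
) -> PrevalenceVector:
    """Stable prevalence of the living states at ``age`` for a profile.

    Computes _t p^{i.} over a growing burn-in window ending at ``age``,
    renormalizes over the living states, and extends the window until the
    result is stable and independent of the starting state.  The window may
    extrapolate the fitted logits below the data's age range (standard
    practice for period prevalence in interpolated-Markov-chain software).
    """
    if tol <= 0:
        raise ModelError("tolerance must be positive")
    x = coeffs.profile_vector(profile)
    w, t_used, converged = _stable_w(coeffs.coef[None], coeffs, age, x, burn_in, tol)
    w1 = float(w[0, :, 0].mean())
    return PrevalenceVector(age=age, w1=w1, w2=1.0 - w1, burn_in=t_used, converged=converged)


def _conditional_e(
    batch: np.ndarray,
    coeffs: TransitionCoefficients,
    age: float,
    x: np.ndarray,
    survival_tol: float = 1e-8,
) -> np.ndarray:
    """Conditional expectancy matrices e^{ij} (B, 2, 2), in years."""
    h = coeffs.step.h
    cap = coeffs.step.age_cap
    B = batch.shape[0]
    V = np.broadcast_to(np.eye(2), (B, 2, 2)).copy()  # occupancy _u p^{ij}
    e = 0.5 * h * np.broadcast_to(np.eye(2), (B, 2, 2)).copy()
    u = 0
    while True:
        a_u = age + u * h
        if a_u >= cap - 1e-12:  # forced death at the cap
            break
        Q, _ = _rates_at(batch, coeffs, a_u, x)
        V = V @ Q
        e = e + h * V
        u += 1
        if V.sum(axis=(1, 2)).max() < survival_tol:
            break
    return e


def conditional_expectancies(
    coeffs: TransitionCoefficients,
    age: float,
    profile: Mapping[str, float] | None = None,
    horizon: float | None = None,
) -> np.ndarray:
    """Conditional expectancies e^{ij}(age) as a (2, 2) array of years.

    e^{ij} = h/2 * delta_ij + h * sum_{u>=1} _u p^{ij}, summed until the
    surviving mass falls below 1e-8 or the age cap forces death.
    """
    if horizon is not None and age + horizon > coeffs.step.age_cap:
        raise ModelError("horizon extends beyond the age cap")
    x = coeffs.profile_vector(profile)
    return _conditional_e(coeffs.coef[None], coeffs, age, x)[0]


def _population_batch(
    batch: np.ndarray,
    coeffs: TransitionCoefficients,
    age: float,
    x: np.ndarray,
    burn_in: float,
    tol: float,
) -> dict[str, np.ndarray]:
    w, _, _ = _stable_w(batch, coeffs, age, x, burn_in, tol)
    w2 = w[:, :, 1].mean(axis=1)  # start-state independent at convergence
    e = _conditional_e(batch, coeffs, age, x)
    hle = (1.0 - w2) * e[:, 0, 0] + w2 * e[:, 1, 0]
    ule = (1.0 - w2) * e[:, 0, 1] + w2 * e[:, 1, 1]
    le = hle + ule
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * hle / le
    return {"w2": w2, "e": e, "hle": hle, "ule": ule, "le": le, "hle_pct": pct}


def population_expectancies(
    coeffs: TransitionCoefficients,
    age: float,
    profile: Mapping[str, float] | None = None,
    burn_in: float = 150.0,
    tol: float = 1e-6,
) -> ExpectancyResult:
    """Population-based LE / HLE / HLE-ratio at ``age`` for a profile.

    Conditional expectancy rows are mixed by the stable prevalence:
    e^{.j} = (1 - w2) e^{1j} + w2 e^{2j}; LE = e^{.1} + e^{.2} by
    construction, and the ratio is reported in percent of unrounded values.
    """
    x = coeffs.profile_vector(profile)
    out = _population_batch(coeffs.coef[None], coeffs, age, x, burn_in, tol)
    le = float(out["le"][0])
    if le <= 0:
        raise ModelError(f"life expectancy is zero at age {age}; ratio undefined")
    return ExpectancyResult(
        age=age,
        profile=dict(profile or {}),
        e_cond=out["e"][0],
        w2=float(out["w2"][0]),
        hle=float(out["hle"][0]),
        ule=float(out["ule"][0]),
        le=le,
        hle_pct=float(out["hle_pct"][0]),
    )


def confidence_intervals(
    coeffs: TransitionCoefficients,
    ages: Sequence[float],
    profile: Mapping[str, float] | None = None,
    n_draws: int = 500,
    seed: int | None = 0,
    burn_in: float = 150.0,
    tol: float = 1e-6,
    level: float = 0.95,
) -> pd.DataFrame:
    """Parametric-bootstrap CIs for LE, HLE, ULE and HLE/LE per age.

    Coefficient vectors are drawn from N(theta_hat, cov); each target is
    recomputed per draw and the percentile interval reported.  Seeded and
    reproducible; requires a positive-semidefinite covariance.
    """
    if coeffs.cov is None:
        raise ModelError("coefficients carry no covariance; fit with covariance first")
    if n_draws < 100:
        raise ModelError("n_draws must be at least 100")
    cov = _nearest_psd(coeffs.cov)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(coeffs.coef.ravel(), cov, size=n_draws, method="cholesky")
    batch = _as_batch(coeffs, draws)
    x = coeffs.profile_vector(profile)
    alpha = 100 * (1 - level) / 2
    rows = []
    for age in ages:
        point = _population_batch(coeffs.coef[None], coeffs, age, x, burn_in, tol)
        boot = _population_batch(batch, coeffs, age, x, burn_in, tol)
        for key in ("le", "hle", "ule", "hle_pct"):
            lo, hi = np.percentile(boot[key], [alpha, 100 - alpha])
            rows.append(
                dict(
                    age=age,
                    quantity=key,
                    estimate=float(point[key][0]),
                    lower=float(lo),
                    upper=float(hi),
                    n_draws=n_draws,
                    seed=seed,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kannisto old-age mortality


class KannistoHazard(BaseEstimator):
    """Binomial maximum-likelihood fit of the Kannisto logistic hazard.

    mu(x) = a e^{b(x - x0)} / (1 + a e^{b(x - x0)}) — the decelerating
    old-age mortality schedule; ``a`` scales the level at ``x0`` and ``b``
    is the log-hazard slope.  Death counts at each age are treated as
    binomial draws from the exposed population.
    """

    def __init__(self, x0: float = 65.0, maxiter: int = 200):
        self.x0 = x0
        self.maxiter = maxiter

    def fit(self, ages: np.ndarray, deaths: np.ndarray, exposures: np.ndarray):
        ages = np.asarray(ages, dtype=float)
        deaths = np.asarray(deaths, dtype=float)
        exposures = np.asarray(exposures, dtype=float)
        ok = exposures > 0
        if ok.sum() < 4:
            raise ModelError("need at least 4 age groups with positive exposure")
        ages, deaths, exposures = ages[ok], deaths[ok], exposures[ok]
        if np.all(deaths == 0):
            warnings.warn("all-zero death counts; hazard level is at the boundary")

        def nll(params: np.ndarray) -> float:
            log_a, b = params
            z = np.exp(np.clip(log_a + b * (ages - self.x0), -500, 500))
            q = np.clip(z / (1.0 + z), 1e-12, 1 - 1e-12)
            return -float(np.sum(deaths * np.log(q) + (exposures - deaths) * np.log1p(-q)))

        crude = np.clip(deaths.sum() / exposures.sum(), 1e-6, 1 - 1e-6)
        start = np.array([np.log(crude / (1 - crude)), 0.05])
        res = optimize.minimize(nll, start, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        res = optimize.minimize(nll, res.x, method="BFGS",
                                options={"maxiter": self.maxiter, "gtol": 1e-10})
        self.a_ = float(np.exp(res.x[0]))
        self.b_ = float(res.x[1])
        # deviance vs the saturated binomial model
        q_obs = np.clip(deaths / exposures, 1e-12, 1 - 1e-12)
        sat = float(np.sum(deaths * np.log(q_obs) + (exposures - deaths) * np.log1p(-q_obs)))
        self.deviance_ = 2 * (sat + res.fun)
        self.age_range_ = (float(ages.min()), float(ages.max()))
        self.converged_ = bool(res.success)
        return self

    def hazard(self, age):
        z = self.a_ * np.exp(self.b_ * (np.asarray(age, dtype=float) - self.x0))
        return z / (1.0 + z)


def kannisto_fit(
    ages: np.ndarray, deaths: np.ndarray, exposures: np.ndarray, x0: float = 65.0
) -> KannistoFit:
    """Functional wrapper over :class:`KannistoHazard`."""
    est = KannistoHazard(x0=x0).fit(ages, deaths, exposures)
    return KannistoFit(
        a=est.a_, b=est.b_, x0=x0, deviance=est.deviance_, age_range=est.age_range_
    )


def exposure_deaths_by_band(
    entry_ages: np.ndarray,
    exit_ages: np.ndarray,
    died: np.ndarray,
    bands: Sequence[float] = (65, 70, 75, 80, 85, 90, 95, 100),
) -> pd.DataFrame:
    """Person-years of exposure and death counts by age band.

    Each individual contributes exposure from entry to exit age within each
    band; a death counts in the band containing the exit age.
    """
    entry = np.asarray(entry_ages, dtype=float)
    exit_ = np.asarray(exit_ages, dtype=float)
    died = np.asarray(died, dtype=bool)
    rows = []
    for lo, hi in zip(bands, list(bands[1:]) + [np.inf]):
        expo = np.clip(np.minimum(exit_, hi) - np.maximum(entry, lo), 0, None).sum()
        d = int((died & (exit_ >= lo) & (exit_ < hi)).sum())
        rows.append(dict(age=lo + min(hi - lo, 5) / 2, band_lo=lo, exposure=expo, deaths=d))
    return pd.DataFrame(rows)
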