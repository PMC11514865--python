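"""Interpolated Markov chain estimation of health-state transitions.

The model: three states — healthy (1), unhealthy (2), dead (3, absorbing) —
observed at irregular panel interviews.  Between interviews the process is a
discrete-time Markov chain on a fine step ``h`` (default one month).  For
origin state ``j`` the per-step transition probabilities follow a multinomial
logit in age and covariates,

    p^{jk}(x) = exp(eta_jk) / (1 + sum_{k' != j} exp(eta_jk')),
    eta_jk = a_jk + b_jk (x - x0) + c_jk' z,

with ``p^{jj}`` the complement and the dead row fixed at (0, 0, 1).  Ages are
centered at ``x0`` (default 80) for numerical conditioning; this is an affine
reparameterization of an uncentered age slope.

Interval probabilities over an interview gap are ordered products of per-step
matrices with age advancing by ``h`` and covariates held fixed within the
episode (last observation carried forward).  The likelihood of an episode
ending in an observed living state is the corresponding product entry; an
episode ending in death at a known age survives in the living states to the
step containing the death and transitions to dead within that step, summing
over the unobserved living path automatically through the matrix products.

Estimation maximizes the weighted (pseudo-)log-likelihood by L-BFGS with an
exact gradient propagated forward through the step products.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

HEALTHY, UNHEALTHY, DEAD = 1, 2, 3

#: transition blocks, in parameter order
TRANSITIONS: tuple[tuple[int, int], ...] = ((1, 2), (1, 3), (2, 1), (2, 3))
_ORIGIN = np.array([0, 0, 1, 1])  # 0-based living origin per transition
_LOGIT_CLIP = 50.0
_TINY = 1e-300


class ModelError(ValueError):
    """Invalid model input (profile, ages, non-PSD covariance ...)."""


@dataclass(frozen=True)
class StepParams:
    """Discretization of the embedded chain.

    h : step length in years (default 1/12, i.e. one month); must satisfy
        0 < h <= 1.
    age_min, age_cap : age grid; all living individuals are forced to die at
        ``age_cap`` so life-table sums terminate.
    age_origin : centering constant of the age covariate.
    """

    h: float = 1.0 / 12.0
    age_min: float = 65.0
    age_cap: float = 110.0
    age_origin: float = 80.0

    def __post_init__(self) -> None:
        if not 0 < self.h <= 1.0:
            raise ModelError(f"step h must be in (0, 1] years, got {self.h}")
        if self.age_cap <= 99.0:
            raise ModelError("age_cap must exceed 99")

    def n_steps(self, elapsed: float) -> int:
        """Nearest integer number of h-steps spanning ``elapsed`` years (>= 1)."""
        m = int(round(elapsed / self.h))
        if abs(elapsed - m * self.h) > 1e-6 * max(1.0, abs(elapsed)):
            warnings.warn(
                f"elapsed time {elapsed:.6f} y is not a multiple of h={self.h:.6f}; "
                f"rounded to {m} steps",
                stacklevel=2,
            )
        return max(m, 1)


@dataclass
class TransitionCoefficients:
    """Fitted (or true) multinomial-logit parameters of the embedded chain.

    coef : array (4, q) — rows in :data:`TRANSITIONS` order; columns are
        [intercept, age slope (if ``age_slope``), covariate effects...].
    cov : covariance of the flattened coefficient vector (row-major over
        transitions then features), or None.
    """

    coef: np.ndarray
    covariates: tuple[str, ...] = ()
    step: StepParams = field(default_factory=StepParams)
    age_slope: bool = True
    cov: np.ndarray | None = None
    loglik: float | None = None
    n_iter: int | None = None
    converged: bool | None = None
    grad_norm: float | None = None

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        q = 1 + int(self.age_slope) + len(self.covariates)
        if self.coef.shape != (4, q):
            raise ModelError(
                f"coef must have shape (4, {q}) for covariates {self.covariates}, "
                f"got {self.coef.shape}"
            )
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)
            p = self.coef.size
            if self.cov.shape != (p, p):
                raise ModelError(f"cov must be ({p}, {p}), got {self.cov.shape}")
            if not np.allclose(self.cov, self.cov.T, atol=1e-8):
                raise ModelError("covariance matrix is not symmetric")

    @property
    def n_params(self) -> int:
        return self.coef.size

    def param_names(self) -> list[str]:
        feats = ["intercept"] + (["age"] if self.age_slope else []) + list(self.covariates)
        return [f"{j}->{k}:{f}" for (j, k) in TRANSITIONS for f in feats]

    def profile_vector(self, profile: Mapping[str, float] | None) -> np.ndarray:
        """Validate a covariate profile and return its value vector."""
        profile = dict(profile or {})
        vals = []
        for name in self.covariates:
            if name not in profile:
                raise ModelError(f"profile missing covariate {name!r}")
            vals.append(float(profile.pop(name)))
        if profile:
            raise ModelError(f"profile has undeclared covariates: {sorted(profile)}")
        return np.asarray(vals)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "covariates": list(self.covariates),
            "age_slope": self.age_slope,
            "step": {
                "h": self.step.h,
                "age_min": self.step.age_min,
                "age_cap": self.step.age_cap,
                "age_origin": self.step.age_origin,
            },
            "cov": None if self.cov is None else self.cov.tolist(),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransitionCoefficients":
        return cls(
            coef=np.asarray(d["coef"], dtype=float),
            covariates=tuple(d.get("covariates", ())),
            step=StepParams(**d.get("step", {})),
            age_slope=bool(d.get("age_slope", True)),
            cov=None if d.get("cov") is None else np.asarray(d["cov"], dtype=float),
            loglik=d.get("loglik"),
            n_iter=d.get("n_iter"),
            converged=d.get("converged"),
            grad_norm=d.get("grad_norm"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TransitionCoefficients":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class TransitionMatrix:
    """A 3x3 stochastic matrix over {healthy, unhealthy, dead} at a given age."""

    probs: np.ndarray
    age: float
    h: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (3, 3):
            raise ModelError(f"transition matrix must be 3x3, got {p.shape}")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ModelError("transition probabilities outside [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ModelError("transition-matrix rows do not sum to 1")
        if not (p[2, 0] == 0 and p[2, 1] == 0 and p[2, 2] == 1):
            raise ModelError("dead row must be exactly (0, 0, 1)")

    def __getitem__(self, idx):
        return self.probs[idx]


# ---------------------------------------------------------------------------
# vectorized per-step rates


def _features(coeffs: TransitionCoefficients, ages: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Design row(s) z = [1, age-x0, covariates] with shape (..., q)."""
    ages = np.asarray(ages, dtype=float)
    cols = [np.ones_like(ages)]
    if coeffs.age_slope:
        cols.append(ages - coeffs.step.age_origin)
    if len(coeffs.covariates):
        X = np.broadcast_to(np.asarray(X, dtype=float), ages.shape + (len(coeffs.covariates),))
        return np.concatenate([np.stack(cols, axis=-1), X], axis=-1)
    return np.stack(cols, axis=-1)


def _rates_from_eta(eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map logits (..., 4) to living 2x2 block Q (..., 2, 2) and death column d (..., 2)."""
    e = np.exp(np.clip(eta, -_LOGIT_CLIP, _LOGIT_CLIP))
    d1 = 1.0 + e[..., 0] + e[..., 1]
    d2 = 1.0 + e[..., 2] + e[..., 3]
    Q = np.empty(eta.shape[:-1] + (2, 2))
    Q[..., 0, 0] = 1.0 / d1
    Q[..., 0, 1] = e[..., 0] / d1
    Q[..., 1, 0] = e[..., 2] / d2
    Q[..., 1, 1] = 1.0 / d2
    d = np.empty(eta.shape[:-1] + (2,))
    d[..., 0] = e[..., 1] / d1
    d[..., 1] = e[..., 3] / d2
    return Q, d


def _step_rates(
    coeffs: TransitionCoefficients, ages: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    z = _features(coeffs, ages, X)
    eta = z @ coeffs.coef.T
    return _rates_from_eta(eta)


def step_matrix(
    coeffs: TransitionCoefficients,
    age: float,
    profile: Mapping[str, float] | None = None,
    step: StepParams | None = None,
) -> TransitionMatrix:
    """One-step 3x3 transition matrix at ``age`` for a covariate profile."""
    step = step or coeffs.step
    x = coeffs.profile_vector(profile)
    Q, d = _step_rates(coeffs, np.asarray(age, dtype=float), x)
    P = np.zeros((3, 3))
    P[:2, :2] = Q
    P[:2, 2] = d
    P[2, 2] = 1.0
    return TransitionMatrix(P, age=float(age), h=step.h)


def interval_probability(
    coeffs: TransitionCoefficients,
    age_start: float,
    elapsed: float,
    profile: Mapping[str, float] | None = None,
    step: StepParams | None = None,
) -> TransitionMatrix:
    """Transition matrix over ``elapsed`` years from ``age_start``.

    Ordered product of per-step matrices with age advancing by ``h`` each
    step and the profile held fixed (last observation carried forward).
    """
    step = step or coeffs.step
    if elapsed <= 0:
        raise ModelError("elapsed must be positive")
    if age_start + elapsed > step.age_cap:
        raise ModelError(
            f"interval end {age_start + elapsed:.2f} beyond age cap {step.age_cap}"
        )
    m = step.n_steps(elapsed)
    x = coeffs.profile_vector(profile)
    ages = age_start + step.h * np.arange(m)
    Q, d = _step_rates(coeffs, ages, x)  # (m,2,2), (m,2)
    P = np.eye(3)
    F = np.zeros((3, 3))
    F[2, 2] = 1.0
    for u in range(m):
        F[:2, :2] = Q[u]
        F[:2, 2] = d[u]
        P = P @ F
    return TransitionMatrix(P, age=age_start, h=step.h)


# ---------------------------------------------------------------------------
# episode likelihood engine


class _EpisodeData:
    """Arrays extracted once per fit from the episode table.

    Precomputes, per chain step, the design matrix and the indices of
    episodes that complete at that step, so likelihood evaluations inside
    the optimizer are pure array algebra.
    """

    def __init__(self, episodes: pd.DataFrame, coeffs: TransitionCoefficients):
        step = coeffs.step
        required = {"age_start", "state_start", "elapsed", "end_state"}
        missing = required - set(episodes.columns)
        if missing:
            raise ModelError(f"episode table lacks columns {sorted(missing)}")
        if episodes.empty:
            raise ModelError("empty episode set")
        self.age0 = episodes["age_start"].to_numpy(dtype=float)
        self.j0 = episodes["state_start"].to_numpy(dtype=int) - 1
        if np.any((self.j0 < 0) | (self.j0 > 1)):
            raise ModelError("state_start must be 1 or 2")
        end = episodes["end_state"].to_numpy(dtype=int)
        if "death_age" in episodes.columns:
            dag = episodes["death_age"].to_numpy(dtype=float)
        else:  # no column: every death episode carries an exact death age
            dag = np.where(end == 3, 0.0, np.nan)
        # exact deaths place the death step; unknown-date deaths are
        # marginalized over the whole interval (dead-column mass at its end)
        self.death = (end == 3) & ~np.isnan(dag)
        self.marginal = (end == 3) & ~self.death
        self.kend = np.where(end == 3, 0, end - 1)
        elapsed = episodes["elapsed"].to_numpy(dtype=float)
        if np.any(elapsed <= 0):
            raise ModelError("episode elapsed times must be positive")
        self.m = np.maximum(np.round(elapsed / step.h).astype(int), 1)
        cov_cols = list(coeffs.covariates)
        absent = [c for c in cov_cols if c not in episodes.columns]
        if absent:
            raise ModelError(f"episode table lacks covariate columns {absent}")
        self.X = (
            episodes[cov_cols].to_numpy(dtype=float)
            if cov_cols
            else np.zeros((len(episodes), 0))
        )
        self.w = (
            episodes["weight"].to_numpy(dtype=float)
            if "weight" in episodes.columns
            else np.ones(len(episodes))
        )
        self.ids = (
            episodes["id"].to_numpy() if "id" in episodes.columns else np.arange(len(episodes))
        )
        self.n = len(episodes)

        # per-step design matrices and completion indices
        self.max_m = int(self.m.max())
        self.Z = np.empty((self.max_m, self.n, coeffs.coef.shape[1]))
        for u in range(self.max_m):
            self.Z[u] = _features(coeffs, self.age0 + u * step.h, self.X)
        self.die_idx = [np.flatnonzero(self.death & (self.m == u + 1)) for u in range(self.max_m)]
        self.fin_idx = [
            np.flatnonzero(~self.death & ~self.marginal & (self.m == u + 1))
            for u in range(self.max_m)
        ]
        self.marg_idx = [
            np.flatnonzero(self.marginal & (self.m == u + 1)) for u in range(self.max_m)
        ]


def _episode_likelihoods(
    coef: np.ndarray,
    data: _EpisodeData,
    coeffs: TransitionCoefficients,
    want_grad: bool,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-episode interval likelihoods L (n,) and dL/dtheta (n, P).

    Forward recursion over steps: v holds the living-state occupancy row
    vector of each episode; death episodes absorb into the dead column at
    their final step, state episodes read off the observed end state.
    """
    E = data.n
    q = coef.shape[1]
    P = 4 * q
    v = np.zeros((E, 2))
    v[np.arange(E), data.j0] = 1.0
    L = np.zeros(E)
    dv = np.zeros((E, P, 2)) if want_grad else None
    dL = np.zeros((E, P)) if want_grad else None
    delta = np.zeros((4, 2))
    delta[0, 1] = 1.0  # 1->2 destination is living column 1
    delta[2, 0] = 1.0  # 2->1 destination is living column 0

    for u in range(data.max_m):
        z = data.Z[u]  # (E, q)
        eta = z @ coef.T  # (E, 4)
        Q, d = _rates_from_eta(eta)
        # probability of each transition's destination from its origin row
        pdest = np.stack([Q[:, 0, 1], d[:, 0], Q[:, 1, 0], d[:, 1]], axis=1)  # (E,4)

        idx = data.die_idx[u]
        if idx.size:
            # death during this step, from the (unobserved) living state at its start
            L[idx] = (v[idx] * d[idx]).sum(axis=1)
            if want_grad:
                dLd = (dv[idx] * d[idx, None, :]).sum(axis=2).reshape(-1, 4, q)
                vr = v[idx][:, _ORIGIN]  # (e,4)
                # dp_{r3}/deta_t: own death logit -> p(1-p); same-row living logit -> -p_r3*pdest
                drow = np.empty_like(vr)
                dd = d[idx]
                pdn = pdest[idx]
                drow[:, 1] = dd[:, 0] * (1 - dd[:, 0])
                drow[:, 0] = -dd[:, 0] * pdn[:, 0]
                drow[:, 3] = dd[:, 1] * (1 - dd[:, 1])
                drow[:, 2] = -dd[:, 1] * pdn[:, 2]
                dLd += (vr * drow)[:, :, None] * z[idx][:, None, :]
                dL[idx] = dLd.reshape(-1, P)

        # unconditional step update (finished episodes' states are never read again)
        if want_grad:
            dv = dv @ Q  # batched (E,P,2) x (E,2,2)
            # dQ/deta_t affects only row _ORIGIN[t]:
            # d p_{r,k} / d eta_t = p_{r,k} * (delta_{k, dest(t)} - pdest_t)
            rowk = Q[:, _ORIGIN, :]  # (E,4,2)
            g = rowk * (delta[None, :, :] - pdest[:, :, None])  # (E,4,2)
            contrib = (v[:, _ORIGIN, None] * g)[:, :, None, :] * z[:, None, :, None]
            dv4 = dv.reshape(E, 4, q, 2)
            dv4 += contrib
            dv = dv4.reshape(E, P, 2)
        v = (v[:, None, :] @ Q)[:, 0, :]

        idx = data.fin_idx[u]
        if idx.size:
            L[idx] = v[idx, data.kend[idx]]
            if want_grad:
                dL[idx] = dv[idx, :, data.kend[idx]]

        idx = data.marg_idx[u]
        if idx.size:
            # unknown death date: probability of being dead by the interval end
            L[idx] = 1.0 - v[idx].sum(axis=1)
            if want_grad:
                dL[idx] = -dv[idx].sum(axis=2)

    return L, dL


def episode_loglik(
    coeffs: TransitionCoefficients,
    episode: Mapping | pd.DataFrame,
    step: StepParams | None = None,
) -> float:
    """Log-likelihood of one episode (or the summed table) under ``coeffs``.

    A survival-to-known-state episode contributes ``log p^{j->k}`` over the
    interval; a death-in-interval episode contributes the log-probability of
    surviving in the living states to the step containing the death age and
    dying within that step.  Zero-probability episodes yield ``-inf``.
    """
    if isinstance(episode, Mapping):
        episode = pd.DataFrame([dict(episode)])
    data = _EpisodeData(episode, coeffs)
    L, _ = _episode_likelihoods(coeffs.coef, data, coeffs, want_grad=False)
    if np.any(L <= 0):
        bad = np.flatnonzero(L <= 0)
        warnings.warn(
            f"zero-probability episodes at rows {bad[:5].tolist()} "
            f"(ids {data.ids[bad[:5]].tolist()})",
            stacklevel=2,
        )
        return float("-inf")
    return float(np.log(L).sum())


# ---------------------------------------------------------------------------
# estimator


class MultistateLogitModel(BaseEstimator):
    """Maximum (pseudo-)likelihood fit of the embedded multistate chain.

    Parameters
    ----------
    h : step length of the embedded chain in years.
    covariates : episode-table columns entering every transition logit
        (loneliness and any baseline controls, coded 0/1).
    age_slope : include a linear age term in each logit.
    age_cap, age_origin : age grid cap (forced death) and centering constant.
    cov_type : "auto" (sandwich clustered on individual when weights vary,
        model-based otherwise), "model" (inverse observed information) or
        "sandwich".
    start : optional (4, q) start values; default intercepts are -4 for the
        death logits and -2 for morbidity/recovery, all slopes 0.
    maxiter, gtol : optimizer controls (L-BFGS-B with exact gradient; a
        Nelder-Mead polish is attempted if the gradient-based search stalls).

    Attributes (after ``fit``)
    --------------------------
    coef_ : (4, q) coefficient array in :data:`TRANSITIONS` order.
    cov_ : covariance of the flattened coefficients.
    coefficients_ : the full :class:`TransitionCoefficients` bundle.
    loglik_, n_iter_, converged_, grad_norm_ : convergence diagnostics.
    """

    def __init__(
        self,
        h: float = 1.0 / 12.0,
        covariates: Sequence[str] = ("lonely",),
        age_slope: bool = True,
        age_min: float = 65.0,
        age_cap: float = 110.0,
        age_origin: float = 80.0,
        cov_type: str = "auto",
        start: np.ndarray | None = None,
        maxiter: int = 500,
        gtol: float = 1e-6,
    ):
        self.h = h
        self.covariates = covariates
        self.age_slope = age_slope
        self.age_min = age_min
        self.age_cap = age_cap
        self.age_origin = age_origin
        self.cov_type = cov_type
        self.start = start
        self.maxiter = maxiter
        self.gtol = gtol

    # -- helpers ------------------------------------------------------------
    def _template(self) -> TransitionCoefficients:
        q = 1 + int(self.age_slope) + len(tuple(self.covariates))
        return TransitionCoefficients(
            coef=np.zeros((4, q)),
            covariates=tuple(self.covariates),
            step=StepParams(
                h=self.h,
                age_min=self.age_min,
                age_cap=self.age_cap,
                age_origin=self.age_origin,
            ),
            age_slope=self.age_slope,
        )

    def _start_coef(self, q: int) -> np.ndarray:
        if self.start is not None:
            start = np.asarray(self.start, dtype=float)
            if start.shape != (4, q):
                raise ModelError(f"start must have shape (4, {q})")
            return start.copy()
        coef = np.zeros((4, q))
        coef[:, 0] = [-2.0, -4.0, -2.0, -4.0]  # death intercepts lower
        return coef

    def fit(self, episodes: pd.DataFrame, weights: np.ndarray | None = None):
        """Fit to an episode table (see :mod:`healthexpect.coding`).

        Weights default to the episode table's ``weight`` column and are
        normalized to mean 1 across individuals before use.
        """
        template = self._template()
        episodes = episodes.copy()
        if weights is not None:
            episodes["weight"] = np.asarray(weights, dtype=float)
        data = _EpisodeData(episodes, template)
        for j in (0, 1):
            if not np.any(data.j0 == j):
                raise ModelError(f"no episodes start in living state {j + 1}")
        # normalize weights to mean 1 over individuals
        ids, first = np.unique(data.ids, return_index=True)
        mean_w = data.w[first].mean()
        if mean_w <= 0:
            raise ModelError("non-positive mean weight")
        data.w = data.w / mean_w

        q = template.coef.shape[1]
        x0 = self._start_coef(q).ravel()

        def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
            L, G = _episode_likelihoods(theta.reshape(4, q), data, template, want_grad=True)
            Lc = np.maximum(L, _TINY)
            nll = -float(np.sum(data.w * np.log(Lc)))
            grad = -(G * (data.w / Lc)[:, None]).sum(axis=0)
            return nll, grad

        # precondition: the age feature spans ~±30 y, so its slope direction is
        # far stiffer than the intercepts; optimize in a rescaled parameter space
        s = np.ones(4 * q)
        if self.age_slope:
            s[1::q] = 0.1
        def objective_scaled(ti: np.ndarray) -> tuple[float, np.ndarray]:
            nll, g = objective(s * ti)
            return nll, g * s

        res = optimize.minimize(
            objective_scaled,
            x0 / s,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.maxiter, "gtol": self.gtol, "ftol": 1e-12},
        )
        if not res.success and np.linalg.norm(res.jac, np.inf) > 1e-3:
            # derivative-free fallback from the best point found
            res2 = optimize.minimize(
                lambda t: objective_scaled(t)[0],
                res.x,
                method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
            )
            if res2.fun <= res.fun:
                res2.jac = objective_scaled(res2.x)[1]
                res = res2
        theta = s * res.x
        grad_norm = float(np.linalg.norm(objective(theta)[1], np.inf))
        if not res.success and grad_norm > 1e-2:
            raise ModelError(
                f"optimizer failed to converge: {res.message} (|grad|={grad_norm:.3g})"
            )

        self.coef_ = theta.reshape(4, q)
        self.loglik_ = -float(res.fun)
        self.n_iter_ = int(getattr(res, "nit", -1))
        self.converged_ = bool(res.success)
        self.grad_norm_ = grad_norm
        self.cov_ = self._covariance(theta, data, template)
        self.coefficients_ = TransitionCoefficients(
            coef=self.coef_,
            covariates=tuple(self.covariates),
            step=template.step,
            age_slope=self.age_slope,
            cov=self.cov_,
            loglik=self.loglik_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            grad_norm=self.grad_norm_,
        )
        return self

    def _covariance(
        self, theta: np.ndarray, data: _EpisodeData, template: TransitionCoefficients
    ) -> np.ndarray:
        p = theta.size
        q = template.coef.shape[1]

        def grad_at(t: np.ndarray) -> np.ndarray:
            L, G = _episode_likelihoods(t.reshape(4, q), data, template, want_grad=True)
            Lc = np.maximum(L, _TINY)
            return (G * (data.w / Lc)[:, None]).sum(axis=0)

        # observed information by central differences of the exact gradient
        H = np.empty((p, p))
        eps = 1e-5 * np.maximum(1.0, np.abs(theta))
        for i in range(p):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps[i]
            tm[i] -= eps[i]
            H[i] = (grad_at(tp) - grad_at(tm)) / (2 * eps[i])
        H = 0.5 * (H + H.T)
        A = -H
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            warnings.warn("singular information matrix; using pseudo-inverse")
            Ainv = np.linalg.pinv(A)

        weights_vary = np.ptp(data.w) > 1e-12
        use_sandwich = self.cov_type == "sandwich" or (
            self.cov_type == "auto" and weights_vary
        )
        if not use_sandwich:
            return 0.5 * (Ainv + Ainv.T)

        # sandwich: cluster per-episode scores by individual
        L, G = _episode_likelihoods(theta.reshape(4, q), data, template, want_grad=True)
        Lc = np.maximum(L, _TINY)
        scores = G * (data.w / Lc)[:, None]  # (E, p)
        df = pd.DataFrame(scores)
        df["_id"] = data.ids
        S = df.groupby("_id", sort=False).sum().to_numpy()  # (n_ind, p)
        B = S.T @ S
        V = Ainv @ B @ Ainv
        return 0.5 * (V + V.T)

    def loglik(self, episodes: pd.DataFrame) -> float:
        """Weighted log-likelihood of an episode table at the fitted optimum."""
        return self.score_params(self.coef_, episodes)

    def score_params(self, coef: np.ndarray, episodes: pd.DataFrame) -> float:
        """Weighted log-likelihood at arbitrary coefficients (same weights rule)."""
        template = self._template()
        data = _EpisodeData(episodes, template)
        ids, first = np.unique(data.ids, return_index=True)
        data.w = data.w / data.w[first].mean()
        coef = np.asarray(coef, dtype=float).reshape(template.coef.shape)
        L, _ = _episode_likelihoods(coef, data, template, want_grad=False)
        return float(np.sum(data.w * np.log(np.maximum(L, _TINY))))


def fit_transitions(
    episodes: pd.DataFrame,
    h: float = 1.0 / 12.0,
    covariates: Sequence[str] = ("lonely",),
    **kwargs,
) -> TransitionCoefficients:
    """Functional wrapper over :class:`MultistateLogitModel`."""
    model = MultistateLogitModel(h=h, covariates=covariates, **kwargs)
    model.fit(episodes)
    return model.coefficients_


# ---------------------------------------------------------------------------
# one-year tables


def one_year_table(
    coeffs: TransitionCoefficients,
    ages: Sequence[float],
    profile: Mapping[str, float] | None = None,
    n_draws: int = 500,
    seed: int | None = 0,
    se_method: str = "bootstrap",
) -> pd.DataFrame:
    """One-year transition probabilities with standard errors, per age.

    The one-year matrix is the ordered product of ``1/h`` per-step matrices.
    Standard errors come from a parametric bootstrap over the coefficient
    sampling distribution (default, seeded) or the delta method via finite
    differences (``se_method="delta"``).
    """
    step = coeffs.step
    ages = list(ages)
    for a in ages:
        if not (step.age_min <= a <= step.age_cap - 1):
            raise ModelError(f"age {a} outside grid [{step.age_min}, {step.age_cap - 1}]")

    def year_matrix(c: TransitionCoefficients, age: float) -> np.ndarray:
        return interval_probability(c, age, 1.0, profile, step).probs

    rows = []
    ses: dict[float, np.ndarray] = {}
    if coeffs.cov is not None and n_draws > 0:
        rng = np.random.default_rng(seed)
        if se_method == "bootstrap":
            draws = rng.multivariate_normal(
                coeffs.coef.ravel(), _nearest_psd(coeffs.cov), size=n_draws, method="cholesky"
            )
            for age in ages:
                mats = np.empty((n_draws, 3, 3))
                for b, th in enumerate(draws):
                    c_b = TransitionCoefficients(
                        coef=th.reshape(coeffs.coef.shape),
                        covariates=coeffs.covariates,
                        step=step,
                        age_slope=coeffs.age_slope,
                    )
                    mats[b] = year_matrix(c_b, age)
                ses[age] = mats.std(axis=0, ddof=1)
        else:  # delta method
            theta = coeffs.coef.ravel()
            for age in ages:
                J = np.empty((theta.size, 9))
                eps = 1e-5
                for i in range(theta.size):
                    tp, tm = theta.copy(), theta.copy()
                    tp[i] += eps
                    tm[i] -= eps
                    cp = TransitionCoefficients(
                        tp.reshape(coeffs.coef.shape), coeffs.covariates, step, coeffs.age_slope
                    )
                    cm = TransitionCoefficients(
                        tm.reshape(coeffs.coef.shape), coeffs.covariates, step, coeffs.age_slope
                    )
                    J[i] = (year_matrix(cp, age) - year_matrix(cm, age)).ravel() / (2 * eps)
                V = J.T @ coeffs.cov @ J
                ses[age] = np.sqrt(np.maximum(np.diag(V), 0)).reshape(3, 3)

    for age in ages:
        P = year_matrix(coeffs, age)
        se = ses.get(age)
        for j in (1, 2):
            for k in (1, 2, 3):
                rows.append(
                    dict(
                        age=age,
                        origin=j,
                        destination=k,
                        estimate=P[j - 1, k - 1],
                        se=np.nan if se is None else se[j - 1, k - 1],
                    )
                )
    return pd.DataFrame(rows)


def _nearest_psd(cov: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Clip tiny negative eigenvalues; raise on genuinely non-PSD input."""
    cov = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() < -1e-6 * max(vals.max(), 1.0):
        raise ModelError(f"covariance is not positive semidefinite (min eig {vals.min():.3g})")
    vals = np.clip(vals, tol * max(vals.max(), 1e-30), None)
    return (vecs * vals) @ vecs.T
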