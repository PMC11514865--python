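"""Synthetic CLHLS-style longitudinal cohorts from a known multistate model.

Ground truth is the same model family the estimator fits: a fine-step Markov
chain over {healthy, unhealthy, dead} with multinomial-logit per-step
probabilities in age and covariates.  Loneliness evolves as its own two-state
chain (per-step onset/remission), individuals are observed at survey waves
three or four years apart, deaths between waves carry exact death ages, and
per-wave dropout censors all later contact — emulating a four-wave aging
panel (~15,000 respondents aged 65–99 at baseline, waves at 0/3/6/10 years).

The generator emits raw questionnaire-style columns (5-level loneliness
response, six ADL independence flags, 5-level self-rated health) so the
coding layer is exercised end-to-end, and returns a ground-truth bundle
(true parameters, latent death ages, its own episode records) so every
downstream stage can be checked against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markov import ModelError, StepParams, TransitionCoefficients, _rates_from_eta

__all__ = [
    "TrueModel",
    "WaveSchedule",
    "SimulationConfig",
    "default_true_model",
    "recovery_true_model",
    "simulate_trajectory",
    "observe_waves",
    "generate_cohort",
]


@dataclass
class TrueModel:
    """Ground-truth generating process.

    health : per-step transition logits of the primary (ADL) health process,
        as a :class:`TransitionCoefficients` (its ``step.h`` is the
        simulation step).
    srh : optional (2, q) logit coefficients for a second living-state
        morbidity process (self-rated health): rows are onset (1→2) and
        recovery (2→1), same feature layout as ``health``; death is shared
        with the primary process.  ``None`` makes SRH mirror the ADL state.
    lonely_onset, lonely_remission : per-step switch probabilities of the
        loneliness chain.
    """

    health: TransitionCoefficients
    srh: np.ndarray | None = None
    lonely_onset: float = 0.0
    lonely_remission: float = 0.0

    def __post_init__(self) -> None:
        for p, name in ((self.lonely_onset, "lonely_onset"), (self.lonely_remission, "lonely_remission")):
            if not 0.0 <= p <= 1.0:
                raise ModelError(f"{name} must be in [0, 1], got {p}")
        if self.srh is not None:
            self.srh = np.asarray(self.srh, dtype=float)
            if self.srh.shape != (2, self.health.coef.shape[1]):
                raise ModelError(
                    f"srh coefficients must have shape (2, {self.health.coef.shape[1]})"
                )

    @property
    def h(self) -> float:
        return self.health.step.h

    @property
    def covariates(self) -> tuple[str, ...]:
        return self.health.covariates


@dataclass(frozen=True)
class WaveSchedule:
    """Interview calendar: baseline plus follow-up offsets in years."""

    baseline_year: float = 2008.0
    offsets: tuple[float, ...] = (0.0, 3.0, 6.0, 10.0)
    dropout: float = 0.07

    def __post_init__(self) -> None:
        if len(self.offsets) == 0:
            raise ModelError("wave schedule must contain at least one wave")
        if any(b <= a for a, b in zip(self.offsets, self.offsets[1:])):
            raise ModelError("wave offsets must be strictly increasing")
        if not 0.0 <= self.dropout < 1.0:
            raise ModelError("dropout probability must be in [0, 1)")


@dataclass
class SimulationConfig:
    """Cohort size, baseline mixture, truth and observation design."""

    n: int = 15000
    true_model: TrueModel | None = None
    schedule: WaveSchedule = field(default_factory=WaveSchedule)
    seed: int = 0
    age_range: tuple[float, float] = (65.0, 99.0)
    age_beta: tuple[float, float] = (1.0, 3.3)  # mean ~73, like an aging panel
    p_female: float = 0.52
    p_lonely: float = 0.25  # ~one quarter lonely at baseline
    p_unhealthy: float = 0.04  # ~96% ADL-independent at baseline
    p_srh_unhealthy: float = 0.16
    weight_values: tuple[float, float] = (0.6, 1.4)  # two-point design weights
    weight_probs: tuple[float, float] = (0.5, 0.5)
    misclassification: float = 0.0
    #: emit exact death ages; if False, deaths are only known to precede the
    #: reporting wave (interval-censored mode)
    exact_death_dates: bool = True
    #: response-label mixture within the lonely / non-lonely groups
    lonely_labels: tuple[tuple[str, float], ...] = (
        ("sometimes", 0.7),
        ("often", 0.2),
        ("always", 0.1),
    )
    nonlonely_labels: tuple[tuple[str, float], ...] = (("seldom", 0.35), ("never", 0.65))
    #: extra baseline dummies (descriptive only unless named in the TrueModel)
    extra_covariates: tuple[tuple[str, float], ...] = (
        ("rural", 0.576),
        ("uneducated", 0.422),
        ("low_income", 0.155),
        ("no_spouse", 0.390),
        ("lives_alone", 0.147),
        ("region_central", 0.276),
        ("region_western", 0.289),
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ModelError("cohort size n must be >= 1")
        if self.true_model is None:
            self.true_model = default_true_model()
        for p in (self.p_female, self.p_lonely, self.p_unhealthy, self.p_srh_unhealthy):
            if not 0.0 <= p <= 1.0:
                raise ModelError("baseline prevalences must be in [0, 1]")


# ---------------------------------------------------------------------------
# calibrated defaults


def _per_step_logit(annual_q: float, h: float) -> float:
    p = 1.0 - (1.0 - annual_q) ** h
    return float(np.log(p / (1.0 - p)))


def default_true_model(h: float = 0.25) -> TrueModel:
    """Calibrated truth with loneliness and gender effects.

    Annual anchor probabilities at age 80 (non-lonely men): morbidity 0.06,
    death-from-healthy 0.05, recovery 0.25, death-from-unhealthy 0.105; log
    slopes near the classical old-age doubling rate (~0.09/y).  Loneliness
    raises the death and morbidity logits (harmful planting); women have
    lower mortality and higher morbidity.  Loneliness onset/remission make a
    stationary lonely share of ~25%.
    """
    cov = ("lonely", "female")
    coef = np.array(
        [
            #               intercept,              age,  lonely, female
            [_per_step_logit(0.060, h), 0.090, 0.30, 0.15],  # 1 -> 2
            [_per_step_logit(0.050, h), 0.092, 0.35, -0.30],  # 1 -> 3
            [_per_step_logit(0.250, h), -0.050, 0.00, -0.10],  # 2 -> 1
            [_per_step_logit(0.105, h), 0.092, 0.35, -0.30],  # 2 -> 3
        ]
    )
    health = TransitionCoefficients(
        coef=coef, covariates=cov, step=StepParams(h=h), age_slope=True
    )
    srh = np.array(
        [
            [_per_step_logit(0.120, h), 0.035, 0.35, 0.10],  # SRH onset
            [_per_step_logit(0.350, h), -0.020, -0.15, -0.05],  # SRH recovery
        ]
    )
    onset = 1.0 - (1.0 - 0.11) ** h
    remission = 1.0 - (1.0 - 0.33) ** h
    return TrueModel(health=health, srh=srh, lonely_onset=onset, lonely_remission=remission)


def recovery_true_model(h: float = 0.25) -> TrueModel:
    """Truth for parameter-recovery experiments: loneliness covariate only.

    Loneliness is held fixed at its baseline value (onset = remission = 0)
    so the generating process lies exactly in the fitted model class — the
    estimator carries the last observed loneliness forward within episodes,
    which is exact only when loneliness does not switch between interviews.
    """
    cov = ("lonely",)
    coef = np.array(
        [
            [_per_step_logit(0.060, h), 0.090, 0.30],
            [_per_step_logit(0.050, h), 0.092, 0.35],
            [_per_step_logit(0.250, h), -0.050, 0.00],
            [_per_step_logit(0.105, h), 0.092, 0.35],
        ]
    )
    health = TransitionCoefficients(
        coef=coef, covariates=cov, step=StepParams(h=h), age_slope=True
    )
    return TrueModel(health=health, srh=None, lonely_onset=0.0, lonely_remission=0.0)


# ---------------------------------------------------------------------------
# stepping engine


def _covariate_matrix(model: TrueModel, values: Mapping[str, np.ndarray], n: int) -> np.ndarray:
    cols = []
    for name in model.covariates:
        if name == "lonely":
            continue  # time-varying, supplied per step
        if name not in values:
            raise ModelError(f"TrueModel covariate {name!r} missing from baseline attributes")
        cols.append(np.asarray(values[name], dtype=float))
    return np.stack(cols, axis=-1) if cols else np.zeros((n, 0))


def _step_probs(
    model: TrueModel, ages: np.ndarray, lonely: np.ndarray, fixed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Living 2x2 block and death column of the primary process, per subject."""
    c = model.health
    cols = [np.ones_like(ages)]
    if c.age_slope:
        cols.append(ages - c.step.age_origin)
    covs = []
    fixed_iter = iter(fixed.T)
    for name in c.covariates:
        covs.append(lonely.astype(float) if name == "lonely" else next(fixed_iter))
    z = np.stack(cols + covs, axis=-1)  # (n, q)
    eta = z @ c.coef.T
    Q, d = _rates_from_eta(eta)
    return Q, d, z


def _srh_probs(model: TrueModel, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    eta = z @ model.srh.T
    e = np.exp(np.clip(eta, -50, 50))
    p = e / (1.0 + e)
    return p[:, 0], p[:, 1]  # onset, recovery


def simulate_trajectory(
    model: TrueModel,
    baseline: Mapping[str, float],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, float | None]:
    """Latent path of one individual at step ``h`` until death or the age cap.

    ``baseline`` must provide ``age``, ``health`` (1/2), ``lonely`` (0/1),
    any fixed covariates named by the TrueModel, and optionally ``srh``
    (1/2).  Returns the path (age, health, lonely[, srh]) and the exact
    death age (``None`` if the cap is reached alive).
    """
    h = model.h
    cap = model.health.step.age_cap
    age = float(baseline["age"])
    if not model.health.step.age_min <= age <= cap:
        raise ModelError(f"baseline age {age} outside [{model.health.step.age_min}, {cap}]")
    state = int(baseline.get("health", 1))
    lonely = int(baseline.get("lonely", 0))
    srh = int(baseline.get("srh", state))
    fixed = _covariate_matrix(model, {k: np.asarray([v]) for k, v in baseline.items()}, 1)

    ages, states, lons, srhs = [age], [state], [lonely], [srh]
    death_age = None
    while age + h <= cap + 1e-12 and death_age is None:
        Q, d, z = _step_probs(model, np.asarray([age]), np.asarray([lonely]), fixed)
        u = rng.random()
        j = state - 1
        if u < d[0, j]:
            death_age = age + h
            break
        elif u < d[0, j] + Q[0, j, 1 - j]:
            state = 2 - j  # switched living state
        if model.srh is not None:
            onset, recov = _srh_probs(model, z)
            u2 = rng.random()
            if srh == 1 and u2 < onset[0]:
                srh = 2
            elif srh == 2 and u2 < recov[0]:
                srh = 1
        else:
            srh = state
        u3 = rng.random()
        if lonely == 0 and u3 < model.lonely_onset:
            lonely = 1
        elif lonely == 1 and u3 < model.lonely_remission:
            lonely = 0
        age += h
        ages.append(age)
        states.append(state)
        lons.append(lonely)
        srhs.append(srh)
    if death_age is None and age + h > cap:
        death_age = cap  # forced closure at the cap
    path = pd.DataFrame({"age": ages, "health": states, "lonely": lons, "srh": srhs})
    return path, death_age


def observe_waves(
    path: pd.DataFrame,
    death_age: float | None,
    schedule: WaveSchedule,
    rng: np.random.Generator,
) -> dict:
    """Panel observation of one latent path.

    States are read off the path at wave ages (baseline age + offsets);
    dropout at a follow-up wave censors that wave and all later ones; a
    death is reported — with its exact age — at the first attempted contact
    after it.  Individuals dead before the first follow-up still contribute
    a death record.
    """
    base_age = float(path["age"].iloc[0])
    wave_ages = [base_age + off for off in schedule.offsets]
    drop = rng.random(len(wave_ages))
    dropout_wave = next(
        (w for w in range(1, len(wave_ages)) if drop[w] < schedule.dropout), None
    )
    observations = []
    for w, wa in enumerate(wave_ages):
        if dropout_wave is not None and w >= dropout_wave:
            break
        if death_age is not None and wa >= death_age:
            break
        idx = int(round((wa - base_age) / (path["age"].iloc[1] - base_age))) if len(path) > 1 else 0
        idx = min(idx, len(path) - 1)
        row = path.iloc[idx]
        observations.append(
            dict(wave=w, interview_age=wa, health=int(row["health"]),
                 lonely=int(row["lonely"]), srh=int(row["srh"]))
        )
    observed_death = None
    if death_age is not None:
        next_contact = next((w for w, wa in enumerate(wave_ages) if wa >= death_age), None)
        if next_contact is not None and (dropout_wave is None or next_contact < dropout_wave):
            observed_death = death_age
    censor_age = observed_death if observed_death is not None else (
        observations[-1]["interview_age"] if observations else base_age
    )
    return {
        "observations": observations,
        "death_age": observed_death,
        "censor_age": censor_age,
        "dropout_wave": dropout_wave,
    }


# ---------------------------------------------------------------------------
# cohort generation (vectorized)

_SRH_HEALTHY_LABELS = (("good", 0.75), ("very good", 0.25))
_SRH_UNHEALTHY_LABELS = (("so-so", 0.6), ("bad", 0.3), ("very bad", 0.1))


def _draw_labels(rng: np.random.Generator, mixture, size: int) -> np.ndarray:
    labels = [m[0] for m in mixture]
    probs = np.asarray([m[1] for m in mixture], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(labels, size=size, p=probs)


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a full panel cohort; reproducible for a fixed seed.

    Returns the person-wave table (questionnaire-style columns, the dialect
    :func:`healthexpect.coding.load_cohort` reads) and a ground-truth bundle
    with the TrueModel, latent per-individual summaries and the generator's
    own episode records per indicator.
    """
    model = config.true_model
    h = model.h
    cap = model.health.step.age_cap
    sched = config.schedule
    for off in sched.offsets:
        if abs(off / h - round(off / h)) > 1e-9:
            raise ModelError(f"wave offset {off} is not a multiple of the step h={h}")
    rng = np.random.default_rng(config.seed)
    n = config.n

    lo, hi = config.age_range
    ages0 = lo + (hi - lo) * rng.beta(*config.age_beta, size=n)
    female = (rng.random(n) < config.p_female).astype(int)
    lonely = (rng.random(n) < config.p_lonely).astype(int)
    health = np.where(rng.random(n) < config.p_unhealthy, 2, 1)
    srh_state = np.where(rng.random(n) < config.p_srh_unhealthy, 2, 1)
    extra = {name: (rng.random(n) < p).astype(int) for name, p in config.extra_covariates}
    w_raw = np.where(rng.random(n) < config.weight_probs[0], *config.weight_values)
    weight = w_raw / w_raw.mean()  # normalized to mean 1

    base_values = {"female": female, **extra}
    fixed = _covariate_matrix(model, base_values, n)

    offsets = np.asarray(sched.offsets)
    wave_steps = np.round(offsets / h).astype(int)
    n_waves = len(offsets)
    wave_health = np.zeros((n, n_waves), dtype=int)
    wave_lonely = np.zeros((n, n_waves), dtype=int)
    wave_srh = np.zeros((n, n_waves), dtype=int)
    wave_health[:, 0], wave_lonely[:, 0], wave_srh[:, 0] = health, lonely, srh_state

    death_age = np.full(n, np.nan)
    alive = np.ones(n, dtype=bool)
    max_steps = int(np.ceil((cap - lo) / h))
    for k in range(max_steps):
        if not alive.any():
            break
        ages = ages0 + k * h
        can_step = alive & (ages + h <= cap + 1e-12)
        Q, d, z = _step_probs(model, ages, lonely, fixed)
        u = rng.random(n)
        j = health - 1  # 0/1
        p_die = d[np.arange(n), j]
        p_switch = Q[np.arange(n), j, 1 - j]
        die = can_step & (u < p_die)
        switch = can_step & ~die & (u < p_die + p_switch)
        death_age[die] = ages[die] + h
        alive &= ~die
        health = np.where(switch, 3 - health, health)
        if model.srh is not None:
            onset, recov = _srh_probs(model, z)
            u2 = rng.random(n)
            go_bad = can_step & ~die & (srh_state == 1) & (u2 < onset)
            get_well = can_step & ~die & (srh_state == 2) & (u2 < recov)
            srh_state = np.where(go_bad, 2, np.where(get_well, 1, srh_state))
        else:
            srh_state = health
        u3 = rng.random(n)
        on = can_step & (lonely == 0) & (u3 < model.lonely_onset)
        off_ = can_step & (lonely == 1) & (u3 < model.lonely_remission)
        lonely = np.where(on, 1, np.where(off_, 0, lonely))
        # force death at the cap for those who can take no further step
        hit_cap = alive & (ages0 + (k + 1) * h + h > cap + 1e-12)
        death_age[hit_cap] = np.minimum(ages0[hit_cap] + (k + 1) * h + h, cap)
        alive &= ~hit_cap
        at_wave = np.flatnonzero(wave_steps == k + 1)
        for wi in at_wave:
            rec = ~np.isnan(death_age) & (death_age <= ages0 + (k + 1) * h - 1e-12)
            wave_health[:, wi] = np.where(rec, 0, health)
            wave_lonely[:, wi] = np.where(rec, -1, lonely)
            wave_srh[:, wi] = np.where(rec, 0, srh_state)

    # observation layer: dropout and death reporting
    drop_draws = rng.random((n, n_waves))
    dropout_wave = np.full(n, n_waves, dtype=int)
    for w in range(1, n_waves):
        hit = (drop_draws[:, w] < sched.dropout) & (dropout_wave == n_waves)
        dropout_wave[hit] = w

    wave_ages = ages0[:, None] + offsets[None, :]
    alive_at_wave = np.isnan(death_age)[:, None] | (wave_ages < death_age[:, None] - 1e-12)
    observed = alive_at_wave & (np.arange(n_waves)[None, :] < dropout_wave[:, None])

    # death observed at the first attempted contact after it
    died = ~np.isnan(death_age)
    first_contact_after = np.full(n, n_waves, dtype=int)
    for w in range(n_waves):
        hits = died & (wave_ages[:, w] >= death_age - 1e-12) & (first_contact_after == n_waves)
        first_contact_after[hits] = w
    death_observed = died & (first_contact_after < n_waves) & (first_contact_after < dropout_wave)
    report_age = np.where(
        death_observed,
        wave_ages[np.arange(n), np.minimum(first_contact_after, n_waves - 1)],
        np.nan,
    )

    if config.misclassification > 0:
        flips = rng.random((n, n_waves)) < config.misclassification
        wave_health = np.where(flips & (wave_health > 0), 3 - wave_health, wave_health)

    # assemble person-wave rows
    rows = []
    for w in range(n_waves):
        sel = np.flatnonzero(observed[:, w])
        if sel.size == 0:
            continue
        m = sel.size
        lon_w = wave_lonely[sel, w]
        lab = np.where(
            lon_w == 1,
            _draw_labels(rng, config.lonely_labels, m),
            _draw_labels(rng, config.nonlonely_labels, m),
        )
        srh_lab = np.where(
            wave_srh[sel, w] == 1,
            _draw_labels(rng, _SRH_HEALTHY_LABELS, m),
            _draw_labels(rng, _SRH_UNHEALTHY_LABELS, m),
        )
        unhealthy = wave_health[sel, w] == 2
        adl = {f"adl_{item}": np.ones(m, dtype=int) for item in
               ("eating", "dressing", "toileting", "transfer", "continence", "bathing")}
        adl["adl_bathing"] = np.where(unhealthy, 0, 1)
        for item in ("eating", "dressing", "toileting", "transfer", "continence"):
            extra_dep = unhealthy & (rng.random(m) < 0.3)
            adl[f"adl_{item}"] = np.where(extra_dep, 0, adl[f"adl_{item}"])
        frame = pd.DataFrame(
            dict(
                id=sel,
                wave=w,
                interview_age=wave_ages[sel, w],
                lonely_response=lab,
                srh_response=srh_lab,
                **adl,
                female=female[sel],
                **{k: v[sel] for k, v in extra.items()},
                weight=weight[sel],
                death_age=(
                    np.where(death_observed[sel], death_age[sel], np.nan)
                    if config.exact_death_dates
                    else np.full(m, np.nan)
                ),
                death_report_age=(
                    np.full(m, np.nan) if config.exact_death_dates else report_age[sel]
                ),
            )
        )
        rows.append(frame)
    cohort = pd.concat(rows, ignore_index=True).sort_values(["id", "wave"], kind="mergesort")
    cohort = cohort.reset_index(drop=True)

    truth = {
        "true_model": {
            "health": model.health.to_dict(),
            "srh": None if model.srh is None else model.srh.tolist(),
            "lonely_onset": model.lonely_onset,
            "lonely_remission": model.lonely_remission,
        },
        "seed": config.seed,
        "latent": pd.DataFrame(
            dict(
                id=np.arange(n),
                baseline_age=ages0,
                female=female,
                lonely0=wave_lonely[:, 0],
                death_age=death_age,
                death_observed=death_observed,
                dropout_wave=dropout_wave,
            )
        ),
        "episodes_adl": _truth_episodes(
            ages0, wave_ages, observed, wave_health, wave_lonely, weight,
            death_age, death_observed, report_age, config.exact_death_dates
        ),
        "episodes_srh": _truth_episodes(
            ages0, wave_ages, observed, wave_srh, wave_lonely, weight,
            death_age, death_observed, report_age, config.exact_death_dates
        ),
    }
    return cohort, truth


def _truth_episodes(
    ages0, wave_ages, observed, wave_state, wave_lonely, weight,
    death_age, death_observed, report_age, exact_death_dates=True,
) -> pd.DataFrame:
    """The generator's own episode records (what build_histories must recover)."""
    n, n_waves = observed.shape
    rows = []
    for i in range(n):
        waves = np.flatnonzero(observed[i])
        for a, b in zip(waves, waves[1:]):
            rows.append(
                dict(
                    id=i,
                    age_start=wave_ages[i, a],
                    state_start=int(wave_state[i, a]),
                    elapsed=wave_ages[i, b] - wave_ages[i, a],
                    end_state=int(wave_state[i, b]),
                    death_age=np.nan,
                    lonely=int(wave_lonely[i, a]),
                    weight=weight[i],
                )
            )
        if death_observed[i] and waves.size:
            last = waves[-1]
            end_age = death_age[i] if exact_death_dates else report_age[i]
            rows.append(
                dict(
                    id=i,
                    age_start=wave_ages[i, last],
                    state_start=int(wave_state[i, last]),
                    elapsed=end_age - wave_ages[i, last],
                    end_state=3,
                    death_age=death_age[i] if exact_death_dates else np.nan,
                    lonely=int(wave_lonely[i, last]),
                    weight=weight[i],
                )
            )
    return pd.DataFrame(
        rows,
        columns=["id", "age_start", "state_start", "elapsed", "end_state",
                 "death_age", "lonely", "weight"],
    )
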