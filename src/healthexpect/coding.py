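"""Reading, recoding and filtering of longitudinal health-panel data.

The functions here turn a person-wave table (one row per individual per
interview) into per-individual transition histories and an *episode* table —
one row per pair of consecutive observations (or observation → death) — which
is the unit of the interval-censored likelihood in :mod:`healthexpect.markov`.

Coding conventions follow single-item loneliness and health instruments used
in aging surveys such as the CLHLS:

* loneliness — "Do you often feel lonely and isolated?" on a 5-level scale
  (always / often / sometimes / seldom / never); "sometimes" or more frequent
  is coded lonely;
* ADL — the six Katz activities of daily living (eating, dressing, toileting,
  indoor transfer, continence, bathing); any dependence codes as limitation;
* SRH — self-rated health on 5 levels; "good" or "very good" codes healthy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LONELINESS_LEVELS: tuple[str, ...] = ("always", "often", "sometimes", "seldom", "never")
SRH_LEVELS: tuple[str, ...] = ("very good", "good", "so-so", "bad", "very bad")
ADL_ITEMS: tuple[str, ...] = (
    "eating",
    "dressing",
    "toileting",
    "transfer",
    "continence",
    "bathing",
)

#: canonical person-wave columns understood by :func:`build_histories`
WAVE_COLUMNS = ("id", "wave", "interview_age", "weight")


class CodingError(ValueError):
    """A response value outside the declared scale, or malformed items."""


@dataclass(frozen=True)
class CodingRules:
    """How raw responses are dichotomized into model states.

    Parameters
    ----------
    loneliness_cutoff : responses coded as lonely (must be a non-empty proper
        subset of the 5-level loneliness scale).
    adl_items : the six ADL item names expected in the input table (columns
        ``adl_<item>`` holding 1 = independent, 0 = dependent).
    srh_healthy_levels : responses coded as healthy.
    indicator : which health indicator defines the living states,
        ``"adl"`` or ``"srh"``.
    """

    loneliness_cutoff: frozenset[str] = frozenset({"always", "often", "sometimes"})
    adl_items: tuple[str, ...] = ADL_ITEMS
    srh_healthy_levels: frozenset[str] = frozenset({"very good", "good"})
    indicator: str = "adl"

    def __post_init__(self) -> None:
        if len(self.adl_items) != 6:
            raise CodingError(f"exactly 6 ADL items required, got {len(self.adl_items)}")
        for cutoff, scale, name in (
            (self.loneliness_cutoff, set(LONELINESS_LEVELS), "loneliness_cutoff"),
            (self.srh_healthy_levels, set(SRH_LEVELS), "srh_healthy_levels"),
        ):
            if not cutoff or not set(cutoff) < scale:
                raise CodingError(
                    f"{name} must be a non-empty proper subset of {sorted(scale)}"
                )
        if self.indicator not in ("adl", "srh"):
            raise CodingError(f"indicator must be 'adl' or 'srh', got {self.indicator!r}")


@dataclass
class ObservationRecord:
    """A single interview of one individual."""

    individual_id: object
    interview_age: float
    health_state: int | None  # 1 = healthy, 2 = unhealthy, None = missing
    lonely: int | None  # 1 = lonely, 0 = non-lonely, None = missing
    covariates: dict[str, float] = field(default_factory=dict)
    weight: float = 1.0


@dataclass
class IndividualHistory:
    """One person's ordered interview sequence plus death/censoring info.

    ``death_age`` is an exact death age; ``death_report_age`` marks a death
    known only to have occurred before that contact age (the likelihood then
    marginalizes the death time over the interval).
    """

    individual_id: object
    observations: list[ObservationRecord]
    death_age: float | None = None
    death_report_age: float | None = None
    covariates: dict[str, float] = field(default_factory=dict)
    weight: float = 1.0

    @property
    def censor_age(self) -> float:
        """Age at last contact (death age if the death was observed)."""
        if self.death_age is not None:
            return self.death_age
        if self.death_report_age is not None:
            return self.death_report_age
        return self.observations[-1].interview_age

    @property
    def n_episodes(self) -> int:
        n = len(self.observations) - 1
        if self.death_age is not None or self.death_report_age is not None:
            n += 1
        return max(n, 0)

    def validate(self) -> None:
        ages = [o.interview_age for o in self.observations]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise CodingError(
                f"individual {self.individual_id}: observation ages not strictly increasing"
            )
        if self.death_age is not None and ages and self.death_age < ages[-1]:
            raise CodingError(
                f"individual {self.individual_id}: state recorded after death "
                f"(last interview {ages[-1]:.3f} > death {self.death_age:.3f})"
            )


@dataclass(frozen=True)
class EligibilityCriteria:
    """Baseline inclusion rules, applied in field order."""

    min_age: float = 65.0
    max_age: float = 99.0
    require_community_dwelling: bool = True
    min_followup_waves: int = 1
    require_valid_health_measures: bool = True

    def __post_init__(self) -> None:
        if not self.min_age < self.max_age:
            raise ValueError("min_age must be < max_age")


# ---------------------------------------------------------------------------
# dichotomization


def dichotomize_loneliness(response: str | None, rules: CodingRules | None = None) -> str | None:
    """Collapse the 5-level loneliness response to ``"lonely"``/``"non-lonely"``.

    "sometimes", "often" and "always" code lonely by default; missing
    responses propagate as ``None``.
    """
    if response is None or (isinstance(response, float) and np.isnan(response)):
        return None
    cutoff = (rules or CodingRules()).loneliness_cutoff
    if response not in LONELINESS_LEVELS:
        raise CodingError(f"unrecognized loneliness response: {response!r}")
    return "lonely" if response in cutoff else "non-lonely"


def dichotomize_adl(item_scores: Sequence[int]) -> str:
    """Code six ADL independence flags (1 = independent) to a limitation label.

    All six independent → ``"no_limitation"``; any dependence → ``"limitation"``.
    """
    scores = list(item_scores)
    if len(scores) != 6:
        raise CodingError(f"exactly 6 ADL items required, got {len(scores)}")
    if any(s not in (0, 1) for s in scores):
        raise CodingError(f"ADL items must be 0/1 flags, got {scores}")
    return "no_limitation" if all(s == 1 for s in scores) else "limitation"


def dichotomize_srh(response: str | None, rules: CodingRules | None = None) -> str | None:
    """Collapse 5-level self-rated health to ``"healthy"``/``"unhealthy"``."""
    if response is None or (isinstance(response, float) and np.isnan(response)):
        return None
    healthy = (rules or CodingRules()).srh_healthy_levels
    if response not in SRH_LEVELS:
        raise CodingError(f"unrecognized self-rated health response: {response!r}")
    return "healthy" if response in healthy else "unhealthy"


_STATE_CODE = {"no_limitation": 1, "limitation": 2, "healthy": 1, "unhealthy": 2}
_LONELY_CODE = {"lonely": 1, "non-lonely": 0}


def to_health_state(label: str | None) -> int | None:
    """Map a dichotomized health label to state code 1 (healthy) / 2 (unhealthy)."""
    if label is None:
        return None
    return _STATE_CODE[label]


# ---------------------------------------------------------------------------
# input


def load_cohort(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a person-wave CSV into the canonical column layout.

    ``column_map`` maps canonical names (``id``, ``interview_age``,
    ``lonely_response``, ``srh_response``, ``adl_<item>``, ``weight``,
    ``death_age``, covariate names) to the columns of the file.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in ("id", "interview_age") if c not in df.columns]
    if missing:
        raise CodingError(f"cohort table lacks required columns: {missing}")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    return df


def recode_cohort(df: pd.DataFrame, rules: CodingRules | None = None) -> pd.DataFrame:
    """Add ``health_state`` (1/2/NaN) and ``lonely`` (0/1/NaN) columns.

    The health state follows ``rules.indicator``: ADL item flags
    (columns ``adl_<item>``) or the SRH response column.
    """
    rules = rules or CodingRules()
    out = df.copy()

    lon = np.full(len(df), np.nan)
    if "lonely_response" in df.columns:
        for i, resp in enumerate(df["lonely_response"]):
            lab = dichotomize_loneliness(None if pd.isna(resp) else resp, rules)
            if lab is not None:
                lon[i] = _LONELY_CODE[lab]
    elif "lonely" in df.columns:
        lon = df["lonely"].to_numpy(dtype=float)
    out["lonely"] = lon

    state = np.full(len(df), np.nan)
    if rules.indicator == "adl":
        cols = [f"adl_{item}" for item in rules.adl_items]
        absent = [c for c in cols if c not in df.columns]
        if absent:
            raise CodingError(f"ADL indicator requested but columns missing: {absent}")
        items = df[cols].to_numpy(dtype=float)
        ok = ~np.isnan(items).any(axis=1)
        for i in np.flatnonzero(ok):
            state[i] = _STATE_CODE[dichotomize_adl(items[i].astype(int))]
    else:
        if "srh_response" not in df.columns:
            raise CodingError("SRH indicator requested but column 'srh_response' missing")
        for i, resp in enumerate(df["srh_response"]):
            lab = dichotomize_srh(None if pd.isna(resp) else resp, rules)
            if lab is not None:
                state[i] = _STATE_CODE[lab]
    out["health_state"] = state
    return out


# ---------------------------------------------------------------------------
# histories and episodes

#: columns of the canonical episode table
EPISODE_COLUMNS = (
    "id",
    "age_start",
    "state_start",
    "elapsed",
    "end_state",
    "death_age",
    "lonely",
    "weight",
)


def build_histories(
    table: pd.DataFrame,
    rules: CodingRules | None = None,
    covariates: Sequence[str] = (),
) -> tuple[list[IndividualHistory], pd.DataFrame]:
    """Assemble per-individual histories and the episode table.

    Parameters
    ----------
    table : person-wave table; either already recoded (columns
        ``health_state`` and ``lonely``) or raw (then ``rules`` is applied
        via :func:`recode_cohort`).  A ``death_age`` column, where present
        and non-missing, records the exact death age of that individual.
    covariates : baseline covariate columns (0/1 dummies) to carry onto each
        episode row.

    Returns
    -------
    histories : validated :class:`IndividualHistory` objects (waves with a
        missing health state or loneliness are dropped, adjacent waves kept).
    episodes : one row per consecutive observation pair, with loneliness
        carried forward from the episode's starting interview; an observed
        death adds a final episode ending in state 3 at the exact death age.
    """
    if table.empty:
        raise CodingError("empty person-wave table")
    if "health_state" not in table.columns or "lonely" not in table.columns:
        table = recode_cohort(table, rules)

    dup = table.duplicated(subset=["id", "interview_age"])
    if dup.any():
        bad = table.loc[dup, ["id", "interview_age"]].iloc[0]
        raise CodingError(
            f"duplicate (id, age) row: id={bad['id']!r} age={bad['interview_age']}"
        )

    table = table.sort_values(["id", "interview_age"], kind="mergesort")
    histories: list[IndividualHistory] = []
    rows: list[dict] = []
    for ind_id, g in table.groupby("id", sort=False):
        death_age = None
        if "death_age" in g.columns:
            d = g["death_age"].dropna()
            if len(d):
                death_age = float(d.iloc[0])
        death_report_age = None
        if death_age is None and "death_report_age" in g.columns:
            d = g["death_report_age"].dropna()
            if len(d):
                death_report_age = float(d.iloc[0])
        weight = float(g["weight"].iloc[0])
        covs = {c: float(g[c].iloc[0]) for c in covariates}

        obs = []
        for _, r in g.iterrows():
            if pd.isna(r["health_state"]) or pd.isna(r["lonely"]):
                continue  # drop this wave, keep the rest
            obs.append(
                ObservationRecord(
                    individual_id=ind_id,
                    interview_age=float(r["interview_age"]),
                    health_state=int(r["health_state"]),
                    lonely=int(r["lonely"]),
                    covariates=covs,
                    weight=weight,
                )
            )
        hist = IndividualHistory(
            individual_id=ind_id,
            observations=obs,
            death_age=death_age,
            death_report_age=death_report_age,
            covariates=covs,
            weight=weight,
        )
        hist.validate()
        histories.append(hist)

        for a, b in zip(obs, obs[1:]):
            rows.append(
                dict(
                    id=ind_id,
                    age_start=a.interview_age,
                    state_start=a.health_state,
                    elapsed=b.interview_age - a.interview_age,
                    end_state=b.health_state,
                    death_age=np.nan,
                    lonely=a.lonely,
                    weight=weight,
                    **covs,
                )
            )
        if (death_age is not None or death_report_age is not None) and obs:
            last = obs[-1]
            end_age = death_age if death_age is not None else death_report_age
            rows.append(
                dict(
                    id=ind_id,
                    age_start=last.interview_age,
                    state_start=last.health_state,
                    elapsed=end_age - last.interview_age,
                    end_state=3,
                    death_age=np.nan if death_age is None else death_age,
                    lonely=last.lonely,
                    weight=weight,
                    **covs,
                )
            )

    episodes = pd.DataFrame(rows, columns=list(EPISODE_COLUMNS) + list(covariates))
    if len(episodes):
        bad = episodes["elapsed"] <= 0
        if bad.any():
            raise CodingError(
                f"non-positive episode durations for ids "
                f"{episodes.loc[bad, 'id'].unique()[:5].tolist()}"
            )
    return histories, episodes


def apply_eligibility(
    histories: Iterable[IndividualHistory],
    criteria: EligibilityCriteria | None = None,
) -> tuple[list[IndividualHistory], pd.DataFrame]:
    """Filter histories by baseline eligibility; log exclusions per criterion.

    Criteria are applied in order: community dwelling (covariate
    ``in_facility`` = 1 excludes), baseline age window, minimum follow-up
    (at least ``min_followup_waves`` episodes, an observed death counts),
    valid baseline health measure.  The exclusion log counts removals per
    criterion; counts sum to input size − output size.
    """
    criteria = criteria or EligibilityCriteria()
    histories = list(histories)
    if not histories:
        raise CodingError("empty input: no individual histories")

    counts = {
        "care_facility": 0,
        "baseline_age": 0,
        "no_followup": 0,
        "invalid_health_measure": 0,
    }
    kept: list[IndividualHistory] = []
    for h in histories:
        if criteria.require_community_dwelling and h.covariates.get("in_facility", 0) == 1:
            counts["care_facility"] += 1
            continue
        if not h.observations:
            if criteria.require_valid_health_measures:
                counts["invalid_health_measure"] += 1
                continue
            counts["no_followup"] += 1
            continue
        base_age = h.observations[0].interview_age
        if not (criteria.min_age <= base_age <= criteria.max_age):
            counts["baseline_age"] += 1
            continue
        if h.n_episodes < criteria.min_followup_waves:
            counts["no_followup"] += 1
            continue
        if criteria.require_valid_health_measures and h.observations[0].health_state is None:
            counts["invalid_health_measure"] += 1
            continue
        kept.append(h)

    if not kept:
        logger.warning("eligibility filtering removed every individual")
    log = pd.DataFrame(
        {"criterion": list(counts), "excluded": list(counts.values())}
    )
    return kept, log


def episodes_from_histories(
    histories: Iterable[IndividualHistory], covariates: Sequence[str] = ()
) -> pd.DataFrame:
    """Episode table for an already-filtered list of histories."""
    rows = []
    for h in histories:
        covs = {c: h.covariates.get(c, 0.0) for c in covariates}
        obs = h.observations
        for a, b in zip(obs, obs[1:]):
            rows.append(
                dict(
                    id=h.individual_id,
                    age_start=a.interview_age,
                    state_start=a.health_state,
                    elapsed=b.interview_age - a.interview_age,
                    end_state=b.health_state,
                    death_age=np.nan,
                    lonely=a.lonely,
                    weight=h.weight,
                    **covs,
                )
            )
        if (h.death_age is not None or h.death_report_age is not None) and obs:
            last = obs[-1]
            end_age = h.death_age if h.death_age is not None else h.death_report_age
            rows.append(
                dict(
                    id=h.individual_id,
                    age_start=last.interview_age,
                    state_start=last.health_state,
                    elapsed=end_age - last.interview_age,
                    end_state=3,
                    death_age=np.nan if h.death_age is None else h.death_age,
                    lonely=last.lonely,
                    weight=h.weight,
                    **covs,
                )
            )
    return pd.DataFrame(rows, columns=list(EPISODE_COLUMNS) + list(covariates))
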