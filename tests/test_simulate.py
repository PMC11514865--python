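"""The synthetic cohort generator against its own ground truth."""

import numpy as np
import pandas as pd
import pytest

from healthexpect.coding import CodingRules, build_histories, recode_cohort
from healthexpect.lifetable import exposure_deaths_by_band, kannisto_fit
from healthexpect.markov import StepParams, TransitionCoefficients, step_matrix
from healthexpect.simulate import (
    SimulationConfig,
    TrueModel,
    WaveSchedule,
    generate_cohort,
    observe_waves,
    recovery_true_model,
    simulate_trajectory,
)


def _model(logits, h=0.25, onset=0.0, remission=0.0):
    coef = np.asarray(logits, dtype=float)[:, None]
    health = TransitionCoefficients(
        coef=coef, covariates=(), step=StepParams(h=h), age_slope=False
    )
    return TrueModel(health=health, lonely_onset=onset, lonely_remission=remission)


class TestTrajectory:
    def test_no_event_model_survives_to_cap(self, rng):
        model = _model([-50, -50, -50, -50])
        path, death_age = simulate_trajectory(model, {"age": 70.0, "health": 2}, rng)
        assert (path["health"] == 2).all()
        assert death_age == pytest.approx(110.0)

    def test_certain_death_in_first_step(self, rng):
        model = _model([-50, 50, -50, 50])
        path, death_age = simulate_trajectory(model, {"age": 70.0, "health": 1}, rng)
        assert death_age == pytest.approx(70.25)
        assert len(path) == 1

    def test_zero_remission_makes_loneliness_absorbing(self, rng):
        model = _model([-50, -50, -50, -50], onset=0.5, remission=0.0)
        path, _ = simulate_trajectory(model, {"age": 70.0, "health": 1, "lonely": 0}, rng)
        lon = path["lonely"].to_numpy()
        assert lon.max() == 1  # onset happened at some point
        first = np.argmax(lon == 1)
        assert (lon[first:] == 1).all()


class TestObserveWaves:
    def test_death_between_waves_reported_exactly(self, rng):
        model = _model([-50, -50, -50, -50])
        path, _ = simulate_trajectory(model, {"age": 70.0, "health": 1}, rng)
        sched = WaveSchedule(offsets=(0.0, 3.0), dropout=0.0)
        hist = observe_waves(path, 71.25, sched, rng)
        assert [o["interview_age"] for o in hist["observations"]] == [70.0]
        assert hist["death_age"] == pytest.approx(71.25)

    def test_dropout_censors_later_waves(self):
        model = _model([-50, -50, -50, -50])
        rng = np.random.default_rng(0)
        path, _ = simulate_trajectory(model, {"age": 70.0, "health": 1}, rng)
        sched = WaveSchedule(offsets=(0.0, 3.0, 6.0, 10.0), dropout=0.999)
        hist = observe_waves(path, None, sched, np.random.default_rng(1))
        assert hist["dropout_wave"] == 1
        assert len(hist["observations"]) == 1
        assert hist["censor_age"] == pytest.approx(70.0)

    def test_complete_followup_gives_all_waves(self, rng):
        model = _model([-50, -50, -50, -50])
        path, _ = simulate_trajectory(model, {"age": 70.0, "health": 1}, rng)
        sched = WaveSchedule(offsets=(0.0, 3.0, 6.0, 10.0), dropout=0.0)
        hist = observe_waves(path, None, sched, rng)
        assert len(hist["observations"]) == 4
        assert hist["death_age"] is None


class TestGenerateCohort:
    def test_same_seed_is_byte_identical(self, true_model_quarter):
        cfg = SimulationConfig(n=300, seed=42, true_model=true_model_quarter)
        c1, _ = generate_cohort(cfg)
        c2, _ = generate_cohort(SimulationConfig(n=300, seed=42, true_model=true_model_quarter))
        assert c1.to_csv(index=False) == c2.to_csv(index=False)

    def test_rebuilt_episodes_match_generator_records(self, small_cohort):
        cohort, truth = small_cohort
        for indicator in ("adl", "srh"):
            rules = CodingRules(indicator=indicator)
            rec = recode_cohort(cohort, rules)
            _, eps = build_histories(rec)
            te = truth[f"episodes_{indicator}"]
            got = eps.sort_values(["id", "age_start"]).reset_index(drop=True)
            want = te.sort_values(["id", "age_start"]).reset_index(drop=True)
            assert len(got) == len(want)
            for col in ("age_start", "state_start", "elapsed", "end_state", "lonely"):
                assert np.allclose(
                    got[col].to_numpy(dtype=float),
                    want[col].to_numpy(dtype=float),
                    equal_nan=True,
                ), f"{indicator}:{col}"

    def test_one_step_frequencies_match_true_probabilities(self):
        # waves one step apart: empirical transition frequencies are binomial
        # draws from the TrueModel's step matrix
        model = recovery_true_model(0.25)
        cfg = SimulationConfig(
            n=10000,
            seed=3,
            true_model=model,
            schedule=WaveSchedule(offsets=(0.0, 0.25), dropout=0.0),
            p_unhealthy=0.30,
            age_range=(74.0, 76.0),
            age_beta=(1.0, 1.0),
        )
        _, truth = generate_cohort(cfg)
        eps = truth["episodes_adl"]
        for j in (1, 2):
            for lon in (0, 1):
                sub = eps[(eps.state_start == j) & (eps.lonely == lon)]
                if len(sub) < 50:
                    continue
                mean_age = sub["age_start"].mean()
                P = step_matrix(model.health, mean_age, {"lonely": lon}).probs
                n = len(sub)
                for k in (1, 2, 3):
                    p_hat = (sub.end_state == k).mean()
                    p = P[j - 1, k - 1]
                    mc_se = np.sqrt(max(p * (1 - p), 1e-6) / n)
                    assert abs(p_hat - p) < 3 * mc_se + 0.01 * p, (j, k, lon)

    def test_raising_death_logits_shortens_lifespans(self, true_model_quarter):
        base = true_model_quarter
        harsher_coef = base.health.coef.copy()
        harsher_coef[[1, 3], 0] += 1.0  # raise both death intercepts
        harsher = TrueModel(
            health=TransitionCoefficients(
                coef=harsher_coef, covariates=base.covariates,
                step=base.health.step, age_slope=True,
            )
        )
        lifespans = {}
        for name, model in (("base", base), ("harsh", harsher)):
            cfg = SimulationConfig(n=2000, seed=9, true_model=model)
            _, truth = generate_cohort(cfg)
            lat = truth["latent"]
            lifespans[name] = (lat["death_age"] - lat["baseline_age"]).mean()
        assert lifespans["harsh"] < lifespans["base"]

    def test_simulated_mortality_has_kannisto_shape(self, small_cohort):
        _, truth = small_cohort
        lat = truth["latent"]
        died = ~np.isnan(lat["death_age"]) & (lat["death_age"] < 109)
        exit_age = np.where(died, lat["death_age"], 109.0)
        tab = exposure_deaths_by_band(lat["baseline_age"], exit_age, died)
        tab = tab[tab.exposure > 0]
        fit = kannisto_fit(tab["age"], tab["deaths"], tab["exposure"])
        assert fit.b > 0  # increasing old-age hazard
        assert fit.hazard(120.0) < 1.0

    def test_invalid_config_rejected(self, true_model_quarter):
        with pytest.raises(Exception):
            SimulationConfig(n=0, true_model=true_model_quarter)
        with pytest.raises(Exception):
            WaveSchedule(offsets=(0.0, 3.0, 3.0))
        with pytest.raises(Exception):
            WaveSchedule(offsets=())
        with pytest.raises(Exception):
            TrueModel(health=true_model_quarter.health, lonely_onset=1.5)
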