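"""Disease engine: hazard arithmetic, stepping, coupling, censoring."""

import numpy as np
import pytest

from t1dcea.disease import (
    ComplicationDef,
    DiseaseParams,
    MortalityTable,
    PatientState,
    adjust_hazard,
    annual_probability,
    default_disease_params,
    simulate_arm,
    step_patient,
    time_free_of,
)
from t1dcea.effects import TreatmentEffects, point_effects

from conftest import make_patient, single_complication_params, uniform_cohort

NULL = TreatmentEffects.null()


class TestHazardAdjustment:
    def test_identity_at_reference(self):
        assert adjust_hazard(0.02, 1.3, 9.2, 9.2) == pytest.approx(0.02)

    def test_rr_one_is_hba1c_independent(self):
        assert adjust_hazard(0.02, 1.0, 15.0, 7.0) == pytest.approx(0.02)

    def test_direct_evaluation(self):
        assert adjust_hazard(0.02, 1.1, 9.0, 7.0) == pytest.approx(0.0242)

    def test_probability_conversion(self):
        assert annual_probability(0.0) == 0.0
        assert annual_probability(np.log(2)) == pytest.approx(0.5)


class TestStepPatient:
    def test_zero_hazards_leave_state_unchanged_except_age(self):
        params = single_complication_params(prob=0.0)
        state = PatientState.from_profile(make_patient(), NULL, "MDI")
        age0 = state.age
        step_patient(state, params, NULL, "MDI", np.random.default_rng(0))
        assert state.alive and state.age == age0 + 1 and not state.active

    def test_forced_fatal_event_kills_in_same_cycle(self):
        params = single_complication_params(prob=1.0, fatality=1.0)
        state = PatientState.from_profile(make_patient(severe_hypo_rate=0), NULL, "MDI")
        step_patient(state, params, NULL, "MDI", np.random.default_rng(0))
        assert not state.alive
        assert state.fatal_complication == "angina"
        assert "angina" in state.events_this_cycle

    def test_stepping_dead_patient_is_contract_violation(self):
        params = single_complication_params(prob=0.0)
        state = PatientState.from_profile(make_patient(), NULL, "MDI")
        state.alive = False
        with pytest.raises(ValueError, match="dead"):
            step_patient(state, params, NULL, "MDI", np.random.default_rng(0))


class TestSimulateArm:
    def test_horizon_one_gives_one_record_each(self):
        run = simulate_arm(
            uniform_cohort(30), single_complication_params(), NULL, "MDI",
            horizon_years=1, seed=0,
        )
        assert all(traj.n_cycles == 1 for traj in run)

    def test_certain_mortality_kills_everyone_in_first_cycle(self):
        ages = np.arange(18, 111)
        table = MortalityTable(ages=ages, q_male=np.ones(93), q_female=np.ones(93))
        params = single_complication_params(mortality=table)
        run = simulate_arm(uniform_cohort(20), params, NULL, "MDI", seed=0)
        assert all(traj.died and traj.death_cycle == 0 for traj in run)
        assert np.all(run.life_years == 1)

    def test_poisson_severe_hypo_mean_matches_rate(self):
        """At 22.4 events/100 p-y the per-cycle count mean is 0.224."""
        n = 50_000
        run = simulate_arm(
            uniform_cohort(n, severe_hypo_rate=22.4),
            single_complication_params(prob=0.0), NULL, "MDI",
            horizon_years=1, seed=1,
        )
        counts = run.acute_counts[:, 0, 0]
        se = np.sqrt(0.224 / n)
        assert abs(counts.mean() - 0.224) < 4 * se

    def test_csii_lowers_hypo_rate_by_the_rate_ratio(self):
        n = 50_000
        eff = point_effects()  # ratio 10.5368
        run = simulate_arm(
            uniform_cohort(n), single_complication_params(prob=0.0), eff, "CSII",
            horizon_years=1, seed=1,
        )
        mu = 22.4 / eff.hypo_rate_ratio / 100
        counts = run.acute_counts[:, 0, 0]
        assert abs(counts.mean() - mu) < 4 * np.sqrt(mu / n)

    def test_unknown_arm_and_bad_horizon_rejected(self):
        with pytest.raises(ValueError, match="arm"):
            simulate_arm(uniform_cohort(1), single_complication_params(), NULL, "PUMP")
        with pytest.raises(ValueError, match="horizon"):
            simulate_arm(
                uniform_cohort(1), single_complication_params(), NULL, "MDI",
                horizon_years=0,
            )


class TestCoupling:
    def test_null_effects_make_arms_identical(self, disease_params):
        cohort = uniform_cohort(300)
        a = simulate_arm(cohort, disease_params, NULL, "CSII", seed=9)
        b = simulate_arm(cohort, disease_params, NULL, "MDI", seed=9)
        assert np.array_equal(a.onset_cycle, b.onset_cycle)
        assert np.array_equal(a.death_cycle, b.death_cycle)
        assert np.array_equal(a.acute_counts, b.acute_counts)

    def test_halving_hazards_never_decreases_life_years(self, disease_params):
        cohort = uniform_cohort(2000)
        full = simulate_arm(cohort, disease_params, NULL, "MDI", seed=4)
        half = simulate_arm(
            cohort, disease_params.scaled_hazards(0.5), NULL, "MDI", seed=4
        )
        assert np.all(half.life_years >= full.life_years)
        assert half.life_years.mean() > full.life_years.mean()  # not vacuous

    def test_treated_arm_dominates_under_common_random_numbers(self, disease_params):
        """With mortality off, CSII's lower HbA1c gives per-patient
        complication counts <= MDI's (coupled onset draws)."""
        from dataclasses import replace

        params = DiseaseParams(
            reference_hba1c=disease_params.reference_hba1c,
            complications=[
                replace(c, fatality_prob=0.0) for c in disease_params.complications
            ],
            background_mortality=MortalityTable.zero(),
            acute_event_rates=dict(disease_params.acute_event_rates),
        )
        cohort = uniform_cohort(3000)
        eff = point_effects()
        csii = simulate_arm(cohort, params, eff, "CSII", seed=2)
        mdi = simulate_arm(cohort, params, eff, "MDI", seed=2)
        assert np.all(csii.complication_counts <= mdi.complication_counts)
        assert csii.complication_counts.mean() < mdi.complication_counts.mean()

    def test_lower_hba1c_never_shortens_life_with_mortality_on(self, disease_params):
        cohort = uniform_cohort(2000)
        eff = point_effects()
        csii = simulate_arm(cohort, disease_params, eff, "CSII", seed=2)
        mdi = simulate_arm(cohort, disease_params, eff, "MDI", seed=2)
        assert np.all(csii.life_years >= mdi.life_years)


class TestStructure:
    def test_predecessor_gating(self):
        """Proliferative retinopathy cannot onset without background."""
        params = DiseaseParams(
            reference_hba1c=9.2,
            complications=[
                ComplicationDef("background_retinopathy", 0.0),
                ComplicationDef(
                    "proliferative_retinopathy", 5.0,
                    predecessor="background_retinopathy",
                ),
            ],
            background_mortality=MortalityTable.zero(),
        )
        run = simulate_arm(uniform_cohort(200), params, NULL, "MDI",
                           horizon_years=10, seed=0)
        k = run.comp_index["proliferative_retinopathy"]
        assert not (run.onset_cycle[:, k] >= 0).any()

    def test_predecessor_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            DiseaseParams(
                reference_hba1c=9.2,
                complications=[
                    ComplicationDef("angina", 0.1, predecessor="stroke"),
                    ComplicationDef("stroke", 0.1, predecessor="angina"),
                ],
                background_mortality=MortalityTable.zero(),
            )

    def test_esrd_modality_assigned_on_onset(self):
        params = DiseaseParams(
            reference_hba1c=9.2,
            complications=[
                ComplicationDef(
                    "end_stage_renal_disease", 5.0,
                    modality_split={
                        "hemodialysis": 0.5, "peritoneal_dialysis": 0.3,
                        "kidney_transplant": 0.2,
                    },
                )
            ],
            background_mortality=MortalityTable.zero(),
        )
        run = simulate_arm(uniform_cohort(2000), params, NULL, "MDI",
                           horizon_years=2, seed=3)
        mods = [t.esrd_modality for t in run if "end_stage_renal_disease" in t.onset_cycles]
        assert len(mods) > 1500
        frac_hd = np.mean([m == "hemodialysis" for m in mods])
        assert frac_hd == pytest.approx(0.5, abs=0.05)


class TestTimeFree:
    def test_no_onsets_gives_mean_observed_lifetime(self):
        params = single_complication_params(prob=0.0)
        run = simulate_arm(uniform_cohort(10), params, NULL, "MDI",
                           horizon_years=30, seed=0)
        assert time_free_of(run, "angina") == 30.0

    def test_onset_in_first_cycle_counts_one_year(self):
        params = single_complication_params(prob=1.0)
        run = simulate_arm(uniform_cohort(10), params, NULL, "MDI", seed=0)
        assert time_free_of(run, "angina") == 1.0

    def test_geometric_onset_mean_matches_closed_form(self):
        params = single_complication_params(prob=0.5)
        run = simulate_arm(uniform_cohort(20_000), params, NULL, "MDI",
                           horizon_years=60, seed=1)
        # E[time] = 1/p = 2 (horizon truncation negligible at p=0.5, T=60)
        se = np.sqrt(2.0) / np.sqrt(20_000)
        assert abs(time_free_of(run, "angina") - 2.0) < 4 * se

    def test_unknown_complication_rejected(self):
        params = single_complication_params()
        run = simulate_arm(uniform_cohort(5), params, NULL, "MDI", seed=0)
        with pytest.raises(KeyError):
            time_free_of(run, "gout")
        # list-of-trajectory path agrees with the array path
        assert time_free_of(list(run), "angina") == time_free_of(run, "angina")


def test_trajectory_records_are_exportable(disease_params):
    run = simulate_arm(
        uniform_cohort(5, complications=("neuropathy",)), disease_params,
        NULL, "MDI", horizon_years=5, seed=0,
    )
    df = run.to_frame()
    assert set(df.columns) >= {"patient", "cycle", "age", "states", "death"}
    assert df.groupby("patient")["cycle"].max().le(4).all()
    assert df[df.patient == 0].iloc[0]["states"].find("neuropathy") >= 0
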