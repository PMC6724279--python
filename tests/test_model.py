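"""Model facade and trajectory valuation."""

import numpy as np
import pytest

from t1dcea.costing import CostTable, DisabilityDurations, SalaryTable
from t1dcea.disease import simulate_arm
from t1dcea.economics import DiscountSpec
from t1dcea.effects import TreatmentEffects, point_effects
from t1dcea.model import CEAModel
from t1dcea.utility import UtilityTable
from t1dcea.valuation import value_trajectory

from conftest import make_patient, single_complication_params, uniform_cohort

NULL = TreatmentEffects.null()


class TestValuation:
    def test_clean_patient_accrues_therapy_and_baseline_utility(self):
        params = single_complication_params(prob=0.0)
        run = simulate_arm(
            uniform_cohort(1, severe_hypo_rate=0.0), params, NULL, "MDI",
            horizon_years=3, seed=0,
        )
        costs, utils = value_trajectory(run[0])
        assert len(costs) == len(utils) == 3
        assert utils == [0.785] * 3
        screening = sum(CostTable.default().screening_annual.values())
        for c in costs:
            assert c["treatment"] == 22_884.97
            assert c["management"] == pytest.approx(screening)
            assert c["total"] == pytest.approx(22_884.97 + screening)

    def test_incident_event_year_then_maintenance(self):
        params = single_complication_params(name="myocardial_infarction", prob=1.0)
        run = simulate_arm(
            uniform_cohort(1, severe_hypo_rate=0.0), params, NULL, "MDI",
            horizon_years=3, seed=0,
        )
        costs, utils = value_trajectory(run[0])
        assert costs[0]["cardiovascular"] == pytest.approx(267_057.59)
        assert costs[1]["cardiovascular"] == pytest.approx(29_673.07)
        assert costs[2]["cardiovascular"] == pytest.approx(29_673.07)
        # one-off disutility in the event cycle, post-MI state afterwards
        assert utils[0] == pytest.approx(0.785 - 0.055)
        assert utils[1] == utils[2] == 0.73

    def test_baseline_post_event_states_value_from_cycle_zero(self):
        params = single_complication_params(prob=0.0)
        run = simulate_arm(
            [make_patient(complications=("myocardial_infarction", "amputation"),
                          severe_hypo_rate=0.0)],
            params, NULL, "MDI", horizon_years=2, seed=0,
        )
        costs, utils = value_trajectory(run[0])
        assert utils[0] == 0.505  # min(post-MI 0.73, post-amputation 0.505)
        # MI maintenance cost; amputation has no maintenance (prosthesis not covered)
        assert costs[0]["cardiovascular"] == pytest.approx(29_673.07)
        assert costs[0]["ulcer_amputation_neuropathy"] == 0.0

    def test_severe_hypo_events_are_costed_and_disutility_applied(self):
        params = single_complication_params(prob=0.0)
        run = simulate_arm(
            uniform_cohort(200, severe_hypo_rate=80.0), params, NULL, "MDI",
            horizon_years=1, seed=5,
        )
        total_events = int(run.acute_counts[:, :, 0].sum())
        assert total_events > 0
        costs, utils = [], []
        for traj in run:
            c, u = value_trajectory(traj)
            costs.append(c)
            utils.append(u)
        hyp = sum(c[0]["hypoglycemia"] for c in costs)
        assert hyp == pytest.approx(total_events * 37_000.53)
        k = int(np.argmax(run.acute_counts[:, 0, 0]))
        n_ev = int(run.acute_counts[k, 0, 0])
        assert utils[k][0] == pytest.approx(max(0.785 - 0.047 * n_ev, 0.0))

    def test_indirect_costs_only_in_working_age_window(self):
        params = single_complication_params(prob=0.0)
        run = simulate_arm(
            uniform_cohort(1, age=58.0, severe_hypo_rate=0.0), params, NULL, "MDI",
            horizon_years=5, seed=0,
        )
        dis = DisabilityDurations(days={"neuropathy_annual": 10.0})
        # give the patient a prevalent neuropathy via baseline
        run2 = simulate_arm(
            [make_patient(age=58.0, complications=("neuropathy",),
                          severe_hypo_rate=0.0)],
            params, NULL, "MDI", horizon_years=5, seed=0,
        )
        costs, _ = value_trajectory(
            run2[0], include_indirect=True, disability=dis, salary=SalaryTable()
        )
        # working-age at 58 and 59 only (retirement at 60)
        assert costs[0]["indirect"] == pytest.approx(10 * 292.88)
        assert costs[1]["indirect"] == pytest.approx(10 * 292.88)
        assert costs[2]["indirect"] == 0.0
        assert all(c["total"] == pytest.approx(sum(v for k, v in c.items() if k != "total"))
                   for c in costs)


class TestCEAModel:
    def test_effects_derived_from_cohort_means(self, imss_cohort_small):
        model = CEAModel(imss_cohort_small)
        mean_h = float(np.mean([p.hba1c for p in imss_cohort_small]))
        assert model.effects.delta_hba1c == pytest.approx(-(-3.60 + 0.52 * mean_h))

    def test_fit_is_deterministic_given_seed(self, imss_cohort_small, disease_params):
        m = CEAModel(imss_cohort_small, disease_params=disease_params, horizon=30)
        a = m.fit(seed=7)
        b = m.fit(seed=7)
        assert a.to_dict() == b.to_dict()
        c = m.fit(seed=8)
        assert a.to_dict() != c.to_dict()

    def test_null_effects_give_identical_arms(self, imss_cohort_small, disease_params):
        m = CEAModel(
            imss_cohort_small, disease_params=disease_params,
            effects=NULL, horizon=40,
        )
        res = m.fit(seed=3)
        assert np.all(res.per_patient_delta_qalys == 0.0)
        assert res.delta_qalys == 0.0
        # outcomes identical; costs differ only through the therapy price
        for cat, v in res.csii.cost_by_category.items():
            if cat != "treatment":
                assert v == res.mdi.cost_by_category[cat]
        assert res.csii.life_years == res.mdi.life_years

    def test_summary_structure_and_usd_derivation(self, imss_cohort_small, disease_params):
        res = CEAModel(imss_cohort_small, disease_params=disease_params,
                       horizon=20).fit(seed=1)
        s = res.summary()
        assert "total_cost_mxn" in s.index
        assert s.loc["total_cost_mxn", "CSII_usd"] == pytest.approx(
            s.loc["total_cost_mxn", "CSII"] / 18.390
        )
        # category rows sum to the total row
        cat_rows = [i for i in s.index if i.startswith("cost_")]
        assert sum(s.loc[cat_rows, "CSII"]) == pytest.approx(
            s.loc["total_cost_mxn", "CSII"]
        )

    def test_dominated_when_effect_reversed(self, disease_params):
        # a positive HbA1c "benefit" (CSII worse) with extra cost -> not ok
        cohort = uniform_cohort(100)
        m = CEAModel(
            cohort, disease_params=disease_params,
            effects=TreatmentEffects(delta_hba1c=1.5, hypo_rate_ratio=1.0,
                                     csii_hypo_rate=22.4),
            horizon=30,
        )
        res = m.fit(seed=2)
        assert res.delta_qalys <= 0
        assert res.icer_per_qaly.flag in ("dominated", "undefined")

    def test_empty_cohort_and_bad_horizon_rejected(self, imss_cohort_small):
        with pytest.raises(ValueError):
            CEAModel([])
        with pytest.raises(ValueError):
            CEAModel(imss_cohort_small, horizon=71)

    def test_from_spec_builds_cohort(self):
        m = CEAModel.from_spec(n=12, seed=4, horizon=10)
        assert len(m.cohort) == 12


class TestModelCEAC:
    def test_small_ceac_runs_and_is_monotone(self, disease_params):
        m = CEAModel.from_spec(n=30, seed=1, disease_params=disease_params,
                               horizon=25)
        curve = m.ceac(n_outer=8, n_inner=30, seed=9,
                       wtp_grid=np.linspace(0, 2e6, 21))
        assert len(curve.probability) == 21
        assert np.all(np.diff(curve.probability) >= -1e-12)
        assert curve.delta_effects.shape == (8,)
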