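"""Cohort construction, outcome rules, propensity, matching, Cox fitting."""

import numpy as np
import pandas as pd
import pytest

import phagoscreen as ps
from phagoscreen.cohort_study import (
    PatientTable,
    build_cohorts,
    covariate_balance,
    cox_partial_loglik,
    extract_outcomes,
    fit_cox,
    fit_propensity,
    ipw_weights,
    match_cohorts,
)
from phagoscreen.errors import StudyInfeasibleError, ValidationError

EXP, DIS = "ADRB2_AGONIST", "SZ"


def patients_from_records(records):
    """Build a PatientTable from compact per-patient dicts."""
    persons, exposures, diagnoses, visits = [], [], [], []
    for r in records:
        pid = r["pid"]
        persons.append(
            {"person_id": pid, "obs_start_age": 0.0, "obs_end_age": r.get("end", 60.0)}
        )
        for age in r.get("exp", []):
            exposures.append({"person_id": pid, "concept_id": EXP, "age": age})
        for age in r.get("dx", []):
            diagnoses.append({"person_id": pid, "concept_id": DIS, "age": age})
        for vt, age in r.get("visits", []):
            visits.append({"person_id": pid, "visit_type": vt, "age": age})
    cols = ["person_id", "concept_id", "age"]
    return PatientTable(
        persons=pd.DataFrame(persons),
        exposures=pd.DataFrame(exposures, columns=cols),
        diagnoses=pd.DataFrame(diagnoses, columns=cols),
        visits=pd.DataFrame(visits, columns=["person_id", "visit_type", "age"]),
        covariates=pd.DataFrame({"person_id": [r["pid"] for r in records]}),
    )


class TestBuildCohorts:
    def test_pediatric_exposure_and_adult_diagnosis_is_target(self):
        pt = patients_from_records(
            [
                {"pid": "a", "exp": [10.0], "dx": [25.0]},
                {"pid": "b", "dx": [25.0]},
            ]
        )
        out = build_cohorts(pt, {EXP}, {DIS})
        assert out.arm["a"] == "target"
        assert out.index_age["a"] == 25.0

    def test_adult_exposure_goes_to_comparator(self):
        pt = patients_from_records(
            [
                {"pid": "a", "exp": [20.0], "dx": [25.0]},
                {"pid": "t", "exp": [12.0], "dx": [25.0]},
            ]
        )
        out = build_cohorts(pt, {EXP}, {DIS})
        assert out.arm["a"] == "comparator"

    def test_edge_ages_closed_exposure_interval_strict_diagnosis(self):
        records = [
            {"pid": "p1", "exp": [5.9], "dx": [25.0]},   # too young: comparator
            {"pid": "p2", "exp": [6.0], "dx": [25.0]},   # boundary in: target
            {"pid": "p3", "exp": [18.0], "dx": [25.0]},  # boundary in: target
            {"pid": "p4", "exp": [18.1], "dx": [25.0]},  # too old: comparator
            {"pid": "p5", "exp": [10.0], "dx": [18.0]},  # dx not adult: excluded
            {"pid": "p6", "exp": [10.0], "dx": [18.1]},  # adult dx: target
            {"pid": "p7", "dx": [30.0, 22.0]},           # comparator, index 22
            {"pid": "p8", "exp": [10.0]},                # no dx: excluded
        ]
        out = build_cohorts(patients_from_records(records), {EXP}, {DIS})
        expected = {
            "p1": "comparator",
            "p2": "target",
            "p3": "target",
            "p4": "comparator",
            "p5": "excluded",
            "p6": "target",
            "p7": "comparator",
            "p8": "excluded",
        }
        assert out.arm.to_dict() == expected
        assert out.index_age["p7"] == 22.0

    def test_empty_arm_is_infeasible(self):
        pt = patients_from_records([{"pid": "a", "exp": [10.0], "dx": [25.0]}])
        with pytest.raises(StudyInfeasibleError):
            build_cohorts(pt, {EXP}, {DIS})


class TestExtractOutcomes:
    def base_records(self):
        return [
            {"pid": "t", "exp": [10.0], "dx": [20.0]},
            {"pid": "c", "dx": [20.0]},
        ]

    def run(self, extra, lag_days=3.0):
        recs = self.base_records() + extra
        pt = patients_from_records(recs)
        assign = build_cohorts(pt, {EXP}, {DIS})
        return extract_outcomes(pt, assign, {DIS}, lag_days=lag_days)

    def test_same_day_inpatient_diagnosis_is_event(self):
        rows = self.run(
            [{"pid": "e", "dx": [20.0, 26.0], "visits": [("inpatient", 26.0)]}]
        )
        r = rows.set_index("person_id").loc["e"]
        assert bool(r["event"]) and np.isclose(r["time"], 6.0)

    def test_diagnosis_four_days_late_is_not_event(self):
        late = 26.0 + 4.0 / 365.25
        rows = self.run(
            [{"pid": "e", "dx": [20.0, late], "visits": [("inpatient", 26.0)]}]
        )
        r = rows.set_index("person_id").loc["e"]
        assert not r["event"]
        assert np.isclose(r["time"], 40.0)  # censored at obs end 60

    def test_visit_patterns_match_hand_enumeration(self):
        day = 1.0 / 365.25
        extra = [
            # outpatient visit with diagnosis: not an outcome
            {"pid": "v1", "dx": [20.0, 25.0], "visits": [("outpatient", 25.0)]},
            # inpatient before index: ignored
            {"pid": "v2", "dx": [20.0, 19.0], "visits": [("inpatient", 19.0)]},
            # diagnosis 2 days after visit: event at the visit age
            {"pid": "v3", "dx": [20.0, 24.0 + 2 * day], "visits": [("inpatient", 24.0)]},
            # diagnosis 1 day BEFORE the visit: not an event
            {"pid": "v4", "dx": [20.0, 23.0 - day], "visits": [("inpatient", 23.0)]},
            # two qualifying visits: first one wins
            {
                "pid": "v5",
                "dx": [20.0, 22.0, 27.0],
                "visits": [("inpatient", 27.0), ("inpatient", 22.0)],
            },
            # inpatient visit with no nearby diagnosis: censored
            {"pid": "v6", "dx": [20.0], "visits": [("inpatient", 25.0)]},
        ]
        rows = self.run(extra).set_index("person_id")
        assert not rows.loc["v1", "event"]
        assert not rows.loc["v2", "event"]
        assert rows.loc["v3", "event"] and np.isclose(rows.loc["v3", "time"], 4.0)
        assert not rows.loc["v4", "event"]
        assert rows.loc["v5", "event"] and np.isclose(rows.loc["v5", "time"], 2.0)
        assert not rows.loc["v6", "event"]


class TestPropensity:
    def make_rows(self, n, signal, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        logits = signal * x
        z = rng.random(n) < 1 / (1 + np.exp(-logits))
        return pd.DataFrame(
            {
                "person_id": range(n),
                "time": 1.0,
                "event": False,
                "exposure": z.astype(int),
                "weight": 1.0,
                "x": x,
            }
        )

    def test_no_signal_auc_near_half(self):
        res = fit_propensity(self.make_rows(5000, 0.0))
        assert abs(res.auc - 0.5) < 0.03

    def test_perfect_binary_predictor_auc_near_one(self):
        rows = self.make_rows(200, 0.0)
        rows["x"] = rows["exposure"] * 1.0
        res = fit_propensity(rows)
        assert res.auc > 0.99
        assert res.scores.between(1e-6, 1 - 1e-6).all()

    def test_auc_equals_pair_count_oracle(self):
        rows = self.make_rows(50, 1.0, seed=3)
        res = fit_propensity(rows)
        s, z = res.scores.to_numpy(), rows["exposure"].to_numpy()
        conc = ties = total = 0
        for i in range(50):
            for j in range(50):
                if z[i] == 1 and z[j] == 0:
                    total += 1
                    conc += s[i] > s[j]
                    ties += s[i] == s[j]
        assert np.isclose(res.auc, (conc + 0.5 * ties) / total)

    def test_constant_exposure_rejected(self):
        rows = self.make_rows(20, 0.0)
        rows["exposure"] = 1
        with pytest.raises(ValidationError):
            fit_propensity(rows)


class TestIpwWeights:
    def test_scores_at_prevalence_give_unit_weights(self):
        z = np.array([1, 1, 0, 0])
        w = ipw_weights(np.full(4, 0.5), z)
        assert np.allclose(w, 1.0)

    def test_stabilized_formula(self):
        z = np.array([1, 0])
        w = ipw_weights(np.array([0.25, 0.4]), z, truncate_percentile=None)
        assert np.isclose(w[0], 0.5 / 0.25)
        assert np.isclose(w[1], 0.5 / 0.6)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValidationError):
            ipw_weights(np.array([0.0, 0.5]), np.array([0, 1]))


class TestMatchCohorts:
    def test_identical_scores_full_ratio(self):
        s = np.full(12, 0.5)
        z = np.array([1, 1] + [0] * 10)
        m = match_cohorts(s, z, max_ratio=5)
        assert m.n_unmatched_targets == 0
        assert sorted(m.ratios.values()) == [5, 5]
        assert len(m.indices) == 12

    def test_target_outside_caliper_dropped(self):
        s = np.array([0.95, 0.5, 0.51, 0.49])
        z = np.array([1, 1, 0, 0])
        m = match_cohorts(s, z, caliper_sd=0.2, max_ratio=1)
        assert m.n_unmatched_targets == 1
        assert 0 not in m.indices

    def test_hand_traced_greedy_fixture(self):
        from scipy.special import expit

        # logits: targets at 2.0, 1.0; comparators at 2.2, 1.9, 1.2, 0.9, 0.0
        logits = np.array([2.0, 1.0, 2.2, 1.9, 1.2, 0.9, 0.0])
        z = np.array([1, 1, 0, 0, 0, 0, 0])
        sd = np.std(logits)
        m = match_cohorts(expit(logits), z, caliper_sd=0.3 / sd, max_ratio=2)
        # caliper 0.3: round 1: target0 takes 1.9 (|0.1|<|0.2|), target1 takes 0.9;
        # round 2: target0 takes 2.2, target1 takes 1.2
        assert set(m.indices) == {0, 1, 2, 3, 4, 5}
        assert m.ratios == {0: 2, 1: 2}
        comp_weights = m.weights[np.isin(m.indices, [2, 3, 4, 5])]
        assert np.allclose(comp_weights, 0.5)

    def test_no_match_is_infeasible(self):
        s = np.array([0.99, 0.01, 0.011])
        z = np.array([1, 0, 0])
        with pytest.raises(StudyInfeasibleError):
            match_cohorts(s, z, caliper_sd=1e-6)


class TestFitCox:
    @staticmethod
    def rows(times, events, exposure, **covs):
        df = pd.DataFrame(
            {
                "time": times,
                "event": events,
                "exposure": exposure,
                "weight": 1.0,
            }
        )
        for k, v in covs.items():
            df[k] = v
        return df

    def test_exchangeable_arms_give_hr_one(self):
        r = self.rows(
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            [True] * 6,
            [1, 1, 1, 0, 0, 0],
        )
        est = fit_cox(r)
        assert abs(np.log(est.hr)) < 1e-7

    @staticmethod
    def grid_argmax(r, step=1e-4):
        """Brute-force partial-likelihood argmax over beta in [-3, 3].

        Coarse pass at 100x the step, then the full-resolution pass in the
        winning neighbourhood: equivalent to the flat grid for a unimodal
        partial likelihood, at a fraction of the evaluations.
        """

        def ll(b):
            return cox_partial_loglik(
                r["time"].to_numpy(),
                r["event"].to_numpy(),
                r[["exposure"]].to_numpy(),
                None,
                [b],
            )

        coarse = np.arange(-3, 3, 100 * step)
        b0 = coarse[int(np.argmax([ll(b) for b in coarse]))]
        fine = np.arange(b0 - 100 * step, b0 + 100 * step, step)
        return fine[int(np.argmax([ll(b) for b in fine]))]

    def test_four_patient_grid_oracle(self):
        r = self.rows([1.0, 3.0, 2.0, 4.0], [True] * 4, [1, 1, 0, 0])
        est = fit_cox(r)
        assert abs(np.log(est.hr) - self.grid_argmax(r)) <= 1e-4

    def test_grid_oracle_on_no_tie_fixtures(self):
        rng = np.random.default_rng(0)
        for trial in range(3):
            n = 8
            r = self.rows(
                np.round(rng.uniform(1, 10, n), 3),
                rng.random(n) < 0.8,
                rng.permutation([1] * 4 + [0] * 4),
            )
            if r["event"].to_numpy()[r["exposure"] == 1].sum() == 0:
                continue
            if r["event"].to_numpy()[r["exposure"] == 0].sum() == 0:
                continue
            est = fit_cox(r)
            assert abs(np.log(est.hr) - self.grid_argmax(r)) <= 1.1e-4

    def test_matches_lifelines_with_covariates_and_weights(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        n = 250
        r = self.rows(
            rng.exponential(1, n),
            rng.random(n) < 0.7,
            rng.integers(0, 2, n),
            x1=rng.normal(size=n),
        )
        est = fit_cox(r, covariates=["x1"])
        cph = CoxPHFitter()
        cph.fit(r[["time", "event", "exposure", "x1"]], "time", "event")
        assert np.allclose(est.beta, cph.params_.values, atol=1e-6)
        assert np.isclose(est.log_hr_se, cph.standard_errors_["exposure"], atol=1e-6)

        w = rng.uniform(0.5, 2.0, n)
        estw = fit_cox(r, covariates=["x1"], weights=w)
        df = r.copy()
        df["w"] = w
        cphw = CoxPHFitter()
        cphw.fit(
            df[["time", "event", "exposure", "x1", "w"]],
            "time",
            "event",
            weights_col="w",
            robust=True,
        )
        # lifelines stops at a looser gradient criterion than our 1e-8
        assert np.allclose(estw.beta, cphw.params_.values, atol=2e-4)
        assert np.isclose(
            estw.log_hr_se, cphw.standard_errors_["exposure"], rtol=1e-3
        )

    def test_label_inversion_maps_hr_to_reciprocal(self):
        rng = np.random.default_rng(9)
        n = 120
        r = self.rows(
            rng.exponential(1, n), rng.random(n) < 0.6, rng.integers(0, 2, n)
        )
        a = fit_cox(r)
        flipped = r.copy()
        flipped["exposure"] = 1 - flipped["exposure"]
        b = fit_cox(flipped)
        assert abs(np.log(a.hr) + np.log(b.hr)) < 1e-8
        assert np.isclose(a.ci_low, 1.0 / b.ci_high, rtol=1e-8)

    def test_time_unit_invariance(self):
        rng = np.random.default_rng(10)
        n = 80
        r = self.rows(
            rng.exponential(1, n), rng.random(n) < 0.6, rng.integers(0, 2, n)
        )
        a = fit_cox(r)
        scaled = r.copy()
        scaled["time"] *= 365.25
        b = fit_cox(scaled)
        assert np.isclose(a.hr, b.hr, rtol=1e-9)
        assert np.isclose(a.log_hr_se, b.log_hr_se, rtol=1e-9)

    def test_unit_weights_equal_unweighted(self):
        rng = np.random.default_rng(12)
        n = 60
        r = self.rows(
            rng.exponential(1, n), rng.random(n) < 0.6, rng.integers(0, 2, n)
        )
        a = fit_cox(r)
        b = fit_cox(r, weights=np.ones(n))
        assert a.hr == b.hr and a.log_hr_se == b.log_hr_se

    def test_no_events_in_one_arm_is_monotone_likelihood(self):
        r = self.rows([1.0, 2.0, 3.0, 4.0], [False, False, True, True], [1, 1, 0, 0])
        with pytest.raises(StudyInfeasibleError, match="monotone"):
            fit_cox(r)


class TestCovariateBalance:
    def test_identical_arms_zero_smd(self):
        r = pd.DataFrame(
            {
                "exposure": [1, 1, 0, 0],
                "time": 1.0,
                "event": False,
                "weight": 1.0,
                "x": [1.0, 2.0, 1.0, 2.0],
            }
        )
        b = covariate_balance(r)
        assert b["smd_before"].abs().max() == 0.0

    def test_binary_smd_closed_form(self):
        # prevalence 0.6 vs 0.4: SMD = 0.2 / sqrt((0.24 + 0.24)/2)
        x_t = [1] * 6 + [0] * 4
        x_c = [1] * 4 + [0] * 6
        r = pd.DataFrame(
            {
                "exposure": [1] * 10 + [0] * 10,
                "time": 1.0,
                "event": False,
                "weight": 1.0,
                "x": x_t + x_c,
            }
        )
        b = covariate_balance(r)
        assert np.isclose(b["smd_before"].iloc[0], 0.2 / np.sqrt(0.24), atol=1e-12)

    def test_constant_covariate_reports_zero(self):
        r = pd.DataFrame(
            {
                "exposure": [1, 0],
                "time": 1.0,
                "event": False,
                "weight": 1.0,
                "x": [3.0, 3.0],
            }
        )
        assert covariate_balance(r)["smd_before"].iloc[0] == 0.0


def test_patient_table_tsv_roundtrip(tmp_path):
    from phagoscreen.synthetic_data import CohortSimConfig, gen_patient_table

    table, _ = gen_patient_table(CohortSimConfig(n_patients=40, seed=3))
    table.write_dir(tmp_path / "cohort")
    back = PatientTable.read_dir(tmp_path / "cohort")
    pd.testing.assert_frame_equal(back.persons, table.persons)
    assert len(back.visits) == len(table.visits)
    # concept lists round-trip through one-id-per-line files
    from phagoscreen.cohort_study import read_concept_list

    (tmp_path / "concepts.txt").write_text("ADRB2_AGONIST\n\n")
    assert read_concept_list(tmp_path / "concepts.txt") == {"ADRB2_AGONIST"}


def test_study_report_structure():
    from phagoscreen.synthetic_data import CohortSimConfig, simulate_survival_rows

    rows = simulate_survival_rows(CohortSimConfig(n_patients=4000, seed=1))
    rep = ps.study_report(rows, design="both", caliper_sd=0.05)
    assert set(rep["estimates"]) == {"IPW", "matched"}
    assert 0 < rep["estimates"]["IPW"]["hr"] < rep["crude"]["hr"]
    assert rep["attrition"]["n_rows"] == len(rows)
    assert 0.5 < rep["propensity_auc"] < 1.0
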