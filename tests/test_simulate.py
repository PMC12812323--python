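"""Synthetic cohort generator: determinism, causal structure, replay oracle,
medication-level round trip and cohort filters."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from gdmtopt import (
    CohortTables,
    PatientSnapshot,
    TruthParams,
    apply_cohort_filters,
    compute_mos,
    generate_cohort_tables,
    generate_score_panel,
)
from gdmtopt.survival import CoxOutcomeModel


class TestTruthParams:
    def test_invalid_parameters_rejected_with_field_name(self):
        with pytest.raises(ValueError, match="baseline_hazard"):
            TruthParams(baseline_hazard=0.0).validate()
        with pytest.raises(ValueError, match="titration_mean_pp"):
            TruthParams(titration_mean_pp=float("nan")).validate()
        with pytest.raises(ValueError, match="n_intervals"):
            TruthParams(n_intervals=1).validate()

    def test_json_round_trip(self, tmp_path):
        params = TruthParams(n_patients=7, seed=3)
        path = tmp_path / "truth.json"
        params.to_json(str(path))
        assert TruthParams.from_json(str(path)) == params


class TestScorePanel:
    def test_identical_seed_gives_byte_identical_tables(self):
        a = generate_score_panel(TruthParams(n_patients=50, seed=4))
        b = generate_score_panel(TruthParams(n_patients=50, seed=4))
        assert a.panel.to_csv(index=False) == b.panel.to_csv(index=False)
        assert a.patients.to_csv(index=False) == b.patients.to_csv(index=False)

    def test_panel_structure_contiguous_terminal_flags(self):
        sp = generate_score_panel(TruthParams(n_patients=100, seed=5))
        for _, grp in sp.panel.groupby("patient_id"):
            assert list(grp["interval"]) == list(range(len(grp)))
            # at most one terminal flag, on the last row only
            assert not grp.iloc[:-1][["event", "censored"]].any().any()
            assert grp.iloc[-1]["event"] ^ grp.iloc[-1]["censored"]

    def test_no_titration_no_noise_keeps_mos_constant(self):
        params = TruthParams(
            n_patients=30, seed=6, titration_mean_pp=0.0, titration_sd_pp=0.0,
            feedback_hfpsi_on_mos=0.0, feedback_mos_on_hfpsi=0.0, mos_noise_sd=0.0,
        )
        panel = generate_score_panel(params).panel
        assert (panel.groupby("patient_id")["mos"].nunique() == 1).all()

    def test_zero_feedback_makes_exposure_independent_of_lagged_severity(self):
        params = TruthParams(
            n_patients=2000, seed=7, feedback_hfpsi_on_mos=0.0,
            feedback_mos_on_hfpsi=0.0,
        )
        df = generate_score_panel(params).analysis_panel()
        # condition on time and prior MOS (score clipping and survivorship
        # induce marginal structure); the lagged-severity coefficient in the
        # titration regression must vanish
        rows = df[(df["interval"] >= 1) & (df["mos"] < 99.9)].copy()
        X = pd.get_dummies(rows["interval"], prefix="k", drop_first=True,
                           dtype=float)
        X["mos_prev"] = rows["mos_prev"]
        X["hfpsi_lag1"] = rows["hfpsi_lag1"].astype(float)
        X["const"] = 1.0
        beta, *_ = np.linalg.lstsq(X.to_numpy(), rows["mos"].to_numpy(), rcond=None)
        coef = beta[list(X.columns).index("hfpsi_lag1")]
        assert abs(coef) < 0.3  # pp per severity level; true value is 0

    def test_null_exposure_effect_recovered_by_time_varying_cox(self):
        params = TruthParams(
            n_patients=1000, seed=8, beta_mos_per10=0.0,
            feedback_hfpsi_on_mos=0.0, feedback_mos_on_hfpsi=0.0,
        )
        df = generate_score_panel(params).analysis_panel()
        fit = CoxOutcomeModel(df, model="C").fit()
        assert fit.ci_lower["cum_mos_lag10"] <= 1.0 <= fit.ci_upper["cum_mos_lag10"]

    def test_replay_oracle_reproduces_trajectories(self):
        """Independently replay the documented per-patient draw order."""
        params = TruthParams(n_patients=3, n_intervals=2, seed=12)
        sp = generate_score_panel(params)
        for i in range(params.n_patients):
            rng = np.random.default_rng([params.seed, i])
            age = float(np.clip(rng.normal(64.7, 14.3), 18.0, 95.0))
            rng.random()  # sex
            rng.random()  # race
            rng.random()  # ethnicity
            distance = float(rng.lognormal(3.7, 0.9))
            u_cci = rng.random()
            cci_idx = int(np.searchsorted(np.cumsum(params.cci_baseline_probs),
                                          u_cci, side="right"))
            u_h = rng.random()
            hfpsi = 1 + int(np.searchsorted(np.cumsum(params.hfpsi_baseline_probs),
                                            u_h, side="right"))
            rng.random()  # fully-optimized draw
            mos = float(np.clip(rng.normal(56.0, 21.0), 0.0, 99.0))
            slope = float(rng.normal(0.0, params.titration_sd_pp))
            expected_rows = []
            p_drop = expit(params.censor_intercept
                           + params.censor_beta_distance * distance)
            for k in range(params.n_intervals):
                lp = (params.beta_mos_per10 * mos / 10
                      + params.beta_age_per10 * age / 10)
                if hfpsi >= 2:
                    lp += params.beta_hfpsi[hfpsi - 2]
                if cci_idx >= 1:
                    lp += params.beta_cci[cci_idx - 1]
                p_event = 1 - math.exp(-params.baseline_hazard * math.exp(lp))
                expected_rows.append((k, mos, hfpsi))
                if rng.random() < p_event:
                    rng.integers(1, 183)
                    rng.random()
                    break
                if rng.random() < p_drop:
                    break
                if k == params.n_intervals - 1:
                    break
                noise = float(rng.normal(0.0, params.mos_noise_sd))
                hf_noise = float(rng.normal(0.0, params.hfpsi_noise_sd))
                next_mos = (mos + params.titration_mean_pp + slope
                            + params.feedback_hfpsi_on_mos * (hfpsi - 1) + noise)
                latent = (hfpsi + params.hfpsi_drift
                          + params.feedback_mos_on_hfpsi * mos / 10 + hf_noise)
                mos = float(np.clip(next_mos, 0.0, 100.0))
                hfpsi = int(np.clip(round(latent), 1, 4))
            got = sp.panel[sp.panel["patient_id"] == f"P{i:06d}"]
            assert len(got) == len(expected_rows)
            for (k, m, h), row in zip(expected_rows, got.itertuples(index=False)):
                assert row.interval == k
                assert row.mos == pytest.approx(m)
                assert row.hfpsi == h


@pytest.fixture(scope="module")
def tables():
    return generate_cohort_tables(TruthParams(n_patients=15, seed=13))


class TestCohortTables:
    def test_referential_integrity_and_outcome_rows(self, tables):
        ids = set(tables.patients["patient_id"])
        for name in ("encounters", "medications", "outcomes"):
            assert set(getattr(tables, name)["patient_id"]) <= ids
        assert len(tables.outcomes) == len(tables.patients)
        merged = tables.outcomes.merge(tables.patients, on="patient_id")
        assert (pd.to_datetime(merged["date"]) >=
                pd.to_datetime(merged["index_date"])).all()

    def test_scoring_engine_reproduces_latent_mos(self, tables, formulary, rules):
        """Round trip: compute_mos on emitted encounters == latent MOS (+-1)."""
        panel = tables.latent.panel
        index_dates = dict(zip(tables.patients["patient_id"],
                               pd.to_datetime(tables.patients["index_date"])))
        meds = tables.medications
        checked = 0
        for rec in tables.encounters.itertuples(index=False):
            day = (pd.Timestamp(rec.date) - index_dates[rec.patient_id]).days
            k = day // 182
            latent = panel[(panel["patient_id"] == rec.patient_id)
                           & (panel["interval"] == k)]
            if latent.empty:
                continue
            mm = meds[(meds["patient_id"] == rec.patient_id) & (meds["date"] == rec.date)]
            snap = PatientSnapshot(
                patient_id=rec.patient_id, sbp=rec.sbp, pulse=rec.pulse,
                potassium=rec.potassium, egfr=rec.egfr, nyha=int(rec.nyha),
                orders=list(zip(mm["drug"], mm["total_daily_dose"].astype(float))),
            )
            result = compute_mos(snap, formulary, rules)
            assert result.mos == pytest.approx(float(latent["mos"].iloc[0]), abs=1.0)
            checked += 1
        assert checked > 20

    def test_latent_extremes_map_to_full_or_empty_regimen(self, formulary):
        from gdmtopt.simulate import _fractions_for_target

        assert _fractions_for_target(100.0) == [1.0, 1.0, 1.0, 1.0]
        assert _fractions_for_target(0.0) == [0.0, 0.0, 0.0, 0.0]

    def test_csv_round_trip(self, tables, tmp_path):
        tables.write_csv(str(tmp_path))
        for name in ("patients", "encounters", "medications", "outcomes"):
            assert (tmp_path / f"{name}.csv").exists()
        assert (tmp_path / "truth.json").exists()


def _hand_built_tables() -> CohortTables:
    """10 patients: 3 fully optimized at baseline, 2 more missing HFPSI data."""
    full = [("lisinopril", 40.0), ("carvedilol", 50.0),
            ("spironolactone", 25.0), ("dapagliflozin", 10.0)]
    partial = [("lisinopril", 20.0)]
    patients, encounters, medications, outcomes = [], [], [], []
    for i in range(10):
        pid = f"H{i}"
        patients.append({"patient_id": pid, "age": 60.0, "sex": "Male",
                         "race": "White", "ethnicity": "Non-Hispanic or Latino",
                         "distance_km": 10.0, "index_date": "2022-01-01",
                         "prior_hospitalization": False})
        missing = i in (3, 4)  # missing BNP at baseline
        encounters.append({"patient_id": pid, "date": "2022-01-01", "sbp": 120.0,
                           "dbp": 70.0, "pulse": 75.0, "scr": 1.0,
                           "potassium": 4.2, "egfr": 65.0, "bun": 15.0,
                           "bnp": "" if missing else 100.0, "nyha": 2, "lvef": 30.0})
        for drug, dose in (full if i < 3 else partial):
            medications.append({"patient_id": pid, "date": "2022-01-01",
                                "drug": drug, "total_daily_dose": dose})
        outcomes.append({"patient_id": pid, "date": "2022-12-01",
                         "event_type": "censored"})
    return CohortTables(
        patients=pd.DataFrame(patients), encounters=pd.DataFrame(encounters),
        medications=pd.DataFrame(medications), conditions=pd.DataFrame(
            columns=["patient_id", "condition"]),
        intolerances=pd.DataFrame(columns=["patient_id", "gdmt_class"]),
        outcomes=pd.DataFrame(outcomes),
    )


class TestCohortFilters:
    def test_hand_enumerated_exclusion_counts(self):
        filtered, counts = apply_cohort_filters(_hand_built_tables())
        assert counts == {"fully_optimized": 3, "missing_hfpsi": 2}
        assert len(filtered.patients) == 5

    def test_no_exclusions_is_identity(self):
        tables = _hand_built_tables()
        # make everyone partial and complete
        tables.medications = tables.medications[
            tables.medications["drug"] == "lisinopril"].reset_index(drop=True)
        tables.encounters["bnp"] = 100.0
        filtered, counts = apply_cohort_filters(tables)
        assert counts == {"fully_optimized": 0, "missing_hfpsi": 0}
        assert len(filtered.patients) == 10

    def test_all_fully_optimized_leaves_empty_cohort(self):
        tables = _hand_built_tables()
        full_meds = tables.medications[tables.medications["patient_id"] == "H0"]
        rows = []
        for pid in tables.patients["patient_id"]:
            rows.append(full_meds.assign(patient_id=pid))
        tables.medications = pd.concat(rows, ignore_index=True)
        filtered, counts = apply_cohort_filters(tables)
        assert counts["fully_optimized"] == 10
        assert filtered.patients.empty
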