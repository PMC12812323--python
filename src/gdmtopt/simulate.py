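"""Synthetic ambulatory-HFrEF cohort generator with known causal truth.

Emulates the statistical structure the outcome analysis assumes: an upward
medication-titration trend with patient-specific random slopes,
treatment-confounder feedback (lagged HF severity slows titration, while
lagged medication optimization improves the severity transition), an event
hazard that depends on the current medication optimization score (MOS),
severity, comorbidity and age, and distance-dependent loss to follow-up.

Two fidelity levels are provided:

* :func:`generate_score_panel` emits per-patient per-interval records with
  the MOS given directly (fast; used for estimator recovery experiments);
* :func:`generate_cohort_tables` emits EHR-like medication/vitals/labs tables
  constructed by inverting the MOS formula, so that running the scoring
  engine over the emitted encounters reproduces the latent MOS trajectory.

Reproducibility: patient ``i`` draws from the independent substream
``numpy.random.default_rng([seed, i])`` with a fixed, documented draw order
(see :func:`_simulate_patient`), so trajectories can be replayed exactly and
are unaffected by the number of patients generated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .formulary import BETA_BLOCKER, GDMT_CLASSES, MRA, RASI, SGLT2I, EligibilityRules, Formulary
from .indices import MISSING, HfpsiComponents, compute_hfpsi
from .scoring import compute_mos

logger = logging.getLogger(__name__)

RACE_LEVELS = ("White", "African American", "Other")
ETHNICITY_LEVELS = ("Non-Hispanic or Latino", "Hispanic or Latino")
CCI_LEVELS = ("MILD", "MODERATE", "SEVERE")


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth coefficients and study conditions of the generator.

    Hazard model (discrete time, per 182-day interval): the event probability
    in interval k is ``1 - exp(-baseline_hazard * exp(lp))`` with

        lp = beta_mos_per10 * MOS_k/10 + beta_hfpsi[HFPSI_k - 2]
             + beta_cci[category - MODERATE] + beta_age_per10 * age/10

    (HFPSI level 1 and CCI category MILD are reference levels). Exposure
    update for k >= 1:

        MOS_k = clip(MOS_{k-1} + titration_mean_pp + slope_i
                     + feedback_hfpsi_on_mos * (HFPSI_{k-1} - 1) + noise, 0, 100)

    Severity transition: HFPSI_k = clip(round(HFPSI_{k-1} + hfpsi_drift
    + feedback_mos_on_hfpsi * MOS_{k-1}/10 + noise), 1, 4). Dropout at the
    end of each interval follows logit P = censor_intercept +
    censor_beta_distance * distance_km.

    Defaults mirror the study cohort: baseline MOS ~= 56 +- 21, HFPSI
    marginals of 46.4/23.0/18.5/12.1%, a true exposure hazard ratio of 0.88
    per 10 MOS units and an overall event rate near 40 per 100 person-years.
    ``titration_mean_pp`` is the per-interval MOS gain at the reference
    severity (HFPSI 1); its default of 7.3 combined with the severity
    feedback of -4.0 pp per HFPSI level yields a net average titration of
    about +3.3 points per 6-month interval at the baseline severity mix,
    with the sickest patients de-escalating.
    """

    n_patients: int = 1000
    n_intervals: int = 8
    beta_mos_per10: float = math.log(0.88)
    beta_hfpsi: tuple[float, float, float] = (0.19, 0.17, 0.69)
    beta_cci: tuple[float, float] = (-0.15, 0.10)
    beta_age_per10: float = 0.15
    baseline_hazard: float = 0.13
    titration_mean_pp: float = 7.3
    titration_sd_pp: float = 2.0
    feedback_hfpsi_on_mos: float = -4.0
    feedback_mos_on_hfpsi: float = -0.08
    censor_beta_distance: float = 0.004
    seed: int = 0
    # Nuisance / fidelity knobs
    mos_noise_sd: float = 5.0
    hfpsi_drift: float = 0.45
    hfpsi_noise_sd: float = 0.7
    censor_intercept: float = -2.4
    interval_days: int = 182
    baseline_mos_mean: float = 56.0
    baseline_mos_sd: float = 21.0
    hfpsi_baseline_probs: tuple[float, ...] = (0.464, 0.230, 0.185, 0.121)
    cci_baseline_probs: tuple[float, ...] = (0.199, 0.210, 0.591)
    death_fraction: float = 0.4
    mean_encounters_per_interval: float = 3.0
    frac_fully_optimized: float = 0.0
    frac_missing_hfpsi: float = 0.0

    def validate(self) -> None:
        for name in (
            "beta_mos_per10", "beta_age_per10", "baseline_hazard", "titration_mean_pp",
            "titration_sd_pp", "feedback_hfpsi_on_mos", "feedback_mos_on_hfpsi",
            "censor_beta_distance", "mos_noise_sd", "hfpsi_drift", "hfpsi_noise_sd",
            "censor_intercept", "baseline_mos_mean", "baseline_mos_sd",
        ):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"TruthParams.{name} must be finite, got {value!r}")
        for name in ("beta_hfpsi", "beta_cci", "hfpsi_baseline_probs", "cci_baseline_probs"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"TruthParams.{name} must be finite, got {vec!r}")
        if len(self.beta_hfpsi) != 3:
            raise ValueError("TruthParams.beta_hfpsi needs 3 entries (levels 2-4 vs 1)")
        if len(self.beta_cci) != 2:
            raise ValueError("TruthParams.beta_cci needs 2 entries (moderate/severe vs mild)")
        if self.n_patients <= 0:
            raise ValueError("TruthParams.n_patients must be positive")
        if self.n_intervals < 2:
            raise ValueError("TruthParams.n_intervals must be >= 2")
        if self.baseline_hazard <= 0:
            raise ValueError("TruthParams.baseline_hazard must be > 0")
        if self.titration_sd_pp < 0:
            raise ValueError("TruthParams.titration_sd_pp must be >= 0")

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "TruthParams":
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        for key in ("beta_hfpsi", "beta_cci", "hfpsi_baseline_probs", "cci_baseline_probs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ScorePanel:
    """Score-level simulation output: baseline table + interval panel + truth."""

    patients: pd.DataFrame
    panel: pd.DataFrame
    params: TruthParams

    def analysis_panel(self) -> pd.DataFrame:
        """Panel merged with baseline covariates plus lagged exposure columns.

        Adds ``mos_prev`` (previous interval's MOS), ``cum_mos_lag`` (running
        mean of all MOS values from intervals strictly before k; at k = 0 the
        baseline MOS itself), ``hfpsi_lag1`` and scaled ``mos10``/``age10``.
        """
        df = self.panel.merge(self.patients, on="patient_id", how="left")
        df = df.sort_values(["patient_id", "interval"]).reset_index(drop=True)
        grp = df.groupby("patient_id")["mos"]
        df["mos_prev"] = grp.shift(1)
        cum = grp.transform(lambda s: s.expanding().mean().shift(1))
        df["cum_mos_lag"] = cum.fillna(df["mos"])
        df["hfpsi_lag1"] = df.groupby("patient_id")["hfpsi"].shift(1).fillna(df["hfpsi"]).astype(int)
        df["mos10"] = df["mos"] / 10.0
        df["cum_mos_lag10"] = df["cum_mos_lag"] / 10.0
        df["age10"] = df["age"] / 10.0
        return df


def _draw_categorical(u: float, probs) -> int:
    edges = np.cumsum(probs)
    return int(np.searchsorted(edges, u, side="right"))


def _linear_predictor(p: TruthParams, mos: float, hfpsi: int, cci_idx: int, age: float) -> float:
    lp = p.beta_mos_per10 * mos / 10.0 + p.beta_age_per10 * age / 10.0
    if hfpsi >= 2:
        lp += p.beta_hfpsi[hfpsi - 2]
    if cci_idx >= 1:
        lp += p.beta_cci[cci_idx - 1]
    return lp


def _simulate_patient(params: TruthParams, i: int) -> tuple[dict, list[dict]]:
    """Simulate one patient from substream ``default_rng([seed, i])``.

    Draw order (fixed contract, relied upon by replay tests):
      1. age ~ Normal(64.7, 14.3) clipped to [18, 95]
      2. u_sex (uniform): Female if u < 0.35
      3. u_race (uniform): White 0.755 / African American 0.190 / Other 0.055
      4. u_ethnicity (uniform): Hispanic or Latino if u < 0.024
      5. distance_km ~ Lognormal(mu=3.7, sigma=0.9)
      6. u_cci (uniform) -> baseline CCI category probabilities
      7. u_hfpsi (uniform) -> baseline HFPSI probabilities
      8. u_fullopt (uniform); then baseline MOS ~ Normal(mean, sd) clipped to
         [0, 99] unless u_fullopt < frac_fully_optimized (then MOS = 100)
      9. slope ~ Normal(0, titration_sd_pp)
      10. per interval k: u_event (uniform); if event, day offset
          ~ integers(1, interval_days+1) then u_type (uniform, death if
          u < death_fraction); else u_dropout (uniform); else, when another
          interval follows, mos noise ~ Normal(0, mos_noise_sd) and hfpsi
          noise ~ Normal(0, hfpsi_noise_sd).
    """
    rng = np.random.default_rng([params.seed, i])
    age = float(np.clip(rng.normal(64.7, 14.3), 18.0, 95.0))
    sex = "Female" if rng.random() < 0.35 else "Male"
    race = RACE_LEVELS[_draw_categorical(rng.random(), (0.755, 0.190, 0.055))]
    ethnicity = ETHNICITY_LEVELS[1] if rng.random() < 0.024 else ETHNICITY_LEVELS[0]
    distance = float(rng.lognormal(3.7, 0.9))
    cci_idx = _draw_categorical(rng.random(), params.cci_baseline_probs)
    hfpsi = 1 + _draw_categorical(rng.random(), params.hfpsi_baseline_probs)
    fully_optimized = rng.random() < params.frac_fully_optimized
    mos = 100.0 if fully_optimized else float(
        np.clip(rng.normal(params.baseline_mos_mean, params.baseline_mos_sd), 0.0, 99.0)
    )
    slope = float(rng.normal(0.0, params.titration_sd_pp)) if params.titration_sd_pp > 0 else 0.0

    patient = {
        "patient_id": f"P{i:06d}",
        "age": age,
        "sex": sex,
        "race": race,
        "ethnicity": ethnicity,
        "distance_km": distance,
        "cci_category": CCI_LEVELS[cci_idx],
        "hfpsi_baseline": hfpsi,
        "fully_optimized_baseline": fully_optimized,
    }

    p_dropout = float(expit(params.censor_intercept + params.censor_beta_distance * distance))
    rows: list[dict] = []
    for k in range(params.n_intervals):
        start = k * params.interval_days
        stop = (k + 1) * params.interval_days
        lp = _linear_predictor(params, mos, hfpsi, cci_idx, age)
        p_event = 1.0 - math.exp(-params.baseline_hazard * math.exp(lp))
        row = {
            "patient_id": patient["patient_id"],
            "interval": k,
            "start": start,
            "stop": stop,
            "mos": mos,
            "hfpsi": hfpsi,
            "event": False,
            "censored": False,
            "dropout": False,
            "event_type": "",
        }
        if rng.random() < p_event:
            offset = int(rng.integers(1, params.interval_days + 1))
            row["stop"] = start + offset
            row["event"] = True
            row["event_type"] = "death" if rng.random() < params.death_fraction else "hospitalization"
            rows.append(row)
            break
        if rng.random() < p_dropout:
            row["censored"] = True
            row["dropout"] = True
            row["event_type"] = "censored"
            rows.append(row)
            break
        if k == params.n_intervals - 1:
            row["censored"] = True  # administrative end of follow-up
            row["event_type"] = "censored"
            rows.append(row)
            break
        rows.append(row)
        noise = float(rng.normal(0.0, params.mos_noise_sd)) if params.mos_noise_sd > 0 else 0.0
        next_mos = (
            mos + params.titration_mean_pp + slope
            + params.feedback_hfpsi_on_mos * (hfpsi - 1) + noise
        )
        hf_noise = float(rng.normal(0.0, params.hfpsi_noise_sd)) if params.hfpsi_noise_sd > 0 else 0.0
        latent = hfpsi + params.hfpsi_drift + params.feedback_mos_on_hfpsi * mos / 10.0 + hf_noise
        mos = float(np.clip(next_mos, 0.0, 100.0))
        hfpsi = int(np.clip(round(latent), 1, 4))
    return patient, rows


def generate_score_panel(params: TruthParams) -> ScorePanel:
    """Generate the score-level per-patient per-interval panel.

    Records exist for every interval a patient is at risk in; the terminal
    row carries the event or censoring flag (``dropout`` distinguishes
    covariate-dependent loss to follow-up from administrative end of study).
    Identical ``params`` (including seed) reproduce the panel exactly.
    """
    params.validate()
    patients, rows = [], []
    for i in range(params.n_patients):
        patient, patient_rows = _simulate_patient(params, i)
        patients.append(patient)
        rows.extend(patient_rows)
    return ScorePanel(
        patients=pd.DataFrame(patients), panel=pd.DataFrame(rows), params=params
    )


# ---------------------------------------------------------------------------
# Medication-level generation (inverse of the scoring engine)
# ---------------------------------------------------------------------------

# One representative drug per class used when materializing regimens.
_CLASS_FILL_ORDER = (RASI, BETA_BLOCKER, MRA, SGLT2I)


@dataclass
class CohortTables:
    """EHR-like delimited tables plus the latent truth they were built from."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    medications: pd.DataFrame
    conditions: pd.DataFrame
    intolerances: pd.DataFrame
    outcomes: pd.DataFrame
    latent: Optional[ScorePanel] = None

    def write_csv(self, out_dir: str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("patients", "encounters", "medications", "conditions",
                     "intolerances", "outcomes"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        if self.latent is not None:
            self.latent.params.to_json(str(out / "truth.json"))


def _fractions_for_target(mos: float, n_classes: int = 4) -> list[float]:
    """Per-class dose fractions whose mean reproduces ``mos`` exactly.

    Classes are filled greedily to target in a fixed order, so MOS 100 means
    every class at target and MOS 0 means no GDMT at all.
    """
    remaining = n_classes * mos / 100.0
    fractions = []
    for _ in range(n_classes):
        f = min(1.0, max(0.0, remaining))
        fractions.append(f)
        remaining -= f
    return fractions


def _snap_fraction(entry, fraction: float) -> float:
    """Nearest representable fraction on the drug's titration grid (or 0)."""
    grid = [0.0] + [s / entry.target_daily_dose for s in entry.titration_steps]
    return min(grid, key=lambda g: abs(g - fraction))


_CONDITION_POOLS = {
    # Condition bundles by target CCI category (weights from the packaged
    # Charlson dictionary): MILD sums to 1-2, MODERATE to 3-4, SEVERE to >= 5.
    "MILD": (["congestive_heart_failure"],
             ["congestive_heart_failure", "chronic_pulmonary_disease"]),
    "MODERATE": (["congestive_heart_failure", "moderate_severe_renal_disease"],
                 ["congestive_heart_failure", "diabetes_with_complications",
                  "myocardial_infarction"]),
    "SEVERE": (["congestive_heart_failure", "metastatic_solid_tumor"],
               ["congestive_heart_failure", "diabetes_with_complications",
                "moderate_severe_renal_disease", "myocardial_infarction"]),
}


def generate_cohort_tables(
    params: TruthParams,
    formulary: Optional[Formulary] = None,
    snap_to_grid: bool = False,
) -> CohortTables:
    """Emit medication-level EHR tables realizing the latent score panel.

    Regimens are constructed by inverting the MOS formula: per-class dose
    fractions are chosen so their mean equals the latent MOS, and doses are
    emitted as fraction x target (exactly representable) unless
    ``snap_to_grid`` forces them onto the titration ladder, in which case the
    nearest representable score is used and logged. Vitals and labs are drawn
    around the study cohort's means, clipped away from every eligibility
    threshold so the scoring engine sees all four classes as eligible.
    """
    params.validate()
    formulary = formulary or Formulary.default()
    if len(formulary) == 0:
        raise ValueError("formulary must be nonempty")
    score = generate_score_panel(params)
    class_drugs = {c: formulary.first_in_class(c) for c in _CLASS_FILL_ORDER}

    index_origin = pd.Timestamp("2021-07-01")
    enc_rows, med_rows, cond_rows, outcome_rows, patient_rows = [], [], [], [], []
    panel_by_patient = dict(tuple(score.panel.groupby("patient_id", sort=False)))

    for i, patient in enumerate(score.patients.to_dict("records")):
        rng = np.random.default_rng([params.seed, 1_000_000 + i])
        pid = patient["patient_id"]
        index_date = index_origin + pd.Timedelta(days=int(rng.integers(0, 366)))
        missing_hfpsi = rng.random() < params.frac_missing_hfpsi
        prows = panel_by_patient[pid]

        for row in prows.itertuples(index=False):
            n_enc = 1 if row.interval == 0 else int(rng.poisson(params.mean_encounters_per_interval))
            span = max(int(row.stop) - int(row.start), 1)
            offsets = [0] if row.interval == 0 else sorted(
                int(d) for d in rng.integers(0, span, size=n_enc)
            )
            for day in offsets:
                date = index_date + pd.Timedelta(days=int(row.start) + day)
                nyha = int(np.clip(row.hfpsi + rng.integers(-1, 2), 1, 4))
                bun = float(np.clip(rng.normal(18 + 8 * (row.hfpsi - 1), 6), 5, 80))
                bnp = float(np.clip(rng.lognormal(5.0 + 0.6 * (row.hfpsi - 1), 0.6), 10, 20000))
                enc_rows.append({
                    "patient_id": pid,
                    "date": date.date().isoformat(),
                    "sbp": round(float(np.clip(rng.normal(121.0, 17.3), 96, 200)), 1),
                    "dbp": round(float(np.clip(rng.normal(68.8, 12.1), 40, 120)), 1),
                    "pulse": round(float(np.clip(rng.normal(76.5, 13.8), 61, 140)), 1),
                    "scr": round(float(np.clip(rng.normal(1.33, 0.94), 0.4, 8.0)), 2),
                    "potassium": round(float(np.clip(rng.normal(4.4, 0.45), 3.2, 5.0)), 2),
                    "egfr": round(float(np.clip(rng.normal(63.0, 23.0), 31, 130)), 1),
                    "bun": "" if missing_hfpsi else round(bun, 1),
                    "bnp": "" if missing_hfpsi else round(bnp, 1),
                    "nyha": nyha,
                    "lvef": round(float(np.clip(rng.normal(28.9, 8.1), 10, 40)), 1),
                })
                fractions = _fractions_for_target(float(row.mos))
                for gdmt_class, fraction in zip(_CLASS_FILL_ORDER, fractions):
                    if fraction <= 0.0:
                        continue
                    entry = class_drugs[gdmt_class]
                    if snap_to_grid:
                        snapped = _snap_fraction(entry, fraction)
                        if abs(snapped - fraction) > 1e-9:
                            logger.info(
                                "snapped %s fraction %.3f -> %.3f for %s",
                                gdmt_class, fraction, snapped, pid,
                            )
                        fraction = snapped
                        if fraction <= 0.0:
                            continue
                    med_rows.append({
                        "patient_id": pid,
                        "date": date.date().isoformat(),
                        "drug": entry.name,
                        "total_daily_dose": round(fraction * entry.target_daily_dose, 6),
                    })

        pool = _CONDITION_POOLS[patient["cci_category"]]
        for code in pool[int(rng.random() < 0.5)]:
            cond_rows.append({"patient_id": pid, "condition": code})

        last = prows.iloc[-1]
        end_date = index_date + pd.Timedelta(days=int(last["stop"]))
        outcome_rows.append({
            "patient_id": pid,
            "date": end_date.date().isoformat(),
            "event_type": last["event_type"] if last["event"] else "censored",
        })
        patient_rows.append({
            "patient_id": pid,
            "age": round(patient["age"], 1),
            "sex": patient["sex"],
            "race": patient["race"],
            "ethnicity": patient["ethnicity"],
            "distance_km": round(patient["distance_km"], 1),
            "index_date": index_date.date().isoformat(),
            "prior_hospitalization": bool(rng.random() < 0.3),
        })

    return CohortTables(
        patients=pd.DataFrame(patient_rows),
        encounters=pd.DataFrame(enc_rows),
        medications=pd.DataFrame(med_rows),
        conditions=pd.DataFrame(cond_rows),
        intolerances=pd.DataFrame(columns=["patient_id", "gdmt_class"]),
        outcomes=pd.DataFrame(outcome_rows),
        latent=score,
    )


def apply_cohort_filters(
    tables: CohortTables,
    formulary: Optional[Formulary] = None,
    rules: Optional[EligibilityRules] = None,
) -> tuple[CohortTables, dict[str, int]]:
    """Apply the cohort's entry filters and report exclusion counts.

    In order: (1) patients fully optimized at baseline (index-date MOS = 100)
    are removed; (2) of the remainder, patients with any missing HFPSI
    component at baseline are removed. Counts are keyed ``fully_optimized``
    and ``missing_hfpsi`` in application order.
    """
    formulary = formulary or Formulary.default()
    rules = rules or EligibilityRules.default()

    enc = tables.encounters.copy()
    kept, n_full, n_missing = [], 0, 0
    diabetes_ids = set(
        tables.conditions.loc[
            tables.conditions["condition"].isin(["diabetes", "diabetes_with_complications"]),
            "patient_id",
        ]
    )
    af_ids = set(
        tables.conditions.loc[
            tables.conditions["condition"] == "atrial_fibrillation", "patient_id"
        ]
    )
    prior_hosp = dict(
        zip(tables.patients["patient_id"], tables.patients.get(
            "prior_hospitalization", pd.Series(False, index=tables.patients.index)))
    )

    for pid, patient_enc in enc.groupby("patient_id", sort=False):
        baseline = patient_enc.sort_values("date").iloc[0]
        meds = tables.medications
        base_meds = meds[(meds["patient_id"] == pid) & (meds["date"] == baseline["date"])]
        intol = tables.intolerances
        intol_classes = frozenset(intol.loc[intol["patient_id"] == pid, "gdmt_class"])

        def _num(value):
            return None if value in ("", None) or pd.isna(value) else float(value)

        from .scoring import PatientSnapshot  # local import to avoid cycle at module load

        snapshot = PatientSnapshot(
            patient_id=pid,
            date=str(baseline["date"]),
            orders=list(zip(base_meds["drug"], base_meds["total_daily_dose"].astype(float))),
            sbp=_num(baseline.get("sbp")),
            pulse=_num(baseline.get("pulse")),
            scr=_num(baseline.get("scr")),
            potassium=_num(baseline.get("potassium")),
            egfr=_num(baseline.get("egfr")),
            nyha=int(baseline["nyha"]) if not pd.isna(baseline.get("nyha")) else None,
            intolerant_classes=intol_classes,
        )
        result = compute_mos(snapshot, formulary, rules)
        if result.mos is not None and result.mos >= 100.0 - 1e-9:
            n_full += 1
            continue
        components = HfpsiComponents(
            bun=_num(baseline.get("bun")),
            bnp=_num(baseline.get("bnp")),
            nyha=int(baseline["nyha"]) if not pd.isna(baseline.get("nyha")) else None,
            diabetes=pid in diabetes_ids,
            af_flutter=pid in af_ids,
            recent_hospitalization=bool(prior_hosp.get(pid, False)),
        )
        if compute_hfpsi(components) == MISSING:
            n_missing += 1
            continue
        kept.append(pid)

    keep = set(kept)

    def _filter(df: pd.DataFrame) -> pd.DataFrame:
        if "patient_id" not in df.columns or df.empty:
            return df.copy()
        return df[df["patient_id"].isin(keep)].reset_index(drop=True)

    filtered = CohortTables(
        patients=_filter(tables.patients),
        encounters=_filter(tables.encounters),
        medications=_filter(tables.medications),
        conditions=_filter(tables.conditions),
        intolerances=_filter(tables.intolerances),
        outcomes=_filter(tables.outcomes),
        latent=tables.latent,
    )
    return filtered, {"fully_optimized": n_full, "missing_hfpsi": n_missing}
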