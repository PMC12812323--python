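"""Survival analysis: Kaplan-Meier, log-rank, event rates and Cox models.

Cox fits maximize the partial likelihood with Efron tie handling (day-granular
panels produce many ties) via lifelines, support counting-process (start,
stop] rows for time-varying exposures, case weights, and patient-clustered
sandwich standard errors. The three outcome models of the analysis are
exposed through :class:`CoxOutcomeModel`:

* model A — unadjusted baseline MOS (per 10 units);
* model B — baseline MOS adjusted for age (per 10 years), sex, race,
  ethnicity, HFPSI class (reference 1) and CCI category (reference mild);
* model C — time-varying one-interval-lagged cumulative mean MOS with the
  same baseline covariates and patient-clustered robust standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test

__all__ = [
    "KmCurve", "km_estimate", "logrank_test", "event_rate_per_100py",
    "CoxResults", "fit_cox", "schoenfeld_ph_test", "CoxOutcomeModel",
    "baseline_design", "BASELINE_COVARIATES",
]


@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival curve with Greenwood-based log-log CI band."""

    label: str
    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray

    @property
    def cumulative_incidence(self) -> np.ndarray:
        """1 - S(t): the cumulative event probability plotted in reports."""
        return 1.0 - self.survival

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Optional[Sequence] = None,
) -> dict[str, KmCurve]:
    """Kaplan-Meier estimate per group (single group label "all" if None)."""
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=bool),
        "group": ["all"] * len(times) if groups is None else list(groups),
    })
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    curves: dict[str, KmCurve] = {}
    for label, grp in df.groupby("group", sort=True):
        if grp.empty:
            warnings.warn(f"group {label!r} has no subjects; omitted", stacklevel=2)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"], label=str(label))
        surv = kmf.survival_function_.iloc[:, 0]
        ci = kmf.confidence_interval_
        curves[str(label)] = KmCurve(
            label=str(label),
            times=surv.index.to_numpy(dtype=float),
            survival=surv.to_numpy(dtype=float),
            ci_lower=ci.iloc[:, 0].to_numpy(dtype=float),
            ci_upper=ci.iloc[:, 1].to_numpy(dtype=float),
            at_risk=kmf.event_table["at_risk"].reindex(surv.index).to_numpy(dtype=float),
        )
    return curves


def logrank_test(
    times: Sequence[float], events: Sequence[bool], groups: Sequence
) -> tuple[float, int, float]:
    """Log-rank chi-square statistic, degrees of freedom and p-value."""
    groups = pd.Series(list(groups))
    n_groups = groups.nunique()
    if n_groups < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), groups, np.asarray(events, dtype=bool)
    )
    return float(res.test_statistic), n_groups - 1, float(res.p_value)


def event_rate_per_100py(events: int, person_years: float) -> float:
    """Events per 100 person-years of follow-up."""
    if person_years <= 0:
        raise ValueError("person-years must be > 0")
    return 100.0 * events / person_years


@dataclass
class CoxResults:
    """Fitted Cox model: log-HRs, their uncertainty and diagnostics."""

    covariates: list[str]
    coef: pd.Series
    se: pd.Series
    se_type: str  # "model" or "cluster-robust"
    hr: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p: pd.Series
    n_events: int
    n_obs: int
    log_likelihood: float
    _fitter: CoxPHFitter = field(repr=False, default=None)
    _df: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        """Table 2-style frame: HR [95% CI], p per covariate."""
        return pd.DataFrame({
            "coef": self.coef,
            f"se ({self.se_type})": self.se,
            "HR": self.hr,
            "HR 95% lower": self.ci_lower,
            "HR 95% upper": self.ci_upper,
            "p": self.p,
        })

    def to_dict(self) -> dict:
        return {
            "se_type": self.se_type,
            "n_events": self.n_events,
            "n_obs": self.n_obs,
            "log_likelihood": self.log_likelihood,
            "covariates": {
                name: {
                    "coef": float(self.coef[name]),
                    "se": float(self.se[name]),
                    "hr": float(self.hr[name]),
                    "ci": [float(self.ci_lower[name]), float(self.ci_upper[name])],
                    "p": float(self.p[name]),
                }
                for name in self.covariates
            },
        }


def fit_cox(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    entry_col: Optional[str] = None,
    weights_col: Optional[str] = None,
    cluster_col: Optional[str] = None,
) -> CoxResults:
    """Cox proportional hazards fit (Efron ties) over the given covariates.

    ``entry_col`` switches to counting-process (entry, duration] rows;
    ``cluster_col`` requests a clustered sandwich (robust) covariance. 95% CIs
    use the normal approximation on the log-HR scale with the reported SE.
    """
    covariates = list(covariates)
    if int(df[event_col].sum()) < 1:
        raise ValueError("Cox fit needs at least one event")
    for cov in covariates:
        if df[cov].nunique() <= 1:
            raise ValueError(f"covariate {cov!r} is constant; degenerate design")
    cols = covariates + [duration_col, event_col]
    for opt in (entry_col, weights_col, cluster_col):
        if opt is not None:
            cols.append(opt)
    model_df = df[cols].copy()
    robust = cluster_col is not None
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            model_df,
            duration_col=duration_col,
            event_col=event_col,
            entry_col=entry_col,
            weights_col=weights_col,
            cluster_col=cluster_col,
            robust=robust,
            formula=" + ".join(f"`{c}`" for c in covariates),
            fit_options={"precision": 1e-09},
        )
    summ = cph.summary
    coef = summ["coef"]
    se = summ["se(coef)"]
    coef.index = [str(i).strip("`") for i in coef.index]
    se.index = coef.index
    p = pd.Series(summ["p"].to_numpy(), index=coef.index)
    z = 1.959963984540054
    ci_lo = np.exp(coef - z * se)
    ci_hi = np.exp(coef + z * se)
    return CoxResults(
        covariates=list(coef.index),
        coef=coef,
        se=se,
        se_type="cluster-robust" if robust else "model",
        hr=np.exp(coef),
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        p=p,
        n_events=int(df[event_col].sum()),
        n_obs=len(df),
        log_likelihood=float(cph.log_likelihood_),
        _fitter=cph,
        _df=model_df,
    )


def schoenfeld_ph_test(results: CoxResults) -> pd.DataFrame:
    """Proportional-hazards check from scaled Schoenfeld residuals.

    Per-covariate chi-square statistics and p-values (rank time transform),
    plus a ``GLOBAL`` row carrying the Bonferroni combination of the
    per-covariate p-values as an overall screen.
    """
    if results.n_events < 2:
        raise ValueError("Schoenfeld test needs at least 2 events")
    if results.n_events < len(results.covariates):
        raise ValueError("fewer events than covariates")
    res = proportional_hazard_test(results._fitter, results._df, time_transform="rank")
    out = res.summary[["test_statistic", "p"]].copy()
    out.index = [str(i).strip("`") for i in out.index]
    global_p = min(1.0, float(out["p"].min()) * len(out))
    out.loc["GLOBAL"] = [np.nan, global_p]
    return out


# ---------------------------------------------------------------------------
# Study outcome models over the analysis panel
# ---------------------------------------------------------------------------

BASELINE_COVARIATES = [
    "age10", "sex_female", "race_african_american", "race_other",
    "ethnicity_hispanic", "hfpsi_2", "hfpsi_3", "hfpsi_4",
    "cci_moderate", "cci_severe",
]


def baseline_design(df: pd.DataFrame) -> pd.DataFrame:
    """Reference-coded baseline covariate columns.

    Reference levels: male, White, non-Hispanic, HFPSI 1, CCI mild. Expects
    columns age10 (or age), sex, race, ethnicity, hfpsi_baseline,
    cci_category.
    """
    out = pd.DataFrame(index=df.index)
    out["age10"] = df["age10"] if "age10" in df else df["age"] / 10.0
    out["sex_female"] = (df["sex"] == "Female").astype(float)
    out["race_african_american"] = (df["race"] == "African American").astype(float)
    out["race_other"] = (df["race"] == "Other").astype(float)
    out["ethnicity_hispanic"] = (df["ethnicity"] == "Hispanic or Latino").astype(float)
    for level in (2, 3, 4):
        out[f"hfpsi_{level}"] = (df["hfpsi_baseline"].astype(int) == level).astype(float)
    out["cci_moderate"] = (df["cci_category"] == "MODERATE").astype(float)
    out["cci_severe"] = (df["cci_category"] == "SEVERE").astype(float)
    return out


class CoxOutcomeModel:
    """Cox models A/B/C over an analysis panel, statsmodels-style.

    ``panel`` is a per-patient per-interval frame as produced by
    :meth:`gdmtopt.simulate.ScorePanel.analysis_panel` (columns patient_id,
    interval, start, stop, mos, event, plus baseline covariates and the
    lagged cumulative exposure ``cum_mos_lag10`` for model C).
    """

    def __init__(self, panel: pd.DataFrame, model: str = "B"):
        model = model.upper()
        if model not in ("A", "B", "C"):
            raise ValueError("model must be 'A', 'B' or 'C'")
        self.model = model
        self.panel = panel.sort_values(["patient_id", "interval"]).reset_index(drop=True)

    def _baseline_frame(self) -> pd.DataFrame:
        first = self.panel.groupby("patient_id", as_index=False).first()
        last = self.panel.groupby("patient_id", as_index=False).last()
        df = baseline_design(first)
        df["mos10_baseline"] = first["mos"] / 10.0
        df["duration"] = last["stop"].astype(float)
        df["event"] = last["event"].astype(bool)
        return df

    def _counting_frame(self) -> pd.DataFrame:
        df = baseline_design(self.panel)
        df["cum_mos_lag10"] = self.panel["cum_mos_lag10"]
        df["patient_id"] = self.panel["patient_id"]
        df["start"] = self.panel["start"].astype(float)
        df["stop"] = self.panel["stop"].astype(float)
        df["event"] = self.panel["event"].astype(bool)
        return df

    @staticmethod
    def _usable(df: pd.DataFrame, covariates: list[str]) -> list[str]:
        kept = [c for c in covariates if df[c].nunique() > 1]
        dropped = sorted(set(covariates) - set(kept))
        if dropped:
            warnings.warn(f"dropping constant covariates {dropped}", stacklevel=3)
        return kept

    def fit(self) -> CoxResults:
        if self.model == "A":
            df = self._baseline_frame()
            return fit_cox(df, "duration", "event", ["mos10_baseline"])
        if self.model == "B":
            df = self._baseline_frame()
            covs = ["mos10_baseline"] + self._usable(df, BASELINE_COVARIATES)
            return fit_cox(df, "duration", "event", covs)
        df = self._counting_frame()
        covs = ["cum_mos_lag10"] + self._usable(df, BASELINE_COVARIATES)
        return fit_cox(
            df, "stop", "event", covs, entry_col="start", cluster_col="patient_id",
        )
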