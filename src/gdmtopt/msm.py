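"""Marginal structural Cox model with IPTW x IPCW for a continuous exposure.

The exposure (MOS) is continuous, so inverse-probability-of-treatment weights
are built from the ratio of conditional normal densities of the observed MOS
under two linear exposure models: the numerator conditions on the prior MOS,
baseline covariates and time; the denominator additionally conditions on the
one-interval-lagged time-varying confounders (HFPSI and CCI). Inverse
probability-of-censoring weights come from pooled logistic models of dropout
with the same numerator/denominator structure plus baseline distance from the
treating center in the numerator. Per-interval contributions are cumulated
multiplicatively within patient, each weight stream is truncated at its own
1st/99th percentiles, and the final weight is the row-wise product. The
outcome model is a weighted Cox fit of the current-interval MOS (per 10
units) with baseline-covariate adjustment and patient-clustered sandwich
standard errors.

Interval 0 carries weight 1: there is no prior MOS to model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .survival import BASELINE_COVARIATES, CoxResults, baseline_design, fit_cox

__all__ = [
    "WeightModelSpec", "DensityModel", "PooledLogisticModel",
    "fit_exposure_density_models", "compute_iptw", "fit_censoring_models",
    "compute_ipcw", "truncate_and_combine", "fit_msm",
    "MarginalStructuralCox", "MSMResults",
]

_BASE_TERMS = ["age10", "sex_female", "race_african_american", "race_other",
               "ethnicity_hispanic"]
_LAGGED_CONFOUNDERS = ["hfpsi_lag1_2", "hfpsi_lag1_3", "hfpsi_lag1_4",
                       "cci_moderate", "cci_severe"]


@dataclass(frozen=True)
class WeightModelSpec:
    """Term sets of the weight models and the truncation percentiles.

    The denominator term set strictly contains the numerator's: both share
    prior MOS, baseline covariates and time (categorical interval
    indicators); the denominator adds the lagged HFPSI/CCI confounders. The
    censoring models additionally place baseline distance in both numerator
    and denominator.
    """

    truncation: tuple[float, float] = (0.01, 0.99)
    include_distance_in_censoring: bool = True

    def __post_init__(self) -> None:
        low, high = self.truncation
        if not (0.0 < low < 0.5 and 0.5 < high < 1.0 and low < high):
            raise ValueError(f"truncation percentiles out of range: {self.truncation}")


def _weight_design(panel: pd.DataFrame, denominator: bool, censoring: bool,
                   spec: WeightModelSpec) -> pd.DataFrame:
    """Design matrix (with intercept) for a weight model on k >= 1 rows.

    Treatment-history terms (prior MOS, baseline MOS and the observed
    per-interval titration rate so far) enter both numerator and denominator
    — stabilization permits any function of exposure history and baseline
    covariates in the numerator; only the lagged confounders are
    denominator-exclusive.
    """
    X = pd.DataFrame(index=panel.index)
    X["const"] = 1.0
    X["mos_prev"] = panel["mos_prev"].astype(float)
    if "mos_baseline" in panel:
        X["mos_baseline"] = panel["mos_baseline"].astype(float)
        k = panel["interval"].astype(float).clip(lower=1.0)
        X["titration_rate_hist"] = (X["mos_prev"] - X["mos_baseline"]) / k
    base = baseline_design(panel)
    for term in _BASE_TERMS:
        X[term] = base[term]
    for k in sorted(panel["interval"].unique())[1:]:
        X[f"interval_{int(k)}"] = (panel["interval"] == k).astype(float)
    if censoring and spec.include_distance_in_censoring:
        X["distance_km"] = panel["distance_km"].astype(float)
    if denominator:
        for level in (2, 3, 4):
            X[f"hfpsi_lag1_{level}"] = (panel["hfpsi_lag1"].astype(int) == level).astype(float)
        X["cci_moderate"] = base["cci_moderate"]
        X["cci_severe"] = base["cci_severe"]
    # Constant columns carry no information and break the normal equations.
    keep = [c for c in X.columns if c == "const" or X[c].nunique() > 1]
    return X[keep]


@dataclass
class DensityModel:
    """Linear-Gaussian conditional density of the current MOS."""

    columns: list[str]
    params: pd.Series
    resid_sd: float

    def mean(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.columns].to_numpy() @ self.params.to_numpy()

    def pdf(self, X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
        return norm.pdf(y, loc=self.mean(X), scale=self.resid_sd)


@dataclass
class PooledLogisticModel:
    """Pooled logistic model of dropout over person-intervals."""

    columns: list[str]
    params: pd.Series

    def prob_uncensored(self, X: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        p_censored = expit(X[self.columns].to_numpy() @ self.params.to_numpy())
        return np.clip(1.0 - p_censored, 1e-10, 1.0)


def _exposure_rows(panel: pd.DataFrame) -> pd.DataFrame:
    rows = panel[panel["interval"] >= 1].copy()
    if rows["mos_prev"].isna().any():
        raise ValueError("prior MOS undefined on k >= 1 rows")
    return rows


def _fit_ols_density(rows: pd.DataFrame, X: pd.DataFrame) -> DensityModel:
    y = rows["mos"].astype(float)
    res = sm.OLS(y, X).fit()
    if res.df_resid <= 0:
        raise ValueError("degenerate exposure-model design (no residual df)")
    resid_sd = float(np.sqrt(res.ssr / res.df_resid))
    if not np.isfinite(resid_sd) or resid_sd <= 0:
        raise ValueError("exposure model residual SD must be positive")
    return DensityModel(columns=list(X.columns), params=res.params, resid_sd=resid_sd)


def fit_exposure_density_models(
    panel: pd.DataFrame, spec: Optional[WeightModelSpec] = None
) -> tuple[DensityModel, DensityModel]:
    """Fit the numerator and denominator conditional-density exposure models.

    Both are linear regressions of the current-interval MOS with homoscedastic
    normal residuals, fitted on k >= 1 rows; the conditional density is the
    normal pdf at the observed MOS.
    """
    spec = spec or WeightModelSpec()
    rows = _exposure_rows(panel)
    num = _fit_ols_density(rows, _weight_design(rows, denominator=False, censoring=False, spec=spec))
    den = _fit_ols_density(rows, _weight_design(rows, denominator=True, censoring=False, spec=spec))
    return num, den


def compute_iptw(
    panel: pd.DataFrame,
    models: tuple[DensityModel, DensityModel],
    spec: Optional[WeightModelSpec] = None,
) -> pd.DataFrame:
    """Stabilized IPTW contributions and their within-patient running product.

    Contribution at k >= 1 is numerator density / denominator density at the
    observed MOS; interval 0 contributes exactly 1.
    """
    spec = spec or WeightModelSpec()
    num_model, den_model = models
    out = panel[["patient_id", "interval"]].copy()
    out["iptw_contrib"] = 1.0
    rows = _exposure_rows(panel)
    Xn = _weight_design(rows, denominator=False, censoring=False, spec=spec)
    Xd = _weight_design(rows, denominator=True, censoring=False, spec=spec)
    y = rows["mos"].to_numpy(dtype=float)
    num = num_model.pdf(Xn, y)
    den = den_model.pdf(Xd, y)
    if np.any(den <= 0):
        bad = rows.index[den <= 0][0]
        raise ValueError(f"zero denominator density at row {bad}")
    out.loc[rows.index, "iptw_contrib"] = num / den
    out = out.sort_values(["patient_id", "interval"])
    out["iptw_cum"] = out.groupby("patient_id")["iptw_contrib"].cumprod()
    return out.sort_index()


def fit_censoring_models(
    panel: pd.DataFrame, spec: Optional[WeightModelSpec] = None
) -> Optional[tuple[PooledLogisticModel, PooledLogisticModel]]:
    """Fit pooled logistic numerator/denominator models of dropout.

    Dropout means loss to follow-up before the administrative end of study
    (the ``dropout`` column when present, else any censoring). Returns None —
    meaning all IPCW are 1 — when no dropout occurs.
    """
    spec = spec or WeightModelSpec()
    rows = _exposure_rows(panel)
    dropout = rows["dropout"] if "dropout" in rows else rows["censored"]
    y = dropout.astype(float)
    if y.sum() == 0:
        warnings.warn("no censoring events; all IPCW set to 1", stacklevel=2)
        return None

    def _fit(X: pd.DataFrame) -> PooledLogisticModel:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        return PooledLogisticModel(columns=list(X.columns), params=res.params)

    num = _fit(_weight_design(rows, denominator=False, censoring=True, spec=spec))
    den = _fit(_weight_design(rows, denominator=True, censoring=True, spec=spec))
    return num, den


def compute_ipcw(
    panel: pd.DataFrame,
    models: Optional[tuple[PooledLogisticModel, PooledLogisticModel]],
    spec: Optional[WeightModelSpec] = None,
) -> pd.DataFrame:
    """Stabilized IPCW contributions and running products (1 at interval 0)."""
    spec = spec or WeightModelSpec()
    out = panel[["patient_id", "interval"]].copy()
    out["ipcw_contrib"] = 1.0
    if models is not None:
        rows = _exposure_rows(panel)
        num_model, den_model = models
        Xn = _weight_design(rows, denominator=False, censoring=True, spec=spec)
        Xd = _weight_design(rows, denominator=True, censoring=True, spec=spec)
        out.loc[rows.index, "ipcw_contrib"] = (
            num_model.prob_uncensored(Xn) / den_model.prob_uncensored(Xd)
        )
    out = out.sort_values(["patient_id", "interval"])
    out["ipcw_cum"] = out.groupby("patient_id")["ipcw_contrib"].cumprod()
    return out.sort_index()


def truncate_and_combine(
    iptw: Sequence[float],
    ipcw: Sequence[float],
    percentiles: tuple[float, float] = (0.01, 0.99),
) -> pd.DataFrame:
    """Winsorize each weight stream at its own percentiles, then multiply.

    Percentiles are computed over all rows pooled (linear interpolation);
    truncation is applied to IPTW and IPCW separately before taking the
    row-wise product.
    """
    low, high = percentiles
    iptw = np.asarray(iptw, dtype=float)
    ipcw = np.asarray(ipcw, dtype=float)
    out = pd.DataFrame({"iptw": iptw, "ipcw": ipcw})
    for col in ("iptw", "ipcw"):
        lo, hi = np.percentile(out[col], [100 * low, 100 * high])
        out[f"{col}_trunc"] = out[col].clip(lo, hi)
    out["weight"] = out["iptw_trunc"] * out["ipcw_trunc"]
    return out


def fit_msm(
    panel: pd.DataFrame,
    weights: Sequence[float],
    adjust_baseline: bool = True,
) -> CoxResults:
    """Weighted Cox fit of the current-interval MOS/10 on counting-process rows.

    Patient-clustered sandwich standard errors; with all weights 1 this is
    identical to the unweighted fit on the same rows.
    """
    df = baseline_design(panel)
    df["mos10"] = panel["mos"].astype(float) / 10.0
    df["patient_id"] = panel["patient_id"]
    df["start"] = panel["start"].astype(float)
    df["stop"] = panel["stop"].astype(float)
    df["event"] = panel["event"].astype(bool)
    df["_w"] = np.asarray(weights, dtype=float)
    if (df["_w"] <= 0).any():
        raise ValueError("weights must be > 0")
    covs = ["mos10"]
    if adjust_baseline:
        covs += [c for c in BASELINE_COVARIATES if df[c].nunique() > 1]
    return fit_cox(
        df, "stop", "event", covs, entry_col="start",
        weights_col="_w", cluster_col="patient_id",
    )


@dataclass
class MSMResults:
    """MSM fit plus the full weight audit trail."""

    results: CoxResults
    weights: pd.DataFrame  # WeightRow audit: contributions, cumulatives, final
    spec: WeightModelSpec
    exposure_models: tuple[DensityModel, DensityModel]
    censoring_models: Optional[tuple[PooledLogisticModel, PooledLogisticModel]]

    @property
    def hr_mos10(self) -> float:
        return float(self.results.hr["mos10"])

    @property
    def ci_mos10(self) -> tuple[float, float]:
        return (float(self.results.ci_lower["mos10"]), float(self.results.ci_upper["mos10"]))

    def summary(self) -> pd.DataFrame:
        return self.results.summary()


class MarginalStructuralCox:
    """Marginal structural Cox model for the time-varying MOS exposure.

    Built from an analysis panel (one row per patient-interval with columns
    patient_id, interval, start, stop, mos, mos_prev, hfpsi_lag1,
    cci_category, event, dropout/censored, baseline covariates and
    distance_km). ``fit()`` estimates the weights and the weighted outcome
    model and returns :class:`MSMResults`.
    """

    def __init__(
        self,
        panel: pd.DataFrame,
        spec: Optional[WeightModelSpec] = None,
        adjust_baseline: bool = True,
    ):
        self.panel = panel.sort_values(["patient_id", "interval"]).reset_index(drop=True)
        if "mos_baseline" not in self.panel:
            self.panel["mos_baseline"] = self.panel.groupby("patient_id")["mos"].transform("first")
        self.spec = spec or WeightModelSpec()
        self.adjust_baseline = adjust_baseline

    def fit(self) -> MSMResults:
        exposure_models = fit_exposure_density_models(self.panel, self.spec)
        iptw = compute_iptw(self.panel, exposure_models, self.spec)
        censoring_models = fit_censoring_models(self.panel, self.spec)
        ipcw = compute_ipcw(self.panel, censoring_models, self.spec)
        combined = truncate_and_combine(
            iptw["iptw_cum"], ipcw["ipcw_cum"], self.spec.truncation
        )
        audit = pd.concat(
            [iptw, ipcw[["ipcw_contrib", "ipcw_cum"]],
             combined[["iptw_trunc", "ipcw_trunc", "weight"]]],
            axis=1,
        )
        results = fit_msm(self.panel, audit["weight"], self.adjust_baseline)
        return MSMResults(
            results=results,
            weights=audit,
            spec=self.spec,
            exposure_models=exposure_models,
            censoring_models=censoring_models,
        )
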