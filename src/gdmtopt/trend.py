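"""Longitudinal MOS trend: linear mixed-effects model with random slopes.

Models the per-patient per-interval mean MOS as a linear function of time
since baseline (in 6-month interval units) with a bivariate-normal random
intercept and slope per patient:

    MOS_ij = b0 + b1 * t_ij + u0_i + u1_i * t_ij + e_ij

REML is used for reported estimates; the contribution of the random slope is
tested with a likelihood-ratio test between ML refits of the
random-intercept-only and random-slope models, referred to the 50:50 mixture
of chi-square(1) and chi-square(2) because the slope variance sits on the
boundary of its parameter space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

__all__ = ["LmmFit", "MosTrendModel", "TrendResults", "fit_lmm", "lrt_random_slope",
           "interval_summary"]

_Z = 1.959963984540054


@dataclass
class LmmFit:
    """Random-slope LMM estimates on the MOS (percentage-point) scale."""

    intercept: float
    intercept_ci: tuple[float, float]
    slope: float  # pp per interval unit
    slope_ci: tuple[float, float]
    random_intercept_sd: float
    random_slope_sd: float
    intercept_slope_corr: float
    resid_sd: float
    log_likelihood: float
    n_patients: int
    n_obs: int
    method: str  # "reml" or "ml"
    converged: bool = True

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.intercept, self.slope, self.random_intercept_sd,
                             self.random_slope_sd, self.intercept_slope_corr, self.resid_sd],
                "ci_lower": [self.intercept_ci[0], self.slope_ci[0]] + [np.nan] * 4,
                "ci_upper": [self.intercept_ci[1], self.slope_ci[1]] + [np.nan] * 4,
            },
            index=["intercept (pp)", "slope (pp/interval)", "random-intercept SD",
                   "random-slope SD", "intercept-slope corr", "residual SD"],
        )


def _prepare(long_df: pd.DataFrame) -> pd.DataFrame:
    df = long_df[["patient_id", "time", "mos"]].dropna().copy()
    counts = df.groupby("patient_id")["time"].nunique()
    if (counts >= 2).sum() == 0:
        raise ValueError("random slope inestimable: no patient has >= 2 distinct time points")
    return df


def fit_lmm(
    long_df: pd.DataFrame,
    random_slope: bool = True,
    reml: bool = True,
) -> LmmFit:
    """Fit the MOS trend LMM on long data (patient_id, time, mos).

    ``time`` is in interval units (one unit = 6 months). A singular
    random-effects covariance triggers a refit with the intercept-slope
    correlation fixed at zero (flagged via ``converged``).
    """
    df = _prepare(long_df)
    exog = sm.add_constant(df[["time"]])
    re_formula = "1 + time" if random_slope else "1"

    def _fit(free_cov: bool):
        model = sm.MixedLM.from_formula(
            "mos ~ time", groups="patient_id",
            re_formula=re_formula if free_cov else "1 + time",
            data=df,
        )
        if not free_cov:
            # diagonal random-effects covariance (correlation fixed at 0)
            from statsmodels.regression.mixed_linear_model import MixedLMParams

            free = MixedLMParams.from_components(
                fe_params=np.ones(2), cov_re=np.eye(2)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return model.fit(reml=reml, free=free, method="lbfgs", maxiter=500)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=reml, method="lbfgs", maxiter=500)

    res = _fit(free_cov=True)
    converged = bool(res.converged)
    cov_re = np.asarray(res.cov_re)

    def _singular(c: np.ndarray) -> bool:
        if c.shape != (2, 2):
            return False
        if c[0, 0] <= 0 or c[1, 1] <= 0:
            return True
        return abs(c[0, 1] / np.sqrt(c[0, 0] * c[1, 1])) > 0.9999

    if random_slope and (not converged or _singular(cov_re)):
        res = _fit(free_cov=False)
        converged = False
        cov_re = np.asarray(res.cov_re)

    scale = float(res.scale)
    if random_slope:
        ri_sd = float(np.sqrt(max(cov_re[0, 0], 0.0)))
        rs_sd = float(np.sqrt(max(cov_re[1, 1], 0.0)))
        corr = float(cov_re[0, 1] / (ri_sd * rs_sd)) if ri_sd > 0 and rs_sd > 0 else 0.0
        corr = float(np.clip(corr, -1.0, 1.0))
    else:
        ri_sd = float(np.sqrt(max(float(cov_re[0, 0]), 0.0)))
        rs_sd, corr = 0.0, 0.0

    params = res.fe_params
    bse = res.bse_fe
    return LmmFit(
        intercept=float(params["Intercept"]),
        intercept_ci=(float(params["Intercept"] - _Z * bse["Intercept"]),
                      float(params["Intercept"] + _Z * bse["Intercept"])),
        slope=float(params["time"]),
        slope_ci=(float(params["time"] - _Z * bse["time"]),
                  float(params["time"] + _Z * bse["time"])),
        random_intercept_sd=ri_sd,
        random_slope_sd=rs_sd,
        intercept_slope_corr=corr,
        resid_sd=float(np.sqrt(scale)),
        log_likelihood=float(res.llf),
        n_patients=int(df["patient_id"].nunique()),
        n_obs=len(df),
        method="reml" if reml else "ml",
        converged=converged,
    )


def lrt_random_slope(
    fit_intercept_only: LmmFit, fit_full: LmmFit
) -> tuple[float, float]:
    """Boundary-corrected likelihood-ratio test for the random slope.

    Both fits must use ML likelihoods and share fixed effects. The statistic
    2 * (ll_full - ll_intercept), floored at 0, is referred to the 50:50
    mixture of chi-square(1) and chi-square(2).
    """
    for fit in (fit_intercept_only, fit_full):
        if fit.method != "ml":
            raise ValueError("likelihood-ratio test requires ML (not REML) fits")
    if fit_full.n_obs != fit_intercept_only.n_obs:
        raise ValueError("fits are not nested: different observation counts")
    stat = 2.0 * (fit_full.log_likelihood - fit_intercept_only.log_likelihood)
    stat = max(stat, 0.0)
    if stat == 0.0:
        return 0.0, 1.0
    p = 0.5 * chi2.sf(stat, 1) + 0.5 * chi2.sf(stat, 2)
    return float(stat), float(p)


def interval_summary(long_df: pd.DataFrame) -> pd.DataFrame:
    """Per-interval MOS distribution: mean, SD, 95% CI, median, IQR."""
    rows = []
    for t, grp in long_df.groupby("time", sort=True):
        values = grp["mos"].dropna()
        mean, sd = float(values.mean()), float(values.std(ddof=1))
        half = _Z * sd / np.sqrt(len(values)) if len(values) > 1 else np.nan
        rows.append({
            "time": t, "n": len(values), "mean": mean, "sd": sd,
            "ci_lower": mean - half, "ci_upper": mean + half,
            "median": float(values.median()),
            "q1": float(values.quantile(0.25)), "q3": float(values.quantile(0.75)),
        })
    return pd.DataFrame(rows)


@dataclass
class TrendResults:
    """REML estimates plus the ML-based random-slope LRT."""

    fit: LmmFit
    fit_intercept_only_ml: LmmFit
    fit_full_ml: LmmFit
    lrt_statistic: float
    lrt_p: float
    by_interval: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        return self.fit.summary()


class MosTrendModel:
    """Linear mixed model of MOS over time, statsmodels-style surface.

    ``long_df`` is long-format (patient_id, time, mos) with time in 6-month
    interval units; patients with baseline MOS = 100 are expected to be
    excluded upstream.
    """

    def __init__(self, long_df: pd.DataFrame):
        self.long_df = _prepare(long_df)

    def fit(self) -> TrendResults:
        reml_fit = fit_lmm(self.long_df, random_slope=True, reml=True)
        ml_intercept = fit_lmm(self.long_df, random_slope=False, reml=False)
        ml_full = fit_lmm(self.long_df, random_slope=True, reml=False)
        stat, p = lrt_random_slope(ml_intercept, ml_full)
        return TrendResults(
            fit=reml_fit,
            fit_intercept_only_ml=ml_intercept,
            fit_full_ml=ml_full,
            lrt_statistic=stat,
            lrt_p=p,
            by_interval=interval_summary(self.long_df),
        )
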