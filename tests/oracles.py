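"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: the Cox partial
likelihood is evaluated directly (Efron tie correction) and maximized by grid
search; the product-limit estimator is computed by hand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def efron_partial_loglik(beta: float, df: pd.DataFrame,
                         tcol: str = "t", ecol: str = "e", xcol: str = "x") -> float:
    """Cox partial log-likelihood with Efron tie handling, one covariate."""
    t = df[tcol].to_numpy(dtype=float)
    e = df[ecol].to_numpy(dtype=bool)
    x = df[xcol].to_numpy(dtype=float)
    theta = np.exp(beta * x)
    ll = 0.0
    for ut in np.unique(t[e]):
        dead = (t == ut) & e
        at_risk = t >= ut
        m = int(dead.sum())
        sum_risk = theta[at_risk].sum()
        sum_dead = theta[dead].sum()
        ll += beta * x[dead].sum()
        for l in range(m):
            ll -= np.log(sum_risk - (l / m) * sum_dead)
    return float(ll)


def grid_search_cox(df: pd.DataFrame, lo: float = -4.0, hi: float = 4.0) -> float:
    """Maximize the one-covariate Efron partial likelihood by nested grids."""
    grid = np.linspace(lo, hi, 8001)
    values = [efron_partial_loglik(b, df) for b in grid]
    best = float(grid[int(np.argmax(values))])
    fine = np.linspace(best - 0.01, best + 0.01, 2001)
    values = [efron_partial_loglik(b, df) for b in fine]
    return float(fine[int(np.argmax(values))])


def product_limit(times, events) -> dict[float, float]:
    """Hand Kaplan-Meier: survival value after each distinct event time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    surv = 1.0
    out = {}
    for ut in sorted(np.unique(times[events])):
        n_risk = int((times >= ut).sum())
        n_events = int(((times == ut) & events).sum())
        surv *= 1.0 - n_events / n_risk
        out[float(ut)] = surv
    return out


def logrank_observed_minus_expected(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank: (O-E for group 1, variance) summed over event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert len(labels) == 2
    o_minus_e, var = 0.0, 0.0
    for ut in sorted(np.unique(times[events])):
        at_risk = times >= ut
        n = int(at_risk.sum())
        n1 = int((at_risk & (groups == labels[0])).sum())
        d = int(((times == ut) & events).sum())
        d1 = int(((times == ut) & events & (groups == labels[0])).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e, var
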