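"""Observed-vs-predicted goodness-of-fit statistics for crop-model testing.

Given paired observed values ``O_i`` and predictions ``E_i``:

    RMSE_a = sqrt( sum (O_i - E_i)^2 / n )                      [Mg ha^-1]
    RMSE_n = RMSE_a * 100 / mean(O)                             [%]
    MAE    = mean |E_i - O_i|                                   [Mg ha^-1]
    WI     = 1 - sum (E_i - O_i)^2
               / sum (|E_i - mean(O)| + |O_i - mean(O)|)^2      [0..1]

RMSE_a is ideally at or below the SD of the observations and RMSE_n at or
below their CV. Willmott's index WI compares the squared error to the
potential error around the observed mean; 1 is a perfect fit. MAE is a
magnitude, so the signed mean bias ``mean(E - O)`` is reported separately
to recover the direction of model error. A linear regression of predicted
on observed (slope alpha, intercept beta, r^2) and Welch's unequal-variance
t-test of the two means complete the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError
from .panel import PairedSeries


@dataclass(frozen=True)
class EvalReport:
    n: int
    mean_obs: float
    mean_pred: float
    sd_obs: float
    cv_obs: float        # %
    bias: float          # mean(E - O), Mg ha^-1; positive = overestimation
    mae: float           # Mg ha^-1
    rmse_a: float        # Mg ha^-1
    rmse_n: float        # %; NaN when mean_obs == 0
    wi: float            # Willmott's index, 0..1
    slope: float         # regression of predicted on observed; NaN if undefined
    intercept: float
    r2: float
    t_welch: float
    df_welch: float
    p_welch: float


def evaluate_pairs(pairs: PairedSeries) -> EvalReport:
    """Compute the full evaluation report for one observed/predicted pairing.

    Requires n >= 3. If the observations have zero variance the regression
    block is returned as NaN but the error statistics are still valid; if
    the observed mean is zero, RMSE_n is NaN.
    """
    if pairs.n < 3:
        raise DomainError(f"need >=3 pairs, got {pairs.n}")
    o = pairs.observed
    e = pairs.predicted
    n = pairs.n
    o_bar = float(o.mean())
    err = e - o
    rmse_a = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    pot = (np.abs(e - o_bar) + np.abs(o - o_bar)) ** 2
    wi = 1.0 - float(np.sum(err ** 2) / np.sum(pot)) if pot.sum() > 0 else 1.0
    sd_obs = float(np.std(o, ddof=1))
    if np.ptp(o) > 0:
        reg = stats.linregress(o, e)
        slope, intercept, r2 = float(reg.slope), float(reg.intercept), float(reg.rvalue ** 2)
    else:
        slope = intercept = r2 = float("nan")
    t, df, p = welch_t(pairs)
    return EvalReport(
        n=n,
        mean_obs=o_bar,
        mean_pred=float(e.mean()),
        sd_obs=sd_obs,
        cv_obs=100.0 * sd_obs / o_bar if o_bar != 0 else float("nan"),
        bias=float(err.mean()),
        mae=mae,
        rmse_a=rmse_a,
        rmse_n=100.0 * rmse_a / o_bar if o_bar != 0 else float("nan"),
        wi=wi,
        slope=slope,
        intercept=intercept,
        r2=r2,
        t_welch=t,
        df_welch=df,
        p_welch=p,
    )


def welch_t(pairs: PairedSeries, paired: bool = False) -> tuple[float, float, float]:
    """Two-sided t-test between observed and predicted means.

    The default is Welch's unpaired test assuming unequal variances, with
    Welch-Satterthwaite degrees of freedom; ``paired=True`` switches to the
    paired-differences t-test. When both sides are constant and equal,
    (0, n-1, 1) is returned by convention.
    """
    o, e = pairs.observed, pairs.predicted
    if np.ptp(o) == 0 and np.ptp(e) == 0:
        if o[0] == e[0]:
            return 0.0, float(len(o) - 1), 1.0
        return float("inf"), float(len(o) - 1), 0.0
    if paired:
        res = stats.ttest_rel(e, o)
        df = float(len(o) - 1)
    else:
        res = stats.ttest_ind(e, o, equal_var=False)
        vo, ve = o.var(ddof=1), e.var(ddof=1)
        no = ne = len(o)
        df = (vo / no + ve / ne) ** 2 / (
            (vo / no) ** 2 / (no - 1) + (ve / ne) ** 2 / (ne - 1)
        )
    return float(res.statistic), float(df), float(res.pvalue)
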