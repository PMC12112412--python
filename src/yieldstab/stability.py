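"""Temporal yield-stability measures for multi-year treatment series.

Three complementary measures are implemented, all operating on a
treatment-by-environment matrix of mean yields:

* the **adjusted coefficient of variation** (aCV), a CV corrected for the
  systematic mean-variance relationship (Taylor's power law
  ``log10(sigma^2) = a + b log10(mean)``) so that stability comparisons are
  not confounded by yield level; high aCV means low stability;
* the **sustainable yield index** ``SYI = (mean - SD) / Y_max``, bounded
  above by 1, with values near 1 indicating sustainable management;
* the **Finlay-Wilkinson regression** of treatment yield on the environment
  mean yield ``omega_j``; slopes near 0 indicate responses insensitive to
  environmental variation, slopes above 1 amplify it.

The aCV of treatment *i* is

    aCV_i = (100 / mean_i) * sqrt(10 ** (v_i + (2 - b) * (m_i - m_bar)))

with ``m_i = log10(mean_i)``, ``v_i = log10(variance_i)``, ``m_bar`` the
average of the ``m_i`` entering the Taylor fit, and ``b`` the Taylor slope.
At ``b = 2`` (variance proportional to mean squared, i.e. constant CV) the
adjustment vanishes and aCV equals the plain CV; the same happens for any
treatment sitting exactly at the group mean log-yield.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, SingularDesignError, StabilityUndefinedError
from .panel import YieldPanel, pivot_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TreatmentSummary:
    """Interannual moments of one treatment: the operands of aCV and SYI."""

    treatment_id: str
    n: int
    mean: float  # Mg ha^-1
    sd: float    # sample (n-1) standard deviation, Mg ha^-1

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DomainError(f"{self.treatment_id}: need >=2 environments, got {self.n}")
        if not (self.mean > 0 and math.isfinite(self.mean)):
            raise DomainError(f"{self.treatment_id}: mean must be positive, got {self.mean}")
        if self.sd < 0 or not math.isfinite(self.sd):
            raise DomainError(f"{self.treatment_id}: sd must be non-negative and finite")

    @property
    def variance(self) -> float:
        return self.sd ** 2

    @property
    def cv(self) -> float:
        """Plain coefficient of variation, %."""
        return 100.0 * self.sd / self.mean

    @property
    def m(self) -> float:
        """log10 of the mean yield."""
        return math.log10(self.mean)

    @property
    def v(self) -> float:
        """log10 of the interannual yield variance; undefined at zero variance."""
        if self.sd == 0:
            raise StabilityUndefinedError(
                f"{self.treatment_id}: zero interannual variance, log-variance undefined"
            )
        return math.log10(self.variance)


@dataclass(frozen=True)
class TaylorFit:
    """OLS fit of log10(variance) on log10(mean) across treatments."""

    a: float        # intercept
    b: float        # slope, the Taylor power-law exponent
    r2: float
    m_bar: float    # mean of the log10 treatment means in the fit group
    group: tuple[str, ...]


@dataclass(frozen=True)
class FWFit:
    """Finlay-Wilkinson regression results for one treatment group."""

    environment_means: pd.Series          # omega_j, indexed by environment
    coefficients: pd.DataFrame            # index treatment_id; slope, intercept, resid_sd, n_env


@dataclass
class StabilityConfig:
    """Policy knobs for :func:`stability_table`.

    y_max
        Explicit maximum yield per source for the SYI denominator; when
        None, the maximum cell of each source's treatment-by-environment
        matrix is used (per-source maxima, so observed SYI is scaled by the
        observed maximum and predicted SYI by the predicted one).
    zero_variance
        "raise" (default) or "skip" treatments with no interannual variance.
    """

    y_max: dict[str, float] | None = None
    zero_variance: str = "raise"
    variable: str = "grain_yield"
    sources: tuple[str, ...] = ("observed", "predicted")
    factors: tuple[str, ...] = field(default_factory=tuple)


def summarize(matrix: pd.DataFrame, zero_variance: str = "raise") -> list[TreatmentSummary]:
    """Per-treatment interannual moments from a treatment x environment matrix.

    Uses the sample (n-1) standard deviation. Treatments with fewer than two
    non-missing environments or a non-positive mean raise ``DomainError``;
    zero-variance treatments raise ``StabilityUndefinedError`` unless
    ``zero_variance="skip"``, in which case they are dropped with a warning.
    """
    out: list[TreatmentSummary] = []
    for tid, row in matrix.iterrows():
        vals = row.dropna().to_numpy(float)
        summary = TreatmentSummary(
            treatment_id=str(tid),
            n=len(vals),
            mean=float(np.mean(vals)) if len(vals) else float("nan"),
            sd=float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan"),
        )
        if summary.sd == 0:
            if zero_variance == "skip":
                logger.warning("treatment %r has zero variance; excluded from stability summaries", tid)
                continue
            raise StabilityUndefinedError(
                f"{tid}: zero interannual variance, log-variance stability undefined"
            )
        out.append(summary)
    return out


def fit_taylor(summaries: list[TreatmentSummary]) -> TaylorFit:
    """Fit Taylor's power law across treatment summaries by ordinary least squares.

    Regresses ``v_i = log10(variance_i)`` on ``m_i = log10(mean_i)``.
    Requires at least three treatments with distinct log-means.
    """
    usable = [s for s in summaries if s.sd > 0]
    if len(usable) < len(summaries):
        logger.warning("excluded %d zero-variance treatment(s) from the Taylor fit",
                       len(summaries) - len(usable))
    summaries = usable
    if len(summaries) < 3:
        raise DomainError(f"Taylor fit needs >=3 treatments, got {len(summaries)}")
    m = np.array([s.m for s in summaries])
    v = np.array([s.v for s in summaries])
    if np.ptp(m) == 0:
        raise SingularDesignError("all treatment log-means identical; Taylor slope undefined")
    res = stats.linregress(m, v)
    return TaylorFit(
        a=float(res.intercept),
        b=float(res.slope),
        r2=float(res.rvalue ** 2),
        m_bar=float(m.mean()),
        group=tuple(s.treatment_id for s in summaries),
    )


def adjusted_cv(
    summaries: list[TreatmentSummary],
    fit: TaylorFit,
    strict: bool = False,
) -> pd.Series:
    """Adjusted CV (%) per treatment given a Taylor power-law fit.

    With ``strict=True``, every summary must belong to the fit group (the
    grouping used to estimate ``b`` and ``m_bar``).
    """
    vals = {}
    for s in summaries:
        if strict and s.treatment_id not in fit.group:
            raise DomainError(f"{s.treatment_id} not in the Taylor fit group")
        exponent = s.v + (2.0 - fit.b) * (s.m - fit.m_bar)
        vals[s.treatment_id] = 100.0 / s.mean * math.sqrt(10.0 ** exponent)
    return pd.Series(vals, name="acv")


def sustainable_yield_index(summary: TreatmentSummary, y_max: float) -> float:
    """SYI = (mean - SD) / Y_max, where Y_max is the maximum yield over all
    years and treatments of the series the summary belongs to."""
    if not y_max > 0:
        raise DomainError(f"y_max must be positive, got {y_max}")
    return (summary.mean - summary.sd) / y_max


def finlay_wilkinson(matrix: pd.DataFrame, min_environments: int = 3) -> FWFit:
    """Finlay-Wilkinson regression of each treatment on the environment mean.

    The environment index ``omega_j`` is the column mean over all treatments
    present in environment *j*. Each treatment is then regressed on
    ``omega_j`` by unweighted OLS over its non-missing environments; on a
    complete matrix the slopes average exactly 1.

    Treatments with fewer than ``min_environments`` non-missing environments
    are skipped with a warning.
    """
    if matrix.shape[1] < 3:
        raise DomainError(f"need >=3 environments, got {matrix.shape[1]}")
    omega = matrix.mean(axis=0)
    rows = {}
    for tid, row in matrix.iterrows():
        mask = row.notna().to_numpy()
        if mask.sum() < min_environments:
            logger.warning("treatment %r has <%d environments; F-W fit skipped", tid, min_environments)
            continue
        x = omega.to_numpy(float)[mask]
        y = row.to_numpy(float)[mask]
        if np.ptp(x) == 0:
            raise SingularDesignError("environment means are constant; F-W slope undefined")
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        resid_sd = float(np.std(resid, ddof=2)) if len(y) > 2 else 0.0
        rows[tid] = {"slope": float(slope), "intercept": float(intercept),
                     "resid_sd": resid_sd, "n_env": int(mask.sum())}
    coef = pd.DataFrame.from_dict(rows, orient="index").rename_axis("treatment_id")
    return FWFit(environment_means=omega, coefficients=coef)


def stability_table(panel: YieldPanel, config: StabilityConfig | None = None) -> pd.DataFrame:
    """All stability measures for every treatment of every source in a panel.

    For each source the panel is pivoted to a treatment x environment
    matrix; the Taylor regression is fitted within that (dataset, source)
    group (pooling all treatment levels of the crop); the SYI denominator is
    the per-source maximum yearly yield unless supplied explicitly.

    Returns one row per (dataset_id, source, treatment_id) with columns
    ``n, mean, sd, cv, acv, syi, fw_slope, fw_intercept``, deterministically
    ordered.
    """
    config = config or StabilityConfig()
    frames = []
    for dataset_id in panel.dataset_ids:
        sub = panel.subset(dataset_id=dataset_id)
        for source in config.sources:
            mat = pivot_matrix(sub, source, variable=config.variable)
            summaries = summarize(mat, zero_variance=config.zero_variance)
            fit = fit_taylor(summaries)
            acv = adjusted_cv(summaries, fit)
            if config.y_max is not None:
                y_max = config.y_max[source]
            else:
                y_max = float(np.nanmax(mat.to_numpy(float)))
            fw = finlay_wilkinson(mat)
            rows = []
            for s in summaries:
                rows.append({
                    "dataset_id": dataset_id,
                    "source": source,
                    "treatment_id": s.treatment_id,
                    "n": s.n,
                    "mean": s.mean,
                    "sd": s.sd,
                    "cv": s.cv,
                    "acv": acv[s.treatment_id],
                    "syi": sustainable_yield_index(s, y_max),
                    "fw_slope": fw.coefficients["slope"].get(s.treatment_id, np.nan),
                    "fw_intercept": fw.coefficients["intercept"].get(s.treatment_id, np.nan),
                })
            frames.append(pd.DataFrame(rows))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["dataset_id", "source", "treatment_id"]).reset_index(drop=True)
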