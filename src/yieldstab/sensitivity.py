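"""Variance-based global sensitivity analysis of a crop-model function.

A model's output variance is decomposed into per-parameter contributions:
the main effect ``S_i = Var{E(f(X)|x_i)} / Var{f(X)}`` (fraction of output
variance removed by learning parameter i alone) and the total effect
``ST_i = 1 - Var{E(f(X)|x_-i)} / Var{f(X)}`` (fraction still in play when
everything *except* i is known). ``ST_i - S_i`` quantifies the parameter's
involvement in interactions.

Designs are built on the LP-tau (Sobol') low-discrepancy sequence. Indices
are estimated by the Saltelli A/B/AB-matrix Monte-Carlo scheme with the
Jansen estimator for total effects:

    S_i  = mean( f(B) * (f(AB_i) - f(A)) ) / V
    ST_i = mean( (f(A) - f(AB_i))^2 ) / (2 V)

where AB_i is A with column i replaced from B and V the output variance
over the pooled A and B runs. Negative estimates are reported as-is (they
are Monte-Carlo noise around small true values); the documented tolerance
is ~0.02 at a base sample of 8192.

Model functions follow one call contract: ``model(params: dict, context)
-> dict of named outputs or None``, where None marks a failed run (crop
failure / maturity not reached). Failed runs are discarded as whole design
row-blocks so the estimator matrices stay paired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .errors import CapabilityError, DomainError, FailureRateError, RangeError


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter with its admissible range in native units."""

    name: str
    min: float
    max: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise RangeError(f"parameter {self.name!r}: min ({self.min}) must be < max ({self.max})")


@dataclass(frozen=True)
class SensitivityDesign:
    """An n x k parameter design in unit-cube and native-unit coordinates."""

    specs: tuple[ParameterSpec, ...]
    unit_points: np.ndarray
    method: str = "lp-tau"

    @property
    def scaled_points(self) -> np.ndarray:
        lo = np.array([s.min for s in self.specs])
        hi = np.array([s.max for s in self.specs])
        return lo + self.unit_points * (hi - lo)

    @property
    def n(self) -> int:
        return self.unit_points.shape[0]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scaled_points, columns=[s.name for s in self.specs])


@dataclass(frozen=True)
class FailureReport:
    n_total: int
    n_discarded: int

    @property
    def fraction(self) -> float:
        return self.n_discarded / self.n_total if self.n_total else 0.0


@dataclass
class SensitivityResult:
    """Tidy per-context (year), per-output, per-parameter index table.

    ``indices`` has columns context, output, parameter, s, st;
    ``runs`` has one row per (context, output) with the total output
    variance and effective/discarded run-block counts.
    """

    indices: pd.DataFrame
    runs: pd.DataFrame
    n_base: int
    parameters: tuple[str, ...] = field(default_factory=tuple)


def lp_tau_design(specs: Sequence[ParameterSpec], n: int, skip: int = 1) -> SensitivityDesign:
    """Generate an n-point LP-tau (Sobol') design over the parameter ranges.

    The sequence is unscrambled and skips the degenerate all-zero first
    point by default, so the first design point is the unit-cube midpoint.
    Deterministic for fixed (specs, n, skip).
    """
    k = len(specs)
    if n < 1 or k < 1:
        raise DomainError("need n >= 1 points and k >= 1 parameters")
    if k > 21201:
        raise CapabilityError(f"Sobol' direction numbers available up to 21201 dimensions, got {k}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        engine = qmc.Sobol(d=k, scramble=False)
        if skip:
            engine.fast_forward(skip)
        pts = engine.random(n)
    return SensitivityDesign(specs=tuple(specs), unit_points=pts)


def discard_failed(outputs: np.ndarray) -> tuple[np.ndarray, np.ndarray, FailureReport]:
    """Drop design row-blocks containing any failed (NaN) run.

    ``outputs`` is an (n_blocks, n_runs_per_block) array of one output
    variable, one row per base design point (its A, B and all AB_i runs).
    Returns the kept rows, the boolean keep-mask, and a failure report.
    Aborts when more than half of the blocks failed, since the surviving
    sample is then too distorted for reliable indices.
    """
    outputs = np.asarray(outputs, dtype=float)
    keep = ~np.isnan(outputs).any(axis=1)
    report = FailureReport(n_total=outputs.shape[0], n_discarded=int((~keep).sum()))
    if report.fraction > 0.5:
        raise FailureRateError(
            f"{report.n_discarded}/{report.n_total} design blocks failed; estimates unreliable"
        )
    return outputs[keep], keep, report


def saltelli_indices(
    model: Callable[[Mapping[str, float], object], Mapping[str, float] | None],
    specs: Sequence[ParameterSpec],
    n_base: int = 1024,
    seed: int | None = None,
    contexts: Sequence[object] = (None,),
    outputs: Sequence[str] | None = None,
) -> SensitivityResult:
    """Estimate S_i and ST_i for every parameter, output and context.

    Parameters
    ----------
    model
        Deterministic function ``model(params, context)`` returning a dict
        of named outputs, or None for a failed run.
    n_base
        Base sample size N; the model is evaluated N * (k + 2) times per
        context. Must be >= 64.
    seed
        Seeds the scrambled Sobol' generator used for the A and B matrices.
    contexts
        Sequence of opaque context labels (e.g. simulation years) passed
        through to the model; one index set is estimated per context.
    """
    if n_base < 64:
        raise DomainError(f"n_base must be >= 64, got {n_base}")
    k = len(specs)
    names = [s.name for s in specs]
    rng_seed = seed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        ab = qmc.Sobol(d=2 * k, scramble=True, rng=rng_seed).random(n_base)
    lo = np.array([s.min for s in specs])
    hi = np.array([s.max for s in specs])
    A = lo + ab[:, :k] * (hi - lo)
    B = lo + ab[:, k:] * (hi - lo)

    # all runs for one base point live in one row-block: A, B, AB_1..AB_k
    blocks = np.empty((n_base, k + 2, k))
    blocks[:, 0, :] = A
    blocks[:, 1, :] = B
    for i in range(k):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        blocks[:, 2 + i, :] = ABi

    idx_rows, run_rows = [], []
    for context in contexts:
        out_names = list(outputs) if outputs else None
        raw = np.empty((n_base, k + 2), dtype=object)
        for j in range(n_base):
            for c in range(k + 2):
                raw[j, c] = model(dict(zip(names, blocks[j, c])), context)
                if out_names is None and raw[j, c] is not None:
                    out_names = list(raw[j, c].keys())
        if out_names is None:
            raise FailureRateError("every model run failed")
        for out in out_names:
            vals = np.full((n_base, k + 2), np.nan)
            for j in range(n_base):
                for c in range(k + 2):
                    if raw[j, c] is not None:
                        vals[j, c] = raw[j, c][out]
            kept, _, report = discard_failed(vals)
            f_A, f_B, f_AB = kept[:, 0], kept[:, 1], kept[:, 2:]
            pooled = np.concatenate([f_A, f_B])
            V = float(pooled.var())
            if V == 0:
                raise DomainError(f"output {out!r} has zero variance over the design")
            for i, name in enumerate(names):
                s_i = float(np.mean(f_B * (f_AB[:, i] - f_A)) / V)
                st_i = float(np.mean((f_A - f_AB[:, i]) ** 2) / (2.0 * V))
                idx_rows.append({"context": context, "output": out, "parameter": name,
                                 "s": s_i, "st": st_i})
            run_rows.append({"context": context, "output": out, "variance": V,
                             "n_effective": kept.shape[0], "n_discarded": report.n_discarded})
    return SensitivityResult(
        indices=pd.DataFrame(idx_rows),
        runs=pd.DataFrame(run_rows),
        n_base=n_base,
        parameters=tuple(names),
    )


def summarize_indices(result: SensitivityResult) -> pd.DataFrame:
    """Tukey boxplot statistics of each index across contexts (years).

    For every (output, parameter, index) the median, quartiles, 1.5*IQR
    whiskers (clamped to the data range) and outlier count are returned —
    the numbers behind a per-parameter box-and-whisker summary of
    year-to-year index variation. Requires at least two contexts.
    """
    idx = result.indices
    if idx["context"].nunique() < 2:
        raise DomainError("need indices from >=2 contexts to summarise")
    long = idx.melt(id_vars=["context", "output", "parameter"],
                    value_vars=["s", "st"], var_name="index", value_name="value")
    rows = []
    for (out, par, which), grp in long.groupby(["output", "parameter", "index"], sort=True):
        v = grp["value"].to_numpy(float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        rows.append({"output": out, "parameter": par, "index": which,
                     "median": med, "q1": q1, "q3": q3,
                     "whisker_lo": inside.min(), "whisker_hi": inside.max(),
                     "n_outliers": int(((v < lo_fence) | (v > hi_fence)).sum())})
    return pd.DataFrame(rows)
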