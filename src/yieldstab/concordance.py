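"""Agreement between trial-based and model-based stability measures.

Lin's concordance correlation coefficient (CCC) measures agreement with the
identity line and decomposes as ``CCC = r * Cb``, where r is the Pearson
correlation (precision) and Cb in (0, 1] the bias-correction factor
(accuracy; 1 means no location or scale shift). Following Lin's original
definition, all moments are population (1/n) estimators:

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2)

Note Cb is computed with the *signed* r, so it stays in (0, 1] even when
the correlation is negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConcordanceUndefinedError, DomainError

#: stability measures that stability_agreement knows how to pair up
MEASURES = ("acv", "syi", "fw_slope")


@dataclass(frozen=True)
class ConcordanceResult:
    n: int
    r: float      # signed Pearson correlation
    ccc: float    # Lin's concordance correlation coefficient
    cb: float     # bias-correction factor = ccc / r (signed r)

    @property
    def r_abs(self) -> float:
        return abs(self.r)


def lin_ccc(x, y) -> ConcordanceResult:
    """Lin's concordance correlation between two measure vectors.

    Requires equal lengths n >= 3, finite values, and non-zero variance on
    both sides.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise DomainError(f"need n >= 3 pairs, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DomainError("non-finite values in concordance input")
    sx2 = float(x.var())   # population (1/n) moments, per Lin
    sy2 = float(y.var())
    if sx2 == 0 or sy2 == 0:
        raise ConcordanceUndefinedError("zero variance in a concordance input vector")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    r = sxy / np.sqrt(sx2 * sy2)
    ccc = 2.0 * sxy / (sx2 + sy2 + (float(x.mean()) - float(y.mean())) ** 2)
    return ConcordanceResult(n=len(x), r=r, ccc=ccc, cb=ccc / r if r != 0 else float("nan"))


def stability_agreement(
    obs: pd.DataFrame,
    pred: pd.DataFrame,
    groupby: list[str] | None = None,
    measures: tuple[str, ...] = MEASURES,
    min_n: int = 3,
) -> pd.DataFrame:
    """Concordance between observed- and predicted-based stability tables.

    ``obs`` and ``pred`` are stability tables indexed (or keyed) by
    ``treatment_id`` with one column per measure; the same treatments must
    appear in both. One :class:`ConcordanceResult` row is produced per
    measure for the pooled "All" group and, when ``groupby`` columns are
    given (factor columns present in ``obs``), per factor level. Groups
    smaller than ``min_n`` are skipped with a ``skipped`` flag.

    Returns a table with columns group, measure, n, r, r_abs, ccc, cb,
    skipped.
    """
    obs = obs.set_index("treatment_id") if "treatment_id" in obs.columns else obs
    pred = pred.set_index("treatment_id") if "treatment_id" in pred.columns else pred
    if set(obs.index) != set(pred.index):
        raise AlignmentError("observed and predicted stability tables cover different treatments")
    pred = pred.loc[obs.index]

    groups: list[tuple[str, pd.Index]] = [("All", obs.index)]
    for col in groupby or []:
        for level, sub in obs.groupby(col, sort=True):
            groups.append((f"{col}={level}", sub.index))

    rows = []
    for gname, idx in groups:
        for measure in measures:
            if measure not in obs.columns or measure not in pred.columns:
                continue
            x = obs.loc[idx, measure].to_numpy(float)
            y = pred.loc[idx, measure].to_numpy(float)
            if len(idx) < min_n:
                rows.append({"group": gname, "measure": measure, "n": len(idx),
                             "r": np.nan, "r_abs": np.nan, "ccc": np.nan,
                             "cb": np.nan, "skipped": True})
                continue
            res = lin_ccc(x, y)
            rows.append({"group": gname, "measure": measure, "n": res.n,
                         "r": res.r, "r_abs": res.r_abs, "ccc": res.ccc,
                         "cb": res.cb, "skipped": False})
    return pd.DataFrame(rows)
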