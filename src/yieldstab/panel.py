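"""Yield-panel data model and tabular I/O.

The universal input of the pipeline is a long ("tidy") table of yield records
keyed by ``(dataset_id, source, treatment_id, environment_id, replicate)``,
where *source* distinguishes field observations from crop-model predictions
and *environment* is a year (or a year-by-season compound label for double
cropping systems). All tabular I/O is comma-delimited UTF-8 with a required
header; missing optional values are explicit NA markers, never zeros, because
a zero yield is a valid crop failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, IntegrityError, ParseError, SchemaError

logger = logging.getLogger(__name__)

#: Mandatory columns of a yield-panel file.
MANDATORY_COLUMNS = ("dataset_id", "source", "treatment_id", "environment_id", "grain_yield")
#: Optional columns recognised by the reader.
OPTIONAL_COLUMNS = ("replicate", "biomass")
#: Admissible values of the ``source`` column.
SOURCES = ("observed", "predicted")

KEY_COLUMNS = ["dataset_id", "source", "treatment_id", "environment_id", "replicate"]


@dataclass
class YieldPanel:
    """A validated long-format yield table plus its declared factor schema.

    Parameters
    ----------
    data
        Long table with at least :data:`MANDATORY_COLUMNS`; one row per
        (source, treatment, environment, replicate).
    factors
        Names of free factor columns (e.g. ``n_rate``, ``residue``,
        ``season``) that must be present in ``data``.
    """

    data: pd.DataFrame
    factors: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing mandatory column {col!r}")
        for col in self.factors:
            if col not in df.columns:
                raise SchemaError(f"declared factor column {col!r} absent from table")
        if "replicate" not in df.columns:
            df["replicate"] = pd.NA
        if "biomass" not in df.columns:
            df["biomass"] = np.nan
        for col in KEY_COLUMNS:
            df[col] = df[col].astype("string")
        bad_source = set(df["source"]) - set(SOURCES)
        if bad_source:
            raise SchemaError(f"source must be one of {SOURCES}, got {sorted(bad_source)}")
        for col in ("grain_yield", "biomass"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if col == "grain_yield" and vals.isna().any():
                row = int(df.index[vals.isna()][0])
                raise ParseError(f"non-numeric {col} in row {row}")
            finite = vals.dropna()
            if not np.isfinite(finite).all() or (finite < 0).any():
                raise IntegrityError(f"{col} must be non-negative and finite")
            df[col] = vals
        key = df[KEY_COLUMNS].astype("string").fillna("")
        dup = key.duplicated()
        if dup.any():
            raise IntegrityError(
                "duplicate record key(s): " + repr(key[dup].iloc[0].tolist())
            )
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dataset_ids(self) -> list[str]:
        return sorted(self.data["dataset_id"].unique())

    def subset(self, **conditions) -> "YieldPanel":
        """Return a sub-panel where each named column equals the given value."""
        df = self.data
        for col, val in conditions.items():
            df = df[df[col] == val]
        return YieldPanel(df.reset_index(drop=True), self.factors)

    def environments(self, source: str, treatment_id: str) -> list[str]:
        sub = self.data[(self.data["source"] == source) & (self.data["treatment_id"] == treatment_id)]
        return sorted(sub["environment_id"].unique())


@dataclass(frozen=True)
class PairedSeries:
    """Aligned observed/predicted value pairs for model evaluation.

    ``observed[i]`` and ``predicted[i]`` refer to the same
    (treatment, environment, replicate) key.
    """

    keys: tuple[tuple, ...]
    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        if len(self.observed) != len(self.predicted) or len(self.observed) != len(self.keys):
            raise IntegrityError("observed, predicted and keys must have equal length")
        if len(self.observed) < 2:
            raise IntegrityError("paired series needs n >= 2")

    @property
    def n(self) -> int:
        return len(self.observed)


def read_yield_table(path: str | Path, factors: Sequence[str] = ()) -> YieldPanel:
    """Read a comma-delimited yield panel and validate it.

    Raises
    ------
    SchemaError
        If a mandatory (or declared factor) column is missing.
    ParseError
        If a yield cell is non-numeric.
    IntegrityError
        On duplicate record keys or negative yields.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={c: "string" for c in ("dataset_id", "source", "treatment_id", "environment_id", "replicate")})
    return YieldPanel(df, tuple(factors))


def write_yield_table(panel: YieldPanel, path: str | Path) -> None:
    """Write a panel back to comma-delimited text (round-trips with the reader)."""
    cols = list(MANDATORY_COLUMNS[:4]) + ["replicate", "grain_yield", "biomass"] + list(panel.factors)
    panel.data[cols].to_csv(path, index=False)


def align_observed_predicted(
    panel: YieldPanel,
    dataset_id: str | None = None,
    variable: str = "grain_yield",
) -> PairedSeries:
    """Inner-join observed against predicted records of one dataset.

    Pairs are matched on (treatment_id, environment_id, replicate) and
    returned in sorted key order, so the result is deterministic. Keys present
    on only one side are dropped and reported through the module logger.
    """
    df = panel.data
    if dataset_id is not None:
        df = df[df["dataset_id"] == dataset_id]
    join_key = ["treatment_id", "environment_id", "replicate"]
    sides = {}
    for source in SOURCES:
        side = df[df["source"] == source][join_key + [variable]].copy()
        side["replicate"] = side["replicate"].astype("string").fillna("")
        if side[join_key].duplicated().any():
            raise IntegrityError(f"duplicate (treatment, environment, replicate) key in {source} records")
        sides[source] = side
    merged = sides["observed"].merge(
        sides["predicted"], on=join_key, suffixes=("_obs", "_pred"), how="inner"
    )
    if merged.empty:
        raise AlignmentError("observed and predicted records share no keys")
    n_extra = len(sides["observed"]) + len(sides["predicted"]) - 2 * len(merged)
    if n_extra:
        logger.info("align_observed_predicted: dropped %d unmatched record(s)", n_extra)
    merged = merged.sort_values(join_key).reset_index(drop=True)
    return PairedSeries(
        keys=tuple(map(tuple, merged[join_key].itertuples(index=False, name=None))),
        observed=merged[f"{variable}_obs"].to_numpy(float),
        predicted=merged[f"{variable}_pred"].to_numpy(float),
    )


def pivot_matrix(panel: YieldPanel, source: str, variable: str = "grain_yield") -> pd.DataFrame:
    """Pivot a panel into a treatment-by-environment matrix of mean yields.

    Replicates within a (treatment, environment) cell are averaged
    arithmetically. Treatments missing from more than half of the
    environments trigger a warning; an entirely empty treatment row is an
    error.
    """
    df = panel.data[panel.data["source"] == source]
    if df.empty:
        raise AlignmentError(f"no records with source {source!r}")
    mat = df.pivot_table(index="treatment_id", columns="environment_id", values=variable, aggfunc="mean")
    mat = mat.sort_index(axis=0).sort_index(axis=1)
    n_env = mat.shape[1]
    for tid, row in mat.iterrows():
        n_missing = int(row.isna().sum())
        if n_missing == n_env:
            raise IntegrityError(f"treatment {tid!r} has no records in any environment")
        if n_missing > n_env / 2:
            logger.warning("treatment %r missing from %d of %d environments", tid, n_missing, n_env)
    return mat


def read_parameter_ranges(path: str | Path):
    """Read a parameter-range table (columns name, min, max[, unit]).

    Returns an ordered list of :class:`~yieldstab.sensitivity.ParameterSpec`;
    a row with min >= max raises ``RangeError`` naming the parameter.
    """
    from .sensitivity import ParameterSpec

    df = pd.read_csv(path)
    missing = {"name", "min", "max"} - set(df.columns)
    if missing:
        raise SchemaError(f"parameter-range table missing column(s) {sorted(missing)}")
    specs = []
    for _, row in df.iterrows():
        specs.append(ParameterSpec(
            name=str(row["name"]),
            min=float(row["min"]),
            max=float(row["max"]),
            unit=str(row["unit"]) if "unit" in df.columns and pd.notna(row["unit"]) else "",
        ))
    return specs


def read_weather_table(path: str | Path) -> pd.DataFrame:
    """Read a daily weather table (date, tmin, tmax, rain, radiation).

    Dates are ISO-8601; temperatures in degrees C, rain in mm, radiation in
    MJ m^-2 d^-1. Enforces tmin <= tmax and rain >= 0.
    """
    df = pd.read_csv(path, parse_dates=["date"])
    missing = {"date", "tmin", "tmax", "rain", "radiation"} - set(df.columns)
    if missing:
        raise SchemaError(f"weather table missing column(s) {sorted(missing)}")
    if (df["tmin"] > df["tmax"]).any():
        raise IntegrityError("tmin exceeds tmax on at least one day")
    if (df["rain"] < 0).any():
        raise IntegrityError("negative rainfall")
    return df


def write_weather_table(weather: pd.DataFrame, path: str | Path) -> None:
    out = weather.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
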