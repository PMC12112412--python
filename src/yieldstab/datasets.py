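"""Bundled reference tables for the Sadoré and Ndiaye long-term experiments.

Two kinds of small plain-text tables ship with the package:

* **stability summaries** — published treatment-level summaries (mean and
  SD of grain yield, adjusted CV, sustainable yield index) for observed
  and APSIM-predicted yields: the 12 fertilizer-by-density-by-residue
  pearl-millet treatments at Sadoré, Niger (8 seasons each) and the 8
  N-rate-by-season rice cells at Ndiaye, Senegal (7-8 seasons each);
* **parameter ranges** — the cultivar-parameter bounds explored in the
  sensitivity analyses of the two crop models (7 rice parameters, 19
  pearl-millet parameters).

These are summary statistics, not raw yearly yields; stability measures
recomputed from them agree with the published values only to within the
rounding of the printed means and SDs (about one percentage point on aCV).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .sensitivity import ParameterSpec

_DATASETS = {
    "sadore_millet": "sadore_millet_stability.csv",
    "ndiaye_rice": "ndiaye_rice_stability.csv",
}
_RANGES = {
    "rice": "rice_parameter_ranges.csv",
    "millet": "millet_parameter_ranges.csv",
}


def _data_path(filename: str):
    return resources.files("yieldstab") / "data" / filename


def available_datasets() -> list[str]:
    return sorted(_DATASETS)


def load_stability_summary(name: str) -> pd.DataFrame:
    """Load a bundled stability-summary table by dataset name.

    ``name`` is ``"sadore_millet"`` or ``"ndiaye_rice"``. Columns:
    treatment_id, the dataset's factor columns, n, yield_obs, sd_obs,
    yield_pred, sd_pred, acv_obs, acv_pred, syi_obs, syi_pred.
    """
    if name not in _DATASETS:
        raise KeyError(f"unknown dataset {name!r}; choose from {available_datasets()}")
    with resources.as_file(_data_path(_DATASETS[name])) as path:
        return pd.read_csv(path)


def load_parameter_ranges(crop: str) -> list[ParameterSpec]:
    """Load the bundled sensitivity parameter ranges for ``"rice"`` or ``"millet"``."""
    if crop not in _RANGES:
        raise KeyError(f"unknown crop {crop!r}; choose from {sorted(_RANGES)}")
    from .panel import read_parameter_ranges

    with resources.as_file(_data_path(_RANGES[crop])) as path:
        return read_parameter_ranges(path)


def measure_pairs(summary: pd.DataFrame, measure: str) -> tuple:
    """Observed/predicted column pair for a measure ('acv', 'syi' or 'yield')."""
    return (summary[f"{measure}_obs"].to_numpy(float),
            summary[f"{measure}_pred"].to_numpy(float))
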