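"""Synthetic stand-ins for the long-term experiments and the crop model.

This module generates data with *known* statistical structure so every
stage of the pipeline can be tested against its own construction:

* :func:`generate_lte_panel` builds an observed/predicted yield panel with
  prescribed Finlay-Wilkinson slopes and intercepts, a prescribed Taylor
  power-law mean-variance exponent for the interannual noise, and a
  prediction series that is a shrunk (less variable) version of the
  observed signal — mirroring the empirical pattern that crop-model
  predictions vary less between years than field observations;
* :func:`preset_panel_config` returns configurations whose treatment
  structure and yield levels emulate the Sadoré pearl-millet panel
  (12 treatments x 8 seasons, means ~0.26-0.55 Mg/ha) and the Ndiaye rice
  panel (4 N rates x 2 seasons, means ~1.6-6.6 Mg/ha);
* :func:`toy_crop_model` is a smooth deterministic response surface with
  strong phenology-like main effects, one designed pairwise interaction
  and a documented failure region, standing in for a process-based crop
  model in sensitivity tests;
* :func:`thermal_time` is the Blackman growing-degree-day increment
  ``max(0, T - TBD)`` with an optimum cutoff TOD;
* :func:`generate_weather` draws daily weather series matching the two
  stations' climate envelopes (annual rainfall ~565 mm at Sadoré,
  ~277 mm at Ndiaye).

Every stochastic operation takes an explicit seed; there is no global
random state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, YieldStabError
from .panel import YieldPanel
from .sensitivity import ParameterSpec

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# thermal time


@dataclass(frozen=True)
class ThermalTimeParams:
    """Cardinal temperatures for thermal-time accumulation (degrees C).

    Defaults are the base (15 C) and optimum (34 C) used for the rice
    cultivar Sahel 108.
    """

    tbd: float = 15.0
    tod: float = 34.0
    above_optimum: str = "plateau"  # or "zero"

    def __post_init__(self) -> None:
        if not self.tbd < self.tod:
            raise DomainError(f"base temperature {self.tbd} must be below optimum {self.tod}")
        if self.above_optimum not in ("plateau", "zero"):
            raise DomainError("above_optimum must be 'plateau' or 'zero'")


def thermal_time(t_mean, params: ThermalTimeParams = ThermalTimeParams()):
    """Daily thermal-time increment (degree-days) at mean temperature ``t_mean``.

    Below the optimum the increment is ``max(0, t_mean - tbd)``. The
    behaviour at and above the optimum is configurable: the default
    "plateau" caps the increment at ``tod - tbd`` (linear-with-plateau
    reading of the Blackman response); "zero" switches development off
    entirely above the optimum.
    """
    t = np.asarray(t_mean, dtype=float)
    below = np.maximum(0.0, t - params.tbd)
    if params.above_optimum == "plateau":
        ti = np.minimum(below, params.tod - params.tbd)
    else:
        ti = np.where(t >= params.tod, 0.0, below)
    return float(ti) if np.isscalar(t_mean) else ti


def cumulative_thermal_time(weather: pd.DataFrame, params: ThermalTimeParams = ThermalTimeParams()) -> pd.Series:
    """Accumulated thermal time over a daily weather table (tmin/tmax mean)."""
    t_mean = (weather["tmin"].to_numpy(float) + weather["tmax"].to_numpy(float)) / 2.0
    return pd.Series(np.cumsum(thermal_time(t_mean, params)), index=weather.index, name="gdd")


# ---------------------------------------------------------------------------
# LTE-like yield panels


@dataclass
class SyntheticPanelConfig:
    """Generator settings for an observed/predicted LTE-like yield panel.

    The observed yield of treatment i in environment j is

        y_ij = beta_i + alpha_i * omega_j + eps_ij,
        eps_ij ~ N(0, taylor_c * mean_i ** taylor_b)   (variance)

    with environment indices omega_j ~ N(env_mean, env_sd^2) and
    ``mean_i = beta_i + alpha_i * env_mean`` the treatment's expected
    yield. The predicted series keeps each treatment's expected level but
    shrinks the interannual signal and noise by ``prediction_shrinkage``
    and shifts it by ``prediction_bias``. Negative draws are truncated at
    zero (a valid crop-failure yield) and the truncation rate is logged.
    """

    n_treatments: int
    n_environments: int
    base_means: tuple[float, ...]            # Mg ha^-1, per treatment
    fw_slopes: tuple[float, ...]             # alpha_i
    env_mean: float                          # mean of omega_j, Mg ha^-1
    env_sd: float                            # SD of omega_j, Mg ha^-1
    taylor_b: float = 1.5
    taylor_c: float = 0.05
    prediction_shrinkage: float = 1.0        # in (0, 1]
    prediction_bias: float = 0.0             # Mg ha^-1
    seed: int = 0
    dataset_id: str = "synthetic"
    treatment_ids: tuple[str, ...] | None = None
    factors: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.base_means) != self.n_treatments or len(self.fw_slopes) != self.n_treatments:
            raise DomainError("base_means and fw_slopes must have one entry per treatment")
        if any(m <= 0 for m in self.base_means):
            raise DomainError("treatment base means must be positive")
        if not 0 < self.prediction_shrinkage <= 1:
            raise DomainError("prediction_shrinkage must be in (0, 1]")
        for fname, levels in self.factors.items():
            if len(levels) != self.n_treatments:
                raise DomainError(f"factor {fname!r} must declare one level per treatment")

    @property
    def fw_intercepts(self) -> np.ndarray:
        """beta_i implied by the base means: beta_i = mean_i - alpha_i * env_mean."""
        return np.asarray(self.base_means) - np.asarray(self.fw_slopes) * self.env_mean

    @property
    def noise_sd(self) -> np.ndarray:
        """Interannual noise SD per treatment from the Taylor power law."""
        return np.sqrt(self.taylor_c * np.asarray(self.base_means) ** self.taylor_b)


def generate_lte_panel(config: SyntheticPanelConfig, strict: bool = False) -> YieldPanel:
    """Draw one observed/predicted panel from a :class:`SyntheticPanelConfig`.

    Deterministic for a fixed config (the seed is part of the config).
    With ``strict=True`` a zero-truncation rate above 10% raises instead
    of warning.
    """
    rng = np.random.default_rng(config.seed)
    nt, ne = config.n_treatments, config.n_environments
    tids = config.treatment_ids or tuple(f"T{i + 1:02d}" for i in range(nt))
    eids = tuple(f"E{j + 1:02d}" for j in range(ne))
    alpha = np.asarray(config.fw_slopes, float)
    beta = config.fw_intercepts
    means = np.asarray(config.base_means, float)
    omega = rng.normal(config.env_mean, config.env_sd, size=ne)
    signal = beta[:, None] + alpha[:, None] * omega[None, :]          # (nt, ne)
    sd = config.noise_sd[:, None]
    obs = signal + rng.normal(0.0, 1.0, size=(nt, ne)) * sd
    s = config.prediction_shrinkage
    pred = (config.prediction_bias + means[:, None]
            + s * (signal - means[:, None])
            + rng.normal(0.0, 1.0, size=(nt, ne)) * s * sd)

    n_neg = int((obs < 0).sum() + (pred < 0).sum())
    rate = n_neg / (2 * nt * ne)
    if n_neg:
        msg = f"truncated {n_neg} negative yield draw(s) at 0 ({rate:.1%})"
        if strict and rate > 0.10:
            raise YieldStabError(msg)
        logger.warning(msg)
    obs = np.maximum(obs, 0.0)
    pred = np.maximum(pred, 0.0)

    rows = []
    for source, mat in (("observed", obs), ("predicted", pred)):
        for i, tid in enumerate(tids):
            for j, eid in enumerate(eids):
                row = {"dataset_id": config.dataset_id, "source": source,
                       "treatment_id": tid, "environment_id": eid,
                       "grain_yield": mat[i, j]}
                for fname, levels in config.factors.items():
                    row[fname] = levels[i]
                rows.append(row)
    return YieldPanel(pd.DataFrame(rows), factors=tuple(config.factors))


def preset_panel_config(name: str, seed: int = 0) -> SyntheticPanelConfig:
    """Generator configuration emulating one of the two study panels.

    ``"sadore_millet"``: 12 fertilizer-by-density-by-residue treatments
    over 8 rainfed seasons, yields ~0.26-0.55 Mg/ha. ``"ndiaye_rice"``:
    8 N-rate-by-season cells over 8 years, yields ~1.6-6.6 Mg/ha, with
    predictions about half as variable as observations. The Taylor
    exponent and scale are fitted to the bundled observed (mean, SD)
    summaries, so generated interannual SDs follow the empirical
    mean-variance scaling; Finlay-Wilkinson slopes are proportional to
    yield level (high-input treatments amplify good years).
    """
    from .datasets import load_stability_summary
    from .stability import TreatmentSummary, fit_taylor

    if name not in ("sadore_millet", "ndiaye_rice"):
        raise KeyError(f"unknown preset {name!r}")
    summary = load_stability_summary(name)
    means = summary["yield_obs"].to_numpy(float)
    sds = summary["sd_obs"].to_numpy(float)
    fit = fit_taylor([
        TreatmentSummary(t, int(n), m, s)
        for t, n, m, s in zip(summary["treatment_id"], summary["n"], means, sds)
    ])
    env_mean = float(means.mean())
    factor_cols = [c for c in summary.columns
                   if c not in ("treatment_id", "n", "yield_obs", "sd_obs", "yield_pred",
                                "sd_pred", "acv_obs", "acv_pred", "syi_obs", "syi_pred")]
    if name == "sadore_millet":
        env_sd, shrink, bias = 0.04, 0.9, 0.0
    else:
        env_sd, shrink, bias = 0.40, 0.45, 0.3
    return SyntheticPanelConfig(
        n_treatments=len(means),
        n_environments=8,
        base_means=tuple(means),
        fw_slopes=tuple(means / env_mean),
        env_mean=env_mean,
        env_sd=env_sd,
        taylor_b=fit.b,
        taylor_c=10.0 ** fit.a,
        prediction_shrinkage=shrink,
        prediction_bias=bias,
        seed=seed,
        dataset_id=name,
        treatment_ids=tuple(summary["treatment_id"]),
        factors={c: tuple(summary[c].astype(str)) for c in factor_cols},
    )


# ---------------------------------------------------------------------------
# toy crop-response function


#: Parameter ranges of the toy crop response surface (a subset of typical
#: cereal phenology/growth parameters).
TOY_CROP_SPECS = (
    ParameterSpec("tt_juvenile", 100.0, 500.0, "degC d"),
    ParameterSpec("tt_grainfill", 200.0, 800.0, "degC d"),
    ParameterSpec("rue", 1.3, 2.0, "g MJ-1"),
    ParameterSpec("grain_wt", 19.0, 30.0, "mg"),
)

#: The failure region: combined pre- plus post-flowering thermal time
#: beyond this cap means the crop does not reach maturity and the run is
#: discarded (about 4.7% of the uniform design space).
TOY_FAILURE_TT_SUM = 1150.0


def toy_crop_model(point: Mapping[str, float], context: object = None) -> dict[str, float] | None:
    """Smooth deterministic yield/biomass response used in sensitivity tests.

    Biomass responds mainly to radiation-use efficiency and juvenile-phase
    duration; the harvest index couples grain-filling duration with
    individual grain weight multiplicatively, so ``tt_grainfill`` and
    ``grain_wt`` interact by construction (their total-effect indices
    exceed their main effects detectably). The ``context`` label (e.g. a
    year) perturbs the response coefficients reproducibly. Points whose
    thermal-time total exceeds :data:`TOY_FAILURE_TT_SUM` return None
    (failed run); points outside the declared ranges raise ``DomainError``.
    """
    u = {}
    for spec in TOY_CROP_SPECS:
        x = float(point[spec.name])
        if not spec.min <= x <= spec.max:
            raise DomainError(f"{spec.name}={x} outside [{spec.min}, {spec.max}]")
        u[spec.name] = (x - spec.min) / (spec.max - spec.min)

    if float(point["tt_juvenile"]) + float(point["tt_grainfill"]) > TOY_FAILURE_TT_SUM:
        return None

    # reproducible per-context coefficient perturbation
    ctx_rng = np.random.default_rng(abs(hash(str(context))) % (2 ** 31))
    year_factor = 0.8 + 0.4 * ctx_rng.random()
    hi_shift = 0.05 * (ctx_rng.random() - 0.5)

    biomass = year_factor * float(point["rue"]) * (3.0 + 2.0 * u["tt_juvenile"])  # Mg ha^-1
    harvest_index = 0.25 + hi_shift + 0.30 * u["tt_grainfill"] * u["grain_wt"]
    return {"yield": biomass * harvest_index, "biomass": biomass}


# ---------------------------------------------------------------------------
# weather generator


_WEATHER_PRESETS = {
    # annual_rain mm; temperature cycle: mean of tmax, seasonal amplitude,
    # diurnal range; rainy-season peak day-of-year and width (days)
    "sadore": {"annual_rain": 565.0, "tmax_mean": 36.5, "tmax_amp": 4.0,
               "diurnal_range": 13.0, "rain_peak": 213, "rain_width": 45.0,
               "p_wet_peak": 0.55},
    "ndiaye": {"annual_rain": 277.0, "tmax_mean": 33.0, "tmax_amp": 4.5,
               "diurnal_range": 11.0, "rain_peak": 240, "rain_width": 35.0,
               "p_wet_peak": 0.45},
}


def generate_weather(site_preset: str, n_years: int, seed: int = 0) -> pd.DataFrame:
    """Daily synthetic weather for one of the two station climates.

    Temperatures follow a sinusoidal annual cycle plus day-to-day noise
    (tmin is tmax minus a noisy diurnal range, clamped so tmin <= tmax).
    Rainfall is an occurrence/intensity process concentrated in a Gaussian
    rainy-season window, with the mean intensity calibrated so the
    long-run annual total matches the preset target (565 mm at Sadoré,
    277 mm at Ndiaye). Radiation follows a mild seasonal cycle.
    Deterministic per (preset, n_years, seed).
    """
    if site_preset not in _WEATHER_PRESETS:
        raise KeyError(f"unknown site preset {site_preset!r}; choose from {sorted(_WEATHER_PRESETS)}")
    if n_years < 1:
        raise DomainError("n_years must be >= 1")
    p = _WEATHER_PRESETS[site_preset]
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2001-01-01", periods=365 * n_years, freq="D")
    doy = dates.dayofyear.to_numpy(float)

    tmax = (p["tmax_mean"] + p["tmax_amp"] * np.sin(2 * math.pi * (doy - 120) / 365.0)
            + rng.normal(0, 1.5, len(doy)))
    tmin = tmax - np.maximum(2.0, p["diurnal_range"] + rng.normal(0, 1.5, len(doy)))

    w = np.exp(-0.5 * ((doy - p["rain_peak"]) / p["rain_width"]) ** 2)
    p_wet = p["p_wet_peak"] * w
    # expected annual rain = sum(p_wet) * mean_intensity over one year
    mean_intensity = p["annual_rain"] / float(p_wet[:365].sum())
    wet = rng.random(len(doy)) < p_wet
    # gamma intensity with shape 0.9 keeps a realistic skew of daily totals
    shape = 0.9
    rain = np.where(wet, rng.gamma(shape, mean_intensity / shape, len(doy)), 0.0)

    radiation = (21.0 + 3.0 * np.sin(2 * math.pi * (doy - 90) / 365.0)
                 + rng.normal(0, 1.0, len(doy)))
    return pd.DataFrame({"date": dates, "tmin": np.round(tmin, 2), "tmax": np.round(tmax, 2),
                         "rain": np.round(rain, 2), "radiation": np.round(np.clip(radiation, 5, None), 2)})
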