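"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes —
not any particular site's weather:

* **Light** — a deterministic clear-sky envelope (half-sine diurnal course,
  day length varying seasonally with latitude, seasonal peak PPFD) scaled
  by a random daily cloudiness factor. The shade series is the sun series
  multiplied by the configured relative irradiance (RI) and, optionally,
  multiplicative log-normal noise with mean one — so RI is preserved in
  expectation and exactly when the noise is off. Night-time values are
  exactly zero.
* **Temperature** — hourly: seasonal sinusoid around the site mean, a
  diurnal cycle peaking mid-afternoon, and AR(1) weather noise.
* **Gas exchange** — net photosynthesis at configured light levels from a
  known true parameter triple of the exponential light-response model plus
  Gaussian observation noise; the true parameters are retained so recovery
  can be tested.
* **Branch records** — paired sun/shade branches per synthetic tree, with a
  shared tree-level log-normal size factor (so equal sun/shade trait
  configurations yield identical paired records), leaf area = leaf mass ×
  SLA and twig mass = leaf area / (LA:BDW).
* **Starch dynamics** — a seasonal concentration curve rising by exactly
  the configured amplitude across the build-up window (pre-budbreak for
  conifers, early-season for broadleaves).

All randomness derives from the scenario seed through named
``numpy.random.SeedSequence`` streams, so each generator is individually
reproducible and regenerating a scenario is bit-identical.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .carbon_costs import BranchRecord
from .config import POSITIONS, ScenarioConfig, SpeciesConfig
from .errors import InvalidConfigError
from .lrc import GasExchangeCurve, LRCParams, predict_net_photosynthesis
from .starch import BROADLEAF_BASIS, CONIFER_BASIS, StarchDynamics

__all__ = [
    "generate_light_series",
    "generate_temperature_series",
    "generate_lrc_observations",
    "generate_branch_records",
    "generate_starch_dynamics",
]

# stream codes for deriving independent RNGs from the scenario seed
_STREAMS = {"cloud": 0, "shade": 1, "temperature": 2, "gasx": 3, "branch": 4}


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _species_index(config: ScenarioConfig, name: str) -> int:
    return [sp.name for sp in config.species].index(name)


def _year_index(year: int, freq: str) -> pd.DatetimeIndex:
    return pd.date_range(
        f"{year}-01-01", f"{year + 1}-01-01", freq=freq, inclusive="left"
    )


def _day_length_hours(latitude_deg: float, doy: np.ndarray) -> np.ndarray:
    """Sinusoidal day length over the year, amplitude set by latitude.

    The solstice day length comes from the standard sunrise-equation
    envelope; between solstices the course is approximated by a sinusoid
    anchored at the March equinox (day-of-year ~80).
    """
    phi = np.radians(latitude_deg)
    x = np.clip(np.tan(phi) * np.tan(np.radians(23.44)), -1.0, 1.0)
    d_max = 24.0 / np.pi * np.arccos(-x)  # summer-solstice day length
    amp = d_max - 12.0
    return 12.0 + amp * np.sin(2 * np.pi * (doy - 80) / 365.25)


def generate_light_series(
    config: ScenarioConfig, species: str, position: str
) -> pd.Series:
    """15-min PPFD series (µmol m⁻² s⁻¹) for one crown position over the year.

    The sun series is the clear-sky half-sine envelope times a daily
    cloudiness factor drawn once per day (shared between positions). The
    shade series is RI × sun × log-normal step noise with mean one
    (``config.shade_noise_sigma``; zero gives exactly RI × sun).
    """
    config.validate()
    sp = config.species_named(species)
    if position not in POSITIONS:
        raise InvalidConfigError(f"unknown crown position {position!r}")
    if not 0 < sp.ri <= 1:
        raise InvalidConfigError(f"RI must be in (0, 1], got {sp.ri}")
    idx = _year_index(config.year, "15min")
    doy = idx.dayofyear.to_numpy(dtype=float)
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0

    daylen = _day_length_hours(config.latitude_deg, doy)
    sunrise = 12.0 - daylen / 2.0
    frac = (hour - sunrise) / daylen
    elev = np.where((frac > 0) & (frac < 1), np.sin(np.pi * np.clip(frac, 0, 1)), 0.0)
    season = 0.5 * (1.0 + np.sin(2 * np.pi * (doy - 80) / 365.25))
    peak = config.peak_ppfd_winter + (
        config.peak_ppfd_summer - config.peak_ppfd_winter
    ) * season

    sp_idx = _species_index(config, species)
    n_days = idx.normalize().nunique()
    cloud_rng = _rng(config.seed, _STREAMS["cloud"], sp_idx)
    cloud = np.exp(-cloud_rng.exponential(config.cloud_tau_scale, n_days))
    sun = peak * elev * np.repeat(cloud, 96)

    if position == "sun":
        out = sun
    else:
        sigma = config.shade_noise_sigma
        shade_rng = _rng(config.seed, _STREAMS["shade"], sp_idx)
        noise = np.exp(shade_rng.normal(-0.5 * sigma**2, sigma, idx.size))
        out = sp.ri * sun * noise
    return pd.Series(out, index=idx, name="ppfd")


def generate_temperature_series(config: ScenarioConfig) -> pd.Series:
    """Hourly air-temperature series (°C) for the scenario year.

    Seasonal sinusoid (coldest late January) around ``mean_temp_c`` plus a
    diurnal cycle peaking around 15:00 and AR(1) noise.
    """
    config.validate()
    idx = _year_index(config.year, "h")
    doy = idx.dayofyear.to_numpy(dtype=float)
    hour = idx.hour.to_numpy(dtype=float)
    seasonal = config.temp_seasonal_amp_c * np.sin(2 * np.pi * (doy - 110) / 365.25)
    diurnal = -config.temp_diurnal_amp_c * np.cos(2 * np.pi * (hour - 3) / 24.0)
    rng = _rng(config.seed, _STREAMS["temperature"])
    eps = rng.normal(0.0, config.temp_noise_sd_c, idx.size)
    noise = np.empty(idx.size)
    prev = 0.0
    rho = 0.9
    scale = np.sqrt(1 - rho**2)  # stationary variance = temp_noise_sd_c**2
    for i in range(idx.size):
        prev = rho * prev + scale * eps[i]
        noise[i] = prev
    return pd.Series(
        config.mean_temp_c + seasonal + diurnal + noise, index=idx, name="temp_c"
    )


def generate_lrc_observations(
    true_params: LRCParams,
    light_levels,
    noise_sd: float,
    rng: np.random.Generator | None = None,
    species: str = "",
    position: str = "",
    curve_id: str = "",
) -> GasExchangeCurve:
    """Gas-exchange observations from known light-response parameters.

    P_N at each light level is the model prediction plus Gaussian noise of
    standard deviation ``noise_sd``. With fewer than 3 distinct light
    levels and no noise a warning is issued: the fit is underdetermined.
    """
    true_params.validate()
    light = np.asarray(light_levels, dtype=float)
    if np.any(light < 0):
        raise ValueError("light levels must be nonnegative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if np.unique(light).size < 3:
        warnings.warn(
            "fewer than 3 distinct light levels: the 3-parameter fit is "
            "underdetermined",
            stacklevel=2,
        )
    pn = predict_net_photosynthesis(light, true_params)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        pn = pn + rng.normal(0.0, noise_sd, light.size)
    return GasExchangeCurve(
        ppfd=light, pn=np.asarray(pn, dtype=float), species=species,
        position=position, curve_id=curve_id,
    )


def generate_gas_exchange(config: ScenarioConfig) -> list[GasExchangeCurve]:
    """All gas-exchange curves of a scenario (curves × species × position)."""
    config.validate()
    curves = []
    for s, sp in enumerate(config.species):
        for p, pos in enumerate(POSITIONS):
            for c in range(config.lrc_curves_per_position):
                rng = _rng(config.seed, _STREAMS["gasx"], s, p, c)
                curves.append(
                    generate_lrc_observations(
                        sp.traits[pos].lrc,
                        config.lrc_light_levels,
                        config.lrc_noise_sd,
                        rng=rng,
                        species=sp.name,
                        position=pos,
                        curve_id=f"{sp.name}_{pos}_{c + 1}",
                    )
                )
    return curves


def generate_branch_records(config: ScenarioConfig) -> list[BranchRecord]:
    """Paired sun/shade branch records for every synthetic tree.

    Tree-level log-normal size factors (one for leaves, one for twigs) are
    shared between the two positions of a tree, emulating the paired
    sampling design; position means come from the configured traits.
    """
    config.validate()
    records = []
    for s, sp in enumerate(config.species):
        for t in range(sp.n_trees):
            rng = _rng(config.seed, _STREAMS["branch"], s, t)
            f_leaf = np.exp(rng.normal(0.0, config.tree_mass_sigma))
            f_twig = np.exp(rng.normal(0.0, config.tree_mass_sigma))
            for pos in POSITIONS:
                tr = sp.traits[pos]
                leaf_mass = tr.leaf_mass_g * f_leaf
                leaf_area = leaf_mass * tr.sla_m2_per_g
                twig_mass = leaf_area / tr.la_bdw_m2_per_g * f_twig
                records.append(
                    BranchRecord(
                        tree_id=f"{sp.name}_t{t + 1}",
                        species=sp.name,
                        position=pos,
                        leaf_area_m2=leaf_area,
                        leaf_mass_g=leaf_mass,
                        twig_mass_g=twig_mass,
                        leaf_c_frac=tr.leaf_c_frac,
                        twig_c_frac=tr.twig_c_frac,
                        budbreak=sp.budbreak(config.year, pos),
                        discoloration=sp.discoloration(config.year, pos),
                        habit=sp.habit,
                        lifespan_years=sp.lifespan_years,
                    ).validate()
                )
    return records


def generate_starch_dynamics(
    config: ScenarioConfig, species: str, position: str
) -> StarchDynamics:
    """Seasonal starch dynamics summary for one species × position.

    Conifer windows precede budbreak (starch accumulates in mature needles
    in early spring); broadleaf windows start at budbreak and lie in the
    first half of the growing season. The tissue-mass basis is the mean
    1-year-old needle mass (conifer) or the mean current-year twig mass
    (broadleaf, upscaled later in the cost calculation).
    """
    config.validate()
    sp = config.species_named(species)
    tr = sp.traits[position]
    start, end = sp.starch_window(config.year, position)
    if sp.habit == "evergreen":
        basis, mass = CONIFER_BASIS, tr.needle_mass_1yr_g
    else:
        basis = BROADLEAF_BASIS
        mass = tr.leaf_mass_g * tr.sla_m2_per_g / tr.la_bdw_m2_per_g
    return StarchDynamics(
        amplitude_g_per_g=tr.starch_amplitude_g_per_g,
        window_start=start,
        window_end=end,
        basis=basis,
        tissue_mass_g=mass,
    ).validate()


def starch_concentration_curve(
    dynamics: StarchDynamics, year: int, base_g_per_g: float = 0.01
) -> pd.Series:
    """Daily starch concentration curve implied by a dynamics summary.

    Flat at ``base`` outside the build-up window and rising linearly by
    exactly the amplitude across it — the conceptual seasonal shape the
    amplitude/window summary is read from. Minimum-to-maximum difference
    equals the amplitude by construction.
    """
    idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    days_in = (idx - dynamics.window_start) / pd.Timedelta("1D")
    span = (dynamics.window_end - dynamics.window_start) / pd.Timedelta("1D")
    rise = np.clip(days_in / span, 0.0, 1.0)
    return pd.Series(
        base_g_per_g + dynamics.amplitude_g_per_g * rise, index=idx, name="starch_conc"
    )
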