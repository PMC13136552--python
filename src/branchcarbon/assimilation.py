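"""Temperature-corrected assimilation time series and daily carbon integration.

From a 15-min PPFD record and a fitted light-response curve this module
builds sub-daily gross photosynthesis (Pg) and dark respiration (Rd) series,
applies two independent temperature corrections, integrates to daily net
carbon assimilation per unit leaf area (A_N, g C m⁻² d⁻¹), averages series
within species × crown position, and scales by branch leaf area to whole
branch assimilation (A_Branch, g C branch⁻¹ d⁻¹).

Temperature enters twice:

* Photosynthesis is multiplied by a piecewise-linear factor with a broad
  optimum (factor 1) between 10 and 30 °C, declining linearly to zero at
  −2 °C and +42 °C.
* Dark respiration follows an exponential Q10 law, ``Rd(T) = Rd_ref *
  Q10**((T - T_ref)/10)`` with Q10 = 2 and the reference at the 25 °C
  cuvette temperature of the light-response measurements.

The same air temperature is used for sun and shade positions: vertical
temperature gradients inside a crown are small compared to the light
gradient. Hourly temperature is applied as a step function to the four
15-min light steps within each hour.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import AlignmentError, GapError
from .lrc import LRCParams, gross_photosynthesis

__all__ = [
    "lux_to_ppfd",
    "temperature_multiplier",
    "correct_respiration",
    "compute_subdaily_series",
    "daily_net_assimilation",
    "average_assimilation",
    "branch_assimilation",
]

#: Anchor temperatures (°C) of the photosynthesis multiplier: zero below the
#: first and above the last, one between the middle two.
TEMP_ANCHORS = (-2.0, 10.0, 30.0, 42.0)

#: Molar mass of carbon, g mol⁻¹ (µmol CO2 → g C conversion uses 12e-6).
C_MOLAR_MASS = 12.0

#: Reference temperature (°C) of the fitted Rd: the gas-exchange cuvette setpoint.
T_REF_C = 25.0

DEFAULT_Q10 = 2.0


def lux_to_ppfd(lux, divisor: float = 120.0):
    """Convert illuminance (lux) to PPFD (µmol m⁻² s⁻¹) as PPFD = lux / 120.

    The divisor is the empirical sensor-specific calibration for the HOBO
    pendant loggers the light records come from.
    """
    lux_arr = np.asarray(lux, dtype=float)
    if np.any(lux_arr < 0):
        raise ValueError("illuminance must be nonnegative")
    out = lux_arr / divisor
    return float(out) if out.ndim == 0 else out


def temperature_multiplier(t_c, anchors=TEMP_ANCHORS):
    """Piecewise-linear photosynthesis temperature factor in [0, 1].

    Zero at and below ``anchors[0]``, rising linearly to one at
    ``anchors[1]``, flat (broad optimum) to ``anchors[2]``, falling linearly
    to zero at ``anchors[3]`` and beyond.
    """
    t = np.asarray(t_c, dtype=float)
    out = np.interp(t, anchors, [0.0, 1.0, 1.0, 0.0])
    return float(out) if out.ndim == 0 else out


def correct_respiration(rd_ref, t_c, t_ref: float = T_REF_C, q10: float = DEFAULT_Q10):
    """Q10 temperature correction of dark respiration.

    ``Rd(T) = Rd_ref * Q10**((T - T_ref) / 10)``; exact exponential law,
    positive for any finite temperature.
    """
    if np.any(np.asarray(rd_ref) < 0):
        raise ValueError("rd_ref must be >= 0")
    if q10 <= 0:
        raise ValueError("Q10 must be > 0")
    t = np.asarray(t_c, dtype=float)
    out = rd_ref * q10 ** ((t - t_ref) / 10.0)
    return float(out) if np.ndim(out) == 0 else out


def _check_regular(index: pd.DatetimeIndex, freq: pd.Timedelta, what: str) -> None:
    if len(index) > 1:
        deltas = np.diff(index.asi8)
        if np.any(deltas <= 0):
            raise GapError(f"{what}: timestamps must be strictly increasing")
        if np.any(deltas != freq.value):
            bad = index[1:][deltas != freq.value]
            raise GapError(f"{what}: irregular spacing at {list(bad[:5])}")


def infill_light_gaps(light: pd.Series, max_gap_steps: int = 2) -> pd.Series:
    """Reindex a 15-min PPFD series onto its full grid, infilling short gaps.

    Runs of at most ``max_gap_steps`` consecutive missing steps are linearly
    interpolated; longer gaps stay NaN so that the affected days are dropped
    (with a warning) by :func:`daily_net_assimilation`.
    """
    full = pd.date_range(light.index[0], light.index[-1], freq="15min")
    out = light.reindex(full)
    return out.interpolate(method="linear", limit=max_gap_steps, limit_area="inside")


def compute_subdaily_series(
    light: pd.Series,
    temperature: pd.Series,
    params: LRCParams,
    t_ref: float = T_REF_C,
    q10: float = DEFAULT_Q10,
) -> pd.DataFrame:
    """15-min Pg, Rd and net assimilation series (µmol CO2 m⁻² s⁻¹).

    Parameters
    ----------
    light : pd.Series
        PPFD at 15-min resolution (µmol m⁻² s⁻¹), DatetimeIndex.
    temperature : pd.Series
        Air temperature (°C) at hourly resolution covering the light span.
    params : LRCParams
        Fitted light-response parameters for this species × position.

    Returns
    -------
    pd.DataFrame with columns ``pg`` (temperature-corrected gross
    photosynthesis), ``rd`` (Q10-corrected respiration) and ``net = pg - rd``.

    Raises
    ------
    GapError
        If the temperature series does not cover every light timestep.
    """
    _check_regular(light.index, pd.Timedelta("15min"), "light series")
    _check_regular(temperature.index, pd.Timedelta("1h"), "temperature series")
    t15 = temperature.reindex(light.index, method="ffill", limit=3)
    if t15.isna().any():
        missing = t15.index[t15.isna()]
        raise GapError(
            f"temperature does not cover {missing.size} light steps "
            f"(first: {missing[0]}, last: {missing[-1]})"
        )
    pg = gross_photosynthesis(light.to_numpy(), params) * temperature_multiplier(
        t15.to_numpy()
    )
    rd = correct_respiration(params.rd, t15.to_numpy(), t_ref=t_ref, q10=q10)
    return pd.DataFrame({"pg": pg, "rd": rd, "net": pg - rd}, index=light.index)


def daily_net_assimilation(
    net: pd.Series, c_molar_mass: float = C_MOLAR_MASS
) -> pd.Series:
    """Integrate a sub-daily net series to daily A_N (g C m⁻² d⁻¹).

    Each complete day is summed as ``Σ net [µmol m⁻² s⁻¹] × step [s]`` and
    converted to grams of carbon with the molar mass of C (12 g mol⁻¹,
    i.e. × 12e-6 g µmol⁻¹). Days may be negative (winter respiration).
    Partial days — at the series edges or containing NaN from long logger
    gaps — are excluded with a warning: amortisation counts whole days only.
    """
    if net.empty:
        return pd.Series(dtype=float, name="a_n")
    step = net.index[1] - net.index[0]
    per_day = int(pd.Timedelta("1D") / step)
    days = net.index.normalize()
    counts = net.groupby(days).size()
    valid = net.notna().groupby(days).sum()
    complete = counts.eq(per_day) & valid.eq(per_day)
    if not complete.all():
        dropped = complete.index[~complete]
        warnings.warn(
            f"dropping {dropped.size} incomplete day(s) "
            f"(first: {dropped[0].date()})",
            stacklevel=2,
        )
    daily = net.groupby(days).sum() * step.total_seconds() * c_molar_mass * 1e-6
    daily = daily[complete]
    daily.name = "a_n"
    return daily


def average_assimilation(series: list[pd.Series]) -> pd.Series:
    """Pointwise arithmetic mean of aligned daily series (species × position).

    All members must share an identical date index; typically the 2 curves ×
    k loggers of one species and crown position.
    """
    if not series:
        raise ValueError("need at least one series to average")
    ref = series[0].index
    for s in series[1:]:
        if not s.index.equals(ref):
            raise AlignmentError("assimilation series have mismatched dates")
    out = pd.concat(series, axis=1).mean(axis=1)
    out.name = "a_n"
    return out


def branch_assimilation(a_n: pd.Series, leaf_area_m2: float) -> pd.Series:
    """Whole-branch daily assimilation A_Branch = leaf area × A_N (g C d⁻¹)."""
    if not leaf_area_m2 > 0:
        raise ValueError(f"leaf area must be > 0 m², got {leaf_area_m2}")
    out = a_n * leaf_area_m2
    out.name = "a_branch"
    return out
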