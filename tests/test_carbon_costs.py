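"""Carbon costs, amortisation scans (vs brute-force oracle), and RCC."""

import numpy as np
import pandas as pd
import pytest

from branchcarbon.carbon_costs import (
    BranchRecord,
    amortisation_time,
    carbon_cost,
    evaluate_branch,
    relative_carbon_cost,
)
from conftest import constant_daily_series


def amortisation_oracle(values, i0, cost, allow_loop, max_loops=10):
    """Independent day-by-day cumulative scan; None = never amortised."""
    if cost == 0:
        return 0
    total, day, i, loops = 0.0, 0, i0, 0
    while True:
        if i >= len(values):
            if not allow_loop or loops >= max_loops:
                return None
            loops += 1
            i = 0
        total += values[i]
        day += 1
        if total >= cost:
            return day
        i += 1


# -- carbon cost -------------------------------------------------------------


def test_carbon_cost_is_mass_times_fraction():
    assert carbon_cost(10.0, 0.5) == 5.0
    assert carbon_cost(10.0, 0.4) == pytest.approx(4.0)


@pytest.mark.parametrize("mass, frac", [(0.0, 0.5), (-1.0, 0.5), (10.0, 0.0),
                                        (10.0, 1.0), (10.0, 1.5)])
def test_carbon_cost_rejects_invalid_inputs(mass, frac):
    with pytest.raises(ValueError):
        carbon_cost(mass, frac)


# -- amortisation ------------------------------------------------------------


def test_amortisation_closed_forms():
    series = constant_daily_series(2021, 1.0)
    start = pd.Timestamp("2021-04-25")
    assert amortisation_time(series, 0.0, start)[0] == 0
    days, flags = amortisation_time(series, 30.0, start)
    assert days == 30
    assert flags == {"looped_years": 0, "never_amortised": False}


def test_amortisation_day_one_is_budbreak():
    series = constant_daily_series(2021, 2.0)
    days, _ = amortisation_time(series, 2.0, pd.Timestamp("2021-04-25"))
    assert days == 1  # met on the budbreak day itself


def test_amortisation_rejects_negative_cost():
    series = constant_daily_series(2021, 1.0)
    with pytest.raises(ValueError):
        amortisation_time(series, -1.0, pd.Timestamp("2021-04-25"))


def test_amortisation_requires_full_calendar_year():
    idx = pd.date_range("2021-03-01", periods=100, freq="D")
    with pytest.raises(ValueError, match="calendar year"):
        amortisation_time(pd.Series(1.0, index=idx), 5.0, idx[10])


def test_amortisation_loops_into_following_years():
    """A late-season cost larger than the remaining uptake wraps to 1 Jan."""
    idx = pd.date_range("2021-01-01", "2021-12-31", freq="D")
    doy = np.arange(len(idx))
    values = np.maximum(np.sin((doy - 90) / 365 * 2 * np.pi), 0.0) - 0.05
    series = pd.Series(values, index=idx)
    start = pd.Timestamp("2021-10-01")
    cost = float(values[273:].sum()) + 50.0  # beyond the remaining-year uptake
    days, flags = amortisation_time(series, cost, start, allow_loop=True)
    assert flags["looped_years"] >= 1
    oracle = amortisation_oracle(values, 273, cost, allow_loop=True)
    assert days == oracle


def test_amortisation_never_flag_for_carbon_negative_branch():
    series = constant_daily_series(2021, -0.5)
    days, flags = amortisation_time(
        series, 10.0, pd.Timestamp("2021-04-25"), allow_loop=True
    )
    assert days == -1
    assert flags["never_amortised"]


def test_amortisation_matches_oracle_on_randomized_scenarios():
    """Integer-exact agreement with the brute-force scan, looping included."""
    rng = np.random.default_rng(2024)
    idx = pd.date_range("2021-01-01", "2021-12-31", freq="D")
    doy = np.arange(len(idx))
    for _ in range(100):
        season = rng.uniform(0.5, 3.0) * np.maximum(
            np.sin((doy - rng.integers(60, 120)) / 365 * 2 * np.pi), 0.0
        )
        values = season - rng.uniform(0.0, 0.3) + rng.normal(0, 0.2, len(idx))
        series = pd.Series(values, index=idx)
        i0 = int(rng.integers(0, len(idx)))
        cost = float(rng.uniform(0.0, 250.0))
        allow_loop = bool(rng.integers(0, 2))
        days, flags = amortisation_time(series, cost, idx[i0], allow_loop=allow_loop)
        expected = amortisation_oracle(values, i0, cost, allow_loop)
        if expected is None:
            assert flags["never_amortised"] and days == -1
        else:
            assert days == expected


def test_amortisation_monotone_in_cost():
    series = constant_daily_series(2021, 1.5)
    start = pd.Timestamp("2021-04-25")
    days = [amortisation_time(series, c, start)[0] for c in (0.0, 5.0, 10.0, 40.0)]
    assert days == sorted(days)


# -- relative carbon cost ----------------------------------------------------


def test_rcc_closed_forms():
    series = constant_daily_series(2021, 1.0)
    bb = pd.Timestamp("2021-04-01")
    disc = bb + pd.Timedelta(days=199)  # 200-day window, endpoints inclusive
    rcc, flags = relative_carbon_cost(series, 30.0, bb, discoloration=disc)
    assert rcc == pytest.approx(15.0)
    assert flags["lifetime_uptake_g"] == pytest.approx(200.0)
    rcc, _ = relative_carbon_cost(series, 200.0, bb, discoloration=disc)
    assert rcc == pytest.approx(100.0)


def test_rcc_is_linear_in_cost_and_inverse_in_uptake():
    series = constant_daily_series(2021, 1.0)
    bb, disc = pd.Timestamp("2021-04-01"), pd.Timestamp("2021-09-30")
    one, _ = relative_carbon_cost(series, 10.0, bb, discoloration=disc)
    two, _ = relative_carbon_cost(series, 20.0, bb, discoloration=disc)
    assert two == pytest.approx(2 * one)
    doubled, _ = relative_carbon_cost(2 * series, 10.0, bb, discoloration=disc)
    assert doubled == pytest.approx(one / 2)


def test_rcc_evergreen_denominator_is_lifespan_times_annual_sum():
    """Periodic looping makes the lifespan uptake exactly N x the annual sum."""
    idx = pd.date_range("2021-01-01", "2021-12-31", freq="D")
    rng = np.random.default_rng(7)
    series = pd.Series(rng.normal(1.0, 0.5, len(idx)), index=idx)
    rcc, flags = relative_carbon_cost(
        series, 50.0, pd.Timestamp("2021-05-10"), lifespan_years=5
    )
    assert flags["lifetime_uptake_g"] == pytest.approx(5 * series.sum(), rel=1e-9)
    assert rcc == pytest.approx(100 * 50.0 / (5 * series.sum()), rel=1e-9)


def test_rcc_carbon_negative_branch_is_flagged():
    series = constant_daily_series(2021, -1.0)
    rcc, flags = relative_carbon_cost(
        series, 10.0, pd.Timestamp("2021-04-01"),
        discoloration=pd.Timestamp("2021-09-30"),
    )
    assert np.isnan(rcc)
    assert flags["c_negative"]


# -- whole-branch evaluation -------------------------------------------------


def _record(**kw):
    base = dict(
        tree_id="t1", species="sp", position="sun",
        leaf_area_m2=0.2, leaf_mass_g=20.0, twig_mass_g=10.0,
        leaf_c_frac=0.48, twig_c_frac=0.47,
        budbreak=pd.Timestamp("2021-04-25"),
        discoloration=pd.Timestamp("2021-10-17"),
        habit="deciduous", lifespan_years=None,
    )
    base.update(kw)
    return BranchRecord(**base)


def test_evaluate_branch_composition():
    a_n = constant_daily_series(2021, 2.0)  # A_Branch = 0.4 g/d
    result = evaluate_branch(_record(), a_n)
    assert result.c_f_g == pytest.approx(9.6)
    assert result.c_t_g == pytest.approx(4.7)
    assert result.leaf_amortisation_days == int(np.ceil(9.6 / 0.4))
    assert result.total_amortisation_days == int(np.ceil(14.3 / 0.4))
    assert result.total_amortisation_days >= result.leaf_amortisation_days
    season_days = 176
    assert result.total_rcc_pct == pytest.approx(100 * 14.3 / (0.4 * season_days))


def test_evaluate_branch_twig_mass_limit():
    """As twig mass vanishes, total amortisation approaches leaf amortisation.

    The rate is chosen so the leaf cost is met strictly inside a day: at an
    exact day boundary any positive twig mass shifts the count by one day.
    """
    a_n = constant_daily_series(2021, 2.1)
    result = evaluate_branch(_record(twig_mass_g=1e-9), a_n)
    assert result.total_amortisation_days == result.leaf_amortisation_days
    assert result.twig_rcc_pct == pytest.approx(0.0, abs=1e-8)


def test_evaluate_branch_leaf_area_monotonicity():
    a_n = constant_daily_series(2021, 2.0)
    small = evaluate_branch(_record(leaf_area_m2=0.2), a_n)
    large = evaluate_branch(_record(leaf_area_m2=0.4), a_n)
    assert large.leaf_amortisation_days <= small.leaf_amortisation_days
    assert large.total_amortisation_days <= small.total_amortisation_days


def test_evaluate_branch_is_deterministic():
    a_n = constant_daily_series(2021, 2.0)
    assert evaluate_branch(_record(), a_n) == evaluate_branch(_record(), a_n)


def test_branch_record_validation():
    with pytest.raises(ValueError):
        _record(leaf_mass_g=0.0).validate()
    with pytest.raises(ValueError, match="discoloration"):
        _record(discoloration=pd.Timestamp("2021-03-01")).validate()
    with pytest.raises(ValueError, match="lifespan"):
        _record(habit="evergreen", lifespan_years=None).validate()
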