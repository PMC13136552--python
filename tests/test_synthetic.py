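"""Synthetic-data generators: structure, invariants, and reproducibility."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from branchcarbon import demo_scenario
from branchcarbon.errors import InvalidConfigError
from branchcarbon.lrc import LRCParams, predict_net_photosynthesis
from branchcarbon.synthetic import (
    generate_branch_records,
    generate_light_series,
    generate_lrc_observations,
    generate_starch_dynamics,
    generate_temperature_series,
    starch_concentration_curve,
)


def _noise_free(seed=3, year=2021):
    sc = demo_scenario(seed=seed, year=year)
    sc.shade_noise_sigma = 0.0
    return sc


@pytest.mark.parametrize("year, n15, nh", [(2021, 35040, 8760), (2020, 35136, 8784)])
def test_series_lengths_follow_the_calendar(year, n15, nh):
    sc = demo_scenario(seed=0, year=year)
    assert len(generate_light_series(sc, "broadleaf", "sun")) == n15
    assert len(generate_temperature_series(sc)) == nh


def test_light_is_nonnegative_and_zero_at_night():
    sc = demo_scenario(seed=1)
    sun = generate_light_series(sc, "broadleaf", "sun")
    assert (sun >= 0).all()
    # deep night: 00:00-02:00 is outside any mid-latitude day window
    night = sun[sun.index.hour < 2]
    assert (night == 0).all()
    assert sun.max() > 500  # and there is real daylight


def test_shade_is_ri_times_sun_without_noise():
    sc = _noise_free()
    sun = generate_light_series(sc, "broadleaf", "sun")
    shade = generate_light_series(sc, "broadleaf", "shade")
    np.testing.assert_array_equal(shade.to_numpy(), 0.3 * sun.to_numpy())


def test_ri_one_gives_identical_series():
    sc = _noise_free()
    sc.species[0].ri = 1.0
    sun = generate_light_series(sc, "broadleaf", "sun")
    shade = generate_light_series(sc, "broadleaf", "shade")
    assert shade.equals(sun)


def test_daylight_ratio_matches_ri_with_noise_on():
    """Multiplicative mean-one noise preserves RI in the daylight average."""
    sc = demo_scenario(seed=5)
    sun = generate_light_series(sc, "broadleaf", "sun")
    shade = generate_light_series(sc, "broadleaf", "shade")
    day = sun > 0
    ratio = (shade[day] / sun[day]).mean()
    assert ratio == pytest.approx(0.3, rel=0.01)


def test_generators_are_deterministic_under_seed():
    a = generate_light_series(demo_scenario(seed=11), "conifer", "shade")
    b = generate_light_series(demo_scenario(seed=11), "conifer", "shade")
    c = generate_light_series(demo_scenario(seed=12), "conifer", "shade")
    assert a.equals(b)
    assert not a.equals(c)
    ta = generate_temperature_series(demo_scenario(seed=11))
    tb = generate_temperature_series(demo_scenario(seed=11))
    assert ta.equals(tb)


def test_invalid_ri_rejected():
    sc = demo_scenario(seed=0)
    sc.species[0].ri = 0.0
    with pytest.raises(InvalidConfigError, match="RI"):
        generate_light_series(sc, "broadleaf", "shade")


def test_temperature_degenerate_amplitudes_give_constant_series():
    sc = demo_scenario(seed=0)
    sc.mean_temp_c = 15.0
    sc.temp_seasonal_amp_c = 0.0
    sc.temp_diurnal_amp_c = 0.0
    sc.temp_noise_sd_c = 0.0
    temp = generate_temperature_series(sc)
    assert (temp == 15.0).all()


def test_default_climate_matches_site_mean():
    """The default configuration is anchored at the 9.6 °C site climatology."""
    sc = demo_scenario(seed=0)
    assert sc.mean_temp_c == 9.6
    temp = generate_temperature_series(sc)
    assert temp.mean() == pytest.approx(9.6, abs=0.5)


# -- gas exchange ------------------------------------------------------------


def test_lrc_observations_noiseless_satisfy_the_model():
    true = LRCParams(10.0, 1.0, 0.05)
    levels = np.array([0.0, 50.0, 200.0, 800.0, 1500.0])
    curve = generate_lrc_observations(true, levels, noise_sd=0.0)
    np.testing.assert_array_equal(
        curve.pn, predict_net_photosynthesis(levels, true)
    )
    assert curve.pn[0] == -true.rd  # I = 0 gives exactly -Rd
    # saturating light approaches Pgmax - Rd
    assert curve.pn[-1] == pytest.approx(true.pgmax - true.rd, abs=0.01)


def test_lrc_observations_warn_when_underdetermined():
    with pytest.warns(UserWarning, match="underdetermined"):
        generate_lrc_observations(LRCParams(10.0, 1.0, 0.05), [0.0, 500.0], 0.0)


def test_lrc_observation_noise_is_reproducible():
    true = LRCParams(10.0, 1.0, 0.05)
    levels = np.linspace(0, 1500, 8)
    a = generate_lrc_observations(true, levels, 0.3, np.random.default_rng(1))
    b = generate_lrc_observations(true, levels, 0.3, np.random.default_rng(1))
    np.testing.assert_array_equal(a.pn, b.pn)
    assert not np.array_equal(
        a.pn, predict_net_photosynthesis(levels, true)
    )


# -- branch records ----------------------------------------------------------


def test_branch_records_are_consistent_and_reproducible():
    sc = demo_scenario(seed=9)
    records = generate_branch_records(sc)
    assert len(records) == 2 * sum(sp.n_trees for sp in sc.species)
    for r in records:
        sp = sc.species_named(r.species)
        tr = sp.traits[r.position]
        # leaf area is definitionally mass x SLA
        assert r.leaf_area_m2 == pytest.approx(r.leaf_mass_g * tr.sla_m2_per_g)
    again = generate_branch_records(sc)
    assert records == again


def test_equal_sun_shade_traits_give_identical_paired_records():
    """Tree-level factors are shared, so zero contrast means identical pairs."""
    sc = demo_scenario(seed=2)
    sp = sc.species[0]
    sp.traits["shade"] = dataclasses.replace(sp.traits["sun"])
    sp.phenology_offset_days = {"sun": (0, 0), "shade": (0, 0)}
    records = [r for r in generate_branch_records(sc) if r.species == sp.name]
    by_tree = {}
    for r in records:
        by_tree.setdefault(r.tree_id, {})[r.position] = r
    for pair in by_tree.values():
        assert pair["sun"].leaf_mass_g == pair["shade"].leaf_mass_g
        assert pair["sun"].twig_mass_g == pair["shade"].twig_mass_g


# -- starch dynamics ---------------------------------------------------------


def test_starch_windows_follow_leaf_habit():
    sc = demo_scenario(seed=0)
    conifer = generate_starch_dynamics(sc, "conifer", "sun")
    broadleaf = generate_starch_dynamics(sc, "broadleaf", "sun")
    bb_conifer = sc.species_named("conifer").budbreak(sc.year, "sun")
    bb_broadleaf = sc.species_named("broadleaf").budbreak(sc.year, "sun")
    assert conifer.window_end < bb_conifer  # pre-budbreak accumulation
    assert broadleaf.window_start == bb_broadleaf  # starts at budbreak
    season = (
        sc.species_named("broadleaf").discoloration(sc.year, "sun") - bb_broadleaf
    )
    assert broadleaf.window_end <= bb_broadleaf + season / 2


def test_starch_concentration_curve_amplitude():
    sc = demo_scenario(seed=0)
    dyn = generate_starch_dynamics(sc, "conifer", "shade")
    curve = starch_concentration_curve(dyn, sc.year)
    assert curve.max() - curve.min() == pytest.approx(dyn.amplitude_g_per_g)
    flat = dataclasses.replace(dyn, amplitude_g_per_g=0.0)
    assert starch_concentration_curve(flat, sc.year).nunique() == 1


def test_starch_window_outside_year_rejected():
    sc = demo_scenario(seed=0)
    sc.species[1].starch_window_offset_days = (-200, -150)  # before 1 January
    with pytest.raises(InvalidConfigError, match="outside the year"):
        generate_starch_dynamics(sc, "conifer", "sun")
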