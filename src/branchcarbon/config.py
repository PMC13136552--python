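"""Scenario and pipeline configuration.

A :class:`ScenarioConfig` fully describes one synthetic study: the calendar
year, the site climate, and per-species crown contrasts (relative
irradiance, sun/shade light-response parameters, specific leaf area, leaf
area : twig mass ratio, tissue carbon fractions, phenology, starch
dynamics). Everything the synthetic-data generators draw is keyed off its
single ``seed``, so a scenario is a complete, reproducible specification of
the study conditions.

:class:`Constants` collects the fixed physical/empirical constants of the
analysis (lux→PPFD divisor, molar mass of carbon, Q10, reference
temperature, temperature anchor points, starch C fraction, biomass
upscaling parameters).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidConfigError
from .lrc import LRCParams

__all__ = [
    "Constants",
    "PositionTraits",
    "SpeciesConfig",
    "ScenarioConfig",
    "demo_scenario",
]

POSITIONS = ("sun", "shade")


@dataclass(frozen=True)
class Constants:
    """Fixed constants of the carbon-balance calculation."""

    lux_divisor: float = 120.0
    c_molar_mass: float = 12.0
    q10: float = 2.0
    t_ref_c: float = 25.0
    temp_anchors: tuple = (-2.0, 10.0, 30.0, 42.0)
    starch_c_fraction: float = 0.4
    upscale_years: int = 5
    shoots_per_parent: float = 2.0
    max_loops: int = 10

    def validate(self) -> "Constants":
        if self.lux_divisor <= 0 or self.c_molar_mass <= 0 or self.q10 <= 0:
            raise InvalidConfigError("constants must be positive")
        if list(self.temp_anchors) != sorted(self.temp_anchors):
            raise InvalidConfigError("temperature anchors must be increasing")
        if not 0 < self.starch_c_fraction < 1:
            raise InvalidConfigError("starch C fraction must be in (0, 1)")
        return self


@dataclass
class PositionTraits:
    """Mean traits of one species at one crown position."""

    lrc: LRCParams
    sla_m2_per_g: float  # specific leaf area
    la_bdw_m2_per_g: float  # leaf area per g current-year twig dry mass
    leaf_c_frac: float
    twig_c_frac: float
    leaf_mass_g: float  # current-year leaf (or needle) dry mass per branch
    starch_amplitude_g_per_g: float
    needle_mass_1yr_g: float | None = None  # conifers: 1-y-old needle mass

    def validate(self, habit: str) -> "PositionTraits":
        self.lrc.validate()
        for name in ("sla_m2_per_g", "la_bdw_m2_per_g", "leaf_mass_g"):
            if not getattr(self, name) > 0:
                raise InvalidConfigError(f"{name} must be > 0")
        for name in ("leaf_c_frac", "twig_c_frac"):
            if not 0 < getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be in (0, 1)")
        if self.starch_amplitude_g_per_g < 0:
            raise InvalidConfigError("starch amplitude must be >= 0")
        if habit == "evergreen" and not (self.needle_mass_1yr_g or 0) > 0:
            raise InvalidConfigError("evergreen traits need needle_mass_1yr_g > 0")
        return self


@dataclass
class SpeciesConfig:
    """Crown contrast and phenology of one species."""

    name: str
    habit: str  # "deciduous" | "evergreen"
    ri: float  # relative irradiance of the shade position, (0, 1]
    budbreak_doy: int  # 50% budbreak, day of year
    traits: dict = field(default_factory=dict)  # position -> PositionTraits
    discoloration_doy: int | None = None  # deciduous: 50% discoloration
    lifespan_years: int | None = None  # evergreen foliage lifespan
    # per-position phenology shifts in days relative to (budbreak_doy,
    # discoloration_doy): shade foliage typically flushes a few days later
    # and senesces earlier, giving a slightly shorter shade season.
    phenology_offset_days: dict = field(
        default_factory=lambda: {"sun": (0, 0), "shade": (0, 0)}
    )
    # starch build-up window as day-of-year offsets relative to budbreak:
    # conifers pre-budbreak (negative offsets), broadleaves post-budbreak.
    starch_window_offset_days: tuple = (0, 60)
    n_trees: int = 3

    def validate(self) -> "SpeciesConfig":
        if not 0 < self.ri <= 1:
            raise InvalidConfigError(f"{self.name}: RI must be in (0, 1], got {self.ri}")
        if self.habit not in ("deciduous", "evergreen"):
            raise InvalidConfigError(f"{self.name}: unknown habit {self.habit!r}")
        if self.habit == "deciduous":
            if self.discoloration_doy is None:
                raise InvalidConfigError(f"{self.name}: deciduous needs discoloration")
            for pos in POSITIONS:
                bb_off, disc_off = self.phenology_offset_days.get(pos, (0, 0))
                if self.discoloration_doy + disc_off <= self.budbreak_doy + bb_off:
                    raise InvalidConfigError(
                        f"{self.name}/{pos}: budbreak must precede discoloration"
                    )
        else:
            if not self.lifespan_years or self.lifespan_years < 1:
                raise InvalidConfigError(f"{self.name}: evergreen needs lifespan_years")
        lo, hi = self.starch_window_offset_days
        if hi <= lo:
            raise InvalidConfigError(f"{self.name}: starch window must be non-empty")
        if self.n_trees < 1:
            raise InvalidConfigError(f"{self.name}: n_trees must be >= 1")
        for pos in POSITIONS:
            if pos not in self.traits:
                raise InvalidConfigError(f"{self.name}: missing {pos} traits")
            self.traits[pos].validate(self.habit)
        return self

    def budbreak(self, year: int, position: str = "sun") -> pd.Timestamp:
        offset = self.phenology_offset_days.get(position, (0, 0))[0]
        return pd.Timestamp(f"{year}-01-01") + pd.Timedelta(
            days=self.budbreak_doy + offset - 1
        )

    def discoloration(self, year: int, position: str = "sun") -> pd.Timestamp | None:
        if self.discoloration_doy is None:
            return None
        offset = self.phenology_offset_days.get(position, (0, 0))[1]
        return pd.Timestamp(f"{year}-01-01") + pd.Timedelta(
            days=self.discoloration_doy + offset - 1
        )

    def starch_window(
        self, year: int, position: str = "sun"
    ) -> tuple[pd.Timestamp, pd.Timestamp]:
        bb = self.budbreak(year, position)
        lo, hi = self.starch_window_offset_days
        return bb + pd.Timedelta(days=lo), bb + pd.Timedelta(days=hi)


@dataclass
class ScenarioConfig:
    """Complete specification of one synthetic study."""

    seed: int = 0
    year: int = 2021
    latitude_deg: float = 47.4
    species: list = field(default_factory=list)  # list[SpeciesConfig]
    # climate of the site (long-term mean 9.6 °C)
    mean_temp_c: float = 9.6
    temp_seasonal_amp_c: float = 9.5
    temp_diurnal_amp_c: float = 4.0
    temp_noise_sd_c: float = 1.2
    # light model
    peak_ppfd_summer: float = 1800.0
    peak_ppfd_winter: float = 350.0
    cloud_tau_scale: float = 1.0  # mean transmission 1/(1+scale); 0 = clear sky
    shade_noise_sigma: float = 0.1  # 0 makes shade exactly RI x sun
    # gas-exchange design
    lrc_light_levels: tuple = (0.0, 25.0, 50.0, 100.0, 200.0, 500.0, 1000.0, 1500.0)
    lrc_noise_sd: float = 0.3
    lrc_curves_per_position: int = 2
    # branch sampling noise (tree-level lognormal sigma, shared across positions)
    tree_mass_sigma: float = 0.15

    def validate(self) -> "ScenarioConfig":
        if self.year < 1:
            raise InvalidConfigError("year must be a valid calendar year")
        if not -90 < self.latitude_deg < 90:
            raise InvalidConfigError("latitude must be in (-90, 90)")
        if not self.species:
            raise InvalidConfigError("scenario needs at least one species")
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise InvalidConfigError("species names must be unique")
        for sp in self.species:
            sp.validate()
            lo, hi = sp.starch_window_offset_days
            ndays = pd.Timestamp(f"{self.year}-12-31").dayofyear
            for off in (lo, hi):
                doy = sp.budbreak_doy + off
                if not 1 <= doy <= ndays:
                    raise InvalidConfigError(
                        f"{sp.name}: starch window falls outside the year"
                    )
        if min(self.shade_noise_sigma, self.lrc_noise_sd, self.cloud_tau_scale) < 0:
            raise InvalidConfigError("noise parameters must be >= 0")
        return self

    def species_named(self, name: str) -> SpeciesConfig:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(name)

    # -- serialization (manifest / config files) ---------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lrc_light_levels"] = list(d["lrc_light_levels"])
        for sp in d["species"]:
            sp["starch_window_offset_days"] = list(sp["starch_window_offset_days"])
            sp["phenology_offset_days"] = {
                pos: list(off) for pos, off in sp["phenology_offset_days"].items()
            }
            for pos, traits in sp["traits"].items():
                traits["lrc"] = {
                    k: traits["lrc"][k] for k in ("pgmax", "rd", "phi0")
                }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        species = []
        for sp in d.pop("species", []):
            sp = dict(sp)
            traits = {}
            for pos, tr in sp.pop("traits", {}).items():
                tr = dict(tr)
                tr["lrc"] = LRCParams(**tr["lrc"])
                traits[pos] = PositionTraits(**tr)
            for key in ("starch_window_offset_days",):
                if key in sp and sp[key] is not None:
                    sp[key] = tuple(sp[key])
            if "phenology_offset_days" in sp:
                sp["phenology_offset_days"] = {
                    pos: tuple(off)
                    for pos, off in sp["phenology_offset_days"].items()
                }
            species.append(SpeciesConfig(traits=traits, **sp))
        for key in ("lrc_light_levels",):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(species=species, **d).validate()


def demo_scenario(seed: int = 0, year: int = 2021) -> ScenarioConfig:
    """Two-species demonstration scenario calibrated to the study conditions.

    One deciduous broadleaf (beech-like: RI 0.3, strong SLA contrast,
    ~176-day season) and one evergreen conifer (spruce-like: RI 0.25,
    5-year needle lifespan, pre-budbreak starch accumulation). Trait
    contrasts follow the canonical sun/shade acclimation pattern: sun
    foliage has higher Pgmax and Rd, lower SLA and quantum yield.
    """
    broadleaf = SpeciesConfig(
        name="broadleaf",
        habit="deciduous",
        ri=0.30,
        budbreak_doy=115,  # late April
        discoloration_doy=291,  # mid October, ~176-day season
        phenology_offset_days={"sun": (0, 0), "shade": (3, -3)},
        traits={
            "sun": PositionTraits(
                lrc=LRCParams(pgmax=11.0, rd=1.2, phi0=0.045),
                sla_m2_per_g=0.009,  # LMA ~110 g m⁻²
                la_bdw_m2_per_g=0.012,
                leaf_c_frac=0.48,
                twig_c_frac=0.47,
                leaf_mass_g=20.0,
                starch_amplitude_g_per_g=0.020,
            ),
            "shade": PositionTraits(
                lrc=LRCParams(pgmax=8.0, rd=0.6, phi0=0.055),
                sla_m2_per_g=0.020,  # LMA ~50 g m⁻²
                la_bdw_m2_per_g=0.025,
                leaf_c_frac=0.47,
                twig_c_frac=0.47,
                leaf_mass_g=10.0,
                starch_amplitude_g_per_g=0.020,
            ),
        },
        starch_window_offset_days=(0, 60),  # first half of the growing season
        n_trees=3,
    )
    conifer = SpeciesConfig(
        name="conifer",
        habit="evergreen",
        ri=0.25,
        budbreak_doy=130,  # mid May
        lifespan_years=5,
        phenology_offset_days={"sun": (0, 0), "shade": (4, 0)},
        traits={
            "sun": PositionTraits(
                lrc=LRCParams(pgmax=6.5, rd=0.9, phi0=0.030),
                sla_m2_per_g=0.004,  # LMA ~250 g m⁻²
                la_bdw_m2_per_g=0.008,
                leaf_c_frac=0.50,
                twig_c_frac=0.50,
                leaf_mass_g=15.0,
                starch_amplitude_g_per_g=0.12,
                needle_mass_1yr_g=15.0,
            ),
            "shade": PositionTraits(
                lrc=LRCParams(pgmax=4.5, rd=0.5, phi0=0.040),
                sla_m2_per_g=0.007,
                la_bdw_m2_per_g=0.015,
                leaf_c_frac=0.50,
                twig_c_frac=0.50,
                leaf_mass_g=10.0,
                starch_amplitude_g_per_g=0.12,
                needle_mass_1yr_g=10.0,
            ),
        },
        starch_window_offset_days=(-55, -5),  # early spring, pre-budbreak
        n_trees=3,
    )
    return ScenarioConfig(seed=seed, year=year, species=[broadleaf, conifer]).validate()
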