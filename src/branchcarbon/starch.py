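"""Relative carbon cost of the seasonal starch build-up in branches.

Young branches rebuild local starch reserves every year: evergreen conifers
in mature needles during early spring *before* budbreak, deciduous
broadleaves in branch sapwood during the first half of the growing season
*after* budbreak. The carbon bound in that build-up is

    starch C = amplitude × tissue dry mass × 0.4

where the amplitude is the seasonal minimum-to-maximum rise in starch
concentration (g starch per g dry mass), the tissue mass is the dry mass of
the storing tissue, and 0.4 is the carbon fraction of starch.

For conifers the storing tissue is the needles on 1-year-old branch
segments. For broadleaves starch is stored in 3–5-year-old wood, while only
current-year twig mass is measured; the current-year mass is upscaled to
the 5-year-old branch it will belong to by assuming constant annual biomass
increment and on average ``s`` new shoots on each previous one (default 2):

    Biomass_n = Biomass_1 × Σ_{i=1..n} i / s^(i-1)   (n = 5, s = 2 → 3.5625)

The relative cost expresses the starch carbon as a percentage of the branch
net carbon uptake over the build-up window.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "StarchDynamics",
    "upscale_branch_biomass",
    "starch_build_up_carbon",
    "starch_relative_cost",
]

STARCH_C_FRACTION = 0.4
DEFAULT_UPSCALE_YEARS = 5
DEFAULT_SHOOTS_PER_PARENT = 2.0

#: Tissue bases for the starch calculation.
CONIFER_BASIS = "conifer_needles_1yr"
BROADLEAF_BASIS = "broadleaf_wood_3to5yr"


@dataclass
class StarchDynamics:
    """Summary of one tissue's seasonal starch dynamics.

    ``amplitude_g_per_g`` is the minimum-to-maximum seasonal rise in starch
    concentration; the window delimits the build-up period over which branch
    uptake is summed; ``tissue_mass_g`` is the dry mass of the storing
    tissue on the measured basis (1-year-old needles for conifers,
    current-year twig wood+bark — to be upscaled — for broadleaves).
    """

    amplitude_g_per_g: float
    window_start: pd.Timestamp
    window_end: pd.Timestamp
    basis: str  # CONIFER_BASIS | BROADLEAF_BASIS
    tissue_mass_g: float

    def validate(self) -> "StarchDynamics":
        if self.amplitude_g_per_g < 0:
            raise ValueError("starch amplitude must be >= 0")
        if self.window_end <= self.window_start:
            raise ValueError("starch build-up window must be non-empty")
        if self.basis not in (CONIFER_BASIS, BROADLEAF_BASIS):
            raise ValueError(f"unknown tissue basis {self.basis!r}")
        if not self.tissue_mass_g > 0:
            raise ValueError("tissue mass must be > 0 g")
        return self


def upscale_branch_biomass(
    biomass1_g: float,
    years: int = DEFAULT_UPSCALE_YEARS,
    shoots_per_parent: float = DEFAULT_SHOOTS_PER_PARENT,
) -> float:
    """Upscale current-year twig biomass to an n-year-old branch.

    ``biomass1 × Σ_{i=1..years} i / shoots_per_parent^(i-1)``; with the
    defaults (5 years, 2 shoots per parent) the factor is exactly 3.5625.
    """
    if not biomass1_g > 0:
        raise ValueError(f"biomass must be > 0 g, got {biomass1_g}")
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    if not shoots_per_parent > 0:
        raise ValueError("shoots_per_parent must be > 0")
    factor = sum(i / shoots_per_parent ** (i - 1) for i in range(1, years + 1))
    return biomass1_g * factor


def starch_build_up_carbon(
    dynamics: StarchDynamics,
    c_fraction: float = STARCH_C_FRACTION,
    upscale_years: int = DEFAULT_UPSCALE_YEARS,
    shoots_per_parent: float = DEFAULT_SHOOTS_PER_PARENT,
) -> float:
    """Carbon bound in the seasonal starch build-up (g C).

    amplitude × tissue mass × starch C fraction, where the broadleaf
    current-year twig mass is first upscaled to the 5-year-old branch.
    """
    dynamics.validate()
    mass = dynamics.tissue_mass_g
    if dynamics.basis == BROADLEAF_BASIS:
        mass = upscale_branch_biomass(mass, upscale_years, shoots_per_parent)
    return dynamics.amplitude_g_per_g * mass * c_fraction


def starch_relative_cost(
    starch_c_g: float,
    a_branch: pd.Series,
    window_start: pd.Timestamp,
    window_end: pd.Timestamp,
) -> tuple[float, dict]:
    """Starch C as % of branch net uptake over the build-up window.

    The window endpoints are inclusive. When the window uptake is not
    positive the percentage is undefined (NaN) and flagged; the signed
    uptake is reported rather than clipped.
    """
    if starch_c_g < 0:
        raise ValueError("starch carbon must be >= 0 g")
    if window_end <= window_start:
        raise ValueError("build-up window must be non-empty")
    uptake = float(a_branch.loc[window_start:window_end].sum())
    if uptake <= 0:
        return float("nan"), {"window_uptake_g": uptake, "uptake_nonpositive": True}
    return 100.0 * starch_c_g / uptake, {
        "window_uptake_g": uptake,
        "uptake_nonpositive": False,
    }
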