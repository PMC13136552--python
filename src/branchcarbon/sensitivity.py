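"""One-at-a-time sensitivity of shade-branch RCC to sun-crown trait values.

The question: which shade acclimations matter most for keeping the relative
carbon cost (RCC) of a shaded branch low? Eight factors of the RCC
calculation are replaced one at a time with the corresponding value from
the upper, sun-exposed crown, the full pipeline (light-response →
temperature-corrected assimilation → daily integration → costs → RCC) is
re-run, and the relative change

    (RCC_replaced − RCC_initial) / RCC_initial

is reported per factor. The factors are the incident light series, the
three light-response parameters (Pgmax, Rd, phi0), specific leaf area
(SLA), the leaf-area-to-twig-mass ratio (LA:BDW), tissue carbon
concentration, and season length (the phenology window).

Substitution semantics for the two morphology ratios (the measurement they
mimic holds the complementary quantity fixed):

* SLA: leaf area is recomputed as leaf mass × SLA_sun (leaf dry mass
  fixed); twig mass is untouched.
* LA:BDW: twig mass is recomputed as leaf area / (LA:BDW)_sun (leaf area
  fixed); leaf mass and area are untouched.

Replacements operate on species × crown-position *mean* inputs, matching
the averaging the RCC calculation itself uses. For evergreens the season
factor swaps only the budbreak date — no season end exists for them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

from .assimilation import (
    branch_assimilation,
    compute_subdaily_series,
    daily_net_assimilation,
)
from .carbon_costs import carbon_cost, relative_carbon_cost
from .config import Constants
from .lrc import LRCParams

__all__ = ["FACTORS", "BranchInputs", "replace_factor", "run_sensitivity",
           "compute_total_rcc"]

#: The eight replaceable factors, in reporting order.
FACTORS = (
    "incident_light",
    "pgmax",
    "rd",
    "phi0",
    "sla",
    "la_bdw",
    "tissue_c",
    "season_length",
)


@dataclass
class BranchInputs:
    """Mean inputs of the RCC calculation for one species × crown position."""

    species: str
    position: str
    light: pd.Series  # 15-min PPFD
    lrc: LRCParams
    sla_m2_per_g: float
    la_bdw_m2_per_g: float
    leaf_mass_g: float
    leaf_area_m2: float
    twig_mass_g: float
    leaf_c_frac: float
    twig_c_frac: float
    budbreak: pd.Timestamp
    discoloration: pd.Timestamp | None
    habit: str
    lifespan_years: int | None = None


def replace_factor(
    shade: BranchInputs, sun: BranchInputs, factor: str
) -> BranchInputs:
    """Return shade inputs with exactly one component taken from the sun crown."""
    if factor == "incident_light":
        return dataclasses.replace(shade, light=sun.light)
    if factor == "pgmax":
        return dataclasses.replace(
            shade, lrc=dataclasses.replace(shade.lrc, pgmax=sun.lrc.pgmax)
        )
    if factor == "rd":
        return dataclasses.replace(
            shade, lrc=dataclasses.replace(shade.lrc, rd=sun.lrc.rd)
        )
    if factor == "phi0":
        return dataclasses.replace(
            shade, lrc=dataclasses.replace(shade.lrc, phi0=sun.lrc.phi0)
        )
    if factor == "sla":
        return dataclasses.replace(
            shade,
            sla_m2_per_g=sun.sla_m2_per_g,
            leaf_area_m2=shade.leaf_mass_g * sun.sla_m2_per_g,
        )
    if factor == "la_bdw":
        return dataclasses.replace(
            shade,
            la_bdw_m2_per_g=sun.la_bdw_m2_per_g,
            twig_mass_g=shade.leaf_area_m2 / sun.la_bdw_m2_per_g,
        )
    if factor == "tissue_c":
        return dataclasses.replace(
            shade, leaf_c_frac=sun.leaf_c_frac, twig_c_frac=sun.twig_c_frac
        )
    if factor == "season_length":
        if shade.habit == "evergreen":
            return dataclasses.replace(shade, budbreak=sun.budbreak)
        return dataclasses.replace(
            shade, budbreak=sun.budbreak, discoloration=sun.discoloration
        )
    raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")


def compute_total_rcc(
    inputs: BranchInputs,
    temperature: pd.Series,
    constants: Constants = Constants(),
) -> float:
    """Whole-branch (leaf + twig) RCC % via the full pipeline, no shortcuts."""
    sub = compute_subdaily_series(
        inputs.light, temperature, inputs.lrc,
        t_ref=constants.t_ref_c, q10=constants.q10,
    )
    a_n = daily_net_assimilation(sub["net"], c_molar_mass=constants.c_molar_mass)
    a_branch = branch_assimilation(a_n, inputs.leaf_area_m2)
    cost = carbon_cost(inputs.leaf_mass_g, inputs.leaf_c_frac) + carbon_cost(
        inputs.twig_mass_g, inputs.twig_c_frac
    )
    if inputs.habit == "deciduous":
        rcc, _ = relative_carbon_cost(
            a_branch, cost, inputs.budbreak, discoloration=inputs.discoloration
        )
    else:
        rcc, _ = relative_carbon_cost(
            a_branch, cost, inputs.budbreak, lifespan_years=inputs.lifespan_years
        )
    return rcc


def run_sensitivity(
    shade: BranchInputs,
    sun: BranchInputs,
    temperature: pd.Series,
    constants: Constants = Constants(),
) -> pd.DataFrame:
    """Eight factor replacements for one species; full pipeline re-run each.

    Returns a DataFrame with columns ``species, factor, rcc_initial,
    rcc_replaced, rel_change``. Raises if the initial shade RCC is not
    positive (relative changes would be undefined).
    """
    rcc0 = compute_total_rcc(shade, temperature, constants)
    if not rcc0 > 0:
        raise ValueError(
            f"initial shade RCC must be positive, got {rcc0} (C-negative branch?)"
        )
    rows = []
    for factor in FACTORS:
        replaced = replace_factor(shade, sun, factor)
        rcc1 = compute_total_rcc(replaced, temperature, constants)
        rows.append(
            {
                "species": shade.species,
                "factor": factor,
                "rcc_initial": rcc0,
                "rcc_replaced": rcc1,
                "rel_change": (rcc1 - rcc0) / rcc0,
            }
        )
    return pd.DataFrame(rows)


def plot_sensitivity(result: pd.DataFrame, ax=None):
    """Bar plot of relative RCC changes per factor (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for i, (species, grp) in enumerate(result.groupby("species")):
        offset = (i - 0.5 * (result["species"].nunique() - 1)) * 0.35
        ax.bar(
            [FACTORS.index(f) + offset for f in grp["factor"]],
            100 * grp["rel_change"],
            width=0.3,
            label=species,
        )
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(range(len(FACTORS)))
    ax.set_xticklabels(FACTORS, rotation=45, ha="right")
    ax.set_ylabel("relative change in shade RCC (%)")
    ax.legend()
    return ax
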