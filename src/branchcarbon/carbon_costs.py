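"""Branch carbon costs, amortisation times and relative carbon costs (RCC).

The carbon cost of a tissue is simply the carbon contained in its dry
biomass (dry mass × C fraction); respiration costs of biosynthesis are
deliberately not included. Two cost-benefit measures relate these costs to
the branch's own daily assimilation series A_Branch:

* **Amortisation time** — the number of days, counting from 50% budbreak
  (day 1 = the budbreak date itself), until cumulative daily A_Branch first
  reaches the cost. Foliage cost C_F is amortised first, then total cost
  C_F + C_T (twig wood + bark). Evergreen conifers may take longer than a
  calendar year, in which case the annual series loops back to 1 January
  and continues; branches that never amortise within ``max_loops`` years
  are flagged instead of looping forever.

* **Relative carbon cost (RCC)** — the cost as a percentage of cumulative
  A_Branch over the whole foliage lifespan: budbreak → 50% discoloration
  for deciduous species (endpoints inclusive), or ``lifespan_years``
  repetitions of the looped annual cycle starting at budbreak for
  evergreens.

Negative daily values (winter respiration losses) are included in all
cumulative sums as they occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assimilation import branch_assimilation

__all__ = [
    "BranchRecord",
    "CostResult",
    "carbon_cost",
    "amortisation_time",
    "relative_carbon_cost",
    "evaluate_branch",
]

DEFAULT_MAX_LOOPS = 10


@dataclass
class BranchRecord:
    """Morphology, chemistry and phenology of one current-year branch."""

    tree_id: str
    species: str
    position: str  # "sun" | "shade"
    leaf_area_m2: float
    leaf_mass_g: float
    twig_mass_g: float
    leaf_c_frac: float
    twig_c_frac: float
    budbreak: pd.Timestamp
    discoloration: pd.Timestamp | None  # deciduous only
    habit: str  # "deciduous" | "evergreen"
    lifespan_years: int | None = None  # evergreen only

    def validate(self) -> "BranchRecord":
        for name in ("leaf_area_m2", "leaf_mass_g", "twig_mass_g"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("leaf_c_frac", "twig_c_frac"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.habit == "deciduous":
            if self.discoloration is None or self.discoloration <= self.budbreak:
                raise ValueError("deciduous branches need discoloration after budbreak")
        elif self.habit == "evergreen":
            if not self.lifespan_years or self.lifespan_years < 1:
                raise ValueError("evergreen branches need lifespan_years >= 1")
        else:
            raise ValueError(f"unknown habit {self.habit!r}")
        return self


@dataclass
class CostResult:
    """Carbon costs and cost-benefit measures for one branch."""

    c_f_g: float
    c_t_g: float
    leaf_amortisation_days: int
    total_amortisation_days: int
    leaf_rcc_pct: float
    twig_rcc_pct: float
    total_rcc_pct: float
    looped_years: int = 0
    never_amortised: bool = False
    c_negative: bool = False


def carbon_cost(dry_mass_g: float, c_fraction: float) -> float:
    """Carbon content of a tissue: dry mass × C fraction (g C)."""
    if not dry_mass_g > 0:
        raise ValueError(f"dry mass must be > 0 g, got {dry_mass_g}")
    if not 0 < c_fraction < 1:
        raise ValueError(f"C fraction must be in (0, 1), got {c_fraction}")
    return dry_mass_g * c_fraction


def _annual_values(a_branch: pd.Series, start: pd.Timestamp):
    """Validate that the series spans one full calendar year containing start."""
    idx = a_branch.index
    year = start.year
    expected = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    if not idx.equals(expected):
        raise ValueError(
            "A_Branch series must cover exactly the calendar year of the start date"
        )
    return a_branch.to_numpy(dtype=float), int(idx.get_loc(start))


def amortisation_time(
    a_branch: pd.Series,
    cost_g: float,
    start: pd.Timestamp,
    allow_loop: bool = False,
    max_loops: int = DEFAULT_MAX_LOOPS,
) -> tuple[int, dict]:
    """Days from budbreak until cumulative A_Branch first reaches ``cost_g``.

    Day 1 is the budbreak date itself and days are whole (no sub-day
    interpolation). With ``allow_loop`` the series wraps from 31 December
    back to 1 January of the same annual series, up to ``max_loops`` times;
    a branch whose cumulative sum never reaches the cost is returned with
    the ``never_amortised`` flag set and days = -1.

    Returns
    -------
    (days, flags) where flags has keys ``looped_years`` and ``never_amortised``.
    """
    if cost_g < 0:
        raise ValueError(f"cost must be >= 0 g C, got {cost_g}")
    flags = {"looped_years": 0, "never_amortised": False}
    if cost_g == 0:
        return 0, flags
    values, i0 = _annual_values(a_branch, start)
    remainder = values[i0:]
    if allow_loop:
        arr = np.concatenate([remainder] + [values] * max_loops)
    else:
        arr = remainder
    csum = np.cumsum(arr)
    hit = np.flatnonzero(csum >= cost_g)
    if hit.size == 0:
        flags["never_amortised"] = True
        return -1, flags
    pos = int(hit[0])
    if pos >= remainder.size:
        flags["looped_years"] = 1 + (pos - remainder.size) // values.size
    return pos + 1, flags


def relative_carbon_cost(
    a_branch: pd.Series,
    cost_g: float,
    budbreak: pd.Timestamp,
    discoloration: pd.Timestamp | None = None,
    lifespan_years: int | None = None,
) -> tuple[float, dict]:
    """Cost as % of cumulative A_Branch over the foliage lifespan.

    Deciduous (``discoloration`` given): the lifespan window is
    budbreak → discoloration, endpoints inclusive. Evergreen
    (``lifespan_years`` given): the window is ``lifespan_years`` annual
    cycles of the looped series starting at budbreak, so for an
    annual-periodic series the denominator equals lifespan_years × the
    annual sum.

    Returns
    -------
    (rcc_pct, flags); ``rcc_pct`` is NaN and ``c_negative`` is set when the
    lifetime uptake is not positive.
    """
    if cost_g < 0:
        raise ValueError(f"cost must be >= 0 g C, got {cost_g}")
    if (discoloration is None) == (lifespan_years is None):
        raise ValueError("give exactly one of discoloration or lifespan_years")
    if discoloration is not None:
        if discoloration <= budbreak:
            raise ValueError("discoloration must come after budbreak")
        uptake = float(a_branch.loc[budbreak:discoloration].sum())
    else:
        values, i0 = _annual_values(a_branch, budbreak)
        arr = np.concatenate([values[i0:]] + [values] * int(lifespan_years))
        uptake = float(arr[: int(lifespan_years) * values.size].sum())
    if uptake <= 0:
        return float("nan"), {"c_negative": True, "lifetime_uptake_g": uptake}
    return 100.0 * cost_g / uptake, {"c_negative": False, "lifetime_uptake_g": uptake}


def evaluate_branch(
    record: BranchRecord,
    a_n: pd.Series,
    max_loops: int = DEFAULT_MAX_LOOPS,
) -> CostResult:
    """Full cost-benefit evaluation of one branch against its mean A_N series.

    ``a_n`` is the species × crown-position mean daily assimilation per unit
    leaf area (g C m⁻² d⁻¹) over one calendar year; it is scaled by the
    branch's leaf area to A_Branch. Leaf amortisation uses C_F, total
    amortisation C_F + C_T; RCCs are computed for leaf, twig and total cost
    over the foliage lifespan window implied by the leaf habit.
    """
    record.validate()
    c_f = carbon_cost(record.leaf_mass_g, record.leaf_c_frac)
    c_t = carbon_cost(record.twig_mass_g, record.twig_c_frac)
    a_branch = branch_assimilation(a_n, record.leaf_area_m2)
    allow_loop = record.habit == "evergreen"
    leaf_days, leaf_flags = amortisation_time(
        a_branch, c_f, record.budbreak, allow_loop=allow_loop, max_loops=max_loops
    )
    total_days, total_flags = amortisation_time(
        a_branch, c_f + c_t, record.budbreak, allow_loop=allow_loop, max_loops=max_loops
    )
    if record.habit == "deciduous":
        window = {"discoloration": record.discoloration}
    else:
        window = {"lifespan_years": record.lifespan_years}
    leaf_rcc, rcc_flags = relative_carbon_cost(a_branch, c_f, record.budbreak, **window)
    twig_rcc, _ = relative_carbon_cost(a_branch, c_t, record.budbreak, **window)
    total_rcc, _ = relative_carbon_cost(a_branch, c_f + c_t, record.budbreak, **window)
    return CostResult(
        c_f_g=c_f,
        c_t_g=c_t,
        leaf_amortisation_days=leaf_days,
        total_amortisation_days=total_days,
        leaf_rcc_pct=leaf_rcc,
        twig_rcc_pct=twig_rcc,
        total_rcc_pct=total_rcc,
        looped_years=total_flags["looped_years"],
        never_amortised=leaf_flags["never_amortised"] or total_flags["never_amortised"],
        c_negative=rcc_flags["c_negative"],
    )
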