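"""Exponential photosynthetic light-response model and per-curve fitting.

The model expresses net photosynthesis ``P_N`` (µmol CO2 m⁻² s⁻¹) as a
saturating exponential function of photosynthetic photon flux density ``I``
(µmol photons m⁻² s⁻¹):

    P_N(I) = Pgmax * (1 - exp(-phi0 * I / Pgmax)) - Rd

with three parameters: ``Pgmax``, the asymptotic maximum gross assimilation
rate; ``Rd``, the dark respiration rate (stored as a positive magnitude and
subtracted); and ``phi0``, the apparent quantum yield at I = 0 (the initial
slope of the curve). Gross photosynthesis is ``Pg = P_N + Rd``, which is zero
in darkness and approaches ``Pgmax`` under saturating light.

Curves are fitted individually (one curve, one parameter triple); any
averaging across curves happens downstream on the derived assimilation
series, not on the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError

__all__ = [
    "LRCParams",
    "GasExchangeCurve",
    "predict_net_photosynthesis",
    "gross_photosynthesis",
    "fit_lrc",
]

#: Default optimizer bounds (pgmax, rd, phi0) in µmol-based curve units.
#: They bracket the physiological range for temperate-tree foliage and keep
#: the optimizer away from degenerate parameter regions.
DEFAULT_BOUNDS = ((1e-6, 0.0, 1e-6), (100.0, 20.0, 0.2))


@dataclass
class LRCParams:
    """Fitted (or true) parameter triple of the exponential light-response model.

    Attributes
    ----------
    pgmax : float
        Maximum gross assimilation rate, µmol CO2 m⁻² s⁻¹. Must be > 0.
    rd : float
        Dark respiration rate as a positive magnitude, µmol CO2 m⁻² s⁻¹.
    phi0 : float
        Quantum yield at I = 0, µmol CO2 µmol photon⁻¹. Must be > 0.
    rss : float
        Residual sum of squares of the fit (NaN for parameters not obtained
        by fitting).
    converged : bool
        Whether the optimizer reported convergence.
    """

    pgmax: float
    rd: float
    phi0: float
    rss: float = float("nan")
    converged: bool = True

    def validate(self) -> "LRCParams":
        if not (self.pgmax > 0):
            raise ValueError(f"pgmax must be > 0, got {self.pgmax}")
        if self.rd < 0:
            raise ValueError(f"rd must be >= 0 (positive magnitude), got {self.rd}")
        if not (self.phi0 > 0):
            raise ValueError(f"phi0 must be > 0, got {self.phi0}")
        return self


@dataclass
class GasExchangeCurve:
    """One measured light-response curve: paired (I, P_N) observations."""

    ppfd: np.ndarray
    pn: np.ndarray
    species: str = ""
    position: str = ""
    curve_id: str = ""

    def __post_init__(self) -> None:
        self.ppfd = np.asarray(self.ppfd, dtype=float)
        self.pn = np.asarray(self.pn, dtype=float)
        if self.ppfd.shape != self.pn.shape:
            raise ValueError("ppfd and pn must have the same length")
        if np.any(self.ppfd < 0):
            raise ValueError("light levels must be nonnegative")

    def __len__(self) -> int:
        return self.ppfd.size


def _check_light(I):
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("PPFD must be nonnegative")
    return I


def predict_net_photosynthesis(I, params: LRCParams):
    """Net photosynthesis P_N(I) of the exponential light-response model.

    Continuous and strictly increasing in ``I`` (for phi0 > 0), equal to
    ``-Rd`` at I = 0 and bounded above by ``Pgmax - Rd``.
    """
    I = _check_light(I)
    out = params.pgmax * (1.0 - np.exp(-params.phi0 * I / params.pgmax)) - params.rd
    return float(out) if np.isscalar(I) or out.ndim == 0 else out


def gross_photosynthesis(I, params: LRCParams):
    """Gross photosynthesis Pg(I) = P_N(I) + Rd; zero at I = 0, < Pgmax."""
    I = _check_light(I)
    out = params.pgmax * (1.0 - np.exp(-params.phi0 * I / params.pgmax))
    return float(out) if np.isscalar(I) or out.ndim == 0 else out


def _initial_guess(I: np.ndarray, pn: np.ndarray, bounds) -> np.ndarray:
    lo, hi = bounds
    rd0 = max(-float(pn.min()), 1e-3)
    pg0 = max(float(pn.max()) + rd0, 1e-2)
    # slope of the two lowest-light observations approximates phi0
    order = np.argsort(I)
    i_lo, pn_lo = I[order], pn[order]
    dI = i_lo[1] - i_lo[0]
    phi0 = (pn_lo[1] - pn_lo[0]) / dI if dI > 0 else 0.05
    guess = np.array([pg0, rd0, phi0])
    return np.clip(guess, np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9)


def fit_lrc(curve: GasExchangeCurve, bounds=DEFAULT_BOUNDS) -> LRCParams:
    """Fit the exponential light-response model to one curve.

    Nonlinear least squares (trust-region reflective) on the residuals of
    P_N; requires at least 3 observations spanning at least 2 distinct
    light levels. Non-convergence is reported through the ``converged``
    flag on the result, never silently.

    Raises
    ------
    FitError
        Fewer than 3 observations, or all observations at one light level.
    """
    I, pn = curve.ppfd, curve.pn
    if len(curve) < 3:
        raise FitError(
            f"curve {curve.curve_id!r}: need >= 3 observations, got {len(curve)}"
        )
    if np.unique(I).size < 2:
        raise FitError(
            f"curve {curve.curve_id!r}: all observations at a single light level; "
            "parameters are unidentifiable"
        )

    def residuals(p):
        pg, rd, phi = p
        return pg * (1.0 - np.exp(-phi * I / pg)) - rd - pn

    res = least_squares(
        residuals,
        _initial_guess(I, pn, bounds),
        bounds=bounds,
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )
    return LRCParams(
        pgmax=float(res.x[0]),
        rd=float(res.x[1]),
        phi0=float(res.x[2]),
        rss=float(np.sum(res.fun**2)),
        converged=bool(res.success),
    )
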