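"""Dose-response and assay metrics: 4PL EC50 fitting, GR values, OxD.

Three quantitative readouts used throughout the cell-panel work:

* ``fit_4pl`` — the "log(inhibitor) versus response, variable slope"
  four-parameter logistic, the model behind every EC50 reported here:

      v(c) = bottom + (top - bottom) / (1 + 10^(hill * (log10 c - log10 EC50)))

  With hill > 0 viability decreases with concentration and v(EC50) is the
  midpoint (top + bottom) / 2.

* ``compute_gr`` — the normalized growth-rate inhibition value
  GR = 2^(log2(x_c/x0) / log2(x_ctrl/x0)) - 1 computed from nuclei counts:
  1 means uninhibited growth, 0 cytostatic, negative cytotoxic.

* ``compute_oxd`` — degree of oxidation of a ratiometric redox probe,
  two-point normalized between the fully reduced (DTT) and fully oxidized
  (diamide) control ratios and clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseCurve",
    "FourPLFit",
    "GRInput",
    "OxDTrace",
    "four_pl",
    "fit_4pl",
    "compute_gr",
    "compute_oxd",
    "NoDoseResponseError",
]


class NoDoseResponseError(ValueError):
    """Raised when the viability data carry no dose-dependent signal."""


@dataclass
class DoseResponseCurve:
    """Viability (%) per replicate at each concentration (µM, > 0).

    ``viability`` has shape (n_concentrations, n_replicates); a single
    replicate may be passed as a 1-D array.
    """

    concentrations: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.atleast_2d(np.asarray(self.viability, dtype=float))
        if self.viability.shape[0] != self.concentrations.size:
            self.viability = self.viability.T
        if self.viability.shape[0] != self.concentrations.size:
            raise ValueError("viability rows must match concentrations")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")


@dataclass
class FourPLFit:
    """Result of a 4PL fit; EC50 in the input concentration units."""

    ec50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.top < self.bottom:
            raise ValueError("top must be >= bottom")

    def predict(self, concentrations: np.ndarray) -> np.ndarray:
        return four_pl(np.asarray(concentrations, float), self.ec50, self.hill,
                       self.top, self.bottom)


def four_pl(c: np.ndarray, ec50: float, hill: float, top: float, bottom: float) -> np.ndarray:
    """Evaluate the four-parameter logistic at concentrations ``c``."""
    logc = np.log10(np.asarray(c, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - np.log10(ec50))))


def fit_4pl(curve: DoseResponseCurve, bounds: tuple[float, float] | None = None,
            flat_tol: float = 1e-6) -> FourPLFit:
    """Least-squares 4PL fit of a dose-response curve.

    Initialization: top/bottom from the max/min of the per-concentration
    mean viability, EC50 from the concentration whose mean response is
    nearest the half-range, hill = 1. EC50 is constrained to
    [min c / 100, max c × 100] unless ``bounds`` overrides it. Data whose
    mean-viability range is below ``flat_tol`` raise
    :class:`NoDoseResponseError` ("no dose response"). If the optimizer
    stops without convergence the best-found parameters are returned with
    ``converged=False``.
    """
    c = curve.concentrations
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations to fit")
    mean_v = np.nanmean(curve.viability, axis=1)
    if np.ptp(mean_v) < flat_tol:
        raise NoDoseResponseError("no dose response")

    top0, bot0 = float(np.max(mean_v)), float(np.min(mean_v))
    half = (top0 + bot0) / 2.0
    ec50_0 = float(c[np.argmin(np.abs(mean_v - half))])
    if bounds is None:
        lo, hi = float(np.min(c)) / 100.0, float(np.max(c)) * 100.0
    else:
        lo, hi = bounds
    ec50_0 = float(np.clip(ec50_0, lo, hi))

    # replicate-expanded observations
    n_rep = curve.viability.shape[1]
    logc = np.repeat(np.log10(c), n_rep)
    v = curve.viability.ravel()
    ok = np.isfinite(v)
    logc, v = logc[ok], v[ok]

    span = max(top0 - bot0, 1.0)

    def resid(theta: np.ndarray) -> np.ndarray:
        log_ec50, hill, top, bottom = theta
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ec50))) - v

    x0 = np.array([np.log10(ec50_0), 1.0, top0, bot0])
    lb = np.array([np.log10(lo), -20.0, bot0 - 5 * span, bot0 - 5 * span])
    ub = np.array([np.log10(hi), 20.0, top0 + 5 * span, top0 + 5 * span])
    sol = least_squares(resid, x0, bounds=(lb, ub), method="trf", max_nfev=2000)

    log_ec50, hill, top, bottom = sol.x
    if top < bottom:
        # the two orderings parameterize the same curve
        top, bottom, hill = bottom, top, -hill
    return FourPLFit(
        ec50=float(10.0 ** log_ec50),
        hill=float(hill),
        top=float(top),
        bottom=float(bottom),
        rss=float(2.0 * sol.cost),
        converged=bool(sol.status > 0),
    )


@dataclass
class GRInput:
    """Nuclei counts: treated x_c, control x_ctrl, day-0 x0 (all > 0)."""

    x_c: float
    x_ctrl: float
    x0: float

    def __post_init__(self) -> None:
        if min(self.x_c, self.x_ctrl, self.x0) <= 0:
            raise ValueError("nuclei counts must be strictly positive")
        if self.x_ctrl == self.x0:
            raise ValueError("x_ctrl must differ from x0")


def compute_gr(g: GRInput) -> float:
    """GR = 2^(log2(x_c/x0) / log2(x_ctrl/x0)) - 1.

    Requires a growing control (x_ctrl > x0). GR is 1 when the treated
    wells match the control, 0 when they match the day-0 count, and
    negative when cells were killed below the starting count.
    """
    if g.x_ctrl <= g.x0:
        raise ValueError("control did not grow")
    k = np.log2(g.x_c / g.x0) / np.log2(g.x_ctrl / g.x0)
    return float(2.0 ** k - 1.0)


@dataclass
class OxDTrace:
    """Probe ratio per timepoint plus fully-reduced / fully-oxidized controls."""

    r: np.ndarray
    r_red: float
    r_ox: float

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r_ox == self.r_red:
            raise ValueError("oxidized and reduced control ratios must differ")


def compute_oxd(t: OxDTrace) -> np.ndarray:
    """Two-point normalized degree of oxidation, clipped to [0, 1].

    OxD = (r - r_red) / (r_ox - r_red); the reduced control maps to 0 and
    the oxidized control to 1.
    """
    oxd = (t.r - t.r_red) / (t.r_ox - t.r_red)
    return np.clip(oxd, 0.0, 1.0)
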