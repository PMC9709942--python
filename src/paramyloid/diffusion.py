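"""Pulsed-field-gradient diffusion analysis and two-state binding fits.

A PFG-NMR experiment attenuates signal intensity according to the
Stejskal-Tanner law ``I(g) = I0 exp(-D b(g))`` with
``b = (gamma g delta)^2 (Delta - delta/3)``, giving the translational
diffusion coefficient ``D``.  Stokes-Einstein converts ``D`` to a
hydrodynamic radius.  Because the printed radius convention of any one
study depends on its (usually unstated) viscosity reference, the module
supports calibrating an *effective* viscosity from a reference (D, R_h)
pair, after which only ratios of radii are convention-free.

Metal-ion binding to a disordered peptide produces a fast-exchange
population-weighted diffusion coefficient.  With a bound state more
compact than the free peptide, ``D_obs/D_free = 1 + p_B (D_B/D_free - 1)``;
a global fit across metal titrations shares one ``D_B/D_free`` and a
linear bound population ``p_B = c_metal * ratio`` per metal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import Boltzmann
from scipy.optimize import least_squares

__all__ = [
    "DiffusionDataset",
    "DiffusionFit",
    "TwoStateFit",
    "GAMMA_H",
    "fit_diffusion",
    "hydrodynamic_radius",
    "effective_viscosity",
    "two_state_global_fit",
]

GAMMA_H = 2.6752218744e8  # 1H gyromagnetic ratio, rad s^-1 T^-1


@dataclass
class DiffusionDataset:
    """One PFG gradient-decay series at a fixed metal:peptide ratio."""

    gradients: np.ndarray  # T/m (or arbitrary linear units with calibration)
    intensities: np.ndarray
    delta: float = 5.0e-3  # gradient pulse length, s
    big_delta: float = 150.0e-3  # diffusion time, s
    temperature: float = 281.0  # K
    metal: str = "none"  # none | Cu | Zn | Ag
    ratio: float = 0.0  # metal:peptide molar ratio
    gradient_calibration: float = 1.0  # multiply gradients to get T/m

    def __post_init__(self) -> None:
        self.gradients = np.asarray(self.gradients, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.gradients.size < 8:
            raise ValueError("diffusion dataset needs >= 8 gradient points")
        if np.any(self.intensities <= 0):
            raise ValueError("intensities must be positive")

    def b_values(self) -> np.ndarray:
        g = self.gradients * self.gradient_calibration
        return (GAMMA_H * g * self.delta) ** 2 * (self.big_delta - self.delta / 3.0)


@dataclass
class DiffusionFit:
    """Fitted translational diffusion coefficient (m^2/s)."""

    d: float
    error: float
    i0: float
    poor_fit: bool = False


def fit_diffusion(ds: DiffusionDataset) -> DiffusionFit:
    """Log-linear Stejskal-Tanner fit: ln I against b(g).

    The slope of the weighted linear regression is ``-D``; the fitted
    intercept is the zero-gradient amplitude.  A non-monotone
    attenuation well beyond the residual scatter sets ``poor_fit``.
    """
    b = ds.b_values()
    ln_i = np.log(ds.intensities)
    coef, cov = np.polyfit(b, ln_i, 1, cov=True)
    d = -float(coef[0])
    err = float(np.sqrt(cov[0, 0]))
    i0 = float(np.exp(coef[1]))

    resid = ln_i - np.polyval(coef, b)
    # robust scatter so a single outlier cannot mask itself
    scatter = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    order = np.argsort(b)
    rises = np.diff(ln_i[order])
    poor = bool(np.any(rises > 5.0 * scatter + 1e-9)) and d > 0
    return DiffusionFit(d=d, error=err, i0=i0, poor_fit=poor)


def hydrodynamic_radius(d: float, temperature: float, viscosity: float) -> float:
    """Stokes-Einstein radius R_h = k_B T / (6 pi eta D), in Angstrom."""
    if d <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("diffusion coefficient, temperature and viscosity must be > 0")
    return Boltzmann * temperature / (6.0 * np.pi * viscosity * d) * 1.0e10


def effective_viscosity(d_ref: float, rh_ref_angstrom: float, temperature: float) -> float:
    """Solve Stokes-Einstein for the effective viscosity (Pa s) of a reference pair."""
    if d_ref <= 0 or rh_ref_angstrom <= 0 or temperature <= 0:
        raise ValueError("reference values must be > 0")
    return Boltzmann * temperature / (6.0 * np.pi * d_ref * rh_ref_angstrom * 1.0e-10)


@dataclass
class TwoStateFit:
    """Global two-state (free/bound) fit across metal titrations."""

    db_over_dfree: float
    d_free: dict  # metal -> D_free (m^2/s)
    slopes: dict  # metal -> d p_B / d ratio
    p_b: dict  # metal -> array of bound populations per titration point
    flagged: list  # (metal, ratio) points with p_B outside [0, 1]
    chi2: float


def two_state_global_fit(series: dict, anchor: str | None = None) -> TwoStateFit:
    """Fit D(ratio) for several metals with one shared D_B/D_free.

    Parameters
    ----------
    series : dict
        ``metal -> (ratios, d_values)`` arrays.  Every series must
        include the ratio-0 anchor that pins its own ``D_free``.
    anchor : str, optional
        Metal whose titration is stoichiometric (bound population equals
        the metal:peptide ratio, slope fixed at 1).  Defaults to ``"Cu"``
        when present, else the metal with the strongest relative response.

    The model is ``D = D_free (1 + c ratio (D_B/D_free - 1))`` with a
    per-metal free-state coefficient ``D_free``, per-metal population
    slope ``c`` and the shared bound/free ratio.  Because only the
    product ``c (D_B/D_free - 1)`` enters each series, the shared ratio
    is identifiable only through the anchor series: at NMR
    concentrations (tens of uM peptide, sub-uM dissociation constant)
    the strongest binder titrates stoichiometrically, pinning its slope
    to 1.  Residuals are relative (scaled by the per-metal D_free) so
    the shared ratio is invariant under rescaling any one series.
    """
    metals = sorted(series)
    prepared = {}
    response = {}
    for metal in metals:
        ratios, dvals = series[metal]
        ratios = np.asarray(ratios, dtype=float)
        dvals = np.asarray(dvals, dtype=float)
        if not np.any(ratios == 0):
            raise ValueError(f"series {metal!r} lacks the ratio-0 anchor")
        prepared[metal] = (ratios, dvals)
        d0 = dvals[ratios == 0].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            slopes = (dvals / d0 - 1.0)[ratios > 0] / ratios[ratios > 0]
        response[metal] = float(np.mean(slopes)) if slopes.size else 0.0

    if anchor is None:
        anchor = "Cu" if "Cu" in metals else max(metals, key=lambda m: response[m])
    if anchor not in metals:
        raise ValueError(f"anchor metal {anchor!r} not among series {metals}")

    # parameters: log(d_ratio - 1), then per metal d_free and (non-anchor) slope
    x0 = [np.log(max(response[anchor], 1e-3))]
    for metal in metals:
        ratios, dvals = prepared[metal]
        x0.append(np.log(dvals[ratios == 0].mean()))
        if metal != anchor:
            x0.append(min(max(response[metal] / max(response[anchor], 1e-12), 0.1), 1.0))

    def unpack(x):
        d_ratio = 1.0 + np.exp(x[0])
        per = {}
        i = 1
        for metal in metals:
            dfree = np.exp(x[i])
            i += 1
            if metal == anchor:
                slope = 1.0
            else:
                slope = x[i]
                i += 1
            per[metal] = (dfree, slope)
        return d_ratio, per

    def resid(x):
        d_ratio, per = unpack(x)
        out = []
        for metal in metals:
            ratios, dvals = prepared[metal]
            dfree, slope = per[metal]
            model = dfree * (1.0 + slope * ratios * (d_ratio - 1.0))
            out.append((model - dvals) / dfree)
        return np.concatenate(out)

    sol = least_squares(resid, x0, method="lm", max_nfev=20000)
    d_ratio, per = unpack(sol.x)

    d_free, slopes, p_b, flagged = {}, {}, {}, []
    for metal in metals:
        ratios, _ = prepared[metal]
        dfree, slope = per[metal]
        d_free[metal] = float(dfree)
        slopes[metal] = float(slope)
        pb = slope * ratios
        p_b[metal] = pb
        for r, p in zip(ratios, pb):
            if not (0.0 <= p <= 1.0):
                flagged.append((metal, float(r)))
    chi2 = float(np.sum(resid(sol.x) ** 2))
    return TwoStateFit(
        db_over_dfree=float(d_ratio),
        d_free=d_free,
        slopes=slopes,
        p_b=p_b,
        flagged=flagged,
        chi2=chi2,
    )
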