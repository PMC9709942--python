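"""Nucleation-elongation model of amyloid aggregation.

The model tracks the first two moments of the fibril length distribution:
the fibril number concentration ``P`` and the fibril mass concentration
``M``, fed by primary nucleation from monomers (rate constant ``k_n``,
reaction order ``n_c``), fibril-surface-catalysed secondary nucleation
(``k_2``, order ``n_2``) and monomer addition at fibril ends (``k_plus``)::

    dP/dt = k_n * m**n_c + k_2 * m**n_2 * M
    dM/dt = 2 * k_plus * m * P
    dm/dt = -dM/dt

with ``m`` the free monomer concentration.  All concentrations are molar
and times are seconds internally.

Two routes to the normalized fibril mass ``alpha(t) = M(t)/m_tot`` are
provided: direct stiff integration of the moment equations
(:func:`solve_moment_odes`, the numerical oracle) and the closed-form
fixed-point solution of the secondary-nucleation-dominated model
(:func:`fibril_mass_closed_form`), which is what curve fitting uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

__all__ = [
    "KineticParameters",
    "InitialState",
    "Trajectory",
    "NucleationProfile",
    "SigmoidFit",
    "IntegrationError",
    "NoTransitionError",
    "solve_moment_odes",
    "fibril_mass_closed_form",
    "extract_halftime",
    "nucleation_rate_profile",
]


class IntegrationError(RuntimeError):
    """Raised when the moment-ODE solver leaves the finite domain."""


class NoTransitionError(ValueError):
    """Raised when a trace shows no detectable sigmoidal transition."""


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and reaction orders of the nucleation model.

    Parameters
    ----------
    k_n : float
        Primary nucleation rate constant, M**(1-n_c) s**-1.
    k_2 : float
        Secondary nucleation rate constant, M**(-n_2) s**-1.
    k_plus : float
        Fibril-end elongation rate constant, M**-1 s**-1.
    n_c : float
        Primary nucleation reaction order (>= 1). Default 2.
    n_2 : float
        Secondary nucleation reaction order (>= 0). Default 2.
    """

    k_n: float
    k_2: float
    k_plus: float
    n_c: float = 2.0
    n_2: float = 2.0

    def __post_init__(self) -> None:
        if self.k_n < 0 or self.k_2 < 0 or self.k_plus < 0:
            raise ValueError("rate constants must be >= 0")
        if self.n_c < 1:
            raise ValueError("primary reaction order n_c must be >= 1")
        if self.n_2 < 0:
            raise ValueError("secondary reaction order n_2 must be >= 0")

    def lam(self, m0: float) -> float:
        """Primary-pathway composite rate lambda = sqrt(2 k+ k_n m0^n_c), s^-1."""
        return float(np.sqrt(2.0 * self.k_plus * self.k_n * m0**self.n_c))

    def kappa(self, m0: float) -> float:
        """Secondary-pathway composite rate kappa = sqrt(2 k+ k_2 m0^(n_2+1)), s^-1."""
        return float(np.sqrt(2.0 * self.k_plus * self.k_2 * m0 ** (self.n_2 + 1.0)))


@dataclass(frozen=True)
class InitialState:
    """Initial monomer, seed-number and seed-mass concentrations (M)."""

    m0: float
    P0: float = 0.0
    M0: float = 0.0

    def __post_init__(self) -> None:
        if self.m0 <= 0:
            raise ValueError("initial monomer concentration m0 must be > 0")
        if self.P0 < 0 or self.M0 < 0:
            raise ValueError("seed concentrations must be >= 0")

    @property
    def m_tot(self) -> float:
        """Total peptide mass concentration m0 + M0 (M)."""
        return self.m0 + self.M0


@dataclass
class Trajectory:
    """Time course of monomer, fibril number/mass and normalized mass."""

    t: np.ndarray
    m: np.ndarray
    P: np.ndarray
    M: np.ndarray
    alpha: np.ndarray
    params: KineticParameters | None = None
    init: InitialState | None = None
    closed_form_valid: bool = True

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.t, "m_M": self.m, "P_M": self.P,
             "M_M": self.M, "alpha": self.alpha}
        )


@dataclass
class NucleationProfile:
    """Nucleation rate r_n(t) and its cumulative integral (new nucleation units)."""

    t: np.ndarray
    r_n: np.ndarray
    n_units: np.ndarray

    @property
    def total_units(self) -> float:
        return float(self.n_units[-1])


def _check_grid(t_grid: np.ndarray) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be 1-D with >= 2 points")
    if t[0] != 0.0:
        raise ValueError("time grid must start at 0")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return t


def solve_moment_odes(
    params: KineticParameters,
    init: InitialState,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the moment equations with a stiff-capable solver.

    This is the package's numerical oracle: the closed-form solution is
    always checked against it.  Near the growth transition the system is
    stiff (kappa-driven exponential amplification), hence BDF with tight
    tolerances (atol in molar).
    """
    t = _check_grid(t_grid)
    m_tot = init.m_tot

    def rhs(_t, y):
        m, P, M = y
        m = max(m, 0.0)
        r_prim = params.k_n * m**params.n_c
        r_sec = params.k_2 * m**params.n_2 * M
        dM = 2.0 * params.k_plus * m * P
        return (-dM, r_prim + r_sec, dM)

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        (init.m0, init.P0, init.M0),
        method="BDF",
        t_eval=t,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(
            f"moment-ODE integration failed for {params!r} / {init!r}: {sol.message}"
        )
    m, P, M = sol.y
    alpha = np.clip(M / m_tot, 0.0, None)
    return Trajectory(t=t, m=m, P=P, M=M, alpha=alpha, params=params, init=init)


def fibril_mass_closed_form(
    params: KineticParameters,
    init: InitialState,
    t_grid: np.ndarray,
    validity_threshold: float = 0.1,
) -> Trajectory:
    """Closed-form normalized fibril mass for the secondary-dominated model.

    Uses the fixed-point (self-consistent) solution of the model
    literature.  With ``kappa`` and ``lambda`` the composite secondary and
    primary rates::

        C_pm  = k_plus*P0/kappa +- lambda^2/(2 kappa^2) +- M0/(2 m_tot)
        k_inf = sqrt((2 k_plus P0)^2 + 2 kappa^2/(n_2 (n_2+1)) + 2 lambda^2/n_c)
        k_bar = sqrt(k_inf^2 - 4 C_+ C_- kappa^2)
        B_pm  = (k_inf +- k_bar)/(2 kappa)
        alpha = 1 - ((B+ + C+)(B- + C+ e^{kappa t}) /
                     ((B- + C+)(B+ + C+ e^{kappa t})))^{k_inf^2/(kappa k_bar)}
                    e^{-k_inf t}

    validated against :func:`solve_moment_odes` to 2 % absolute in the
    secondary-nucleation-dominated, at most lightly seeded regime
    (``lambda/kappa``, ``2 k_plus P0/kappa`` and ``M0/m_tot`` all below
    ``validity_threshold``).  Outside that regime the result carries
    ``closed_form_valid=False`` and a warning, not an exception.
    """
    t = _check_grid(t_grid)
    m0, P0, M0 = init.m0, init.P0, init.M0
    m_tot = init.m_tot

    lam = params.lam(m0)
    kap = params.kappa(m0)

    valid = True
    seed_rate = 2.0 * params.k_plus * P0
    if kap == 0.0 or (lam > 0 and lam / kap > validity_threshold) or (
        kap > 0 and (seed_rate / kap > validity_threshold or M0 / m_tot > validity_threshold)
    ):
        valid = False
        warnings.warn(
            "closed-form solution used outside its secondary-nucleation-"
            f"dominated regime (lambda/kappa = {lam / kap if kap else np.inf:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )

    if kap == 0.0:
        # no secondary pathway: fall back to the ODE oracle
        traj = solve_moment_odes(params, init, t)
        traj.closed_form_valid = False
        return traj

    # seeded/unseeded fixed-point solution
    cp = params.k_plus * P0 / kap + lam**2 / (2.0 * kap**2) + M0 / (2.0 * m_tot)
    cm = params.k_plus * P0 / kap - lam**2 / (2.0 * kap**2) - M0 / (2.0 * m_tot)
    k_inf = np.sqrt(
        (2.0 * params.k_plus * P0) ** 2
        + 2.0 * kap**2 / (params.n_2 * (params.n_2 + 1.0))
        + 2.0 * lam**2 / params.n_c
    )
    k_bar = np.sqrt(k_inf**2 - 4.0 * cp * cm * kap**2)
    bp = (k_inf + k_bar) / (2.0 * kap)
    bm = (k_inf - k_bar) / (2.0 * kap)

    with np.errstate(over="ignore"):
        ekt = np.exp(np.minimum(kap * t, 700.0))
        frac = (bp + cp) * (bm + cp * ekt) / ((bm + cp) * (bp + cp * ekt))
        alpha = 1.0 - frac ** (k_inf**2 / (kap * k_bar)) * np.exp(-k_inf * t)

    alpha = np.clip(alpha, 0.0, 1.0)
    M = alpha * m_tot
    m = m_tot - M
    # P is not part of the closed form; expose NaN to avoid silent misuse
    P = np.full_like(t, np.nan)
    traj = Trajectory(t=t, m=m, P=P, M=M, alpha=alpha, params=params, init=init)
    traj.closed_form_valid = valid
    return traj


@dataclass
class SigmoidFit:
    """Generalized-logistic fit report for a single aggregation trace."""

    tau_half: float
    baseline: float
    amplitude: float
    midpoint: float
    width: float

    def __iter__(self):
        yield self.tau_half
        yield self


def _logistic(t, baseline, amplitude, midpoint, width):
    return baseline + amplitude / (1.0 + np.exp(-(t - midpoint) / width))


def extract_halftime(t: np.ndarray, signal: np.ndarray) -> SigmoidFit:
    """Fit a logistic sigmoid and return the half-amplitude crossing time.

    The fitted form is ``base + amp / (1 + exp(-(t - t50)/w))`` with free
    baseline, amplitude, midpoint and width; ``tau_half`` is the time at
    which the fit crosses ``base + amp/2`` (the midpoint for this form).

    Raises
    ------
    NoTransitionError
        If the trace is flat (amplitude indistinguishable from noise) or
        the sigmoid fit cannot converge.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.size < 10:
        raise ValueError("need >= 10 points spanning baseline and plateau")

    amp0 = y.max() - y.min()
    noise = np.std(np.diff(y)) / np.sqrt(2.0) if y.size > 3 else 0.0
    if amp0 <= 0 or (noise > 0 and amp0 < 5.0 * noise):
        raise NoTransitionError("no sigmoidal transition detectable (flat trace)")

    mid0 = t[np.argmin(np.abs(y - (y.min() + amp0 / 2.0)))]
    width0 = max((t[-1] - t[0]) / 20.0, np.finfo(float).tiny)
    try:
        popt, _ = curve_fit(
            _logistic,
            t,
            y,
            p0=(y.min(), amp0, mid0, width0),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological traces
        raise NoTransitionError(f"sigmoid fit failed: {exc}") from exc
    baseline, amplitude, midpoint, width = popt
    resid_sd = float(np.std(y - _logistic(t, *popt)))
    if amplitude <= 0 or amplitude < 5.0 * resid_sd:
        raise NoTransitionError("no sigmoidal transition detectable (flat trace)")
    if not (t[0] - (t[-1] - t[0]) <= midpoint <= t[-1] + (t[-1] - t[0])):
        raise NoTransitionError("sigmoid fit did not locate a transition in range")
    return SigmoidFit(
        tau_half=float(midpoint),
        baseline=float(baseline),
        amplitude=float(amplitude),
        midpoint=float(midpoint),
        width=float(width),
    )


def nucleation_rate_profile(
    params: KineticParameters, traj: Trajectory
) -> NucleationProfile:
    """Nucleation rate r_n(t) = k_n m^n_c + k_2 m^n_2 M along a trajectory.

    The cumulative trapezoidal integral of ``r_n`` counts the new
    nucleation units (an estimate of low-molecular-weight oligomers)
    generated over the reaction.
    """
    if traj.params is not None and traj.init is not None:
        # guard against profiles computed for a different monomer pool
        if not np.isclose(traj.m[0] + traj.M[0], traj.init.m_tot, rtol=1e-6):
            raise ValueError("trajectory initial state inconsistent with its metadata")
    r_n = params.k_n * np.clip(traj.m, 0.0, None) ** params.n_c
    r_n = r_n + params.k_2 * np.clip(traj.m, 0.0, None) ** params.n_2 * traj.M
    n_units = np.concatenate(
        ([0.0], np.cumsum(0.5 * (r_n[1:] + r_n[:-1]) * np.diff(traj.t)))
    )
    return NucleationProfile(t=traj.t, r_n=r_n, n_units=n_units)
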