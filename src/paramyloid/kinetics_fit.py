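"""Fitting the nucleation model to aggregation traces.

Three complementary analyses of dye-monitored aggregation kinetics,
mirroring how metal-ion perturbations of amyloid assembly are dissected:

1. **Individual fits** of each trace with the two combined rate
   constants ``k_n*k_plus`` and ``k_plus*k_2`` free — a first look at
   which pathway a perturbant modulates.
2. **Constrained global fits** in which the constants of the
   metal-free condition are held fixed and a single rate constant
   (``k_n``, ``k_2`` or ``k_plus``) is allowed to vary with metal
   concentration; comparing the three global chi^2 values selects the
   perturbed step.
3. **Seeded initial-slope analysis**: under heavy seeding the initial
   signal slope is proportional to the elongation rate constant, giving
   a model-free readout of ``k_plus``.

The reduction of the relative elongation rate with metal:peptide ratio
is finally interpreted with a monomer-sequestration binding model,
yielding an apparent dissociation constant ``K_D``, and the fitted rate
constants feed a nucleation-rate integral that predicts the change in
oligomer generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .kinetics_model import (
    InitialState,
    KineticParameters,
    Trajectory,
    extract_halftime,
    fibril_mass_closed_form,
    nucleation_rate_profile,
    solve_moment_odes,
)

__all__ = [
    "AggregationTrace",
    "CombinedConstants",
    "GlobalFitResult",
    "KdFitResult",
    "normalize_trace",
    "fit_individual",
    "fit_global_single_free",
    "select_free_constant",
    "seeded_elongation_rate",
    "relative_elongation_rates",
    "free_monomer_fraction",
    "fit_kd_from_elongation",
    "oligomer_fold_change",
]

FREE_CONSTANTS = ("k_n", "k_2", "k_plus")


@dataclass
class AggregationTrace:
    """One well's aggregation time course with its condition metadata."""

    t: np.ndarray
    signal: np.ndarray
    cu_conc: float
    ab_conc: float
    dye: str = "ThT"
    seeded: bool = False
    seed_mass: float = 0.0
    replicate: int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.t.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trace time must be strictly increasing")


def normalize_trace(trace: AggregationTrace) -> AggregationTrace:
    """Min-max normalize using the fitted sigmoid baseline and plateau.

    The final dye amplitude carries quenching and morphology effects and
    is deliberately discarded: only the normalized shape enters the
    kinetic fits.
    """
    fit = extract_halftime(trace.t, trace.signal)
    y = (trace.signal - fit.baseline) / fit.amplitude
    return AggregationTrace(
        t=trace.t,
        signal=y,
        cu_conc=trace.cu_conc,
        ab_conc=trace.ab_conc,
        dye=trace.dye,
        seeded=trace.seeded,
        seed_mass=trace.seed_mass,
        replicate=trace.replicate,
        normalized=True,
    )


def _group_by_condition(traces):
    groups: dict[float, list[AggregationTrace]] = {}
    for tr in traces:
        groups.setdefault(float(tr.cu_conc), []).append(tr)
    return dict(sorted(groups.items()))


def _average_condition(group):
    """Average replicate signals on the common grid; per-point std as weight."""
    t = group[0].t
    for tr in group[1:]:
        if tr.t.shape != t.shape or not np.allclose(tr.t, t):
            raise ValueError("replicates must share one time grid")
    ys = np.vstack([tr.signal for tr in group])
    mean = ys.mean(axis=0)
    std = ys.std(axis=0, ddof=1) if len(group) > 1 else None
    return t, mean, std


def _weights(std):
    if std is None:
        return None
    floor = np.max(std) * 1e-3 + np.finfo(float).tiny
    return 1.0 / np.clip(std, floor, None)


def _model_alpha(t, lam, kap, m0, n_c, n_2):
    """Closed-form alpha(t) for composite rates (lam, kap) at monomer m0."""
    if lam <= 0 or kap <= 0:
        raise ValueError("composite rates must be positive")
    # decompose into rate constants with an arbitrary k_plus: alpha depends
    # only on (lam, kap, n_c, n_2)
    k_plus = 1.0
    k_n = lam**2 / (2.0 * k_plus * m0**n_c)
    k_2 = kap**2 / (2.0 * k_plus * m0 ** (n_2 + 1.0))
    params = KineticParameters(k_n=k_n, k_2=k_2, k_plus=k_plus, n_c=n_c, n_2=n_2)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        traj = fibril_mass_closed_form(params, InitialState(m0=m0), t)
    return traj.alpha


def _chi2(resid, w):
    r = resid if w is None else resid * w
    return float(np.sum(r * r))


def _fit_lam_kappa(t, y, m0, n_c, n_2, w=None, lam0=None, kap0=None):
    """Least-squares fit of the two composite rates on one averaged trace."""
    if kap0 is None:
        # half-time sets the scale of kappa; lambda starts well below it
        try:
            tau = extract_halftime(t, y).tau_half
        except Exception:
            tau = t[len(t) // 2]
        kap0 = 5.0 / max(tau, t[1])
    if lam0 is None:
        lam0 = 0.02 * kap0

    def resid(logx):
        lam, kap = np.exp(logx)
        r = _model_alpha(t, lam, kap, m0, n_c, n_2) - y
        return r if w is None else r * w

    sol = least_squares(resid, np.log([lam0, kap0]), method="lm", max_nfev=4000)
    lam, kap = np.exp(sol.x)
    return lam, kap, _chi2(_model_alpha(t, lam, kap, m0, n_c, n_2) - y, w), sol.success


@dataclass
class CombinedConstants:
    """Per-trace combined rate constants from an individual fit."""

    cu_conc: float
    kn_kplus: float
    kplus_k2: float
    chi2: float
    converged: bool
    rel_kn_kplus: float = np.nan
    rel_kplus_k2: float = np.nan


def fit_individual(traces, n_c: float = 2.0, n_2: float = 2.0):
    """Fit each condition with both combined constants free.

    Traces are grouped by Cu concentration, replicates averaged, and the
    combined constants ``k_n*k_plus`` and ``k_plus*k_2`` fitted per
    condition.  Values are also reported relative to the Cu-free
    condition, which must be present for relative columns to be finite.
    Non-converged conditions are flagged but still returned.
    """
    groups = _group_by_condition(traces)
    out = []
    for cu, group in groups.items():
        t, y, std = _average_condition(group)
        m0 = group[0].ab_conc
        try:
            lam, kap, chi2, ok = _fit_lam_kappa(t, y, m0, n_c, n_2, _weights(std))
        except Exception:
            out.append(CombinedConstants(cu, np.nan, np.nan, np.nan, False))
            continue
        kn_kplus = lam**2 / (2.0 * m0**n_c)
        kplus_k2 = kap**2 / (2.0 * m0 ** (n_2 + 1.0))
        out.append(CombinedConstants(cu, kn_kplus, kplus_k2, chi2, ok))
    ref = next((c for c in out if c.cu_conc == 0.0 and c.converged), None)
    if ref is not None:
        for c in out:
            c.rel_kn_kplus = c.kn_kplus / ref.kn_kplus
            c.rel_kplus_k2 = c.kplus_k2 / ref.kplus_k2
    return out


@dataclass
class GlobalFitResult:
    """Constrained global fit with a single free rate constant."""

    free_constant: str
    cu_concs: np.ndarray
    rel_values: np.ndarray  # free constant relative to the Cu-free condition
    lam0: float
    kap0: float
    chi2_global: float
    chi2_per_condition: np.ndarray
    converged: np.ndarray
    ab_conc: float
    n_c: float = 2.0
    n_2: float = 2.0


def _scaled_rates(lam0, kap0, f, free_constant):
    if free_constant == "k_plus":
        return lam0 * np.sqrt(f), kap0 * np.sqrt(f)
    if free_constant == "k_n":
        return lam0 * np.sqrt(f), kap0
    if free_constant == "k_2":
        return lam0, kap0 * np.sqrt(f)
    raise ValueError(f"free_constant must be one of {FREE_CONSTANTS}, got {free_constant!r}")


def fit_global_single_free(traces, free_constant: str, n_c: float = 2.0, n_2: float = 2.0) -> GlobalFitResult:
    """Global fit with two constants fixed from the metal-free condition.

    The Cu-free averaged trace determines the shared composite rates
    (lambda_0, kappa_0).  For every other condition a single scale factor
    on the chosen constant is fitted; the summed weighted residual
    ``chi2_global`` is directly comparable across choices of the free
    constant because grids, weights and the fixed reference are shared.
    """
    if free_constant not in FREE_CONSTANTS:
        raise ValueError(f"free_constant must be one of {FREE_CONSTANTS}, got {free_constant!r}")
    groups = _group_by_condition(traces)
    if 0.0 not in groups:
        raise ValueError("global fit requires a Cu = 0 reference condition")
    if len(groups) < 3:
        raise ValueError("global fit requires >= 3 Cu conditions")

    m0 = traces[0].ab_conc
    t0, y0, std0 = _average_condition(groups[0.0])
    lam0, kap0, chi2_0, ok0 = _fit_lam_kappa(t0, y0, m0, n_c, n_2, _weights(std0))

    cu_concs, rel_values, chi2s, conv = [], [], [], []
    for cu, group in groups.items():
        t, y, std = _average_condition(group)
        w = _weights(std)
        if cu == 0.0:
            cu_concs.append(cu)
            rel_values.append(1.0)
            chi2s.append(chi2_0)
            conv.append(ok0)
            continue

        def resid(logf, _t=t, _y=y, _w=w):
            lam, kap = _scaled_rates(lam0, kap0, np.exp(logf[0]), free_constant)
            r = _model_alpha(_t, lam, kap, m0, n_c, n_2) - _y
            return r if _w is None else r * _w

        # initial guess from the half-time shift (kappa sets the time scale)
        try:
            f0 = (extract_halftime(t0, y0).tau_half / extract_halftime(t, y).tau_half) ** 2
        except Exception:
            f0 = 1.0
        sol = least_squares(resid, [np.log(max(f0, 1e-6))], method="lm", max_nfev=4000)
        f = float(np.exp(sol.x[0]))
        cu_concs.append(cu)
        rel_values.append(f)
        chi2s.append(_chi2(resid(sol.x) if w is None else resid(sol.x) / 1.0, None))
        conv.append(sol.success)

    return GlobalFitResult(
        free_constant=free_constant,
        cu_concs=np.asarray(cu_concs),
        rel_values=np.asarray(rel_values),
        lam0=lam0,
        kap0=kap0,
        chi2_global=float(np.sum(chi2s)),
        chi2_per_condition=np.asarray(chi2s),
        converged=np.asarray(conv, dtype=bool),
        ab_conc=m0,
        n_c=n_c,
        n_2=n_2,
    )


def select_free_constant(traces, n_c: float = 2.0, n_2: float = 2.0):
    """Run the three constrained global fits and rank by global chi^2.

    Returns ``(best_name, {name: GlobalFitResult})``.
    """
    fits = {c: fit_global_single_free(traces, c, n_c, n_2) for c in FREE_CONSTANTS}
    best = min(fits, key=lambda c: fits[c].chi2_global)
    return best, fits


def seeded_elongation_rate(
    trace: AggregationTrace,
    window: float = 9.0 * 60.0,
    burn_in: float = 60.0,
):
    """Initial slope of a highly seeded trace (proportional to k_plus).

    Linear fit over ``burn_in < t <= window`` (seconds); the first points
    are excluded as an equilibration phase.  Returns ``(slope, intercept)``
    in signal units per second.
    """
    if not trace.seeded:
        raise ValueError("seeded_elongation_rate requires a trace flagged seeded")
    mask = (trace.t > burn_in) & (trace.t <= window)
    if mask.sum() < 4:
        raise ValueError(
            f"insufficient data: only {int(mask.sum())} points in ({burn_in}, {window}] s"
        )
    slope, intercept = np.polyfit(trace.t[mask], trace.signal[mask], 1)
    return float(slope), float(intercept)


def relative_elongation_rates(traces, window: float = 9.0 * 60.0, burn_in: float = 60.0):
    """Slopes of seeded traces relative to the Cu-free condition.

    Returns ``(ratios, rel_rates)`` with ratios the Cu:peptide molar ratio.
    """
    groups = _group_by_condition(traces)
    if 0.0 not in groups:
        raise ValueError("relative rates require a Cu = 0 condition")
    slopes = {}
    for cu, group in groups.items():
        s = [seeded_elongation_rate(tr, window, burn_in)[0] for tr in group]
        slopes[cu] = float(np.mean(s))
    s0 = slopes[0.0]
    ratios = np.array([cu / groups[cu][0].ab_conc for cu in slopes])
    rel = np.array([slopes[cu] / s0 for cu in slopes])
    return ratios, rel


def free_monomer_fraction(ratio, ab_tot: float, kd: float):
    """Free-monomer fraction for 1:1 metal binding at total concentrations.

    Solves the binding quadratic for free peptide ``m``:
    ``m^2 + (K_D + Cu_tot - m_tot) m - K_D m_tot = 0`` (positive root),
    with ``Cu_tot = ratio * m_tot``.  Monomer sequestration predicts the
    relative elongation rate ``k_plus/k_plus0 = m/m_tot``.
    """
    ratio = np.asarray(ratio, dtype=float)
    cu = ratio * ab_tot
    b = kd + cu - ab_tot
    m_free = 0.5 * (-b + np.sqrt(b * b + 4.0 * kd * ab_tot))
    return m_free / ab_tot


@dataclass
class KdFitResult:
    """Apparent dissociation constant from monomer-sequestration fit."""

    kd_app: float | None
    kd_err: float
    kd_range: tuple
    ab_conc: float
    unbounded: bool = False

    def curve(self, ratios):
        if self.kd_app is None:
            return np.ones_like(np.asarray(ratios, dtype=float))
        return free_monomer_fraction(ratios, self.ab_conc, self.kd_app)


def _fit_kd_once(ratios, rel, ab_tot, sigma=None):
    def model(r, log_kd):
        return free_monomer_fraction(r, ab_tot, np.exp(log_kd))

    popt, _ = curve_fit(
        model, ratios, rel, p0=[np.log(ab_tot)], sigma=sigma,
        absolute_sigma=sigma is not None, maxfev=10000,
    )
    return float(np.exp(popt[0]))


def fit_kd_from_elongation(
    ratios,
    rel_rates,
    errors=None,
    ab_conc: float = 3.0e-6,
) -> KdFitResult:
    """Apparent K_D of metal-monomer binding from relative elongation rates.

    Central estimate from an unweighted least-squares fit of the
    sequestration model.  The error range is the spread between a refit
    on error-weighted data and a refit with the three largest-error
    points removed; when no per-point errors are supplied both
    side-fits degenerate to the central one and the error is 0.
    """
    ratios = np.asarray(ratios, dtype=float)
    rel = np.asarray(rel_rates, dtype=float)
    if ratios.shape != rel.shape:
        raise ValueError("ratios and rel_rates must have equal length")
    if np.any(ratios < 0):
        raise ValueError("ratios must be >= 0")

    # flat data: binding too weak to quantify
    if np.all(rel > 0.95):
        return KdFitResult(None, np.nan, (np.nan, np.nan), ab_conc, unbounded=True)

    kd = _fit_kd_once(ratios, rel, ab_conc)
    side = [kd]
    if errors is not None:
        errors = np.asarray(errors, dtype=float)
        side.append(_fit_kd_once(ratios, rel, ab_conc, sigma=np.clip(errors, 1e-6, None)))
        if ratios.size > 4:
            keep = np.argsort(errors)[:-3]
            side.append(_fit_kd_once(ratios[keep], rel[keep], ab_conc))
    lo, hi = float(np.min(side)), float(np.max(side))
    return KdFitResult(kd, (hi - lo) / 2.0, (lo, hi), ab_conc)


def oligomer_fold_change(
    fit: GlobalFitResult,
    init: InitialState,
    t_end: float | None = None,
    n_t: int = 800,
    use_ode: bool = False,
    k_plus_ref: float = 1.0,
):
    """Fold change of generated nucleation units per Cu condition.

    For each condition the rate constants implied by the global fit are
    instantiated (the arbitrary reference ``k_plus_ref`` cancels in the
    ratio), the reaction integrated to completion, and the integral of
    the nucleation rate divided by the Cu-free integral.  A reduction of
    the elongation rate alone slows monomer consumption and therefore
    *increases* the number of nucleation events before the monomer pool
    is exhausted — fold changes > 1.
    """
    m0 = init.m0
    kn0 = fit.lam0**2 / (2.0 * k_plus_ref * m0**fit.n_c)
    k20 = fit.kap0**2 / (2.0 * k_plus_ref * m0 ** (fit.n_2 + 1.0))

    folds, integrals = [], []
    for f, ok in zip(fit.rel_values, fit.converged):
        if not ok:
            folds.append(np.nan)
            integrals.append(np.nan)
            continue
        if fit.free_constant == "k_plus":
            params = KineticParameters(kn0, k20, k_plus_ref * f, fit.n_c, fit.n_2)
        elif fit.free_constant == "k_n":
            params = KineticParameters(kn0 * f, k20, k_plus_ref, fit.n_c, fit.n_2)
        else:
            params = KineticParameters(kn0, k20 * f, k_plus_ref, fit.n_c, fit.n_2)
        # integrate until monomers are exhausted for the slowest condition
        kap = params.kappa(m0)
        horizon = t_end if t_end is not None else 30.0 / max(kap, 1e-12)
        t = np.linspace(0.0, horizon, n_t)
        if use_ode:
            traj = solve_moment_odes(params, init, t)
        else:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore", RuntimeWarning)
                traj = fibril_mass_closed_form(params, init, t)
        prof = nucleation_rate_profile(params, traj)
        integrals.append(prof.total_units)
        folds.append(prof.total_units)
    integrals = np.asarray(integrals)
    i_ref = int(np.argmin(np.abs(fit.cu_concs)))
    return integrals / integrals[i_ref]
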