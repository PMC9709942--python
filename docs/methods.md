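# Methods

This note records the models implemented in `paramyloid`, their
assumptions, the defaults that matter, and the design choices made
where conventions in the field genuinely diverge.

## Aggregation kinetics

### Model

The nucleation–elongation model with monomer-dependent secondary
nucleation tracks the fibril number concentration `P` and fibril mass
concentration `M` (both molar, time in seconds):

    dP/dt = k_n m^{n_c} + k_2 m^{n_2} M
    dM/dt = 2 k_+ m P
    dm/dt = −dM/dt

Reaction orders default to `n_c = n_2 = 2`, the standard choice for Aβ
in the global-fitting literature; both are configurable. The model
assumes mass conservation (no off-pathway loss), no fragmentation, no
saturation of the secondary pathway, and no explicit oligomer
intermediates — those model families are out of scope.

Two solution routes are provided and continuously cross-checked:

* `solve_moment_odes` — BDF integration at `rtol 1e-8`, `atol 1e-12`
  (molar). The system is stiff near the growth transition because the
  composite rate κ = √(2 k₊ k₂ m₀^{n₂+1}) drives exponential
  amplification. This route is the package's numerical oracle.
* `fibril_mass_closed_form` — the fixed-point solution of the
  secondary-nucleation-dominated model,

      α(t) = 1 − [ (B₊+C₊)(B₋+C₊e^{κt}) / ((B₋+C₊)(B₊+C₊e^{κt})) ]^{k∞²/(κ·k̄∞)} · e^{−k∞ t}

  with λ = √(2 k₊ k_n m₀^{n_c}),
  C± = k₊P₀/κ ± λ²/(2κ²) ± M₀/(2 m_tot),
  k∞ = √((2k₊P₀)² + 2κ²/(n₂(n₂+1)) + 2λ²/n_c),
  k̄∞ = √(k∞² − 4C₊C₋κ²), B± = (k∞ ± k̄∞)/(2κ).

  Validity is flagged (not raised) when λ/κ, 2k₊P₀/κ or M₀/m_tot
  exceed 0.1; inside that regime the closed form agrees with the ODE
  oracle to better than 2 % absolute in α (tested over seeded random
  parameter draws). With κ = 0 the function falls back to the oracle.

### Fitting strategies

*Individual fits* expose the two combined constants `k_n·k_+` and
`k_+·k_2` (equivalently λ and κ) per condition. Note an algebraic
fact with practical consequences: both products are linear in `k_+`,
so a perturbation acting only on elongation moves both by the same
factor in a well-conditioned fit. Divergent behaviour of the two
products on experimental data reflects the shallow λ–κ likelihood
valley (the half-time depends on λ only logarithmically), not the
generating mechanism, which is why the constrained global fit — not
the individual fit — is the package's instrument for mechanism
assignment.

*Constrained global fits* determine (λ₀, κ₀) from the metal-free
condition, then fit one scale factor per condition on a single chosen
constant (`k_n`: λ² scales; `k_2`: κ² scales; `k_+`: both scale). The
global χ² (sum of weighted squared residuals, un-reduced; per-point
replicate standard deviations as weights when replicates exist) is
comparable across the three choices because grids, weights and the
reference are shared. Replicates are averaged after normalization.
Normalization is min–max via the fitted sigmoid baseline and
amplitude: the final dye amplitude carries Cu-dependent quenching and
morphology effects and is deliberately discarded.

*Seeded slopes*: under heavy seeding the initial signal slope is
`2 k₊ P₀ m₀/m_tot` per normalized signal unit, so slopes relative to
the metal-free condition read out `k₊/k₊⁰` without any model fit.
The linear fit uses the first 9 minutes, excluding a 1-minute burn-in
(both configurable). The window must satisfy two smallness conditions:
seed depletion `2k₊P₀·t ≲ 0.06` and secondary-nucleation contamination
`k₂ m² M₀ t/(2P₀) ≲ 0.1`. Their product is fixed by `k₊k₂ m² M₀ t²` —
a property of the assay, not of the seed number — so seeded assays are
only informative when the unseeded κ is slow on the scale of the fit
window. The synthetic generator's defaults respect this (below).

*Apparent K_D*: the relative elongation rate is fitted with the
monomer-sequestration law `k₊/k₊⁰ = m_free/m_tot`, `m_free` the
positive root of the 1:1 binding quadratic in total concentrations;
stoichiometry is fixed at 1:1 and the independent variable is the
Cu:peptide molar ratio. The error range is the spread between a refit
on error-weighted data and a refit with the three largest-error points
removed. If all relative rates stay near 1 the estimate is flagged
unbounded instead of returning a number.

*Oligomer generation*: the nucleation rate
`r_n(t) = k_n m^{n_c} + k_2 m^{n_2} M` is integrated (trapezoid) over
the full reaction; the per-condition integral divided by the metal-free
integral estimates the fold change in new nucleation units. The
decomposition of fitted products into absolute constants requires an
arbitrary reference `k_+`; the fold change is invariant to it (tested).
When only `k_+` varies, all conditions share the λ/κ shape, so the
closed-form and ODE routes agree on the fold change to numerical
precision; the 5 % tolerance in the tests covers the general case.

## Paramagnetic relaxation and restraints

Relaxation decays are fitted per nucleus: `A·exp(−R₁t) + c` for
longitudinal data, `A·exp(−R₂τ)·cos(πJτ)` for transverse data with the
HN–HA scalar coupling fixed to its published value (with `J = 0` the
model is a plain exponential). The transverse PRE is
`Γ₂ = R₂(para) − R₂(dia)` with errors propagated in quadrature;
negative differences are clipped to zero and flagged.

Distance conversion uses the Solomon dipolar expression with the
canonical constant

    Γ₂ = (1/15)(μ₀/4π)² γ_H² g² μ_B² S(S+1) · r⁻⁶ · [4J(0) + 3J(ω_H)],
    J(ω) = τ_c/(1 + (ωτ_c)²),   τ_c = (τ_r⁻¹ + τ_s⁻¹)⁻¹.

Defaults: 950 MHz proton frequency, τ_r = 2.56 ns, τ_s = 5.0 ns
(τ_c = 1.69 ns), g = 2.0023, S = 1/2. The prefactor equals the
standard 1.23·10⁻³² cm⁶ s⁻² of the PRE literature. Two conventions
deserve comment:

* The τ_c combination is implemented with the outer inverse
  (harmonic form); that is the only reading consistent with
  τ_c = 1.69 ns from the stated τ_r and τ_s.
* The electron g-factor is configurable because Cu(II) EPR g values
  run 2.1–2.2; the distance scales only as g^(1/3) (~3 % for g = 2.2).
* On this canonical convention, distances of 7.6–9.1 Å at 1.69 ns and
  950 MHz correspond to Γ₂ ≈ 150–440 s⁻¹ — i.e. hundreds, not tens,
  of s⁻¹. Conventions that would compress this into a 1–100 s⁻¹ band
  while preserving the distance window do not exist among documented
  normalizations; the package keeps the canonical constant and treats
  absolute Γ₂ magnitudes as convention-dependent.

Blind-sphere classification maps visibility patterns to bounds
(Å, nucleus → paramagnetic center): para-recovered amide protons
[6.5, 9.0]; para-recovered carbons [4.5, 9.0]; para-invisible nuclei
[2.5, 6.5] (the lower bound sits just above metal-contact distance,
since only the upper limit is physically dictated); assigned ligand
atoms [1.8, 2.3]; measured PREs r ± 0.5. Dia-visible nuclei without a
PRE get a lower bound of 9.0 Å, but only within the modeled N-terminal
segment (residues 1–23); beyond it they are reported unconstrained.
Precedence per nucleus: ligand > PRE > shell > para-invisible >
dia-visible. Restraints export to upper/lower-limit text files in a
torsion-angle-dynamics dialect (IUPAC/PDB v3 atom names, 1-based Aβ40
numbering, Cu as a pseudo-residue), byte-stable for fixed input order.

The bundled reference annotation table (`paramyloid.annotations`)
encodes the reported per-experiment visibility census for the
Cu(II)-bound Aβ40 monomer (42 para-derived nuclei). The individually
named entries follow the reported assignments; CaCO/CbCaCO entries
without printed identities are assigned to N-terminal residues
consistent with the per-experiment counts — the census and bound
classes do not depend on those identities.

## Diffusion

`fit_diffusion` performs the log-linear Stejskal–Tanner regression
with `b = (γgδ)²(Δ − δ/3)`; gradient strengths may be in arbitrary
linear units with a calibration constant. Defaults follow the
measurement design: δ = 5 ms, Δ = 150 ms, 16 gradients, 281 K.
Non-monotone attenuation beyond a robust (MAD-based) scatter estimate
flags a poor fit.

Stokes–Einstein conversion `R_h = k_BT/(6πηD)` is convention-dependent
through η. The measured reference pair (D = 6.82·10⁻¹¹ m²/s,
R_h = 16.8 Å at 281 K) implies an effective viscosity of 1.80 mPa·s —
well above tabulated water values at 281 K — so the package treats
absolute radii as calibration-dependent: `effective_viscosity` solves
Stokes–Einstein for η from a reference pair, after which only radius
*ratios* are asserted as exact.

The two-state fit `D_obs/D_free = 1 + p_B(D_B/D_free − 1)` with
`p_B = c·ratio` shares one D_B/D_free across metal titrations. As
written, each series constrains only the product `c(D_B/D_free − 1)`,
so the shared ratio is pinned by an anchor metal whose binding is
stoichiometric at NMR concentrations (sub-µM dissociation constant
against tens of µM peptide ⇒ p_B = ratio); Cu is the default anchor.
Residuals are relative, making the shared ratio invariant under
rescaling any one series. `D_B/D_free > 1` (the bound state diffuses
faster) encodes the compaction of the metal-wrapped N-terminus.

## Ensemble precision

`rmsd_to_mean` centers all conformers, Kabsch-superimposes each onto
the running mean structure, recomputes the mean, and iterates to
1·10⁻⁶ Å convergence (≤ 100 iterations), then averages the per-
conformer RMSD to the converged mean. The statistic is invariant to
rigid motions of any conformer and to conformer order. The default
atom selection is the heavy backbone (N, CA, C, O); N, CA, C is
available where a deposition's convention differs. The N-terminal
amine protons and the metal ion are excluded by default. Reading
deposited PDB/mmCIF ensembles goes through gemmi and enforces
identical atom sets across models within the selection.

## Synthetic data

The generators emulate the study conditions: unseeded plates of 3 µM
peptide at 0/2.5/5/7.5/10 µM Cu(II) in five replicates; seeded assays
of 3.2 µM monomer with 1.5 µM pre-formed seeds; 16-delay relaxation
schedules (0.002–2 s for R₁, 5–200 ms for R₂); 16-gradient diffusion
decays; and a toy 3D chain around a paramagnetic center for the
blind-sphere phenomenology. Each dataset ships with its truth record;
identical seeds give identical bytes.

Defaults that constitute the simulated "study conditions":

* Kinetic truth `k_n = 3·10⁻⁵ M⁻¹s⁻¹, k_2 = 3·10³ M⁻²s⁻¹,
  k_+ = 10⁶ M⁻¹s⁻¹` (λ/κ ≈ 0.06, τ½ ≈ 4.6 h at 3 µM) — a
  secondary-dominated, hours-scale system chosen jointly with the
  seeded design so the 9-minute slope window is faithful: seed
  depletion and secondary contamination each stay below ~6 % with
  P₀ = M₀/20000. With common literature-speed constants the
  product of those two error terms is fixed too large for *any* seed
  number at the stated seed mass and window — the assay conditions and
  the kinetic truth must be chosen together, as an experimentalist
  would titrate seed load against reaction speed.
* Binding truth K_D = 0.7 µM; Cu scales `k_+` by the free-monomer
  fraction of the 1:1 equilibrium.
* Quenching: final amplitude × (1 − 0.9·Cu/(Cu + 5 µM)), i.e. a 60 %
  amplitude loss at 10 µM Cu; the half-saturation is a generator knob.
* Noise: i.i.d. Gaussian — fractional of the (quenched) final
  amplitude for plate-reader traces (3 %), of the first-point
  intensity for NMR decays (2 %), multiplicative at 0.5 % for
  diffusion decays. Real plate data additionally drift and scatter
  between wells; real NMR noise is closer to constant thermal noise
  plus t₁-noise streaks. Passing recovery tests therefore demonstrate
  estimator correctness and statistical power under clean conditions,
  not robustness to instrument artifacts.
* Diffusion truth D_free = 6.82·10⁻¹¹ m²/s, D_B/D_free = 1.094,
  bound-population slopes 1.0/0.8/0.5 per unit ratio for Cu/Zn/Ag
  (Cu stoichiometric, matching its anchor role).
* PRE truth: toy coordinates spiral outward from the metal site at
  residue 6 (closest nucleus at 2.6 Å, just above the contact floor);
  visibility thresholds default to the Γ₂ values at the 9.0/6.5/4.5 Å
  shell radii, making the shell classification internally consistent
  with the generating distances.

## Numerical choices and degenerate inputs

* Sigmoid half-time: 4-parameter logistic, free baseline/amplitude/
  midpoint/width; a trace whose fitted amplitude is under five times
  the residual scatter raises a no-transition error instead of
  returning a midpoint.
* All positive-definite fit parameters are optimized in log space;
  non-convergence in per-trace fits yields flagged records, not
  exceptions, so one bad well cannot abort a plate.
* Constant relaxation series return rate 0 exactly; increasing decays
  return a flagged negative rate.
* Γ₂ ≤ 0 has no defined distance and raises; negative Γ₂ within error
  is clipped upstream with a flag.
* The closed form caps κt at 700 before exponentiation; α is clipped
  to [0, 1].

## Known limitations

* The closed-form solution is first-order in the primary/seed
  perturbation; heavily seeded or primary-dominated regimes fall back
  to (or must use) the ODE route.
* Individual two-product fits are ill-conditioned along λ at fixed κ;
  mechanism claims should rest on the constrained global fits.
* Absolute hydrodynamic radii and absolute Γ₂ magnitudes are
  convention-dependent (viscosity reference; PRE constant); ratios and
  distances are the robust outputs.
* The ensemble statistic assumes equal atom sets across models; no
  handling of alternate locations or partial occupancy.
* The deposited-ensemble precision check requires the coordinate files
  under `data/`; they are not bundled and no network fetch is
  attempted.
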