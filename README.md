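# paramyloid

Quantitative analysis of how Cu(II) ions modulate amyloid-β (Aβ)
self-assembly, for structural biologists and biophysicists working with
paramagnetic NMR and aggregation kinetics. The package covers the four
quantitative strands of such a study:

1. **Paramagnetic NMR restraints** — converting relaxation decays into
   PRE values (Γ₂ = R₂,para − R₂,dia), inverting PREs into distances via
   the Solomon–Bloembergen equation, and classifying blind-sphere
   visibility patterns into lower/upper distance restraints for
   structure calculation.
2. **Aggregation kinetics** — the nucleation–elongation model with
   secondary nucleation, fitted individually, globally (one free rate
   constant, χ² model selection) and via seeded initial slopes; an
   apparent monomer-binding K_D from the sequestration model; and the
   nucleation-rate integral that predicts oligomer generation.
3. **PFG diffusion** — Stejskal–Tanner fits, Stokes–Einstein radii and
   a multi-metal two-state (free/bound) global fit of bound populations.
4. **Ensemble precision** — backbone RMSD to the iteratively superposed
   mean of a deposited multi-model structure.

A synthetic-data generator (`paramyloid.synth`) reproduces every input
the pipeline consumes with known ground truth, so all stages are
testable without instrument data.

## The model

Fibril number `P` and mass `M` evolve under primary nucleation,
surface-catalysed secondary nucleation and fibril-end elongation:

    dP/dt = k_n m^{n_c} + k_2 m^{n_2} M
    dM/dt = 2 k_+ m P,          dm/dt = −dM/dt

with composite rates λ = √(2 k₊ k_n m₀^{n_c}) and
κ = √(2 k₊ k₂ m₀^{n₂+1}). The normalized fibril mass α(t) = M/m_tot is
available both by stiff integration of the moment equations (the
oracle) and as the closed-form fixed-point solution used for fitting.
Metal inhibition is modeled as monomer sequestration: a 1:1
Cu–monomer equilibrium with apparent dissociation constant K_D reduces
the aggregation-competent pool, so the relative elongation rate equals
the free-monomer fraction

    k₊/k₊⁰ = m_free/m_tot,   m_free the positive root of
    m² + (K_D + Cu_tot − m_tot) m − K_D m_tot = 0.

PRE distances follow Γ₂ = (1/15)(μ₀/4π)² γ_H² g² μ_B² S(S+1) r⁻⁶
[4J(0) + 3J(ω_H)] with J(ω) = τ_c/(1+(ωτ_c)²) and
τ_c = (τ_r⁻¹ + τ_s⁻¹)⁻¹. Diffusion decays follow
I(g) = I₀ exp[−D (γ g δ)² (Δ − δ/3)], with
D_obs/D_free = 1 + p_B (D_B/D_free − 1) under fast exchange.

## Worked example

Generate a synthetic plate (3 µM peptide, five Cu(II) levels, five
replicates, 3 % noise), run the constrained global fits, and ask which
single rate constant explains the Cu dependence:

```python
import numpy as np
from paramyloid.synth import GeneratorConfig, gen_tht_traces
from paramyloid.kinetics_fit import normalize_trace, select_free_constant, oligomer_fold_change
from paramyloid.kinetics_model import InitialState

cfg = GeneratorConfig(seed=1)
traces, truth = gen_tht_traces(cfg)
normalized = [normalize_trace(t) for t in traces]

best, fits = select_free_constant(normalized)
print(f"best-supported free constant: {best}")
for name, fit in fits.items():
    print(f"  chi2({name:6s}) = {fit.chi2_global:8.1f}")
fit = fits[best]
for cu, rel in zip(fit.cu_concs, fit.rel_values):
    print(f"  Cu = {cu*1e6:4.1f} uM   k_plus / k_plus(0) = {rel:.3f}")
print("oligomer fold change:", np.round(oligomer_fold_change(fit, InitialState(m0=cfg.ab_conc)), 2))
```

Output:

```
best-supported free constant: k_plus
  chi2(k_n   ) =  18914.2
  chi2(k_2   ) =  14787.1
  chi2(k_plus) =    899.6
  Cu =  0.0 uM   k_plus / k_plus(0) = 1.000
  Cu =  2.5 uM   k_plus / k_plus(0) = 0.450
  Cu =  5.0 uM   k_plus / k_plus(0) = 0.210
  Cu =  7.5 uM   k_plus / k_plus(0) = 0.127
  Cu = 10.0 uM   k_plus / k_plus(0) = 0.089
oligomer fold change: [1.   1.49 2.18 2.8  3.35]
```

The χ² comparison singles out fibril-end elongation (`k_plus`) as the
step Cu(II) retards — the generating truth — and the recovered relative
elongation rates follow the free-monomer fraction of the binding
equilibrium (truth K_D = 0.7 µM). The final line is the mechanistic
consequence: slower elongation leaves monomers available longer, so the
integral of the nucleation rate — a proxy for oligomer generation —
*rises* with Cu(II), by ~3.4× at 10 µM here.

The same functionality is exposed on the command line
(`paramyloid simulate`, `paramyloid kinetics fit|kd|oligomers`,
`paramyloid pre fit-rates|distances|restraints`,
`paramyloid diffusion fit|twostate`, `paramyloid rmsd`,
`paramyloid synth ...`).

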