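"""Individual/global trace fitting, seeded slopes, K_D and oligomer analysis."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paramyloid.kinetics_fit import (
    AggregationTrace,
    fit_global_single_free,
    fit_individual,
    fit_kd_from_elongation,
    free_monomer_fraction,
    normalize_trace,
    oligomer_fold_change,
    relative_elongation_rates,
    seeded_elongation_rate,
    select_free_constant,
)
from paramyloid.kinetics_model import (
    InitialState,
    KineticParameters,
    fibril_mass_closed_form,
    nucleation_rate_profile,
    solve_moment_odes,
)
from paramyloid.synth import GeneratorConfig, gen_seeded_traces, gen_tht_traces


def _trace_from_params(params, m0=3e-6, cu=0.0, t_max_factor=15.0, n=250, scale=1.0):
    t = np.linspace(0.0, t_max_factor / params.kappa(m0), n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        alpha = fibril_mass_closed_form(params, InitialState(m0=m0), t).alpha
    return AggregationTrace(t=t, signal=alpha * scale, cu_conc=cu, ab_conc=m0)


class TestIndividualFit:
    def test_noiseless_product_recovery(self, ab42_params):
        """Both combined constants recovered within 1 % on clean traces."""
        tr = _trace_from_params(ab42_params)
        res = fit_individual([tr])[0]
        m0 = 3e-6
        true_knkp = ab42_params.k_n * ab42_params.k_plus
        true_kpk2 = ab42_params.k_plus * ab42_params.k_2
        assert res.kn_kplus == pytest.approx(true_knkp, rel=0.01)
        assert res.kplus_k2 == pytest.approx(true_kpk2, rel=0.01)

    def test_reference_trace_relative_unity(self, ab42_params):
        tr0 = _trace_from_params(ab42_params, cu=0.0)
        tr1 = AggregationTrace(t=tr0.t, signal=tr0.signal.copy(), cu_conc=1e-6, ab_conc=3e-6)
        out = fit_individual([tr0, tr1])
        by_cu = {c.cu_conc: c for c in out}
        assert by_cu[0.0].rel_kn_kplus == pytest.approx(1.0, rel=1e-6)
        assert by_cu[1e-6].rel_kn_kplus == pytest.approx(1.0, rel=0.01)
        assert by_cu[1e-6].rel_kplus_k2 == pytest.approx(1.0, rel=0.01)

    def test_kplus_reduction_scales_both_products(self, ab42_params):
        """When only k_plus falls with Cu, both combined products scale
        with it identically (lambda^2 and kappa^2 are each linear in
        k_plus), so a well-conditioned fit tracks the same factor in
        k_n*k_plus and k_plus*k_2."""
        scales = [1.0, 0.3, 0.1, 0.03]
        traces = [
            _trace_from_params(replace(ab42_params, k_plus=ab42_params.k_plus * s),
                               cu=i * 1e-6)
            for i, s in enumerate(scales)
        ]
        out = fit_individual(traces)
        rel_knkp = np.array([c.rel_kn_kplus for c in out])
        rel_kpk2 = np.array([c.rel_kplus_k2 for c in out])
        span_knkp = np.log10(rel_knkp.max() / rel_knkp.min())
        span_kpk2 = np.log10(rel_kpk2.max() / rel_kpk2.min())
        assert span_knkp == pytest.approx(span_kpk2, abs=0.1)  # both track k_plus
        assert rel_knkp[-1] == pytest.approx(0.03, rel=0.1)


class TestGlobalFit:
    def test_identical_traces_give_unity(self, ab42_params):
        tr0 = _trace_from_params(ab42_params)
        traces = [
            AggregationTrace(t=tr0.t, signal=tr0.signal.copy(), cu_conc=cu, ab_conc=3e-6)
            for cu in (0.0, 1e-6, 2e-6)
        ]
        for free in ("k_n", "k_2", "k_plus"):
            res = fit_global_single_free(traces, free)
            assert np.allclose(res.rel_values, 1.0, atol=1e-3)

    @pytest.mark.parametrize("varied", ["k_plus", "k_2"])
    def test_model_selection_recovers_varied_constant(self, ab42_params, varied):
        scales = [1.0, 0.5, 0.25, 0.12]
        traces = []
        for i, s in enumerate(scales):
            params = replace(ab42_params, **{varied: getattr(ab42_params, varied) * s})
            traces.append(_trace_from_params(params, cu=i * 1e-6, t_max_factor=25.0))
        best, fits = select_free_constant(traces)
        assert best == varied
        res = fits[varied]
        assert np.allclose(res.rel_values, scales, rtol=0.05)

    def test_missing_reference_condition_rejected(self, ab42_params):
        tr = _trace_from_params(ab42_params, cu=1e-6)
        with pytest.raises(ValueError, match="Cu = 0"):
            fit_global_single_free([tr] * 3, "k_plus")

    def test_selection_rate_on_noisy_replicates(self):
        """On generated plates with only k_plus modulated and 3 % noise,
        k_plus is selected in >= 90 % of seeded repetitions."""
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            cfg = GeneratorConfig(seed=100 + seed)
            traces, _ = gen_tht_traces(cfg)
            norm = [normalize_trace(t) for t in traces]
            best, _ = select_free_constant(norm)
            hits += best == "k_plus"
        assert hits >= 0.9 * n_rep


class TestNormalization:
    def test_scaling_invariance_of_relative_constants(self, ab42_params):
        """Multiplying raw fluorescence by any positive constant leaves
        fitted relative constants unchanged after normalization."""
        traces_a, traces_b = [], []
        for i, s in enumerate([1.0, 0.4, 0.15]):
            params = replace(ab42_params, k_plus=ab42_params.k_plus * s)
            base = _trace_from_params(params, cu=i * 1e-6, t_max_factor=25.0)
            traces_a.append(normalize_trace(replace_signal(base, base.signal * 1.0 + 0.05)))
            traces_b.append(normalize_trace(replace_signal(base, base.signal * 37.0 + 2.0)))
        ra = fit_global_single_free(traces_a, "k_plus").rel_values
        rb = fit_global_single_free(traces_b, "k_plus").rel_values
        assert np.allclose(ra, rb, rtol=1e-4)


def replace_signal(trace, signal):
    return AggregationTrace(
        t=trace.t, signal=signal, cu_conc=trace.cu_conc, ab_conc=trace.ab_conc,
        dye=trace.dye, seeded=trace.seeded, seed_mass=trace.seed_mass,
        replicate=trace.replicate,
    )


class TestSeededSlopes:
    def test_pure_elongation_recovers_kplus(self):
        params = KineticParameters(k_n=0.0, k_2=0.0, k_plus=1e6)
        init = InitialState(m0=3.2e-6, P0=3e-11, M0=1.5e-6)
        t = np.linspace(0.0, 1800.0, 300)
        traj = solve_moment_odes(params, init, t)
        signal = (traj.M - traj.M[0]) / (init.m_tot - traj.M[0])
        tr = AggregationTrace(t=t, signal=signal, cu_conc=0.0, ab_conc=init.m0,
                              seeded=True, seed_mass=init.M0)
        slope, _ = seeded_elongation_rate(tr)
        k_plus = slope * (init.m_tot - init.M0) / (2.0 * init.P0 * init.m0)
        assert k_plus == pytest.approx(1e6, rel=0.02)

    def test_relative_slope_of_self_is_unity(self):
        cfg = GeneratorConfig(seed=0, noise_tht=0.0, cu_concs=(0.0,))
        traces, _ = gen_seeded_traces(cfg)
        ratios, rel = relative_elongation_rates(traces)
        assert rel[0] == pytest.approx(1.0)

    def test_halved_kplus_halves_slope(self):
        """Generator traces at k_plus and k_plus/2: relative slope 0.5 +- 0.02."""
        cfg = GeneratorConfig(seed=0, noise_tht=0.0)
        base, _ = gen_seeded_traces(cfg)
        halved_kin = replace(cfg.kinetics, k_plus=cfg.kinetics.k_plus / 2.0)
        cfg2 = replace(cfg, kinetics=halved_kin)
        half, _ = gen_seeded_traces(cfg2)
        s1, _ = seeded_elongation_rate(base[0])
        s2, _ = seeded_elongation_rate(half[0])
        assert s2 / s1 == pytest.approx(0.5, abs=0.02)

    def test_window_must_hold_enough_points(self):
        t = np.linspace(0.0, 3600.0, 10)
        tr = AggregationTrace(t=t, signal=t * 1e-5, cu_conc=0.0, ab_conc=3e-6, seeded=True)
        with pytest.raises(ValueError, match="insufficient"):
            seeded_elongation_rate(tr, window=120.0)

    def test_unseeded_trace_rejected(self):
        t = np.linspace(0.0, 3600.0, 100)
        tr = AggregationTrace(t=t, signal=t * 1e-5, cu_conc=0.0, ab_conc=3e-6)
        with pytest.raises(ValueError, match="seeded"):
            seeded_elongation_rate(tr)


class TestKdFit:
    def test_sequestration_model_limits(self):
        assert free_monomer_fraction(0.0, 3e-6, 1e-6) == pytest.approx(1.0)
        # K_D -> 0 with excess metal: full sequestration
        assert free_monomer_fraction(2.0, 3e-6, 1e-12) == pytest.approx(0.0, abs=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        ratio=st.floats(0.01, 5.0),
        kd=st.floats(1e-8, 1e-5),
    )
    def test_sequestration_curve_monotone(self, ratio, kd):
        """Free fraction decreases with metal:peptide ratio and with 1/K_D."""
        f = free_monomer_fraction(ratio, 3e-6, kd)
        assert 0.0 < f <= 1.0
        assert free_monomer_fraction(ratio * 1.3, 3e-6, kd) < f
        assert free_monomer_fraction(ratio, 3e-6, kd * 0.5) < f

    def test_recovery_at_low_noise(self):
        """Median recovered K_D biased < 10 % at 2 % noise, 10 ratio points."""
        kd_true = 1e-6
        estimates = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            ratios = np.linspace(0.0, 3.0, 10)
            rel = free_monomer_fraction(ratios, 3e-6, kd_true)
            rel = np.clip(rel + rng.normal(0.0, 0.02, ratios.size), 1e-3, 1.2)
            estimates.append(fit_kd_from_elongation(ratios, rel, ab_conc=3e-6).kd_app)
        med = np.median(estimates)
        assert abs(med - kd_true) / kd_true < 0.10

    def test_flat_data_flags_unbounded(self):
        ratios = np.linspace(0.0, 3.0, 8)
        res = fit_kd_from_elongation(ratios, np.ones_like(ratios), ab_conc=3e-6)
        assert res.unbounded
        assert res.kd_app is None

    def test_error_range_from_weighted_and_trimmed_refits(self):
        rng = np.random.default_rng(5)
        ratios = np.linspace(0.0, 3.0, 10)
        rel = free_monomer_fraction(ratios, 3e-6, 0.7e-6) + rng.normal(0, 0.04, 10)
        errors = np.abs(rng.normal(0.04, 0.02, 10))
        res = fit_kd_from_elongation(ratios, np.clip(rel, 1e-3, 1.2), errors=errors,
                                     ab_conc=3e-6)
        lo, hi = res.kd_range
        assert lo <= res.kd_app <= hi
        assert res.kd_err >= 0.0


class TestOligomerFoldChange:
    def test_fold_change_reference_is_unity_and_increases(self, tht_dataset):
        cfg, traces, truth = tht_dataset
        norm = [normalize_trace(t) for t in traces]
        fit = fit_global_single_free(norm, "k_plus")
        folds = oligomer_fold_change(fit, InitialState(m0=cfg.ab_conc))
        assert folds[0] == pytest.approx(1.0)
        assert np.all(np.diff(folds) > 0)  # more Cu, more oligomers
        assert folds[-1] > 1.0

    def test_closed_form_and_ode_pipelines_agree(self, tht_dataset):
        cfg, traces, _ = tht_dataset
        norm = [normalize_trace(t) for t in traces]
        fit = fit_global_single_free(norm, "k_plus")
        init = InitialState(m0=cfg.ab_conc)
        f_cf = oligomer_fold_change(fit, init)
        f_ode = oligomer_fold_change(fit, init, use_ode=True)
        assert np.allclose(f_cf, f_ode, rtol=0.05)

    def test_result_invariant_to_reference_kplus(self, tht_dataset):
        cfg, traces, _ = tht_dataset
        norm = [normalize_trace(t) for t in traces]
        fit = fit_global_single_free(norm, "k_plus")
        init = InitialState(m0=cfg.ab_conc)
        f1 = oligomer_fold_change(fit, init, k_plus_ref=1.0)
        f2 = oligomer_fold_change(fit, init, k_plus_ref=1e6)
        assert np.allclose(f1, f2, rtol=1e-6)
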