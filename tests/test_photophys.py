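"""rETR, Eilers-Peeters fitting, Beer-Lambert pools, kinetics, spectra."""

import math

import numpy as np
import pytest

from cyanokit.errors import DomainError, EstimationError, FitError
from cyanokit.photophys import (
    AbsorbanceDelta,
    EilersPeetersModel,
    EmissionSpectrum,
    LightResponseCurve,
    compute_retr,
    ep_model,
    estimate_halftime,
    fit_ep,
    pool_concentration,
    preprocess_spectrum,
    rate_from_halftime,
)
from cyanokit.synthetic_data import KineticsSpec, RlcSpec, synth_rereduction_trace, synth_rlc


class TestRetr:
    def test_elementwise_product(self):
        curve = LightResponseCurve(
            irradiance=[100.0, 200.0], phi_psii=[0.5, 0.0]
        )
        out = compute_retr(curve)
        assert out.retr == pytest.approx([50.0, 0.0])

    def test_matches_brute_force_oracle(self, random_dna):
        rng = np.random.default_rng(3)
        irr = np.sort(rng.uniform(10, 2400, size=12))
        phi = rng.uniform(0, 0.6, size=12)
        out = compute_retr(LightResponseCurve(irradiance=irr, phi_psii=phi))
        expected = [p * i for p, i in zip(phi, irr)]
        assert out.retr == pytest.approx(expected, rel=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            LightResponseCurve(irradiance=[10.0, 20.0], phi_psii=[0.5])

    def test_yield_bounds_enforced(self):
        with pytest.raises(DomainError):
            LightResponseCurve(irradiance=[10.0], phi_psii=[1.4])


class TestEilersPeeters:
    def test_derived_formulas_verified_symbolically(self):
        """The closed forms for s, P_m, I_m follow from the model's calculus."""
        import sympy

        a, b, c, I = sympy.symbols("a b c I", positive=True)
        P = I / (a * I**2 + b * I + c)
        # initial slope: dP/dI at I -> 0
        s = sympy.limit(sympy.diff(P, I), I, 0)
        assert sympy.simplify(s - 1 / c) == 0
        # optimum: the interior stationary point and the value there
        crit = sympy.solve(sympy.diff(P, I), I)
        i_m = [r for r in crit if sympy.simplify(r) != 0 and r.is_positive][0]
        assert sympy.simplify(i_m - sympy.sqrt(c / a)) == 0
        p_m = sympy.simplify(P.subs(I, i_m))
        assert sympy.simplify(p_m - 1 / (b + 2 * sympy.sqrt(a * c))) == 0

    def test_noiseless_recovery_and_derived_values(self):
        curve, truth = synth_rlc(RlcSpec(a=1e-5, b=0.01, c=1.0), seed=0)
        res = fit_ep(curve)
        assert res.a == pytest.approx(1e-5, rel=1e-3)
        assert res.b == pytest.approx(0.01, rel=1e-3)
        assert res.c == pytest.approx(1.0, rel=1e-3)
        assert res.p_m == pytest.approx(1.0 / (0.01 + 2 * math.sqrt(1e-5)), rel=1e-6)
        assert res.i_m == pytest.approx(math.sqrt(1e5), rel=1e-6)

    def test_internal_consistency_identities(self):
        curve, _ = synth_rlc(RlcSpec(), seed=1)
        res = fit_ep(curve)
        assert res.i_k * res.s == pytest.approx(res.p_m, rel=1e-9)
        assert res.predict(res.i_m) == pytest.approx(res.p_m, rel=1e-9)

    def test_scaling_homogeneity(self):
        """Scaling rETR by gamma scales s and P_m by gamma; I_m, I_k unchanged."""
        curve, _ = synth_rlc(RlcSpec(), seed=2)
        res = fit_ep(curve)
        gamma = 3.5
        scaled = LightResponseCurve(irradiance=curve.irradiance, retr=gamma * curve.retr)
        res2 = EilersPeetersModel(scaled).fit()
        assert res2.s == pytest.approx(gamma * res.s, rel=1e-6)
        assert res2.p_m == pytest.approx(gamma * res.p_m, rel=1e-6)
        assert res2.i_m == pytest.approx(res.i_m, rel=1e-6)
        assert res2.i_k == pytest.approx(res.i_k, rel=1e-6)

    def test_noisy_median_bias_below_two_percent(self):
        """sigma = 2% of P_m: the P_m estimate stays nearly unbiased."""
        spec = RlcSpec(a=1e-5, b=0.01, c=1.0)
        p_m_true = 1.0 / (spec.b + 2 * math.sqrt(spec.a * spec.c))
        rel = []
        for seed in range(100):
            curve, _ = synth_rlc(
                RlcSpec(a=spec.a, b=spec.b, c=spec.c, noise_sd=0.02 * p_m_true), seed=seed
            )
            rel.append(fit_ep(curve).p_m / p_m_true - 1.0)
        assert abs(np.median(rel)) < 0.02

    def test_summary_mentions_all_parameters(self):
        curve, _ = synth_rlc(RlcSpec(), seed=3)
        text = fit_ep(curve).summary()
        for token in ("P_m", "I_m", "I_k", "residual SS"):
            assert token in text

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            EilersPeetersModel([10.0, 20.0, 30.0], [1.0, 2.0, 3.0])

    def test_degenerate_data_raises_fit_error(self):
        # rETR decreasing from the first point cannot satisfy a>0, c>0 with
        # a positive initial slope; the fit either converges admissibly or
        # raises a diagnostic FitError - never a silent bad answer
        irr = np.array([10.0, 50.0, 100.0, 500.0, 1000.0])
        retr = np.array([100.0, 10.0, 5.0, 1.0, 0.5])
        try:
            res = EilersPeetersModel(irr, retr).fit()
        except FitError as err:
            assert err.diagnostics
        else:
            assert res.a > 0 and res.c > 0


class TestPools:
    def test_zero_signal(self):
        assert pool_concentration(AbsorbanceDelta("PC", 0.0)) == 0.0

    def test_default_extinction_coefficients(self):
        for name, eps in (("PSI", 70.0), ("b6f", 18.0), ("PC", 4.7)):
            assert AbsorbanceDelta(name, 1e-3).resolved_epsilon() == eps

    def test_beer_lambert_round_trip(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            c_nM = rng.uniform(10, 2000)
            eps = rng.uniform(1, 100)
            length = rng.uniform(0.2, 2.0)
            delta_a = (c_nM * 1e-6) * eps * length
            x = AbsorbanceDelta("X", delta_a, epsilon=eps, path_length=length)
            assert pool_concentration(x) == pytest.approx(c_nM, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            pool_concentration(AbsorbanceDelta("PC", 1e-3, epsilon=-1.0))
        with pytest.raises(DomainError):
            pool_concentration(AbsorbanceDelta("PC", 1e-3, path_length=0.0))
        with pytest.raises(DomainError):
            pool_concentration(AbsorbanceDelta("unknown", 1e-3))


class TestHalftime:
    def test_exact_exponential_rise(self):
        t, y, truth = synth_rereduction_trace(
            KineticsSpec(half_time=1.0, n_points=2001), seed=0
        )
        assert estimate_halftime(t, y) == pytest.approx(1.0, rel=0.02)

    def test_translation_invariance(self):
        t, y, _ = synth_rereduction_trace(KineticsSpec(half_time=0.5), seed=0)
        assert estimate_halftime(t, y + 7.3) == pytest.approx(
            estimate_halftime(t, y), rel=1e-12
        )

    def test_amplitude_invariance(self):
        base = KineticsSpec(half_time=0.2, amplitude=1.0)
        tall = KineticsSpec(half_time=0.2, amplitude=40.0)
        t1, y1, _ = synth_rereduction_trace(base, seed=0)
        t2, y2, _ = synth_rereduction_trace(tall, seed=0)
        assert estimate_halftime(t1, y1) == pytest.approx(estimate_halftime(t2, y2), rel=1e-9)

    def test_noisy_median_error_below_five_percent(self):
        errors = []
        for seed in range(100):
            t, y, _ = synth_rereduction_trace(
                KineticsSpec(half_time=1.0, noise_sd=0.01), seed=seed
            )
            errors.append(abs(estimate_halftime(t, y) - 1.0))
        assert np.median(errors) < 0.05

    def test_plateau_free_trace_rejected(self):
        t = np.linspace(0, 1, 200)
        with pytest.raises(EstimationError):
            estimate_halftime(t, t * 5.0)  # linear, never plateaus

    def test_flat_trace_rejected(self):
        t = np.linspace(0, 1, 200)
        with pytest.raises(EstimationError):
            estimate_halftime(t, np.ones_like(t))


class TestRateConversion:
    def test_definitional_fixed_point(self):
        assert rate_from_halftime(math.log(2.0)) == pytest.approx(1.0, rel=1e-12)

    def test_reciprocal_scaling(self):
        assert rate_from_halftime(0.5) == pytest.approx(2 * rate_from_halftime(1.0))

    def test_end_to_end_rate_recovery(self):
        spec = KineticsSpec(half_time=0.02, noise_sd=0.005)
        t, y, truth = synth_rereduction_trace(spec, seed=11)
        rate = rate_from_halftime(estimate_halftime(t, y))
        assert rate == pytest.approx(truth["rate"], rel=0.05)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            rate_from_halftime(0.0)


class TestSpectrum:
    lam = np.arange(650.0, 761.0, 0.5)

    def test_three_identical_scans_average_to_one(self):
        y = np.sin(self.lam / 20) + 2.0
        spec = EmissionSpectrum(self.lam, np.vstack([y, y, y]), excitation=435)
        out = preprocess_spectrum(spec)
        mask = (self.lam >= 670) & (self.lam <= 740)
        assert out.intensity == pytest.approx(y[mask])
        assert out.n_scans == 3

    def test_pure_exponential_self_cancels_for_620(self):
        y = 3.0 * np.exp(0.01 * (self.lam - 670)) + 5.0
        out = preprocess_spectrum(EmissionSpectrum(self.lam, y, excitation=620))
        assert np.sqrt((out.intensity**2).mean()) < 1e-6 * np.sqrt((y**2).mean())

    def test_435_excitation_skips_baseline(self):
        y = 3.0 * np.exp(0.01 * (self.lam - 670)) + 5.0
        out = preprocess_spectrum(EmissionSpectrum(self.lam, y, excitation=435))
        mask = (self.lam >= 670) & (self.lam <= 740)
        assert out.intensity == pytest.approx(y[mask])

    def test_window_restriction(self):
        y = np.ones_like(self.lam)
        out = preprocess_spectrum(EmissionSpectrum(self.lam, y, excitation=435))
        assert out.wavelength[0] >= 670 and out.wavelength[-1] <= 740

    def test_grid_not_covering_window_rejected(self):
        lam = np.arange(680.0, 720.0)
        with pytest.raises(DomainError):
            preprocess_spectrum(EmissionSpectrum(lam, np.ones_like(lam), excitation=435))
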