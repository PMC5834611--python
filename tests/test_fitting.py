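"""Fitting primitives: exact recovery, ensembles, oracles, determinism."""

import numpy as np
import pytest

from conftest import seeds
from hemeco import fitting
from hemeco.fitting import (
    FitError,
    KineticTrace,
    SpectroTemporalMatrix,
    fit_first_order,
    fit_kobs_curve,
    fit_multiexp,
    geminate_summary,
    global_das_fit,
    select_n_phases,
)
from hemeco.kinetics import ObservedRatePoint, kobs_hyperbolic
from hemeco.synth import NoiseModel, gen_ultrafast

PHASES = [(22.0, 0.14), (150.0, 0.26), (2500.0, 0.50)]


def _survival_trace(noise_sigma=0.0, seed=0, long_lived=0.10):
    t = np.geomspace(10.0, 4000.0, 80)
    clean = long_lived + sum(a * np.exp(-t / tau) for tau, a in PHASES)
    rng = np.random.default_rng(seed)
    y = clean + rng.normal(0.0, noise_sigma * np.max(np.abs(clean)), t.shape)
    return KineticTrace(times=t, signal=y, time_unit="ps")


class TestMultiExp:
    def test_noiseless_single_exponential_exact(self):
        t = np.linspace(0.0, 120.0, 60)
        trace = KineticTrace(t, 0.1 + 0.9 * np.exp(-t / 20.0))
        fit = fit_multiexp(trace, 1)
        assert fit.lifetimes[0] == pytest.approx(20.0, rel=1e-6)
        assert fit.offset == pytest.approx(0.1, abs=1e-9)
        assert fit.converged

    def test_triexponential_recovery_ensemble(self):
        """Geminate-phase lifetimes within 15% and fractional amplitudes
        within 5 points, median over a seeded ensemble at 2% noise."""
        taus, fracs = [], []
        for s in seeds(25):
            fit = fit_multiexp(_survival_trace(noise_sigma=0.02, seed=s), 3)
            taus.append(fit.lifetimes)
            total = sum(abs(a) for a in fit.amplitudes) + abs(fit.offset)
            fracs.append([abs(a) / total for a in fit.amplitudes])
        med_tau = np.median(taus, axis=0)
        med_frac = np.median(fracs, axis=0)
        for est, (tau, amp) in zip(med_tau, PHASES):
            assert abs(est - tau) / tau < 0.15
        for est, (_, amp) in zip(med_frac, PHASES):
            assert abs(est - amp) < 0.05

    def test_nested_ssr_monotone(self):
        trace = _survival_trace(noise_sigma=0.02, seed=7)
        ssr = [fit_multiexp(trace, n).ssr for n in (1, 2, 3)]
        assert ssr[2] < ssr[1] < ssr[0]

    def test_deterministic(self):
        trace = _survival_trace(noise_sigma=0.02, seed=3)
        a, b = fit_multiexp(trace, 3), fit_multiexp(trace, 3)
        assert a == b

    def test_too_few_points_rejected(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            fit_multiexp(KineticTrace(t, np.exp(-t)), 2)

    def test_fractional_amplitudes_normalized(self):
        fit = fit_multiexp(_survival_trace(noise_sigma=0.01, seed=1), 3)
        assert sum(fit.fractional_amplitudes) == pytest.approx(1.0, abs=1e-9)
        assert list(fit.lifetimes) == sorted(fit.lifetimes)


class TestSelectNPhases:
    def test_single_exponential_low_noise(self):
        t = np.linspace(0.0, 100.0, 120)
        rng = np.random.default_rng(0)
        y = 1.0 * np.exp(-t / 15.0) + rng.normal(0, 1e-3, t.shape)
        assert select_n_phases(KineticTrace(t, y), max_n=3) == 1

    def test_three_phase_data_selects_three(self):
        hits = sum(
            select_n_phases(_survival_trace(noise_sigma=0.02, seed=s), max_n=4) == 3
            for s in seeds(25)
        )
        assert hits >= 20  # >= 80% of seeds

    def test_noise_does_not_inflate_complexity(self):
        """Median recommendation at very high noise never exceeds that at
        low noise for the same underlying truth."""
        low = np.median([
            select_n_phases(_survival_trace(noise_sigma=0.02, seed=s), 4)
            for s in seeds(15)
        ])
        high = np.median([
            select_n_phases(_survival_trace(noise_sigma=0.5, seed=s), 4)
            for s in seeds(15)
        ])
        assert high <= low


class TestKobsCurve:
    def test_noiseless_exact(self, default_rates):
        c = np.geomspace(25.0, 800.0, 8)
        pts = [ObservedRatePoint(ci, kobs_hyperbolic(default_rates, ci)) for ci in c]
        fit = fit_kobs_curve(pts)
        assert fit.k1 == pytest.approx(default_rates.k1, rel=1e-6)
        assert fit.k_co == pytest.approx(default_rates.k_co, rel=1e-6)

    def test_recovery_ensemble(self, default_rates):
        """8 concentrations 25-800 uM, 5% multiplicative noise."""
        c = np.geomspace(25.0, 800.0, 8)
        truth = kobs_hyperbolic(default_rates, c)
        k1s = []
        for s in seeds(25):
            rng = np.random.default_rng(s)
            noisy = truth * (1.0 + rng.normal(0.0, 0.05, c.shape))
            fit = fit_kobs_curve([ObservedRatePoint(ci, ki) for ci, ki in zip(c, noisy)])
            k1s.append(fit.k1)
        assert abs(np.median(k1s) - 25.0) / 25.0 < 0.10

    def test_linear_regime_unidentifiable_k1_but_good_kco(self, default_rates):
        """c << K: only the initial slope kCO is determined; the fit must
        report a wide k1 confidence interval."""
        c = np.linspace(0.5, 8.0, 8)  # K ~ 92.6 uM
        truth = kobs_hyperbolic(default_rates, c)
        rng = np.random.default_rng(1)
        noisy = truth * (1.0 + rng.normal(0.0, 0.02, c.shape))
        fit = fit_kobs_curve([ObservedRatePoint(ci, ki) for ci, ki in zip(c, noisy)])
        # saturating-range reference at the same noise level
        c_full = np.geomspace(25.0, 800.0, 8)
        tr_full = kobs_hyperbolic(default_rates, c_full)
        noisy_full = tr_full * (1.0 + rng.normal(0.0, 0.02, c_full.shape))
        ref = fit_kobs_curve(
            [ObservedRatePoint(ci, ki) for ci, ki in zip(c_full, noisy_full)]
        )
        assert fit.k1_stderr / fit.k1 > 0.2  # k1 poorly determined
        assert fit.k1_stderr / fit.k1 > 3.0 * ref.k1_stderr / ref.k1
        assert abs(fit.k_co - default_rates.k_co) / default_rates.k_co < 0.10

    def test_too_few_distinct_concentrations(self):
        pts = [ObservedRatePoint(10.0, 1.0)] * 5
        with pytest.raises(ValueError):
            fit_kobs_curve(pts)


class TestFirstOrder:
    def test_noiseless_exact(self):
        t = np.linspace(0.0, 10800.0, 200)
        k = 4.8e-4
        trace = KineticTrace(t, 0.2 + 0.6 * np.exp(-k * t))
        fit = fit_first_order(trace)
        assert fit.rate == pytest.approx(k, rel=1e-8)
        assert fit.converged

    def test_recovery_ensemble(self):
        """1% noise over a 3 h window: median bias below 2%."""
        t = np.linspace(0.0, 10800.0, 360)
        k = 4.8e-4
        clean = 0.2 + 0.6 * np.exp(-k * t)
        rates = []
        for s in seeds(25):
            rng = np.random.default_rng(s)
            y = clean + rng.normal(0.0, 0.01 * 0.6, t.shape)
            rates.append(fit_first_order(KineticTrace(t, y)).rate)
        assert abs(np.median(rates) - k) / k < 0.02

    def test_flat_trace_flagged(self):
        t = np.linspace(0.0, 10.0, 50)
        rng = np.random.default_rng(0)
        fit = fit_first_order(KineticTrace(t, 1.0 + rng.normal(0, 1e-6, t.shape)))
        # either non-converged or rate indistinguishable from zero
        assert (not fit.converged) or fit.rate_stderr >= fit.rate or fit.rate < 1e-6

    def test_grid_search_oracle(self):
        """On a short trace the optimum matches an exhaustive 400x400
        (rate x amplitude) grid search within the grid resolution."""
        t = np.linspace(0.0, 8.0, 12)
        y = 2.0 * np.exp(-0.45 * t)
        trace = KineticTrace(t, y + np.sin(7 * t) * 0.05)  # deterministic "noise"
        fit = fit_first_order(trace, fit_offset=False)
        rates = np.linspace(0.05, 2.0, 400)
        amps = np.linspace(0.5, 4.0, 400)
        model = amps[None, :, None] * np.exp(-np.outer(rates, t))[:, None, :]
        ssr = ((model - trace.signal) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(ssr), ssr.shape)
        assert abs(fit.rate - rates[i]) <= rates[1] - rates[0]
        assert abs(fit.amplitude - amps[j]) <= amps[1] - amps[0]


class TestGlobalDAS:
    def test_noiseless_roundtrip(self):
        m = gen_ultrafast()
        fit = global_das_fit(m, 3, include_nondecaying=True)
        assert np.allclose(fit.lifetimes, [22.0, 150.0, 2500.0], rtol=0.01)
        # DAS spectra: each component's spectrum equals amp_i * shared shape
        from hemeco.synth import default_das_shape

        shape = default_das_shape(m.wavelengths)
        for comp, (tau, amp) in zip(fit.components, PHASES):
            assert np.allclose(comp.spectrum, amp * shape, atol=0.01 * np.abs(shape).max())

    def test_nondecaying_fraction_recovery(self):
        fracs = []
        for s in seeds(25):
            m = gen_ultrafast(noise=NoiseModel(sigma=0.02, relative=True, seed=s))
            fit = global_das_fit(m, 3, include_nondecaying=True)
            fracs.append(geminate_summary(fit).long_lived_fraction)
        assert abs(np.median(fracs) - 0.10) < 0.03

    def test_wavelength_order_invariance(self):
        m = gen_ultrafast(noise=NoiseModel(sigma=0.02, relative=True, seed=4))
        fit1 = global_das_fit(m, 2)
        # reversed wavelength axis encodes the same data
        m2 = SpectroTemporalMatrix(m.delays, m.wavelengths, m.delta_a)
        fit2 = global_das_fit(m2, 2)
        assert fit1.lifetimes == fit2.lifetimes

    def test_input_validation(self):
        m = gen_ultrafast()
        with pytest.raises(ValueError):
            global_das_fit(m, n_phases=m.delays.size)
        small = SpectroTemporalMatrix(m.delays[:5], m.wavelengths, m.delta_a[:5])
        with pytest.raises(ValueError):
            global_das_fit(small, 2)


class TestGeminateSummary:
    def test_paper_phase_yield(self):
        """Decaying phases of 14%, 26% and 50% give a 90% geminate yield."""
        fit = fitting.MultiExpFit(
            lifetimes=(22.0, 150.0, 2500.0),
            amplitudes=(0.14, 0.26, 0.50),
            offset=0.10,
            ssr=0.0,
            converged=True,
            n_points=100,
        )
        s = geminate_summary(fit)
        assert s.geminate_yield == pytest.approx(0.90, abs=1e-12)
        assert s.long_lived_fraction == pytest.approx(0.10, abs=1e-12)

    def test_single_phase_no_long_lived(self):
        fit = fitting.MultiExpFit(
            lifetimes=(10.0,), amplitudes=(1.0,), offset=0.0,
            ssr=0.0, converged=True, n_points=50,
        )
        assert geminate_summary(fit).geminate_yield == pytest.approx(1.0)

    def test_yield_complement_identity(self):
        for s in seeds(5):
            fit = fit_multiexp(_survival_trace(noise_sigma=0.02, seed=s), 3)
            summ = geminate_summary(fit)
            assert summ.geminate_yield + summ.long_lived_fraction == pytest.approx(
                1.0, abs=1e-9
            )

    def test_nonconverged_rejected(self):
        fit = fitting.MultiExpFit(
            lifetimes=(10.0,), amplitudes=(1.0,), offset=0.0,
            ssr=0.0, converged=False, n_points=50,
        )
        with pytest.raises(ValueError):
            geminate_summary(fit)
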