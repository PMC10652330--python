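"""Lorentzian/Gaussian peak fits and saturation-curve construction."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from mtmrs.peak_fitting import (
    PeakFit,
    SaturationCurve,
    build_saturation_curve,
    fit_pi_window,
    fit_single_peak,
    gaussian,
    lorentzian,
)
from mtmrs.spectral_processing import Spectrum, to_spectrum
from mtmrs.synthetic_data import (
    Condition,
    GroundTruth,
    Peak,
    decay_fraction,
    simulate_fid,
    simulate_session,
)


def _spectrum_from(ppm, y):
    return Spectrum(ppm, np.asarray(y, dtype=complex), 49.9)


def _two_lorentzians(ppm, p1=(1.1, 4.9, 0.22), p2=(0.45, 5.2, 0.22)):
    return lorentzian(ppm, *p1) + lorentzian(ppm, *p2)


class TestAreaFormulas:
    @pytest.mark.parametrize(
        "shape,func,tol",
        [
            # Lorentzian tails hold ~0.6% of the area beyond +-50 FWHM
            ("lorentzian", lorentzian, 7e-3),
            ("gaussian", gaussian, 1e-6),
        ],
    )
    def test_analytic_area_matches_numeric_integral(self, shape, func, tol):
        fit = PeakFit(label="x", shape=shape, center=5.0, amplitude=1.3, fwhm=0.31)
        numeric, _ = quad(
            lambda x: func(x, 1.3, 5.0, 0.31), 5.0 - 50 * 0.31, 5.0 + 50 * 0.31,
            limit=400,
        )
        assert fit.area == pytest.approx(numeric, rel=tol)

    def test_lorentzian_area_closed_form(self):
        fit = PeakFit(label="x", shape="lorentzian", center=0, amplitude=2.0, fwhm=0.5)
        assert fit.area == pytest.approx(2.0 * math.pi * 0.5 / 2.0)


class TestPiWindowFit:
    def test_noiseless_two_peak_recovery(self):
        ppm = np.linspace(6.5, 3.5, 400)
        spec = _spectrum_from(ppm, _two_lorentzians(ppm))
        pi_i, pi_e, _ = fit_pi_window(spec)
        assert pi_i.center == pytest.approx(4.9, abs=1e-3)
        assert pi_e.center == pytest.approx(5.2, abs=1e-3)
        assert pi_i.amplitude == pytest.approx(1.1, rel=1e-3)
        assert pi_e.amplitude == pytest.approx(0.45, rel=1e-3)
        assert pi_i.fwhm == pytest.approx(0.22, rel=1e-3)
        assert pi_e.fwhm == pytest.approx(0.22, rel=1e-3)
        assert not pi_i.flagged and not pi_e.flagged

    def test_scale_invariance_of_normalised_curve(self):
        ppm = np.linspace(6.5, 3.5, 400)
        y = _two_lorentzians(ppm)
        a1 = fit_pi_window(_spectrum_from(ppm, y))[0]
        a2 = fit_pi_window(_spectrum_from(ppm, 7.3 * y))[0]
        assert a2.area == pytest.approx(7.3 * a1.area, rel=1e-6)

    def test_overlapping_peaks_vs_grid_oracle(self):
        """Noisy overlapped doublet: areas within 10% of a brute-force
        grid search over (center, fwhm) pairs with linear least squares
        for the heights."""
        rng = np.random.default_rng(5)
        ppm = np.linspace(6.0, 4.0, 300)
        truth = _two_lorentzians(ppm)
        noise_sd = truth.max() / 10.0
        y = truth + rng.normal(0, noise_sd, len(ppm))
        spec = _spectrum_from(ppm, y)
        pi_i, pi_e, _ = fit_pi_window(spec, baseline_order=0)

        best = None
        for c1 in np.arange(4.80, 5.01, 0.02):
            for c2 in np.arange(5.10, 5.31, 0.02):
                for w in np.arange(0.14, 0.32, 0.02):
                    basis = np.column_stack(
                        [lorentzian(ppm, 1.0, c1, w), lorentzian(ppm, 1.0, c2, w),
                         np.ones_like(ppm)]
                    )
                    coef, res, *_ = np.linalg.lstsq(basis, y, rcond=None)
                    rss = float(res[0]) if len(res) else float(
                        np.sum((basis @ coef - y) ** 2)
                    )
                    if best is None or rss < best[0]:
                        best = (rss, coef[0] * math.pi * w / 2, coef[1] * math.pi * w / 2)
        _, oracle_i, oracle_e = best
        assert pi_i.area == pytest.approx(oracle_i, rel=0.10)
        assert pi_e.area == pytest.approx(oracle_e, rel=0.10)

    def test_noise_only_window_flagged(self):
        rng = np.random.default_rng(0)
        ppm = np.linspace(6.5, 3.5, 400)
        spec = _spectrum_from(ppm, rng.normal(0, 1.0, len(ppm)))
        pi_i, pi_e, _ = fit_pi_window(spec)
        assert pi_i.flagged


class TestSinglePeak:
    def test_noiseless_exact_recovery_and_linearity(self):
        ppm = np.linspace(1.5, -1.5, 300)
        y = lorentzian(ppm, 5.0, 0.0, 0.16)
        fit = fit_single_peak(_spectrum_from(ppm, y), "PCr", 0.0, (-1.2, 1.2))
        assert fit.amplitude == pytest.approx(5.0, rel=1e-4)
        assert fit.fwhm == pytest.approx(0.16, rel=1e-4)
        half = fit_single_peak(_spectrum_from(ppm, y / 2), "PCr", 0.0, (-1.2, 1.2))
        assert half.area == pytest.approx(fit.area / 2, rel=1e-6)

    def test_converges_from_offset_initial_center(self):
        ppm = np.linspace(1.5, -1.5, 300)
        y = lorentzian(ppm, 5.0, 0.0, 0.16)
        fit = fit_single_peak(_spectrum_from(ppm, y), "PCr", 0.3, (-1.2, 1.2))
        assert fit.center == pytest.approx(0.0, abs=1e-3)


class TestSaturationCurve:
    def _fit(self, area_scale=1.0):
        return PeakFit(
            label="Pi_i", shape="lorentzian", center=4.9,
            amplitude=1.1 * area_scale, fwhm=0.22, residual_rms=0.01,
        )

    def test_identical_condition_and_control_gives_one(self):
        curve = build_saturation_curve([(0.0, self._fit())], self._fit(), "Pi_i")
        assert curve.values[0] == pytest.approx(1.0)

    def test_missing_condition_shortens_curve_with_warning(self):
        fits = [(t, self._fit()) for t in (0.0, 0.5, 1.0)]
        bad = PeakFit(
            label="Pi_i", shape="lorentzian", center=4.9,
            amplitude=0.0, fwhm=0.1, residual_rms=0.01,
        )
        fits.append((2.0, bad))
        with pytest.warns(UserWarning):
            curve = build_saturation_curve(fits, self._fit(), "Pi_i")
        assert len(curve.taus) == 3

    def test_nonpositive_control_rejected(self):
        bad_ctrl = PeakFit(
            label="Pi_i", shape="lorentzian", center=4.9,
            amplitude=0.0, fwhm=0.1,
        )
        with pytest.raises(ValueError):
            build_saturation_curve([(0.0, self._fit())], bad_ctrl, "Pi_i")

    def test_mixed_metabolites_rejected(self):
        other = PeakFit(label="PCr", shape="lorentzian", center=0.0,
                        amplitude=1.0, fwhm=0.2)
        with pytest.raises(ValueError):
            build_saturation_curve([(0.0, other)], self._fit(), "Pi_i")

    def test_curve_invariants(self):
        with pytest.raises(ValueError):
            SaturationCurve("Pi_i", [0, 0], [1, 1], [0, 0])  # duplicate taus
        with pytest.raises(ValueError):
            SaturationCurve("Pi_i", [0, 1], [1, -1], [0, 0])  # nonpositive


class TestEndToEndCurve:
    def test_noiseless_curve_matches_decay_fraction(self, noiseless_session, noiseless_truth):
        """Full spectral route reproduces the exchange model pointwise."""
        from mtmrs.pipeline import RunConfig, run_session

        res = run_session(noiseless_session, RunConfig(phase_mode="none"))
        expected = decay_fraction(
            noiseless_truth.kf_pi, noiseless_truth.t1_pi, res.pi_curve.taus
        )
        assert np.allclose(res.pi_curve.values, expected, rtol=2e-3)

    def test_noisy_curves_decrease_with_tau(self):
        """Spearman correlation of the Pi(i) curve with tau is negative in
        nearly all noisy realisations at the default SNR."""
        from scipy.stats import spearmanr

        from mtmrs.pipeline import run_session

        negatives = 0
        n_seeds = 8
        for seed in range(n_seeds):
            truth = GroundTruth(noise_sd=0.025, kf_pi=0.25)
            res = run_session(simulate_session(truth, seed=seed))
            rho = spearmanr(res.pi_curve.taus, res.pi_curve.values).statistic
            negatives += rho < 0
        assert negatives >= n_seeds - 1
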