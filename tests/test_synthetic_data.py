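"""Forward model: exchange decay, FID synthesis, phantom cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtmrs.io import write_cohort_bundle
from mtmrs.synthetic_data import (
    AcquisitionConfig,
    Condition,
    GroundTruth,
    Peak,
    bloch_mcconnell_decay,
    decay_fraction,
    make_phantom_cohort,
    simulate_fid,
)


class TestDecayFraction:
    @pytest.mark.parametrize(
        "kf,t1,tau,expected",
        [
            (0.0, 3.1, 7.4, 1.0),            # no exchange, no transfer
            (0.0, 1.0, 0.5, 1.0),
            (0.3, 3.1, 0.0, 1.0),            # zero saturation time
            (0.2, 3.1, 7.4, 0.6252899930),   # closed form, checked by hand
            (0.2, 3.1, 1e6, 1.0 / (1.0 + 0.2 * 3.1)),  # steady-state limit
        ],
    )
    def test_values(self, kf, t1, tau, expected):
        assert decay_fraction(kf, t1, tau) == pytest.approx(expected, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            decay_fraction(0.2, 0.0, 1.0)
        with pytest.raises(ValueError):
            decay_fraction(0.2, -1.0, 1.0)
        with pytest.raises(ValueError):
            decay_fraction(-0.1, 3.1, 1.0)

    @given(
        kf=st.floats(0.0, 1.0),
        t1=st.floats(1.0, 7.0),
        tau1=st.floats(0.0, 10.0),
        tau2=st.floats(0.0, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_bounded(self, kf, t1, tau1, tau2):
        lo, hi = sorted((tau1, tau2))
        s_lo = decay_fraction(kf, t1, lo)
        s_hi = decay_fraction(kf, t1, hi)
        assert 0.0 < s_hi <= s_lo <= 1.0
        # also nonincreasing in kf
        assert decay_fraction(kf + 0.1, t1, hi) <= s_hi + 1e-12


class TestBlochMcConnell:
    def test_matches_closed_form_on_grid(self):
        taus = np.linspace(0.0, 10.0, 11)
        for kf in (0.0, 0.05, 0.2, 0.5, 1.0):
            for t1 in (1.0, 3.1, 7.0):
                ode = bloch_mcconnell_decay(kf, t1, taus)
                closed = decay_fraction(kf, t1, taus)
                assert np.allclose(ode, closed, rtol=1e-6, atol=1e-9)

    def test_partial_saturation_decays_less(self):
        taus = [1.0, 3.0, 7.4]
        full = bloch_mcconnell_decay(0.3, 3.1, taus, saturation_efficiency=1.0)
        partial = bloch_mcconnell_decay(0.3, 3.1, taus, saturation_efficiency=0.6)
        none = bloch_mcconnell_decay(0.3, 3.1, taus, saturation_efficiency=0.0)
        assert np.all(partial > full)
        assert np.allclose(none, 1.0, atol=1e-9)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            bloch_mcconnell_decay(0.2, 3.1, [])


class TestAcquisition:
    def test_tau_grid_matches_pulse_train_timing(self):
        acq = AcquisitionConfig()
        assert acq.pulse_unit_duration == pytest.approx(0.16929)
        # 44 pulses x 169.29 ms ~ 7.45 s; labels ~0, 0.5, 1, 2, 3, 5, 7.4 s
        labels = [0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 7.4]
        assert np.allclose(acq.tau_grid, labels, atol=0.09)
        assert acq.tau(44) == pytest.approx(7.44876)
        assert acq.dwell_time == pytest.approx(1.0 / acq.bandwidth)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            AcquisitionConfig(n_points=2000)  # not a power of two
        with pytest.raises(ValueError):
            AcquisitionConfig(bandwidth=0.0)
        with pytest.raises(ValueError):
            AcquisitionConfig(pulse_counts=(0, 6, 3))

    def test_ground_truth_validation(self):
        with pytest.raises(ValueError):
            GroundTruth(kf_pi=-0.1)
        with pytest.raises(ValueError):
            GroundTruth(delta_pi_i=6.5)


class TestSimulateFid:
    def test_deterministic_given_seed(self):
        truth = GroundTruth(noise_sd=0.05)
        a = simulate_fid(truth, Condition.saturation(12), seed=42)
        b = simulate_fid(truth, Condition.saturation(12), seed=42)
        assert np.array_equal(a.samples, b.samples)
        c = simulate_fid(truth, Condition.saturation(12), seed=43)
        assert not np.array_equal(a.samples, c.samples)

    def test_peak_positions_in_spectrum(self, noiseless_truth):
        fid = simulate_fid(noiseless_truth, Condition.control(), seed=0)
        acq = fid.acquisition
        spec = np.fft.fftshift(np.fft.fft(fid.samples))
        ppm = np.fft.fftshift(
            np.fft.fftfreq(acq.n_points, d=acq.dwell_time)
        ) / acq.spectrometer_frequency
        step = ppm[1] - ppm[0]
        mag = np.abs(spec)
        # skip the overlapping Pi doublet and the broad PME/PDE resonances,
        # whose maxima shift a few points on the phospholipid shoulder
        isolated = {"PCr", "gATP", "aATP", "bATP"}
        for peak in noiseless_truth.peak_table:
            if peak.label not in isolated:
                continue
            window = np.abs(ppm - peak.shift) < 0.3
            local_max_ppm = ppm[window][np.argmax(mag[window])]
            assert abs(local_max_ppm - peak.shift) <= step + 1e-12

    def test_single_peak_height_matches_analytic_lorentzian(self):
        # FT of A*exp(2pi i f t - t/T2): absorption height = A*T2/dwell
        acq = AcquisitionConfig()
        truth = GroundTruth(
            peak_table=(Peak("PCr", 0.0, 2.0, 8.0),),
            baseline_amplitude=0.0,
            noise_sd=0.0,
        )
        fid = simulate_fid(truth, Condition.control(), acq=acq, seed=0)
        samples = fid.samples.copy()
        samples[0] *= 0.5  # trapezoid correction of the half-sample offset
        spec = np.fft.fftshift(np.fft.fft(samples)).real
        t2 = 1.0 / (np.pi * 8.0)
        expected_height = 2.0 * t2 / acq.dwell_time
        assert spec.max() == pytest.approx(expected_height, rel=2e-3)

    def test_saturation_scales_pi_by_decay_fraction(self):
        """Control vs saturation Pi(i) signal ratio equals the exchange
        decay fraction exactly (isolated-peak phantom)."""
        truth = GroundTruth(
            peak_table=(Peak("Pi_i", 4.9, 1.1, 11.0),),
            baseline_amplitude=0.0,
            noise_sd=0.0,
        )
        ctrl = simulate_fid(truth, Condition.control(), seed=0)
        sat = simulate_fid(truth, Condition.saturation(44), seed=0)

        def pi_signal(fid):
            return np.abs(np.fft.fft(fid.samples)).max()

        expected = decay_fraction(truth.kf_pi, truth.t1_pi, sat.tau)
        assert pi_signal(sat) / pi_signal(ctrl) == pytest.approx(expected, rel=1e-9)

    def test_peak_outside_window_rejected(self):
        truth = GroundTruth(
            peak_table=(Peak("rogue", 0.0, 1.0, 10.0),), delta_pi_i=4.9
        )
        bad = GroundTruth(
            peak_table=(Peak("rogue", 40.0, 1.0, 10.0),), delta_pi_i=4.9
        )
        simulate_fid(truth, Condition.control(), seed=0)
        with pytest.raises(ValueError, match="rogue"):
            simulate_fid(bad, Condition.control(), seed=0)


class TestPhantomCohort:
    def test_structure_and_ground_truth_table(self):
        cohort = make_phantom_cohort(n_subjects=3, seed=7)
        assert len(cohort.subjects) == 3
        acq = cohort.acquisition
        for s in cohort.subjects:
            assert set(s.sessions) == {"pre", "post"}
            for fids in s.sessions.values():
                kinds = [f.condition.kind for f in fids]
                assert kinds.count("saturation") == len(acq.pulse_counts)
                assert kinds.count("control") == 1
        table = cohort.ground_truth_table()
        assert len(table) == 6
        assert {"kf_pi", "noise_sd", "phase0"} <= set(table.columns)

    def test_fixed_seed_byte_identical_bundle(self, tmp_path):
        for sub in ("a", "b"):
            cohort = make_phantom_cohort(n_subjects=2, seed=11)
            write_cohort_bundle(cohort, tmp_path / sub)
        files_a = sorted((tmp_path / "a").rglob("*.*"))
        files_b = sorted((tmp_path / "b").rglob("*.*"))
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes()

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError):
            make_phantom_cohort(n_subjects=2, pre_kf_distribution=(-0.1, 0.05))
        with pytest.raises(ValueError):
            make_phantom_cohort(n_subjects=0)
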