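"""Phasor transform, lifetimes, calibration and bi-exponential fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermoflim.phasor import (
    DecayHistogram,
    Phasor,
    PhasorDomainError,
    ReferenceStandard,
    calibration_factor,
    fit_biexponential,
    lifetimes_from_phasor,
    multiexp_phasor,
    phasor_transform,
    reference_calibrate,
    roi_phasor_summary,
    single_exp_phasor,
)
from thermoflim.synthetic import FPTDecayModel, simulate_decay

PERIOD = 25.0
OMEGA = 2 * np.pi / PERIOD


def mono_decay(tau, n_bins=256, irf_sigma=0.0, photons=1e6, noiseless=True, seed=0):
    model = FPTDecayModel((tau, tau), (1.0, 0.0), irf_sigma=irf_sigma,
                          period=PERIOD, n_bins=n_bins)
    return simulate_decay(model, photons, seed=seed, noiseless=noiseless)


class TestPhasorTransform:
    def test_prompt_spike_maps_to_unit_phasor(self):
        counts = np.zeros(256)
        counts[0] = 1000
        p = phasor_transform(DecayHistogram(counts, PERIOD / 256, PERIOD))
        # exact up to the half-bin phase of the bin-center convention
        assert p.g == pytest.approx(1.0, abs=1e-3)
        assert p.s == pytest.approx(0.0, abs=0.02)

    def test_uniform_counts_map_to_origin(self):
        counts = np.full(256, 50.0)
        p = phasor_transform(DecayHistogram(counts, PERIOD / 256, PERIOD))
        assert abs(p.g) < 1e-12 and abs(p.s) < 1e-12

    def test_two_ns_mono_exponential_lands_at_closed_form_point(self):
        p = phasor_transform(mono_decay(2.0))
        assert p.g == pytest.approx(0.798, abs=0.002)
        assert p.s == pytest.approx(0.401, abs=0.002)

    def test_empty_histogram_raises_instead_of_nan(self):
        with pytest.raises(ValueError, match="empty"):
            phasor_transform(DecayHistogram(np.zeros(64), PERIOD / 64, PERIOD))

    def test_linearity_phasor_of_sum_is_weighted_mean(self, rng):
        d1 = mono_decay(1.0, noiseless=False, photons=2e5, seed=1)
        d2 = mono_decay(4.0, noiseless=False, photons=8e5, seed=2)
        pooled = DecayHistogram(d1.counts + d2.counts, d1.bin_width, d1.period)
        p1, p2, pp = (phasor_transform(d) for d in (d1, d2, pooled))
        w1 = d1.total_counts / pooled.total_counts
        assert pp.g == pytest.approx(w1 * p1.g + (1 - w1) * p2.g, abs=1e-12)
        assert pp.s == pytest.approx(w1 * p1.s + (1 - w1) * p2.s, abs=1e-12)

    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0, 4.0, 8.0])
    def test_mono_exponential_on_universal_semicircle(self, tau):
        p = phasor_transform(mono_decay(tau))
        lt = lifetimes_from_phasor(p)
        assert (p.g - 0.5) ** 2 + p.s**2 == pytest.approx(0.25, abs=0.005)
        assert lt.tau_phi == pytest.approx(tau, rel=0.01)
        assert lt.tau_M == pytest.approx(tau, rel=0.01)


class TestLifetimesFromPhasor:
    def test_unit_phasor_gives_zero_lifetimes(self):
        lt = lifetimes_from_phasor(Phasor(1.0, 0.0, omega=OMEGA))
        assert lt.tau_phi == 0.0 and lt.tau_M == 0.0

    def test_closed_form_two_ns_point(self):
        g, s = single_exp_phasor(2.0, OMEGA)
        lt = lifetimes_from_phasor(Phasor(g, s, omega=OMEGA))
        assert lt.tau_phi == pytest.approx(2.0, rel=1e-9)
        assert lt.tau_M == pytest.approx(2.0, rel=1e-9)

    def test_equal_intensity_mixture_phase_below_modulation(self):
        # equal photon fractions of 1 ns and 4 ns -> pre-exp amplitudes 1/tau
        g, s = multiexp_phasor([1.0, 4.0], [1.0, 0.25], OMEGA)
        lt = lifetimes_from_phasor(Phasor(g, s, omega=OMEGA))
        assert lt.tau_phi == pytest.approx(2.04, abs=0.01)
        assert lt.tau_M == pytest.approx(2.90, abs=0.01)
        assert lt.tau_phi < lt.tau_M

    @pytest.mark.parametrize("g,s", [(-0.1, 0.3), (0.9, 0.6), (0.2, -0.2)])
    def test_out_of_domain_points_flagged_not_clipped(self, g, s):
        with pytest.raises(PhasorDomainError):
            lifetimes_from_phasor(Phasor(g, s, omega=OMEGA))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        taus=st.lists(st.floats(0.05, 12.0), min_size=2, max_size=5),
        amps=st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5),
    )
    def test_multiexponential_ordering_tau_phi_below_tau_m(self, taus, amps):
        g, s = multiexp_phasor(taus, amps[: len(taus)], OMEGA)
        lt = lifetimes_from_phasor(Phasor(g, s, omega=OMEGA))
        assert lt.tau_phi <= lt.tau_M + 1e-9


class TestReferenceCalibration:
    def test_ideal_reference_is_identity(self):
        g, s = single_exp_phasor(3.0, OMEGA)
        ref = ReferenceStandard(3.0, Phasor(g, s, omega=OMEGA))
        sample = Phasor(0.6, 0.3, omega=OMEGA)
        out = reference_calibrate(sample, ref)
        assert out.g == pytest.approx(0.6) and out.s == pytest.approx(0.3)

    def test_reference_maps_onto_its_ideal_position(self):
        measured = phasor_transform(mono_decay(2.0, irf_sigma=0.4))
        ref = ReferenceStandard(2.0, measured)
        out = reference_calibrate(measured, ref)
        g, s = single_exp_phasor(2.0, OMEGA)
        assert out.g == pytest.approx(g, abs=1e-12)
        assert out.s == pytest.approx(s, abs=1e-12)

    @pytest.mark.parametrize("irf_sigma", [0.1, 0.3, 0.6])
    def test_irf_bias_removed_across_widths(self, irf_sigma):
        measured_ref = phasor_transform(mono_decay(2.5, irf_sigma=irf_sigma))
        ref = ReferenceStandard(2.5, measured_ref)
        sample = phasor_transform(mono_decay(1.3, irf_sigma=irf_sigma))
        out = reference_calibrate(sample, ref)
        lt = lifetimes_from_phasor(out)
        assert lt.tau_phi == pytest.approx(1.3, rel=0.01)
        assert lt.tau_M == pytest.approx(1.3, rel=0.01)

    def test_vanishing_reference_modulus_rejected(self):
        ref = ReferenceStandard(2.0, Phasor(1e-9, 0.0, omega=OMEGA))
        with pytest.raises(ValueError, match="modulus"):
            calibration_factor(ref)


class TestRoiSummary:
    def test_pooled_phasor_equals_summed_histogram_phasor(self, two_cell_scene):
        meta = two_cell_scene.meta
        summaries = roi_phasor_summary(
            two_cell_scene.stack, two_cell_scene.mask,
            meta["bin_width_ns"], meta["period_ns"], min_photons_per_pixel=0.0,
        )
        s1 = summaries[0]
        pooled_counts = two_cell_scene.stack[:, two_cell_scene.mask == 1].sum(axis=1)
        direct = phasor_transform(
            DecayHistogram(pooled_counts, meta["bin_width_ns"], meta["period_ns"])
        )
        assert s1.phasor.g == pytest.approx(direct.g, abs=1e-9)
        assert s1.phasor.s == pytest.approx(direct.s, abs=1e-9)
        assert s1.photons == pytest.approx(direct.total_counts)

    def test_impossible_threshold_flags_cells_insufficient(self, two_cell_scene):
        meta = two_cell_scene.meta
        summaries = roi_phasor_summary(
            two_cell_scene.stack, two_cell_scene.mask,
            meta["bin_width_ns"], meta["period_ns"],
            min_photons_per_pixel=1e12,
        )
        assert all(s.status == "insufficient photons" for s in summaries)
        assert all(s.n_pixels == 0 for s in summaries)

    def test_hotter_cell_lies_anticlockwise(self, two_cell_scene):
        meta = two_cell_scene.meta
        summaries = roi_phasor_summary(
            two_cell_scene.stack, two_cell_scene.mask,
            meta["bin_width_ns"], meta["period_ns"],
        )
        # anticlockwise along the semicircle = larger polar angle
        ang = [np.arctan2(s.phasor.s, s.phasor.g) for s in summaries]
        assert ang[1] > ang[0]  # cell 2 is the hotter one

    def test_mismatched_mask_rejected(self, two_cell_scene):
        meta = two_cell_scene.meta
        with pytest.raises(ValueError, match="mask"):
            roi_phasor_summary(
                two_cell_scene.stack, np.zeros((3, 3), dtype=np.uint16),
                meta["bin_width_ns"], meta["period_ns"],
            )


class TestBiexponentialFit:
    def test_mono_exponential_input_collapses_with_correct_lifetime(self):
        decay = mono_decay(2.0, photons=1e6, noiseless=False, seed=3)
        fit = fit_biexponential(decay)
        assert fit.tau_m == pytest.approx(2.0, rel=0.02)
        assert fit.collapsed or min(fit.a1, fit.a2) < 0.05

    def test_parameter_recovery_from_generator_truth(self):
        model = FPTDecayModel((1.2, 3.5), (0.6, 0.4), irf_sigma=0.0)
        decay = simulate_decay(model, 1e6, seed=5)
        fit = fit_biexponential(decay)
        assert fit.tau1 == pytest.approx(1.2, rel=0.05)
        assert fit.tau2 == pytest.approx(3.5, rel=0.05)
        assert fit.a1 == pytest.approx(0.6, rel=0.05)
        true_tau_m = 0.6 * 1.2 + 0.4 * 3.5
        assert fit.tau_m == pytest.approx(true_tau_m, rel=0.05)

    def test_low_count_histogram_rejected(self):
        decay = mono_decay(2.0, photons=100, noiseless=False, seed=0)
        with pytest.raises(ValueError, match="floor"):
            fit_biexponential(decay)
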