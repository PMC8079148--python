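"""Polarized-decay processing chain: alignment, g, anisotropy, fits."""

import numpy as np
import pytest

from dicerkin import (
    InstrumentModel,
    PhotophysicsModel,
    PolarizedDecay,
    align_channels,
    analyze_run,
    anisotropy_trace,
    estimate_g,
    expected_counts,
    fit_anisotropy,
    fit_lifetime,
    refit_fast_phase,
    simulate_decay,
    subtract_background,
    total_intensity,
)
from dicerkin.tcspc.analysis import AnisotropyTrace


def noiseless_decay(model, inst):
    """PolarizedDecay built from expected (Poisson-mean) counts."""
    lam_vv, lam_vh = expected_counts(model, inst)
    return PolarizedDecay(
        bin_ps=inst.bin_centers_ps,
        i_vv=lam_vv,
        i_vh=lam_vh,
        bin_width_ps=inst.bin_width_ps,
        metadata={"instrument": {"window_ns": inst.window_ns}},
    )


class TestAlignChannels:
    def test_zero_delay_recovers_zero_shift(self, cy3_control):
        inst = InstrumentModel(channel_delay_ps=0.0, background_rate=1.0, total_counts=1e6)
        decay = simulate_decay(cy3_control, inst, seed=2)
        assert align_channels(decay).metadata["applied_shift_bins"] == 0

    def test_380ps_delay_recovers_24_bins(self, cy3_control, study_instrument):
        """380 ps on a 16 ps grid is recovered as the nearest-bin shift, 24
        bins (384 ps)."""
        decay = simulate_decay(cy3_control, study_instrument, seed=3)
        assert align_channels(decay).metadata["applied_shift_bins"] == 24

    def test_shift_invariant_to_channel_scaling(self, cy3_control, study_instrument):
        decay = simulate_decay(cy3_control, study_instrument, seed=4)
        scaled = PolarizedDecay(
            bin_ps=decay.bin_ps,
            i_vv=decay.i_vv,
            i_vh=decay.i_vh * 10,
            bin_width_ps=decay.bin_width_ps,
            metadata=decay.metadata,
        )
        assert (
            align_channels(scaled).metadata["applied_shift_bins"]
            == align_channels(decay).metadata["applied_shift_bins"]
        )


class TestSubtractBackground:
    def test_background_free_estimate_near_zero(self, cy3_control):
        inst = InstrumentModel(background_rate=0.0, total_counts=1e6)
        out = subtract_background(align_channels(simulate_decay(cy3_control, inst, seed=5)))
        assert out.metadata["background_vv"] == pytest.approx(0.0, abs=0.3)
        assert out.metadata["background_vh"] == pytest.approx(0.0, abs=0.3)

    def test_injected_background_recovered(self, cy3_control):
        inst = InstrumentModel(background_rate=5.0, total_counts=1e6)
        out = subtract_background(align_channels(simulate_decay(cy3_control, inst, seed=6)))
        # ~85 pre-rise bins -> s.e. of the mean ~ sqrt(5/85)
        se = np.sqrt(5.0 / 80.0)
        assert out.metadata["background_vh"] == pytest.approx(5.0, abs=4 * se)

    def test_subtraction_preserves_tail_slope(self, cy3_control):
        """Fitted lifetime shifts < 1% after background subtraction."""
        inst = InstrumentModel(background_rate=5.0, total_counts=1e7)
        decay = align_channels(simulate_decay(cy3_control, inst, seed=7))
        sub = subtract_background(decay)
        g = estimate_g(sub)
        tau_sub = fit_lifetime(*total_intensity(sub, g), n_components=1).mean_lifetime
        clean_inst = InstrumentModel(background_rate=0.0, total_counts=1e7)
        clean = subtract_background(align_channels(simulate_decay(cy3_control, clean_inst, seed=7)))
        tau_clean = fit_lifetime(*total_intensity(clean, g), n_components=1).mean_lifetime
        assert tau_sub == pytest.approx(tau_clean, rel=0.01)

    def test_insufficient_prerise_region_rejected(self, cy3_control):
        inst = InstrumentModel(irf_peak_ns=0.1, background_rate=1.0, total_counts=1e6)
        decay = simulate_decay(cy3_control, inst, seed=8)
        with pytest.raises(ValueError, match="pre-rise"):
            subtract_background(decay)


class TestEstimateG:
    def test_matched_channels_give_unity(self, cy3_control):
        inst = InstrumentModel(
            g_true=1.0, nd_attenuation=1.0, channel_delay_ps=0.0,
            background_rate=0.0, total_counts=1e7,
        )
        decay = subtract_background(align_channels(simulate_decay(cy3_control, inst, seed=9)))
        assert estimate_g(decay) == pytest.approx(1.0, rel=0.02)

    def test_injected_mismatch_recovered_within_2pct(self, cy3_control, study_instrument):
        """g_true * nd = 10 recovered from the control's tail over seeds."""
        gs = []
        for seed in range(10):
            decay = subtract_background(
                align_channels(simulate_decay(cy3_control, study_instrument, seed=100 + seed))
            )
            gs.append(estimate_g(decay))
        assert np.median(gs) == pytest.approx(10.0, rel=0.02)

    def test_invariant_to_background_level(self, cy3_control):
        """After subtraction, the median g does not depend on the injected
        dark rate (single-seed estimates carry ~3% tail Poisson noise, so
        medians over seeds are compared)."""
        inst_bg = InstrumentModel(background_rate=8.0, total_counts=1e7)
        inst_clean = InstrumentModel(background_rate=0.0, total_counts=1e7)
        g_bg, g_clean = [], []
        for seed in range(8):
            g_bg.append(estimate_g(subtract_background(align_channels(
                simulate_decay(cy3_control, inst_bg, seed=700 + seed)))))
            g_clean.append(estimate_g(subtract_background(align_channels(
                simulate_decay(cy3_control, inst_clean, seed=800 + seed)))))
        assert np.median(g_bg) == pytest.approx(np.median(g_clean), rel=0.02)


class TestAnisotropyAlgebra:
    def test_identity_recovers_input_r(self, blt_dsrna, clean_instrument):
        """Noiseless channels through the anisotropy ratio reproduce the
        model r(t) within 0.005 beyond 3 IRF widths of the origin."""
        decay = noiseless_decay(blt_dsrna, clean_instrument)
        tracer = anisotropy_trace(decay, g=1.0)
        t_rel = tracer.time_ns - tracer.origin_ns
        sel = tracer.valid_mask & (t_rel > 3 * 0.060) & (t_rel < 8.0)
        expected = blt_dsrna.anisotropy(t_rel[sel])
        assert np.all(np.abs(tracer.r[sel] - expected) < 0.005)

    def test_channel_reconstruction_identity(self, blt_dsrna, clean_instrument):
        """g*I_VV = I_tot (1+2r)/3 and I_VH = I_tot (1-r)/3 reconstruct the
        corrected channels exactly."""
        decay = noiseless_decay(blt_dsrna, clean_instrument)
        g = 1.0
        _, itot = total_intensity(decay, g)
        tracer = anisotropy_trace(decay, g)
        m = tracer.valid_mask
        r = tracer.r[m]
        assert np.allclose(g * decay.i_vv[m], itot[m] * (1 + 2 * r) / 3, rtol=1e-10)
        assert np.allclose(decay.i_vh[m], itot[m] * (1 - r) / 3, rtol=1e-10)

    def test_equal_scaled_channels_give_zero_r(self):
        n = 300
        vv = np.full(n, 500.0)
        decay = PolarizedDecay(
            bin_ps=np.arange(n) * 16.0, i_vv=vv, i_vh=2.0 * vv, bin_width_ps=16.0
        )
        tracer = anisotropy_trace(decay, g=2.0)
        assert np.allclose(tracer.r[tracer.valid_mask], 0.0)

    def test_r_bounded_for_physical_simulations(self, blt_dsrna, cy3_control, study_instrument):
        """-0.2 < r <= 0.42 on well-populated bins (at the default 100-count
        mask threshold pure counting noise can reach |dr| ~ 0.2 per bin, so
        the physical bound is asserted where it is statistically meaningful)."""
        for model, seed in ((blt_dsrna, 21), (cy3_control, 22)):
            decay = subtract_background(
                align_channels(simulate_decay(model, study_instrument, seed=seed))
            )
            g = estimate_g(
                subtract_background(
                    align_channels(simulate_decay(cy3_control, study_instrument, seed=seed + 50))
                )
            )
            tracer = anisotropy_trace(decay, g, min_denominator_counts=2000.0)
            r = tracer.r[tracer.valid_mask]
            assert np.all(r > -0.2) and np.all(r <= 0.42)

    def test_low_count_bins_masked(self, blt_dsrna):
        inst = InstrumentModel(total_counts=3e4, background_rate=0.0)
        decay = subtract_background(align_channels(simulate_decay(blt_dsrna, inst, seed=23)))
        tracer = anisotropy_trace(decay, g=10.0, min_denominator_counts=100.0)
        denom = 10.0 * decay.i_vv + 2 * decay.i_vh
        assert not np.any(denom[tracer.valid_mask] < 100.0)


class TestLifetimeFit:
    def test_control_lifetime_within_2pct(self, cy3_control, study_instrument):
        decay = subtract_background(
            align_channels(simulate_decay(cy3_control, study_instrument, seed=31))
        )
        g = estimate_g(decay)
        fit = fit_lifetime(*total_intensity(decay, g), n_components=1)
        assert fit.mean_lifetime == pytest.approx(0.300, rel=0.02)

    def test_biexponential_components_recovered(self, study_instrument):
        """Bound-complex lifetimes (1.21 / 2.28 ns, 88% / 12%) recovered
        within 5% at 1e7 counts."""
        model = PhotophysicsModel(
            lifetimes=((1.21, 0.88), (2.28, 0.12)),
            anisotropy_components=((0.3, 0.5),),
        )
        taus1, taus2 = [], []
        for seed in range(5):
            decay = subtract_background(
                align_channels(simulate_decay(model, study_instrument, seed=300 + seed))
            )
            fit = fit_lifetime(*total_intensity(decay, 10.0), n_components=2)
            taus1.append(fit.components[0][0])
            taus2.append(fit.components[1][0])
        assert np.median(taus1) == pytest.approx(1.21, rel=0.05)
        assert np.median(taus2) == pytest.approx(2.28, rel=0.05)

    def test_single_component_source_selects_one(self, cy3_control, study_instrument):
        decay = subtract_background(
            align_channels(simulate_decay(cy3_control, study_instrument, seed=33))
        )
        fit = fit_lifetime(*total_intensity(decay, estimate_g(decay)))
        assert len(fit.components) == 1


class TestAnisotropyFit:
    def test_blt_model_phases_recovered(self, blt_dsrna, cy3_control, study_instrument):
        """Both rotational correlation times of the free-dsRNA model are
        recovered through the full chain at 1e7 counts."""
        res = analyze_run(
            simulate_decay(blt_dsrna, study_instrument, seed=41),
            simulate_decay(cy3_control, study_instrument, seed=42),
            n_phases=2,
        )
        phases = res["anisotropy"].phases
        assert phases[1][1] == pytest.approx(2.6, rel=0.15)
        assert res["fast_phase"][1] == pytest.approx(0.34, rel=0.25)

    def test_minimal_terms_rule_selects_two_phases(self, blt_dsrna, cy3_control, study_instrument):
        res = analyze_run(
            simulate_decay(blt_dsrna, study_instrument, seed=43),
            simulate_decay(cy3_control, study_instrument, seed=44),
        )
        assert len(res["anisotropy"].phases) == 2

    def test_constant_r_trace_has_no_decay(self):
        n = 400
        t = np.arange(n) * 0.016
        tracer = AnisotropyTrace(
            time_ns=t,
            r=np.full(n, 0.25),
            sigma_r=np.full(n, 0.002),
            valid_mask=np.ones(n, dtype=bool),
            origin_ns=0.0,
            g=1.0,
        )
        fit = fit_anisotropy(tracer, n_phases=1)
        assert abs(fit.delta_r) < 1e-3
        assert fit.r0 == pytest.approx(0.25, abs=1e-3)

    def test_delta_r_identity(self, cy3_control, study_instrument):
        res = analyze_run(
            simulate_decay(cy3_control, study_instrument, seed=45),
            simulate_decay(cy3_control, study_instrument, seed=46),
            n_phases=1,
        )
        afit = res["anisotropy"]
        assert afit.delta_r == afit.r0 - afit.r_infinity  # exact identity

    def test_unphysical_r0_flagged(self):
        n = 400
        t = np.arange(n) * 0.016
        r = 0.5 * np.exp(-t / 0.5) + 0.01
        tracer = AnisotropyTrace(
            time_ns=t, r=r, sigma_r=np.full(n, 0.002),
            valid_mask=np.ones(n, dtype=bool), origin_ns=0.0, g=1.0,
        )
        fit = fit_anisotropy(tracer, n_phases=1)
        assert "r0_above_one_photon_limit" in fit.flags


class TestRefitFastPhase:
    def _single_phase_trace(self):
        n = 500
        t = np.arange(n) * 0.016
        r = 0.4 * np.exp(-t / 0.44) + 0.01
        return AnisotropyTrace(
            time_ns=t, r=r, sigma_r=np.full(n, 0.001),
            valid_mask=np.ones(n, dtype=bool), origin_ns=0.0, g=1.0,
        )

    def test_pure_single_phase_matches_global(self):
        tracer = self._single_phase_trace()
        global_fit = fit_anisotropy(tracer, n_phases=1)
        a1, phi1 = refit_fast_phase(tracer, window_ns=1.5)
        assert phi1 == pytest.approx(global_fit.phases[0][1], rel=0.02)
        assert a1 == pytest.approx(global_fit.phases[0][0], rel=0.02)

    def test_full_window_matches_global_single_exp(self):
        tracer = self._single_phase_trace()
        global_fit = fit_anisotropy(tracer, n_phases=1)
        a1, phi1 = refit_fast_phase(tracer, window_ns=tracer.time_ns[-1])
        assert phi1 == pytest.approx(global_fit.phases[0][1], rel=0.01)

    def test_window_too_short_rejected(self):
        tracer = self._single_phase_trace()
        with pytest.raises(ValueError, match="too short"):
            refit_fast_phase(tracer, window_ns=0.2)

    def test_windowed_refit_is_accurate_independent_estimate(
        self, blt_dsrna, cy3_control, study_instrument
    ):
        """The slow-phase-subtracted windowed refit recovers the fast
        correlation time of the free-dsRNA model (median within 15%, every
        seed within 40%)."""
        phi1 = []
        for seed in range(12):
            res = analyze_run(
                simulate_decay(blt_dsrna, study_instrument, seed=500 + 2 * seed),
                simulate_decay(cy3_control, study_instrument, seed=501 + 2 * seed),
                n_phases=2,
            )
            phi1.append(res["fast_phase"][1])
        assert np.median(phi1) == pytest.approx(0.34, rel=0.15)
        assert np.all(np.abs(np.array(phi1) - 0.34) < 0.5 * 0.34)
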