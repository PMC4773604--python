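"""Kernel analytics and event-rule semantics, checked against brute force."""

import numpy as np
import pytest
from scipy.integrate import quad

from cereblearn.plasticity import (
    EligibilityBuffer,
    MFDCNRuleConfig,
    PCDCNRuleConfig,
    PFPCRuleConfig,
    calibrate_tau_ltd,
    ltd_kernel_argmax,
    mfdcn_deferred_on_mf_spike,
    mfdcn_kernel,
    mfdcn_on_mf_spike,
    mfdcn_on_pc_spike,
    normalize_istdp_rates,
    pcdcn_hebbian,
    pcdcn_symmetric,
    pcdcn_symmetric_on_dcn_spike,
    pcdcn_symmetric_on_pc_spike,
    pfpc_ltd_kernel,
    pfpc_on_cf_spike,
    pfpc_on_pf_spike,
)


class TestLTDKernel:
    def test_zero_at_origin(self):
        assert pfpc_ltd_kernel(0.0) == 0.0

    def test_negative_arguments_are_zero(self):
        assert pfpc_ltd_kernel(-1.0) == 0.0

    def test_peak_location_and_value(self):
        # dense-grid numerical maximization oracle
        x = np.arange(0.0, 3.0, 1e-5)
        k = pfpc_ltd_kernel(x)
        i = int(np.argmax(k))
        assert x[i] == pytest.approx(np.arctan(20.0), abs=1e-3)
        assert x[i] == pytest.approx(1.5208, abs=1e-3)
        assert k[i] == pytest.approx(0.2130, abs=5e-4)
        assert ltd_kernel_argmax() == pytest.approx(np.arctan(20.0), rel=1e-9)

    def test_side_lobe_below_five_percent(self):
        x = np.arange(0.0, 10.0, 1e-4)
        k = pfpc_ltd_kernel(x)
        main = k[x < np.pi].max()
        secondary = k[x >= np.pi].max()
        assert 0 < secondary / main < 0.05

    def test_non_negative_and_integrable(self):
        x = np.linspace(0, 50, 20001)
        k = pfpc_ltd_kernel(x)
        assert np.all(k >= 0)
        val, _ = quad(pfpc_ltd_kernel, 0, 30, limit=200)
        assert np.isfinite(val) and val > 0


class TestMFDCNKernel:
    def test_unity_at_origin(self):
        assert mfdcn_kernel(0.0, 2.0) == pytest.approx(1.0)

    def test_zero_at_half_pi(self):
        assert mfdcn_kernel(np.pi / 2, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_direct_evaluation_at_pi(self):
        assert mfdcn_kernel(np.pi, 2.0) == pytest.approx(np.exp(-2 * np.pi), rel=1e-9)

    def test_even_and_bounded(self):
        x = np.linspace(-8, 8, 1001)
        k = mfdcn_kernel(x, 1.5)
        assert np.allclose(k, mfdcn_kernel(-x, 1.5))
        assert np.all((k >= 0) & (k <= 1))

    def test_side_lobes_shrink_with_beta(self):
        lobes = [mfdcn_kernel(np.pi, b) for b in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(lobes, lobes[1:]))


class TestCalibration:
    def test_hundred_ms_delay(self):
        tau = calibrate_tau_ltd(0.100)
        assert tau == pytest.approx(0.100 / 1.5208, abs=1e-4)
        assert tau == pytest.approx(0.0658, abs=2e-4)

    def test_linear_scaling(self):
        assert calibrate_tau_ltd(0.050) == pytest.approx(calibrate_tau_ltd(0.100) / 2)

    def test_kernel_peaks_at_target_delay(self):
        tau = calibrate_tau_ltd(0.125)
        lags = np.arange(0.0, 0.4, 1e-4)
        assert lags[np.argmax(pfpc_ltd_kernel(lags / tau))] == pytest.approx(0.125, abs=1e-3)

    def test_rejects_nonpositive_delay(self):
        with pytest.raises(ValueError):
            calibrate_tau_ltd(0.0)


class TestPFPCEvents:
    def test_empty_buffers_give_zero(self):
        cfg = PFPCRuleConfig()
        dw = pfpc_on_cf_spike([[], [], []], 1.0, cfg)
        assert np.all(dw == 0)

    def test_peak_lag_depression(self):
        cfg = PFPCRuleConfig(tau_ltd=calibrate_tau_ltd(0.100), ltd_scale=1.0)
        dw = pfpc_on_cf_spike([[0.9]], 1.0, cfg)  # PF spike 100 ms before CF
        assert dw[0] == pytest.approx(-0.2130, abs=5e-4)

    def test_coincident_spike_ignored(self):
        cfg = PFPCRuleConfig()
        dw = pfpc_on_cf_spike([[1.0]], 1.0, cfg)
        assert dw[0] == 0.0

    def test_future_spike_rejected(self):
        with pytest.raises(ValueError):
            pfpc_on_cf_spike([[2.0]], 1.0, PFPCRuleConfig())

    def test_ltp_is_fixed_increment(self):
        assert pfpc_on_pf_spike(PFPCRuleConfig(alpha_ltp=0.0)) == 0.0
        assert pfpc_on_pf_spike(PFPCRuleConfig(alpha_ltp=0.002)) == 0.002

    def test_brute_force_oracle_on_random_spikes(self, rng):
        cfg = PFPCRuleConfig(tau_ltd=0.0658, ltd_scale=0.7, truncation_window=0.3)
        t_cf = 2.0
        buffers = [np.sort(rng.uniform(1.5, 2.0, rng.integers(0, 40))) for _ in range(8)]
        dw = pfpc_on_cf_spike(buffers, t_cf, cfg)
        for j, buf in enumerate(buffers):
            expected = -cfg.ltd_scale * sum(
                np.exp(-(t_cf - t) / cfg.tau_ltd) * np.sin((t_cf - t) / cfg.tau_ltd) ** 20
                for t in buf
                if t_cf - t <= cfg.truncation_window
            )
            assert dw[j] == pytest.approx(expected, abs=1e-9)


class TestMFDCNEvents:
    def test_no_spikes_in_window(self):
        assert np.all(mfdcn_on_pc_spike([[], []], 1.0, MFDCNRuleConfig()) == 0)

    def test_coincident_spike_gives_peak_depression(self):
        cfg = MFDCNRuleConfig(ltd_scale=0.5)
        dw = mfdcn_on_pc_spike([[1.0]], 1.0, cfg)
        assert dw[0] == pytest.approx(-0.5)

    def test_cos_zero_lag_contributes_nothing(self):
        cfg = MFDCNRuleConfig(sigma=0.01, ltd_scale=1.0, truncation_window=0.1)
        dw = mfdcn_on_pc_spike([[1.0 - cfg.sigma * np.pi / 2]], 1.0, cfg)
        assert dw[0] == pytest.approx(0.0, abs=1e-12)

    def test_ltp_fixed_increment(self):
        assert mfdcn_on_mf_spike(MFDCNRuleConfig(alpha_ltp=0.01)) == 0.01

    def test_two_sided_window_equals_brute_force(self, rng):
        """Past-sum plus deferred future-sum equals the full double loop."""
        cfg = MFDCNRuleConfig(sigma=0.012, beta=2.0, ltd_scale=0.3, truncation_window=0.036)
        mf_times = np.sort(rng.uniform(0, 1.0, 60))
        pc_times = np.sort(rng.uniform(0, 1.0, 40))
        # event-driven accumulation
        total = 0.0
        for t_pc in pc_times:
            past = mf_times[mf_times <= t_pc]
            total += mfdcn_on_pc_spike([past], t_pc, cfg)[0]
        for t_mf in mf_times:
            total += mfdcn_deferred_on_mf_spike(pc_times, t_mf, cfg)
        # brute-force double loop over all pairs
        brute = 0.0
        for t_pc in pc_times:
            for t_mf in mf_times:
                lag = t_pc - t_mf
                if abs(lag) <= cfg.truncation_window:
                    u = lag / cfg.sigma
                    brute += -cfg.ltd_scale * np.exp(-abs(u * cfg.beta)) * np.cos(u) ** 2
        assert total == pytest.approx(brute, abs=1e-9)


class TestPCDCNRules:
    def test_hebbian_closed_forms(self):
        cfg = PCDCNRuleConfig(tau1=0.02, tau2=0.01, scale=1.0)
        assert pcdcn_hebbian(0.02, cfg) == pytest.approx(np.exp(-1))
        assert pcdcn_hebbian(-0.01, cfg) == pytest.approx(-np.exp(-1))
        assert pcdcn_hebbian(5.0, cfg) == pytest.approx(0.0, abs=1e-9)
        assert pcdcn_hebbian(-5.0, cfg) == pytest.approx(0.0, abs=1e-9)

    def test_hebbian_coincidence_potentiates(self):
        cfg = PCDCNRuleConfig(scale=0.5)
        assert pcdcn_hebbian(0.0, cfg) == pytest.approx(0.5)

    def test_symmetric_pair_values(self):
        cfg = PCDCNRuleConfig(kernel_choice="symmetric", sigma=0.02,
                              ltp_max=0.025, ltd_max=0.005)
        assert pcdcn_symmetric(0.0, cfg) == pytest.approx(0.020)
        assert pcdcn_symmetric(0.02 * np.pi / 2, cfg) == pytest.approx(-0.005)

    def test_symmetric_isolated_pre_spike_depresses(self):
        cfg = PCDCNRuleConfig(kernel_choice="symmetric", ltp_max=0.025, ltd_max=0.005)
        assert pcdcn_symmetric_on_pc_spike([], 1.0, cfg) == pytest.approx(-0.005)

    def test_symmetric_event_sum_equals_brute_force(self, rng):
        cfg = PCDCNRuleConfig(kernel_choice="symmetric", sigma=0.02,
                              ltp_max=0.04, ltd_max=0.008, truncation_window=0.06)
        pre = np.sort(rng.uniform(0, 1, 50))
        post = np.sort(rng.uniform(0, 1, 30))
        total = 0.0
        for t in pre:
            total += pcdcn_symmetric_on_pc_spike(post[post <= t], t, cfg)
        for t in post:
            total += pcdcn_symmetric_on_dcn_spike(pre[pre < t], t, cfg)
        brute = -cfg.ltd_max * len(pre)
        for tp in pre:
            for td in post:
                if abs(tp - td) <= cfg.truncation_window:
                    u = (tp - td) / cfg.sigma
                    brute += cfg.ltp_max * np.exp(-abs(u)) * np.cos(u) ** 2
        assert total == pytest.approx(brute, abs=1e-9)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PCDCNRuleConfig(kernel_choice="other")
        with pytest.raises(ValueError):
            PCDCNRuleConfig(ltp_max=0.001, ltd_max=0.005)


class TestIstdpContracts:
    """The two robustness conditions both nuclear kernels must satisfy."""

    def _simulate(self, kernel_choice, pre_rate, post_rate, rng, w0=1.0, T=20.0):
        cfg = PCDCNRuleConfig(kernel_choice=kernel_choice, tau1=0.02, tau2=0.02,
                              sigma=0.02, ltp_max=0.025, ltd_max=0.005, scale=0.02)
        pre = np.sort(rng.uniform(0, T, int(pre_rate * T)))
        if post_rate == "coincident":
            post = pre + 0.002
        elif post_rate == 0:
            post = np.array([])
        w = w0
        if kernel_choice == "hebbian":
            for t in pre:
                earlier = post[post < t] if len(post) else np.array([])
                if earlier.size:
                    w = max(w + pcdcn_hebbian(-(t - earlier[-1]), cfg), 0.0)
            for t in post:
                earlier = pre[pre <= t]
                if earlier.size:
                    w += pcdcn_hebbian(t - earlier[-1], cfg)
        else:
            for t in pre:
                w = max(w + pcdcn_symmetric_on_pc_spike(post[post <= t], t, cfg), 0.0)
            for t in post:
                w += pcdcn_symmetric_on_dcn_spike(pre[pre < t], t, cfg)
        return w, w0

    @pytest.mark.parametrize("kernel", ["hebbian", "symmetric"])
    def test_decay_without_postsynaptic_firing(self, kernel, rng):
        w, w0 = self._simulate(kernel, pre_rate=50, post_rate=0, rng=rng)
        assert w <= w0

    @pytest.mark.parametrize("kernel", ["hebbian", "symmetric"])
    def test_coincident_activity_potentiates(self, kernel, rng):
        w, w0 = self._simulate(kernel, pre_rate=50, post_rate="coincident", rng=rng)
        assert w > w0


class TestEligibilityBuffer:
    def test_prunes_outside_window(self):
        buf = EligibilityBuffer(window=0.1)
        buf.append(0.0)
        buf.append(0.05)
        buf.advance(0.12)
        assert len(buf) == 1 and buf.times[0] == 0.05
        buf.advance(0.3)
        assert len(buf) == 0

    def test_rejects_bad_window(self):
        with pytest.raises(ValueError):
            EligibilityBuffer(0.0)


def test_rate_normalisation_matches_mean_step(rng):
    hebb = PCDCNRuleConfig(kernel_choice="hebbian", scale=0.01, tau2=0.015)
    sym = PCDCNRuleConfig(kernel_choice="symmetric", ltp_max=0.025, ltd_max=0.005)
    _, scaled, ratio = normalize_istdp_rates(hebb, sym, rng)
    assert ratio > 0
    assert scaled.ltp_max == pytest.approx(sym.ltp_max * ratio)
    # the ltp/ltd ratio (the rule's set-point) is preserved
    assert scaled.ltp_max / scaled.ltd_max == pytest.approx(sym.ltp_max / sym.ltd_max)
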