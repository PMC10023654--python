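"""Ratio computation and spontaneous-activity feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abneuro import calcium_traces as ct
from abneuro import synthetic_data as sd

from conftest import make_dual_trace, make_ratio_trace


class TestComputeRatio:
    def test_formula(self):
        tr = ct.DualChannelTrace(
            t=np.array([0.0, 0.1]),
            F_ven_soma=np.array([200.0, 200.0]),
            F_ven_bg=np.array([50.0, 50.0]),
            F_cer_soma=np.array([150.0, 150.0]),
            F_cer_bg=np.array([50.0, 50.0]),
            frame_rate_hz=10.0,
        )
        assert ct.compute_ratio(tr).ratio == pytest.approx([1.5, 1.5])

    def test_zero_denominator_names_sample(self):
        tr = ct.DualChannelTrace(
            t=np.array([0.0, 0.1]),
            F_ven_soma=np.array([100.0, 100.0]),
            F_ven_bg=np.array([100.0, 100.0]),
            F_cer_soma=np.array([100.0, 100.0]),
            F_cer_bg=np.array([100.0, 100.0]),
            frame_rate_hz=10.0,
        )
        with pytest.raises(ValueError, match="sample index 0"):
            ct.compute_ratio(tr)

    def test_matches_generator_ratio(self):
        res = sd.gen_traces(sd.TraceSimSpec(n_cells=5, frac_fluctuating=1.0, seed=7))
        for tr in res.traces:
            rt = ct.compute_ratio(tr)
            np.testing.assert_allclose(rt.ratio, res.ratios[tr.cell_id], atol=1e-12)

    def test_scale_invariance(self, rng):
        ratio = 1.0 + 0.2 * rng.standard_normal(50)
        tr = make_dual_trace(ratio)
        for c in (0.5, 3.0, 117.0):
            scaled = ct.DualChannelTrace(
                t=tr.t,
                F_ven_soma=c * tr.F_ven_soma,
                F_ven_bg=c * tr.F_ven_bg,
                F_cer_soma=c * tr.F_cer_soma,
                F_cer_bg=c * tr.F_cer_bg,
                frame_rate_hz=tr.frame_rate_hz,
            )
            np.testing.assert_allclose(
                ct.compute_ratio(scaled).ratio, ct.compute_ratio(tr).ratio, atol=1e-9
            )


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        rt = make_ratio_trace(np.full(200, 1.37))
        np.testing.assert_allclose(ct.lowpass_filter(rt).ratio, 1.37, atol=1e-9)

    def test_stopband_attenuation(self):
        # 3 Hz tone at 10 Hz sampling, 5x above the 0.6 Hz cutoff
        t = np.arange(0, 60, 0.1)
        rt = ct.RatioTrace(t=t, ratio=np.sin(2 * np.pi * 3.0 * t), frame_rate_hz=10.0)
        out = ct.lowpass_filter(rt).ratio
        assert np.abs(out[100:-100]).max() < 0.05

    def test_passband_preserved(self):
        t = np.arange(0, 120, 0.1)
        rt = ct.RatioTrace(t=t, ratio=np.sin(2 * np.pi * 0.05 * t), frame_rate_hz=10.0)
        out = ct.lowpass_filter(rt).ratio
        assert np.abs(out).max() == pytest.approx(1.0, rel=0.02)

    def test_cutoff_above_nyquist_rejected(self):
        rt = make_ratio_trace(np.ones(50), frame_rate_hz=1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            ct.lowpass_filter(rt, cutoff_hz=0.6)


class TestBasalRatio:
    def test_constant(self):
        assert ct.basal_ratio(make_ratio_trace(np.full(100, 1.2))) == pytest.approx(1.2)

    def test_lowest_decile_mean(self):
        rt = make_ratio_trace(np.arange(1.0, 101.0))
        assert ct.basal_ratio(rt) == pytest.approx(5.5)  # mean of 1..10

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            ct.basal_ratio(make_ratio_trace(np.ones(5)))

    def test_noisy_baseline_recovered(self, rng):
        b, sd_ = 1.1, 0.02
        rt = make_ratio_trace(b + rng.normal(0, sd_, 1000))
        assert abs(ct.basal_ratio(rt) - b) < 2 * sd_


class TestMaxRatio:
    def test_constant(self):
        assert ct.max_ratio(make_ratio_trace(np.full(100, 0.9))) == pytest.approx(0.9)

    def test_single_spike_averaged_over_window(self):
        x = np.zeros(200)
        x[100] = 3.0
        # 1.5 s at 10 Hz -> 15-sample window; spike contributes h/15
        assert ct.max_ratio(make_ratio_trace(x)) == pytest.approx(3.0 / 15)

    def test_matches_bruteforce_on_random_traces(self, rng):
        for _ in range(100):
            fs = rng.uniform(7, 10)
            x = rng.standard_normal(rng.integers(100, 400))
            rt = make_ratio_trace(x, frame_rate_hz=fs)
            w = int(round(1.5 * fs))
            oracle = max(x[i : i + w].mean() for i in range(len(x) - w + 1))
            assert ct.max_ratio(rt) == pytest.approx(oracle, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ct.max_ratio(make_ratio_trace(np.ones(5), frame_rate_hz=10.0))


class TestAucPerSec:
    def test_at_baseline_zero(self):
        rt = make_ratio_trace(np.full(100, 1.3))
        assert ct.auc_per_sec(rt, 1.3) == pytest.approx(0.0)

    def test_constant_offset(self):
        rt = make_ratio_trace(np.full(100, 1.5))
        assert ct.auc_per_sec(rt, 1.3) == pytest.approx(0.2)

    def test_event_train_matches_analytic_integral(self):
        # double-exponential integral: amp/peak * (tau_d - tau_r)
        fs, dur, amp, tr_, td = 50.0, 400.0, 0.5, 0.5, 2.0
        t = np.arange(0, dur, 1 / fs)
        onsets = [50.0, 150.0, 250.0]
        x = np.zeros_like(t)
        t_peak = np.log(td / tr_) * tr_ * td / (td - tr_)
        peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr_)
        for t0 in onsets:
            m = t >= t0
            x[m] += amp / peak * (np.exp(-(t[m] - t0) / td) - np.exp(-(t[m] - t0) / tr_))
        rt = ct.RatioTrace(t=t, ratio=1.0 + x, frame_rate_hz=fs)
        analytic = len(onsets) * amp / peak * (td - tr_) / (t[-1] - t[0])
        assert ct.auc_per_sec(rt, 1.0) == pytest.approx(analytic, rel=0.01)


class TestMidcrossings:
    def test_constant_warns_zero(self):
        with pytest.warns(UserWarning):
            assert ct.count_midcrossings(make_ratio_trace(np.ones(20))) == 0

    def test_square_wave(self):
        x = np.repeat([0.0, 1.0, 0.0, 1.0, 0.0], 20)  # 4 transitions
        assert ct.count_midcrossings(make_ratio_trace(x)) == 4

    def test_monotone_ramp(self):
        assert ct.count_midcrossings(make_ratio_trace(np.linspace(0, 1, 100))) == 1

    def test_matches_state_level_oracle_on_two_valued_signals(self, rng):
        for _ in range(100):
            lo, span = rng.uniform(-5, 5), rng.uniform(0.5, 10)
            hi = lo + span
            n_seg = int(rng.integers(2, 12))
            lengths = rng.integers(5, 30, size=n_seg)
            levels = [lo if i % 2 == 0 else hi for i in range(n_seg)]
            x = np.concatenate([np.full(k, v) for k, v in zip(lengths, levels)])
            # oracle: on a two-valued signal the state levels are the values
            # themselves; crossings = transitions between them
            mid = (lo + hi) / 2
            s = x - mid
            oracle = int(np.count_nonzero(s[:-1] * s[1:] < 0))
            assert oracle == n_seg - 1
            assert ct.count_midcrossings(make_ratio_trace(x)) == oracle

    @settings(derandomize=True, max_examples=30)
    @given(
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-50, max_value=50),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_affine_invariance(self, a, b, seed):
        r = np.random.default_rng(seed)
        x = np.repeat(r.choice([0.0, 1.0], size=30), 5) + 0.01 * r.standard_normal(150)
        rt = make_ratio_trace(x)
        rt2 = make_ratio_trace(a * x + b)
        assert ct.count_midcrossings(rt) == ct.count_midcrossings(rt2)


class TestFeaturePipeline:
    def test_basal_below_mean_below_max(self, rng):
        for _ in range(20):
            x = rng.standard_normal(rng.integers(50, 300))
            rt = make_ratio_trace(x)
            assert ct.basal_ratio(rt) <= x.mean() <= ct.max_ratio(rt)

    def test_flat_spec_yields_constant_traces(self):
        res = sd.gen_traces(
            sd.TraceSimSpec(n_cells=4, frac_fluctuating=0.0, noise_sd=0.0, seed=0)
        )
        for tr in res.traces:
            rt = ct.compute_ratio(tr)
            np.testing.assert_allclose(rt.ratio, 1.0, atol=1e-12)

    def test_fluctuating_cells_cross_more(self):
        spec = sd.TraceSimSpec(
            n_cells=40, frac_fluctuating=0.5, event_amp=0.5, noise_sd=0.01, seed=3
        )
        res = sd.gen_traces(spec)
        truth = res.truth.set_index("cell_id")
        crossings = {}
        for tr in res.traces:
            rt = ct.lowpass_filter(ct.compute_ratio(tr))
            crossings[tr.cell_id] = ct.count_midcrossings(rt)
        fluct = [v for k, v in crossings.items() if truth.loc[k, "fluctuating"]]
        flat = [v for k, v in crossings.items() if not truth.loc[k, "fluctuating"]]
        assert np.median(fluct) > np.median(flat)
        # pairwise separation: nearly all fluctuating cells above nearly all flat
        thresh = np.percentile(flat, 95)
        assert np.mean(np.array(fluct) > thresh) >= 0.95
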