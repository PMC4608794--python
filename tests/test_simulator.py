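import numpy as np
import pytest
from scipy import stats as sps

import eodloop as el
from eodloop.simulator import _sample_baseline_batch, squared_sum_signal


def zero_dispersion(median=140.0, **kw):
    return el.FishParams(mix_weights=(1.0,), mix_medians_ms=(median,),
                         mix_shapes=(0.0,), **kw)


class TestBaselineIpi:
    def test_zero_dispersion_is_exact(self, rng):
        p = zero_dispersion(140.0)
        assert el.sample_baseline_ipi(p, rng) == pytest.approx(140.0)

    def test_draws_respect_refractory(self, default_params, rng):
        draws = _sample_baseline_batch(default_params, rng, 5000)
        assert np.all(draws >= default_params.refractory_ms)

    def test_mixture_modes_match_density_oracle(self, default_params, rng):
        """Sample histogram modes agree (within 10%) with the modes of the
        directly evaluated log-normal mixture density."""
        draws = _sample_baseline_batch(default_params, rng, 100_000)
        grid = np.linspace(5, 600, 2000)
        dens = np.zeros_like(grid)
        for w, med, sig in zip(default_params.mix_weights,
                               default_params.mix_medians_ms,
                               default_params.mix_shapes):
            dens += w * sps.lognorm.pdf(grid, s=sig, scale=med)
        # per-component expected modes from the analytic density
        expected_modes = []
        for med in default_params.mix_medians_ms:
            sel = (grid > med * 0.6) & (grid < med * 1.4)
            expected_modes.append(grid[sel][np.argmax(dens[sel])])
        counts, edges = np.histogram(draws, bins=np.arange(0, 600, 10))
        centers = (edges[:-1] + edges[1:]) / 2
        for med, mode in zip(default_params.mix_medians_ms, expected_modes):
            sel = (centers > med * 0.6) & (centers < med * 1.4)
            observed = centers[sel][np.argmax(counts[sel])]
            assert abs(observed - mode) / mode < 0.10

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            el.FishParams(mix_weights=(0.5, 0.4))  # does not sum to 1
        with pytest.raises(ValueError):
            el.FishParams(refractory_ms=200.0)  # above smallest median
        with pytest.raises(ValueError):
            el.FishParams(p_echo=1.5)


class TestEffectScale:
    @pytest.mark.parametrize("delay,expected", [(50, 0.5), (200, 1.0), (100, 1.0)])
    def test_step_response(self, delay, expected):
        p = el.FishParams(scale_short=0.5, scale_long=1.0, critical_delay_ms=100)
        assert el.effect_scale(delay, p) == expected

    def test_smooth_response_interpolates(self):
        p = el.FishParams(scale_short=0.5, scale_long=1.0,
                          critical_delay_ms=100, response_smoothness_ms=10)
        assert el.effect_scale(100, p) == pytest.approx(0.75)
        assert el.effect_scale(0, p) == pytest.approx(0.5, abs=1e-4)
        assert el.effect_scale(300, p) == pytest.approx(1.0, abs=1e-4)


class TestControlSession:
    def test_deterministic_renewal_count(self):
        train = el.simulate_control(zero_dispersion(140.0), 1.0, 0)
        assert train.n == 428  # floor(60000 / 140)

    def test_same_seed_identical(self, default_params):
        a = el.simulate_control(default_params, 2.0, 123)
        b = el.simulate_control(default_params, 2.0, 123)
        np.testing.assert_array_equal(a.times_ms, b.times_ms)

    def test_refractory_conserved(self, default_params):
        train = el.simulate_control(default_params, 5.0, 5)
        assert np.all(np.diff(train.times_ms) >= default_params.refractory_ms)


class TestClosedLoop:
    def test_forced_echo_single_latency_mode(self):
        """p_echo=1, no blind period, sparse deterministic baseline: every
        stimulus is followed by a fish pulse exactly echo_latency_ms later."""
        p = zero_dispersion(300.0, p_echo=1.0, blind_ms=0.0,
                            echo_latency_ms=12.0, scale_short=1.0, scale_long=1.0)
        proto = el.ProtocolConfig(delay_ms=22, control_min=1, stim_min=1, seed=3)
        pair = el.simulate_closed_loop(p, proto)
        fish = pair.stim_fish.times_ms
        for t_s in pair.stimulus_log.times_ms:
            after = fish[fish > t_s]
            if after.size:
                assert after[0] - t_s == pytest.approx(12.0)

    def test_protocol_bookkeeping(self, short_pair):
        off = short_pair.meta["detect_latency_ms"] + short_pair.delay_ms
        trig = short_pair.stimulus_log.times_ms - off
        fish = np.round(short_pair.stim_fish.times_ms, 9)
        assert np.all(np.isin(np.round(trig, 9), fish))
        assert short_pair.stimulus_log.n <= short_pair.stim_fish.n

    def test_causality_and_refractory(self, short_pair, default_params):
        assert np.all(np.diff(short_pair.stim_fish.times_ms)
                      >= default_params.refractory_ms - 1e-12)

    def test_same_seed_bit_identical(self, default_params):
        proto = el.ProtocolConfig(delay_ms=40, control_min=1, stim_min=1, seed=77)
        a = el.simulate_closed_loop(default_params, proto)
        b = el.simulate_closed_loop(default_params, proto)
        np.testing.assert_array_equal(a.control.times_ms, b.control.times_ms)
        np.testing.assert_array_equal(a.stim_fish.times_ms, b.stim_fish.times_ms)
        np.testing.assert_array_equal(a.stimulus_log.times_ms, b.stimulus_log.times_ms)

    def test_null_configuration_matches_control_distribution(self):
        """No echo, both scales 1: stimulation-session IPIs are statistically
        indistinguishable from control (self-consistency of the generator)."""
        p = el.FishParams(p_echo=0.0, scale_short=1.0, scale_long=1.0)
        proto = el.ProtocolConfig(delay_ms=22, control_min=30, stim_min=30, seed=8)
        pair = el.simulate_closed_loop(p, proto)
        d, pval = el.ks_two_sample(pair.control.ipis_ms(), pair.stim_fish.ipis_ms())
        assert pval > 0.01

    def test_mean_stim_ipi_monotone_in_effect_scale(self):
        means = []
        for scale in (0.5, 0.7, 0.9, 1.1):
            vals = []
            for seed in range(5):
                p = el.FishParams(p_echo=0.0, scale_short=scale, scale_long=1.0)
                proto = el.ProtocolConfig(delay_ms=40, control_min=1, stim_min=2,
                                          seed=seed)
                pair = el.simulate_closed_loop(p, proto)
                vals.append(pair.stim_fish.ipis_ms().mean())
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)


class TestRecordingSynthesis:
    def test_single_pulse_peak_location(self):
        fish = el.PulseTrain(np.array([100.0]), duration_ms=200.0, source="fish")
        rec = el.synthesize_recording(fish, noise_sd=0.0, seed=0)
        peak_ms = np.argmax(rec.samples) * 1000.0 / rec.fs_hz
        assert abs(peak_ms - 100.0) <= el.default_eod_waveform().duration_ms

    def test_silence_is_identically_zero(self):
        fish = el.PulseTrain(np.empty(0), duration_ms=100.0, source="fish")
        rec = el.synthesize_recording(fish, noise_sd=0.0, seed=0)
        assert not rec.samples.any()

    def test_pointwise_oracle(self, rng):
        """Output equals a naive per-sample oracle: for each channel, sum of
        amplitude-scaled template samples plus noise, squared, then summed
        over channels."""
        wf = el.default_eod_waveform()
        n = 25_000  # 1 s
        times = np.sort(rng.uniform(50, 950, 100))
        times = times[np.insert(np.diff(times) > 3, 0, True)]
        amps = rng.uniform(0.3, 1.0, (times.size, 4))
        noise = rng.normal(0, 0.02, (4, n))
        sig = squared_sum_signal(times, amps, wf, n, noise=noise)
        assert np.all(sig >= 0)
        starts = np.round(times * wf.fs_hz / 1000).astype(int) - wf.peak_index
        for j in rng.integers(0, n, 10):
            val = 0.0
            for c in range(4):
                ch = noise[c, j]
                for i, s in enumerate(starts):
                    if s <= j < s + wf.samples.size:
                        ch += amps[i, c] * wf.samples[j - s]
                val += ch * ch
            assert sig[j] == pytest.approx(val, abs=1e-9)
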