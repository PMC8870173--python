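"""Spectral pipeline: epoching, artifact rejection, windowed power, log
aggregation, band extraction, and baseline normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_windowed_power
from tacsfx import spectral
from tacsfx.simulate import EegSimConfig, generate_eeg
from tacsfx.spectral import (
    EpochedEEG,
    InputError,
    LogPowerSpectrum,
    PipelineError,
    aggregate_log_power,
    band_power,
    epoch_power,
    normalize_change,
    reject_artifacts,
    split_epochs,
)


def _spectrum(values: np.ndarray) -> LogPowerSpectrum:
    return LogPowerSpectrum(
        freqs=np.arange(41), logpower=values, n_epochs_used=1
    )


class TestSplitEpochs:
    def test_three_minutes_gives_180_epochs(self):
        rec = generate_eeg(EegSimConfig(duration_s=180.0, seed=0))
        assert split_epochs(rec).n_epochs == 180

    def test_too_short_recording_rejected(self):
        with pytest.raises(InputError):
            split_epochs(np.zeros((1, 500)), fs=1000.0)

    def test_partial_trailing_epoch_dropped(self):
        ep = split_epochs(np.zeros((2, 5500)), fs=1000.0)
        assert ep.n_epochs == 5
        assert ep.epochs.shape == (5, 2, 1000)


class TestRejectArtifacts:
    def test_quiet_epochs_all_retained(self):
        ep = split_epochs(np.zeros((1, 5000)), fs=1000.0)
        assert reject_artifacts(ep, 100.0).n_kept == 5

    def test_only_contaminated_epoch_rejected(self):
        data = np.zeros((2, 10_000))
        data[1, 3_500] = 500.0  # one excursion inside epoch 3
        kept = reject_artifacts(split_epochs(data, fs=1000.0), 100.0).kept_mask
        assert list(np.flatnonzero(~kept)) == [3]

    def test_everything_rejected_is_an_error(self):
        data = np.full((1, 3000), 200.0)
        with pytest.raises(PipelineError):
            reject_artifacts(split_epochs(data, fs=1000.0), 100.0)

    def test_lower_threshold_never_retains_more(self, rng):
        data = rng.normal(0, 50, size=(3, 20_000))
        ep = split_epochs(data, fs=1000.0)
        kept = [
            reject_artifacts(ep, th).n_kept if _survives(ep, th) else 0
            for th in (200.0, 150.0, 120.0, 100.0)
        ]
        assert all(a >= b for a, b in zip(kept, kept[1:]))


def _survives(ep, th):
    return bool((np.abs(ep.epochs).max(axis=(1, 2)) <= th).any())


class TestEpochPower:
    def test_zero_signal_zero_power(self):
        assert np.all(epoch_power(np.zeros(1000), fs=1000.0) == 0.0)

    def test_sinusoid_peaks_at_its_bin(self):
        t = np.arange(1000) / 1000.0
        p = epoch_power(np.sin(2 * np.pi * 10 * t), fs=1000.0)
        assert p.size == 41
        assert int(np.argmax(p[1:])) + 1 == 10

    def test_wrong_epoch_length_rejected(self):
        with pytest.raises(InputError):
            epoch_power(np.zeros(999), fs=1000.0)

    @pytest.mark.parametrize("fs", [250, 1000])
    def test_matches_brute_force_dft(self, fs, rng):
        from scipy.signal.windows import hann

        x = rng.normal(0, 10, size=fs)
        expected = brute_windowed_power(x, hann(fs, sym=False), 40)
        got = epoch_power(x, fs=float(fs))
        np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-12)


class TestAggregateLogPower:
    def _epoched(self, data, fs=1000.0):
        return split_epochs(data, fs=fs)

    def test_constant_power_gives_its_log(self):
        # a pure DC-free sinusoid on all channels: aggregated value at the
        # tone's bin equals the log of the per-epoch power there
        t = np.arange(3000) / 1000.0
        x = np.tile(np.sin(2 * np.pi * 10 * t), (2, 1))
        spec = aggregate_log_power(self._epoched(x))
        single = epoch_power(x[0, :1000], fs=1000.0)
        assert spec.logpower[10] == pytest.approx(np.log(single[10]))

    def test_mean_of_two_epochs(self):
        x = np.concatenate(
            [np.sin(2 * np.pi * 10 * np.arange(1000) / 1000.0) * a for a in (1.0, 2.0)]
        )[None, :]
        spec = aggregate_log_power(self._epoched(x))
        p1 = np.log(np.maximum(epoch_power(x[0, :1000], 1000.0), 1e-12))
        p2 = np.log(np.maximum(epoch_power(x[0, 1000:], 1000.0), 1e-12))
        np.testing.assert_allclose(spec.logpower, (p1 + p2) / 2)

    def test_zero_power_floored_not_minus_inf(self):
        spec = aggregate_log_power(self._epoched(np.zeros((1, 2000))))
        assert np.all(np.isfinite(spec.logpower))
        assert spec.logpower[0] == pytest.approx(np.log(1e-12))

    def test_channel_vs_epoch_average_order_is_immaterial(self, rng):
        data = rng.normal(0, 5, size=(3, 4000))
        ep = split_epochs(data, fs=1000.0)
        powers = np.array(
            [
                [epoch_power(ep.epochs[e, c], 1000.0) for c in range(3)]
                for e in range(4)
            ]
        )
        logp = np.log(np.maximum(powers, 1e-12))
        np.testing.assert_allclose(
            logp.mean(axis=0).mean(axis=0), logp.mean(axis=1).mean(axis=0)
        )
        np.testing.assert_allclose(
            aggregate_log_power(ep).logpower, logp.mean(axis=(0, 1))
        )


class TestBandPower:
    def test_alpha_uses_bins_9_10_11(self):
        values = np.zeros(41)
        values[[9, 10, 11]] = [1.0, 2.0, 3.0]
        assert band_power(_spectrum(values), "alpha").value == pytest.approx(2.0)

    def test_beta_mean_of_19_20_21(self):
        values = np.zeros(41)
        values[[19, 20, 21]] = [1.0, 2.0, 3.0]
        assert band_power(_spectrum(values), "beta").value == pytest.approx(2.0)

    def test_flat_spectrum_returns_constant(self):
        assert band_power(_spectrum(np.full(41, 3.7)), "alpha").value == pytest.approx(3.7)

    def test_unknown_band_rejected(self):
        with pytest.raises(InputError):
            band_power(_spectrum(np.zeros(41)), "gamma")

    def test_alpha_band_power_increases_with_component_amplitude(self):
        values = []
        for amp in (2.0, 5.0, 10.0):
            cfg = EegSimConfig(
                duration_s=20.0,
                band_components=((10.0, amp, 0.0),),
                blink_rate_per_min=0.0,
                seed=11,
            )
            spec = spectral.recording_log_spectrum(
                generate_eeg(cfg), amp_threshold=1e9
            )
            values.append(band_power(spec, "alpha").value)
        assert values[0] < values[1] < values[2]


class TestNormalizeChange:
    def test_no_change_is_zero(self):
        assert normalize_change(1.5, 1.5).np_value == 0.0

    def test_doubling_is_plus_one(self):
        assert normalize_change(2.4, 1.2).np_value == pytest.approx(1.0)

    def test_arithmetic(self):
        assert normalize_change(1.5, 1.2).np_value == pytest.approx(0.25)

    def test_near_zero_baseline_rejected(self):
        with pytest.raises(PipelineError):
            normalize_change(1.0, 1e-9)

    @given(
        a=st.floats(-100, 100),
        r=st.floats(0.01, 100),
        c=st.floats(0.001, 1000),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, a, r, c):
        base = normalize_change(a, r).np_value
        scaled = normalize_change(c * a, c * r).np_value
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestErsRecovery:
    def test_raised_alpha_amplitude_yields_alpha_ers_only(self):
        # post 10 Hz amplitude doubled; beta unchanged -> alpha NP clearly
        # positive, beta NP within noise of zero (thresholds frozen from the
        # generator's measured noise floor: |beta NP| < 0.02 at 180 s)
        alpha_np, beta_np = [], []
        for r in range(20):
            seeds = np.random.default_rng(500 + r).integers(0, 2**31 - 1, 2)
            pre = generate_eeg(EegSimConfig(seed=int(seeds[0])))
            post = generate_eeg(
                EegSimConfig(
                    band_components=((10.0, 10.0, 0.0), (20.0, 3.0, 0.0)),
                    seed=int(seeds[1]),
                )
            )
            sp_pre = spectral.recording_log_spectrum(pre)
            sp_post = spectral.recording_log_spectrum(post)
            alpha_np.append(
                normalize_change(
                    band_power(sp_post, "alpha").value,
                    band_power(sp_pre, "alpha").value,
                ).np_value
            )
            beta_np.append(
                normalize_change(
                    band_power(sp_post, "beta").value,
                    band_power(sp_pre, "beta").value,
                ).np_value
            )
        assert min(alpha_np) > 0.05
        assert max(np.abs(beta_np)) < 0.02
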