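"""Morlet wavelet bank, FFT-convolution power, and decibel baselining."""

import numpy as np
import pytest

from conflictlab.eeg import EpochArray
from conflictlab.tfr import (
    TFRArray,
    build_wavelet_bank,
    db_baseline,
    undo_db_baseline,
    wavelet_power,
)

SFREQ = 250.0


def sinusoid_epochs(freq=6.0, amplitude=1.0, n_trials=1, ch=("FCz",)):
    times = np.arange(-1.2, 2.0 + 1e-9, 1 / SFREQ)
    sig = amplitude * np.sin(2 * np.pi * freq * times)
    values = np.tile(sig, (n_trials, len(ch), 1))
    return EpochArray(values=values, times=times, ch_names=list(ch), sfreq=SFREQ)


class TestWaveletBank:
    def test_grid_endpoints(self):
        bank = build_wavelet_bank()
        assert bank.freqs[0] == pytest.approx(2.0)
        assert bank.freqs[-1] == pytest.approx(30.0)
        assert bank.cycles[0] == pytest.approx(3.0)
        assert bank.cycles[-1] == pytest.approx(10.0)

    def test_grid_formula_at_bin_8(self):
        bank = build_wavelet_bank()
        assert bank.freqs[8] == pytest.approx(2 * 15 ** (8 / 19), abs=1e-9)
        assert bank.freqs[8] == pytest.approx(6.255, abs=1e-3)

    def test_monotonicity(self):
        bank = build_wavelet_bank()
        assert np.all(np.diff(bank.freqs) > 0)
        assert np.all(np.diff(bank.cycles) >= 0)

    def test_kernel_unit_energy(self):
        bank = build_wavelet_bank()
        for k in (0, 10, 19):
            kern = bank.kernel(k, SFREQ)
            assert np.sum(np.abs(kern) ** 2) == pytest.approx(1.0)

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            build_wavelet_bank(fmin=30, fmax=2)
        with pytest.raises(ValueError):
            build_wavelet_bank(n_freqs=1)


class TestWaveletPower:
    def test_pure_6hz_peaks_at_nearest_grid_bin(self):
        tfr = wavelet_power(sinusoid_epochs(6.0))
        mean_spectrum = tfr.power[0, 0].mean(axis=1)
        assert tfr.freqs[np.argmax(mean_spectrum)] == pytest.approx(
            6.255, abs=1e-3
        )

    def test_power_scales_with_amplitude_squared(self):
        t1 = wavelet_power(sinusoid_epochs(6.0, amplitude=1.0))
        t2 = wavelet_power(sinusoid_epochs(6.0, amplitude=2.0))
        k = int(np.argmax(t1.power[0, 0].mean(axis=1)))
        ratio = t2.power[0, 0, k].mean() / t1.power[0, 0, k].mean()
        assert ratio == pytest.approx(4.0, rel=1e-6)

    def test_zero_signal_zero_power(self):
        epochs = sinusoid_epochs(6.0, amplitude=0.0)
        assert np.max(np.abs(wavelet_power(epochs).power)) == 0.0

    def test_output_decimated_to_125hz(self):
        tfr = wavelet_power(sinusoid_epochs())
        assert tfr.sfreq == pytest.approx(125.0)
        assert np.allclose(np.diff(tfr.times), 1 / 125.0)

    def test_power_monotone_in_signal_variance(self, rng):
        times = np.arange(-1.2, 2.0 + 1e-9, 1 / SFREQ)
        noise = rng.standard_normal((1, 1, len(times)))
        totals = []
        for scale in (0.5, 1.0, 2.0):
            ep = EpochArray(
                values=scale * noise, times=times, ch_names=["Cz"], sfreq=SFREQ
            )
            totals.append(wavelet_power(ep).power.sum())
        assert totals[0] < totals[1] < totals[2]

    def test_decimation_preserves_peak_location(self):
        # burst centred at t = 0.5 s must peak within one output sample
        times = np.arange(-1.2, 2.0 + 1e-9, 1 / SFREQ)
        env = np.exp(-((times - 0.5) ** 2) / (2 * 0.15**2))
        sig = (env * np.sin(2 * np.pi * 6 * times))[None, None, :]
        ep = EpochArray(values=sig, times=times, ch_names=["Cz"], sfreq=SFREQ)
        tfr = wavelet_power(ep)
        k = int(np.argmax(tfr.power[0, 0].mean(axis=1)))
        t_peak = tfr.times[np.argmax(tfr.power[0, 0, k])]
        assert abs(t_peak - 0.5) <= 1 / 125.0 + 1e-9

    def test_short_epoch_warns(self):
        times = np.arange(0, 0.5, 1 / SFREQ)
        ep = EpochArray(
            values=np.zeros((1, 1, len(times))),
            times=times,
            ch_names=["Cz"],
            sfreq=SFREQ,
        )
        with pytest.warns(UserWarning, match="edge"):
            wavelet_power(ep)

    def test_matches_mne_timecourse_shape(self, rng):
        """Independent cross-check: per-frequency power time courses of a
        broadband signal agree with MNE's Morlet implementation up to the
        kernel normalization convention (away from the epoch edges, where
        the padding strategies differ)."""
        pytest.importorskip("mne")
        from mne.time_frequency import tfr_array_morlet

        bank = build_wavelet_bank()
        times = np.arange(-1.2, 2.0 + 1e-9, 1 / SFREQ)
        ep = EpochArray(
            values=rng.standard_normal((1, 1, len(times))),
            times=times, ch_names=["FCz"], sfreq=SFREQ,
        )
        mine = wavelet_power(ep, bank, out_sfreq=SFREQ)  # no decimation
        theirs = tfr_array_morlet(
            ep.values,
            sfreq=SFREQ,
            freqs=bank.freqs,
            n_cycles=bank.cycles,
            output="power",
            zero_mean=False,
        )
        sel = slice(150, -150)
        for k in range(len(bank.freqs)):
            a, b = mine.power[0, 0, k, sel], theirs[0, 0, k, sel]
            assert np.corrcoef(a, b)[0, 1] > 0.999


class TestDbBaseline:
    def make_noise_tfr(self, rng, n_trials=40):
        times = np.arange(-1.2, 2.0 + 1e-9, 1 / SFREQ)
        ep = EpochArray(
            values=rng.standard_normal((n_trials, 2, len(times))),
            times=times,
            ch_names=["FCz", "Cz"],
            sfreq=SFREQ,
        )
        return wavelet_power(ep)

    def test_trial_average_self_normalizes_to_zero(self, rng):
        raw = self.make_noise_tfr(rng)
        mean_tfr = TFRArray(
            power=raw.power.mean(axis=0, keepdims=True),
            times=raw.times,
            freqs=raw.freqs,
            ch_names=raw.ch_names,
            sfreq=raw.sfreq,
        )
        db = db_baseline(mean_tfr, window=(0.0, 1.0))
        sel = (db.times >= 0) & (db.times <= 1.0)
        assert abs(db.power[..., sel].mean()) < 0.1

    def test_tenfold_power_is_plus_10db(self, rng):
        raw = self.make_noise_tfr(rng, n_trials=4)
        boosted = raw.power.copy()
        sel = raw.times > 1.2
        boosted[..., sel] *= 10.0
        tfr = TFRArray(
            power=boosted, times=raw.times, freqs=raw.freqs,
            ch_names=raw.ch_names, sfreq=raw.sfreq,
        )
        db = db_baseline(tfr, window=(0.0, 1.0))
        db_ref = db_baseline(raw, window=(0.0, 1.0))
        diff = db.power[..., sel] - db_ref.power[..., sel]
        assert np.allclose(diff, 10.0)

    def test_default_windows_follow_alignment(self, rng):
        raw = self.make_noise_tfr(rng, n_trials=2)
        assert db_baseline(raw).baseline["window"] == (0.0, 1.0)
        resp = TFRArray(
            power=raw.power, times=raw.times - 0.5, freqs=raw.freqs,
            ch_names=raw.ch_names, sfreq=raw.sfreq, alignment="response",
        )
        assert db_baseline(resp).baseline["window"] == (-1.0, 0.0)

    def test_conversion_invertible(self, rng):
        raw = self.make_noise_tfr(rng, n_trials=3)
        roundtrip = undo_db_baseline(db_baseline(raw, window=(0.0, 1.0)))
        assert np.allclose(roundtrip.power, raw.power)

    def test_window_outside_epoch_rejected(self, rng):
        raw = self.make_noise_tfr(rng, n_trials=2)
        with pytest.raises(ValueError):
            db_baseline(raw, window=(1.5, 3.0))
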