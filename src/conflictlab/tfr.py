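"""Morlet-wavelet time–frequency power with decibel baseline normalization.

Power is computed by FFT convolution of each epoch with a bank of complex
Morlet wavelets: 20 centre frequencies logarithmically spaced from 2 to
30 Hz, with cycle counts logarithmically spaced from 3 to 10 (better band
resolution at high frequencies, better time resolution at low ones).
Kernels are unit-energy normalized so raw power is comparable across
frequencies.  After convolution the time axis is decimated to 125 Hz.
Decibel conversion divides by the mean power of a reference window,
computed per channel x frequency over the condition-agnostic trial
average (a per-trial single-trial mode is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as sp_fft

__all__ = [
    "WaveletBank",
    "TFRArray",
    "build_wavelet_bank",
    "wavelet_power",
    "db_baseline",
    "undo_db_baseline",
]


@dataclass(frozen=True)
class WaveletBank:
    """Bank of complex Morlet wavelets on a log-spaced frequency grid."""

    freqs: np.ndarray  # Hz, strictly increasing
    cycles: np.ndarray  # non-decreasing with frequency

    @property
    def sigma_t(self) -> np.ndarray:
        """Gaussian time SD of each kernel (s): cycles / (2 pi f)."""
        return self.cycles / (2 * np.pi * self.freqs)

    def half_width_samples(self, sfreq: float) -> np.ndarray:
        """Kernel half-widths in samples (3.5 time-SDs)."""
        return np.ceil(3.5 * self.sigma_t * sfreq).astype(int)

    def kernel(self, k: int, sfreq: float) -> np.ndarray:
        """Discrete unit-energy complex Morlet kernel for frequency bin k."""
        hw = self.half_width_samples(sfreq)[k]
        t = np.arange(-hw, hw + 1) / sfreq
        st = self.sigma_t[k]
        w = np.exp(2j * np.pi * self.freqs[k] * t) * np.exp(-(t**2) / (2 * st**2))
        return w / np.sqrt(np.sum(np.abs(w) ** 2))


def build_wavelet_bank(
    fmin: float = 2.0,
    fmax: float = 30.0,
    n_freqs: int = 20,
    cmin: float = 3.0,
    cmax: float = 10.0,
) -> WaveletBank:
    """Log-spaced frequency grid f_k = fmin * (fmax/fmin)^(k/(n-1)) with
    cycles log-spaced cmin -> cmax in the same order."""
    if not (0 < fmin < fmax):
        raise ValueError("need 0 < fmin < fmax")
    if n_freqs < 2:
        raise ValueError("need at least two frequencies")
    if not (0 < cmin <= cmax):
        raise ValueError("need 0 < cmin <= cmax")
    k = np.arange(n_freqs)
    freqs = fmin * (fmax / fmin) ** (k / (n_freqs - 1))
    cycles = cmin * (cmax / cmin) ** (k / (n_freqs - 1))
    return WaveletBank(freqs=freqs, cycles=cycles)


@dataclass
class TFRArray:
    """Per-trial spectral power: trials x channels x frequencies x time.

    ``baseline`` is None for raw power; after decibel conversion it records
    the window and the divisor so the conversion is invertible.
    """

    power: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    ch_names: list
    sfreq: float
    alignment: str = "stimulus"
    baseline: dict | None = None

    def __post_init__(self) -> None:
        t, c, f, s = self.power.shape
        if c != len(self.ch_names) or f != len(self.freqs) or s != len(self.times):
            raise ValueError("axis metadata inconsistent with power array")


def wavelet_power(
    epochs,
    bank: WaveletBank | None = None,
    out_sfreq: float = 125.0,
) -> TFRArray:
    """Raw Morlet power of an epoch array via FFT convolution.

    The signal is mirror-padded by the longest kernel half-width before
    the FFT so kernel tails never wrap around the epoch; an explicit
    edge-effect warning is raised when the epoch is shorter than the
    longest kernel.  Output time axis is decimated to ``out_sfreq``.
    """
    if bank is None:
        bank = build_wavelet_bank()
    sfreq = epochs.sfreq
    if sfreq <= 2 * bank.freqs[-1]:
        raise ValueError("sampling rate must exceed twice the highest frequency")
    values = np.asarray(epochs.values)
    n_trials, n_ch, n_samp = values.shape

    hw = bank.half_width_samples(sfreq)
    pad = int(hw.max())
    if n_samp < 2 * pad + 1:
        warnings.warn(
            "epoch shorter than the longest wavelet kernel; edge effects "
            "will dominate low frequencies",
            stacklevel=2,
        )
        pad = min(pad, n_samp - 1)
    # mirror padding
    left = values[..., 1 : pad + 1][..., ::-1]
    right = values[..., -pad - 1 : -1][..., ::-1]
    padded = np.concatenate([left, values, right], axis=-1)
    n_pad = padded.shape[-1]

    step = max(int(round(sfreq / out_sfreq)), 1)
    out_idx = np.arange(0, n_samp, step)
    times = epochs.times[out_idx]
    n_out = len(out_idx)

    # circular FFT convolution: the mirror pad (>= every kernel half-width)
    # absorbs the wrap-around, so nfft only needs to cover the padded
    # signal; the inverse transform is taken on the spectrum folded
    # ``step`` times, which evaluates the convolution directly on the
    # decimated output grid at 1/step of the cost.
    nfft = step * sp_fft.next_fast_len(
        int(np.ceil(max(n_pad, 2 * pad + 1) / step))
    )
    flat = padded.reshape(n_trials * n_ch, n_pad)
    spec = sp_fft.fft(flat, nfft, axis=-1)
    k_idx = np.arange(nfft)

    power = np.empty((n_trials, n_ch, len(bank.freqs), n_out))
    for k in range(len(bank.freqs)):
        kern = bank.kernel(k, sfreq)
        kw = len(kern) // 2
        # fold the alignment shift (mirror pad + kernel group delay) into
        # the kernel spectrum as a phase ramp
        shift = pad + kw
        kspec = sp_fft.fft(kern, nfft) * np.exp(2j * np.pi * k_idx * shift / nfft)
        prod = spec * kspec
        folded = prod.reshape(prod.shape[0], step, nfft // step).sum(axis=1)
        conv = sp_fft.ifft(folded, axis=-1) / step
        power[:, :, k, :] = (np.abs(conv[:, :n_out]) ** 2).reshape(
            n_trials, n_ch, -1
        )

    return TFRArray(
        power=power,
        times=times,
        freqs=bank.freqs.copy(),
        ch_names=list(epochs.ch_names),
        sfreq=sfreq / step,
        alignment=epochs.alignment,
    )


DEFAULT_BASELINE = {"stimulus": (0.0, 1.0), "response": (-1.0, 0.0)}


def db_baseline(
    tfr: TFRArray,
    window: tuple[float, float] | None = None,
    mode: str | None = None,
    per_trial: bool = False,
) -> TFRArray:
    """Decibel conversion: dB(t) = 10 log10(power(t) / baseline mean).

    The default window follows the epoch alignment: [0, 1] s stimulus-
    locked, [-1, 0] s response-locked.  The divisor is the mean power over
    the window per channel x frequency across the condition-agnostic trial
    average; ``per_trial=True`` instead divides each trial by its own
    window mean.
    """
    if tfr.baseline is not None:
        raise ValueError("TFR is already baseline-converted")
    if window is None:
        window = DEFAULT_BASELINE[mode or tfr.alignment]
    lo, hi = window
    if lo < tfr.times[0] - 1e-9 or hi > tfr.times[-1] + 1e-9:
        raise ValueError("baseline window outside the epoch")
    sel = (tfr.times >= lo) & (tfr.times <= hi)
    if per_trial:
        ref = tfr.power[..., sel].mean(axis=-1, keepdims=True)
    else:
        ref = tfr.power[..., sel].mean(axis=(0, -1), keepdims=True)
    if np.any(ref <= 0):
        raise FloatingPointError("baseline mean power is zero; cannot form dB")
    db = 10.0 * np.log10(tfr.power / ref)
    return replace(
        tfr,
        power=db,
        baseline={
            "window": (float(lo), float(hi)),
            "per_trial": per_trial,
            "reference": ref,
        },
    )


def undo_db_baseline(tfr: TFRArray) -> TFRArray:
    """Invert a stored decibel conversion back to raw power."""
    if tfr.baseline is None:
        raise ValueError("TFR carries no baseline state")
    raw = 10.0 ** (tfr.power / 10.0) * tfr.baseline["reference"]
    return replace(tfr, power=raw, baseline=None)
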