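"""Synthetic epoched EEG with condition-dependent midline-frontal theta.

Each trial is fresh 1/f ("pink") background noise in every channel plus a
Hanning-windowed theta burst over fronto-central channels.  The burst
amplitude encodes the conflict-monitoring signal under study:

    amplitude = base_theta + conflict_gain * 1[incongruent]
                             * (1 - proportion_reduction * 1[MI])

i.e. incongruent trials carry extra theta, and that conflict response is
attenuated when conflict is expected (MI context) — the adaptive-control
signature.  Burst phase is randomized per trial so the injected power is
non-phase-locked (total power, not an evoked potential).  Channel montage
is a schematic 31-electrode 10-20 layout with 2-D positions in normalized
head coordinates; spatial adjacency for cluster statistics derives from a
neighbour radius on those positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MONTAGE_31",
    "EEGSimParams",
    "EpochArray",
    "montage_positions",
    "montage_adjacency",
    "burst_spatial_weights",
    "simulate_epochs",
    "save_epochs",
    "load_epochs",
]

# Schematic 10-20 positions (x: left-right, y: posterior-anterior), unit
# head radius.  Not digitized electrode locations; spacing is what matters
# for adjacency.
MONTAGE_31: dict[str, tuple[float, float]] = {
    "Fp1": (-0.22, 0.85), "Fp2": (0.22, 0.85),
    "F7": (-0.65, 0.52), "F3": (-0.35, 0.50), "Fz": (0.0, 0.48),
    "F4": (0.35, 0.50), "F8": (0.65, 0.52),
    "FC5": (-0.55, 0.25), "FC1": (-0.20, 0.25), "FCz": (0.0, 0.24),
    "FC2": (0.20, 0.25), "FC6": (0.55, 0.25),
    "T7": (-0.85, 0.0), "C3": (-0.42, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.42, 0.0), "T8": (0.85, 0.0),
    "CP5": (-0.55, -0.25), "CP1": (-0.20, -0.25), "CPz": (0.0, -0.24),
    "CP2": (0.20, -0.25), "CP6": (0.55, -0.25),
    "P7": (-0.65, -0.52), "P3": (-0.35, -0.50), "Pz": (0.0, -0.48),
    "P4": (0.35, -0.50), "P8": (0.65, -0.52),
    "POz": (0.0, -0.70),
    "O1": (-0.22, -0.85), "Oz": (0.0, -0.88), "O2": (0.22, -0.85),
}


def montage_positions(ch_names=None) -> dict[str, tuple[float, float]]:
    if ch_names is None:
        return dict(MONTAGE_31)
    missing = [c for c in ch_names if c not in MONTAGE_31]
    if missing:
        raise KeyError(f"channels without montage positions: {missing}")
    return {c: MONTAGE_31[c] for c in ch_names}


def montage_adjacency(
    positions: dict[str, tuple[float, float]], radius: float = 0.45
) -> dict[str, list[str]]:
    """Symmetric neighbour lists: channels within ``radius`` of each other."""
    names = list(positions)
    xy = np.array([positions[c] for c in names])
    adj: dict[str, list[str]] = {c: [] for c in names}
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j and np.hypot(*(xy[i] - xy[j])) <= radius:
                adj[a].append(b)
                adj[b].append(a)
    return adj


def burst_spatial_weights(
    positions: dict[str, tuple[float, float]],
    centre: str = "FCz",
    spread: float = 0.35,
) -> np.ndarray:
    """Gaussian spatial profile of the theta burst around a centre channel."""
    if centre not in positions:
        raise KeyError(f"montage lacks burst centre channel {centre!r}")
    cx, cy = positions[centre]
    xy = np.array(list(positions.values()))
    d2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
    return np.exp(-d2 / (2 * spread**2))


@dataclass(frozen=True)
class EEGSimParams:
    """Parameters of the epoched-EEG simulator.

    Amplitudes are in microvolts.  ``noise_amplitude`` is the RMS of the
    1/f background; burst gains are amplitudes of the injected theta
    sinusoid at the centre channel (power in dB follows from amplitude
    ratios).  The stated defaults place a 6 Hz burst at 0.30-0.80 s
    post-stimulus whose conflict response is halved in the MI context.
    """

    ch_names: tuple = tuple(MONTAGE_31)
    sfreq: float = 250.0
    epoch_window: tuple[float, float] = (-1.2, 2.0)
    noise_exponent: float = 1.0
    noise_amplitude: float = 10.0
    burst_freq: float = 6.0
    burst_window: tuple[float, float] = (0.30, 0.80)
    burst_centre: str = "FCz"
    burst_spread: float = 0.35
    base_theta: float = 8.0
    conflict_gain: float = 8.0
    proportion_reduction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.epoch_window[0] <= self.burst_window[0]
            and self.burst_window[1] <= self.epoch_window[1]
        ):
            raise ValueError("burst window must lie inside the epoch")
        if self.sfreq <= 2 * self.burst_freq:
            raise ValueError("sampling rate must exceed twice the burst frequency")
        if not (0 <= self.proportion_reduction <= 1):
            raise ValueError("proportion_reduction must lie in [0, 1]")


@dataclass
class EpochArray:
    """Epoched multichannel EEG: trials x channels x samples (microvolts)."""

    values: np.ndarray
    times: np.ndarray
    ch_names: list
    sfreq: float
    alignment: str = "stimulus"

    def __post_init__(self) -> None:
        t, c, s = self.values.shape
        if c != len(self.ch_names) or s != len(self.times):
            raise ValueError("axis metadata inconsistent with value array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("epoch values must be finite")


def _pink_noise(rng, n_signals: int, n_samples: int, sfreq: float,
                exponent: float, amplitude: float) -> np.ndarray:
    """1/f^exponent Gaussian noise, RMS-normalized to ``amplitude``."""
    freqs = np.fft.rfftfreq(n_samples, 1 / sfreq)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2)
    scale[0] = 0.0
    spec = (
        rng.standard_normal((n_signals, len(freqs)))
        + 1j * rng.standard_normal((n_signals, len(freqs)))
    ) * scale
    sig = np.fft.irfft(spec, n_samples, axis=-1)
    rms = np.sqrt(np.mean(sig**2, axis=-1, keepdims=True))
    return sig / rms * amplitude


def simulate_epochs(
    behavior: pd.DataFrame,
    params: EEGSimParams | None = None,
    alignment: str = "stimulus",
    seed: int | np.random.Generator | None = None,
) -> EpochArray:
    """Simulate one epoch per behaviour-table row.

    Stimulus-locked epochs place the theta burst at the configured
    post-stimulus window; response-locked epochs shift the burst by each
    trial's RT so that it precedes the response by the same latency.
    """
    if params is None:
        params = EEGSimParams()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(params.seed if seed is None else seed)
    )
    positions = montage_positions(params.ch_names)
    weights = burst_spatial_weights(
        positions, params.burst_centre, params.burst_spread
    )
    if not np.any(weights > 0):
        raise ValueError("montage has no channel with positive burst weight")

    t0, t1 = params.epoch_window
    if alignment == "response":
        t0, t1 = -t1, -t0  # mirror the window, e.g. [-2.0, 1.2]
    n_samp = int(round((t1 - t0) * params.sfreq)) + 1
    times = t0 + np.arange(n_samp) / params.sfreq
    n_trials = len(behavior)
    n_ch = len(params.ch_names)

    values = _pink_noise(
        rng,
        n_trials * n_ch,
        n_samp,
        params.sfreq,
        params.noise_exponent,
        params.noise_amplitude,
    ).reshape(n_trials, n_ch, n_samp)

    incongruent = (behavior["congruency"].to_numpy() == "incongruent").astype(float)
    mi = (behavior["proportion_condition"].to_numpy() == "MI").astype(float)
    amplitude = params.base_theta + params.conflict_gain * incongruent * (
        1 - params.proportion_reduction * mi
    )

    b0, b1 = params.burst_window
    if alignment == "response":
        # burst keeps its stimulus latency, so it sits RT seconds before
        # the response marker
        rt_s = behavior["rt_ms"].to_numpy() / 1000.0
        onsets = b0 - rt_s
        offsets = b1 - rt_s
    else:
        onsets = np.full(n_trials, b0)
        offsets = np.full(n_trials, b1)

    phases = rng.uniform(0, 2 * np.pi, n_trials)
    for i in range(n_trials):
        sel = (times >= onsets[i]) & (times <= offsets[i])
        if not sel.any():
            continue
        tt = times[sel]
        envelope = np.hanning(sel.sum())
        carrier = np.sin(2 * np.pi * params.burst_freq * tt + phases[i])
        burst = amplitude[i] * envelope * carrier
        values[i, :, sel] += np.outer(burst, weights)
    return EpochArray(
        values=values,
        times=times,
        ch_names=list(params.ch_names),
        sfreq=params.sfreq,
        alignment=alignment,
    )


def save_epochs(epochs: EpochArray, path_prefix: str) -> None:
    """Write epochs as a binary array container plus a JSON sidecar."""
    np.save(f"{path_prefix}.npy", epochs.values)
    sidecar = {
        "ch_names": list(epochs.ch_names),
        "sfreq": epochs.sfreq,
        "times": epochs.times.tolist(),
        "alignment": epochs.alignment,
    }
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(sidecar, fh)


def load_epochs(path_prefix: str) -> EpochArray:
    values = np.load(f"{path_prefix}.npy")
    with open(f"{path_prefix}.json") as fh:
        sidecar = json.load(fh)
    return EpochArray(
        values=values,
        times=np.asarray(sidecar["times"]),
        ch_names=sidecar["ch_names"],
        sfreq=sidecar["sfreq"],
        alignment=sidecar["alignment"],
    )
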