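"""Spectrogram images of sonified audio, and the stacked multichannel input.

The grader consumes one image per recording: a short-time Fourier magnitude
spectrogram per channel (128-sample Hann window, 64-sample hop — at 512 Hz
audio this gives 65 frequency rows of 4 Hz each and a 125 ms time step),
log-scaled and vertically stacked across the 8 montage channels into a
520-row image.  A Mel spectrogram of the band-passed raw EEG is provided as
the comparison baseline representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .sonify import AudioSignal

__all__ = [
    "SpectrogramImage",
    "stft_spectrogram",
    "stack_channels",
    "split_channels",
    "normalize_image",
    "mel_filterbank",
    "mel_spectrogram",
]

_LOG_EPS = 1e-10


@dataclass
class SpectrogramImage:
    """A (rows x cols) nonnegative-log-magnitude time-frequency image.

    ``freq_axis`` gives the frequency (Hz) of each row within one channel
    block; ``time_axis`` the centre time (s) of each column.  For stacked
    images ``n_channels`` > 1 and rows = n_channels * channel_block_rows.
    """

    values: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    n_channels: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram contains non-finite values")
        if self.values.shape[0] % self.n_channels:
            raise ValueError("rows not divisible by n_channels")

    @property
    def channel_block_rows(self) -> int:
        return self.values.shape[0] // self.n_channels

    @property
    def freq_resolution(self) -> float:
        return float(self.freq_axis[1] - self.freq_axis[0])

    @property
    def time_step(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0])


def stft_spectrogram(
    audio: AudioSignal,
    win_length: int = 128,
    hop: int = 64,
    window: str = "hann",
) -> SpectrogramImage:
    """Log-magnitude STFT with frames fully inside the signal (no padding).

    Columns = floor((n − win_length)/hop) + 1; rows = win_length/2 + 1.
    """
    x = audio.samples
    if x.size < win_length:
        raise ValueError(
            f"audio of {x.size} samples shorter than window {win_length}"
        )
    freqs, times, sxx = sps.spectrogram(
        x,
        fs=audio.rate,
        window=window,
        nperseg=win_length,
        noverlap=win_length - hop,
        mode="magnitude",
        scaling="spectrum",
        detrend=False,
    )
    values = 20.0 * np.log10(sxx + _LOG_EPS)
    return SpectrogramImage(values=values, freq_axis=freqs, time_axis=times)


def stack_channels(specs: list[SpectrogramImage]) -> SpectrogramImage:
    """Vertically stack per-channel spectrograms into one image.

    Row block b (rows ``b*rows_per_channel`` onward) is channel b; the
    stacking preserves the montage channel order so the CNN sees
    cross-channel structure at fixed vertical offsets.
    """
    shapes = {s.values.shape for s in specs}
    if len(shapes) != 1:
        raise ValueError(f"channel spectrograms differ in shape: {shapes}")
    first = specs[0]
    return SpectrogramImage(
        values=np.vstack([s.values for s in specs]),
        freq_axis=first.freq_axis,
        time_axis=first.time_axis,
        n_channels=len(specs),
    )


def split_channels(img: SpectrogramImage) -> list[SpectrogramImage]:
    """Inverse of :func:`stack_channels`."""
    rows = img.channel_block_rows
    return [
        SpectrogramImage(
            values=img.values[b * rows : (b + 1) * rows],
            freq_axis=img.freq_axis,
            time_axis=img.time_axis,
        )
        for b in range(img.n_channels)
    ]


def normalize_image(
    img: SpectrogramImage, policy: str = "per_image_standardize"
) -> SpectrogramImage:
    """Zero-mean unit-variance standardization (constant image -> zeros)."""
    if policy != "per_image_standardize":
        raise ValueError(f"unknown normalization policy {policy!r}")
    v = img.values
    std = v.std()
    values = (v - v.mean()) / std if std > 0 else np.zeros_like(v)
    return SpectrogramImage(
        values=values,
        freq_axis=img.freq_axis,
        time_axis=img.time_axis,
        n_channels=img.n_channels,
    )


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft: int, rate: float, fmin: float = 0.0,
    fmax: float | None = None,
) -> np.ndarray:
    """Triangular Mel filterbank, slaney-style area normalization.

    Each row integrates to a constant (2 / bandwidth weighting), so white
    spectra map to approximately flat Mel energies.
    """
    if fmax is None:
        fmax = rate / 2.0
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
        fb[i] *= 2.0 / (hi - lo)  # slaney area normalization
    return fb


def mel_spectrogram(
    eeg: np.ndarray,
    rate: float,
    n_mels: int = 64,
    win_length: int = 128,
    hop: int = 64,
) -> SpectrogramImage:
    """Baseline representation: log Mel spectrogram of the raw (filtered)
    EEG, bypassing sonification entirely."""
    x = np.asarray(eeg, dtype=float).ravel()
    if x.size < win_length:
        raise ValueError("EEG shorter than one analysis window")
    freqs, times, sxx = sps.spectrogram(
        x,
        fs=rate,
        window="hann",
        nperseg=win_length,
        noverlap=win_length - hop,
        mode="psd",
        detrend=False,
    )
    fb = mel_filterbank(n_mels, win_length, rate)
    mel = fb @ sxx
    values = 10.0 * np.log10(mel + _LOG_EPS)
    mel_centers = _mel_to_hz(
        np.linspace(_hz_to_mel(0.0), _hz_to_mel(rate / 2), n_mels + 2)
    )[1:-1]
    return SpectrogramImage(values=values, freq_axis=mel_centers,
                            time_axis=times)


def save_png(path, img: SpectrogramImage) -> None:
    """Export the image for visual inspection (low frequencies at bottom)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(str(path), img.values[::-1], cmap="magma")
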