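"""FM/AM sonification of long EEG epochs.

A single EEG channel is turned into a short audio clip in five stages:

1.  **preprocess** — mains notch, zero-phase 0.5–7.5 Hz band-pass (the
    delta/theta band that carries the background rhythm), decimation to a
    low working rate;
2.  **envelope** — magnitude of the analytic signal, smoothed, capturing
    signal energy, with dynamic-range **compression** above a −20 dB
    threshold so high-amplitude stretches do not distort the modulation;
3.  **FM** — a 500 Hz carrier whose instantaneous frequency follows the
    normalized EEG on an exponential semitone scale (+12 semitones = one
    octave = double frequency);
4.  **AM** — the FM tone is multiplied by the compressed envelope,
    emphasising burst/suppression alternation;
5.  **time compression + Fourier resampling** — playback is sped up by a
    factor of 20 and the result resampled to 512 Hz, so one hour of EEG
    becomes 180 s of audio.

All stages are deterministic; identical input and configuration give
bit-identical audio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "SonifyConfig",
    "AudioSignal",
    "preprocess",
    "envelope",
    "compress_envelope",
    "normalized_modulator",
    "fm_modulate",
    "am_modulate",
    "compress_and_resample",
    "sonify_channel",
    "sonify_record",
    "write_wav",
]


@dataclass(frozen=True)
class SonifyConfig:
    """Parameters of the sonification chain.

    band_low, band_high : Hz
        Band-pass edges; neonatal background rhythm lives in delta/theta,
        hence the default 0.5–7.5 Hz.
    notch_freq : Hz
        Mains frequency to notch out (50 Hz default, set 60 for US data).
    carrier_freq : Hz
        FM carrier at the original (uncompressed) time base.
    ref_amplitude : μV
        Full-scale EEG amplitude reference (the ±50 μV clinical display
        range); the compression threshold and the AM output level are both
        taken relative to it, so near-isoelectric recordings stay quiet
        rather than being renormalized up to full scale.
    compress_threshold_db : dB
        Envelope level (re. ``ref_amplitude``) above which dynamic-range
        compression engages.
    compress_ratio : dimensionless
        Slope reduction of the compressor above threshold (4:1 default).
    semitone_span : semitones
        Full-scale modulator swing; 24 maps the modulator range onto ±1
        octave around the carrier.
    compression_rate : dimensionless
        Playback speed-up; 20 turns one hour into three minutes.
    audio_rate : Hz
        Output audio sampling rate after the speed-up.
    eeg_work_rate : Hz
        Internal EEG rate after decimation.
    fm_rate : Hz
        Intermediate audio rate at which FM phase is accumulated (must
        comfortably exceed twice the highest instantaneous frequency).
    """

    band_low: float = 0.5
    band_high: float = 7.5
    notch_freq: float = 50.0
    carrier_freq: float = 500.0
    ref_amplitude: float = 50.0
    compress_threshold_db: float = -20.0
    compress_ratio: float = 4.0
    semitone_span: float = 24.0
    compression_rate: float = 20.0
    audio_rate: float = 512.0
    eeg_work_rate: float = 64.0
    fm_rate: float = 4096.0

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high < self.eeg_work_rate / 2:
            raise ValueError(
                "need 0 < band_low < band_high < eeg_work_rate/2, got "
                f"{self.band_low}, {self.band_high}, {self.eeg_work_rate}"
            )
        if self.compression_rate < 1:
            raise ValueError("compression_rate must be >= 1")
        if self.compress_threshold_db >= 0:
            raise ValueError("compress_threshold_db must be negative")


@dataclass
class AudioSignal:
    """A single-channel audio waveform with amplitudes in [−1, 1]."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


def preprocess(
    x: np.ndarray, rate: float, cfg: SonifyConfig = SonifyConfig()
) -> np.ndarray:
    """Notch, band-pass (zero-phase) and decimate to ``cfg.eeg_work_rate``."""
    if rate <= 2 * cfg.band_high:
        raise ValueError(
            f"sampling rate {rate} too low for band edge {cfg.band_high}"
        )
    x = np.asarray(x, dtype=float).ravel()
    if cfg.notch_freq < rate / 2:
        b, a = sps.iirnotch(cfg.notch_freq, Q=30.0, fs=rate)
        x = sps.filtfilt(b, a, x)
    sos = sps.butter(
        4, [cfg.band_low, cfg.band_high], btype="bandpass", fs=rate,
        output="sos",
    )
    x = sps.sosfiltfilt(sos, x)
    from fractions import Fraction

    frac = Fraction(cfg.eeg_work_rate / rate).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def envelope(x: np.ndarray, rate: float, smooth_s: float = 0.25) -> np.ndarray:
    """Nonnegative amplitude envelope: |analytic signal|, then a moving
    average of ``smooth_s`` seconds."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        return x.copy()
    env = np.abs(sps.hilbert(x))
    width = max(1, int(round(smooth_s * rate)))
    if width > 1:
        kernel = np.ones(width) / width
        pad = width // 2
        padded = np.pad(env, pad, mode="edge")
        env = np.convolve(padded, kernel, mode="same")[pad : pad + x.size]
    return env


def compress_envelope(
    env: np.ndarray,
    threshold_db: float = -20.0,
    ref: float | None = None,
    ratio: float = 4.0,
) -> np.ndarray:
    """Power-law dynamic-range compression above an amplitude threshold.

    Values at or below ``T = ref * 10^(threshold_db/20)`` pass unchanged;
    values above are mapped to ``T * (v/T)^(1/ratio)``.  The map is
    continuous, monotone and leaves the threshold a fixed point.  ``ref``
    defaults to the envelope maximum (full scale).
    """
    env = np.asarray(env, dtype=float)
    if np.any(env < 0):
        raise ValueError("envelope must be nonnegative")
    if ref is None:
        ref = float(env.max()) if env.size else 1.0
    if ref <= 0:
        return env.copy()
    thresh = ref * 10.0 ** (threshold_db / 20.0)
    out = env.copy()
    over = env > thresh
    out[over] = thresh * (env[over] / thresh) ** (1.0 / ratio)
    return out


def normalized_modulator(filtered: np.ndarray, env: np.ndarray,
                         floor_frac: float = 1e-3) -> np.ndarray:
    """Divide the filtered EEG by its own envelope (floored at a fraction
    of the envelope peak).  The result is scale-free: rescaling the EEG
    rescales the envelope identically, so the FM content it drives is
    invariant to overall amplitude."""
    scale = env.max() if env.size else 0.0
    if scale <= 0:
        return np.zeros_like(filtered)
    return filtered / np.maximum(env, floor_frac * scale)


def fm_modulate(
    modulator: np.ndarray, rate: float, cfg: SonifyConfig = SonifyConfig()
) -> AudioSignal:
    """Frequency-modulate the carrier with a normalized modulator.

    The modulator (values in [−1, 1]) is linearly interpolated up to
    ``cfg.fm_rate`` and drives the instantaneous frequency

        f(t) = carrier_freq * 2^(s(t)/12),   s(t) = semitone_span/2 * m(t),

    so a full-scale swing covers ``semitone_span`` semitones and +12
    semitones doubles the frequency (one octave).  Phase is accumulated by
    cumulative summation, which keeps it continuous.
    """
    m = np.clip(np.asarray(modulator, dtype=float).ravel(), -1.0, 1.0)
    n_out = int(round(m.size * cfg.fm_rate / rate))
    if n_out == 0:
        return AudioSignal(np.zeros(0), cfg.fm_rate)
    t_in = np.arange(m.size) / rate
    t_out = np.arange(n_out) / cfg.fm_rate
    m_up = np.interp(t_out, t_in, m)
    semitones = 0.5 * cfg.semitone_span * m_up
    inst_freq = cfg.carrier_freq * 2.0 ** (semitones / 12.0)
    phase = 2.0 * np.pi * np.cumsum(inst_freq) / cfg.fm_rate
    return AudioSignal(np.cos(phase), cfg.fm_rate)


def am_modulate(fm: AudioSignal, env: np.ndarray) -> AudioSignal:
    """Multiply the FM tone by the (resampled) envelope.

    ``env`` must already have the same length as the FM signal and be on a
    [0, 1]-ish scale (full scale = 1).  The product is scaled down to a
    0.99 peak only when it would otherwise clip, so quiet input yields
    quiet audio.
    """
    env = np.asarray(env, dtype=float).ravel()
    if env.size != fm.samples.size:
        raise ValueError(
            f"envelope length {env.size} != audio length {fm.samples.size}"
        )
    out = fm.samples * env
    peak = np.abs(out).max() if out.size else 0.0
    if peak > 0.99:
        out = out * (0.99 / peak)
    return AudioSignal(out, fm.rate)


def compress_and_resample(
    audio: AudioSignal, compression_rate: float, target_rate: float
) -> AudioSignal:
    """Speed playback up by ``compression_rate`` and Fourier-resample.

    Time compression is a relabelling of the nominal rate (the samples are
    untouched, they just play faster); the Fourier resampling then brings
    the sped-up signal to ``target_rate``.  Output duration is input
    duration divided by ``compression_rate``.
    """
    if compression_rate < 1:
        raise ValueError("compression_rate must be >= 1")
    sped_rate = audio.rate * compression_rate
    if abs(sped_rate - target_rate) < 1e-9:
        return AudioSignal(audio.samples.copy(), target_rate)
    n_out = int(round(audio.samples.size * target_rate / sped_rate))
    out = sps.resample(audio.samples, n_out)
    return AudioSignal(out, target_rate)


def sonify_channel(
    eeg: np.ndarray, rate: float, cfg: SonifyConfig = SonifyConfig()
) -> AudioSignal:
    """Full chain: preprocess → envelope/compress → FM → AM → compress.

    One hour of EEG at the default configuration becomes 180 s of audio at
    512 Hz (92,160 samples).
    """
    filtered = preprocess(eeg, rate, cfg)
    env = envelope(filtered, cfg.eeg_work_rate)
    # Threshold and output level are relative to the fixed full-scale
    # reference: a −20 dB threshold on a 50 μV range engages at 5 μV, so
    # bursts are compressed while suppressions pass linearly and
    # near-isoelectric records stay near-silent.
    env_c = compress_envelope(
        env, cfg.compress_threshold_db, ref=cfg.ref_amplitude,
        ratio=cfg.compress_ratio,
    )
    full_scale = compress_envelope(
        np.array([cfg.ref_amplitude]), cfg.compress_threshold_db,
        ref=cfg.ref_amplitude, ratio=cfg.compress_ratio,
    )[0]
    env_c = env_c / full_scale
    # Pointwise normalization by the raw envelope whitens amplitude before
    # FM, so the FM content is exactly invariant to an overall rescaling of
    # the EEG; amplitude information travels through the AM stage instead.
    m = normalized_modulator(filtered, env)
    fm = fm_modulate(m, cfg.eeg_work_rate, cfg)
    t_env = np.arange(env_c.size) / cfg.eeg_work_rate
    t_fm = np.arange(fm.samples.size) / cfg.fm_rate
    env_up = np.interp(t_fm, t_env, env_c) if env_c.size else np.zeros_like(t_fm)
    am = am_modulate(fm, env_up)
    return compress_and_resample(am, cfg.compression_rate, cfg.audio_rate)


def sonify_record(record, cfg: SonifyConfig = SonifyConfig()) -> list[AudioSignal]:
    """Sonify every channel of an :class:`~hiegrade.io_eeg.EegRecord`."""
    return [sonify_channel(ch, record.rate, cfg) for ch in record.samples]


def write_wav(path: str | Path, audio: AudioSignal) -> None:
    """Export 16-bit PCM WAV for auditory inspection."""
    from scipy.io import wavfile

    pcm = np.clip(audio.samples, -1.0, 1.0)
    wavfile.write(str(path), int(round(audio.rate)),
                  (pcm * 32767).astype(np.int16))
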