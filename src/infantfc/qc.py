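"""Windowed physiological signal-quality scoring and channel pruning.

Optode–scalp coupling is scored from the cardiac pulsation that a
well-coupled channel records at both wavelengths: the scalp coupling index
(SCI) is the zero-lag Pearson correlation of the cardiac-band-filtered,
unit-variance wavelength pair, and the peak spectral power (PSP) is the peak
of the power spectrum of their normalized cross-correlation within the
cardiac band. Scores are computed in non-overlapping 3 s windows; a channel
is excluded when both scores are below threshold (SCI < 0.70 and PSP < 0.1)
in more than 70% of windows, and a recording is excluded when more than 40%
of its channels are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

CARDIAC_BAND_HZ = (0.5, 2.5)   # infant heart rate ~70–150 bpm plus margin


@dataclass
class QCParams:
    window_s: float = 3.0
    window_stride_s: float | None = None   # None → non-overlapping
    sci_threshold: float = 0.70
    psp_threshold: float = 0.1
    fail_fraction: float = 0.70
    recording_exclusion_fraction: float = 0.40
    cardiac_band_hz: tuple[float, float] = CARDIAC_BAND_HZ


@dataclass
class QualityReport:
    sci: np.ndarray                  # (n_channels, n_windows)
    psp: np.ndarray                  # (n_channels, n_windows)
    fail_fraction: np.ndarray        # (n_channels,) fraction of windows failing both
    excluded_channels: set[int] = field(default_factory=set)   # 1-based indices
    recording_excluded: bool = False
    params: QCParams = field(default_factory=QCParams)

    @property
    def excluded_fraction(self) -> float:
        return len(self.excluded_channels) / self.sci.shape[0]

    def surviving_channels(self, n_channels: int | None = None) -> list[int]:
        n = n_channels or self.sci.shape[0]
        return [c for c in range(1, n + 1) if c not in self.excluded_channels]


def sliding_windows(n_samples: int, fs: float, window_s: float = 3.0,
                    stride_s: float | None = None) -> list[tuple[int, int]]:
    """Contiguous window [start, end) index pairs; trailing partial dropped."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    w = int(round(window_s * fs))
    step = w if stride_s is None else int(round(stride_s * fs))
    if step <= 0 or w <= 0:
        raise ValueError("window and stride must be positive")
    if n_samples < w:
        raise ValueError("recording shorter than one window")
    return [(s, s + w) for s in range(0, n_samples - w + 1, step)]


def cardiac_filter(x: np.ndarray, fs: float,
                   band: tuple[float, float] = CARDIAC_BAND_HZ, axis: int = -1) -> np.ndarray:
    sos = signal.butter(3, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def _standardize(w: np.ndarray) -> np.ndarray | None:
    sd = w.std()
    if not np.isfinite(sd) or sd == 0:
        return None
    return (w - w.mean()) / sd


def compute_sci(window_a: np.ndarray, window_b: np.ndarray, fs: float,
                *, prefiltered: bool = False,
                band: tuple[float, float] = CARDIAC_BAND_HZ) -> float:
    """Scalp coupling index of a two-wavelength window pair.

    Zero-lag correlation of the cardiac-band components. A zero-variance
    (dead/saturated) window yields NaN, which counts as a failing window.
    """
    a, b = np.asarray(window_a, float), np.asarray(window_b, float)
    if a.shape != b.shape:
        raise ValueError("windows must have equal length")
    if not prefiltered:
        a, b = cardiac_filter(a, fs, band), cardiac_filter(b, fs, band)
    az, bz = _standardize(a), _standardize(b)
    if az is None or bz is None:
        return float("nan")
    return float(np.mean(az * bz))


def compute_psp(window_a: np.ndarray, window_b: np.ndarray, fs: float,
                *, prefiltered: bool = False,
                band: tuple[float, float] = CARDIAC_BAND_HZ,
                return_freq: bool = False):
    """Peak spectral power of the windowed normalized cross-correlation.

    The cardiac-band-filtered windows are standardized, their full
    cross-correlation sequence (normalized so the zero-lag value is the
    Pearson coefficient) is computed, and the peak of its Hamming-windowed
    power spectrum within the cardiac band is returned. Invariant to common
    amplitude rescaling of both inputs.
    """
    a, b = np.asarray(window_a, float), np.asarray(window_b, float)
    if a.shape != b.shape:
        raise ValueError("windows must have equal length")
    if not prefiltered:
        a, b = cardiac_filter(a, fs, band), cardiac_filter(b, fs, band)
    az, bz = _standardize(a), _standardize(b)
    if az is None or bz is None:
        return (float("nan"), float("nan")) if return_freq else float("nan")
    n = len(az)
    cc = signal.correlate(az, bz, mode="full") / n       # zero lag = Pearson r
    freqs, pxx = signal.periodogram(cc, fs=fs, window="hamming", scaling="spectrum")
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        return (0.0, float("nan")) if return_freq else 0.0
    k = int(np.argmax(pxx[in_band]))
    peak = float(pxx[in_band][k])
    if return_freq:
        return peak, float(freqs[in_band][k])
    return peak


def channel_quality(intensity: np.ndarray, fs: float,
                    params: QCParams | None = None) -> QualityReport:
    """Windowed SCI/PSP for every channel of a two-wavelength recording.

    ``intensity`` has shape (n_channels, 2, n_samples). The cardiac-band
    filter is applied to the full series once; windows are then scored on
    the filtered signal.
    """
    params = params or QCParams()
    x = np.asarray(intensity, dtype=float)
    wins = sliding_windows(x.shape[2], fs, params.window_s, params.window_stride_s)
    filt = cardiac_filter(x, fs, params.cardiac_band_hz, axis=-1)
    sci, psp = _batched_scores(filt, wins, fs, params.cardiac_band_hz)
    return prune_channels(sci, psp, params)


def _batched_scores(filt: np.ndarray, wins: list[tuple[int, int]], fs: float,
                    band: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized SCI/PSP over all channels and windows; numerically equal to
    the per-window :func:`compute_sci` / :func:`compute_psp` on prefiltered
    windows (asserted in the test suite)."""
    starts = np.array([s for s, _ in wins])
    w = wins[0][1] - wins[0][0]
    idx = starts[:, None] + np.arange(w)[None, :]
    a = filt[:, 0, :][:, idx]                    # (C, n_win, w)
    b = filt[:, 1, :][:, idx]
    sd_a = a.std(axis=-1, keepdims=True)
    sd_b = b.std(axis=-1, keepdims=True)
    bad = (sd_a[..., 0] == 0) | (sd_b[..., 0] == 0) | ~np.isfinite(sd_a[..., 0] * sd_b[..., 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        az = (a - a.mean(axis=-1, keepdims=True)) / sd_a
        bz = (b - b.mean(axis=-1, keepdims=True)) / sd_b
    sci = np.mean(az * bz, axis=-1)

    n2 = 2 * w - 1
    A = np.fft.rfft(az, n=n2, axis=-1)
    B = np.fft.rfft(bz, n=n2, axis=-1)
    cc = np.roll(np.fft.irfft(A * np.conj(B), n=n2, axis=-1), w - 1, axis=-1) / w
    freqs, pxx = signal.periodogram(cc, fs=fs, window="hamming",
                                    scaling="spectrum", axis=-1)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    psp = pxx[..., in_band].max(axis=-1)
    sci[bad] = np.nan
    psp[bad] = np.nan
    return sci, psp


def prune_channels(sci: np.ndarray, psp: np.ndarray,
                   params: QCParams | None = None) -> QualityReport:
    """Apply the both-below-threshold exclusion rule.

    A window fails when SCI < sci_threshold AND PSP < psp_threshold (NaN
    scores fail); a channel is excluded when its failing fraction exceeds
    ``fail_fraction``; the recording is excluded when the excluded channel
    fraction exceeds ``recording_exclusion_fraction``.
    """
    params = params or QCParams()
    sci = np.atleast_2d(sci)
    psp = np.atleast_2d(psp)
    sci_bad = ~(sci >= params.sci_threshold)     # NaN → bad
    psp_bad = ~(psp >= params.psp_threshold)
    fail = sci_bad & psp_bad
    frac = fail.mean(axis=1)
    excluded = {c + 1 for c in range(sci.shape[0]) if frac[c] > params.fail_fraction}
    rec_excl = len(excluded) / sci.shape[0] > params.recording_exclusion_fraction
    return QualityReport(sci=sci, psp=psp, fail_fraction=frac,
                         excluded_channels=excluded, recording_excluded=rec_excl,
                         params=params)
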