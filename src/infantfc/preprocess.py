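"""Optical-density conversion, filtering, GSR, GVTD censoring and the MBLL.

The preprocessing chain operates on optical density (OD) per wavelength:

    prune → OD → bandpass 0.009–3 Hz → global signal regression →
    bandpass 0.009–0.08 Hz → GVTD artifact censoring → modified
    Beer–Lambert conversion → section averaging

Censoring is applied as masking: samples within ``pad_s`` of a detected
artifact are invalidated and only contiguous valid chunks of at least
``min_chunk_s`` are retained. No interpolation is ever performed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import signal
from scipy.stats import gaussian_kde

from .probe import Probe

__all__ = [
    "ODSeries", "ChromophoreSeries", "GvtdTrace",
    "intensity_to_od", "bandpass", "global_signal_regression",
    "compute_gvtd", "mask_and_segment", "dpf", "dpf_table", "od_to_hb",
    "extinction_coefficients",
]


@dataclass
class ODSeries:
    """Optical-density change series, shape (n_channels, n_wavelengths, n_samples)."""

    data: np.ndarray
    fs: float
    wavelengths_nm: tuple[float, ...]
    channel_valid: np.ndarray  # (n_channels,) bool

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "ODSeries":
        return ODSeries(self.data.copy(), self.fs, tuple(self.wavelengths_nm),
                        self.channel_valid.copy())


@dataclass
class ChromophoreSeries:
    """HbO2/HHb concentration changes (µM) with per-sample validity and chunks."""

    hbo2: np.ndarray            # (n_channels, n_samples)
    hhb: np.ndarray             # (n_channels, n_samples)
    fs: float
    mask: np.ndarray            # (n_samples,) bool, True = valid
    chunks: list[tuple[int, int]] = field(default_factory=list)  # [start, end) sample indices
    channel_valid: np.ndarray | None = None

    @property
    def valid_seconds(self) -> float:
        return float(self.mask.sum()) / self.fs


@dataclass
class GvtdTrace:
    gvtd: np.ndarray            # (n_samples,), gvtd[0] == 0
    threshold: float
    artifact: np.ndarray        # (n_samples,) bool, True where gvtd > threshold


def intensity_to_od(intensity: np.ndarray, fs: float,
                    wavelengths_nm: tuple[float, ...]) -> ODSeries:
    """−ln(I / temporal mean I) per channel and wavelength.

    Channels containing non-positive samples at any wavelength carry no
    usable light level and are invalidated (their OD is set to zero).
    """
    I = np.asarray(intensity, dtype=float)
    if I.ndim != 3:
        raise ValueError("intensity must have shape (channels, wavelengths, samples)")
    valid = np.all(I > 0, axis=(1, 2)) & np.all(np.isfinite(I), axis=(1, 2))
    od = np.zeros_like(I)
    if valid.any():
        Iv = I[valid]
        od[valid] = -np.log(Iv / Iv.mean(axis=2, keepdims=True))
    return ODSeries(od, fs, tuple(wavelengths_nm), valid)


def bandpass(x: np.ndarray, fs: float, low_hz: float, high_hz: float,
             order: int = 3, axis: int = -1) -> np.ndarray:
    """Zero-phase forward–backward Butterworth band-pass."""
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) at fs={fs}")
    x = np.asarray(x, dtype=float)
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    # the impulse response extends ~1/low_hz seconds; pad accordingly (the
    # sosfiltfilt default is far too short for a 0.009 Hz edge)
    padlen = min(x.shape[axis] - 1, int(3 * fs / low_hz))
    return signal.sosfiltfilt(sos, x, axis=axis, padlen=padlen)


def global_signal_regression(od: ODSeries) -> ODSeries:
    """Regress the array-mean time course out of every channel, per wavelength.

    Each valid channel is replaced by its least-squares residual from a
    regression on (intercept, array mean); residuals are orthogonal to the
    mean regressor. One regressor is built per wavelength.
    """
    if int(od.channel_valid.sum()) < 2:
        raise ValueError("global signal regression requires at least 2 valid channels")
    out = od.copy()
    for w in range(od.data.shape[1]):
        y = od.data[od.channel_valid, w, :]            # (Cv, T)
        g = y.mean(axis=0)
        X = np.column_stack([np.ones_like(g), g])      # (T, 2)
        beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
        out.data[od.channel_valid, w, :] = (y.T - X @ beta).T
    return out


def compute_gvtd(series: np.ndarray, multiplier: float = 5.0,
                 mode_estimator: str = "kde") -> GvtdTrace:
    """Global variance of temporal derivatives and its censoring threshold.

    GVTD(t) = sqrt(mean over series of (y(t) − y(t−1))²), with GVTD(0) = 0.
    The threshold is the mode of the GVTD distribution plus ``multiplier``
    times the spread of the sub-mode values (RMS deviation below the mode) —
    the left half of the distribution estimates the motion-free noise floor.
    """
    y = np.atleast_2d(np.asarray(series, dtype=float))
    if y.shape[1] < 2:
        raise ValueError("need at least 2 samples to differentiate")
    d = np.diff(y, axis=1)
    g = np.sqrt(np.mean(d * d, axis=0))
    gvtd = np.concatenate([[0.0], g])

    vals = g
    if mode_estimator == "kde" and np.ptp(vals) > 0 and len(vals) >= 10:
        sample = vals if len(vals) <= 4000 else np.sort(vals)[:: len(vals) // 4000 + 1]
        kde = gaussian_kde(sample)
        grid = np.linspace(vals.min(), np.quantile(vals, 0.99), 512)
        mode = float(grid[np.argmax(kde(grid))])
    else:  # median fallback, also used for degenerate distributions
        mode = float(np.median(vals))
    sub = vals[vals <= mode]
    spread = float(np.sqrt(np.mean((sub - mode) ** 2))) if len(sub) else 0.0
    threshold = mode + multiplier * spread
    artifact = gvtd > threshold
    artifact[0] = False
    return GvtdTrace(gvtd, threshold, artifact)


def mask_and_segment(trace: GvtdTrace, fs: float, pad_s: float = 5.0,
                     min_chunk_s: float = 20.0) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Validity mask and retained chunks from a GVTD trace.

    Samples within ``pad_s`` seconds of any artifact sample are invalid;
    maximal valid runs shorter than ``min_chunk_s`` are discarded. Returns
    (mask, chunks) where chunks are [start, end) sample index pairs.
    """
    n = len(trace.gvtd)
    mask = np.ones(n, dtype=bool)
    pad = int(round(pad_s * fs))
    art = np.flatnonzero(trace.artifact)
    for t in art:
        mask[max(0, t - pad): min(n, t + pad + 1)] = False
    min_len = int(round(min_chunk_s * fs))
    chunks: list[tuple[int, int]] = []
    # enumerate maximal True runs
    padded = np.concatenate([[False], mask, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            chunks.append((int(s), int(e)))
        else:
            mask[s:e] = False
    return mask, chunks


def dpf(wavelength_nm: float, age_years: float) -> float:
    """Differential pathlength factor from the general age/wavelength fit.

    DPF(λ, A) = 223.3 + 0.05624·A^0.8493 − 5.723e-7·λ³ + 0.001245·λ² − 0.9025·λ
    with A in years and λ in nm; valid for λ in [690, 900] nm, A ≥ 0.
    Strictly increasing in age at fixed wavelength.
    """
    l = float(wavelength_nm)
    if not 690.0 <= l <= 900.0:
        raise ValueError("wavelength outside the 690–900 nm validity range")
    if age_years < 0:
        raise ValueError("age must be non-negative")
    A = float(age_years)
    return 223.3 + 0.05624 * A ** 0.8493 - 5.723e-7 * l ** 3 + 0.001245 * l ** 2 - 0.9025 * l


def dpf_table(wavelengths_nm, ages_years) -> dict[tuple[float, float], float]:
    """DPF values on a (wavelength, age) grid."""
    return {(l, a): dpf(l, a) for l in wavelengths_nm for a in ages_years}


def extinction_coefficients(wavelengths_nm) -> np.ndarray:
    """ε matrix (cm⁻¹/M), rows per wavelength, columns (HbO2, HHb).

    Values are linearly interpolated from the packaged compilation of molar
    extinction coefficients.
    """
    import pandas as pd
    text = resources.files("infantfc.data").joinpath("extinction_coefficients.csv").read_text()
    rows = pd.read_csv(io.StringIO(text), comment="#")
    tab_l = rows["wavelength_nm"].to_numpy()
    tab_o = rows["eps_hbo2"].to_numpy()
    tab_h = rows["eps_hhb"].to_numpy()
    E = np.empty((len(wavelengths_nm), 2))
    for i, l in enumerate(wavelengths_nm):
        if not tab_l.min() <= l <= tab_l.max():
            raise ValueError(f"wavelength {l} nm outside tabulated extinction range")
        E[i, 0] = np.interp(l, tab_l, tab_o)
        E[i, 1] = np.interp(l, tab_l, tab_h)
    return E


def od_to_hb(od: ODSeries, probe: Probe, age_years: float) -> ChromophoreSeries:
    """Modified Beer–Lambert inversion of two-wavelength OD to ΔHbO2/ΔHHb (µM).

    Per channel the 2×2 system ΔOD_λ = (ε_HbO2,λ·ΔHbO2 + ε_HHb,λ·ΔHHb)·d·DPF(λ)
    is solved sample-wise, with d the source–detector separation in cm and ε
    in cm⁻¹/M (concentrations returned in µM).
    """
    wl = od.wavelengths_nm
    if len(wl) != 2:
        raise ValueError("MBLL inversion requires exactly two wavelengths")
    E = extinction_coefficients(wl)                       # (2, 2)
    if abs(np.linalg.det(E)) < 1e-12:
        raise ValueError("singular extinction matrix")
    dpfs = np.array([dpf(l, age_years) for l in wl])      # (2,)
    d = probe.separation_cm
    # b_λ = OD_λ / (d · DPF_λ);  C = E⁻¹ b  (mol/L) → µM
    b = od.data / (d * dpfs[None, :, None])               # (C, 2, T)
    Einv = np.linalg.inv(E)
    conc = np.einsum("kw,cwt->ckt", Einv, b) * 1e6        # (C, 2, T) µM
    mask = np.ones(od.n_samples, dtype=bool)
    return ChromophoreSeries(hbo2=conc[:, 0, :], hhb=conc[:, 1, :], fs=od.fs,
                             mask=mask, chunks=[(0, od.n_samples)],
                             channel_valid=od.channel_valid.copy())


def hb_to_od(hbo2: np.ndarray, hhb: np.ndarray, probe: Probe, age_years: float,
             fs: float) -> ODSeries:
    """Forward Beer–Lambert model: chromophore µM series → OD per wavelength.

    Exact inverse of :func:`od_to_hb`; used by the synthetic generator so that
    forward-then-invert round-trips are identities up to float precision.
    """
    wl = probe.wavelengths_nm
    E = extinction_coefficients(wl)
    dpfs = np.array([dpf(l, age_years) for l in wl])
    C = np.stack([hbo2, hhb], axis=1) * 1e-6              # (C, 2, T) mol/L
    od = np.einsum("wk,ckt->cwt", E, C) * probe.separation_cm * dpfs[None, :, None]
    return ODSeries(od, fs, tuple(wl), np.ones(hbo2.shape[0], dtype=bool))
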