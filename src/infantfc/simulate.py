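"""Synthetic raw recordings and longitudinal cohorts with known ground truth.

The recording generator inverts the pipeline's own forward model: slow
section hemodynamics (band-limited 0.009–0.08 Hz, with a prescribed 6x6
covariance) plus a shared systemic global signal are mapped to per-channel
chromophore series, converted to optical density through the forward
Beer–Lambert model, and overlaid with cardiac pulsation (scaled by
per-channel scalp coupling), motion transients, and white measurement noise;
intensities are I0·exp(−OD).

The default scenario generates section hemodynamics whose unweighted array
mean is identically zero (the covariance is projected by P = I − 11'/6), so
the array-mean regressor used by GSR isolates the systemic signal — the
regime in which global signal regression is valid.

The cohort generator draws per-infant connection-wise Fisher-z trajectories
with a random intercept and AR(1) visit-to-visit residual correlation,
missing visits, WHO-style growth z-score trajectories with prescribed
ΔWLZ→FC(24 mo) slopes, and preschool cognitive-flexibility scores with
prescribed FC→score slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import hb_to_od
from .probe import Probe, SectionMap, SECTIONS, load_probe_fixture

__all__ = [
    "RecordingScenario", "RawRecording", "RecordingGroundTruth", "simulate_recording",
    "CohortSpec", "GrowthModel", "OutcomeModel", "CohortTable", "CohortGroundTruth",
    "simulate_cohort", "default_section_covariance",
]

SLOW_BAND_HZ = (0.009, 0.08)

# Canonical anthropometry visit schedule (label → age in days).
GROWTH_VISITS = {"birth": 0, "7/14d": 10, "1mo": 30, "5mo": 152, "8mo": 243,
                 "12mo": 365, "18mo": 548, "24mo": 730}
# Visits entering ΔWLZ intervals (7 → C(7,2)=21 intervals); 7/14d is the
# HCZ-covariate visit only.
DELTA_VISITS = ("birth", "1mo", "5mo", "8mo", "12mo", "18mo", "24mo")


def _pattern_correlation() -> np.ndarray:
    """Section correlation pattern: homotopic positive, fronto-middle
    anticorrelated, long-range fronto-posterior mildly negative early."""
    A = np.array([  # within hemisphere (front, middle, back)
        [1.00, -0.35, -0.20],
        [-0.35, 1.00, 0.30],
        [-0.20, 0.30, 1.00],
    ])
    B = np.array([  # across hemispheres
        [0.55, -0.30, -0.20],
        [-0.30, 0.45, 0.15],
        [-0.20, 0.15, 0.45],
    ])
    return np.block([[A, B], [B.T, A]])


def default_section_covariance(sd_um: float = 0.5) -> np.ndarray:
    """Default 6x6 slow-hemodynamics covariance (µM²).

    The correlation pattern is projected onto the zero-array-mean subspace
    (P = I − 11'/6) so the generated sections sum to zero at every sample.
    """
    P = np.eye(6) - np.ones((6, 6)) / 6.0
    return sd_um ** 2 * (P @ _pattern_correlation() @ P)


@dataclass
class RecordingScenario:
    """Generative settings for one synthetic recording."""

    duration_s: float = 600.0
    heart_rate_hz: float = 2.2          # infant ~130 bpm
    cardiac_amplitude_per_channel: np.ndarray | float = 0.01   # OD units; 0 = decoupled
    global_signal_sd: float = 1.0       # µM, systemic signal
    section_covariance: np.ndarray = field(default_factory=default_section_covariance)
    motion_events: tuple[tuple[float, float, float], ...] = (
        (150.0, 2.0, 0.3), (300.0, 2.0, 0.3), (450.0, 2.0, 0.3))
    motion_shift_fraction: float = 0.0  # baseline-shift amplitude as fraction of event amp
    noise_sd: float = 0.003             # OD white noise
    hhb_ratio: float = 0.5              # ΔHHb = −ratio·ΔHbO2
    age_months: float = 24.0
    seed: int = 0

    def validate(self, n_channels: int) -> np.ndarray:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        S = np.asarray(self.section_covariance, dtype=float)
        if S.shape != (6, 6) or not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("section_covariance must be a symmetric 6x6 matrix")
        if np.linalg.eigvalsh(S).min() < -1e-8:
            raise ValueError("section_covariance must be positive semidefinite")
        amp = np.asarray(self.cardiac_amplitude_per_channel, dtype=float)
        if amp.ndim == 0:
            amp = np.full(n_channels, float(amp))
        if len(amp) != n_channels:
            raise ValueError("cardiac amplitude vector length must match channel count")
        if (amp < 0).any():
            raise ValueError("cardiac amplitudes must be non-negative")
        for onset, dur, a in self.motion_events:
            if a < 0 or dur <= 0:
                raise ValueError("motion events need positive duration and non-negative amplitude")
        return amp


@dataclass
class RawRecording:
    """Per-channel two-wavelength intensity with acquisition metadata."""

    intensity: np.ndarray               # (n_channels, 2, n_samples)
    fs: float
    wavelengths_nm: tuple[float, float]
    probe_name: str = "bright_infant"
    subject: str = "sim"
    visit_age_months: float = 24.0

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]


@dataclass
class RecordingGroundTruth:
    section_hbo2: np.ndarray            # (6, n_samples), µM
    section_hhb: np.ndarray
    global_hbo2: np.ndarray             # (n_samples,), µM
    artifact_mask: np.ndarray           # (n_samples,) bool, True inside an injected event
    coupled: np.ndarray                 # (n_channels,) bool
    population_corr: np.ndarray         # 6x6, from the scenario covariance
    population_z: np.ndarray            # atanh of off-diagonal population_corr

    def realized_corr(self, sample_index: np.ndarray | None = None) -> np.ndarray:
        """Correlation matrix of the realized section HbO2 series (optionally
        restricted to a sample subset, e.g. the pipeline's valid samples)."""
        x = self.section_hbo2 if sample_index is None else self.section_hbo2[:, sample_index]
        return np.corrcoef(x)


def _cov_to_corr(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    d = np.where(d > 0, d, 1.0)
    return S / np.outer(d, d)


def _band_limited_noise(rng: np.random.Generator, n_series: int, n: int, fs: float,
                        band: tuple[float, float] = SLOW_BAND_HZ) -> np.ndarray:
    """Unit-variance rows of exactly band-limited Gaussian noise.

    Synthesized in the frequency domain (independent complex-Gaussian
    coefficients on the in-band bins, zero elsewhere) so rows are mutually
    independent with a flat in-band spectrum and no filter edge transients.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.zeros((n_series, len(freqs)), dtype=complex)
    k = int(in_band.sum())
    spec[:, in_band] = (rng.standard_normal((n_series, k))
                        + 1j * rng.standard_normal((n_series, k)))
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def simulate_recording(probe: Probe, smap: SectionMap,
                       scenario: RecordingScenario) -> tuple[RawRecording, RecordingGroundTruth]:
    """Generate one raw recording plus its ground truth. Seed-deterministic."""
    amp = scenario.validate(probe.n_channels)
    rng = np.random.default_rng(scenario.seed)
    fs = probe.sampling_rate_hz
    n = int(round(scenario.duration_s * fs))
    C = probe.n_channels
    age_years = scenario.age_months / 12.0

    # --- slow section hemodynamics with prescribed covariance (µM) ---
    S = np.asarray(scenario.section_covariance, dtype=float)
    w, V = np.linalg.eigh(S)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T
    latent = _band_limited_noise(rng, 6, n, fs)
    sec_hbo2 = root @ latent
    sec_hhb = -scenario.hhb_ratio * sec_hbo2

    # --- systemic global signal, same slow band ---
    g = scenario.global_signal_sd * _band_limited_noise(rng, 1, n, fs)[0]

    # --- per-channel chromophores → forward MBLL OD ---
    sec_index = np.array([SECTIONS.index(smap.section_of_channel[c.index])
                          for c in probe.channels])
    hbo2 = sec_hbo2[sec_index] + g[None, :]
    hhb = sec_hhb[sec_index] - scenario.hhb_ratio * g[None, :]
    od = hb_to_od(hbo2, hhb, probe, age_years, fs).data     # (C, 2, n)

    # --- cardiac pulsation: common waveform with slow phase drift,
    #     per-channel coupling amplitude, wavelength-dependent gain ---
    t = np.arange(n) / fs
    phase = 2 * np.pi * scenario.heart_rate_hz * t \
        + np.cumsum(rng.standard_normal(n)) * 0.02 + rng.uniform(0, 2 * np.pi)
    cardiac = np.sin(phase)
    gains = np.array([0.8, 1.2])    # arterial pulsation is HbO2-weighted → larger at 850 nm
    od += amp[:, None, None] * gains[None, :, None] * cardiac[None, None, :]

    # --- motion events: high-amplitude transients, random sign per channel ---
    artifact_mask = np.zeros(n, dtype=bool)
    for onset, dur, a in scenario.motion_events:
        s0 = int(round(onset * fs))
        ln = max(2, int(round(dur * fs)))
        if s0 >= n:
            continue
        e0 = min(n, s0 + ln)
        bump = np.hanning(ln)[: e0 - s0]
        sign = rng.choice([-1.0, 1.0], size=C)
        scale = rng.uniform(0.5, 1.5, size=C)
        od[:, :, s0:e0] += (a * sign * scale)[:, None, None] * bump[None, None, :]
        if scenario.motion_shift_fraction > 0:
            shift = scenario.motion_shift_fraction * a * rng.choice([-1.0, 1.0], size=C) \
                * rng.uniform(0.5, 1.5, size=C)
            od[:, :, e0:] += shift[:, None, None]
        artifact_mask[s0:e0] = True

    # --- white measurement noise, then intensity ---
    od += scenario.noise_sd * rng.standard_normal(od.shape)
    intensity = np.exp(-od)     # I0 = 1

    pop_corr = _cov_to_corr(S)
    iu = np.triu_indices(6, 1)
    pop_z = np.arctanh(np.clip(pop_corr[iu], -1 + 1e-7, 1 - 1e-7))
    truth = RecordingGroundTruth(
        section_hbo2=sec_hbo2, section_hhb=sec_hhb, global_hbo2=g,
        artifact_mask=artifact_mask, coupled=amp > 0,
        population_corr=pop_corr, population_z=pop_z)
    rec = RawRecording(intensity=intensity, fs=fs,
                       wavelengths_nm=tuple(probe.wavelengths_nm),
                       visit_age_months=scenario.age_months)
    return rec, truth


def qc_benchmark_scenario(n_channels: int = 34, n_decoupled: int = 8,
                          seed: int = 0, duration_s: float = 120.0) -> RecordingScenario:
    """Default scenario variant with a fixed set of decoupled channels
    (every ceil(n/k)-th channel has zero cardiac coupling)."""
    amp = np.full(n_channels, 0.01)
    step = max(1, n_channels // n_decoupled)
    decoupled = np.arange(0, n_channels, step)[:n_decoupled]
    amp[decoupled] = 0.0
    return RecordingScenario(duration_s=duration_s,
                             cardiac_amplitude_per_channel=amp, seed=seed)


# ----------------------------------------------------------------------------
# Longitudinal cohort
# ----------------------------------------------------------------------------

#: Fixed-effect defaults: per-connection (baseline z at 5 months, change at
#: 8/12/18/24 months relative to 5 months). Connections not listed are flat
#: at the given baseline. Shapes mirror a developmental pattern in which
#: frontal interhemispheric FC declines with age while short-range
#: fronto-middle and long-range right fronto-posterior FC strengthen.
DEFAULT_FIXED_EFFECTS: dict[str, tuple[float, tuple[float, float, float, float]]] = {
    "L-front|R-front": (0.28, (-0.09, -0.20, -0.25, -0.33)),
    "L-front|L-middle": (-0.28, (0.06, 0.09, 0.19, 0.23)),
    "R-front|R-middle": (-0.30, (0.01, 0.05, 0.13, 0.19)),
    "R-front|R-back": (-0.20, (0.16, 0.14, 0.20, 0.22)),
}


@dataclass
class GrowthModel:
    """WLZ/HCZ trajectory generator with ΔWLZ→FC(24 mo) couplings.

    ``fc_slopes`` maps (connection, (earlier visit, later visit)) to the
    slope by which that interval's ΔWLZ shifts the connection's 24-month z.
    """

    wlz_mean: float = -0.3
    wlz_between_sd: float = 0.7      # stable inter-infant component
    wlz_step_sd: float = 0.35        # visit-to-visit random-walk step
    hcz_mean: float = -0.7
    hcz_sd: float = 0.9
    fc_slopes: dict[tuple[str, tuple[str, str]], float] = field(default_factory=lambda: {
        ("L-front|R-front", ("birth", "24mo")): 0.30,
        ("L-front|L-middle", ("birth", "24mo")): -0.20,
    })


@dataclass
class OutcomeModel:
    """Preschool cognitive-flexibility score generator.

    ``slopes`` maps (connection, fc visit age months, group) to the slope of
    score on the connection's Fisher z at that visit.
    """

    intercept: float = 6.0
    noise_sd: float = 2.0
    present_probability: float = 0.8
    slopes: dict[tuple[str, float, str], float] = field(default_factory=lambda: {
        ("L-front|R-front", 5.0, "younger"): 2.0,
        ("R-front|R-back", 24.0, "older"): 2.0,
    })


@dataclass
class CohortSpec:
    n_subjects: int = 132
    visit_ages_months: tuple[float, ...] = (5.0, 8.0, 12.0, 18.0, 24.0)
    fixed_effects: dict[str, tuple[float, tuple[float, ...]]] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS))
    default_baseline: float = 0.0
    random_intercept_sd: float = 0.15
    ar1_rho: float = 0.3
    residual_sd: float = 0.25
    missingness_probability: float = 0.40
    chromophores: tuple[str, ...] = ("HbO2", "HHb")
    growth_model: GrowthModel = field(default_factory=GrowthModel)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    seed: int = 0

    def validate(self):
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        if not 0 <= self.missingness_probability <= 1:
            raise ValueError("missingness_probability must lie in [0, 1]")
        if self.n_subjects < 1 or len(self.visit_ages_months) < 2:
            raise ValueError("need at least one subject and two visit ages")
        for conn, (_, deltas) in self.fixed_effects.items():
            if len(deltas) != len(self.visit_ages_months) - 1:
                raise ValueError(f"fixed effects for {conn}: need one change per post-baseline visit")


@dataclass
class CohortTable:
    """Long-format synthetic cohort: FC, growth, and outcome tables."""

    fc: pd.DataFrame         # subject, visit_age_months, connection, class, chromophore, z
    growth: pd.DataFrame     # subject, visit_label, age_days, sex, wlz, hcz (+raw measures)
    outcomes: pd.DataFrame   # subject, group, age_months, score


@dataclass
class CohortGroundTruth:
    spec: CohortSpec
    random_intercepts: pd.DataFrame      # subject x connection (per chromophore)
    fc_complete: pd.DataFrame            # pre-missingness FC table


def _connection_labels() -> list[tuple[str, str]]:
    """(label, class) for the 15 unordered section pairs. Import-cycle-free
    duplicate of connectivity.enumerate_connections kept private; the public
    enumeration lives in infantfc.connectivity."""
    from .connectivity import enumerate_connections
    return [(c.label, c.klass) for c in enumerate_connections()]


def _ar1_noise(rng: np.random.Generator, n_visits: int, rho: float, sd: float,
               size: int) -> np.ndarray:
    """(size, n_visits) stationary AR(1) rows with marginal sd."""
    e = np.empty((size, n_visits))
    e[:, 0] = rng.standard_normal(size)
    innov_sd = np.sqrt(1 - rho ** 2)
    for k in range(1, n_visits):
        e[:, k] = rho * e[:, k - 1] + innov_sd * rng.standard_normal(size)
    return sd * e


def simulate_cohort(spec: CohortSpec) -> tuple[CohortTable, CohortGroundTruth]:
    """Generate a longitudinal cohort with known ground truth. Seed-deterministic."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ages = tuple(spec.visit_ages_months)
    n_vis = len(ages)
    conns = _connection_labels()
    subjects = [f"sub-{i + 1:03d}" for i in range(spec.n_subjects)]

    # --- growth: stable between-infant level + random-walk steps ---
    gm = spec.growth_model
    g_labels = list(GROWTH_VISITS)
    w_base = gm.wlz_mean + gm.wlz_between_sd * rng.standard_normal(spec.n_subjects)
    steps = gm.wlz_step_sd * rng.standard_normal((spec.n_subjects, len(g_labels) - 1))
    wlz = np.concatenate([w_base[:, None], w_base[:, None] + np.cumsum(steps, axis=1)], axis=1)
    hcz = gm.hcz_mean + gm.hcz_sd * rng.standard_normal((spec.n_subjects, len(g_labels)))
    sex = rng.choice(["F", "M"], size=spec.n_subjects)
    growth = pd.DataFrame({
        "subject": np.repeat(subjects, len(g_labels)),
        "visit_label": np.tile(g_labels, spec.n_subjects),
        "age_days": np.tile([GROWTH_VISITS[v] for v in g_labels], spec.n_subjects),
        "sex": np.repeat(sex, len(g_labels)),
        "wlz": wlz.ravel(),
        "hcz": hcz.ravel(),
    })
    wlz_by_label = {lab: wlz[:, j] for j, lab in enumerate(g_labels)}

    # --- FC trajectories ---
    present = rng.random((spec.n_subjects, n_vis)) >= spec.missingness_probability
    rows = []
    ri_rows = []
    for chrom in spec.chromophores:
        for conn, klass in conns:
            base, deltas = spec.fixed_effects.get(
                conn, (spec.default_baseline, (0.0,) * (n_vis - 1)))
            mean = np.array([base] + [base + d for d in deltas])
            b = spec.random_intercept_sd * rng.standard_normal(spec.n_subjects)
            eps = _ar1_noise(rng, n_vis, spec.ar1_rho, spec.residual_sd, spec.n_subjects)
            z = mean[None, :] + b[:, None] + eps
            # ΔWLZ coupling acts on the final (24 mo) visit
            for (slope_conn, (v_from, v_to)), slope in gm.fc_slopes.items():
                if slope_conn == conn:
                    dwlz = wlz_by_label[v_to] - wlz_by_label[v_from]
                    z[:, -1] += slope * (dwlz - dwlz.mean())
            for i, subj in enumerate(subjects):
                ri_rows.append({"subject": subj, "connection": conn,
                                "chromophore": chrom, "b": b[i]})
                for k, age in enumerate(ages):
                    rows.append((subj, age, conn, klass, chrom, z[i, k], bool(present[i, k])))
    fc_complete = pd.DataFrame(rows, columns=[
        "subject", "visit_age_months", "connection", "class", "chromophore", "z", "present"])
    fc = fc_complete[fc_complete["present"]].drop(columns="present").reset_index(drop=True)

    # --- preschool outcomes ---
    om = spec.outcome_model
    group = np.where(rng.random(spec.n_subjects) < 0.5, "younger", "older")
    score = om.intercept + om.noise_sd * rng.standard_normal(spec.n_subjects)
    z_lookup = fc_complete[fc_complete["chromophore"] == spec.chromophores[0]]
    z_piv = z_lookup.pivot_table(index="subject", columns=["connection", "visit_age_months"],
                                 values="z")
    for (conn, fc_age, grp), slope in om.slopes.items():
        if (conn, fc_age) in z_piv.columns:
            vals = z_piv[(conn, fc_age)].reindex(subjects).to_numpy()
            sel = group == grp
            score[sel] += slope * (vals[sel] - np.nanmean(vals))
    has_score = rng.random(spec.n_subjects) < om.present_probability
    outcomes = pd.DataFrame({
        "subject": subjects, "group": group,
        "age_months": np.where(group == "younger", 48.0, 58.0),
        "score": score,
    })[has_score].reset_index(drop=True)

    table = CohortTable(fc=fc, growth=growth, outcomes=outcomes)
    truth = CohortGroundTruth(spec=spec, random_intercepts=pd.DataFrame(ri_rows),
                              fc_complete=fc_complete)
    return table, truth
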