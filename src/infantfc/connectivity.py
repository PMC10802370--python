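"""Section-level functional connectivity: averaging, FC matrices, stability.

Surviving channels are averaged into the six sections; the Pearson
correlation matrix between section chromophore series is computed over the
concatenation of valid censored chunks, Fisher-z transformed, and labelled
by connection class. A recording contributes only if it retains at least
250 s of valid data after censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ChromophoreSeries
from .probe import SectionMap, SECTIONS
from .qc import QualityReport

MIN_VALID_SECONDS = 250.0
R_CLIP = 1.0 - 1e-7

_POSITION = {"front": 0, "middle": 1, "back": 2}


class InsufficientDataError(ValueError):
    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


@dataclass(frozen=True)
class Connection:
    section_a: str
    section_b: str
    klass: str                    # interhemispheric-homotopic | intrahemispheric | crossed | self
    fronto_posterior: bool        # True for front↔back pairs (long-range)

    @property
    def label(self) -> str:
        return f"{self.section_a}|{self.section_b}"


def enumerate_connections(include_diagonal: bool = False) -> list[Connection]:
    """Labelled section pairs: 3 homotopic + 6 intrahemispheric + 6 crossed
    = 15 unordered off-diagonal pairs; ``include_diagonal`` appends the six
    self-connections for a total of 21 entries."""
    conns = []
    for i, a in enumerate(SECTIONS):
        for b in SECTIONS[i + 1:]:
            ha, pa = a.split("-")
            hb, pb = b.split("-")
            if ha == hb:
                klass = "intrahemispheric"
            elif pa == pb:
                klass = "interhemispheric-homotopic"
            else:
                klass = "crossed"
            fp = {pa, pb} == {"front", "back"}
            conns.append(Connection(a, b, klass, fp))
    if include_diagonal:
        conns += [Connection(s, s, "self", False) for s in SECTIONS]
    return conns


@dataclass
class FCMatrix:
    chromophore: str              # "HbO2" | "HHb"
    r: np.ndarray                 # 6x6, symmetric, unit diagonal
    z: np.ndarray                 # atanh of clipped r (diagonal: atanh of clip(1))
    valid_seconds: float
    connections: list[Connection] = field(default_factory=enumerate_connections)

    def z_of(self, conn: Connection) -> float:
        i, j = SECTIONS.index(conn.section_a), SECTIONS.index(conn.section_b)
        return float(self.z[i, j])

    def to_long(self) -> list[dict]:
        return [{"chromophore": self.chromophore, "section_a": c.section_a,
                 "section_b": c.section_b, "class": c.klass,
                 "fronto_posterior": c.fronto_posterior,
                 "r": float(self.r[SECTIONS.index(c.section_a), SECTIONS.index(c.section_b)]),
                 "z": self.z_of(c), "valid_seconds": self.valid_seconds}
                for c in self.connections]


def section_timeseries(hb: ChromophoreSeries, smap: SectionMap,
                       qc: QualityReport | None = None,
                       chromophore: str = "HbO2") -> tuple[np.ndarray, np.ndarray]:
    """Average surviving channels into the six sections.

    Returns (sections, mask): sections has shape (6, n_samples) with NaN
    rows for sections left without any surviving channel; mask is the
    per-sample validity carried over from censoring.
    """
    data = hb.hbo2 if chromophore == "HbO2" else hb.hhb
    excluded = qc.excluded_channels if qc is not None else set()
    ch_ok = hb.channel_valid if hb.channel_valid is not None else np.ones(data.shape[0], bool)
    out = np.full((len(SECTIONS), data.shape[1]), np.nan)
    for si, sec in enumerate(SECTIONS):
        chans = [c for c in smap.channels_in_section(sec)
                 if c not in excluded and ch_ok[c - 1]]
        if chans:
            out[si] = data[[c - 1 for c in chans]].mean(axis=0)
    return out, hb.mask.copy()


def section_fc(sections: np.ndarray, mask: np.ndarray, fs: float,
               chromophore: str = "HbO2",
               min_valid_s: float = MIN_VALID_SECONDS,
               include_diagonal: bool = False) -> FCMatrix:
    """Pearson/Fisher-z FC over the concatenated valid samples.

    Raises :class:`InsufficientDataError` (reason ``min-valid-seconds``)
    below the minimum-data rule. Section pairs involving a missing section
    propagate as NaN entries.
    """
    valid_seconds = float(mask.sum()) / fs
    if valid_seconds < min_valid_s:
        raise InsufficientDataError(
            "min-valid-seconds",
            f"only {valid_seconds:.1f} s valid data (< {min_valid_s:g} s)")
    x = sections[:, mask]
    r = np.full((6, 6), np.nan)
    ok = ~np.isnan(x).any(axis=1)
    if ok.any():
        r_ok = np.corrcoef(x[ok])
        idx = np.flatnonzero(ok)
        r[np.ix_(idx, idx)] = r_ok
    np.fill_diagonal(r, np.where(ok, 1.0, np.nan))
    with np.errstate(invalid="ignore"):
        z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return FCMatrix(chromophore=chromophore, r=r, z=z, valid_seconds=valid_seconds,
                    connections=enumerate_connections(include_diagonal))


def _upper(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(6, 1)]


def stability_curve(sections: np.ndarray, mask: np.ndarray, fs: float,
                    k_grid: tuple[float, ...] = (60, 100, 120, 150, 200, 250)) -> list[tuple[float, float]]:
    """Split-half FC stability: for each k seconds, the correlation between
    the vectorized upper triangles of FC computed on the first k and the
    last k valid seconds. Entries with 2·k exceeding the valid duration are
    omitted."""
    valid_idx = np.flatnonzero(mask)
    out = []
    for k in k_grid:
        nk = int(round(k * fs))
        if 2 * nk > len(valid_idx):
            continue
        first = sections[:, valid_idx[:nk]]
        last = sections[:, valid_idx[-nk:]]
        f1 = _upper(np.corrcoef(first))
        f2 = _upper(np.corrcoef(last))
        ok = np.isfinite(f1) & np.isfinite(f2)
        if ok.sum() < 3:
            continue
        out.append((float(k), float(np.corrcoef(f1[ok], f2[ok])[0, 1])))
    return out
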