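"""LMS growth z-scores (weight-for-length, head-circumference-for-age) and ΔWLZ.

The LMS transformation maps a measurement x against reference skewness (L),
median (M) and coefficient of variation (S):

    z = ((x/M)^L − 1) / (L·S)   for L ≠ 0,   z = ln(x/M)/S   for L = 0,

continuous in L. Reference tables are CSVs of (measure, sex, key, L, M, S)
with linear interpolation between keys; the packaged table is a synthetic
stand-in with smooth plausible curves so everything runs offline — real WHO
tables can be supplied through the same schema.

ΔWLZ between two visits is WLZ(later) − WLZ(earlier): positive values mean
relative growth gain over the interval.
"""

from __future__ import annotations

import io
import itertools
from importlib import resources

import numpy as np
import pandas as pd

DELTA_VISITS = ("birth", "1mo", "5mo", "8mo", "12mo", "18mo", "24mo")

MEASURES = ("weight-for-length", "head-circumference-for-age")


def lms_zscore(x: float | np.ndarray, L: float | np.ndarray,
               M: float | np.ndarray, S: float | np.ndarray) -> float | np.ndarray:
    """LMS z-score; strictly increasing in x and zero at the median."""
    x, L, M, S = (np.asarray(v, dtype=float) for v in (x, L, M, S))
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S must be positive")
    if np.any(x <= 0):
        raise ValueError("measurement must be positive")
    ratio = x / M
    # |L| below ~1e-4 is numerically the log form (difference O(L·ln²r))
    small = np.abs(L) < 1e-4
    Lsafe = np.where(small, 1.0, L)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(small,
                     np.log(ratio) / S,
                     np.expm1(Lsafe * np.log(ratio)) / (Lsafe * S))
    return z if z.ndim else float(z)


def lms_inverse(z: float | np.ndarray, L: float | np.ndarray,
                M: float | np.ndarray, S: float | np.ndarray) -> float | np.ndarray:
    """Measurement at a given z (inverse of :func:`lms_zscore`)."""
    z, L, M, S = (np.asarray(v, dtype=float) for v in (z, L, M, S))
    small = np.abs(L) < 1e-4
    Lsafe = np.where(small, 1.0, L)
    x = np.where(small,
                 M * np.exp(S * z),
                 M * np.power(np.maximum(1 + Lsafe * S * z, 1e-12), 1 / Lsafe))
    return x if x.ndim else float(x)


class LmsTable:
    """Reference table with linear interpolation per (measure, sex)."""

    def __init__(self, table: pd.DataFrame):
        required = {"measure", "sex", "key", "L", "M", "S"}
        if not required.issubset(table.columns):
            raise ValueError(f"LMS table needs columns {sorted(required)}")
        if (table["M"] <= 0).any() or (table["S"] <= 0).any():
            raise ValueError("M and S must be positive")
        self._groups = {}
        for (measure, sex), g in table.groupby(["measure", "sex"]):
            g = g.sort_values("key")
            if g["key"].duplicated().any():
                raise ValueError(f"duplicate keys for ({measure}, {sex})")
            self._groups[(measure, sex)] = g[["key", "L", "M", "S"]].to_numpy()

    @classmethod
    def from_csv(cls, path_or_buf) -> "LmsTable":
        return cls(pd.read_csv(path_or_buf, comment="#"))

    @classmethod
    def synthetic_fixture(cls) -> "LmsTable":
        """The packaged synthetic reference table."""
        text = resources.files("infantfc.data").joinpath("lms_synthetic.csv").read_text()
        return cls.from_csv(io.StringIO(text))

    def lms_at(self, measure: str, sex: str, key: float) -> tuple[float, float, float]:
        arr = self._groups.get((measure, sex))
        if arr is None:
            raise KeyError(f"no LMS rows for ({measure}, {sex})")
        k = arr[:, 0]
        if not k[0] <= key <= k[-1]:
            raise ValueError(f"key {key} outside table range [{k[0]}, {k[-1]}]")
        return tuple(np.interp(key, k, arr[:, j]) for j in (1, 2, 3))

    def zscore(self, measure: str, sex: str, key: float, x: float) -> float:
        L, M, S = self.lms_at(measure, sex, key)
        return float(lms_zscore(x, L, M, S))

    def inverse(self, measure: str, sex: str, key: float, z: float) -> float:
        L, M, S = self.lms_at(measure, sex, key)
        return float(lms_inverse(z, L, M, S))


def attach_zscores(records: pd.DataFrame, table: LmsTable) -> pd.DataFrame:
    """Append/refresh ``wlz`` and ``hcz`` columns computed from raw measures.

    Expects columns subject, visit_label, age_days, sex, weight_kg,
    length_cm, hc_cm (raw values may be NaN → z is NaN).
    """
    out = records.copy()
    wlz, hcz = [], []
    for row in out.itertuples():
        try:
            wlz.append(table.zscore("weight-for-length", row.sex, row.length_cm, row.weight_kg))
        except (ValueError, TypeError):
            wlz.append(np.nan)
        try:
            hcz.append(table.zscore("head-circumference-for-age", row.sex, row.age_days, row.hc_cm))
        except (ValueError, TypeError):
            hcz.append(np.nan)
    out["wlz"] = wlz
    out["hcz"] = hcz
    return out


def delta_wlz(growth: pd.DataFrame, from_visit: str, to_visit: str) -> pd.Series:
    """Per-subject ΔWLZ = WLZ(to_visit) − WLZ(from_visit).

    Subjects missing either visit get NaN (dropped from that interval's
    regression downstream). Antisymmetric under interval reversal.
    """
    piv = growth.pivot_table(index="subject", columns="visit_label", values="wlz")
    for v in (from_visit, to_visit):
        if v not in piv.columns:
            piv[v] = np.nan
    return (piv[to_visit] - piv[from_visit]).rename(f"dwlz_{from_visit}_{to_visit}")


def enumerate_intervals(visits: tuple[str, ...] = DELTA_VISITS) -> list[tuple[str, str]]:
    """All (earlier, later) visit pairs — 21 for the canonical 7 visits."""
    return list(itertools.combinations(visits, 2))
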