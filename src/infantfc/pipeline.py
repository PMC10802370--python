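"""Run configuration, per-subject pipeline, and cohort-level orchestration.

Stage order (fixed): channel pruning → OD conversion → 0.009–3 Hz band-pass
→ global signal regression → 0.009–0.08 Hz band-pass → GVTD censoring
(±5 s padding, ≥20 s chunks) → modified Beer–Lambert conversion → section
averaging → FC. A recording is excluded when more than 40% of channels fail
QC ("channel-fraction") or when fewer than 250 s of valid data survive
censoring ("min-valid-seconds").

Every report embeds provenance: a config hash, the package version, and
per-stage exclusion counts. Given a config and seed, reruns are
deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (FCMatrix, InsufficientDataError, enumerate_connections,
                           section_fc, section_timeseries)
from .growth import enumerate_intervals
from .preprocess import (ChromophoreSeries, GvtdTrace, bandpass, compute_gvtd,
                         global_signal_regression, intensity_to_od, mask_and_segment,
                         od_to_hb)
from .probe import PlacementInfo, load_probe_fixture, renumber_for_displacement
from .qc import QCParams, QualityReport, channel_quality
from .simulate import CohortTable, RawRecording
from .stats import (LmmResult, RegressionResult, bonferroni_threshold, fdr_bh,
                    fc_outcome_regression, fit_fc_age_lmm, growth_fc_regression)


@dataclass
class RunConfig:
    """All stage parameters; defaults are the pipeline's reference values."""

    # quality control
    qc_window_s: float = 3.0
    sci_threshold: float = 0.70
    psp_threshold: float = 0.1
    fail_fraction: float = 0.70
    recording_exclusion_fraction: float = 0.40
    # preprocessing
    band_wide_hz: tuple[float, float] = (0.009, 3.0)
    band_narrow_hz: tuple[float, float] = (0.009, 0.08)
    enable_gsr: bool = True
    enable_filters: bool = True
    gvtd_multiplier: float = 5.0
    pad_s: float = 5.0
    min_chunk_s: float = 20.0
    # connectivity
    min_valid_s: float = 250.0
    include_diagonal: bool = False
    # statistics
    alpha: float = 0.05
    bonferroni_m: int | None = None      # None → number of connections analysed
    fdr_q: float = 0.05
    min_visits: int = 2
    # reproducibility
    seed: int = 0

    def qc_params(self) -> QCParams:
        return QCParams(window_s=self.qc_window_s, sci_threshold=self.sci_threshold,
                        psp_threshold=self.psp_threshold, fail_fraction=self.fail_fraction,
                        recording_exclusion_fraction=self.recording_exclusion_fraction)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("band_wide_hz", "band_narrow_hz"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def provenance(self, **extra) -> dict:
        return {"config_hash": self.config_hash(), "package_version": __version__,
                "config": self.to_dict(), **extra}


@dataclass
class SubjectResult:
    subject: str
    visit_age_months: float
    included: bool
    exclusion_reason: str | None
    qc: QualityReport | None
    fc: dict[str, FCMatrix] = field(default_factory=dict)
    gvtd: GvtdTrace | None = None
    valid_seconds: float = 0.0
    stage_counts: dict = field(default_factory=dict)


def preprocess_recording(rec: RawRecording, probe, smap, config: RunConfig,
                         qc: QualityReport) -> tuple[ChromophoreSeries, GvtdTrace]:
    """OD → filters → GSR → filters → GVTD censoring → MBLL."""
    od = intensity_to_od(rec.intensity, rec.fs, rec.wavelengths_nm)
    for c in qc.excluded_channels:
        od.channel_valid[c - 1] = False
    if config.enable_filters:
        od.data[od.channel_valid] = bandpass(od.data[od.channel_valid], rec.fs,
                                             *config.band_wide_hz)
    if config.enable_gsr:
        od = global_signal_regression(od)
    if config.enable_filters:
        od.data[od.channel_valid] = bandpass(od.data[od.channel_valid], rec.fs,
                                             *config.band_narrow_hz)
    stacked = od.data[od.channel_valid].reshape(-1, od.n_samples)
    trace = compute_gvtd(stacked, multiplier=config.gvtd_multiplier)
    mask, chunks = mask_and_segment(trace, rec.fs, config.pad_s, config.min_chunk_s)
    hb = od_to_hb(od, probe, rec.visit_age_months / 12.0)
    hb.mask = mask
    hb.chunks = chunks
    return hb, trace


def run_subject(rec: RawRecording, config: RunConfig | None = None,
                probe=None, smap=None,
                placement: PlacementInfo | None = None) -> SubjectResult:
    """Full per-recording pipeline: QC → preprocessing → section FC."""
    config = config or RunConfig()
    if probe is None or smap is None:
        probe, smap = load_probe_fixture(rec.probe_name)
    if placement is not None:
        if placement.excluded:
            return SubjectResult(rec.subject, rec.visit_age_months, False,
                                 "frontal-placement", None)
        smap = renumber_for_displacement(smap, placement)

    qc = channel_quality(rec.intensity, rec.fs, config.qc_params())
    counts = {"n_channels": probe.n_channels,
              "n_channels_excluded": len(qc.excluded_channels)}
    if qc.recording_excluded:
        return SubjectResult(rec.subject, rec.visit_age_months, False,
                             "channel-fraction", qc, stage_counts=counts)

    hb, trace = preprocess_recording(rec, probe, smap, config, qc)
    counts["n_artifact_samples"] = int(trace.artifact.sum())
    counts["n_chunks"] = len(hb.chunks)
    result = SubjectResult(rec.subject, rec.visit_age_months, True, None, qc,
                           gvtd=trace, valid_seconds=hb.valid_seconds,
                           stage_counts=counts)
    for chrom in ("HbO2", "HHb"):
        sections, mask = section_timeseries(hb, smap, qc, chrom)
        try:
            result.fc[chrom] = section_fc(sections, mask, rec.fs, chrom,
                                          config.min_valid_s, config.include_diagonal)
        except InsufficientDataError as err:
            result.included = False
            result.exclusion_reason = err.reason
            result.fc = {}
            break
    return result


def fc_table_from_results(results: list[SubjectResult]) -> pd.DataFrame:
    """Long FC table (subject, visit, connection, class, chromophore, r, z,
    valid_seconds) from included subject results."""
    rows = []
    for res in results:
        if not res.included:
            continue
        for chrom, fc in res.fc.items():
            for rec in fc.to_long():
                rows.append({"subject": res.subject,
                             "visit_age_months": res.visit_age_months,
                             "connection": f"{rec['section_a']}|{rec['section_b']}",
                             "class": rec["class"], "chromophore": chrom,
                             "r": rec["r"], "z": rec["z"],
                             "valid_seconds": rec["valid_seconds"]})
    return pd.DataFrame(rows)


@dataclass
class CohortReports:
    lmm: pd.DataFrame                  # Table-1-style: one row per connection x chromophore
    growth_regressions: pd.DataFrame   # Table-2-style: connection x interval grid
    outcome_regressions: pd.DataFrame
    significant_connections: list[str]
    provenance: dict

    def write(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.lmm.to_csv(out / "fc_age_lmm.csv", index=False)
        self.growth_regressions.to_csv(out / "growth_fc_regressions.csv", index=False)
        self.outcome_regressions.to_csv(out / "fc_outcome_regressions.csv", index=False)
        with open(out / "provenance.json", "w") as f:
            json.dump({**self.provenance,
                       "significant_connections": self.significant_connections},
                      f, indent=2, default=str)


def run_cohort(cohort: CohortTable, config: RunConfig | None = None) -> CohortReports:
    """The three cohort analyses: FC-vs-age mixed models (Bonferroni), ΔWLZ →
    FC(24 mo) regressions (BH-FDR per connection), and FC → preschool
    cognitive-flexibility regressions, gated on connections whose FC changed
    significantly with age."""
    config = config or RunConfig()
    fc, growth, outcomes = cohort.fc, cohort.growth, cohort.outcomes
    conns = [c.label for c in enumerate_connections(config.include_diagonal)
             if c.klass != "self"]
    chroms = sorted(fc["chromophore"].unique())
    m = config.bonferroni_m or len(conns)
    thresh = bonferroni_threshold(config.alpha, m)

    lmm_rows, fits = [], {}
    for chrom in chroms:
        for conn in conns:
            try:
                res = fit_fc_age_lmm(fc, conn, chrom, min_visits=config.min_visits)
            except ValueError:
                continue
            fits[(conn, chrom)] = res
            row = res.to_row()
            row["bonferroni_threshold"] = thresh
            row["significant"] = res.p_value < thresh
            lmm_rows.append(row)
    lmm_df = pd.DataFrame(lmm_rows)

    primary = chroms[0] if "HbO2" not in chroms else "HbO2"
    significant = [c for c in conns
                   if (c, primary) in fits and fits[(c, primary)].p_value < thresh]

    growth_rows = []
    for conn in significant:
        for covariate in ("none", "WLZ_birth", "HCZ_7_14d"):
            block = []
            for interval in enumerate_intervals():
                try:
                    r = growth_fc_regression(fc, growth, conn, interval,
                                             covariate=covariate, chromophore=primary)
                except ValueError:
                    continue
                block.append((interval, r))
            if not block:
                continue
            _, p_adj = fdr_bh([r.p_value for _, r in block], config.fdr_q)
            for (interval, r), pa in zip(block, p_adj):
                growth_rows.append({
                    "connection": conn, "interval_from": interval[0],
                    "interval_to": interval[1], "covariate": covariate,
                    "F": r.f_stat, "df1": r.df[0], "df2": r.df[1], "p": r.p_value,
                    "p_fdr": pa, "R2": r.r_squared, "slope": r.slope, "n": r.n,
                    "significant_fdr": pa < config.fdr_q})
    growth_df = pd.DataFrame(growth_rows)

    outcome_rows = []
    fc_ages = sorted(fc["visit_age_months"].unique())
    groups = sorted(outcomes["group"].unique()) if len(outcomes) else []
    for conn in significant:
        block = []
        for age in fc_ages:
            for grp in groups:
                try:
                    r = fc_outcome_regression(fc, outcomes, conn, age, grp,
                                              chromophore=primary)
                except ValueError:
                    continue
                block.append((age, grp, r))
        if not block:
            continue
        _, p_adj = fdr_bh([r.p_value for *_, r in block], config.fdr_q)
        for (age, grp, r), pa in zip(block, p_adj):
            outcome_rows.append({
                "connection": conn, "fc_age_months": age, "group": grp,
                "F": r.f_stat, "df1": r.df[0], "df2": r.df[1], "p": r.p_value,
                "p_fdr": pa, "R2": r.r_squared, "slope": r.slope, "n": r.n,
                "significant_fdr": pa < config.fdr_q})
    outcome_df = pd.DataFrame(outcome_rows)

    prov = config.provenance(
        n_subjects=int(fc["subject"].nunique()),
        n_connections=len(conns), bonferroni_m=m,
        bonferroni_threshold=thresh)
    return CohortReports(lmm=lmm_df, growth_regressions=growth_df,
                         outcome_regressions=outcome_df,
                         significant_connections=significant, provenance=prov)
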