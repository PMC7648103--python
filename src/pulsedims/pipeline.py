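"""End-to-end pipeline driver: pulse processing -> table -> filters -> stats.

One ``StudyConfig`` carries every threshold (all defaults mirror the printed
processing protocol: instrument abundance threshold, 3x blank rule, 80%
prevalence, 80% QC missingness, 20% sample missingness, half-min imputation,
30% QC-RSD ceiling, volcano p < 0.05 with FC > 2 or < 0.5, VIP > 1.8) plus
the seeds, so a pipeline run is reproducible from its manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import features as ft
from . import stats as st
from .design import StudyDesign, make_run_order
from .pulses import (
    ScanSpectrum,
    RepresentativeSpectrum,
    compute_tic,
    extract_eic,
    detect_pulses,
    pulse_area,
    integrate_over_pulses,
    reject_outlier_pulses,
    select_pulses,
    representative_spectrum,
)

logger = logging.getLogger("pulsedims")

__all__ = [
    "INSTRUMENT_PROFILES",
    "StudyConfig",
    "PulseQcReport",
    "process_run",
    "build_table",
    "apply_filter_cascade",
    "StatsResult",
    "run_statistics",
    "StudyResult",
    "analyze_study",
    "run_pipeline",
    "load_config",
]

#: Printed acquisition profiles of the two instruments used for pulsed DI-MS.
INSTRUMENT_PROFILES = {
    "synapt": {"threshold": 2e3, "mz_range": (50.0, 750.0), "polarity": "-", "k_pulses": 5},
    "orbitrap": {"threshold": 1.5e4, "mz_range": (67.0, 1000.0), "polarity": "+", "k_pulses": 3},
}


@dataclass
class StudyConfig:
    """All pipeline parameters; defaults mirror the published protocol."""

    instrument: str = "synapt"
    is_mz: float = 183.0879
    k_pulses: int | None = None  # None -> instrument profile default
    instrument_threshold: float | None = None
    min_pulse_scans: int = 3
    pulse_min_height_frac: float = 0.05  # of the TIC maximum
    eic_tol_ppm: float = 10.0
    align_tol_ppm: float = 10.0
    blank_factor: float = 3.0
    blank_per_sample: bool = False
    prevalence_min_fraction: float = 0.8
    qc_max_missing: float = 0.8
    sample_max_missing: float = 0.2
    rsd_qc_max: float = 0.30
    glog_lambda: float | str = "auto"
    p_cut: float = 0.05
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    n_pls_components: int = 2
    vip_cut: float = 1.8
    n_ortho: int = 1
    #: (reference, challenged) group labels; fold change = second/first.
    #: None falls back to order of first appearance in the metadata.
    group_labels: tuple[str, str] | None = None
    seed: int = 7

    def __post_init__(self) -> None:
        if self.instrument not in INSTRUMENT_PROFILES:
            raise ValueError(f"unknown instrument profile {self.instrument!r}")
        prof = INSTRUMENT_PROFILES[self.instrument]
        if self.k_pulses is None:
            self.k_pulses = prof["k_pulses"]
        if self.instrument_threshold is None:
            self.instrument_threshold = prof["threshold"]


def load_config(path) -> StudyConfig:
    """Load a StudyConfig from a YAML file (unknown keys rejected)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    allowed = set(StudyConfig.__dataclass_fields__)
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "k_pulses" in doc and doc["k_pulses"] is not None:
        doc["k_pulses"] = int(doc["k_pulses"])
    if doc.get("group_labels") is not None:
        doc["group_labels"] = tuple(doc["group_labels"])
    return StudyConfig(**doc)


@dataclass
class PulseQcReport:
    """Pulse bookkeeping for one run."""

    run_id: str
    n_detected: int
    n_kept: int
    n_rejected: int
    n_selected: int
    seed: int
    failed: bool = False
    reason: str = ""


def process_run(
    run: Sequence[ScanSpectrum],
    config: StudyConfig,
    seed: int,
    run_id: str = "",
) -> tuple[RepresentativeSpectrum | None, PulseQcReport]:
    """Scan list -> representative spectrum for one acquisition.

    Detects pulses on the TIC (threshold = ``pulse_min_height_frac`` of the
    TIC maximum), measures the internal-standard EIC area inside each pulse,
    rejects pulses outside the +/-20%-of-median IS window, randomly selects
    ``k_pulses`` survivors with the given seed, and averages their scans.
    Returns (None, report) with ``failed=True`` when fewer than ``k_pulses``
    pulses survive QC — the replicate is discarded, not padded.
    """
    tic = compute_tic(run)
    min_height = config.pulse_min_height_frac * float(tic.intensities.max())
    if min_height <= 0:
        return None, PulseQcReport(run_id, 0, 0, 0, 0, seed, True, "empty TIC")
    pulses = detect_pulses(tic, min_height, config.min_pulse_scans)
    if not pulses:
        return None, PulseQcReport(run_id, 0, 0, 0, 0, seed, True, "no pulses detected")
    eic = extract_eic(run, config.is_mz, config.eic_tol_ppm)
    is_areas = integrate_over_pulses(eic, pulses)
    kept, rejected = reject_outlier_pulses(pulses, is_areas)
    try:
        selected = select_pulses(kept, config.k_pulses, seed)
    except ValueError as exc:
        return None, PulseQcReport(
            run_id, len(pulses), len(kept), len(rejected), 0, seed, True, str(exc)
        )
    spec = representative_spectrum(
        run,
        selected,
        mz_bin_ppm=config.align_tol_ppm,
        instrument_threshold=config.instrument_threshold,
        sample_id=run_id,
    )
    report = PulseQcReport(
        run_id, len(pulses), len(kept), len(rejected), len(selected), seed
    )
    return spec, report


def build_table(
    runs: dict[str, Sequence[ScanSpectrum]],
    meta: pd.DataFrame,
    config: StudyConfig,
) -> tuple[ft.FeatureTable, list[PulseQcReport]]:
    """Process every run and align the representative spectra into a table.

    Per-run pulse-selection seeds are spawned deterministically from
    ``config.seed`` in metadata order.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(meta))
    spectra, reports, kept_ids = [], [], []
    for run_id, child in zip(meta.index, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        spec, rep = process_run(runs[run_id], config, sub_seed, run_id)
        reports.append(rep)
        if spec is None:
            logger.warning("run %s failed pulse QC: %s", run_id, rep.reason)
            continue
        spectra.append(spec)
        kept_ids.append(run_id)
    if not spectra:
        raise ValueError("all runs failed pulse QC")
    table = ft.align_features(spectra, meta.loc[kept_ids], tol_ppm=config.align_tol_ppm)
    return table, reports


def apply_filter_cascade(table: ft.FeatureTable, config: StudyConfig) -> ft.FeatureTable:
    """The canonical filter order: normalize -> blank -> prevalence -> QC ->
    sample outlier -> QC-RSD -> impute.

    The four quality filters (blank, prevalence, QC-missingness/sample-outlier,
    QC-RSD) are interchangeable because each uses missing-aware statistics; in
    particular the QC RSD is computed over *observed* QC values, so imputation
    runs last (imputing first would hand every QC-missing feature an
    artificial near-zero replicate and inflate its RSD).  Abundance
    thresholding already happened per spectrum."""
    t = ft.normalize_to_is(table, config.is_mz, config.eic_tol_ppm)
    t = ft.blank_filter(t, config.blank_factor, config.blank_per_sample)
    t = ft.prevalence_filter(t, config.prevalence_min_fraction)
    t = ft.qc_feature_filter(t, config.qc_max_missing)
    t = ft.sample_outlier_filter(t, config.sample_max_missing)
    t = ft.rsd_qc_filter(t, config.rsd_qc_max)
    t = ft.impute_half_min(t)
    return t


@dataclass
class StatsResult:
    """Everything the statistical stage computes."""

    volcano: st.VolcanoResult
    vip: pd.Series
    selected_features: list
    pls: st.PlsModel
    opls: st.OplsModel | None
    cv: st.CvResult | None
    transformed: st.TransformedMatrix
    median_rsd_qc: float


def run_statistics(table: ft.FeatureTable, config: StudyConfig) -> StatsResult:
    """Volcano + PLS-DA VIP selection and O-PLS-DA LOO-CV on a filtered table."""
    groups = list(config.group_labels) if config.group_labels else table.groups()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups}")
    present = set(table.meta.loc[table.sample_ids, "group"])
    if set(groups) != present:
        raise ValueError(f"configured groups {groups} do not match table groups {sorted(present)}")
    bio = table.sample_ids
    raw = table.data.loc[bio]
    y = table.meta.loc[bio, "group"]
    g1 = bio[y == groups[0]]
    g2 = bio[y == groups[1]]
    med_rsd = ft.median_rsd_qc(table)
    glog = st.glog_transform(raw, config.glog_lambda)
    scaled = st.autoscale(glog)
    volc = st.volcano(raw, scaled, g1, g2, config.p_cut, config.fc_hi, config.fc_lo)
    pls = st.plsda_fit(scaled.values, y, config.n_pls_components, classes=tuple(groups))
    vip = st.vip_scores(pls)
    selected = st.select_significant(volc.passing, vip, config.vip_cut)
    opls = cv = None
    if selected:
        Xsel_glog = glog.values[selected]
        Xsel_scaled = scaled.values[selected]
        opls = st.oplsda_fit(Xsel_scaled, y, config.n_ortho, classes=tuple(groups))
        cv = st.loo_cv(
            Xsel_glog,
            y,
            fit=lambda Xt, yt: st.oplsda_fit(Xt, yt, config.n_ortho, classes=tuple(groups)),
            positive_class=groups[1],
        )
    return StatsResult(volc, vip, selected, pls, opls, cv, scaled, med_rsd)


@dataclass
class StudyResult:
    """Pipeline output bundle: table stages, statistics, and the manifest."""

    table_raw: ft.FeatureTable
    table_filtered: ft.FeatureTable
    stats: StatsResult
    pulse_reports: list[PulseQcReport]
    manifest: dict


def _feature_counts(table: ft.FeatureTable) -> list[dict]:
    counts = []
    for entry in table.log:
        rec = {"op": entry["op"]}
        if "removed" in entry:
            rec["n_removed"] = len(entry["removed"])
        if "n_features" in entry:
            rec["n_features"] = entry["n_features"]
        counts.append(rec)
    return counts


def analyze_study(
    runs: dict[str, Sequence[ScanSpectrum]],
    meta: pd.DataFrame,
    config: StudyConfig,
) -> StudyResult:
    """Full pipeline on in-memory runs: process -> tabulate -> filter -> stats."""
    table_raw, reports = build_table(runs, meta, config)
    table = apply_filter_cascade(table_raw, config)
    stats_res = run_statistics(table, config)
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "n_runs": len(meta),
        "pulse_qc": [asdict(r) for r in reports],
        "feature_counts": _feature_counts(table),
        "n_features_final": int(table.data.shape[1]),
        "n_samples_final": int(len(table.sample_ids)),
        "selected_features": [float(f) for f in stats_res.selected_features],
        "median_rsd_qc": stats_res.median_rsd_qc,
        "loo_accuracy": stats_res.cv.accuracy if stats_res.cv else None,
    }
    return StudyResult(table_raw, table, stats_res, reports, manifest)


def run_pipeline(
    run_dir,
    metadata_csv,
    config: StudyConfig,
    out_dir,
) -> StudyResult:
    """Disk-based driver: read native scan-JSON runs and a metadata CSV,
    execute the full pipeline, and write tables, results and the manifest."""
    from . import io as pio

    run_dir, out_dir = Path(run_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(metadata_csv, index_col="run_id")
    if "blank" not in set(meta["role"]) and config.blank_factor > 0:
        raise ValueError("blank filtering enabled but no blank run in metadata")
    runs = {}
    for run_id in meta.index:
        path = run_dir / f"{run_id}.json"
        if not path.exists():
            raise FileNotFoundError(f"missing run file: {path}")
        runs[run_id] = pio.read_run(path)
    result = analyze_study(runs, meta, config)
    pio.write_table(result.table_filtered, out_dir / "table.csv", out_dir / "table_provenance.json")
    result.stats.volcano.table.to_csv(out_dir / "volcano.csv", index_label="feature_mz")
    result.stats.vip.to_csv(out_dir / "vip.csv", index_label="feature_mz")
    pd.Series(result.stats.selected_features, name="feature_mz").to_csv(
        out_dir / "selected_features.csv", index=False
    )
    if result.stats.cv is not None:
        with open(out_dir / "cv.json", "w") as fh:
            json.dump(
                {
                    "sensitivity": result.stats.cv.sensitivity,
                    "specificity": result.stats.cv.specificity,
                    "accuracy": result.stats.cv.accuracy,
                    "confusion": result.stats.cv.confusion,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
    return result
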