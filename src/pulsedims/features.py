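"""Feature-table assembly and the quality-filter cascade.

Representative spectra from all runs are aligned into a samples x features
matrix (missing = NaN) and pushed through the standard direct-infusion QC
cascade: internal-standard normalization, blank filtering (3x rule),
prevalence filtering (>=80% of biological samples), QC-missingness filtering,
sample-outlier removal (>20% missing), half-minimum imputation, and removal
of features whose relative standard deviation across pooled-QC runs exceeds
30%.  Every operation appends a provenance record so the applied cascade is
fully reconstructible.

Boundary semantics follow the written rules literally: "at least 80%
prevalence" is inclusive, "more than 20% missing" and "RSD > 30%" are strict.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .pulses import RepresentativeSpectrum

__all__ = [
    "FeatureTable",
    "align_features",
    "normalize_to_is",
    "blank_filter",
    "prevalence_filter",
    "qc_feature_filter",
    "sample_outlier_filter",
    "impute_half_min",
    "rsd_qc_filter",
    "qc_rsd",
    "median_rsd_qc",
    "filter_order_report",
]


@dataclass
class FeatureTable:
    """Samples x features abundance matrix with roles and provenance.

    ``data``: DataFrame, index = run/sample ids, columns = feature m/z
    (floats, strictly increasing), NaN marks a missing value.
    ``meta``: DataFrame indexed like ``data`` with columns ``role``
    ("sample" | "QC" | "blank") and ``group``.
    ``log``: append-only list of applied-operation records.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.meta.index):
            raise ValueError("data and meta must share the same sample index")
        cols = np.asarray(self.data.columns, dtype=float)
        if cols.size > 1 and not np.all(np.diff(cols) > 0):
            raise ValueError("feature m/z columns must be strictly increasing")

    # -- convenience selectors -------------------------------------------------
    def ids(self, role: str) -> pd.Index:
        return self.meta.index[self.meta["role"] == role]

    @property
    def sample_ids(self) -> pd.Index:
        return self.ids("sample")

    @property
    def qc_ids(self) -> pd.Index:
        return self.ids("QC")

    @property
    def blank_ids(self) -> pd.Index:
        return self.ids("blank")

    @property
    def feature_mzs(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)

    def groups(self) -> list[str]:
        g = self.meta.loc[self.sample_ids, "group"].dropna().unique().tolist()
        return g

    def _evolve(self, data: pd.DataFrame, meta: pd.DataFrame, entry: dict) -> "FeatureTable":
        return FeatureTable(data=data, meta=meta, log=self.log + [entry])

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())


def align_features(
    spectra: Sequence[RepresentativeSpectrum],
    meta: pd.DataFrame,
    tol_ppm: float = 10.0,
) -> FeatureTable:
    """Single-linkage m/z clustering of peaks across representative spectra.

    Peaks from all samples are pooled, sorted, and split wherever the gap to
    the next peak exceeds the ppm tolerance; each cluster becomes one feature
    whose m/z is the intensity-weighted mean.  A sample contributing several
    peaks to one cluster has them summed; a sample contributing none is
    missing (NaN) for that feature.
    """
    if len(spectra) == 0:
        raise ValueError("no spectra to align")
    ids = [s.sample_id for s in spectra]
    if sorted(ids) != sorted(meta.index.tolist()):
        raise ValueError("spectrum sample ids must match metadata index")
    mz = np.concatenate([s.mz for s in spectra])
    inten = np.concatenate([s.intensity for s in spectra])
    samp = np.concatenate(
        [np.full(s.mz.size, i, dtype=int) for i, s in enumerate(spectra)]
    )
    if mz.size == 0:
        data = pd.DataFrame(index=pd.Index(ids, name="run_id"))
        return FeatureTable(data, meta.loc[ids], [{"op": "align", "tol_ppm": tol_ppm, "n_features": 0}])
    order = np.argsort(mz, kind="stable")
    mz, inten, samp = mz[order], inten[order], samp[order]
    gaps = np.diff(mz) > mz[:-1] * tol_ppm * 1e-6
    labels = np.concatenate([[0], np.cumsum(gaps)])
    n_feat = int(labels[-1]) + 1
    sums = np.bincount(labels, weights=inten, minlength=n_feat)
    wmz = np.bincount(labels, weights=inten * mz, minlength=n_feat)
    counts = np.bincount(labels, minlength=n_feat)
    feat_mz = np.where(sums > 0, wmz / np.where(sums > 0, sums, 1.0),
                       np.bincount(labels, weights=mz, minlength=n_feat) / counts)
    values = np.full((len(spectra), n_feat), np.nan)
    flat = samp * n_feat + labels
    accum = np.bincount(flat, weights=inten, minlength=len(spectra) * n_feat)
    present = np.bincount(flat, minlength=len(spectra) * n_feat) > 0
    accum = accum.reshape(len(spectra), n_feat)
    present = present.reshape(len(spectra), n_feat)
    values[present] = accum[present]
    col_order = np.argsort(feat_mz)
    data = pd.DataFrame(
        values[:, col_order], index=pd.Index(ids, name="run_id"), columns=feat_mz[col_order]
    )
    entry = {"op": "align", "tol_ppm": tol_ppm, "n_features": n_feat}
    return FeatureTable(data, meta.loc[ids].copy(), [entry])


def _find_feature(table: FeatureTable, target_mz: float, tol_ppm: float) -> float:
    mzs = table.feature_mzs
    if mzs.size == 0:
        raise ValueError("table has no features")
    i = int(np.argmin(np.abs(mzs - target_mz)))
    if abs(mzs[i] - target_mz) > target_mz * tol_ppm * 1e-6:
        raise ValueError(f"no feature within {tol_ppm} ppm of m/z {target_mz}")
    return float(table.data.columns[i])


def normalize_to_is(
    table: FeatureTable, is_mz: float, tol_ppm: float = 10.0
) -> FeatureTable:
    """Divide each run's abundances by its internal-standard value, drop the IS.

    Raises if the IS feature is missing in any run (a failed replicate).
    """
    col = _find_feature(table, is_mz, tol_ppm)
    is_values = table.data[col]
    if is_values.isna().any() or (is_values <= 0).any():
        bad = table.data.index[is_values.isna() | (is_values <= 0)].tolist()
        raise ValueError(f"internal standard missing or non-positive in runs: {bad}")
    data = table.data.div(is_values, axis=0).drop(columns=[col])
    entry = {"op": "normalize_to_is", "is_mz": is_mz, "is_feature": col}
    return table._evolve(data, table.meta, entry)


def blank_filter(
    table: FeatureTable, factor: float = 3.0, per_sample: bool = False
) -> FeatureTable:
    """Remove features not exceeding ``factor`` x the blank level.

    Group-mean mode (default): a feature is removed when the mean abundance
    over non-missing biological samples is below ``factor`` times the mean
    over blank runs.  ``per_sample`` mode removes the feature when *no*
    biological sample exceeds the threshold.  Features absent from every
    blank are kept.
    """
    blanks = table.blank_ids
    if len(blanks) == 0:
        raise ValueError("blank filtering requires at least one blank run")
    bio = table.sample_ids
    blank_mean = table.data.loc[blanks].mean(axis=0, skipna=True)
    removed = []
    for col in table.data.columns:
        b = blank_mean[col]
        if pd.isna(b) or b == 0:
            continue
        vals = table.data.loc[bio, col].dropna()
        if per_sample:
            drop = vals.empty or not (vals >= factor * b).any()
        else:
            drop = vals.empty or vals.mean() < factor * b
        if drop:
            removed.append(col)
    data = table.data.drop(columns=removed)
    entry = {
        "op": "blank_filter",
        "factor": factor,
        "per_sample": per_sample,
        "removed": [float(c) for c in removed],
    }
    return table._evolve(data, table.meta, entry)


def prevalence_filter(table: FeatureTable, min_fraction: float = 0.8) -> FeatureTable:
    """Keep features detected in at least ``min_fraction`` of biological samples."""
    bio = table.sample_ids
    if len(bio) == 0:
        raise ValueError("no biological samples in table")
    frac = table.data.loc[bio].notna().mean(axis=0)
    removed = [c for c in table.data.columns if frac[c] < min_fraction]
    entry = {
        "op": "prevalence_filter",
        "min_fraction": min_fraction,
        "removed": [float(c) for c in removed],
    }
    return table._evolve(table.data.drop(columns=removed), table.meta, entry)


def qc_feature_filter(table: FeatureTable, max_missing: float = 0.8) -> FeatureTable:
    """Remove features missing in >= ``max_missing`` of QC runs or absent from all."""
    qcs = table.qc_ids
    if len(qcs) == 0:
        raise ValueError("QC filtering requires at least one QC run")
    miss = table.data.loc[qcs].isna().mean(axis=0)
    removed = [c for c in table.data.columns if miss[c] >= max_missing]
    entry = {
        "op": "qc_feature_filter",
        "max_missing": max_missing,
        "removed": [float(c) for c in removed],
    }
    return table._evolve(table.data.drop(columns=removed), table.meta, entry)


def sample_outlier_filter(table: FeatureTable, max_missing: float = 0.2) -> FeatureTable:
    """Remove biological samples with strictly more than ``max_missing`` missing.

    Missingness is evaluated over the currently retained features, before
    imputation.  QC and blank runs are never removed here.
    """
    bio = table.sample_ids
    n_feat = table.data.shape[1]
    removed = []
    if n_feat > 0:
        miss = table.data.loc[bio].isna().mean(axis=1)
        removed = [i for i in bio if miss[i] > max_missing]
    data = table.data.drop(index=removed)
    meta = table.meta.drop(index=removed)
    entry = {
        "op": "sample_outlier_filter",
        "max_missing": max_missing,
        "removed": list(removed),
    }
    return FeatureTable(data, meta, table.log + [entry])


def impute_half_min(table: FeatureTable) -> FeatureTable:
    """Replace every missing value by half the table's minimum positive value."""
    vals = table.data.to_numpy(dtype=float)
    positive = vals[np.isfinite(vals) & (vals > 0)]
    if positive.size == 0:
        raise ValueError("cannot impute: table has no positive values")
    fill = 0.5 * float(positive.min())
    n_missing = table.n_missing()
    data = table.data.fillna(fill)
    entry = {"op": "impute_half_min", "fill_value": fill, "n_imputed": n_missing}
    return table._evolve(data, table.meta, entry)


def qc_rsd(table: FeatureTable) -> pd.Series:
    """Per-feature relative standard deviation (sd/mean, n-1) across QC runs."""
    qcs = table.qc_ids
    if len(qcs) < 2:
        raise ValueError("QC RSD requires at least two QC runs")
    sub = table.data.loc[qcs]
    return sub.std(axis=0, ddof=1, skipna=True) / sub.mean(axis=0, skipna=True)


def rsd_qc_filter(table: FeatureTable, max_rsd: float = 0.30) -> FeatureTable:
    """Remove features whose QC RSD is strictly greater than ``max_rsd``."""
    rsd = qc_rsd(table)
    removed = [c for c in table.data.columns if pd.notna(rsd[c]) and rsd[c] > max_rsd]
    entry = {
        "op": "rsd_qc_filter",
        "max_rsd": max_rsd,
        "removed": [float(c) for c in removed],
    }
    return table._evolve(table.data.drop(columns=removed), table.meta, entry)


def median_rsd_qc(table: FeatureTable) -> float:
    """Median over retained features of the per-feature QC RSD."""
    rsd = qc_rsd(table).dropna()
    if rsd.empty:
        raise ValueError("no features with defined QC RSD")
    return float(rsd.median())


def _qc_missingness_step(table: FeatureTable) -> FeatureTable:
    """QC-missingness feature filter followed by sample-outlier removal."""
    return sample_outlier_filter(qc_feature_filter(table))


_ORDERABLE = {
    "blank": blank_filter,
    "prevalence": prevalence_filter,
    "qc_missingness": _qc_missingness_step,
    "rsd_qc": rsd_qc_filter,
}


def filter_order_report(table: FeatureTable) -> dict[tuple[str, ...], dict]:
    """Apply the four interchangeable quality filters in all 24 orders.

    The four steps are blank filtering, prevalence filtering, QC-missingness
    (feature filter plus sample-outlier removal), and QC-RSD filtering.
    Returns, per order, the retained feature and sample sets, so callers can
    check on which tables the cascade is genuinely order-independent and
    report divergences where one filter changes another's inputs.
    """
    out = {}
    for perm in itertools.permutations(_ORDERABLE):
        t = table
        for name in perm:
            t = _ORDERABLE[name](t)
        out[perm] = {
            "features": frozenset(float(c) for c in t.data.columns),
            "samples": frozenset(t.data.index),
        }
    return out
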