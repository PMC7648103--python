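"""Scan-level data structures and pulse-train processing.

A pulsed nanoelectrospray source emits discrete spray events (~0.8 Hz), each
spanning several mass-analyzer scans.  This module turns one run's scan list
into a single representative spectrum:

1. extract a total or extracted-ion chronogram (TIC/EIC),
2. segment it into pulses by threshold crossing and integrate their areas,
3. reject outlier pulses whose internal-standard EIC area falls outside a
   +/-20% window centred on the median (single pass, inclusive bounds),
4. randomly select k of the surviving pulses (seeded),
5. pool all scans inside the selected pulses, cluster peaks by m/z within a
   ppm tolerance, average them, and drop peaks below the instrument's
   abundance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ScanSpectrum",
    "Chronogram",
    "Pulse",
    "RepresentativeSpectrum",
    "compute_tic",
    "extract_eic",
    "detect_pulses",
    "pulse_area",
    "reject_outlier_pulses",
    "select_pulses",
    "representative_spectrum",
]


@dataclass
class ScanSpectrum:
    """One centroided MS scan: time (s), polarity, and (m/z, intensity) peaks."""

    scan_time: float
    polarity: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("scan m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("scan intensities must be non-negative")
        if self.polarity not in ("+", "-"):
            raise ValueError("polarity must be '+' or '-'")


@dataclass
class Chronogram:
    """Summed intensity versus scan time; TIC or EIC for one target m/z."""

    times: np.ndarray
    intensities: np.ndarray
    kind: str = "TIC"
    target_mz: float | None = None
    tol_ppm: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("chronogram times must be strictly increasing")


@dataclass(frozen=True)
class Pulse:
    """One detected spray event on a chronogram (inclusive scan-index bounds)."""

    start_index: int
    end_index: int
    apex_index: int
    area: float
    scan_count: int

    def __post_init__(self) -> None:
        if not (self.start_index <= self.apex_index <= self.end_index):
            raise ValueError("pulse indices must satisfy start <= apex <= end")
        if self.scan_count != self.end_index - self.start_index + 1:
            raise ValueError("scan_count must equal end - start + 1")


@dataclass
class RepresentativeSpectrum:
    """Averaged spectrum over the selected pulses of one sample run."""

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    pulses_used: list[Pulse] = field(default_factory=list)
    instrument_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("representative spectrum m/z must be strictly increasing")


def compute_tic(run: Sequence[ScanSpectrum]) -> Chronogram:
    """Total ion chronogram: per-scan sum of all peak intensities."""
    if len(run) == 0:
        raise ValueError("empty run")
    times = np.array([s.scan_time for s in run])
    tic = np.array([float(s.intensity.sum()) for s in run])
    return Chronogram(times, tic, kind="TIC")


def extract_eic(
    run: Sequence[ScanSpectrum], target_mz: float, tol_ppm: float = 10.0
) -> Chronogram:
    """Extracted ion chronogram: per-scan summed intensity within a ppm window."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    tol = target_mz * tol_ppm * 1e-6
    lo, hi = target_mz - tol, target_mz + tol
    times = np.array([s.scan_time for s in run])
    out = np.zeros(len(run))
    for i, s in enumerate(run):
        a = np.searchsorted(s.mz, lo, side="left")
        b = np.searchsorted(s.mz, hi, side="right")
        if b > a:
            out[i] = float(s.intensity[a:b].sum())
    return Chronogram(times, out, kind="EIC", target_mz=target_mz, tol_ppm=tol_ppm)


def detect_pulses(
    chron: Chronogram, min_height: float, min_scans: int = 3
) -> list[Pulse]:
    """Segment a chronogram into pulses by threshold crossing.

    A pulse is a maximal contiguous run of scans with intensity >= min_height
    that is at least ``min_scans`` long.  Area is the trapezoidal integral over
    the run (zero baseline); the apex is the earliest argmax.
    """
    if min_height <= 0:
        raise ValueError("min_height must be positive")
    if min_scans < 1:
        raise ValueError("min_scans must be >= 1")
    y = chron.intensities
    if y.size == 0:
        return []
    above = y >= min_height
    # boundaries of contiguous True runs
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1) if edges.size else []
    ends = list(edges[above[edges]]) if edges.size else []
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(y.size - 1)
    pulses = []
    for a, b in zip(starts, ends):
        if b - a + 1 < min_scans:
            continue
        pulses.append(
            Pulse(
                start_index=int(a),
                end_index=int(b),
                apex_index=int(a + np.argmax(y[a : b + 1])),
                area=pulse_area(chron, int(a), int(b)),
                scan_count=int(b - a + 1),
            )
        )
    return pulses


def pulse_area(chron: Chronogram, start: int, end: int) -> float:
    """Trapezoidal integral (counts*s) of a chronogram slice, zero baseline."""
    if end <= start:
        return 0.0
    return float(
        np.trapezoid(chron.intensities[start : end + 1], chron.times[start : end + 1])
    )


def integrate_over_pulses(
    chron: Chronogram, pulses: Sequence[Pulse], pad_scans: int = 2
) -> list[float]:
    """Integrate a chronogram over each pulse's window, padded into the tails.

    Threshold-crossing bounds clip the pulse tails at scan-grid resolution,
    which by itself adds a couple of percent of pulse-to-pulse area scatter.
    Padding the window by ``pad_scans`` scans on each side (clipped at the
    midpoint to the neighbouring pulse) recovers the tail mass and makes the
    area a faithful measure of the pulse's true intensity.
    """
    areas = []
    n = chron.times.size
    for i, p in enumerate(pulses):
        lo = p.start_index - pad_scans
        hi = p.end_index + pad_scans
        if i > 0:
            lo = max(lo, (pulses[i - 1].end_index + p.start_index + 1) // 2)
        if i + 1 < len(pulses):
            hi = min(hi, (p.end_index + pulses[i + 1].start_index) // 2)
        areas.append(pulse_area(chron, max(lo, 0), min(hi, n - 1)))
    return areas


def reject_outlier_pulses(
    pulses: Sequence[Pulse],
    is_areas: Sequence[float],
    lower: float = 0.8,
    upper: float = 1.2,
) -> tuple[list[Pulse], list[Pulse]]:
    """Single-pass +/-20% internal-standard pulse QC.

    The median of the IS EIC areas is computed once over *all* candidate
    pulses; pulses whose IS area lies inside ``[lower*median, upper*median]``
    (inclusive) are kept, the rest rejected.  The median is not recomputed
    after removals.
    """
    if len(pulses) == 0:
        raise ValueError("no pulses to QC")
    if len(pulses) != len(is_areas):
        raise ValueError("one IS area required per pulse")
    areas = np.asarray(is_areas, dtype=float)
    med = float(np.median(areas))
    lo, hi = lower * med, upper * med
    kept, rejected = [], []
    for p, a in zip(pulses, areas):
        (kept if lo <= a <= hi else rejected).append(p)
    return kept, rejected


def select_pulses(kept: Sequence[Pulse], k: int, seed: int) -> list[Pulse]:
    """Uniform random subset of k pulses, returned in time order.

    Raises ``ValueError`` when fewer than k pulses survived QC — the caller
    should flag the replicate as failed rather than pad the selection.
    """
    if k > len(kept):
        raise ValueError(
            f"only {len(kept)} usable pulses, cannot select {k}; replicate failed"
        )
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(kept), size=k, replace=False))
    return [kept[i] for i in idx]


def representative_spectrum(
    run: Sequence[ScanSpectrum],
    selected: Sequence[Pulse],
    mz_bin_ppm: float = 10.0,
    instrument_threshold: float = 2e3,
    sample_id: str = "",
) -> RepresentativeSpectrum:
    """Average the scans inside the selected pulses into one spectrum.

    All scans in the selected pulses are pooled; peaks are clustered by
    single-linkage in m/z with ``mz_bin_ppm`` tolerance; each cluster's m/z is
    the intensity-weighted mean and its intensity the mean over all pooled
    scans (a scan without a member peak contributes 0).  Peaks below the
    instrument abundance threshold are then removed.
    """
    if len(selected) == 0:
        raise ValueError("no pulses selected")
    scan_idx = sorted(
        {i for p in selected for i in range(p.start_index, p.end_index + 1)}
    )
    n_scans = len(scan_idx)
    mzs = np.concatenate([run[i].mz for i in scan_idx]) if n_scans else np.array([])
    ints = (
        np.concatenate([run[i].intensity for i in scan_idx]) if n_scans else np.array([])
    )
    if mzs.size == 0:
        return RepresentativeSpectrum(
            sample_id, np.array([]), np.array([]), list(selected), instrument_threshold
        )
    order = np.argsort(mzs, kind="stable")
    mzs, ints = mzs[order], ints[order]
    # single linkage: break clusters where the gap exceeds the ppm tolerance
    gaps = np.diff(mzs) > mzs[:-1] * mz_bin_ppm * 1e-6
    labels = np.concatenate([[0], np.cumsum(gaps)])
    n_clusters = int(labels[-1]) + 1
    sums = np.bincount(labels, weights=ints, minlength=n_clusters)
    wmz = np.bincount(labels, weights=ints * mzs, minlength=n_clusters)
    with np.errstate(invalid="ignore"):
        cmz = np.where(sums > 0, wmz / sums, 0.0)
    # unweighted m/z for clusters of all-zero intensity peaks
    zero = sums == 0
    if zero.any():
        counts = np.bincount(labels, minlength=n_clusters)
        cmz[zero] = np.bincount(labels, weights=mzs, minlength=n_clusters)[zero] / counts[zero]
    cint = sums / n_scans
    keep = cint >= instrument_threshold
    cmz, cint = cmz[keep], cint[keep]
    order = np.argsort(cmz)
    return RepresentativeSpectrum(
        sample_id, cmz[order], cint[order], list(selected), instrument_threshold
    )
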