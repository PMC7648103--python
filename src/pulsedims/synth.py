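"""Synthetic pulsed direct-infusion MS studies with known ground truth.

Emulates the acquisition statistics of a triboelectrically pulsed nanospray
source: ~0.8 Hz pulse trains, 6-7 scans per pulse with 8.9% pulse-width
variation, a spiked isotope-labelled internal standard present in every run,
per-pulse amplitude variability that is *common-mode* across all m/z within a
pulse (which is what makes IS-based pulse QC meaningful), occasional outlier
pulses, two-group designs with planted fold changes, pooled-QC and blank
runs, and per-sample missing features.

Every random draw flows from a single study seed through spawned
``numpy.random.SeedSequence`` children, so studies are byte-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .design import StudyDesign, RunSlot, make_run_order
from .pulses import ScanSpectrum

__all__ = [
    "MetabolitePanel",
    "AcquisitionConfig",
    "RunTruth",
    "SyntheticStudy",
    "generate_panel",
    "generate_run",
    "generate_study",
    "save_ground_truth",
    "load_ground_truth",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class MetabolitePanel:
    """The simulated metabolome: feature m/z values, abundances, and truth.

    ``base_abundance`` is the expected per-pulse EIC area (counts*s) of each
    feature in group 1; group 2 means are ``base * group_fold_change``.
    ``is_mz``/``is_area`` describe the spiked internal standard.
    """

    mz: np.ndarray
    base_abundance: np.ndarray
    group_fold_change: np.ndarray
    detection_probability: np.ndarray
    is_mz: float = 183.0879
    is_area: float = 5e4

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.base_abundance = np.asarray(self.base_abundance, dtype=float)
        self.group_fold_change = np.asarray(self.group_fold_change, dtype=float)
        self.detection_probability = np.asarray(self.detection_probability, dtype=float)
        n = self.mz.size
        if not all(
            a.size == n
            for a in (self.base_abundance, self.group_fold_change, self.detection_probability)
        ):
            raise ValueError("panel arrays must have equal length")
        if np.min(np.abs(self.mz - self.is_mz)) < 0.1:
            raise ValueError("feature m/z too close to the internal standard")

    @property
    def n_features(self) -> int:
        return int(self.mz.size)

    @property
    def differential(self) -> np.ndarray:
        """Boolean mask of features with a planted fold change != 1."""
        return self.group_fold_change != 1.0

    def to_dict(self) -> dict:
        return {
            "mz": self.mz.tolist(),
            "base_abundance": self.base_abundance.tolist(),
            "group_fold_change": self.group_fold_change.tolist(),
            "detection_probability": self.detection_probability.tolist(),
            "is_mz": self.is_mz,
            "is_area": self.is_area,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolitePanel":
        return cls(
            mz=np.array(d["mz"]),
            base_abundance=np.array(d["base_abundance"]),
            group_fold_change=np.array(d["group_fold_change"]),
            detection_probability=np.array(d["detection_probability"]),
            is_mz=d["is_mz"],
            is_area=d["is_area"],
        )


@dataclass
class AcquisitionConfig:
    """Instrument-side simulation parameters.

    Defaults give ~0.8 Hz pulses whose above-threshold span covers 6-7 scans
    at a 0.1 s scan period, with 8.9% width variation and 10% common-mode
    pulse-to-pulse amplitude variability.
    """

    pulse_rate: float = 0.8  # Hz
    scan_period: float = 0.1  # s
    pulse_sigma: float = 0.13  # s, Gaussian envelope width
    pulse_width_cv: float = 0.089
    n_pulses: int = 40
    mz_range: tuple[float, float] = (50.0, 750.0)
    noise_sd: float = 200.0  # counts, per channel per scan
    amplitude_cv: float = 0.10
    outlier_pulse_prob: float = 0.1
    outlier_pulse_scale: float = 1.5
    polarity: str = "-"

    def __post_init__(self) -> None:
        if self.pulse_rate <= 0 or self.scan_period <= 0 or self.pulse_sigma <= 0:
            raise ValueError("rates, periods and widths must be positive")
        if self.pulse_width_cv < 0:
            raise ValueError("pulse_width_cv must be >= 0")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValueError("mz_range must satisfy low < high")


@dataclass
class RunTruth:
    """Per-run generator ground truth (pulse placement and amplitudes)."""

    pulse_centers: np.ndarray
    pulse_sigmas: np.ndarray
    pulse_amplitudes: np.ndarray  # common-mode multiplier incl. outlier scale
    outlier_pulse: np.ndarray  # bool
    feature_detected: np.ndarray  # bool per panel feature

    def to_dict(self) -> dict:
        return {
            "pulse_centers": self.pulse_centers.tolist(),
            "pulse_sigmas": self.pulse_sigmas.tolist(),
            "pulse_amplitudes": self.pulse_amplitudes.tolist(),
            "outlier_pulse": self.outlier_pulse.astype(bool).tolist(),
            "feature_detected": self.feature_detected.astype(bool).tolist(),
        }


def generate_panel(
    n_features: int = 100,
    n_differential: int = 10,
    fc: float = 5.0,
    abundance_log_mean: float = math.log(3e5),
    abundance_log_sd: float = 0.8,
    seed: int = 0,
    mz_range: tuple[float, float] = (50.0, 750.0),
    sporadic_fraction: float = 0.1,
    sporadic_detection: tuple[float, float] = (0.6, 0.95),
    is_mz: float = 183.0879,
    is_area: float = 5e4,
) -> MetabolitePanel:
    """Draw a metabolite panel with planted differential features.

    Base abundances are log-normal.  Exactly ``n_differential`` features carry
    the fold change: half up-regulated (fc) and half down-regulated (1/fc)
    when fc > 1 (two-sided interpretation).  Feature m/z values are spread
    over ``mz_range`` with a guaranteed minimum spacing well above the 10 ppm
    alignment tolerance, and kept away from the internal-standard m/z.

    Missingness mimics detection-limit censoring: most features are detected
    in every run, while a random ``sporadic_fraction`` of features sit near
    the detection limit and flicker, with per-run detection probability drawn
    uniformly from ``sporadic_detection``.  (Abundant signals do not vanish
    at random in direct-infusion data; sporadic detection is a property of
    borderline features.)
    """
    if n_differential > n_features:
        raise ValueError("n_differential cannot exceed n_features")
    if fc <= 0:
        raise ValueError("fold change must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = mz_range
    grid = np.arange(lo + 1.0, hi - 1.0, 0.7)
    grid = grid[np.abs(grid - is_mz) > 0.5]
    if grid.size < n_features:
        raise ValueError("mz_range too narrow for the requested feature count")
    mz = np.sort(rng.choice(grid, size=n_features, replace=False))
    mz = mz + rng.uniform(-0.2, 0.2, size=n_features)
    base = np.exp(rng.normal(abundance_log_mean, abundance_log_sd, size=n_features))
    fcs = np.ones(n_features)
    diff_idx = rng.choice(n_features, size=n_differential, replace=False)
    n_up = n_differential - n_differential // 2
    fcs[diff_idx[:n_up]] = fc
    fcs[diff_idx[n_up:]] = 1.0 / fc
    det = np.ones(n_features)
    n_sporadic = int(round(sporadic_fraction * n_features))
    if n_sporadic:
        spor_idx = rng.choice(n_features, size=n_sporadic, replace=False)
        det[spor_idx] = rng.uniform(*sporadic_detection, size=n_sporadic)
    return MetabolitePanel(mz, base, fcs, det, is_mz=is_mz, is_area=is_area)


def generate_run(
    panel: MetabolitePanel,
    sample_abundances: np.ndarray,
    acq: AcquisitionConfig,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[ScanSpectrum], RunTruth]:
    """Simulate the scan list for one acquisition.

    Each feature channel receives a Gaussian-shaped intensity envelope per
    pulse whose integral equals ``abundance * amplitude_multiplier``; the
    multiplier is shared by all channels within a pulse (spray-efficiency
    coupling), log-normal with CV ``amplitude_cv``, and scaled by
    ``outlier_pulse_scale`` for outlier pulses.  Gaussian baseline noise is
    added per channel and clipped at zero; features are absent for the whole
    run with probability ``1 - detection_probability``.
    """
    rng = np.random.default_rng(seed)
    n_p = acq.n_pulses
    duration = (n_p + 1) / acq.pulse_rate
    times = np.arange(0.0, duration, acq.scan_period)
    centers = (np.arange(n_p) + 1.0) / acq.pulse_rate + rng.normal(0, 0.02, n_p)
    sigmas = acq.pulse_sigma * np.clip(
        rng.normal(1.0, acq.pulse_width_cv, n_p), 0.2, None
    )
    if acq.amplitude_cv > 0:
        sd_log = math.sqrt(math.log(1.0 + acq.amplitude_cv**2))
        amps = np.exp(rng.normal(0.0, sd_log, n_p))
    else:
        amps = np.ones(n_p)
    outlier = rng.random(n_p) < acq.outlier_pulse_prob
    amps = np.where(outlier, amps * acq.outlier_pulse_scale, amps)

    detected = rng.random(panel.n_features) < panel.detection_probability
    areas = np.concatenate([np.asarray(sample_abundances) * detected, [panel.is_area]])
    channel_mz = np.concatenate([panel.mz, [panel.is_mz]])
    order = np.argsort(channel_mz)
    channel_mz, areas = channel_mz[order], areas[order]

    # g[t] = sum_p amp_p * N(t; c_p, sigma_p) so that each channel's continuous
    # per-pulse EIC integral equals area * amp_p
    dt = times[:, None] - centers[None, :]
    env = np.exp(-0.5 * (dt / sigmas[None, :]) ** 2) / (sigmas[None, :] * SQRT_2PI)
    g = env @ amps
    signal = np.outer(g, areas)
    if acq.noise_sd > 0:
        signal = signal + rng.normal(0.0, acq.noise_sd, size=signal.shape)
        np.clip(signal, 0.0, None, out=signal)

    run = []
    for i, t in enumerate(times):
        row = signal[i]
        nz = row > 0
        run.append(
            ScanSpectrum(
                scan_time=float(t),
                polarity=acq.polarity,
                mz=channel_mz[nz],
                intensity=row[nz],
            )
        )
    truth = RunTruth(centers, sigmas, amps, outlier, detected)
    return run, truth


@dataclass
class SyntheticStudy:
    """A complete simulated study: runs, schedule, and ground truth."""

    panel: MetabolitePanel
    design: StudyDesign
    acq: AcquisitionConfig
    runs: dict[str, list[ScanSpectrum]]
    run_order: list[RunSlot]
    truths: dict[str, RunTruth]
    sample_abundances: pd.DataFrame  # rows = run ids, cols = feature index
    seed: int
    between_sample_cv: float

    @property
    def metadata(self) -> pd.DataFrame:
        """Run metadata frame (index = run id; role, group, sample id, order)."""
        return pd.DataFrame(
            {
                "run_id": [s.run_id for s in self.run_order],
                "sample_id": [s.sample_id for s in self.run_order],
                "role": [s.role for s in self.run_order],
                "group": [s.group for s in self.run_order],
                "order": np.arange(len(self.run_order)),
            }
        ).set_index("run_id")

    def ground_truth(self) -> dict:
        """JSON-serializable ground-truth record for the whole study."""
        return {
            "seed": self.seed,
            "between_sample_cv": self.between_sample_cv,
            "panel": self.panel.to_dict(),
            "design": asdict(self.design),
            "differential_mz": self.panel.mz[self.panel.differential].tolist(),
            "sample_abundances": {
                rid: self.sample_abundances.loc[rid].tolist()
                for rid in self.sample_abundances.index
            },
            "run_truths": {rid: t.to_dict() for rid, t in self.truths.items()},
        }


def generate_study(
    design: StudyDesign,
    panel: MetabolitePanel,
    acq: AcquisitionConfig,
    between_sample_cv: float = 0.2,
    seed: int = 0,
) -> SyntheticStudy:
    """Simulate every run of a two-group study in acquisition order.

    Per-sample feature abundances are log-normal around the group mean
    (group 2 mean = base * fold change); pooled-QC runs use the mean of all
    realized sample abundance vectors; blanks carry zero feature signal (the
    internal standard and noise remain).
    """
    ss = np.random.SeedSequence(seed)
    order_seed, abund_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    slots = make_run_order(design, order_seed)
    rng = np.random.default_rng(abund_seed)
    sd_log = math.sqrt(math.log(1.0 + between_sample_cv**2)) if between_sample_cv > 0 else 0.0

    group_mean = {
        design.group_labels[0]: panel.base_abundance,
        design.group_labels[1]: panel.base_abundance * panel.group_fold_change,
    }
    sample_ab: dict[str, np.ndarray] = {}
    for sid, g in design.sample_ids:
        noise = np.exp(rng.normal(0.0, sd_log, panel.n_features)) if sd_log else 1.0
        sample_ab[sid] = group_mean[g] * noise
    pooled = np.mean(np.vstack(list(sample_ab.values())), axis=0)

    run_seeds = ss.spawn(len(slots))
    runs: dict[str, list[ScanSpectrum]] = {}
    truths: dict[str, RunTruth] = {}
    abund_rows = {}
    for slot, child in zip(slots, run_seeds):
        if slot.role == "blank":
            ab = np.zeros(panel.n_features)
        elif slot.role == "QC":
            ab = pooled
        else:
            ab = sample_ab[slot.sample_id]
        run, truth = generate_run(panel, ab, acq, seed=child)
        runs[slot.run_id] = run
        truths[slot.run_id] = truth
        abund_rows[slot.run_id] = ab
    sample_abundances = pd.DataFrame.from_dict(abund_rows, orient="index")
    sample_abundances = sample_abundances.loc[[s.run_id for s in slots]]
    return SyntheticStudy(
        panel=panel,
        design=design,
        acq=acq,
        runs=runs,
        run_order=slots,
        truths=truths,
        sample_abundances=sample_abundances,
        seed=seed,
        between_sample_cv=between_sample_cv,
    )


def save_ground_truth(study: SyntheticStudy, path) -> None:
    with open(path, "w") as fh:
        json.dump(study.ground_truth(), fh, indent=1, sort_keys=True)


def load_ground_truth(path) -> dict:
    """Reload a ground-truth record; the differential set round-trips exactly."""
    with open(path) as fh:
        gt = json.load(fh)
    gt["panel"] = MetabolitePanel.from_dict(gt["panel"])
    return gt
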