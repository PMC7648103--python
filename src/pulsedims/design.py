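"""Study design and acquisition run-order generation.

A pulsed-DI-MS metabolomics study runs method blanks first, then a pooled-QC
triplicate, then the biological samples with the two groups interleaved in
randomized pairs, inserting a QC triplicate after every ``qc_interval``
samples (the every-six-samples convention for cell studies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["StudyDesign", "RunSlot", "make_run_order"]


@dataclass(frozen=True)
class RunSlot:
    """One scheduled acquisition: run id, sample id, role, group label."""

    run_id: str
    sample_id: str
    role: str  # "sample" | "QC" | "blank"
    group: str | None = None


@dataclass
class StudyDesign:
    """Two-group design with pooled QCs and method blanks."""

    group_labels: tuple[str, str] = ("pre", "post")
    n_per_group: int = 10
    n_qc: int = 3
    n_blank: int = 1
    replicates_per_sample: int = 1
    qc_interval: int = 6

    def __post_init__(self) -> None:
        if len(self.group_labels) != 2:
            raise ValueError("exactly two group labels required")
        if self.n_per_group < 1 or self.qc_interval < 1:
            raise ValueError("n_per_group and qc_interval must be >= 1")

    @property
    def sample_ids(self) -> list[tuple[str, str]]:
        """(sample_id, group) pairs for all biological samples."""
        out = []
        for g in self.group_labels:
            for i in range(self.n_per_group):
                out.append((f"{g}_{i + 1:02d}", g))
        return out


def make_run_order(design: StudyDesign, seed: int) -> list[RunSlot]:
    """Deterministic acquisition schedule for a study design.

    Blanks first, then a QC triplicate, then sample segments: group-1/group-2
    sample pairs in randomized order, each pair internally in random order
    (interleaving the groups), with a QC triplicate inserted after every
    ``qc_interval`` biological runs.  Unbalanced designs are scheduled
    best-effort with a warning.
    """
    rng = np.random.default_rng(seed)
    slots: list[RunSlot] = []
    for b in range(design.n_blank):
        slots.append(RunSlot(f"blank_{b + 1:02d}", f"blank_{b + 1:02d}", "blank"))

    qc_counter = [0]

    def qc_triplicate() -> None:
        for _ in range(design.n_qc):
            qc_counter[0] += 1
            slots.append(RunSlot(f"qc_{qc_counter[0]:02d}", "pooled_qc", "QC"))

    qc_triplicate()

    g1 = [s for s in design.sample_ids if s[1] == design.group_labels[0]]
    g2 = [s for s in design.sample_ids if s[1] == design.group_labels[1]]
    if len(g1) != len(g2):
        warnings.warn("unbalanced groups: interleaving best-effort", stacklevel=2)
    rng.shuffle(g1)
    rng.shuffle(g2)
    pairs = []
    for a, b in zip(g1, g2):
        pair = [a, b]
        rng.shuffle(pair)
        pairs.append(pair)
    leftovers = g1[len(g2):] + g2[len(g1):]
    ordered = [s for pair in pairs for s in pair] + leftovers

    n_run = 0
    for rep in range(1, design.replicates_per_sample + 1):
        for sample_id, group in ordered:
            rid = sample_id if design.replicates_per_sample == 1 else f"{sample_id}_r{rep}"
            slots.append(RunSlot(rid, sample_id, "sample", group))
            n_run += 1
            if n_run % design.qc_interval == 0:
                qc_triplicate()
    return slots
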