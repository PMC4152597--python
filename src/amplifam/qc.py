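"""Read quality filtering and length demultiplexing.

Reads are kept when they have at least ``min_passes`` circular-consensus
passes and at least ``min_fraction_at_threshold`` of their bases at or above
``phred_threshold``.  The published wording of the quality rule is ambiguous;
the default per-base reading (>=90% of bases individually >= Q20) is the
parameter-free one, and the alternative (mean quality of the best 90% of
bases >= 20) is available via ``rule="best_fraction_mean"``.

The two amplicon classes differ by ~65 bp, so demultiplexing assigns each
read to the unique class whose length window contains it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .io_formats import CCSRead


class RejectReason(str, enum.Enum):
    PASS_COUNT = "PASS_COUNT"
    QUALITY = "QUALITY"


@dataclass(frozen=True)
class QCParams:
    min_passes: int = 4
    phred_threshold: int = 20
    min_fraction_at_threshold: float = 0.90
    rule: str = "per_base"  # or "best_fraction_mean"

    def __post_init__(self) -> None:
        if self.min_passes < 1:
            raise ValueError("min_passes must be >= 1")
        if not 0.0 < self.min_fraction_at_threshold <= 1.0:
            raise ValueError("min_fraction_at_threshold must be in (0, 1]")
        if self.rule not in ("per_base", "best_fraction_mean"):
            raise ValueError(f"unknown quality rule {self.rule!r}")


@dataclass(frozen=True)
class AmpliconClass:
    name: str
    expected_length: int
    window: int = 30  # +/- bp tolerance

    @property
    def lo(self) -> int:
        return self.expected_length - self.window

    @property
    def hi(self) -> int:
        return self.expected_length + self.window

    def contains(self, length: int) -> bool:
        return self.lo <= length <= self.hi


DEFAULT_CLASSES = (
    AmpliconClass("V1RI", 725, 30),
    AmpliconClass("V1RIX", 800, 30),
)


@dataclass
class Rejection:
    read: CCSRead
    reason: RejectReason
    fraction_at_threshold: float


def quality_fraction(read: CCSRead, phred_threshold: int) -> float:
    """Fraction of bases with quality >= the threshold."""
    q = np.asarray(read.qualities)
    return float(np.count_nonzero(q >= phred_threshold)) / len(q)


def _passes_quality(read: CCSRead, params: QCParams) -> tuple[bool, float]:
    q = np.asarray(read.qualities)
    frac = float(np.count_nonzero(q >= params.phred_threshold)) / len(q)
    if params.rule == "per_base":
        return frac >= params.min_fraction_at_threshold, frac
    # best_fraction_mean: mean quality of the best min_fraction of bases
    n_keep = max(1, int(np.ceil(params.min_fraction_at_threshold * len(q))))
    best = np.sort(q)[::-1][:n_keep]
    return float(best.mean()) >= params.phred_threshold, frac


def filter_reads(
    reads: list[CCSRead], params: QCParams | None = None
) -> tuple[list[CCSRead], list[Rejection]]:
    """Split reads into (kept, rejected-with-reason).

    A read failing both gates is attributed to PASS_COUNT (the first gate in
    the published workflow), so every rejection has exactly one reason.
    """
    params = params or QCParams()
    kept: list[CCSRead] = []
    rejected: list[Rejection] = []
    for read in reads:
        ok_quality, frac = _passes_quality(read, params)
        if read.num_passes < params.min_passes:
            rejected.append(Rejection(read, RejectReason.PASS_COUNT, frac))
        elif not ok_quality:
            rejected.append(Rejection(read, RejectReason.QUALITY, frac))
        else:
            kept.append(read)
    return kept, rejected


def check_class_windows(classes: list[AmpliconClass] | tuple[AmpliconClass, ...]) -> None:
    """Raise if any two class windows overlap."""
    ordered = sorted(classes, key=lambda c: c.expected_length)
    for a, b in zip(ordered, ordered[1:]):
        if a.hi >= b.lo:
            raise ValueError(
                f"amplicon class windows overlap: {a.name} [{a.lo},{a.hi}] vs "
                f"{b.name} [{b.lo},{b.hi}]"
            )


def demultiplex_by_length(
    reads: list[CCSRead],
    classes: list[AmpliconClass] | tuple[AmpliconClass, ...] = DEFAULT_CLASSES,
) -> tuple[dict[str, list[CCSRead]], list[CCSRead]]:
    """Assign each read to the unique class whose window contains its length.

    Returns (class name -> reads, unassigned).  The partition is exhaustive
    and disjoint; overlapping windows are a configuration error.
    """
    check_class_windows(classes)
    assigned: dict[str, list[CCSRead]] = {c.name: [] for c in classes}
    unassigned: list[CCSRead] = []
    for read in reads:
        for c in classes:
            if c.contains(len(read)):
                assigned[c.name].append(read)
                break
        else:
            unassigned.append(read)
    return assigned, unassigned


def rejection_log_rows(
    rejected: list[Rejection],
) -> list[dict[str, object]]:
    """Rows for the TSV rejection log."""
    return [
        {
            "read_id": r.read.read_id,
            "reason": r.reason.value,
            "passes": r.read.num_passes,
            "fraction_ge_threshold": f"{r.fraction_at_threshold:.4f}",
            "length": len(r.read),
        }
        for r in rejected
    ]
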