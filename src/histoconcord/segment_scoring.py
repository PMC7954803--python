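"""Per-segment positivity and segment-level diagnostic performance.

A segment is "positive" for a structure when the structure overlaps it by
at least a configurable amount; the default — any single overlapping
voxel — is the closest objective surrogate for the visual slice-by-slice
assessment used in reader studies.  Confusion counts are taken over the
nonempty (analysable) segments only, and sensitivity/specificity carry an
explicit *undefined* state (``None``) when their denominator is zero,
e.g. specificity in a patient whose reference involves every segment.
Undefined values propagate to cohort tables as missing — never as 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .mask_model import VoxelMask, _require_same_grid
from .partitioning import Scheme, SegmentLabelMap


@dataclass(frozen=True)
class PositivityRule:
    """A segment is positive iff BOTH thresholds are met.

    The defaults (1 voxel, fraction 0) reproduce the any-overlap rule.
    """

    min_overlap_voxels: int = 1
    min_overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.min_overlap_voxels < 1:
            raise ValueError("min_overlap_voxels must be >= 1")
        if not 0.0 <= self.min_overlap_fraction <= 1.0:
            raise ValueError("min_overlap_fraction must lie in [0, 1]")

    def is_positive(self, overlap_voxels: int, segment_voxels: int) -> bool:
        return (
            overlap_voxels >= self.min_overlap_voxels
            and overlap_voxels >= self.min_overlap_fraction * segment_voxels
        )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    scheme: Scheme
    n_segments: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn != self.n_segments:
            raise ValueError("confusion counts must sum to n_segments")


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Sensitivity/specificity with explicit undefined states.

    ``sensitivity`` is ``None`` when no segment is reference-positive;
    ``specificity`` is ``None`` when no segment is reference-negative
    (the "not plausibly determinable" situation in whole-gland disease).
    """

    counts: ConfusionCounts

    @property
    def sensitivity(self) -> float | None:
        denom = self.counts.tp + self.counts.fn
        return self.counts.tp / denom if denom > 0 else None

    @property
    def specificity(self) -> float | None:
        denom = self.counts.tn + self.counts.fp
        return self.counts.tn / denom if denom > 0 else None

    def as_row(self) -> dict:
        """Flat record for CSV export; undefined metrics become NaN (which
        pandas serializes as an empty field)."""
        s, p = self.sensitivity, self.specificity
        return {
            "scheme": self.counts.scheme.value,
            "n_segments": self.counts.n_segments,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "sensitivity": math.nan if s is None else s,
            "specificity": math.nan if p is None else p,
        }


def _overlap_counts(labelmap: SegmentLabelMap, mask: VoxelMask) -> np.ndarray:
    """Overlap voxel count per segment_id (index 0 = outside gland)."""
    _require_same_grid(
        VoxelMask(labelmap.geometry, labelmap.labels > 0, "labelmap"), mask
    )
    n = len(labelmap.descriptors)
    inside = labelmap.labels[mask.occupancy]
    if (inside == 0).any():
        raise ContractError(
            f"mask {mask.label!r} has {int((inside == 0).sum())} voxel(s) outside "
            "the gland; trim it with trim_gtv before segment scoring"
        )
    return np.bincount(inside, minlength=n + 1)


def segment_status(
    labelmap: SegmentLabelMap,
    mask: VoxelMask,
    rule: PositivityRule = PositivityRule(),
) -> dict[int, bool]:
    """Positivity per nonempty segment, keyed by segment_id."""
    overlaps = _overlap_counts(labelmap, mask)
    return {
        d.segment_id: rule.is_positive(int(overlaps[d.segment_id]), d.voxel_count)
        for d in labelmap.nonempty_descriptors()
    }


def score_scheme(
    labelmap: SegmentLabelMap,
    reference: VoxelMask,
    test: VoxelMask,
    rule: PositivityRule = PositivityRule(),
) -> DiagnosticPerformance:
    """Segment-level confusion counts of a test mask against the reference."""
    ref_status = segment_status(labelmap, reference, rule)
    test_status = segment_status(labelmap, test, rule)
    tp = fp = tn = fn = 0
    for seg_id, ref_pos in ref_status.items():
        test_pos = test_status[seg_id]
        if ref_pos and test_pos:
            tp += 1
        elif ref_pos:
            fn += 1
        elif test_pos:
            fp += 1
        else:
            tn += 1
    counts = ConfusionCounts(
        tp=tp, fp=fp, tn=tn, fn=fn, scheme=labelmap.scheme, n_segments=len(ref_status)
    )
    return DiagnosticPerformance(counts)
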