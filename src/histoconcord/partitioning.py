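"""Partition a gland mask into exclusive spatial segments.

Three schemes of decreasing spatial resolution are supported, mirroring the
analysis methods commonly used in imaging-vs-histology comparison studies:

* ``QUADRANT_SLICE`` — every axial slice of the gland is split into four
  quadrants (right/left x anterior/posterior) around the per-slice gland
  center of mass; each nonempty (slice, quadrant) pair is one segment.
* ``SEG18`` — the gland is split along the craniocaudal axis into base,
  mid and apex thirds, and each third into 6 in-plane parts
  (left/right at the third's center of mass x three anterior–posterior
  bands of equal physical extent): 18 segments.
* ``SEG6`` — base/mid/apex x left/right: the classic sextant scheme.

Conventions (all deterministic):

* the first grid axis increases toward patient-left, the second toward
  posterior, the third toward superior (see :mod:`histoconcord.mask_model`);
  "base" is the most superior third;
* thirds contain equal slice counts; a remainder of 1 goes to mid, a
  remainder of 2 to mid then base;
* voxel centers exactly on a split plane go left (left–right axis),
  anterior (anterior–posterior axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import DegenerateAnatomyError
from .mask_model import ImageGeometry, VoxelMask

#: tolerance (mm) when comparing a voxel-center coordinate to a split plane
SPLIT_EPS_MM = 1e-9

THIRDS = ("base", "mid", "apex")
QUADRANTS = ("right-anterior", "left-anterior", "right-posterior", "left-posterior")
AP_BANDS = ("anterior", "middle", "posterior")


class Scheme(str, Enum):
    QUADRANT_SLICE = "QUADRANT_SLICE"
    SEG18 = "SEG18"
    SEG6 = "SEG6"


@dataclass(frozen=True)
class SegmentDescriptor:
    segment_id: int
    scheme: Scheme
    slice_index: int | None
    third: str | None
    sector: str
    voxel_count: int

    @property
    def empty(self) -> bool:
        return self.voxel_count == 0


@dataclass
class SegmentLabelMap:
    """Exclusive integer segment labels tiling the gland (0 = outside)."""

    geometry: ImageGeometry
    labels: np.ndarray
    descriptors: list[SegmentDescriptor]
    scheme: Scheme

    def nonempty_descriptors(self) -> list[SegmentDescriptor]:
        return [d for d in self.descriptors if not d.empty]

    @property
    def n_segments(self) -> int:
        """Number of analysable (nonempty) segments."""
        return len(self.nonempty_descriptors())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_id": [d.segment_id for d in self.descriptors],
                "scheme": [d.scheme.value for d in self.descriptors],
                "slice": [d.slice_index for d in self.descriptors],
                "third": [d.third for d in self.descriptors],
                "sector": [d.sector for d in self.descriptors],
                "voxel_count": [d.voxel_count for d in self.descriptors],
            }
        )


def _gland_slices(gland: VoxelMask) -> np.ndarray:
    """Sorted axial slice indices containing at least one gland voxel."""
    return np.flatnonzero(gland.occupancy.any(axis=(0, 1)))


def split_thirds(gland: VoxelMask, mode: str = "slices") -> dict[int, str]:
    """Assign each gland-containing slice to base/mid/apex.

    ``mode='slices'`` (default) splits the ordered gland slices into three
    contiguous blocks of equal slice count (remainder to mid, then base).
    ``mode='volume'`` places the block boundaries at the cumulative-volume
    thirds instead.  Base is the most superior block.
    """
    slices = _gland_slices(gland)
    n = len(slices)
    if n < 3:
        raise DegenerateAnatomyError(
            f"gland occupies {n} axial slice(s); at least 3 required for thirds"
        )
    if mode == "slices":
        q, r = divmod(n, 3)
        n_base = q + (1 if r == 2 else 0)
        n_mid = q + (1 if r >= 1 else 0)
        n_apex = q
    elif mode == "volume":
        per_slice = gland.occupancy.sum(axis=(0, 1))[slices]
        cum = np.cumsum(per_slice)
        total = cum[-1]
        # boundary index = first slice whose cumulative count reaches k/3;
        # ties go to the superior (later) block
        b1 = int(np.searchsorted(cum, total / 3.0, side="left"))
        b2 = int(np.searchsorted(cum, 2.0 * total / 3.0, side="left"))
        b1 = max(1, min(b1, n - 2))
        b2 = max(b1 + 1, min(b2, n - 1))
        n_apex, n_mid = b1, b2 - b1
        n_base = n - b2
    else:
        raise ValueError(f"unknown thirds mode {mode!r}")
    # slices are ordered inferior -> superior; apex is inferior, base superior
    assignment: dict[int, str] = {}
    for i, k in enumerate(slices):
        if i < n_apex:
            assignment[int(k)] = "apex"
        elif i < n_apex + n_mid:
            assignment[int(k)] = "mid"
        else:
            assignment[int(k)] = "base"
    return assignment


def _coords_mm(geometry: ImageGeometry, axis: int, idx: np.ndarray) -> np.ndarray:
    return geometry.origin[axis] + idx * geometry.spacing[axis]


def partition_quadrants(gland: VoxelMask, split: str = "centroid") -> SegmentLabelMap:
    """Per-slice quadrant partition around the slice gland centroid.

    ``split='bbox'`` uses the slice bounding-box center instead of the
    center of mass.  Only nonempty (slice, quadrant) pairs become segments.
    """
    if gland.is_empty():
        raise ValueError("cannot partition an empty gland mask")
    geom = gland.geometry
    labels = np.zeros(geom.shape, dtype=np.int32)
    descriptors: list[SegmentDescriptor] = []
    next_id = 1
    for k in _gland_slices(gland):
        ii, jj = np.nonzero(gland.occupancy[:, :, k])
        x = _coords_mm(geom, 0, ii)
        y = _coords_mm(geom, 1, jj)
        if split == "centroid":
            cx, cy = float(x.mean()), float(y.mean())
        elif split == "bbox":
            cx = float((x.min() + x.max()) / 2.0)
            cy = float((y.min() + y.max()) / 2.0)
        else:
            raise ValueError(f"unknown split {split!r}")
        left = (x - cx) >= -SPLIT_EPS_MM          # axis 0 increases to left
        anterior = (y - cy) <= SPLIT_EPS_MM       # axis 1 increases posterior
        quadrant_of = np.where(
            anterior,
            np.where(left, 1, 0),                 # left-anterior / right-anterior
            np.where(left, 3, 2),                 # left-posterior / right-posterior
        )
        for q, sector in enumerate(QUADRANTS):
            sel = quadrant_of == q
            count = int(sel.sum())
            if count == 0:
                continue
            labels[ii[sel], jj[sel], k] = next_id
            descriptors.append(
                SegmentDescriptor(
                    segment_id=next_id,
                    scheme=Scheme.QUADRANT_SLICE,
                    slice_index=int(k),
                    third=None,
                    sector=sector,
                    voxel_count=count,
                )
            )
            next_id += 1
    return SegmentLabelMap(geom, labels, descriptors, Scheme.QUADRANT_SLICE)


def _third_voxels(gland: VoxelMask, assignment: dict[int, str], third: str):
    ks = np.array([k for k, t in assignment.items() if t == third], dtype=int)
    sub = np.zeros(gland.geometry.shape, dtype=bool)
    sub[:, :, ks] = gland.occupancy[:, :, ks]
    return np.nonzero(sub)


def partition_6(gland: VoxelMask, thirds_mode: str = "slices") -> SegmentLabelMap:
    """Sextant partition: base/mid/apex x left/right.

    The left/right plane is each third's own gland center of mass along the
    left–right axis; ties go left.  Exactly 6 descriptors are produced.
    """
    geom = gland.geometry
    assignment = split_thirds(gland, mode=thirds_mode)
    labels = np.zeros(geom.shape, dtype=np.int32)
    descriptors: list[SegmentDescriptor] = []
    next_id = 1
    for third in THIRDS:
        ii, jj, kk = _third_voxels(gland, assignment, third)
        x = _coords_mm(geom, 0, ii)
        cx = float(x.mean()) if len(x) else 0.0
        left = (x - cx) >= -SPLIT_EPS_MM
        for side, sel in (("left", left), ("right", ~left)):
            count = int(sel.sum())
            labels[ii[sel], jj[sel], kk[sel]] = next_id
            descriptors.append(
                SegmentDescriptor(
                    segment_id=next_id,
                    scheme=Scheme.SEG6,
                    slice_index=None,
                    third=third,
                    sector=f"{third}-{side}",
                    voxel_count=count,
                )
            )
            next_id += 1
    return SegmentLabelMap(geom, labels, descriptors, Scheme.SEG6)


def partition_18(gland: VoxelMask, thirds_mode: str = "slices") -> SegmentLabelMap:
    """18-segment partition: thirds x (left/right x 3 AP bands).

    Within each third, the left/right plane is the third's gland center of
    mass and the three anterior/middle/posterior bands have equal physical
    extent between the third's gland AP extremes.  Band boundaries assign
    to the more anterior band.  Exactly 18 descriptors, possibly empty.
    """
    geom = gland.geometry
    assignment = split_thirds(gland, mode=thirds_mode)
    labels = np.zeros(geom.shape, dtype=np.int32)
    descriptors: list[SegmentDescriptor] = []
    next_id = 1
    for third in THIRDS:
        ii, jj, kk = _third_voxels(gland, assignment, third)
        x = _coords_mm(geom, 0, ii)
        y = _coords_mm(geom, 1, jj)
        cx = float(x.mean()) if len(x) else 0.0
        left = (x - cx) >= -SPLIT_EPS_MM
        if len(y):
            ymin, ymax = float(y.min()), float(y.max())
        else:
            ymin = ymax = 0.0
        h = (ymax - ymin) / 3.0
        if h <= 0:
            band_of = np.zeros(len(ii), dtype=int)
        else:
            # band k covers (ymin + k*h, ymin + (k+1)*h]; a center exactly on
            # a boundary joins the more anterior band
            t = (y - ymin) / h
            band_of = np.clip(np.ceil(t - SPLIT_EPS_MM).astype(int) - 1, 0, 2)
        for side, side_sel in (("left", left), ("right", ~left)):
            for b, band in enumerate(AP_BANDS):
                sel = side_sel & (band_of == b)
                count = int(sel.sum())
                labels[ii[sel], jj[sel], kk[sel]] = next_id
                descriptors.append(
                    SegmentDescriptor(
                        segment_id=next_id,
                        scheme=Scheme.SEG18,
                        slice_index=None,
                        third=third,
                        sector=f"{third}-{side}-{band}",
                        voxel_count=count,
                    )
                )
                next_id += 1
    return SegmentLabelMap(geom, labels, descriptors, Scheme.SEG18)


def partition(gland: VoxelMask, scheme: Scheme | str, **kwargs) -> SegmentLabelMap:
    """Dispatch to the partitioner for ``scheme``."""
    scheme = Scheme(scheme)
    if scheme is Scheme.QUADRANT_SLICE:
        return partition_quadrants(gland, **kwargs)
    if scheme is Scheme.SEG18:
        return partition_18(gland, **kwargs)
    return partition_6(gland, **kwargs)
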