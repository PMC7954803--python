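"""Voxel-level spatial overlap between two binary masks.

The Sørensen–Dice coefficient DSC = 2|A ∩ B| / (|A| + |B|) is the
voxel-level concordance measure; intersection volumes are reported in ml.
Evaluating two empty masks is an error (the metric is undefined), and the
cohort layer records such cases as missing rather than 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError
from .mask_model import VoxelMask, _require_same_grid, volume_ml


@dataclass(frozen=True)
class OverlapResult:
    dsc: float
    intersection_ml: float
    volume_a_ml: float
    volume_b_ml: float


def intersection_volume(a: VoxelMask, b: VoxelMask) -> float:
    """Volume (ml) of the voxelwise intersection."""
    _require_same_grid(a, b)
    n = int(np.count_nonzero(a.occupancy & b.occupancy))
    return n * a.geometry.voxel_volume_mm3 / 1000.0


def dsc(a: VoxelMask, b: VoxelMask) -> float:
    """Sørensen–Dice coefficient 2|A∩B| / (|A|+|B|) by voxel counts."""
    _require_same_grid(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na + nb == 0:
        raise UndefinedMetricError(
            "DSC of two empty masks is undefined"
        )
    ni = int(np.count_nonzero(a.occupancy & b.occupancy))
    return 2.0 * ni / (na + nb)


def overlap(a: VoxelMask, b: VoxelMask) -> OverlapResult:
    """DSC plus the volumes it is built from."""
    return OverlapResult(
        dsc=dsc(a, b),
        intersection_ml=intersection_volume(a, b),
        volume_a_ml=volume_ml(a),
        volume_b_ml=volume_ml(b),
    )
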