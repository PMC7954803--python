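"""Lesion-level analysis: connected components, size, and detection.

A lesion is one coherent (connected) region of the reference mask;
spatially separated regions count as separate lesions.  Index lesions are
those with maximum 3D diameter >= 10 mm (inclusive); only they enter the
detection analysis, while test-side false positives are reported at any
size together with their diameters so a size filter can be applied
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .mask_model import ImageGeometry, VoxelMask, _require_same_grid
from .segment_scoring import PositivityRule

#: largest component size for which the pairwise brute force is used
_BRUTE_FORCE_LIMIT = 1000

DEFAULT_CONNECTIVITY = 26
INDEX_DIAMETER_MM = 10.0

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class Lesion:
    lesion_id: int
    voxel_count: int
    volume_ml: float
    max_diameter_mm: float
    centroid_mm: tuple[float, float, float]
    voxel_indices: np.ndarray = field(repr=False, default=None)  # (n, 3) int

    @property
    def is_index(self) -> bool:
        return self.max_diameter_mm >= INDEX_DIAMETER_MM


@dataclass
class LesionMatch:
    reference: Lesion
    detected: bool
    matched_test_ids: list[int]


@dataclass
class DetectionTable:
    matches: list[LesionMatch]
    false_positive_lesions: list[Lesion]

    @property
    def n_detected(self) -> int:
        return sum(m.detected for m in self.matches)

    @property
    def lesion_sensitivity(self) -> float | None:
        return self.n_detected / len(self.matches) if self.matches else None


def max_diameter(voxel_indices: np.ndarray, geometry: ImageGeometry) -> float:
    """Maximum pairwise distance (mm) between voxel centers (3D Feret).

    Exact brute force for small components; convex-hull extreme points
    otherwise (the diameter of a point set is attained on its hull).
    """
    pts = np.asarray(voxel_indices, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("max_diameter requires a nonempty (n, 3) index array")
    if pts.shape[0] == 1:
        return 0.0
    phys = pts * np.asarray(geometry.spacing)
    if phys.shape[0] > _BRUTE_FORCE_LIMIT:
        try:
            phys = phys[ConvexHull(phys).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) component: brute force
    return float(pdist(phys).max())


def label_components(
    mask: VoxelMask, connectivity: int = DEFAULT_CONNECTIVITY
) -> list[Lesion]:
    """Maximal connected components of a mask under 6/18/26 connectivity."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    labels, n = ndimage.label(mask.occupancy, structure=_STRUCTURES[connectivity])
    geom = mask.geometry
    spacing = np.asarray(geom.spacing)
    origin = np.asarray(geom.origin)
    lesions = []
    for lid in range(1, n + 1):
        idx = np.argwhere(labels == lid)
        phys = origin + idx * spacing
        lesions.append(
            Lesion(
                lesion_id=lid,
                voxel_count=idx.shape[0],
                volume_ml=idx.shape[0] * geom.voxel_volume_mm3 / 1000.0,
                max_diameter_mm=max_diameter(idx, geom),
                centroid_mm=tuple(phys.mean(axis=0)),
                voxel_indices=idx,
            )
        )
    return lesions


def filter_index(
    lesions: list[Lesion], min_diameter_mm: float = INDEX_DIAMETER_MM
) -> list[Lesion]:
    """Keep lesions with maximum diameter >= threshold (inclusive)."""
    return [l for l in lesions if l.max_diameter_mm >= min_diameter_mm]


def match_detections(
    reference_lesions: list[Lesion],
    test_mask: VoxelMask,
    rule: PositivityRule = PositivityRule(),
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> DetectionTable:
    """Match reference lesions against a test mask.

    A reference lesion is detected iff the test mask overlaps it per the
    rule; every connected component of the test mask that overlaps no
    reference lesion is reported as a false-positive lesion.
    """
    test_components = label_components(test_mask, connectivity)
    occ_test = test_mask.occupancy
    matched_test: set[int] = set()
    matches: list[LesionMatch] = []
    # per-reference-lesion overlap with the test mask as a whole decides
    # detection; per-test-component overlap decides which components matched
    for ref in reference_lesions:
        if ref.voxel_indices is None:
            raise ValueError(
                f"reference lesion {ref.lesion_id} carries no voxel indices; "
                "use lesions produced by label_components"
            )
        ii, jj, kk = ref.voxel_indices.T
        overlap = int(occ_test[ii, jj, kk].sum())
        detected = rule.is_positive(overlap, ref.voxel_count)
        ref_occ = np.zeros(test_mask.geometry.shape, dtype=bool)
        ref_occ[ii, jj, kk] = True
        ids = []
        for comp in test_components:
            ci, cj, ck = comp.voxel_indices.T
            comp_overlap = int(ref_occ[ci, cj, ck].sum())
            if comp_overlap > 0:
                ids.append(comp.lesion_id)
                matched_test.add(comp.lesion_id)
        matches.append(LesionMatch(reference=ref, detected=detected, matched_test_ids=ids))
    false_pos = [c for c in test_components if c.lesion_id not in matched_test]
    return DetectionTable(matches=matches, false_positive_lesions=false_pos)


def analyse_lesions(
    reference: VoxelMask,
    test_mask: VoxelMask,
    rule: PositivityRule = PositivityRule(),
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_diameter_mm: float = INDEX_DIAMETER_MM,
) -> DetectionTable:
    """Convenience pipeline: label the reference, match, filter to index.

    False positives are decided against *all* reference components (a test
    component overlapping a real but sub-index tumor focus is not a false
    positive); the detection table itself is restricted to index lesions.
    """
    _require_same_grid(reference, test_mask)
    ref_lesions = label_components(reference, connectivity)
    table = match_detections(ref_lesions, test_mask, rule, connectivity)
    index_matches = [
        m for m in table.matches if m.reference.max_diameter_mm >= min_diameter_mm
    ]
    return DetectionTable(
        matches=index_matches,
        false_positive_lesions=table.false_positive_lesions,
    )
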