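"""Domain types for binary voxel masks plus NIfTI I/O.

The whole pipeline operates on co-registered binary masks that live on one
shared axial voxel grid.  Internally every volume is held in a canonical
orientation: axis 0 increases toward the patient's left (L), axis 1 toward
posterior (P), axis 2 toward superior (S).  Quadrant and sector naming in
:mod:`histoconcord.partitioning` relies on these fixed anatomical axes.

Masks must already share a grid — registration and resampling happen
upstream; a grid mismatch here is an error, never a silent resample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml

from .errors import FormatError, GridMismatchError, OrientationError

CANONICAL_AXCODES: tuple[str, str, str] = ("L", "P", "S")

#: absolute tolerance (mm) for spacing/origin equality between grids
GRID_TOL_MM = 1e-3

#: relative tolerance for off-axis affine components before a volume is
#: declared oblique
OBLIQUE_RTOL = 1e-3


@dataclass(frozen=True)
class ImageGeometry:
    """Axial voxel grid: shape, physical spacing and position.

    ``origin`` is the physical position (mm) of the center of voxel
    (0, 0, 0) expressed along the internal L/P/S axes, so the center of
    voxel (i, j, k) sits at ``origin + (i*sx, j*sy, k*sz)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_codes: tuple[str, str, str] = CANONICAL_AXCODES

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be a positive mm triple, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "axis_codes", tuple(self.axis_codes))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def approx_equal(self, other: "ImageGeometry", tol: float = GRID_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and self.axis_codes == other.axis_codes
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def mismatch_field(self, other: "ImageGeometry", tol: float = GRID_TOL_MM) -> str | None:
        """Name of the first differing field, or None if grids agree."""
        if self.shape != other.shape:
            return "shape"
        if self.axis_codes != other.axis_codes:
            return "axis_codes"
        if any(abs(a - b) > tol for a, b in zip(self.spacing, other.spacing)):
            return "spacing"
        if any(abs(a - b) > tol for a, b in zip(self.origin, other.origin)):
            return "origin"
        return None


@dataclass
class VoxelMask:
    """Binary occupancy on an :class:`ImageGeometry` grid.

    ``occupancy`` is stored as a boolean array; any strictly positive source
    value counts as occupied (tolerates probability-like exports).
    """

    geometry: ImageGeometry
    occupancy: np.ndarray
    label: str = ""
    # round-trip metadata: affine and orientation transform of the source
    # file, so write_mask can restore the original on-disk axis order
    source_affine: np.ndarray | None = field(default=None, repr=False)
    source_ornt: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.shape != self.geometry.shape:
            raise ValueError(
                f"occupancy shape {occ.shape} != geometry shape {self.geometry.shape}"
            )
        self.occupancy = occ > 0 if occ.dtype != bool else occ

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.occupancy))

    def with_occupancy(self, occ: np.ndarray, label: str | None = None) -> "VoxelMask":
        return replace(
            self, occupancy=occ, label=self.label if label is None else label
        )

    def is_empty(self) -> bool:
        return not bool(self.occupancy.any())


@dataclass
class StructureSet:
    """Per-patient bundle of co-registered masks: gland, histology
    reference and one or more imaging test structures."""

    patient_id: str
    gland: VoxelMask
    reference: VoxelMask
    tests: dict[str, VoxelMask]
    examined_region: VoxelMask | None = None

    def all_masks(self) -> dict[str, VoxelMask]:
        out = {"gland": self.gland, "reference": self.reference}
        out.update(self.tests)
        if self.examined_region is not None:
            out["examined_region"] = self.examined_region
        return out


# ---------------------------------------------------------------------------
# NIfTI I/O


def _check_axis_separable(affine: np.ndarray) -> None:
    rot = affine[:3, :3]
    for j in range(3):
        col = rot[:, j]
        norm = float(np.linalg.norm(col))
        if norm == 0:
            raise OrientationError(f"affine column {j} is zero")
        dom = int(np.argmax(np.abs(col)))
        off = np.sqrt(norm**2 - col[dom] ** 2)
        if off > OBLIQUE_RTOL * norm:
            raise OrientationError(
                f"volume is oblique beyond tolerance on axis {j} "
                f"(off-axis fraction {off / norm:.3g})"
            )


def _invert_ornt(ornt: np.ndarray) -> np.ndarray:
    inv = np.empty_like(ornt)
    for new_axis, (old_axis, flip) in enumerate(ornt):
        inv[int(old_axis)] = [new_axis, flip]
    return inv


def read_mask(path: str | Path, label: str = "") -> VoxelMask:
    """Read a 3D NIfTI volume as a binary mask in canonical L/P/S order.

    Raises :class:`FormatError` for non-3D volumes and
    :class:`OrientationError` for oblique acquisitions.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float)
    _check_axis_separable(affine)

    src_ornt = nib.orientations.io_orientation(affine)
    tgt_ornt = nib.orientations.axcodes2ornt(CANONICAL_AXCODES)
    xfm = nib.orientations.ornt_transform(src_ornt, tgt_ornt)
    data_c = nib.orientations.apply_orientation(data, xfm)
    aff_c = affine @ nib.orientations.inv_ornt_aff(xfm, data.shape)

    spacing = tuple(float(abs(aff_c[i, i])) for i in range(3))
    # NIfTI affines map to RAS world coordinates; the internal frame is LPS
    # along the first two axes, so those origin components flip sign.
    t = aff_c[:3, 3]
    origin = (-float(t[0]), -float(t[1]), float(t[2]))
    geom = ImageGeometry(shape=data_c.shape, spacing=spacing, origin=origin)
    return VoxelMask(
        geometry=geom,
        occupancy=data_c > 0,
        label=label,
        source_affine=affine,
        source_ornt=xfm,
    )


def canonical_affine(geometry: ImageGeometry) -> np.ndarray:
    """RAS affine of a canonical L/P/S grid."""
    sx, sy, sz = geometry.spacing
    ox, oy, oz = geometry.origin
    aff = np.diag([-sx, -sy, sz, 1.0])
    aff[:3, 3] = (-ox, -oy, oz)
    return aff


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    """Write a mask as uint8 NIfTI.

    If the mask was read from disk, data are restored to the source file's
    axis order and affine so the round trip is voxel- and geometry-exact;
    otherwise the canonical affine is used.
    """
    data = mask.occupancy.astype(np.uint8)
    if mask.source_affine is not None and mask.source_ornt is not None:
        data = nib.orientations.apply_orientation(data, _invert_ornt(mask.source_ornt))
        affine = mask.source_affine
    else:
        affine = canonical_affine(mask.geometry)
    img = nib.Nifti1Image(data, affine)
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))


def write_labelmap(labels: np.ndarray, geometry: ImageGeometry, path: str | Path) -> None:
    """Write an integer label volume (canonical orientation) as NIfTI."""
    img = nib.Nifti1Image(labels.astype(np.int32), canonical_affine(geometry))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# grid checks and mask algebra


def assert_shared_grid(sset: StructureSet, tol: float = GRID_TOL_MM) -> StructureSet:
    """Validate that all member masks share one grid; returns the set.

    Raises :class:`GridMismatchError` naming both structures and the first
    differing geometry field.
    """
    masks = sset.all_masks()
    names = list(masks)
    ref_name = names[0]
    ref_geom = masks[ref_name].geometry
    for name in names[1:]:
        bad = ref_geom.mismatch_field(masks[name].geometry, tol=tol)
        if bad is not None:
            raise GridMismatchError(
                f"patient {sset.patient_id!r}: structures {ref_name!r} and "
                f"{name!r} differ in {bad}"
            )
    return sset


def _require_same_grid(a: VoxelMask, b: VoxelMask) -> None:
    bad = a.geometry.mismatch_field(b.geometry)
    if bad is not None:
        raise GridMismatchError(
            f"masks {a.label!r} and {b.label!r} differ in {bad}"
        )


def trim_gtv(
    gtv: VoxelMask, gland: VoxelMask, examined_region: VoxelMask | None = None
) -> VoxelMask:
    """Restrict a GTV to the gland (and, when given, to the histologically
    examined region): voxelwise intersection."""
    _require_same_grid(gtv, gland)
    occ = gtv.occupancy & gland.occupancy
    if examined_region is not None:
        _require_same_grid(gtv, examined_region)
        occ = occ & examined_region.occupancy
    return gtv.with_occupancy(occ)


def volume_ml(mask: VoxelMask) -> float:
    """Physical volume in ml: occupied voxels x voxel volume / 1000."""
    return mask.voxel_count * mask.geometry.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# manifests


def load_structure_set(manifest_path: str | Path) -> StructureSet:
    """Load a per-patient structure set from a JSON or YAML manifest.

    The manifest maps roles to NIfTI paths (relative paths resolve against
    the manifest's directory)::

        {"patient_id": "P01",
         "gland": "p01_gland.nii.gz",
         "reference": "p01_histo.nii.gz",
         "tests": {"MRI": "p01_mri.nii.gz", "PET": "p01_pet.nii.gz"},
         "examined_region": "p01_examined.nii.gz"}   # optional
    """
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text()
    if manifest_path.suffix.lower() in {".yaml", ".yml"}:
        spec: Mapping = yaml.safe_load(text)
    else:
        spec = json.loads(text)
    base = manifest_path.parent

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    missing = [k for k in ("patient_id", "gland", "reference", "tests") if k not in spec]
    if missing:
        raise FormatError(f"{manifest_path}: manifest missing fields {missing}")
    sset = StructureSet(
        patient_id=str(spec["patient_id"]),
        gland=read_mask(_resolve(spec["gland"]), label="gland"),
        reference=read_mask(_resolve(spec["reference"]), label="reference"),
        tests={
            name: read_mask(_resolve(p), label=name)
            for name, p in dict(spec["tests"]).items()
        },
        examined_region=(
            read_mask(_resolve(spec["examined_region"]), label="examined_region")
            if spec.get("examined_region")
            else None
        ),
    )
    return assert_shared_grid(sset)
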