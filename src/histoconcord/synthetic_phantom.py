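"""Seeded synthetic phantom cohort with analytically known ground truth.

No public dataset exists for co-registered histology/imaging prostate
masks, so the phantom emulates the geometry and statistical structure of a
small prostatectomy cohort: an ellipsoidal gland of ~20-60 ml, 1-3
ellipsoidal intraprostatic lesions per patient (some crossing the 1 cm
index-lesion diameter threshold), and per-modality imaging GTVs derived
from the histology reference by controlled erosion/dilation, small rigid
translation, optional deletion of lesions and optional false-positive
lesions.  An erosive modality (MRI-like) is systematically smaller than
the reference and produces segment-level misses; a mildly dilative one
(PET-like) is similar or larger and occasionally adds a false lesion.

All primitives are ellipsoids so that per-lesion volumes and diameters
are known by construction; ground-truth segment positivity and confusion
counts are computed at generation time with the independent per-voxel
classifiers in :mod:`histoconcord._bruteforce`, never with the scoring
pipeline under test.  Everything is a pure function of the spec and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._bruteforce import confusion_bruteforce
from .errors import ExtentError, PhantomSpecError
from .mask_model import ImageGeometry, StructureSet, VoxelMask, trim_gtv
from .partitioning import Scheme

DEFAULT_GEOMETRY = ImageGeometry(shape=(96, 96, 40), spacing=(1.0, 1.0, 2.0))

#: coarse grid for fast test profiles
FAST_GEOMETRY = ImageGeometry(shape=(48, 48, 24), spacing=(2.0, 2.0, 4.0))


@dataclass(frozen=True)
class LesionSpec:
    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]

    @property
    def analytic_volume_ml(self) -> float:
        a, b, c = self.semiaxes_mm
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0

    @property
    def analytic_diameter_mm(self) -> float:
        return 2.0 * max(self.semiaxes_mm)


@dataclass(frozen=True)
class DeviationSpec:
    """How an imaging modality's GTV deviates from the histology reference."""

    erode_mm: float = 0.0
    dilate_mm: float = 0.0
    translate_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    miss_lesion_ids: tuple[int, ...] = ()
    false_lesions: tuple[LesionSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.erode_mm and self.dilate_mm:
            raise PhantomSpecError("specify erosion or dilation, not both")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one synthetic patient."""

    geometry: ImageGeometry
    gland_center_mm: tuple[float, float, float]
    gland_semiaxes_mm: tuple[float, float, float]
    lesions: tuple[LesionSpec, ...]
    deviations: dict[str, DeviationSpec] = field(default_factory=dict)
    seed: int = 0
    whole_gland_reference: bool = False


@dataclass
class TruthLesion:
    lesion_id: int
    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]
    analytic_volume_ml: float
    analytic_diameter_mm: float
    voxel_count: int
    voxel_volume_ml: float
    feret_diameter_mm: float       # exact Feret of the voxelized lesion
    is_index: bool
    merged_with: tuple[int, ...] = ()
    detected_by: dict[str, bool] = field(default_factory=dict)


@dataclass
class PhantomTruth:
    """Ground truth computed at generation time, by construction."""

    patient_id: str
    lesions: list[TruthLesion]
    false_positive_counts: dict[str, int]
    # (scheme, modality) -> {"tp","fp","tn","fn","n_segments",...}
    confusion: dict[tuple[str, str], dict]
    # scheme -> {segment_name: bool}
    reference_positivity: dict[str, dict[str, bool]]

    def index_lesion_ids(self) -> list[int]:
        return [l.lesion_id for l in self.lesions if l.is_index]


# ---------------------------------------------------------------------------
# geometric primitives


def _ellipsoid_occ(
    geometry: ImageGeometry,
    center_mm: tuple[float, float, float],
    semiaxes_mm: tuple[float, float, float],
) -> np.ndarray:
    x = geometry.axis_coords(0)
    y = geometry.axis_coords(1)
    z = geometry.axis_coords(2)
    a, b, c = semiaxes_mm
    cx, cy, cz = center_mm
    u = ((x - cx) / a) ** 2
    v = ((y - cy) / b) ** 2
    w = ((z - cz) / c) ** 2
    return (u[:, None, None] + v[None, :, None] + w[None, None, :]) <= 1.0


def make_gland(spec: PhantomSpec) -> VoxelMask:
    """Ellipsoidal gland mask; raises ExtentError if it exceeds the grid."""
    geom = spec.geometry
    for axis in range(3):
        lo = spec.gland_center_mm[axis] - spec.gland_semiaxes_mm[axis]
        hi = spec.gland_center_mm[axis] + spec.gland_semiaxes_mm[axis]
        coords = geom.axis_coords(axis)
        if lo < coords[0] - geom.spacing[axis] / 2 or hi > coords[-1] + geom.spacing[axis] / 2:
            raise ExtentError(
                f"gland ellipsoid exceeds the grid along axis {axis} "
                f"([{lo:.1f}, {hi:.1f}] mm)"
            )
    occ = _ellipsoid_occ(geom, spec.gland_center_mm, spec.gland_semiaxes_mm)
    if not occ.any():
        # sub-voxel ellipsoid: keep the voxel nearest to the center
        nearest = tuple(
            int(np.clip(round((spec.gland_center_mm[i] - geom.origin[i]) / geom.spacing[i]),
                        0, geom.shape[i] - 1))
            for i in range(3)
        )
        occ[nearest] = True
    return VoxelMask(geometry=geom, occupancy=occ, label="gland")


def _feret_exact(occ: np.ndarray, geometry: ImageGeometry) -> float:
    idx = np.argwhere(occ).astype(float)
    if idx.shape[0] <= 1:
        return 0.0
    phys = idx * np.asarray(geometry.spacing)
    # direct pairwise max via broadcasting in chunks
    best = 0.0
    for start in range(0, phys.shape[0], 512):
        chunk = phys[start : start + 512]
        d2 = ((chunk[:, None, :] - phys[None, :, :]) ** 2).sum(axis=2)
        best = max(best, float(d2.max()))
    return float(np.sqrt(best))


def make_lesions(spec: PhantomSpec) -> tuple[VoxelMask, list[TruthLesion], list[np.ndarray]]:
    """Rasterize all lesions, clipped to the gland.

    Returns the union reference mask, per-lesion truth records and the
    per-lesion boolean occupancy arrays (clipped).  Overlapping lesion
    specs are flagged as merged in the truth (they form one connected
    component downstream).
    """
    gland = make_gland(spec)
    geom = spec.geometry
    if spec.whole_gland_reference:
        truth = TruthLesion(
            lesion_id=1,
            center_mm=spec.gland_center_mm,
            semiaxes_mm=spec.gland_semiaxes_mm,
            analytic_volume_ml=4 / 3 * np.pi * np.prod(spec.gland_semiaxes_mm) / 1000.0,
            analytic_diameter_mm=2.0 * max(spec.gland_semiaxes_mm),
            voxel_count=gland.voxel_count,
            voxel_volume_ml=gland.voxel_count * geom.voxel_volume_mm3 / 1000.0,
            feret_diameter_mm=_feret_exact(gland.occupancy, geom),
            is_index=True,
        )
        ref = gland.with_occupancy(gland.occupancy.copy(), label="reference")
        return ref, [truth], [gland.occupancy.copy()]

    per_lesion: list[np.ndarray] = []
    truths: list[TruthLesion] = []
    for lid, lesion in enumerate(spec.lesions, start=1):
        # center must lie inside the gland ellipsoid
        rho = sum(
            ((lesion.center_mm[i] - spec.gland_center_mm[i]) / spec.gland_semiaxes_mm[i]) ** 2
            for i in range(3)
        )
        if rho > 1.0:
            raise PhantomSpecError(
                f"lesion {lid} center {lesion.center_mm} lies outside the gland"
            )
        occ = _ellipsoid_occ(geom, lesion.center_mm, lesion.semiaxes_mm) & gland.occupancy
        per_lesion.append(occ)
        truths.append(
            TruthLesion(
                lesion_id=lid,
                center_mm=lesion.center_mm,
                semiaxes_mm=lesion.semiaxes_mm,
                analytic_volume_ml=lesion.analytic_volume_ml,
                analytic_diameter_mm=lesion.analytic_diameter_mm,
                voxel_count=int(occ.sum()),
                voxel_volume_ml=int(occ.sum()) * geom.voxel_volume_mm3 / 1000.0,
                feret_diameter_mm=_feret_exact(occ, geom),
                is_index=lesion.analytic_diameter_mm >= 10.0,
            )
        )
    # flag overlapping spec pairs as merged
    for i in range(len(per_lesion)):
        merged = tuple(
            truths[j].lesion_id
            for j in range(len(per_lesion))
            if j != i and (per_lesion[i] & per_lesion[j]).any()
        )
        truths[i].merged_with = merged
    union = np.zeros(geom.shape, dtype=bool)
    for occ in per_lesion:
        union |= occ
    ref = VoxelMask(geometry=geom, occupancy=union, label="reference")
    return ref, truths, per_lesion


# ---------------------------------------------------------------------------
# modality derivation


def _erode_metric(occ: np.ndarray, geometry: ImageGeometry, r_mm: float) -> np.ndarray:
    if not occ.any() or r_mm <= 0:
        return occ.copy()
    dist_in = ndimage.distance_transform_edt(occ, sampling=geometry.spacing)
    return dist_in > r_mm


def _dilate_metric(occ: np.ndarray, geometry: ImageGeometry, r_mm: float) -> np.ndarray:
    if r_mm <= 0:
        return occ.copy()
    if not occ.any():
        return occ.copy()
    dist_out = ndimage.distance_transform_edt(~occ, sampling=geometry.spacing)
    return occ | (dist_out <= r_mm)


def _translate(occ: np.ndarray, shift_vox: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros_like(occ)
    src = []
    dst = []
    for axis, s in enumerate(shift_vox):
        n = occ.shape[axis]
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = occ[tuple(src)]
    return out


def derive_imaging_gtv(
    reference: VoxelMask,
    deviation: DeviationSpec,
    gland: VoxelMask,
    per_lesion: list[np.ndarray] | None = None,
    label: str = "test",
) -> VoxelMask:
    """Derive an imaging GTV from the histology reference.

    Per lesion: metric erosion or dilation, then a rigid translation
    (rounded to whole voxels), deletion of "missed" lesions, addition of
    false lesions; the result is trimmed to the gland.  With a zero
    deviation the output equals the reference.  If erosion annihilates a
    lesion that was not meant to be missed, a warning is emitted.
    """
    geom = reference.geometry
    if per_lesion is None:
        labels, n = ndimage.label(
            reference.occupancy, structure=ndimage.generate_binary_structure(3, 3)
        )
        per_lesion = [labels == lid for lid in range(1, n + 1)]
    shift_vox = tuple(
        int(round(deviation.translate_mm[axis] / geom.spacing[axis])) for axis in range(3)
    )
    out = np.zeros(geom.shape, dtype=bool)
    for lid, occ in enumerate(per_lesion, start=1):
        if lid in deviation.miss_lesion_ids:
            continue
        if deviation.erode_mm > 0:
            occ2 = _erode_metric(occ, geom, deviation.erode_mm)
            if occ.any() and not occ2.any():
                warnings.warn(
                    f"erosion by {deviation.erode_mm} mm annihilated lesion {lid}"
                )
        elif deviation.dilate_mm > 0:
            occ2 = _dilate_metric(occ, geom, deviation.dilate_mm)
        else:
            occ2 = occ.copy()
        out |= _translate(occ2, shift_vox)
    for false_spec in deviation.false_lesions:
        out |= _ellipsoid_occ(geom, false_spec.center_mm, false_spec.semiaxes_mm)
    mask = VoxelMask(geometry=geom, occupancy=out, label=label)
    return trim_gtv(mask, gland)


# ---------------------------------------------------------------------------
# cohort generation

DEFAULT_DEVIATION_PROFILES = {
    # erosive modality: systematically smaller than histology, segment misses
    "MRI-like": {"erode_mm": 1.5, "max_translate_mm": 1.5, "false_lesion_prob": 0.0},
    # mildly dilative modality: similar/larger volume, occasional false lesion
    "PET-like": {"dilate_mm": 1.0, "max_translate_mm": 1.5, "false_lesion_prob": 0.4},
}

#: deviation designed to produce partial segment-level misses: boundary
#: erosion plus a through-plane shift of up to 1.5 section steps, the
#: dominant error mode when step-section histology is registered to axial
#: imaging.  ``max_translate_mm`` may be a per-axis triple.
PARTIAL_MISS_PROFILES = {
    "eroded-shifted": {"erode_mm": 2.0, "max_translate_mm": (1.0, 1.0, 6.0)},
    "dilated": {"dilate_mm": 1.0, "max_translate_mm": 1.5},
}

SCHEMES = (Scheme.QUADRANT_SLICE, Scheme.SEG18, Scheme.SEG6)


def _sample_patient_spec(
    rng: np.random.Generator,
    geometry: ImageGeometry,
    seed: int,
    whole_gland_reference: bool = False,
) -> PhantomSpec:
    extent = tuple(
        geometry.origin[i] + (geometry.shape[i] - 1) * geometry.spacing[i] for i in range(3)
    )
    center = tuple(round((extent[i]) / 2.0 / geometry.spacing[i]) * geometry.spacing[i] for i in range(3))
    # gland semi-axes (mm): LR / AP / SI, resampled into the 20-60 ml band
    for _ in range(200):
        g = (
            float(rng.uniform(19.0, 27.0)),
            float(rng.uniform(15.0, 20.0)),
            float(rng.uniform(17.0, 26.0)),
        )
        vol = 4.0 / 3.0 * np.pi * g[0] * g[1] * g[2] / 1000.0
        if 20.0 <= vol <= 60.0:
            # must fit the grid
            if all(
                center[i] - g[i] >= geometry.origin[i]
                and center[i] + g[i] <= extent[i]
                for i in range(3)
            ):
                break
    gland_semi = g

    if whole_gland_reference:
        return PhantomSpec(
            geometry=geometry,
            gland_center_mm=center,
            gland_semiaxes_mm=gland_semi,
            lesions=(),
            seed=seed,
            whole_gland_reference=True,
        )

    n_lesions = int(rng.integers(1, 4))
    lesions: list[LesionSpec] = []
    for li in range(n_lesions):
        is_index = li == 0 or rng.random() < 0.35
        placed = False
        for attempt in range(300):
            shrink = 0.85 ** (attempt // 100)
            if is_index:
                u = float(rng.uniform(7.0, 10.5)) * shrink
                factors = rng.uniform(0.65, 0.9, size=2)
            else:
                u = float(rng.uniform(4.3, 4.95)) * shrink
                factors = rng.uniform(0.9, 1.0, size=2)
            semis = np.array([u, u * factors[0], u * factors[1]])
            rng.shuffle(semis)
            semis = tuple(float(s) for s in semis)
            # containment: in gland-normalized coordinates the lesion lies in
            # a ball of radius max(a_i/g_i) around its center
            slack = 0.95 - max(semis[i] / gland_semi[i] for i in range(3))
            if slack <= 0.02:
                continue
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = float(rng.uniform(0.0, slack))
            c = tuple(
                center[i] + radius * direction[i] * gland_semi[i] for i in range(3)
            )
            # pairwise disjointness with a safety margin (deviations included)
            ok = all(
                np.linalg.norm(np.subtract(c, prev.center_mm))
                > max(semis) + max(prev.semiaxes_mm) + 4.0
                for prev in lesions
            )
            if ok:
                lesions.append(LesionSpec(center_mm=c, semiaxes_mm=semis))
                placed = True
                break
        if not placed and li == 0:
            # central fallback for the mandatory index lesion
            lesions.append(
                LesionSpec(center_mm=center, semiaxes_mm=(7.0, 5.0, 5.0))
            )
    return PhantomSpec(
        geometry=geometry,
        gland_center_mm=center,
        gland_semiaxes_mm=gland_semi,
        lesions=tuple(lesions),
        seed=seed,
    )


def _sample_deviation(
    rng: np.random.Generator,
    profile: dict,
    spec: PhantomSpec,
    gland: VoxelMask,
) -> DeviationSpec:
    t_max = profile.get("max_translate_mm", 0.0)
    if np.isscalar(t_max):
        t_max = (t_max, t_max, t_max)
    translate = tuple(float(rng.uniform(-t_max[i], t_max[i])) for i in range(3))
    false_lesions: tuple[LesionSpec, ...] = ()
    if rng.random() < profile.get("false_lesion_prob", 0.0) and not spec.whole_gland_reference:
        # a small false lesion inside the gland, well away from true lesions
        for _ in range(300):
            u = float(rng.uniform(3.0, 4.5))
            slack = 0.9 - max(u / g for g in spec.gland_semiaxes_mm)
            if slack <= 0.02:
                break
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = float(rng.uniform(0.3 * slack, slack))
            c = tuple(
                spec.gland_center_mm[i] + radius * direction[i] * spec.gland_semiaxes_mm[i]
                for i in range(3)
            )
            far = all(
                np.linalg.norm(np.subtract(c, l.center_mm))
                > u + max(l.semiaxes_mm) + 8.0
                for l in spec.lesions
            )
            if far:
                false_lesions = (LesionSpec(center_mm=c, semiaxes_mm=(u, u, u)),)
                break
    return DeviationSpec(
        erode_mm=float(profile.get("erode_mm", 0.0)),
        dilate_mm=float(profile.get("dilate_mm", 0.0)),
        translate_mm=translate,
        false_lesions=false_lesions,
    )


def _compute_truth(
    patient_id: str,
    gland: VoxelMask,
    reference: VoxelMask,
    tests: dict[str, VoxelMask],
    truths: list[TruthLesion],
    per_lesion: list[np.ndarray],
    deviations: dict[str, DeviationSpec],
) -> PhantomTruth:
    # lesion detectability per modality: any-overlap, by direct voxel count
    for t, occ in zip(truths, per_lesion):
        t.detected_by = {
            name: bool((occ & mask.occupancy).any()) for name, mask in tests.items()
        }
    false_counts = {}
    for name, dev in deviations.items():
        n_fp = 0
        for fspec in dev.false_lesions:
            focc = _ellipsoid_occ(gland.geometry, fspec.center_mm, fspec.semiaxes_mm)
            focc &= gland.occupancy
            if focc.any() and not (focc & reference.occupancy).any():
                n_fp += 1
        false_counts[name] = n_fp

    confusion: dict[tuple[str, str], dict] = {}
    ref_positivity: dict[str, dict[str, bool]] = {}
    for scheme in SCHEMES:
        for name, mask in tests.items():
            result = confusion_bruteforce(gland, reference, mask, scheme)
            confusion[(scheme.value, name)] = {
                k: result[k] for k in ("tp", "fp", "tn", "fn", "n_segments")
            }
            ref_positivity[scheme.value] = result["ref_positive"]
    return PhantomTruth(
        patient_id=patient_id,
        lesions=truths,
        false_positive_counts=false_counts,
        confusion=confusion,
        reference_positivity=ref_positivity,
    )


def generate_patient(
    spec: PhantomSpec,
    deviations: dict[str, DeviationSpec],
    patient_id: str,
    compute_truth: bool = True,
) -> tuple[StructureSet, PhantomTruth | None]:
    """Build one patient's structure set (and optionally its ground truth)."""
    gland = make_gland(spec)
    reference, truths, per_lesion = make_lesions(spec)
    tests = {
        name: derive_imaging_gtv(reference, dev, gland, per_lesion, label=name)
        for name, dev in deviations.items()
    }
    sset = StructureSet(
        patient_id=patient_id, gland=gland, reference=reference, tests=tests
    )
    truth = (
        _compute_truth(patient_id, gland, reference, tests, truths, per_lesion, deviations)
        if compute_truth
        else None
    )
    return sset, truth


def generate_cohort(
    n_patients: int = 10,
    master_seed: int = 0,
    geometry: ImageGeometry = DEFAULT_GEOMETRY,
    deviation_profiles: dict[str, dict] | None = None,
    whole_gland_patient_index: int | None = None,
    compute_truth: bool = True,
) -> list[tuple[StructureSet, PhantomTruth | None]]:
    """Generate a cohort of seeded phantom patients.

    Child seeds derive deterministically from ``master_seed`` via
    ``numpy.random.SeedSequence.spawn``, so regeneration with the same
    master seed is bit-identical.  ``whole_gland_patient_index`` makes one
    patient's reference cover the entire gland, which renders specificity
    undefined in coarse schemes.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    profiles = (
        DEFAULT_DEVIATION_PROFILES if deviation_profiles is None else deviation_profiles
    )
    children = np.random.SeedSequence(master_seed).spawn(n_patients)
    cohort = []
    for p, child in enumerate(children):
        rng = np.random.default_rng(child)
        patient_id = f"PH{p + 1:02d}"
        spec = _sample_patient_spec(
            rng,
            geometry,
            seed=master_seed,
            whole_gland_reference=(p == whole_gland_patient_index),
        )
        gland = make_gland(spec)
        deviations = {
            name: _sample_deviation(rng, profile, spec, gland)
            for name, profile in profiles.items()
        }
        cohort.append(
            generate_patient(spec, deviations, patient_id, compute_truth=compute_truth)
        )
    return cohort
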