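"""Independent brute-force per-voxel classifiers and scorers.

These deliberately naive implementations (explicit per-voxel loops, no
shared code with :mod:`histoconcord.partitioning` or
:mod:`histoconcord.segment_scoring`) serve two purposes: the synthetic
phantom uses them to compute ground-truth confusion counts at generation
time, and the test suite uses them as an independent oracle against the
vectorized pipeline.  They implement the same documented conventions:
centroid splits, ties to left/anterior, thirds with remainder to mid then
base.
"""

from __future__ import annotations

import numpy as np

from .mask_model import VoxelMask
from .partitioning import Scheme

_EPS = 1e-9


def _thirds_of_slices(slices: list[int]) -> dict[int, str]:
    n = len(slices)
    q, r = divmod(n, 3)
    n_base = q + (1 if r == 2 else 0)
    n_mid = q + (1 if r >= 1 else 0)
    out = {}
    for i, k in enumerate(slices):  # slices ascend inferior -> superior
        if i < n - n_base - n_mid:
            out[k] = "apex"
        elif i < n - n_base:
            out[k] = "mid"
        else:
            out[k] = "base"
    return out


def classify_voxels(gland: VoxelMask, scheme: Scheme) -> dict[tuple, str]:
    """Map every gland voxel (i, j, k) to its named segment.

    Segment names: ``"s{k}:{quadrant}"`` for QUADRANT_SLICE, the sector
    string (e.g. ``"mid-left-anterior"``, ``"base-right"``) otherwise.
    """
    geom = gland.geometry
    sx, sy, _ = geom.spacing
    ox, oy, _ = geom.origin
    occ = gland.occupancy
    voxels = [tuple(v) for v in np.argwhere(occ)]
    slices = sorted({k for _, _, k in voxels})
    out: dict[tuple, str] = {}

    if scheme is Scheme.QUADRANT_SLICE:
        for k in slices:
            vox_k = [(i, j) for i, j, kk in voxels if kk == k]
            xs = [ox + i * sx for i, _ in vox_k]
            ys = [oy + j * sy for _, j in vox_k]
            cx = float(np.mean(xs))
            cy = float(np.mean(ys))
            for (i, j), x, y in zip(vox_k, xs, ys):
                left = (x - cx) >= -_EPS
                anterior = (y - cy) <= _EPS
                side = "left" if left else "right"
                ap = "anterior" if anterior else "posterior"
                out[(i, j, k)] = f"s{k}:{side}-{ap}"
        return out

    thirds = _thirds_of_slices(slices)
    for third in ("base", "mid", "apex"):
        vox_t = [(i, j, k) for i, j, k in voxels if thirds[k] == third]
        if not vox_t:
            continue
        xs = [ox + i * sx for i, _, _ in vox_t]
        ys = [oy + j * sy for _, j, _ in vox_t]
        cx = float(np.mean(xs))
        if scheme is Scheme.SEG6:
            for (i, j, k), x in zip(vox_t, xs):
                side = "left" if (x - cx) >= -_EPS else "right"
                out[(i, j, k)] = f"{third}-{side}"
        else:  # SEG18
            ymin, ymax = min(ys), max(ys)
            h = (ymax - ymin) / 3.0
            for (i, j, k), x, y in zip(vox_t, xs, ys):
                side = "left" if (x - cx) >= -_EPS else "right"
                if h <= 0:
                    band = "anterior"
                else:
                    t = (y - ymin) / h
                    b = min(2, max(0, int(np.ceil(t - _EPS)) - 1))
                    band = ("anterior", "middle", "posterior")[b]
                out[(i, j, k)] = f"{third}-{side}-{band}"
    return out


def confusion_bruteforce(
    gland: VoxelMask,
    reference: VoxelMask,
    test: VoxelMask,
    scheme: Scheme,
    min_overlap_voxels: int = 1,
    min_overlap_fraction: float = 0.0,
) -> dict:
    """Double-loop confusion counts over named segments.

    Returns ``{"tp", "fp", "tn", "fn", "n_segments", "ref_positive",
    "test_positive"}`` where the last two map segment name -> bool.
    """
    assignment = classify_voxels(gland, scheme)
    segments: dict[str, list[tuple]] = {}
    for voxel, name in assignment.items():
        segments.setdefault(name, []).append(voxel)

    ref_occ, test_occ = reference.occupancy, test.occupancy
    ref_pos: dict[str, bool] = {}
    test_pos: dict[str, bool] = {}
    for name, voxel_list in segments.items():
        n_seg = len(voxel_list)
        n_ref = sum(1 for i, j, k in voxel_list if ref_occ[i, j, k])
        n_test = sum(1 for i, j, k in voxel_list if test_occ[i, j, k])
        ref_pos[name] = (
            n_ref >= min_overlap_voxels and n_ref >= min_overlap_fraction * n_seg
        )
        test_pos[name] = (
            n_test >= min_overlap_voxels and n_test >= min_overlap_fraction * n_seg
        )

    tp = sum(1 for s in segments if ref_pos[s] and test_pos[s])
    fn = sum(1 for s in segments if ref_pos[s] and not test_pos[s])
    fp = sum(1 for s in segments if not ref_pos[s] and test_pos[s])
    tn = sum(1 for s in segments if not ref_pos[s] and not test_pos[s])
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "n_segments": len(segments),
        "ref_positive": ref_pos,
        "test_positive": test_pos,
    }


def flood_fill_components(occ: np.ndarray, connectivity: int = 26) -> list[set]:
    """Connected components by explicit stack-based flood fill."""
    if connectivity == 6:
        offsets = [
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
        ]
    else:
        offsets = [
            (di, dj, dk)
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
            for dk in (-1, 0, 1)
            if (di, dj, dk) != (0, 0, 0)
            and (connectivity == 26 or abs(di) + abs(dj) + abs(dk) <= 2)
        ]
    remaining = {tuple(v) for v in np.argwhere(occ)}
    shape = occ.shape
    components = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        stack = [seed]
        while stack:
            i, j, k = stack.pop()
            for di, dj, dk in offsets:
                nb = (i + di, j + dj, k + dk)
                if (
                    0 <= nb[0] < shape[0]
                    and 0 <= nb[1] < shape[1]
                    and 0 <= nb[2] < shape[2]
                    and nb in remaining
                ):
                    remaining.remove(nb)
                    comp.add(nb)
                    stack.append(nb)
        components.append(comp)
    return components
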