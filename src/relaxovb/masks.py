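"""Mask construction and lesion bookkeeping.

Implements the segmentation and mask-hygiene rules of the analysis: seeded
k-nearest-neighbour lesion segmentation, the three-consecutive-slice
persistence filter, the periventricular NAWM reference band, ventricular
CSF ROIs restricted to pure-CSF voxels, and inter-rater overlap metrics.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from sklearn.neighbors import KNeighborsClassifier

from .volumes import VolumeMap

__all__ = [
    "knn_segment",
    "consensus_mask",
    "persistence_filter",
    "nawm_band_mask",
    "mask_overlap",
    "csf_roi",
]


def knn_segment(intensity: VolumeMap, seeds, background_seeds, k: int = 5,
                candidate_mask: VolumeMap | None = None,
                spatial_weight: float = 0.02) -> VolumeMap:
    """Binary lesion mask by seeded k-nearest-neighbour classification.

    Each candidate voxel is assigned the majority class of its ``k`` nearest
    seed voxels in a feature space of normalised intensity plus spatial
    coordinates (mm, scaled by ``spatial_weight`` relative to one intensity
    standard deviation).  Deterministic given the inputs and invariant to
    seed ordering.

    Parameters
    ----------
    intensity : VolumeMap
        FLAIR-like intensity image.
    seeds, background_seeds : sequence of (x, y, z) voxel indices
        Manually placed lesion and background seed points.
    k : int
        Number of neighbours; must be odd so majority vote is unambiguous.
    candidate_mask : VolumeMap, optional
        Voxels to classify (default: all voxels).
    """
    seeds = [tuple(int(i) for i in s) for s in seeds]
    background_seeds = [tuple(int(i) for i in s) for s in background_seeds]
    if not seeds or not background_seeds:
        raise ValueError("need at least one lesion seed and one background seed")
    if k % 2 == 0:
        raise ValueError("k must be odd")

    img = np.asarray(intensity.values, dtype=float)
    vx = np.asarray(intensity.voxel_size_mm)
    scale = img.std()
    if scale == 0:
        scale = 1.0

    def features(idx):
        idx = np.asarray(idx)
        return np.column_stack([
            img[tuple(idx.astype(int).T)] / scale,
            idx.astype(float) * vx * spatial_weight,
        ])

    all_seeds = sorted(set(seeds) | set(background_seeds))
    labels = np.array([1 if s in set(seeds) else 0 for s in all_seeds])
    X = features(all_seeds)
    clf = KNeighborsClassifier(n_neighbors=min(k, len(all_seeds)))
    clf.fit(X, labels)

    if candidate_mask is not None:
        intensity.require_same_grid(candidate_mask, "candidate mask")
        cand = np.asarray(candidate_mask.values, dtype=bool)
    else:
        cand = np.ones(img.shape, dtype=bool)
    idx = np.argwhere(cand)
    pred = np.zeros(img.shape, dtype=bool)
    if idx.size:
        pred[tuple(idx.T)] = clf.predict(features(idx)).astype(bool)
    return VolumeMap(pred, intensity.voxel_size_mm, {"kind": "mask"})


def consensus_mask(a: VolumeMap, b: VolumeMap) -> VolumeMap:
    """Voxels selected by both raters (intersection of two binary masks)."""
    a.require_same_grid(b, "mask")
    return VolumeMap(np.asarray(a.values, bool) & np.asarray(b.values, bool),
                     a.voxel_size_mm, {"kind": "mask"})


def persistence_filter(mask: VolumeMap) -> VolumeMap:
    """Drop lesion components that do not span 3 consecutive slices in all
    three orientations.

    A connected component (26-connectivity) is retained only if, along each
    of the x, y and z axes, it occupies at least three consecutive slices.
    Idempotent.
    """
    m = np.asarray(mask.values, dtype=bool)
    lab, n = ndimage.label(m, structure=np.ones((3, 3, 3), dtype=bool))
    keep = np.zeros(n + 1, dtype=bool)
    slices = ndimage.find_objects(lab)
    for comp in range(1, n + 1):
        sl = slices[comp - 1]
        comp_mask = lab[sl] == comp
        ok = True
        for ax in range(3):
            other = tuple(a for a in range(3) if a != ax)
            occupied = comp_mask.any(axis=other)
            if _max_consecutive_run(occupied) < 3:
                ok = False
                break
        keep[comp] = ok
    return VolumeMap(keep[lab], mask.voxel_size_mm, {"kind": "mask"})


def _max_consecutive_run(occupied: np.ndarray) -> int:
    best = run = 0
    for v in occupied:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def nawm_band_mask(wm_mask: VolumeMap, ventricle_mask: VolumeMap,
                   distance_mm: float = 15.0, tolerance_mm: float = 3.0,
                   wmh_mask: VolumeMap | None = None,
                   method: str = "column") -> VolumeMap:
    """Reference NAWM band above the superior ventricular surface.

    Selects WM voxels whose distance above the superior surface of the
    lateral ventricles lies in [distance - tolerance, distance + tolerance]
    mm, excluding lesion voxels.  ``method='column'`` measures distance along
    +z from the topmost ventricle voxel in each (x, y) column;
    ``method='euclidean'`` uses the full 3-D distance to the ventricle.
    """
    wm_mask.require_same_grid(ventricle_mask, "ventricle mask")
    vent = np.asarray(ventricle_mask.values, dtype=bool)
    if not vent.any():
        raise ValueError("ventricle mask is empty")
    wm = np.asarray(wm_mask.values, dtype=bool)
    vz = wm_mask.voxel_size_mm[2]
    lo, hi = distance_mm - tolerance_mm, distance_mm + tolerance_mm

    if method == "column":
        nz = vent.shape[2]
        zidx = np.arange(nz)
        has = vent.any(axis=2)
        top = np.where(has, (vent * zidx[None, None, :]).max(axis=2), -1)
        dz_mm = (zidx[None, None, :] - top[:, :, None]) * vz
        band = has[:, :, None] & (dz_mm >= lo) & (dz_mm <= hi)
    elif method == "euclidean":
        dist = ndimage.distance_transform_edt(~vent, sampling=wm_mask.voxel_size_mm)
        band = (dist >= lo) & (dist <= hi)
        # keep only voxels above the ventricle top
        ztop = np.max(np.argwhere(vent)[:, 2])
        band[:, :, : int(ztop)] = False
    else:
        raise ValueError(f"unknown method {method!r}")

    band &= wm
    if wmh_mask is not None:
        wm_mask.require_same_grid(wmh_mask, "WMH mask")
        band &= ~np.asarray(wmh_mask.values, dtype=bool)
    return VolumeMap(band, wm_mask.voxel_size_mm, {"kind": "mask"})


def mask_overlap(a: VolumeMap, b: VolumeMap, metric: str = "jaccard") -> float:
    """Pixel overlap of two binary masks, in percent.

    Jaccard (default): 100 * |a & b| / |a | b|.  Dice available via
    ``metric='dice'``.  Two empty masks overlap perfectly (100%).
    """
    a.require_same_grid(b, "mask")
    am = np.asarray(a.values, dtype=bool)
    bm = np.asarray(b.values, dtype=bool)
    inter = np.count_nonzero(am & bm)
    if metric == "jaccard":
        union = np.count_nonzero(am | bm)
        return 100.0 if union == 0 else 100.0 * inter / union
    if metric == "dice":
        tot = np.count_nonzero(am) + np.count_nonzero(bm)
        return 100.0 if tot == 0 else 200.0 * inter / tot
    raise ValueError(f"unknown metric {metric!r}")


def csf_roi(ventricle_mask: VolumeMap, csf_pve: VolumeMap, side: str = "left",
            target_volume_ul: float = 16.0) -> np.ndarray:
    """Posterior-horn ventricular ROI of pure-CSF voxels.

    Restricts to the requested lateral half (``side``: 'left' = lower x) and
    the posterior half (larger y) of the ventricle, keeps only voxels with a
    fractional CSF volume of 1 (within 1e-6) to avoid partial-volume
    contamination, ranks them by distance from tissue interfaces, and
    returns voxel indices up to the target ROI volume.

    Returns an (n, 3) integer index array.
    """
    ventricle_mask.require_same_grid(csf_pve, "CSF PVE map")
    vent = np.asarray(ventricle_mask.values, dtype=bool)
    pve = np.asarray(csf_pve.values, dtype=float)
    if np.any(pve < -1e-9) or np.any(pve > 1 + 1e-9):
        raise ValueError("PVE values must lie in [0, 1]")
    pure = vent & (pve >= 1.0 - 1e-6)
    if not pure.any():
        raise ValueError("no pure-CSF voxels available (partial-volume failure)")

    nx, ny = vent.shape[0], vent.shape[1]
    xs = np.argwhere(vent)
    x_mid = xs[:, 0].mean()
    y_mid = xs[:, 1].mean()
    xg = np.arange(nx)[:, None, None]
    yg = np.arange(ny)[None, :, None]
    half = xg < x_mid if side == "left" else xg > x_mid
    region = pure & half & (yg > y_mid)
    if not region.any():
        raise ValueError(f"no pure-CSF voxels in the {side} posterior horn")

    # prefer voxels deep inside the CSF, far from tissue interfaces
    dist = ndimage.distance_transform_edt(pure, sampling=ventricle_mask.voxel_size_mm)
    idx = np.argwhere(region)
    order = np.argsort(-dist[tuple(idx.T)], kind="stable")
    n_target = max(1, int(round(target_volume_ul / ventricle_mask.voxel_volume_ul)))
    if n_target > len(idx):
        warnings.warn("posterior horn smaller than the target ROI volume")
        n_target = len(idx)
    return idx[order[:n_target]]
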