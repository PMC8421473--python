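"""Master-VOI threshold segmentation of myocardial uptake and the CT/sphere
reference regions.

The myocardial workflow: an operator-drawn master VOI of the left ventricle
(wall plus lumen, contoured on CT) is projected onto the co-registered SPECT
SUV volume; SUVmax is detected within it; voxels at or above a fraction f of
SUVmax are segmented (f = 0.20, 0.40, 0.60); the mean SUV over each segment
is the "SUV mean above threshold", SMaT_f.  Thresholding discards the
low-uptake blood pool that the CT-drawn master VOI unavoidably includes.

Reference regions: bone and lung masks come from CT Hounsfield-unit windows
(bone HU >= 150; lung -950..-350 restricted to the two largest connected
components); liver and soft tissue use operator-placed 25 ml and 15 ml
spheres.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.measure import label as cc_label

from .core import RegionMask, UptakeMetrics, VolumeGrid

__all__ = [
    "THRESHOLD_FRACTIONS",
    "BONE_HU_MIN",
    "LUNG_HU_WINDOW",
    "resample_mask",
    "detect_suvmax",
    "threshold_segment",
    "smat",
    "segment_hu",
    "sphere_voi",
    "region_mean",
    "quantify_uptake",
]

#: Default segmentation thresholds as fractions of SUVmax.
THRESHOLD_FRACTIONS = (0.20, 0.40, 0.60)
#: CT windows (HU) for the automatic bone / lung segmentation.
BONE_HU_MIN = 150.0
LUNG_HU_WINDOW = (-950.0, -350.0)


def resample_mask(mask: RegionMask, target: VolumeGrid) -> RegionMask:
    """Project a mask onto another grid by nearest-neighbour membership.

    Each target voxel center is mapped to world coordinates (the grids are
    rigidly co-registered; axis-aligned here) and takes the membership of
    the nearest source voxel.  Identity when source and target grids match.
    Raises if the grids' fields of view do not overlap.
    """
    if mask.same_grid(target):
        return RegionMask(mask.name, mask.voxels.copy(), mask.spacing, mask.origin)

    idx = []
    overlap = True
    for ax in range(3):
        centers = target.voxel_centers_world(ax)
        src = np.round((centers - mask.origin[ax]) / mask.spacing[ax]).astype(int)
        inside = (src >= 0) & (src < mask.shape[ax])
        if not inside.any():
            overlap = False
        idx.append((src, inside))
    if not overlap:
        raise ValueError(f"mask '{mask.name}' and target grid do not overlap")

    out = np.zeros(target.shape, dtype=bool)
    ii, oki = idx[0]
    jj, okj = idx[1]
    kk, okk = idx[2]
    valid = oki[:, None, None] & okj[None, :, None] & okk[None, None, :]
    src_vals = mask.voxels[np.clip(ii, 0, mask.shape[0] - 1)[:, None, None],
                           np.clip(jj, 0, mask.shape[1] - 1)[None, :, None],
                           np.clip(kk, 0, mask.shape[2] - 1)[None, None, :]]
    out[valid] = src_vals[valid]
    return RegionMask(mask.name, out, target.spacing, target.origin)


def detect_suvmax(suv: VolumeGrid, master: RegionMask) -> tuple[float, tuple[int, int, int]]:
    """Maximum SUV within the master VOI and its voxel index.

    Ties are broken toward the first voxel in scan (C-array) order.
    Raises on an empty master VOI.
    """
    if not master.same_grid(suv):
        raise ValueError("master VOI is not on the SUV grid")
    if master.count == 0:
        raise ValueError("master VOI is empty")
    vals = np.where(master.voxels, suv.data, -np.inf)
    flat = int(np.argmax(vals))
    loc = np.unravel_index(flat, suv.shape)
    return float(vals.flat[flat]), tuple(int(i) for i in loc)


def threshold_segment(suv: VolumeGrid, master: RegionMask, f: float) -> RegionMask:
    """Voxels of the master VOI with SUV >= f * SUVmax (inclusive).

    No connectivity filtering is applied: every voxel above the threshold
    inside the master VOI is kept.  Requires f in (0, 1] and SUVmax > 0.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError(f"threshold fraction must be in (0, 1], got {f}")
    suv_max, _ = detect_suvmax(suv, master)
    if suv_max <= 0:
        raise ValueError("SUVmax is not positive: no uptake to segment")
    sel = master.voxels & (suv.data >= f * suv_max)
    return RegionMask(f"seg_{int(round(f * 100))}", sel, master.spacing,
                      master.origin)


def smat(suv: VolumeGrid, segmented: RegionMask) -> float:
    """Mean SUV over a threshold segment (SUV mean above threshold)."""
    return region_mean(suv, segmented)


def region_mean(suv: VolumeGrid, mask: RegionMask) -> float:
    """Arithmetic mean SUV over an arbitrary non-empty mask."""
    if not mask.same_grid(suv):
        raise ValueError(f"mask '{mask.name}' is not on the SUV grid")
    if mask.count == 0:
        raise ValueError(f"mask '{mask.name}' is empty")
    return float(suv.data[mask.voxels].mean())


def segment_hu(ct: VolumeGrid, tissue: str,
               bone_hu_min: float = BONE_HU_MIN,
               lung_hu_window: tuple[float, float] = LUNG_HU_WINDOW) -> RegionMask:
    """Automatic CT Hounsfield-unit window segmentation of bone or lung.

    Bone: HU >= ``bone_hu_min``.  Lung: HU within ``lung_hu_window``,
    restricted to the two largest connected components (the two lung
    fields), which drops air pockets and partial-volume shells.  The mask
    is returned on the CT grid; resample to SPECT before SUV statistics.
    """
    if tissue == "bone":
        sel = ct.data >= bone_hu_min
    elif tissue == "lung":
        lo, hi = lung_hu_window
        sel = (ct.data >= lo) & (ct.data <= hi)
        if sel.any():
            lab = cc_label(sel, connectivity=1)
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            keep = np.argsort(sizes)[::-1][:2]
            keep = keep[sizes[keep] > 0]
            sel = np.isin(lab, keep)
    else:
        raise ValueError(f"tissue must be 'bone' or 'lung', got {tissue!r}")
    if not sel.any():
        warnings.warn(f"segment_hu: empty {tissue} mask")
    return RegionMask(tissue, sel, ct.spacing, ct.origin)


def sphere_voi(grid: VolumeGrid, center_mm: tuple[float, float, float],
               volume_ml: float) -> RegionMask:
    """Spherical VOI of nominal volume (ml) around a world-space center.

    Membership is by voxel-center test against r = (3V/4pi)^(1/3); the
    realized volume therefore differs from nominal by at most one surface
    voxel layer.  A sphere extending past the grid raises; a sphere smaller
    than one voxel degenerates to the single nearest voxel with a warning.
    """
    if volume_ml <= 0:
        raise ValueError("volume_ml must be > 0")
    center = np.asarray(center_mm, dtype=float)
    extent = np.array([n * s for n, s in zip(grid.shape, grid.spacing)])
    lo = np.asarray(grid.origin)
    if np.any(center < lo) or np.any(center > lo + extent):
        raise ValueError(f"sphere center {tuple(center)} outside grid")
    r_mm = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    if np.any(center - r_mm < lo) or np.any(center + r_mm > lo + extent):
        raise ValueError("sphere extends beyond the grid")

    axes = [grid.origin[ax] + grid.spacing[ax] * (np.arange(grid.shape[ax]) + 0.5)
            for ax in range(3)]
    dx, dy, dz = np.meshgrid(*[a - c for a, c in zip(axes, center)],
                             indexing="ij", sparse=True)
    sel = dx ** 2 + dy ** 2 + dz ** 2 <= r_mm ** 2
    if not sel.any():
        warnings.warn("sphere smaller than one voxel; using the nearest voxel")
        d2 = dx ** 2 + dy ** 2 + dz ** 2
        sel = np.zeros(grid.shape, dtype=bool)
        sel[np.unravel_index(int(np.argmin(d2)), grid.shape)] = True
    return RegionMask(f"sphere_{volume_ml:g}ml", sel, grid.spacing, grid.origin)


def quantify_uptake(suv: VolumeGrid, master: RegionMask,
                    fractions: tuple[float, ...] = THRESHOLD_FRACTIONS) -> UptakeMetrics:
    """SUVmax and SMaT_f / segmented volume at each threshold fraction."""
    suv_max, _ = detect_suvmax(suv, master)
    metrics = UptakeMetrics(suv_max=suv_max)
    for f in fractions:
        segm = threshold_segment(suv, master, f)
        metrics.smat[f] = smat(suv, segm)
        metrics.seg_volume_ml[f] = segm.volume_ml
    return metrics
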