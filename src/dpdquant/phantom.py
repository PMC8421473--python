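"""Digital chest phantom with grade-dependent myocardial tracer uptake.

Generates paired CT/SPECT volumes, ground-truth organ masks and acquisition
metadata that emulate an already-reconstructed bone-tracer SPECT/CT study of
a patient with suspected cardiac ATTR amyloidosis.  The geometry is
schematic — an ellipsoidal-shell left-ventricular wall around a blood-pool
lumen, two lung fields, a liver block, spine/rib bone rods and a soft-tissue
body — because the downstream analysis depends only on region membership and
uptake levels, not on anthropomorphic shape.

Organ dimensions scale with the physical grid extent so the same anatomy is
generated on any grid of at least 48^3 voxels.  The SPECT volume is built by
inverting the body-weight SUV definition, so that converting it back to SUV
recovers each region's target value exactly in the noiseless, blur-free
case.  Degradation is applied to the SPECT volume only: isotropic Gaussian
blur (the reconstructed point-spread function) followed by Poisson noise on
expected counts.  All randomness flows from the scenario's single integer
seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import AcquisitionMeta, RegionMask, UptakeMetrics, VolumeGrid
from .suv import percent_id, suv_to_concentration
from . import segmentation as seg

__all__ = ["GradeScenario", "PhantomOutput", "build_phantom", "jitter_reader",
           "GRADE_MYOCARDIAL_SUV"]

#: Default myocardial target SUV (g/ml) per visual grade 0-3; cohort means.
GRADE_MYOCARDIAL_SUV = {0: 1.85, 1: 2.79, 2: 14.05, 3: 15.26}
#: Blood-pool SUV per grade; kept below 20% of the myocardial target so the
#: lowest segmentation threshold excludes the lumen interior.
GRADE_LUMEN_SUV = {0: 0.25, 1: 0.40, 2: 1.00, 3: 1.00}
#: Background organ SUVs per grade.  Bone and liver uptake decline with
#: increasing cardiac grade while lung and soft tissue rise slightly,
#: mirroring the direction of the reported extracardiac trends.
GRADE_BONE_SUV = {0: 5.0, 1: 4.5, 2: 3.5, 3: 3.0}
GRADE_LIVER_SUV = {0: 2.0, 1: 1.8, 2: 1.4, 3: 1.2}
GRADE_LUNG_SUV = {0: 0.35, 1: 0.40, 2: 0.45, 3: 0.50}
GRADE_SOFT_SUV = {0: 0.60, 1: 0.65, 2: 0.70, 3: 0.75}

#: CT numbers assigned per tissue class.  Only the ordering and the
#: bone/lung separability from soft tissue matter downstream.
TISSUE_HU = {
    "air": -1000.0,
    "soft_tissue": 40.0,
    "liver": 55.0,
    "lungs": -750.0,
    "bone": 700.0,
    "lv_wall": 40.0,
    "lumen": 45.0,
}


@dataclass
class GradeScenario:
    """Uptake scenario for one phantom study.

    Any SUV left as ``None`` is filled from the per-grade defaults above.
    ``counts_per_suv`` is the expected detected counts per voxel per unit
    SUV; ``None`` disables the Poisson noise stage (infinite-count limit).
    """

    grade: int
    myocardial_suv: float | None = None
    lumen_suv: float | None = None
    bone_suv: float | None = None
    lung_suv: float | None = None
    liver_suv: float | None = None
    soft_suv: float | None = None
    psf_sigma_mm: float = 6.0
    counts_per_suv: float | None = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grade not in (0, 1, 2, 3):
            raise ValueError(f"grade must be 0-3, got {self.grade}")
        if self.myocardial_suv is None:
            self.myocardial_suv = GRADE_MYOCARDIAL_SUV[self.grade]
        if self.myocardial_suv < 0:
            raise ValueError("myocardial_suv must be >= 0")
        if self.lumen_suv is None:
            self.lumen_suv = GRADE_LUMEN_SUV[self.grade]
        if self.bone_suv is None:
            self.bone_suv = GRADE_BONE_SUV[self.grade]
        if self.lung_suv is None:
            self.lung_suv = GRADE_LUNG_SUV[self.grade]
        if self.liver_suv is None:
            self.liver_suv = GRADE_LIVER_SUV[self.grade]
        if self.soft_suv is None:
            self.soft_suv = GRADE_SOFT_SUV[self.grade]
        if self.psf_sigma_mm < 0:
            raise ValueError("psf_sigma_mm must be >= 0")

    @property
    def region_suv(self) -> dict[str, float]:
        return {
            "lv_wall": float(self.myocardial_suv),
            "lumen": float(self.lumen_suv),
            "bone": float(self.bone_suv),
            "lungs": float(self.lung_suv),
            "liver": float(self.liver_suv),
            "soft_tissue": float(self.soft_suv),
            "air": 0.0,
        }


@dataclass
class PhantomOutput:
    """One synthetic study: volumes, truth masks, metadata, expected metrics."""

    ct: VolumeGrid
    spect: VolumeGrid
    truth_masks: dict[str, RegionMask]
    meta: AcquisitionMeta
    truth_metrics: UptakeMetrics
    sphere_centers: dict[str, tuple[float, float, float]]
    scenario: GradeScenario | None = None
    flags: list[str] = field(default_factory=list)


def _default_meta() -> AcquisitionMeta:
    t0 = datetime(2016, 1, 1, 9, 0, 0)
    return AcquisitionMeta(
        injected_activity_MBq=743.0,
        t_injection=t0,
        t_scan=t0 + timedelta(hours=3),
        weight_kg=75.0,
        height_cm=170.0,
        calibration=1.0,
    )


def _ellipsoid(coords, center, semi) -> np.ndarray:
    x, y, z = coords
    return (((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2) <= 1.0


def _build_labels(grid_shape, spacing_mm):
    """Voxelize the schematic anatomy; returns label volume and sphere centers.

    Labels are assigned with priority (later overrides earlier):
    body -> lungs -> liver -> bone -> heart (wall, lumen).
    """
    shape = tuple(int(n) for n in grid_shape)
    spacing = tuple(float(s) for s in spacing_mm)
    if any(n < 48 for n in shape):
        raise ValueError(f"grid {shape} too small: at least 48 voxels per axis")
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")

    extent = np.array([n * s for n, s in zip(shape, spacing)])
    c = extent / 2.0
    axes = [sp * (np.arange(n) + 0.5) for n, sp in zip(shape, spacing)]
    coords = np.meshgrid(*axes, indexing="ij", sparse=True)
    x, y, z = coords

    body_semi = extent * np.array([0.39, 0.30, 0.43])
    lung_semi = extent * np.array([0.117, 0.156, 0.221])
    lung_dx = 0.195 * extent[0]
    lung_c = c + np.array([0.0, -0.026 * extent[1], 0.078 * extent[2]])
    heart_c = c + extent * np.array([-0.039, -0.065, 0.143])
    heart_outer = extent * np.array([0.094, 0.094, 0.120])
    heart_inner = extent * np.array([0.065, 0.065, 0.091])
    if np.any(heart_outer - heart_inner < np.array(spacing)):
        raise ValueError("LV wall thinner than one voxel on this grid; "
                         "use a finer grid or larger extent")

    labels = np.zeros(shape, dtype=np.uint8)
    order = ["air", "soft_tissue", "lungs", "liver", "bone", "lumen", "lv_wall"]
    code = {name: i for i, name in enumerate(order)}

    labels[_ellipsoid(coords, c, body_semi)] = code["soft_tissue"]
    for sgn in (-1.0, 1.0):
        lc = lung_c + np.array([sgn * lung_dx, 0.0, 0.0])
        labels[_ellipsoid(coords, lc, lung_semi)] = code["lungs"]

    liver_lo = c + extent * np.array([-0.208, -0.104, -0.365])
    liver_hi = c + extent * np.array([0.078, 0.130, -0.156])
    liver = ((x >= liver_lo[0]) & (x <= liver_hi[0])
             & (y >= liver_lo[1]) & (y <= liver_hi[1])
             & (z >= liver_lo[2]) & (z <= liver_hi[2]))
    labels[liver] = code["liver"]

    # spine: posterior cylinder along z; ribs: two lateral rods
    spine_r = 0.039 * extent[0]
    spine = (((x - c[0]) ** 2 + (y - (c[1] + 0.221 * extent[1])) ** 2)
             <= spine_r ** 2) & (z >= 0.104 * extent[2]) & (z <= 0.896 * extent[2])
    labels[spine] = code["bone"]
    rod_r = 0.026 * extent[0]
    for sgn in (-1.0, 1.0):
        rod = (((x - (c[0] + sgn * 0.339 * extent[0])) ** 2
                + (y - c[1]) ** 2) <= rod_r ** 2) \
            & (z >= 0.156 * extent[2]) & (z <= 0.859 * extent[2])
        labels[rod] = code["bone"]

    outer = _ellipsoid(coords, heart_c, heart_outer)
    inner = _ellipsoid(coords, heart_c, heart_inner)
    labels[outer & ~inner] = code["lv_wall"]
    labels[inner] = code["lumen"]

    for organ in ("lv_wall", "lumen", "lungs", "liver", "bone"):
        if not np.any(labels == code[organ]):
            raise ValueError(f"organ '{organ}' voxelized to zero voxels on "
                             f"grid {shape} at spacing {spacing}")

    sphere_centers = {
        "liver": tuple(c + extent * np.array([-0.065, 0.013, -0.260])),
        "soft_tissue": tuple(c + extent * np.array([0.100, -0.213, 0.100])),
    }
    return labels, code, sphere_centers


def build_phantom(scenario: GradeScenario,
                  grid_shape: tuple[int, int, int] = (96, 96, 96),
                  spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0),
                  meta: AcquisitionMeta | None = None) -> PhantomOutput:
    """Generate one synthetic CT/SPECT study for the given uptake scenario.

    The noiseless SUV field assigns each region its scenario target.  The
    expected (truth) metrics are computed from that field before blur and
    noise, so they are the values an ideal scanner would recover.
    """
    labels, code, sphere_centers = _build_labels(grid_shape, spacing_mm)
    spacing = tuple(float(s) for s in spacing_mm)
    meta = meta if meta is not None else _default_meta()

    ct_data = np.full(labels.shape, TISSUE_HU["air"], dtype=np.float64)
    suv_data = np.zeros(labels.shape, dtype=np.float64)
    region_suv = scenario.region_suv
    for name, idx in code.items():
        sel = labels == idx
        ct_data[sel] = TISSUE_HU[name]
        suv_data[sel] = region_suv[name]

    ct = VolumeGrid(ct_data, spacing, units="HU")

    masks = {
        name: RegionMask(name, labels == code[name], spacing)
        for name in ("lv_wall", "lumen", "lungs", "liver", "bone", "soft_tissue")
    }
    master = RegionMask("master_voi",
                        masks["lv_wall"].voxels | masks["lumen"].voxels, spacing)
    masks["master_voi"] = master

    # expected metrics from the degradation-free SUV field
    suv_truth = VolumeGrid(suv_data, spacing, units="g/ml")
    truth_metrics = seg.quantify_uptake(suv_truth, master)
    conc = suv_to_concentration(1.0, meta)
    truth_metrics.percent_id = _noiseless_percent_id(suv_truth, master, meta)

    # SPECT: SUV -> concentration, then PSF blur, then Poisson counts
    spect_data = suv_data * conc
    if scenario.psf_sigma_mm > 0:
        sigma_vox = [scenario.psf_sigma_mm / s for s in spacing]
        spect_data = gaussian_filter(spect_data, sigma_vox, mode="constant")
    if scenario.counts_per_suv is not None and np.isfinite(scenario.counts_per_suv):
        rng = np.random.default_rng(scenario.seed)
        expected_counts = np.maximum(spect_data / conc, 0.0) * scenario.counts_per_suv
        counts = rng.poisson(expected_counts)
        spect_data = counts / scenario.counts_per_suv * conc

    spect = VolumeGrid(spect_data, spacing, units="kBq/ml")
    return PhantomOutput(ct=ct, spect=spect, truth_masks=masks, meta=meta,
                         truth_metrics=truth_metrics,
                         sphere_centers=sphere_centers, scenario=scenario)


def _noiseless_percent_id(suv_truth: VolumeGrid, mask: RegionMask,
                          meta: AcquisitionMeta) -> float:
    conc = suv_to_concentration(1.0, meta)
    spect = suv_truth.with_data(suv_truth.data * conc, units="kBq/ml")
    return percent_id(spect, mask, meta)


def jitter_reader(output: PhantomOutput, translation_sd_mm: float,
                  seed: int = 0) -> PhantomOutput:
    """Emulate a second operator: rigidly displace the master VOI and the
    liver/soft-tissue sphere-center suggestions by a random translation.

    The mask displacement is rounded to whole voxels; sphere centers keep
    the continuous draw.  A displaced sphere whose default volume would
    leave its organ is flagged in ``flags`` rather than silently accepted.
    Zero ``translation_sd_mm`` returns an identical copy.
    """
    if translation_sd_mm < 0:
        raise ValueError("translation_sd_mm must be >= 0")
    out = copy.deepcopy(output)
    if translation_sd_mm == 0:
        return out
    rng = np.random.default_rng(seed)
    shift_mm = rng.normal(0.0, translation_sd_mm, size=3)
    spacing = np.array(out.spect.spacing)
    shift_vox = np.rint(shift_mm / spacing).astype(int)

    master = out.truth_masks["master_voi"]
    out.truth_masks["master_voi"] = RegionMask(
        master.name, np.roll(master.voxels, shift_vox, axis=(0, 1, 2)),
        master.spacing, master.origin)

    default_volume = {"liver": 25.0, "soft_tissue": 15.0}
    for organ, center in out.sphere_centers.items():
        new_center = tuple(np.array(center) + shift_mm)
        out.sphere_centers[organ] = new_center
        try:
            sphere = seg.sphere_voi(out.spect, new_center, default_volume[organ])
            if organ in out.truth_masks and np.any(
                    sphere.voxels & ~out.truth_masks[organ].voxels):
                out.flags.append(f"{organ} sphere displaced outside organ")
        except ValueError:
            out.flags.append(f"{organ} sphere displaced outside grid")
    return out
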