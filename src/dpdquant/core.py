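"""Shared domain types for quantitative bone-tracer SPECT/CT analysis.

The pipeline works on pairs of co-registered 3D volumes — an attenuation CT
in Hounsfield units and a reconstructed SPECT volume in activity
concentration (kBq/ml) — plus an acquisition metadata record and boolean
region masks.  Volumes are carried as :class:`VolumeGrid` objects: a scalar
field with isotropic-or-not voxel spacing in mm and a world-space origin,
RAS axis convention, voxel-center coordinates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "RegionMask",
    "AcquisitionMeta",
    "UptakeMetrics",
    "load_volume",
    "load_mask",
    "load_meta",
]


@dataclass
class VolumeGrid:
    """A 3D scalar field with voxel spacing (mm) and world origin (mm).

    ``units`` documents what the voxels carry: ``"HU"`` for CT,
    ``"kBq/ml"`` for reconstructed SPECT activity concentration, or
    ``"g/ml"`` for a derived SUV volume.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in ml (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """RAS voxel-to-world affine (axis-aligned, no rotation)."""
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def same_grid(self, other: "VolumeGrid | RegionMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def voxel_centers_world(self, axis: int) -> np.ndarray:
        """World-space coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def with_data(self, data: np.ndarray, units: str | None = None) -> "VolumeGrid":
        return VolumeGrid(data, self.spacing, self.origin,
                          self.units if units is None else units)

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))


@dataclass
class RegionMask:
    """A named boolean voxel set on a grid (master VOI, bone, lung, ...)."""

    name: str
    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def volume_ml(self) -> float:
        return self.count * self.voxel_volume_ml

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def same_grid(self, other: "VolumeGrid | RegionMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.voxels.astype(np.uint8), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))


@dataclass
class AcquisitionMeta:
    """Injected activity, timing, patient habitus and scanner calibration.

    ``injected_activity_MBq`` is the activity at injection time; decay to
    scan time is applied downstream.  Height is recorded for completeness
    but body-weight SUV does not use it.  ``calibration`` converts stored
    voxel units to kBq/ml (1.0 when the volume is already in kBq/ml).
    """

    injected_activity_MBq: float
    t_injection: datetime
    t_scan: datetime
    weight_kg: float
    height_cm: float = float("nan")
    calibration: float = 1.0

    def __post_init__(self) -> None:
        if self.injected_activity_MBq <= 0:
            raise ValueError("injected_activity_MBq must be > 0")
        if self.weight_kg <= 0:
            raise ValueError("weight_kg must be > 0")
        if self.t_scan < self.t_injection:
            raise ValueError("t_scan precedes t_injection")

    @property
    def dt_hours(self) -> float:
        """Injection-to-scan interval in hours."""
        return (self.t_scan - self.t_injection).total_seconds() / 3600.0

    # JSON sidecar schema
    def to_json(self, path: str | Path) -> None:
        payload = {
            "injected_MBq": self.injected_activity_MBq,
            "t_injection_iso8601": self.t_injection.isoformat(),
            "t_scan_iso8601": self.t_scan.isoformat(),
            "weight_kg": self.weight_kg,
            "height_cm": self.height_cm,
            "calibration_kBq_per_count": self.calibration,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionMeta":
        payload = json.loads(Path(path).read_text())
        required = ["injected_MBq", "t_injection_iso8601", "t_scan_iso8601",
                    "weight_kg"]
        for key in required:
            if key not in payload:
                raise KeyError(f"metadata file {path} missing required field "
                               f"'{key}'")
        return cls(
            injected_activity_MBq=float(payload["injected_MBq"]),
            t_injection=datetime.fromisoformat(payload["t_injection_iso8601"]),
            t_scan=datetime.fromisoformat(payload["t_scan_iso8601"]),
            weight_kg=float(payload["weight_kg"]),
            height_cm=float(payload.get("height_cm", float("nan"))),
            calibration=float(payload.get("calibration_kBq_per_count", 1.0)),
        )


@dataclass
class UptakeMetrics:
    """Per-patient myocardial uptake metrics.

    ``smat`` maps threshold fraction (0.20, 0.40, 0.60) to the mean SUV over
    voxels above that fraction of SUVmax; ``seg_volume_ml`` maps the same
    fractions to the segmented volume.
    """

    suv_max: float
    smat: dict[float, float] = field(default_factory=dict)
    seg_volume_ml: dict[float, float] = field(default_factory=dict)
    percent_id: float = float("nan")

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {"suv_max": self.suv_max}
        for f in sorted(self.smat):
            row[f"smat{int(round(f * 100))}"] = self.smat[f]
        for f in sorted(self.seg_volume_ml):
            row[f"vol{int(round(f * 100))}_ml"] = self.seg_volume_ml[f]
        row["percent_id"] = self.percent_id
        return row


def _grid_from_nifti(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple, tuple]:
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return data, zooms, origin


def load_volume(path: str | Path, units: str = "") -> VolumeGrid:
    data, zooms, origin = _grid_from_nifti(nib.load(str(path)))
    return VolumeGrid(data, zooms, origin, units)


def load_mask(path: str | Path, name: str | None = None) -> RegionMask:
    data, zooms, origin = _grid_from_nifti(nib.load(str(path)))
    return RegionMask(name or Path(path).name.split(".")[0],
                      data > 0.5, zooms, origin)


def load_meta(path: str | Path) -> AcquisitionMeta:
    return AcquisitionMeta.from_json(path)
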