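"""Pipeline orchestration: configuration, per-patient quantification, cohort
runs and file layout.

One patient study = co-registered CT (HU) + SPECT (kBq/ml) volumes, an
acquisition-metadata JSON sidecar, a myocardial master-VOI mask, and
operator-chosen liver / soft-tissue sphere centers.  ``quantify_patient``
runs the full chain — SUV conversion, master-VOI threshold segmentation,
CT-window and sphere reference regions, normalization ratios — and returns
one flat metrics row.  ``run_pipeline`` maps it over a cohort; a failure in
one patient is logged and reported, it does not abort the cohort.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import segmentation as seg
from .core import AcquisitionMeta, RegionMask, VolumeGrid, load_mask, load_meta, load_volume
from .normalization import ReferenceUptake, normalize
from .phantom import PhantomOutput
from .suv import TC99M_HALF_LIFE_H, percent_id, to_suv

__all__ = ["PipelineConfig", "PatientStudy", "quantify_patient",
           "run_pipeline", "write_phantom", "load_study"]

log = logging.getLogger("dpdquant")


@dataclass
class PipelineConfig:
    """All tunable analysis parameters with their defaults.

    The cut-off table carries the published decision thresholds: the
    grades-2/3-vs-0/1 cut-offs (SUVmax 6.0; SMaT 2.5/3.3/4.2), the
    grade-0-vs-rest cut-offs (3.0; 1.3/1.5/2.1) and the liver/lung-ratio
    thresholds (41.9/15.8/20.2/24.4).
    """

    threshold_fractions: tuple[float, ...] = (0.20, 0.40, 0.60)
    half_life_hours: float = TC99M_HALF_LIFE_H
    bone_hu_min: float = seg.BONE_HU_MIN
    lung_hu_window: tuple[float, float] = seg.LUNG_HU_WINDOW
    liver_sphere_ml: float = 25.0
    soft_sphere_ml: float = 15.0
    cutoffs: dict = field(default_factory=lambda: {
        "grades23_vs_01": {"suv_max": 6.0, "smat20": 2.5, "smat40": 3.3,
                           "smat60": 4.2},
        "grade0_vs_rest": {"suv_max": 3.0, "smat20": 1.3, "smat40": 1.5,
                           "smat60": 2.1},
        "liver_lung_ratio_grades3_vs_2": {"suv_max": 41.9, "smat20": 15.8,
                                          "smat40": 20.2, "smat60": 24.4},
    })
    sd_convention: str = "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.threshold_fractions)
        if any(not 0 < f < 1 for f in fr) or list(fr) != sorted(set(fr)):
            raise ValueError("threshold fractions must be strictly increasing "
                             "within (0, 1)")
        self.threshold_fractions = fr
        if self.liver_sphere_ml <= 0 or self.soft_sphere_ml <= 0:
            raise ValueError("sphere volumes must be > 0")

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["threshold_fractions"] = list(self.threshold_fractions)
        payload["lung_hu_window"] = list(self.lung_hu_window)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["threshold_fractions"] = tuple(payload["threshold_fractions"])
        payload["lung_hu_window"] = tuple(payload["lung_hu_window"])
        return cls(**payload)


@dataclass
class PatientStudy:
    """In-memory inputs for one patient."""

    patient_id: str
    ct: VolumeGrid
    spect: VolumeGrid
    meta: AcquisitionMeta
    master: RegionMask
    liver_center_mm: tuple[float, float, float]
    soft_center_mm: tuple[float, float, float]
    visual_grade: int | None = None

    @classmethod
    def from_phantom(cls, patient_id: str, ph: PhantomOutput,
                     master: RegionMask | None = None) -> "PatientStudy":
        return cls(
            patient_id=patient_id, ct=ph.ct, spect=ph.spect, meta=ph.meta,
            master=master if master is not None else ph.truth_masks["master_voi"],
            liver_center_mm=ph.sphere_centers["liver"],
            soft_center_mm=ph.sphere_centers["soft_tissue"],
            visual_grade=ph.scenario.grade if ph.scenario else None,
        )


def quantify_patient(study: PatientStudy,
                     config: PipelineConfig | None = None) -> dict:
    """Full quantification of one study; returns one flat metrics row."""
    cfg = config or PipelineConfig()
    suv = to_suv(study.spect, study.meta, cfg.half_life_hours)
    master = seg.resample_mask(study.master, suv)

    metrics = seg.quantify_uptake(suv, master, cfg.threshold_fractions)
    metrics.percent_id = percent_id(study.spect, master, study.meta,
                                    cfg.half_life_hours)

    bone_ct = seg.segment_hu(study.ct, "bone", bone_hu_min=cfg.bone_hu_min)
    lung_ct = seg.segment_hu(study.ct, "lung", lung_hu_window=cfg.lung_hu_window)
    bone = seg.resample_mask(bone_ct, suv)
    lung = seg.resample_mask(lung_ct, suv)
    liver = seg.sphere_voi(suv, study.liver_center_mm, cfg.liver_sphere_ml)
    soft = seg.sphere_voi(suv, study.soft_center_mm, cfg.soft_sphere_ml)

    ref = ReferenceUptake(
        suvmean_bone=seg.region_mean(suv, bone),
        suvmean_lung=seg.region_mean(suv, lung),
        suvmean_liver=seg.region_mean(suv, liver),
        suvmean_soft=seg.region_mean(suv, soft),
    )
    log.info("patient %s: SUVmax=%.3f thresholds=%s half_life=%.4f h "
             "bone_hu>=%.0f lung_hu=%s", study.patient_id, metrics.suv_max,
             cfg.threshold_fractions, cfg.half_life_hours, cfg.bone_hu_min,
             cfg.lung_hu_window)

    row: dict = {"patient_id": study.patient_id}
    if study.visual_grade is not None:
        row["visual_grade"] = study.visual_grade
    row.update(metrics.as_row())
    row.update({
        "suvmean_bone": ref.suvmean_bone,
        "suvmean_lung": ref.suvmean_lung,
        "suvmean_liver": ref.suvmean_liver,
        "suvmean_soft": ref.suvmean_soft,
    })
    row.update(normalize(metrics, ref))
    return row


def run_pipeline(studies, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Quantify a cohort of studies into one metrics table.

    A patient whose quantification raises is recorded with an ``error``
    column and skipped; the rest of the cohort completes.
    """
    cfg = config or PipelineConfig()
    rows = []
    for study in studies:
        try:
            rows.append(quantify_patient(study, cfg))
        except Exception as exc:  # noqa: BLE001 - isolate per-patient failure
            log.error("patient %s failed: %s", study.patient_id, exc)
            rows.append({"patient_id": study.patient_id, "error": str(exc)})
    return pd.DataFrame(rows)


# -- file layout -----------------------------------------------------------

def write_phantom(ph: PhantomOutput, out_dir: str | Path) -> Path:
    """Write one phantom study to disk: NIfTI volumes and masks, JSON
    metadata sidecar, sphere-center suggestions."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ph.ct.save(out / "ct.nii.gz")
    ph.spect.save(out / "spect.nii.gz")
    (out / "masks").mkdir(exist_ok=True)
    for name, mask in ph.truth_masks.items():
        mask.save(out / "masks" / f"{name}.nii.gz")
    ph.meta.to_json(out / "meta.json")
    import json
    (out / "sphere_centers.json").write_text(json.dumps(
        {k: list(v) for k, v in ph.sphere_centers.items()}, indent=2) + "\n")
    return out


def load_study(study_dir: str | Path, patient_id: str | None = None,
               master_path: str | Path | None = None) -> PatientStudy:
    """Load a study from the on-disk layout written by :func:`write_phantom`."""
    d = Path(study_dir)
    import json
    centers = json.loads((d / "sphere_centers.json").read_text())
    return PatientStudy(
        patient_id=patient_id or d.name,
        ct=load_volume(d / "ct.nii.gz", units="HU"),
        spect=load_volume(d / "spect.nii.gz", units="kBq/ml"),
        meta=load_meta(d / "meta.json"),
        master=load_mask(master_path or d / "masks" / "master_voi.nii.gz",
                         "master_voi"),
        liver_center_mm=tuple(centers["liver"]),
        soft_center_mm=tuple(centers["soft_tissue"]),
    )
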