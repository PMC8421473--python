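"""Organ-normalized cardiac uptake ratios.

Each cardiac metric m (SUVmax, SMaT_20, SMaT_40, SMaT_60) is divided by the
mean SUV of each reference organ (lungs, liver, bone, soft tissue) and by
the two composite references liver/lung and bone/soft:

    m / (liver/lung) = m * lung_mean / liver_mean
    m / (bone/soft)  = m * soft_mean / bone_mean

Because a global rescaling of the SUV volume multiplies numerator and
denominator alike, every ratio is invariant to calibration error — the
practical point of normalizing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import UptakeMetrics

__all__ = ["ReferenceUptake", "normalize"]

_ORGANS = ("lung", "liver", "bone", "soft")


@dataclass
class ReferenceUptake:
    """Mean SUV (g/ml) of the four reference regions."""

    suvmean_bone: float
    suvmean_lung: float
    suvmean_liver: float
    suvmean_soft: float

    def validate(self) -> None:
        for organ in _ORGANS:
            v = getattr(self, f"suvmean_{organ}")
            if not v > 0:
                raise ValueError(f"reference SUVmean for {organ} must be > 0, "
                                 f"got {v}")


def normalize(metrics: UptakeMetrics, ref: ReferenceUptake) -> dict[str, float]:
    """All 24 normalization ratios for one patient, keyed
    ``<metric>_per_<reference>`` with metric in {suv_max, smat20, smat40,
    smat60} and reference in {lung, liver, bone, soft, liver_lung,
    bone_soft}.  Pure arithmetic, no rounding."""
    ref.validate()
    cardiac = {"suv_max": metrics.suv_max}
    for f, v in metrics.smat.items():
        cardiac[f"smat{int(round(f * 100))}"] = v

    out: dict[str, float] = {}
    for name, m in cardiac.items():
        for organ in _ORGANS:
            out[f"{name}_per_{organ}"] = m / getattr(ref, f"suvmean_{organ}")
        out[f"{name}_per_liver_lung"] = m * ref.suvmean_lung / ref.suvmean_liver
        out[f"{name}_per_bone_soft"] = m * ref.suvmean_soft / ref.suvmean_bone
    return out
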