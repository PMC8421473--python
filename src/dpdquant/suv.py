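"""Body-weight SUV conversion and percent-injected-dose computation.

SUV (body weight) for a voxel with activity concentration C (kBq/ml) is

    SUV = C * (weight * 1000 g) / (injected activity decayed to scan time, kBq)

with tissue density taken as 1 g/ml so SUV carries units of g/ml.  The
decayed denominator uses the 99mTc physical half-life (6.0067 h by default;
configurable for other isotopes).
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import AcquisitionMeta, RegionMask, VolumeGrid

__all__ = ["TC99M_HALF_LIFE_H", "decay_factor", "to_suv", "percent_id"]

#: Physical half-life of 99mTc in hours.
TC99M_HALF_LIFE_H = 6.0067


def decay_factor(dt_hours: float, half_life_hours: float = TC99M_HALF_LIFE_H) -> float:
    """Fraction of activity remaining after ``dt_hours``: 2**(-dt/T1/2).

    Raises ``ValueError`` for negative ``dt_hours`` (a scan cannot precede
    the injection) or non-positive half-life.
    """
    if dt_hours < 0:
        raise ValueError(f"negative decay interval {dt_hours} h: scan before injection")
    if half_life_hours <= 0:
        raise ValueError("half_life_hours must be > 0")
    return float(2.0 ** (-dt_hours / half_life_hours))


def to_suv(spect: VolumeGrid, meta: AcquisitionMeta,
           half_life_hours: float = TC99M_HALF_LIFE_H) -> VolumeGrid:
    """Convert a SPECT activity-concentration volume to body-weight SUV.

    The stored voxel values are first scaled by ``meta.calibration`` to
    kBq/ml, then normalized by decay-corrected injected activity and body
    mass.  Returns a new :class:`VolumeGrid` in g/ml on the same grid.
    """
    decayed_kBq = (meta.injected_activity_MBq * 1000.0
                   * decay_factor(meta.dt_hours, half_life_hours))
    conc_kBq_ml = spect.data * meta.calibration
    suv = conc_kBq_ml * (meta.weight_kg * 1000.0) / decayed_kBq
    return spect.with_data(suv, units="g/ml")


def suv_to_concentration(suv_value: float, meta: AcquisitionMeta,
                         half_life_hours: float = TC99M_HALF_LIFE_H) -> float:
    """Inverse of :func:`to_suv` for a scalar: the kBq/ml concentration that
    yields ``suv_value`` under ``meta``.  Used by the phantom generator so the
    downstream SUV computation recovers its target exactly."""
    decayed_kBq = (meta.injected_activity_MBq * 1000.0
                   * decay_factor(meta.dt_hours, half_life_hours))
    return suv_value * decayed_kBq / (meta.weight_kg * 1000.0)


def percent_id(spect: VolumeGrid, mask: RegionMask, meta: AcquisitionMeta,
               half_life_hours: float = TC99M_HALF_LIFE_H) -> float:
    """Percent of the (decay-corrected) injected dose inside a VOI.

    100 * sum over mask of C(v) * voxel_volume / decayed injected activity.
    An empty mask yields 0 with a warning.
    """
    if not mask.same_grid(spect):
        raise ValueError("mask and SPECT volume are on different grids")
    if mask.count == 0:
        warnings.warn(f"percent_id: mask '{mask.name}' is empty; returning 0")
        return 0.0
    decayed_kBq = (meta.injected_activity_MBq * 1000.0
                   * decay_factor(meta.dt_hours, half_life_hours))
    activity_kBq = float(np.sum(spect.data[mask.voxels]) * meta.calibration
                         * spect.voxel_volume_ml)
    return 100.0 * activity_kBq / decayed_kBq
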