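"""Direct dose mapping (DDM) along displacement fields and accumulation.

Fraction doses are mapped into the fraction-1 frame by sampling each dose at
the displaced voxel positions (trilinear interpolation, no energy rescaling)
and summed voxelwise.  DDM preserves pointwise dose values; it does not
conserve integral dose under deformation — that is a property of the method,
not a defect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ScalarVolume, VectorField
from .registration import apply_field_to_volume

__all__ = ["AccumulatedDose", "warp_dose", "accumulate", "accumulate_arm"]

ARMS = ("refPlan", "conv-IGRT", "OA-MRgRT")


@dataclass
class AccumulatedDose:
    """Total dose of one treatment arm in its evaluation frame."""

    arm: str
    dose: ScalarVolume
    frame: str  # "reference" (refPlan) or "fraction1" (accumulated arms)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")


def warp_dose(dose: ScalarVolume, dvf: VectorField) -> ScalarVolume:
    """Map a dose onto the field's grid: ``out(x) = dose(x + u(x))``.

    Pure direct dose mapping: trilinear sampling at displaced points, values
    clamped at 0, out-of-field contributions 0.
    """
    out = apply_field_to_volume(dose, dvf, order=1, cval=0.0)
    np.maximum(out.values, 0.0, out=out.values)
    return out


def accumulate(fraction_doses: list[ScalarVolume]) -> ScalarVolume:
    """Voxelwise sum of fraction doses sharing one grid."""
    if not fraction_doses:
        raise ValueError("no fraction doses to accumulate")
    grid = fraction_doses[0].grid
    total = np.zeros(grid.shape, dtype=np.float64)
    for k, d in enumerate(fraction_doses, start=1):
        if not d.grid.same_geometry(grid):
            raise ValueError(f"fraction {k}: dose grid does not match the accumulation grid")
        total += np.asarray(d.values, dtype=np.float64)
    return ScalarVolume(grid, total.astype(np.float32))


def accumulate_arm(case, arm: str, dvfs: list[VectorField]) -> AccumulatedDose:
    """Accumulate one arm's fraction doses into the fraction-1 frame.

    ``dvfs[k]`` must be the pull-back field on the fraction-1 grid pointing
    into fraction k+1's frame (``dvfs[0]`` is the identity).
    """
    if arm not in ("conv-IGRT", "OA-MRgRT"):
        raise ValueError(f"accumulation is defined for conv-IGRT / OA-MRgRT, got {arm!r}")
    if len(dvfs) != len(case.fractions):
        raise ValueError("need one displacement field per fraction")
    warped = []
    for fx, dvf in zip(case.fractions, dvfs):
        dose = fx.dose_oa if arm == "OA-MRgRT" else fx.dose_conv
        if dose is None:
            raise ValueError(f"fraction {fx.index}: {arm} dose missing")
        warped.append(warp_dose(dose, dvf))
    return AccumulatedDose(arm=arm, dose=accumulate(warped), frame="fraction1")
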