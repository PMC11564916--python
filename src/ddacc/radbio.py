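"""Radiobiological dose response: EQD2, gEUD, and the LKB NTCP model.

The pipeline follows the standard Lyman-Kutcher-Burman chain: the physical
total dose is first converted voxelwise to the equivalent dose in 2 Gy
fractions (linear-quadratic model, uniform fractionation), the EQD2
distribution is reduced to a generalized equivalent uniform dose (power mean
with volume parameter ``n``), and the scalar gEUD enters a logistic
dose-response curve with position ``TD50`` and slope ``m``:

    NTCP = 1 / (1 + exp(-(gEUD - TD50) / (m * TD50)))

so that NTCP(TD50) = 0.5 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ScalarVolume, StructureMask

__all__ = [
    "RadiobioParams",
    "NTCPResult",
    "BLADDER_INCONTINENCE_G2",
    "RECTUM_LATE_TOXICITY_G2",
    "eqd2_transform",
    "geud",
    "lkb_ntcp",
    "structure_ntcp",
]


@dataclass(frozen=True)
class RadiobioParams:
    """LKB parameter set for one endpoint.

    alpha_beta : tissue fractionation sensitivity ratio (Gy)
    TD50       : uniform dose giving 50% complication probability (Gy)
    m          : slope of the dose-response curve (dimensionless)
    n          : volume-effect parameter of the gEUD reduction, in (0, 1]
    """

    alpha_beta: float
    TD50: float
    m: float
    n: float
    endpoint: str = ""

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0 or self.TD50 <= 0:
            raise ValueError("alpha_beta and TD50 must be positive")
        if not (0 < self.m <= 1) or not (0 < self.n <= 1):
            raise ValueError("m and n must lie in (0, 1]")


#: Late bladder incontinence grade 2+.
BLADDER_INCONTINENCE_G2 = RadiobioParams(
    alpha_beta=1.5, TD50=108.9, m=0.24, n=0.02, endpoint="bladder incontinence G2+"
)
#: Late rectal toxicity grade 2+.
RECTUM_LATE_TOXICITY_G2 = RadiobioParams(
    alpha_beta=3.0, TD50=80.8, m=0.15, n=0.12, endpoint="rectum late toxicity G2+"
)


@dataclass
class NTCPResult:
    ntcp: float
    geud_eqd2: float
    params: RadiobioParams


def eqd2_transform(total_dose, n_fractions: int, alpha_beta: float):
    """Voxelwise equivalent dose in 2 Gy fractions.

    ``EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)`` with per-voxel fraction
    dose ``d = D / n_fractions`` (uniform fractionation across the schedule).
    Accepts scalars or arrays; monotone increasing in D.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if alpha_beta <= 0:
        raise ValueError("alpha_beta must be positive")
    d_total = np.asarray(total_dose, dtype=np.float64)
    d_per_fx = d_total / n_fractions
    out = d_total * (d_per_fx + alpha_beta) / (2.0 + alpha_beta)
    return out if out.ndim else float(out)


def geud(eqd2_dose: ScalarVolume, mask: StructureMask, n: float) -> float:
    """Generalized equivalent uniform dose: power mean of in-mask EQD2.

    ``gEUD = (mean(EQD2 ** (1/n))) ** n``; ``n = 1`` gives the mean dose, and
    as n -> 0+ the gEUD approaches the maximum voxel dose.
    """
    if not (0 < n <= 1):
        raise ValueError("n must lie in (0, 1]")
    if not eqd2_dose.grid.same_geometry(mask.grid):
        raise ValueError("dose and mask grids do not match")
    doses = np.asarray(eqd2_dose.values, dtype=np.float64)[mask.values]
    if doses.size == 0:
        raise ValueError(f"empty mask: {mask.label}")
    # factor out the maximum for numerical stability at small n
    dmax = doses.max()
    if dmax <= 0:
        return 0.0
    return float(dmax * np.mean((doses / dmax) ** (1.0 / n)) ** n)


def lkb_ntcp(geud_eqd2: float, params: RadiobioParams) -> NTCPResult:
    """Logistic LKB complication probability at a given gEUD (EQD2 scale)."""
    t = (geud_eqd2 - params.TD50) / (params.m * params.TD50)
    ntcp = float(1.0 / (1.0 + np.exp(-t)))
    return NTCPResult(ntcp=ntcp, geud_eqd2=float(geud_eqd2), params=params)


def structure_ntcp(
    total_dose: ScalarVolume,
    mask: StructureMask,
    n_fractions: int,
    params: RadiobioParams,
) -> NTCPResult:
    """Full chain for one structure: EQD2 -> gEUD -> logistic NTCP."""
    eqd2 = ScalarVolume(
        total_dose.grid,
        eqd2_transform(total_dose.values, n_fractions, params.alpha_beta),
    )
    g = geud(eqd2, mask, params.n)
    return lkb_ntcp(g, params)
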