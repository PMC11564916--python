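"""Cumulative dose-volume histograms, dose-volume parameters, plan objectives.

DVHs are cumulative, binned at 0.01 Gy by default (the resolution the analysis
reports DVPs at): ``cumulative_volume[i]`` is the percentage of the structure
receiving at least ``bin_edges[i]``.  Dmax is always the single hottest voxel,
computed voxelwise rather than from the histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ScalarVolume, StructureMask

__all__ = [
    "DVH",
    "DVPSet",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "dmax",
    "compute_dvps",
    "check_objectives",
    "OBJECTIVES",
]

DEFAULT_BIN_WIDTH_GY = 0.01


@dataclass
class DVH:
    """Cumulative DVH of one structure.

    ``bin_edges`` run from 0 to ceil(max dose) in uniform steps;
    ``cumulative_volume`` (percent) is monotone non-increasing and starts at 100.
    """

    bin_edges: np.ndarray
    cumulative_volume: np.ndarray
    structure_label: str
    voxel_volume_mm3: float

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.cumulative_volume = np.asarray(self.cumulative_volume, dtype=np.float64)
        if self.bin_edges.shape != self.cumulative_volume.shape:
            raise ValueError("bin_edges and cumulative_volume must have equal length")


@dataclass
class DVPSet:
    """Scalar dose-volume parameters read off one structure's dose."""

    label: str
    D50: float = np.nan
    D98: float = np.nan
    Dmax: float = np.nan
    V56: float = np.nan


def _in_mask_doses(dose: ScalarVolume, mask: StructureMask) -> np.ndarray:
    if not dose.grid.same_geometry(mask.grid):
        raise ValueError("dose and mask grids do not match")
    sel = np.asarray(dose.values, dtype=np.float64)[mask.values]
    if sel.size == 0:
        raise ValueError(f"empty mask: {mask.label}")
    return sel


def compute_dvh(
    dose: ScalarVolume, mask: StructureMask, bin_width: float = DEFAULT_BIN_WIDTH_GY
) -> DVH:
    """Cumulative DVH over in-mask voxels, volume in percent."""
    doses = _in_mask_doses(dose, mask)
    top = float(np.ceil(max(doses.max(), bin_width)))
    n_bins = int(round(top / bin_width)) + 1
    edges = np.arange(n_bins, dtype=np.float64) * bin_width
    # count of voxels with dose >= edge; half-open histogram on [edge, edge+w)
    counts, _ = np.histogram(doses, bins=np.append(edges, edges[-1] + bin_width))
    cum = counts[::-1].cumsum()[::-1] / doses.size * 100.0
    return DVH(edges, cum, mask.label, mask.grid.voxel_volume_mm3)


def volume_at_dose(dvh: DVH, d: float) -> float:
    """V(d): percent of the structure receiving >= d Gy (interpolated)."""
    if d < 0:
        raise ValueError("dose must be >= 0")
    if d > dvh.bin_edges[-1]:
        return 0.0
    return float(np.interp(d, dvh.bin_edges, dvh.cumulative_volume))


def dose_at_volume(dvh: DVH, q: float) -> float:
    """Dq%: the largest dose received by at least q percent of the structure.

    Linear interpolation between bins; q must lie in (0, 100].
    """
    if not 0 < q <= 100:
        raise ValueError("q must be in (0, 100]")
    v = dvh.cumulative_volume
    e = dvh.bin_edges
    if q <= v[-1]:
        return float(e[-1])
    # v is non-increasing; find the last index with v >= q
    i = int(np.searchsorted(-v, -q, side="right")) - 1
    i = max(i, 0)
    if v[i] == q or i == len(v) - 1 or v[i + 1] == v[i]:
        return float(e[i])
    # interpolate within the bin where the curve crosses q
    frac = (v[i] - q) / (v[i] - v[i + 1])
    return float(e[i] + frac * (e[i + 1] - e[i]))


def dmax(dose: ScalarVolume, mask: StructureMask) -> float:
    """Hottest single voxel inside the mask (independent of DVH binning)."""
    return float(_in_mask_doses(dose, mask).max())


def compute_dvps(
    dose: ScalarVolume,
    masks: dict[str, StructureMask],
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
) -> dict[str, DVPSet]:
    """All reported DVPs per structure: D50%, D98%, Dmax, V56Gy."""
    out: dict[str, DVPSet] = {}
    for label, mask in masks.items():
        dvh = compute_dvh(dose, mask, bin_width)
        out[label] = DVPSet(
            label=label,
            D50=dose_at_volume(dvh, 50.0),
            D98=dose_at_volume(dvh, 98.0),
            Dmax=dmax(dose, mask),
            V56=volume_at_dose(dvh, 56.0),
        )
    return out


# Planning objectives: (structure, parameter, limit, sense). Sense "ge" means
# value >= limit passes (inclusive); "le" value <= limit; "lt" value < limit.
OBJECTIVES: tuple[tuple[str, str, float, str], ...] = (
    ("CTV", "D50", 60.0, "ge"),
    ("CTV", "D98", 57.0, "ge"),
    ("rectum", "Dmax", 61.0, "le"),
    ("bladder", "Dmax", 61.0, "le"),
    ("urethra", "Dmax", 61.0, "le"),
    ("rectum", "V56", 13.5, "lt"),
    ("bladder", "V56", 18.0, "lt"),
)


def check_objectives(dvps: dict[str, DVPSet]) -> dict[str, dict]:
    """Evaluate every planning objective against a DVP table.

    Returns ``{objective_name: {"value", "limit", "sense", "pass"}}``.
    Raises ``KeyError`` if a required structure is missing.
    """
    result: dict[str, dict] = {}
    for structure, param, limit, sense in OBJECTIVES:
        if structure not in dvps:
            raise KeyError(f"missing structure for objective check: {structure}")
        value = float(getattr(dvps[structure], param))
        if sense == "ge":
            ok = value >= limit
        elif sense == "le":
            ok = value <= limit
        else:
            ok = value < limit
        result[f"{structure}_{param}"] = {
            "value": value,
            "limit": limit,
            "sense": sense,
            "pass": bool(ok),
        }
    return result


def all_objectives_pass(dvps: dict[str, DVPSet]) -> bool:
    return all(row["pass"] for row in check_objectives(dvps).values())
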