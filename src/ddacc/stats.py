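"""Paired nonparametric statistics and cohort report tables.

The three treatment arms are compared pairwise per dose-volume parameter with
the Wilcoxon signed-rank test (exact null distribution by enumeration of all
2^n sign assignments for small n, normal approximation with continuity and tie
correction otherwise), Bonferroni correction for the three arm pairs, and the
paired Cohen's d (d_z = mean of differences / SD of differences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dvh import DVH

__all__ = [
    "PairedSample",
    "ComparisonResult",
    "PopulationDVH",
    "wilcoxon_signed_rank",
    "bonferroni",
    "cohens_d",
    "compare_paired",
    "population_dvh",
    "build_report",
]

EXACT_ENUMERATION_LIMIT = 15
N_COMPARISONS = 3  # three treatment approaches -> three pairwise tests


@dataclass
class PairedSample:
    """Per-patient paired measurements for two arms."""

    values_a: np.ndarray
    values_b: np.ndarray
    labels: tuple[str, str] = ("a", "b")

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=np.float64)
        self.values_b = np.asarray(self.values_b, dtype=np.float64)
        if self.values_a.shape != self.values_b.shape or self.values_a.ndim != 1:
            raise ValueError("paired samples must be 1-D and of equal length")
        if self.values_a.size < 2:
            raise ValueError("paired samples need at least 2 patients")

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


@dataclass
class ComparisonResult:
    labels: tuple[str, str]
    p_raw: float
    p_adjusted: float
    cohens_d: float
    n: int


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nonzero differences -> (ranks of |d| with midranks for ties, signs)."""
    nz = diffs[diffs != 0.0]
    ranks = sps.rankdata(np.abs(nz))
    return ranks, np.sign(nz)


def wilcoxon_signed_rank(sample: PairedSample, mode: str = "auto") -> float:
    """Two-sided Wilcoxon signed-rank p value.

    Zero differences are dropped (Wilcoxon's convention); ties are midranked.
    ``mode`` selects the null: "exact" enumerates all 2^n sign assignments
    (n <= 15), "normal-approx" uses the tie-corrected normal approximation
    with continuity correction, "auto" picks exact when feasible.  If every
    difference is zero the test carries no evidence and p = 1.0 is returned
    with a warning.
    """
    ranks, signs = _signed_ranks(sample.differences)
    n = ranks.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1.0", stacklevel=2)
        return 1.0
    w_plus = float(ranks[signs > 0].sum())
    if mode == "auto":
        mode = "exact" if n <= EXACT_ENUMERATION_LIMIT else "normal-approx"
    if mode == "exact":
        if n > EXACT_ENUMERATION_LIMIT:
            raise ValueError(f"exact enumeration limited to n <= {EXACT_ENUMERATION_LIMIT}")
        assignments = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
        w_all = assignments @ ranks
        eps = 1e-9
        p_ge = np.mean(w_all >= w_plus - eps)
        p_le = np.mean(w_all <= w_plus + eps)
        return float(min(1.0, 2.0 * min(p_ge, p_le)))
    if mode == "normal-approx":
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= float(((counts**3 - counts) / 48.0).sum())
        if var <= 0:
            return 1.0
        cc = 0.5 * np.sign(w_plus - mu)  # continuity correction toward the mean
        z = (w_plus - mu - cc) / np.sqrt(var)
        return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    raise ValueError(f"unknown mode {mode!r}")


def bonferroni(p_raw: float, k: int = N_COMPARISONS) -> float:
    """Bonferroni adjustment: min(1, k * p)."""
    if not 0 < p_raw <= 1:
        raise ValueError("p_raw must lie in (0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return min(1.0, k * p_raw)


def cohens_d(sample: PairedSample) -> float:
    """Paired effect size d_z = mean(diff) / SD(diff, n-1 denominator).

    Returns NaN (with a warning) when the differences have zero spread.
    """
    d = sample.differences
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        warnings.warn("zero SD of paired differences; Cohen's d undefined", stacklevel=2)
        return float("nan")
    return float(np.mean(d) / sd)


def compare_paired(sample: PairedSample, mode: str = "auto", k: int = N_COMPARISONS) -> ComparisonResult:
    p = wilcoxon_signed_rank(sample, mode=mode)
    return ComparisonResult(
        labels=sample.labels,
        p_raw=p,
        p_adjusted=bonferroni(p, k),
        cohens_d=cohens_d(sample) if np.std(sample.differences, ddof=1) > 0 else float("nan"),
        n=sample.values_a.size,
    )


@dataclass
class PopulationDVH:
    bin_edges: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    structure_label: str


def population_dvh(dvhs: list[DVH]) -> PopulationDVH:
    """Pointwise mean and SD of cumulative DVH curves across patients.

    Curves are extended onto the union dose range (100 % below each curve's
    first bin is implicit; 0 % beyond its last).
    """
    if not dvhs:
        raise ValueError("no DVHs to summarize")
    width = float(dvhs[0].bin_edges[1] - dvhs[0].bin_edges[0]) if dvhs[0].bin_edges.size > 1 else 0.01
    top = max(float(d.bin_edges[-1]) for d in dvhs)
    edges = np.arange(0.0, top + width / 2, width)
    curves = []
    for d in dvhs:
        v = np.zeros_like(edges)
        m = min(d.cumulative_volume.size, edges.size)
        v[:m] = d.cumulative_volume[:m]
        curves.append(v)
    stack = np.vstack(curves)
    return PopulationDVH(
        bin_edges=edges,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0),
        structure_label=dvhs[0].structure_label,
    )


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------

_ARM_PAIRS = (("refPlan", "conv-IGRT"), ("refPlan", "OA-MRgRT"), ("conv-IGRT", "OA-MRgRT"))
_DVP_COLUMNS = ("D50", "D98", "Dmax", "V56")


def _safe_compare(va: np.ndarray, vb: np.ndarray, labels) -> ComparisonResult:
    """Pairwise comparison, degrading to NaNs for degenerate cohorts (n < 2)."""
    if va.size < 2:
        return ComparisonResult(labels, float("nan"), float("nan"), float("nan"), int(va.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compare_paired(PairedSample(va, vb, labels))


def _median_range(values: np.ndarray) -> str:
    return f"{np.median(values):.1f} ({values.min():.1f}–{values.max():.1f})"


def build_report(cohort_dvps: pd.DataFrame, cohort_ntcps: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summary tables across the cohort.

    Returns per-DVP median (range) per arm, the three pairwise comparisons
    (Wilcoxon p raw/Bonferroni-adjusted, Cohen's d) per structure/DVP and per
    NTCP endpoint, the NTCP summary, and objective-attainment percentages.
    Raises ``ValueError`` if an arm is missing.
    """
    arms = set(cohort_dvps["arm"].unique())
    missing = {"refPlan", "conv-IGRT", "OA-MRgRT"} - arms
    if missing:
        raise ValueError(f"missing arm(s) in DVP table: {sorted(missing)}")

    summary_rows, comparison_rows = [], []
    for structure in sorted(cohort_dvps["structure"].unique()):
        sdf = cohort_dvps[cohort_dvps["structure"] == structure].sort_values("patient")
        for param in _DVP_COLUMNS:
            row = {"structure": structure, "parameter": param}
            for arm in ("refPlan", "conv-IGRT", "OA-MRgRT"):
                vals = sdf[sdf["arm"] == arm][param].to_numpy()
                row[arm] = _median_range(vals)
            summary_rows.append(row)
            for a, b in _ARM_PAIRS:
                va = sdf[sdf["arm"] == a][param].to_numpy()
                vb = sdf[sdf["arm"] == b][param].to_numpy()
                res = _safe_compare(va, vb, (a, b))
                comparison_rows.append(
                    {
                        "structure": structure,
                        "parameter": param,
                        "arm_a": a,
                        "arm_b": b,
                        "p_raw": res.p_raw,
                        "p_adjusted": res.p_adjusted,
                        "cohens_d": res.cohens_d,
                        "n": res.n,
                    }
                )

    ntcp_rows, ntcp_cmp_rows = [], []
    for structure in sorted(cohort_ntcps["structure"].unique()):
        sdf = cohort_ntcps[cohort_ntcps["structure"] == structure].sort_values("patient")
        row = {"structure": structure, "endpoint": sdf["endpoint"].iloc[0]}
        for arm in ("refPlan", "conv-IGRT", "OA-MRgRT"):
            vals = 100.0 * sdf[sdf["arm"] == arm]["ntcp"].to_numpy()
            row[arm] = _median_range(vals)
        ntcp_rows.append(row)
        for a, b in _ARM_PAIRS:
            va = sdf[sdf["arm"] == a]["ntcp"].to_numpy()
            vb = sdf[sdf["arm"] == b]["ntcp"].to_numpy()
            res = _safe_compare(va, vb, (a, b))
            ntcp_cmp_rows.append(
                {
                    "structure": structure,
                    "arm_a": a,
                    "arm_b": b,
                    "p_raw": res.p_raw,
                    "p_adjusted": res.p_adjusted,
                    "n": res.n,
                }
            )

    from .pipeline import objective_attainment

    return {
        "dvp_summary": pd.DataFrame(summary_rows),
        "dvp_comparisons": pd.DataFrame(comparison_rows),
        "ntcp_summary": pd.DataFrame(ntcp_rows),
        "ntcp_comparisons": pd.DataFrame(ntcp_cmp_rows),
        "attainment": objective_attainment(cohort_dvps),
    }
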