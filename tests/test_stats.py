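"""Paired statistics: Wilcoxon signed-rank, Cohen's d, report tables."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ddacc.dvh import DVH
from ddacc.stats import (
    PairedSample,
    bonferroni,
    build_report,
    cohens_d,
    population_dvh,
    wilcoxon_signed_rank,
)


def _enumerate_wilcoxon_p(diffs: np.ndarray) -> float:
    """Independent brute-force oracle: iterate every sign assignment."""
    nz = diffs[diffs != 0]
    ranks = sps.rankdata(np.abs(nz))
    w_obs = ranks[nz > 0].sum()
    n = len(nz)
    w_all = [np.dot(signs, ranks) for signs in itertools.product([0, 1], repeat=n)]
    w_all = np.asarray(w_all)
    p_ge = np.mean(w_all >= w_obs - 1e-9)
    p_le = np.mean(w_all <= w_obs + 1e-9)
    return min(1.0, 2.0 * min(p_ge, p_le))


class TestWilcoxon:
    def test_all_zero_differences_give_p_one(self):
        s = PairedSample(np.ones(6), np.ones(6))
        with pytest.warns(UserWarning, match="zero"):
            assert wilcoxon_signed_rank(s) == 1.0

    def test_six_positive_differences_exact_tail(self):
        s = PairedSample(np.array([1, 2, 3, 4, 5, 6.0]), np.zeros(6))
        assert wilcoxon_signed_rank(s, mode="exact") == pytest.approx(2.0 / 64.0, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_exact_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            diffs = rng.normal(0.5, 1.0, n)
            s = PairedSample(diffs, np.zeros(n))
            assert wilcoxon_signed_rank(s, mode="exact") == pytest.approx(
                _enumerate_wilcoxon_p(diffs), abs=1e-12
            )

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        for n in (6, 8, 10, 12):
            a = rng.normal(1.0, 2.0, n)
            b = rng.normal(0.0, 2.0, n)
            ours = wilcoxon_signed_rank(PairedSample(a, b), mode="exact")
            ref = sps.wilcoxon(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_tracks_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.8, 1.0, 25)
        b = rng.normal(0.0, 1.0, 25)
        ours = wilcoxon_signed_rank(PairedSample(a, b), mode="normal-approx")
        ref = sps.wilcoxon(a, b, alternative="two-sided", method="approx", correction=True).pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_auto_switches_to_approximation_for_large_n(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.5, 1.0, 30)
        s = PairedSample(a, np.zeros(30))
        assert wilcoxon_signed_rank(s, mode="auto") == wilcoxon_signed_rank(
            s, mode="normal-approx"
        )

    def test_ties_are_midranked(self):
        # duplicate |differences| force midranks; p must stay a valid probability
        s = PairedSample(np.array([2.0, 2.0, -2.0, 3.0, 3.0]), np.zeros(5))
        p = wilcoxon_signed_rank(s, mode="exact")
        assert 0 < p <= 1


class TestEffectSizeAndAdjustment:
    def test_bonferroni_definition_and_clamp(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)
        assert bonferroni(0.5, 3) == 1.0
        assert bonferroni(0.2, 1) == pytest.approx(0.2)

    def test_bonferroni_rejects_invalid(self):
        with pytest.raises(ValueError):
            bonferroni(0.0)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)

    def test_paired_d_hand_value(self):
        s = PairedSample(np.array([1.0, 3.0]), np.zeros(2))
        assert cohens_d(s) == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=8), rng.normal(size=8)
        assert cohens_d(PairedSample(a, b)) == pytest.approx(-cohens_d(PairedSample(b, a)))

    def test_degenerate_differences_reported_missing(self):
        s = PairedSample(np.array([2.0, 2.0, 2.0]), np.array([1.0, 1.0, 1.0]))
        with pytest.warns(UserWarning, match="zero SD"):
            assert np.isnan(cohens_d(s))


class TestPopulationDVH:
    @staticmethod
    def _dvh(cum, label="rectum"):
        edges = np.arange(len(cum)) * 0.01
        return DVH(edges, np.asarray(cum, float), label, 8.0)

    def test_single_patient_mean_is_self_sd_zero(self):
        d = self._dvh([100, 80, 40, 0])
        pop = population_dvh([d])
        np.testing.assert_allclose(pop.mean, d.cumulative_volume)
        np.testing.assert_allclose(pop.sd, 0.0)

    def test_identical_curves_have_zero_sd(self):
        d = self._dvh([100, 90, 10, 0])
        pop = population_dvh([d, self._dvh([100, 90, 10, 0])])
        np.testing.assert_allclose(pop.sd, 0.0)

    def test_two_curves_hand_computed(self):
        pop = population_dvh([self._dvh([100, 80, 20, 0]), self._dvh([100, 60, 40, 20])])
        np.testing.assert_allclose(pop.mean, [100, 70, 30, 10])
        np.testing.assert_allclose(pop.sd, [0, 10, 10, 10])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            population_dvh([])


def _toy_cohort(n_patients=6, rng_seed=0, identical=False):
    rng = np.random.default_rng(rng_seed)
    rows, nrows = [], []
    for p in range(n_patients):
        base = {
            "CTV": dict(D50=60.5, D98=58.0, Dmax=61.0, V56=100.0),
            "rectum": dict(D50=20.0, D98=5.0, Dmax=59.5, V56=6.0),
            "bladder": dict(D50=10.0, D98=4.0, Dmax=60.0, V56=3.0),
            "urethra": dict(D50=59.0, D98=58.5, Dmax=60.0, V56=100.0),
        }
        for arm_i, arm in enumerate(("refPlan", "conv-IGRT", "OA-MRgRT")):
            for structure, vals in base.items():
                jitter = 0.0 if identical else rng.normal(0, 0.3) + 0.2 * arm_i
                rows.append(
                    {"patient": f"P{p:03d}", "arm": arm, "structure": structure}
                    | {k: v + (jitter if k != "V56" else 0.0) for k, v in vals.items()}
                )
            for structure in ("rectum", "bladder"):
                nrows.append(
                    {
                        "patient": f"P{p:03d}",
                        "arm": arm,
                        "structure": structure,
                        "endpoint": "late G2+",
                        "geud_eqd2": 60.0,
                        "ntcp": 0.05 if identical else 0.05 + 0.001 * arm_i + rng.normal(0, 1e-4),
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(nrows)


class TestReport:
    def test_zero_variation_cohort_degenerate(self):
        dvps, ntcps = _toy_cohort(identical=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tables = build_report(dvps, ntcps)
        cmp = tables["dvp_comparisons"]
        assert (cmp["p_raw"] == 1.0).all()
        summ = tables["dvp_summary"]
        assert (summ["refPlan"] == summ["conv-IGRT"]).all()

    def test_three_pairwise_comparisons_per_dvp(self):
        dvps, ntcps = _toy_cohort()
        tables = build_report(dvps, ntcps)
        cmp = tables["dvp_comparisons"]
        counts = cmp.groupby(["structure", "parameter"]).size()
        assert (counts == 3).all()

    def test_missing_arm_rejected(self):
        dvps, ntcps = _toy_cohort()
        with pytest.raises(ValueError, match="missing arm"):
            build_report(dvps[dvps.arm != "OA-MRgRT"], ntcps)

    def test_medians_invariant_to_patient_order(self):
        dvps, ntcps = _toy_cohort()
        shuffled = dvps.sample(frac=1.0, random_state=9).reset_index(drop=True)
        t1 = build_report(dvps, ntcps)["dvp_summary"]
        t2 = build_report(shuffled, ntcps)["dvp_summary"]
        pd.testing.assert_frame_equal(t1, t2)

    def test_attainment_counts_violators(self):
        dvps, ntcps = _toy_cohort(n_patients=10, identical=True)
        # push one conv patient's rectum Dmax over the 61 Gy limit
        sel = (dvps.patient == "P003") & (dvps.arm == "conv-IGRT") & (dvps.structure == "rectum")
        dvps.loc[sel, "Dmax"] = 61.4
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            att = build_report(dvps, ntcps)["attainment"]
        row = att[(att.arm == "conv-IGRT") & (att.objective == "rectum_Dmax")]
        assert row["attainment_pct"].iloc[0] == pytest.approx(90.0)
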