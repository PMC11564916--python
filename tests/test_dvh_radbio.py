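"""DVH extraction, objective checking, and LKB radiobiology."""

import numpy as np
import pytest

from ddacc.dvh import (
    DVPSet,
    check_objectives,
    compute_dvh,
    compute_dvps,
    dmax,
    dose_at_volume,
    volume_at_dose,
)
from ddacc.grids import GridSpec, ScalarVolume, StructureMask
from ddacc.radbio import (
    BLADDER_INCONTINENCE_G2,
    RECTUM_LATE_TOXICITY_G2,
    RadiobioParams,
    eqd2_transform,
    geud,
    lkb_ntcp,
)


def _vol_and_mask(doses):
    """One-axis volume holding the given in-mask doses (rest masked out)."""
    n = len(doses)
    grid = GridSpec(shape=(n, 1, 1), spacing=(1.0, 1.0, 1.0))
    vol = ScalarVolume(grid, np.asarray(doses, dtype=float).reshape(n, 1, 1))
    mask = StructureMask(grid, np.ones((n, 1, 1), bool), "CTV")
    return vol, mask


class TestDVH:
    def test_uniform_dose_step_curve(self):
        vol, mask = _vol_and_mask([60.0] * 8)
        dvh = compute_dvh(vol, mask)
        assert volume_at_dose(dvh, 30.0) == 100.0
        assert volume_at_dose(dvh, 60.0) == 100.0
        assert volume_at_dose(dvh, 60.02) == 0.0
        assert dose_at_volume(dvh, 50.0) == pytest.approx(60.0, abs=0.01)
        assert dose_at_volume(dvh, 98.0) == pytest.approx(60.0, abs=0.01)

    def test_two_voxel_dvps_match_enumeration(self):
        vol, mask = _vol_and_mask([50.0, 60.0])
        dvh = compute_dvh(vol, mask)
        assert volume_at_dose(dvh, 55.0) == pytest.approx(50.0)
        assert volume_at_dose(dvh, 56.0) == pytest.approx(50.0)
        assert dose_at_volume(dvh, 50.0) == pytest.approx(60.0, abs=0.011)
        assert dose_at_volume(dvh, 98.0) == pytest.approx(50.0, abs=0.011)
        assert dmax(vol, mask) == 60.0

    def test_q100_gives_minimum_dose(self):
        vol, mask = _vol_and_mask([48.0, 55.0, 60.0])
        dvh = compute_dvh(vol, mask)
        assert dose_at_volume(dvh, 100.0) == pytest.approx(48.0, abs=0.011)

    def test_volume_above_max_dose_is_zero(self):
        vol, mask = _vol_and_mask([10.0, 20.0])
        assert volume_at_dose(compute_dvh(vol, mask), 25.0) == 0.0

    def test_empty_mask_raises(self):
        vol, mask = _vol_and_mask([60.0])
        mask.values[:] = False
        with pytest.raises(ValueError, match="empty mask"):
            compute_dvh(vol, mask)
        with pytest.raises(ValueError, match="empty mask"):
            dmax(vol, mask)

    def test_out_of_range_quantile_rejected(self):
        vol, mask = _vol_and_mask([60.0])
        dvh = compute_dvh(vol, mask)
        for q in (0.0, -5.0, 101.0):
            with pytest.raises(ValueError):
                dose_at_volume(dvh, q)

    def test_dvps_match_brute_force_on_random_masks(self):
        """Dq% and VdGy agree with direct voxel enumeration within one bin."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(5, 400))
            doses = rng.uniform(0, 65, n)
            vol, mask = _vol_and_mask(doses)
            dvh = compute_dvh(vol, mask)
            srt = np.sort(doses)[::-1]
            for q in (50.0, 98.0):
                brute = srt[int(np.ceil(q / 100.0 * n)) - 1]
                assert dose_at_volume(dvh, q) == pytest.approx(brute, abs=0.0101)
            brute_v56 = 100.0 * (doses >= 56.0).mean()
            assert volume_at_dose(dvh, 56.0) == pytest.approx(brute_v56, abs=0.5)
            assert dmax(vol, mask) == pytest.approx(doses.max(), abs=1e-12)

    def test_self_consistency_up_to_local_plateau(self):
        """Dq(V(d)) returns d wherever the curve decreases; where the dose
        distribution has a gap the curve is flat and the far end of the
        plateau (the next voxel value) is the correct answer."""
        rng = np.random.default_rng(7)
        doses = rng.uniform(20, 60, 500)
        vol, mask = _vol_and_mask(doses)
        dvh = compute_dvh(vol, mask)
        for d in (30.0, 40.0, 50.0, 55.0):
            v = volume_at_dose(dvh, d)
            next_voxel_above = doses[doses >= d].min()
            roundtrip = dose_at_volume(dvh, v)
            assert d - 0.011 <= roundtrip <= next_voxel_above + 0.011

    def test_dvp_ordering(self):
        rng = np.random.default_rng(11)
        vol, mask = _vol_and_mask(rng.uniform(10, 62, 300))
        dvps = compute_dvps(vol, {"CTV": mask})["CTV"]
        assert dvps.Dmax >= dvps.D50 >= dvps.D98


class TestObjectives:
    @staticmethod
    def _passing_dvps():
        return {
            "CTV": DVPSet("CTV", D50=60.5, D98=58.0, Dmax=61.5, V56=100.0),
            "rectum": DVPSet("rectum", D50=20.0, D98=5.0, Dmax=60.0, V56=5.0),
            "bladder": DVPSet("bladder", D50=10.0, D98=4.0, Dmax=60.5, V56=2.0),
            "urethra": DVPSet("urethra", D50=59.0, D98=58.0, Dmax=60.0, V56=100.0),
        }

    def test_all_pass(self):
        checks = check_objectives(self._passing_dvps())
        assert all(row["pass"] for row in checks.values())

    def test_single_violation_isolated(self):
        dvps = self._passing_dvps()
        dvps["CTV"].D98 = 56.9
        checks = check_objectives(dvps)
        failed = [k for k, v in checks.items() if not v["pass"]]
        assert failed == ["CTV_D98"]

    def test_boundary_inclusive_for_coverage(self):
        dvps = self._passing_dvps()
        dvps["CTV"].D98 = 57.00
        assert check_objectives(dvps)["CTV_D98"]["pass"]

    def test_missing_structure_raises(self):
        dvps = self._passing_dvps()
        del dvps["rectum"]
        with pytest.raises(KeyError, match="rectum"):
            check_objectives(dvps)


class TestEQD2:
    def test_two_gray_fractions_are_fixed_point(self):
        for n in (10, 20, 30):
            assert eqd2_transform(2.0 * n, n, 3.0) == pytest.approx(2.0 * n, rel=1e-12)

    def test_hand_computed_values(self):
        assert eqd2_transform(60.0, 20, 3.0) == pytest.approx(72.0, rel=1e-12)
        assert eqd2_transform(60.0, 20, 1.5) == pytest.approx(60.0 * 4.5 / 3.5, rel=1e-12)

    def test_monotone_in_dose(self):
        d = np.linspace(0, 80, 100)
        out = eqd2_transform(d, 20, 1.5)
        assert np.all(np.diff(out) > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            eqd2_transform(60.0, 0, 3.0)
        with pytest.raises(ValueError):
            eqd2_transform(60.0, 20, -1.0)


class TestGEUD:
    def test_n_equal_one_is_mean(self):
        vol, mask = _vol_and_mask([40.0, 50.0, 60.0])
        assert geud(vol, mask, 1.0) == pytest.approx(50.0, rel=1e-12)

    def test_uniform_dose_invariant(self):
        vol, mask = _vol_and_mask([55.0] * 10)
        for n in (0.02, 0.12, 0.5, 1.0):
            assert geud(vol, mask, n) == pytest.approx(55.0, rel=1e-9)

    def test_two_voxel_power_mean(self):
        vol, mask = _vol_and_mask([50.0, 60.0])
        expected = 60.0 * (0.5 * (50.0 / 60.0) ** 50 + 0.5) ** 0.02
        assert geud(vol, mask, 0.02) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(59.17, abs=0.01)

    def test_small_n_approaches_max(self):
        # exact sandwich: dmax * (1/N)^n <= gEUD <= dmax for any dose set
        rng = np.random.default_rng(5)
        doses = rng.uniform(30, 64, 200)
        vol, mask = _vol_and_mask(doses)
        g_small = geud(vol, mask, 0.001)
        dmax_val = doses.max()
        assert dmax_val * (1.0 / doses.size) ** 0.001 <= g_small <= dmax_val + 1e-9
        assert geud(vol, mask, 0.02) < g_small

    def test_invalid_n(self):
        vol, mask = _vol_and_mask([50.0])
        with pytest.raises(ValueError):
            geud(vol, mask, 0.0)


class TestLKB:
    def test_half_probability_at_td50(self):
        for params in (BLADDER_INCONTINENCE_G2, RECTUM_LATE_TOXICITY_G2):
            assert lkb_ntcp(params.TD50, params).ntcp == pytest.approx(0.5, abs=1e-12)

    def test_zero_dose_bladder_value(self):
        expected = 1.0 / (1.0 + np.exp(1.0 / 0.24))
        assert lkb_ntcp(0.0, BLADDER_INCONTINENCE_G2).ntcp == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.01527, abs=2e-5)

    def test_monotone_limit(self):
        doses = np.linspace(0, 400, 50)
        vals = [lkb_ntcp(d, RECTUM_LATE_TOXICITY_G2).ntcp for d in doses]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] > 0.999

    def test_logistic_symmetry_about_td50(self):
        p = BLADDER_INCONTINENCE_G2
        for x in (1.0, 5.0, 20.0, 75.0):
            total = lkb_ntcp(p.TD50 + x, p).ntcp + lkb_ntcp(p.TD50 - x, p).ntcp
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            RadiobioParams(alpha_beta=3.0, TD50=80.0, m=0.0, n=0.1)
        with pytest.raises(ValueError):
            RadiobioParams(alpha_beta=-1.0, TD50=80.0, m=0.2, n=0.1)
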