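"""Synthetic cohort generator: objectives, determinism, ground-truth contracts."""

import dataclasses

import numpy as np
import pytest

from ddacc.dvh import check_objectives, compute_dvps, dose_at_volume, compute_dvh
from ddacc.grids import ScalarVolume, VectorField
from ddacc.phantom import (
    PhantomParams,
    generate_fraction,
    generate_fraction_doses,
    generate_reference_case,
    sample_fraction_anatomy,
)
from ddacc.registration import apply_field_to_mask, apply_field_to_volume, jacobian_determinant


def _collapsed(params, case, **overrides):
    base = dict(
        prostate_shift_sd=0.0,
        drift_mm_per_fraction=(0.0, 0.0, 0.0),
        bladder_volume_range=(case.ref_structures["bladder"].volume_cm3,) * 2,
        rectum_volume_range=(case.ref_structures["rectum"].volume_cm3,) * 2,
    )
    base.update(overrides)
    return dataclasses.replace(params, **base)


class TestParams:
    def test_schedule_consistency_enforced(self):
        with pytest.raises(ValueError, match="prescription"):
            PhantomParams(n_fractions=19)

    def test_volume_ranges_validated(self):
        with pytest.raises(ValueError, match="ranges"):
            PhantomParams(bladder_volume_range=(200.0, 100.0))


class TestReferenceCase:
    def test_all_planning_objectives_pass(self, ref_case):
        dvps = compute_dvps(
            ref_case.ref_dose,
            {k: ref_case.ref_structures[k] for k in ("CTV", "bladder", "rectum", "urethra")},
        )
        checks = check_objectives(dvps)
        failed = [k for k, v in checks.items() if not v["pass"]]
        assert failed == []

    def test_structure_topology(self, ref_case):
        s = ref_case.ref_structures
        assert s["CTV"].values.any()
        assert np.all(s["PTV"].values[s["CTV"].values])  # CTV inside PTV
        assert not np.logical_and(s["CTV"].values, s["bladder"].values).any()
        assert not np.logical_and(s["CTV"].values, s["rectum"].values).any()
        assert np.all(s["CTV"].values[s["urethra"].values])  # urethra within CTV

    def test_same_seed_bit_identical(self, default_params, ref_case):
        again = generate_reference_case(default_params, 1)
        np.testing.assert_array_equal(again.ref_dose.values, ref_case.ref_dose.values)
        for lab in ("CTV", "bladder", "rectum", "urethra", "PTV"):
            np.testing.assert_array_equal(
                again.ref_structures[lab].values, ref_case.ref_structures[lab].values
            )

    def test_dose_nonnegative_finite(self, ref_case):
        assert np.all(np.isfinite(ref_case.ref_dose.values))
        assert ref_case.ref_dose.values.min() >= 0.0


class TestFractionAnatomy:
    def test_zero_variance_config_deforms_nothing(self, ref_case, default_params):
        p = _collapsed(default_params, ref_case)
        fx = sample_fraction_anatomy(ref_case, 3, p)
        assert fx.gt_dvf_ref_to_fx.max_displacement() < 1e-6

    def test_fraction_one_is_the_reference(self, ref_case, default_params):
        fx = sample_fraction_anatomy(ref_case, 1, default_params)
        assert fx.gt_dvf_ref_to_fx.max_displacement() == 0.0
        np.testing.assert_array_equal(fx.image.values, ref_case.ref_image.values)

    def test_organ_volumes_within_configured_ranges(self, ref_case, default_params, fraction10):
        lo_b, hi_b = default_params.bladder_volume_range
        lo_r, hi_r = default_params.rectum_volume_range
        for fx in (fraction10, sample_fraction_anatomy(ref_case, 4, default_params)):
            assert lo_b <= fx.structures["bladder"].volume_cm3 <= hi_b
            assert lo_r <= fx.structures["rectum"].volume_cm3 <= hi_r

    def test_ctv_volume_preserved_when_only_organs_vary(self, ref_case, default_params):
        p = dataclasses.replace(
            default_params, prostate_shift_sd=0.0, drift_mm_per_fraction=(0.0, 0.0, 0.0)
        )
        fx = sample_fraction_anatomy(ref_case, 5, p)
        ref_vol = ref_case.ref_structures["CTV"].volume_cm3
        assert fx.structures["CTV"].volume_cm3 == pytest.approx(ref_vol, rel=0.05)

    def test_ground_truth_reproduces_fraction_structures(self, ref_case, fraction10):
        """The generator's contract: fraction masks are the warped reference masks."""
        for lab in ("CTV", "bladder", "rectum", "urethra"):
            warped = apply_field_to_mask(
                ref_case.ref_structures[lab], fraction10.gt_dvf_ref_to_fx
            )
            np.testing.assert_array_equal(warped.values, fraction10.structures[lab].values)

    def test_fields_are_foldfree(self, fraction10):
        assert jacobian_determinant(fraction10.gt_dvf_ref_to_fx).min() > 0.05

    def test_invalid_fraction_index_rejected(self, ref_case, default_params):
        with pytest.raises(ValueError, match="index"):
            sample_fraction_anatomy(ref_case, 0, default_params)


class TestFractionDoses:
    def test_zero_variation_arms_coincide(self, ref_case, default_params):
        p = _collapsed(default_params, ref_case)
        fx = generate_fraction(ref_case, 1, p)
        n = p.n_fractions
        np.testing.assert_allclose(
            fx.dose_oa.values, ref_case.ref_dose.values / n, atol=1e-6
        )
        np.testing.assert_allclose(
            fx.dose_conv.values, ref_case.ref_dose.values / n, atol=1e-6
        )

    def test_daily_replan_meets_daily_coverage(self, ref_case, default_params, fraction10):
        fx = generate_fraction_doses(ref_case, fraction10, default_params)
        total = ScalarVolume(ref_case.grid, fx.dose_oa.values * default_params.n_fractions)
        dvh = compute_dvh(total, fx.structures["CTV"])
        assert dose_at_volume(dvh, 98.0) >= 57.0

    def test_conv_dose_is_analytically_shifted_reference(self, ref_case, default_params):
        p = _collapsed(default_params, ref_case, drift_mm_per_fraction=(0.0, -2.5, 0.0))
        fx = generate_fraction(ref_case, 2, p)  # pure (0, -5, 0) mm shift
        t_true = np.array(fx.applied_shift)
        np.testing.assert_allclose(t_true, (0.0, -5.0, 0.0))
        # oracle: reference dose evaluated at analytically shifted coordinates
        u = np.broadcast_to(
            (-t_true).astype(np.float32), (*ref_case.grid.shape, 3)
        ).copy()
        expected = apply_field_to_volume(ref_case.ref_dose, VectorField(ref_case.grid, u))
        n = p.n_fractions
        diff = np.abs(fx.dose_conv.values * n - expected.values)
        assert diff.mean() < 0.3  # limited only by the registration residual

    def test_arms_deliver_comparable_integral_dose(self, ref_case, default_params, fraction10):
        fx = generate_fraction_doses(ref_case, fraction10, default_params)
        ratio = float(fx.dose_oa.values.sum() / fx.dose_conv.values.sum())
        assert 0.8 < ratio < 1.2


class TestCohort:
    def test_smoke_scale_cohort_shape_and_determinism(self):
        from ddacc.phantom import generate_cohort

        p = PhantomParams(n_patients=1, n_fractions=2, dose_per_fraction=30.0, seed=7)
        cohort_a = generate_cohort(p)
        assert len(cohort_a) == 1
        assert len(cohort_a[0].fractions) == 2
        cohort_b = generate_cohort(p)
        np.testing.assert_array_equal(
            cohort_a[0].fractions[1].dose_conv.values,
            cohort_b[0].fractions[1].dose_conv.values,
        )
        np.testing.assert_array_equal(
            cohort_a[0].fractions[1].image.values, cohort_b[0].fractions[1].image.values
        )

    def test_different_seeds_differ(self, ref_case, default_params):
        fx_a = sample_fraction_anatomy(ref_case, 2, default_params, seed=100)
        fx_b = sample_fraction_anatomy(ref_case, 2, default_params, seed=101)
        assert not np.allclose(fx_a.applied_shift, fx_b.applied_shift)
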