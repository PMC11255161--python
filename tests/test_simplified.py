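import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lutadose import (
    DomainError,
    SingleTimePointObservation,
    generate_cohort,
    make_region,
    run_reference_dosimetry,
    run_simplified,
    sm1_dose,
    sm2_dose,
    sm3_dose,
)
from lutadose.fitting import TACFit
from lutadose.simplified import TP_LABELS, fill_from_reference
from _helpers import constant_kinetics_config

LN2 = math.log(2)

activities = st.floats(min_value=1000.0, max_value=10000.0)
doses = st.floats(min_value=100.0, max_value=10000.0)


class TestSM2SM3ClosedForms:
    def test_sm2_identity_when_activity_unchanged(self):
        assert sm2_dose(4000.0, 6200.0, 6200.0) == pytest.approx(4000.0)

    def test_sm2_hand_value(self):
        assert sm2_dose(4000.0, 6200.0, 5000.0) == pytest.approx(3225.8, abs=0.05)

    def test_sm2_zero_activity(self):
        assert sm2_dose(4000.0, 6200.0, 0.0) == 0.0

    def test_sm3_hand_value(self):
        # mean normalized dose (0.6 + 0.8)/2 = 0.7 mGy/MBq times 6000 MBq
        assert sm3_dose(0.6 * 6200, 6200.0, 0.8 * 5900, 5900.0, 6000.0) == pytest.approx(4200.0)

    def test_sm3_reduces_to_sm2_for_equal_kinetics(self):
        assert sm3_dose(4000.0, 6200.0, 4000.0, 6200.0, 5500.0) == pytest.approx(
            sm2_dose(4000.0, 6200.0, 5500.0)
        )

    @settings(deadline=None, derandomize=True)
    @given(doses, activities, doses, activities, activities)
    def test_sm3_is_mean_of_sm2_variants(self, d1, a1, d2, a2, ai):
        lhs = sm3_dose(d1, a1, d2, a2, ai)
        rhs = 0.5 * (sm2_dose(d1, a1, ai) + sm2_dose(d2, a2, ai))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_nonpositive_reference_activity_rejected(self):
        with pytest.raises(DomainError):
            sm2_dose(4000.0, 0.0, 5000.0)
        with pytest.raises(DomainError):
            sm3_dose(4000.0, 6200.0, 4000.0, -5.0, 5000.0)


class TestSM1Dose:
    region = make_region("r", "kidney", mass_g=300.0)
    ref_fit = TACFit("monoexp", 150.0, LN2 / 40.0)
    ref_tia = 150.0 / (LN2 / 40.0)

    def obs(self, t, measured, injected=6200.0):
        return SingleTimePointObservation("P01", 2, "r", t, measured, injected, "48h")

    def test_matching_observation_reproduces_reference(self):
        rec = sm1_dose(self.ref_fit, self.ref_tia,
                       self.obs(48.0, float(self.ref_fit.predict(48.0))), self.region)
        assert rec["tia_MBqh"] == pytest.approx(self.ref_tia, rel=1e-12)

    def test_linear_in_measured_activity(self):
        full = sm1_dose(self.ref_fit, self.ref_tia,
                        self.obs(48.0, float(self.ref_fit.predict(48.0))), self.region)
        half = sm1_dose(self.ref_fit, self.ref_tia,
                        self.obs(48.0, 0.5 * float(self.ref_fit.predict(48.0))), self.region)
        assert half["dose_mGy"] == pytest.approx(0.5 * full["dose_mGy"], rel=1e-12)

    def test_inherits_reference_half_life(self):
        rec = sm1_dose(self.ref_fit, self.ref_tia, self.obs(48.0, 100.0), self.region)
        assert rec["t_eff_h"] == pytest.approx(40.0)

    def test_error_against_brute_force_oracle(self):
        """When the true later-cycle half-life differs from cycle 1, the SM1/true
        dose ratio equals (lam_true/lam_ref) * exp((lam_ref - lam_true) * t)."""
        lam_ref, lam_true = LN2 / 40.0, LN2 / 55.0
        a_true = 120.0
        true_tia = a_true / lam_true
        for t in (2.0, 24.0, 48.0, 120.0):
            measured = a_true * math.exp(-lam_true * t)
            rec = sm1_dose(self.ref_fit, self.ref_tia, self.obs(t, measured), self.region)
            expected_ratio = (lam_true / lam_ref) * math.exp((lam_ref - lam_true) * t)
            assert rec["tia_MBqh"] / true_tia == pytest.approx(expected_ratio, rel=1e-9)

    def test_out_of_window_time_rejected(self):
        with pytest.raises(DomainError):
            self.obs(500.0, 10.0)

    def test_cycle_one_observation_rejected(self):
        with pytest.raises(DomainError):
            SingleTimePointObservation("P01", 1, "r", 48.0, 10.0, 6200.0, "48h")

    def test_trapezoid_reference_uses_tail_curve(self, caplog):
        trap = TACFit("trapezoid_tail", 150.0, LN2 / 40.0, tail_points_used=2)
        import logging

        with caplog.at_level(logging.WARNING, logger="lutadose.simplified"):
            rec = sm1_dose(trap, 8000.0, self.obs(48.0, float(trap.predict(48.0))), self.region)
        assert rec["tia_MBqh"] == pytest.approx(8000.0, rel=1e-12)
        assert any("trapezoid" in m for m in caplog.messages)


@pytest.fixture(scope="module")
def frozen():
    cfg = constant_kinetics_config(activity_MBq_sd=0.0)
    cohort = generate_cohort(cfg)
    rm, fits = run_reference_dosimetry(cohort, return_fits=True)
    return cohort, rm, fits


class TestRunSimplified:

    @pytest.mark.parametrize("tp", TP_LABELS)
    def test_sm1_equals_rm_without_variability(self, frozen, tp):
        cohort, rm, fits = frozen
        sm1 = run_simplified(cohort, rm, "SM1", tp_label=tp, cycle1_fits=fits)
        merged = sm1.merge(rm, on=["patient", "cycle", "region"], suffixes=("_sm", "_rm"))
        assert len(merged) == len(sm1) > 0
        assert np.allclose(
            merged["norm_dose_mGy_per_MBq_sm"], merged["norm_dose_mGy_per_MBq_rm"],
            rtol=1e-6,
        )

    def test_sm1_kidney_bookkeeping(self, default_cohort, default_rm):
        rm, fits = default_rm
        sm1 = run_simplified(default_cohort, rm, "SM1", tp_label="48h", cycle1_fits=fits)
        kidneys = sm1[sm1["kind"] == "kidney"]
        assert len(kidneys) == 16 * 3
        assert set(kidneys["cycle"]) == {2, 3, 4}

    def test_sm2_totals_with_equal_activities(self, frozen):
        cohort, rm, _ = frozen
        sm2 = run_simplified(cohort, rm, "SM2")
        from lutadose import cumulate_doses

        totals = cumulate_doses(sm2[sm2["kind"] == "kidney"])
        rm_c1 = rm[(rm["kind"] == "kidney") & (rm["cycle"] == 1)].set_index("patient")
        for _, row in totals.iterrows():
            d1 = rm_c1.loc[row.patient, "dose_mGy"]
            assert row.total_Gy == pytest.approx(4 * d1 / 1000, rel=1e-9)

    def test_sm3_copies_two_reference_cycles(self, frozen):
        cohort, rm, _ = frozen
        sm3 = run_simplified(cohort, rm, "SM3")
        copied = sm3[sm3["fit_model"] == "copied_rm"]
        assert set(copied["cycle"]) == {1, 2}
        assert set(sm3["cycle"]) == {1, 2, 3, 4}

    def test_sm2_for_lesions_refused(self, frozen):
        cohort, rm, _ = frozen
        with pytest.raises(DomainError, match="lesion"):
            run_simplified(cohort, rm, "SM2", include_lesions=True)

    def test_fill_from_reference_restores_cycle_one(self, frozen):
        cohort, rm, fits = frozen
        sm1 = run_simplified(cohort, rm, "SM1", tp_label="48h", cycle1_fits=fits)
        filled = fill_from_reference(sm1, rm)
        assert set(filled["cycle"]) == {1, 2, 3, 4}
        assert (filled["method"] == "SM1").all()
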