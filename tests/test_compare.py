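import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lutadose import (
    DomainError,
    between_cycle_test,
    bland_altman,
    cycle_deviation_summary,
    percent_difference,
    rmse,
)
from lutadose.compare import compare_methods, pair_records, patient_mean_lesion_records

finite = st.floats(min_value=0.1, max_value=100.0)


class TestPercentDifference:
    def test_equal_values(self):
        assert percent_difference(1.0, 1.0) == 0.0

    def test_reference_denominator(self):
        assert percent_difference(1.1, 1.0) == pytest.approx(10.0)

    def test_mean_denominator(self):
        assert percent_difference(1.1, 1.0, "mean") == pytest.approx(9.524, abs=1e-3)

    def test_zero_denominator_rejected(self):
        with pytest.raises(DomainError):
            percent_difference(1.0, 0.0)


class TestRMSE:
    def test_identical_pairs(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    @pytest.mark.parametrize(
        "diffs, expected", [((1.0, 0.0), 0.70711), ((3.0, 4.0), 3.53553)]
    )
    def test_hand_values(self, diffs, expected):
        d_rm = np.zeros(len(diffs))
        assert rmse(np.asarray(diffs), d_rm) == pytest.approx(expected, abs=1e-5)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(finite, min_size=1, max_size=20))
    def test_sign_flip_invariance(self, diffs):
        d = np.asarray(diffs)
        zero = np.zeros_like(d)
        assert rmse(d, zero) == pytest.approx(rmse(zero, d))

    def test_constant_ratio_identity(self):
        d_rm = np.array([1.0, 2.0, 5.0, 9.0])
        d_sm = 1.3 * d_rm
        assert rmse(d_sm, d_rm) == pytest.approx(0.3 * np.sqrt(np.mean(d_rm**2)))

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            rmse([], [])


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_bias_pct == 0.0
        assert res.loa_pct == 0.0
        assert res.rmse == 0.0

    def test_constant_ratio(self):
        d_rm = np.array([1.0, 2.0, 3.0])
        res = bland_altman(1.2 * d_rm, d_rm)
        assert res.mean_bias_pct == pytest.approx(20.0)
        assert res.loa_pct == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_spread(self):
        # percent differences -10, 0, +10: bias 0, sample SD 10, LoA 19.6
        d_rm = np.array([1.0, 1.0, 1.0])
        d_sm = np.array([0.9, 1.0, 1.1])
        res = bland_altman(d_sm, d_rm)
        assert res.mean_bias_pct == pytest.approx(0.0, abs=1e-9)
        assert res.loa_pct == pytest.approx(19.6)
        assert res.loa_low_pct == pytest.approx(-19.6)
        assert res.loa_high_pct == pytest.approx(19.6)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(finite, finite), min_size=2, max_size=30))
    def test_pair_order_invariance(self, pairs):
        d_sm = np.array([p[0] for p in pairs])
        d_rm = np.array([p[1] for p in pairs])
        perm = np.random.default_rng(0).permutation(len(pairs))
        a = bland_altman(d_sm, d_rm)
        b = bland_altman(d_sm[perm], d_rm[perm])
        assert a.mean_bias_pct == pytest.approx(b.mean_bias_pct)
        assert a.loa_pct == pytest.approx(b.loa_pct)
        assert a.rmse == pytest.approx(b.rmse)

    def test_single_pair_rejected(self):
        with pytest.raises(DomainError):
            bland_altman([1.0], [1.0])


def _records(values_by_cycle, kind="kidney", patients=4):
    rows = []
    for p in range(patients):
        for cyc, v in values_by_cycle.items():
            val = v[p] if isinstance(v, (list, tuple, np.ndarray)) else v
            rows.append(
                {"patient": f"P{p:02d}", "cycle": cyc, "region": "r", "kind": kind,
                 "method": "RM", "norm_dose_mGy_per_MBq": val}
            )
    return pd.DataFrame(rows)


class TestCycleDeviation:
    def test_constant_cycles_have_zero_deviation(self):
        per, summary = cycle_deviation_summary(_records({1: 1.0, 2: 1.0, 3: 1.0}))
        assert (per["deviation_pct"] == 0).all()
        assert (summary["mean_deviation_pct"] == 0).all()

    def test_halved_dose_is_minus_fifty(self):
        per, _ = cycle_deviation_summary(_records({1: 1.0, 2: 0.5}))
        assert np.allclose(per.loc[per.cycle == 2, "deviation_pct"], -50.0)

    def test_missing_cycle_one_excluded(self, caplog):
        df = _records({2: 1.0, 3: 1.0})
        per, summary = cycle_deviation_summary(df)
        assert per.empty

    def test_default_cohort_lesions_decline(self, default_rm):
        records, _ = default_rm
        lesions = records[records["kind"].str.startswith("lesion")]
        _, summary = cycle_deviation_summary(lesions)
        cyc4 = summary[summary["cycle"] == 4]
        assert (cyc4["mean_deviation_pct"] < 0).all()


class TestBetweenCycleTest:
    def test_identical_values_give_p_one(self):
        p = between_cycle_test(_records({1: 1.0, 2: 1.0, 3: 1.0}), "kidney", n_perm=200)
        assert p == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        df = _records({c: list(rng.lognormal(0, 0.3, 6)) for c in (1, 2, 3, 4)}, patients=6)
        p1 = between_cycle_test(df, "kidney", n_perm=500, seed=9)
        p2 = between_cycle_test(df, "kidney", n_perm=500, seed=9)
        assert p1 == p2

    def test_strong_decline_detected(self, default_rm):
        records, _ = default_rm
        p = between_cycle_test(records, "lesion", n_perm=2000, seed=0)
        assert p < 0.05

    def test_single_cycle_rejected(self):
        with pytest.raises(DomainError):
            between_cycle_test(_records({1: 1.0}), "kidney")

    def test_type_one_error_controlled(self):
        """Null simulations: rejection rate at alpha=0.05 stays near nominal."""
        rng = np.random.default_rng(21)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            df = _records(
                {c: list(rng.lognormal(0, 0.4, 8)) for c in (1, 2, 3, 4)}, patients=8
            )
            if between_cycle_test(df, "kidney", n_perm=199, seed=int(rng.integers(2**31))) <= 0.05:
                rejections += 1
        assert rejections / n_sim <= 0.07


class TestPairing:
    def test_pooled_kidney_pairs_bookkeeping(self, default_cohort, default_rm):
        from lutadose import run_simplified

        rm, fits = default_rm
        sm1 = run_simplified(default_cohort, rm, "SM1", tp_label="24h", cycle1_fits=fits)
        pairs = pair_records(sm1, rm)
        assert len(pairs[pairs["kind"] == "kidney"]) == 16 * 3
        table = compare_methods(sm1, rm, by=("kind",))
        assert set(table["kind"]) >= {"kidney", "parotid", "submandibular"}

    def test_patient_mean_lesion_collapse(self, default_rm):
        rm, _ = default_rm
        collapsed = patient_mean_lesion_records(rm)
        assert (collapsed["kind"] == "lesion_mean").all()
        assert collapsed.groupby(["patient", "cycle"]).size().max() == 1
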