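"""Dual-reader protocol: disagreement rules, adjudication, kappa and ICC."""

import numpy as np
import pytest

from focaldx.agreement import (
    PairingError,
    adjudicate,
    cohen_kappa,
    flag_disagreements,
    icc,
)

from conftest import make_reading


def dopa_pair(lesion_a, lesion_b, ref=4.0, call_a="focal", call_b="focal", t=10.0):
    a = [make_reading(timepoint_min=t, suv_max_lesion=lesion_a, suv_max_reference=ref,
                      visual_call=call_a)]
    b = [make_reading(reader_id="R2", timepoint_min=t, suv_max_lesion=lesion_b,
                      suv_max_reference=ref, visual_call=call_b)]
    return a, b


class TestDisagreementFlags:
    def test_suv_difference_above_ten_percent(self):
        """|10.0 - 11.5| / mean = 0.1395 > 0.10 fires the SUV rule."""
        flags = flag_disagreements(*dopa_pair(10.0, 11.5))
        assert len(flags) == 1
        assert "suv_gt_10pct" in flags[0].rules_triggered

    def test_conclusion_differs_without_other_rules(self):
        """Ratios 1.40 vs 1.50: |delta| = 0.10 <= 0.2 and SUVs within 10%,
        but the calls at the predefined cut-off 1.45 disagree."""
        flags = flag_disagreements(*dopa_pair(1.40 * 4.0, 1.50 * 4.0))
        assert len(flags) == 1
        assert flags[0].rules_triggered == ("conclusion_differs",)

    def test_identical_reads_produce_no_flags(self):
        a, _ = dopa_pair(6.0, 6.0)
        assert flag_disagreements(a, a) == []

    def test_visual_disagreement(self):
        flags = flag_disagreements(*dopa_pair(6.0, 6.0, call_a="focal", call_b="non_focal"))
        assert flags[0].rules_triggered == ("visual_differs",)

    def test_output_invariant_to_reader_order(self, rng):
        a = [make_reading(timepoint_min=t, suv_max_lesion=float(l), suv_max_reference=4.0)
             for t, l in zip((10.0, 30.0, 60.0), rng.uniform(4, 8, 3))]
        b = [make_reading(reader_id="R2", timepoint_min=r.timepoint_min,
                          suv_max_lesion=r.suv_max_lesion * float(rng.uniform(0.85, 1.15)),
                          suv_max_reference=4.0)
             for r in a]
        fab = flag_disagreements(a, b)
        fba = flag_disagreements(b, a)
        assert [f.rules_triggered for f in fab] == [f.rules_triggered for f in fba]

    def test_unmatched_patients_raise_pairing_error(self):
        a, b = dopa_pair(6.0, 6.0)
        b = [make_reading(patient_id="P2", reader_id="R2")]
        with pytest.raises(PairingError):
            flag_disagreements(a, b)


class TestAdjudication:
    def test_third_reader_replaces_flagged_series(self):
        a, b = dopa_pair(10.0, 11.5)
        c = [make_reading(reader_id="R3", suv_max_lesion=10.5)]
        flags = flag_disagreements(a, b)
        consensus, resolved = adjudicate(a, b, c, flags)
        assert consensus[0].suv_max_lesion == 10.5
        assert resolved[0].resolved_by == "R3"

    def test_unflagged_series_average_the_readers(self):
        a, b = dopa_pair(6.0, 6.2)
        consensus, resolved = adjudicate(a, b, [], [])
        assert consensus[0].suv_max_lesion == pytest.approx(6.1)
        assert resolved == []


class TestCohenKappa:
    def test_perfect_agreement(self):
        r = cohen_kappa(list("aabb"), list("aabb"))
        assert r.estimate == 1.0

    def test_two_by_two_table_hand_value(self):
        """Counts [[20,5],[10,15]]: p_o = 0.70, p_e = 0.50, kappa = 0.40."""
        A = ["a"] * 25 + ["b"] * 25
        B = ["a"] * 20 + ["b"] * 5 + ["a"] * 10 + ["b"] * 15
        r = cohen_kappa(A, B)
        assert r.estimate == pytest.approx(0.40)
        assert r.ci_low < 0.40 < r.ci_high

    def test_matches_statsmodels_variance(self):
        sm_ir = pytest.importorskip("statsmodels.stats.inter_rater")
        A = ["a"] * 25 + ["b"] * 25
        B = ["a"] * 20 + ["b"] * 5 + ["a"] * 10 + ["b"] * 15
        r = cohen_kappa(A, B)
        sm = sm_ir.cohens_kappa(np.array([[20, 5], [10, 15]]))
        assert r.estimate == pytest.approx(sm.kappa, abs=1e-12)
        se = (r.ci_high - r.ci_low) / (2 * 1.959963984540054)
        assert se == pytest.approx(np.sqrt(sm.var_kappa), rel=1e-9)

    def test_matches_sklearn_on_random_labels(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        A = rng.choice(list("abc"), size=60).tolist()
        B = rng.choice(list("abc"), size=60).tolist()
        assert cohen_kappa(A, B).estimate == pytest.approx(
            sk.cohen_kappa_score(A, B), abs=1e-12
        )

    def test_complete_balanced_disagreement(self):
        A = ["a"] * 5 + ["b"] * 5
        B = ["b"] * 5 + ["a"] * 5
        assert cohen_kappa(A, B).estimate == -1.0

    def test_constant_equal_raters_undefined(self):
        r = cohen_kappa(["a"] * 10, ["a"] * 10)
        assert r.undefined

    def test_symmetric_in_raters(self, rng):
        A = rng.choice(["x", "y"], size=40).tolist()
        B = rng.choice(["x", "y"], size=40).tolist()
        assert cohen_kappa(A, B).estimate == pytest.approx(cohen_kappa(B, A).estimate)


class TestIcc:
    def test_duplicated_reads_give_unity(self, rng):
        x = rng.uniform(1, 3, size=20)
        r = icc(np.column_stack([x, x]))
        assert r.estimate == pytest.approx(1.0)

    def test_fixed_offset_lowers_absolute_agreement_only(self, rng):
        x = rng.uniform(1, 3, size=30)
        data = np.column_stack([x, x + 2.0])
        absolute = icc(data, form="absolute_agreement").estimate
        consistency = icc(data, form="consistency").estimate
        assert consistency == pytest.approx(1.0)
        assert absolute < consistency - 0.3

    def test_independent_noise_near_zero(self, rng):
        data = rng.standard_normal((800, 2))
        assert abs(icc(data).estimate) < 0.1

    @pytest.mark.parametrize("form, pg_type", [("absolute_agreement", "ICC(A,1)"),
                                               ("consistency", "ICC(C,1)")])
    def test_matches_pingouin(self, rng, form, pg_type):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        true = rng.uniform(1, 4, size=25)
        data = np.column_stack([true + 0.2 * rng.standard_normal(25),
                                true + 0.2 * rng.standard_normal(25) + 0.1])
        ours = icc(data, form=form)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(25), 2),
            "rater": np.tile(["A", "B"], 25),
            "value": data.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="value").set_index("Type").loc[pg_type]
        assert ours.estimate == pytest.approx(float(ref["ICC"]), abs=1e-9)
        ref_lo, ref_hi = ref["CI95"]  # pingouin rounds bounds to 2 decimals
        assert ours.ci_low == pytest.approx(float(ref_lo), abs=0.011)
        assert ours.ci_high == pytest.approx(float(ref_hi), abs=0.011)

    def test_symmetric_in_raters(self, rng):
        data = rng.uniform(0, 1, size=(15, 2))
        assert icc(data).estimate == pytest.approx(icc(data[:, ::-1]).estimate)

    def test_zero_variance_undefined(self):
        r = icc(np.ones((5, 2)))
        assert r.undefined
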