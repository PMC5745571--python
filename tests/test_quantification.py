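"""SUV scoring: time-maximum ratios, cut-off rule, localization concordance."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from focaldx.cohort import PatientRecord
from focaldx.quantification import (
    MissingDataError,
    SuvScore,
    classify_by_cutoff,
    compute_suv_max,
    compute_suv_ratio,
    localization_concordance,
)

from conftest import make_reading


def series(values, tracer="DOPA"):
    """values: {timepoint: (lesion, reference)}"""
    return [
        make_reading(tracer=tracer, timepoint_min=t, suv_max_lesion=l, suv_max_reference=r)
        for t, (l, r) in values.items()
    ]


class TestSuvRatio:
    def test_elementwise_division_and_max(self):
        s = compute_suv_ratio(series({10: (4.8, 4.0), 30: (6.0, 4.0), 60: (5.5, 4.4)}))
        assert s.score == pytest.approx(1.50)
        assert s.timepoint_of_max == 30

    def test_lesion_equals_reference_gives_unity_at_earliest(self):
        s = compute_suv_ratio(series({10: (4.0, 4.0), 30: (5.0, 5.0)}))
        assert s.score == 1.0 and s.timepoint_of_max == 10

    def test_single_timepoint(self):
        s = compute_suv_ratio(series({45: (6.93, 4.2)}))
        assert s.score == pytest.approx(6.93 / 4.2)
        assert s.timepoint_of_max == 45

    def test_empty_series_is_missing_data(self):
        with pytest.raises(MissingDataError):
            compute_suv_ratio([])

    @given(k=st.floats(0.1, 10.0), base=st.floats(0.5, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, k, base):
        """Multiplying lesion and reference at a timepoint by k > 0 leaves
        the ratio unchanged."""
        plain = compute_suv_ratio(series({10: (base * 1.5, base), 30: (base, base)}))
        scaled = compute_suv_ratio(series({10: (k * base * 1.5, k * base), 30: (base, base)}))
        assert scaled.score == pytest.approx(plain.score)

    def test_monotone_in_lesion_antitone_in_reference(self):
        base = compute_suv_ratio(series({10: (6.0, 4.0)})).score
        assert compute_suv_ratio(series({10: (6.5, 4.0)})).score > base
        assert compute_suv_ratio(series({10: (6.0, 4.5)})).score < base


class TestSuvMax:
    def test_max_over_timepoints(self):
        s = compute_suv_max(series({30: (5.0, 4.0), 60: (9.43, 4.0)}, tracer="DOTANOC"))
        assert s.score == 9.43 and s.timepoint_of_max == 60

    def test_single_value(self):
        s = compute_suv_max(series({45: (2.31, 4.0)}, tracer="DOTANOC"))
        assert s.score == 2.31

    def test_ties_break_to_earliest(self):
        s = compute_suv_max(series({10: (5.0, 4.0), 30: (5.0, 4.1), 60: (5.0, 3.9)},
                                   tracer="DOTANOC"))
        assert s.score == 5.0 and s.timepoint_of_max == 10


class TestCutoffRule:
    @pytest.mark.parametrize(
        "score, cutoff, expected",
        [
            (1.47, 1.44, "focal"),  # smallest focal ratio clears the cut-off
            (1.73, 1.44, "focal"),  # the study's single false positive
            (1.44, 1.44, "non_focal"),  # boundary: strict inequality
            (1.12, 1.44, "non_focal"),
        ],
    )
    def test_strict_inequality(self, score, cutoff, expected):
        assert classify_by_cutoff(score, cutoff) == expected

    def test_raising_cutoff_never_creates_focal_calls(self, rng):
        scores = rng.uniform(0.5, 5.0, size=100)
        for s in scores:
            calls = [classify_by_cutoff(s, c) for c in (1.0, 1.44, 2.0, 4.0)]
            # once non_focal at some cutoff, non_focal at every higher cutoff
            seen_nonfocal = False
            for c in calls:
                if c == "non_focal":
                    seen_nonfocal = True
                assert not (seen_nonfocal and c == "focal")


def _focal_patient(pid, region):
    return PatientRecord(patient_id=pid, sex="male", age_at_scan_months=5.0,
                         surgery=True, histology="focal", lesion_location_surgical=region)


def _score(pid, location):
    return SuvScore(patient_id=pid, tracer="DOPA", reader_id="R1", score=2.0,
                    timepoint_of_max=10.0, predicted_location=location)


class TestLocalization:
    def test_twenty_of_twentytwo(self):
        patients = [_focal_patient(f"P{i}", "head") for i in range(22)]
        scores = {f"P{i}": _score(f"P{i}", "head" if i < 20 else "tail") for i in range(22)}
        frac, matches, eligible, _ = localization_concordance(scores, patients)
        assert (matches, eligible) == (20, 22)
        assert frac == pytest.approx(0.909, abs=5e-4)

    def test_perfect_seven(self):
        patients = [_focal_patient(f"P{i}", "body") for i in range(7)]
        scores = {f"P{i}": _score(f"P{i}", "body") for i in range(7)}
        frac, *_ = localization_concordance(scores, patients)
        assert frac == 1.0

    def test_zero_eligible_reports_absent(self):
        frac, matches, eligible, _ = localization_concordance({}, [])
        assert frac is None and eligible == 0

    def test_ectopic_lesion_requires_ectopic_prediction(self):
        patients = [_focal_patient("P0", "ectopic")]
        frac_miss, *_ = localization_concordance({"P0": _score("P0", "head")}, patients)
        frac_hit, *_ = localization_concordance({"P0": _score("P0", "ectopic")}, patients)
        assert frac_miss == 0.0 and frac_hit == 1.0

    def test_nonsurgical_patients_not_eligible(self):
        p = PatientRecord(patient_id="P0", sex="male", age_at_scan_months=5.0, surgery=False)
        frac, _, eligible, _ = localization_concordance({"P0": _score("P0", "head")}, [p])
        assert frac is None and eligible == 0
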