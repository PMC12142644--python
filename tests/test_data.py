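"""Cohort IO, normalization, imputation, and splitting."""

import math

import numpy as np
import pytest

from secondgram.data import (Cohort, CohortSchema, PatientRecord, SplitCohorts,
                             denormalize, impute_within_vector, load_cohort,
                             normalize, split_cohort, write_cohort)

from conftest import make_tiny_cohort


CSV_BASIC = """patient_id,volA,volB,volA__followup,volB__followup,disease
P1,10.0,3.0,9.5,2.8,1
P2,12.0,4.0,,,0
P3,11.0,3.5,10.0,3.1,0
"""


class TestLoadCohort:
    def test_basic_parse_with_absent_followup(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(CSV_BASIC)
        cohort = load_cohort(path)
        assert len(cohort) == 3
        assert cohort.feature_names == ["volA", "volB"]
        assert cohort.label_names == ["disease"]
        assert [r.has_followup for r in cohort] == [True, False, True]
        np.testing.assert_array_equal(cohort.records[0].i2, [9.5, 2.8])

    def test_duplicate_id_error_names_the_id(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("patient_id,volA,disease\nP1,1.0,0\nP1,2.0,1\n")
        with pytest.raises(ValueError, match="P1"):
            load_cohort(path)

    def test_header_only_yields_empty_cohort(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("patient_id,volA,volB,disease\n")
        cohort = load_cohort(path, CohortSchema(label_cols=["disease"]))
        assert len(cohort) == 0
        assert cohort.n_features == 2

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("patient_id,volA,disease\nP1,oops,0\n")
        with pytest.raises(ValueError, match="volA"):
            load_cohort(path)

    def test_roundtrip_through_write(self, tmp_path):
        cohort = make_tiny_cohort(normalized=False)
        path = tmp_path / "c.csv"
        write_cohort(cohort, path)
        back = load_cohort(path)
        assert len(back) == len(cohort)
        for a, b in zip(cohort, back):
            assert a.patient_id == b.patient_id
            np.testing.assert_allclose(a.i1, b.i1)
            assert a.has_followup == b.has_followup


class TestNormalize:
    def test_endpoints_and_midpoint(self):
        rec = PatientRecord("P1", [10.0, 30.0], None, [0.0])
        rec2 = PatientRecord("P2", [30.0, 10.0], None, [0.0])
        rec3 = PatientRecord("P3", [20.0, 20.0], None, [0.0])
        cohort = Cohort([rec, rec2, rec3], ["a", "b"], ["l"])
        out = normalize(cohort)
        np.testing.assert_allclose(out.records[0].i1, [-1.0, 1.0])
        np.testing.assert_allclose(out.records[1].i1, [1.0, -1.0])
        np.testing.assert_allclose(out.records[2].i1, [0.0, 0.0])

    def test_constant_feature_maps_to_zero_and_inverts(self):
        recs = [PatientRecord(f"P{i}", [5.0, float(i)], None, [0.0])
                for i in range(3)]
        cohort = Cohort(recs, ["const", "x"], ["l"])
        out = normalize(cohort)
        assert all(r.i1[0] == 0.0 for r in out)
        raw = denormalize(out)
        assert all(r.i1[0] == 5.0 for r in raw)

    def test_out_of_range_values_clipped_with_supplied_ranges(self):
        cohort = Cohort([PatientRecord("P1", [100.0], None, [])], ["a"], [])
        out = normalize(cohort, ranges=np.array([[0.0, 10.0]]))
        assert out.records[0].i1[0] == 1.0

    def test_roundtrip_identity_within_1e9(self):
        rng = np.random.default_rng(3)
        recs = [PatientRecord(f"P{i}", rng.uniform(5, 50, 6),
                              rng.uniform(5, 50, 6), [1.0]) for i in range(20)]
        cohort = Cohort(recs, [f"f{j}" for j in range(6)], ["l"])
        back = denormalize(normalize(cohort))
        for a, b in zip(cohort, back):
            np.testing.assert_allclose(b.i1, a.i1, atol=1e-9)
            np.testing.assert_allclose(b.i2, a.i2, atol=1e-9)

    def test_midpoint_denormalizes_exactly(self):
        cohort = Cohort([PatientRecord("P1", [0.0], None, [])], ["a"], [],
                        feature_ranges=np.array([[10.0, 30.0]]),
                        is_normalized=True)
        assert denormalize(cohort).records[0].i1[0] == 20.0

    def test_denormalize_without_ranges_errors(self, tiny_cohort):
        tiny_cohort.feature_ranges = None
        with pytest.raises(ValueError, match="ranges"):
            denormalize(tiny_cohort)


class TestImpute:
    def test_no_missing_returns_unchanged(self, tiny_cohort):
        assert impute_within_vector(tiny_cohort) is tiny_cohort

    def test_collinear_feature_recovered_exactly(self):
        rng = np.random.default_rng(0)
        x1 = rng.uniform(-1, 1, 12)
        recs = []
        for i in range(12):
            v = np.array([x1[i], 2.0 * x1[i]])
            if i == 5:
                v[1] = np.nan
            recs.append(PatientRecord(f"P{i}", v, None, []))
        cohort = Cohort(recs, ["x1", "x2"], [])
        out = impute_within_vector(cohort, seed=0)
        assert abs(out.records[5].i1[1] - 2.0 * x1[5]) < 1e-6
        # observed entries are untouched, bitwise
        for i, rec in enumerate(out):
            assert rec.i1[0] == recs[i].i1[0]

    def test_entirely_missing_feature_errors_with_name(self):
        recs = [PatientRecord(f"P{i}", [1.0 * i, np.nan], None, [])
                for i in range(4)]
        cohort = Cohort(recs, ["ok", "gone"], [])
        with pytest.raises(ValueError, match="gone"):
            impute_within_vector(cohort)


def _counts(split: SplitCohorts):
    def pair(c):
        return (sum(r.has_followup for r in c),
                sum(not r.has_followup for r in c))
    return pair(split.train), pair(split.validation), pair(split.test)


class TestSplit:
    def test_biobank_scale_cell_sizes(self):
        # 41,706 patients of whom 4,997 have follow-up imaging
        recs = [PatientRecord(f"P{i}", [0.0], [0.0] if i < 4997 else None, [])
                for i in range(41706)]
        cohort = Cohort(recs, ["f"], [])
        split = split_cohort(cohort, 0.2, 0.1, seed=0)
        assert _counts(split) == ((3597, 33038), (400, 3671), (1000, 0))

    def test_small_all_longitudinal(self):
        recs = [PatientRecord(f"P{i}", [0.0], [0.0], []) for i in range(10)]
        split = split_cohort(Cohort(recs, ["f"], []), 0.2, 0.1, seed=1)
        assert _counts(split) == ((7, 0), (1, 0), (2, 0))

    @pytest.mark.parametrize("n_long,n_nonlong", [
        (n_long, n_nonlong)
        for n_long in range(2, 21, 3)
        for n_nonlong in range(0, 31, 6)
    ])
    def test_ceiling_arithmetic_all_small_cohorts(self, n_long, n_nonlong):
        recs = [PatientRecord(f"L{i}", [0.0], [0.0], []) for i in range(n_long)]
        recs += [PatientRecord(f"N{i}", [0.0], None, []) for i in range(n_nonlong)]
        split = split_cohort(Cohort(recs, ["f"], []), 0.2, 0.1, seed=2)
        n_test = math.ceil(0.2 * n_long)
        rest_long = n_long - n_test
        n_val_long = math.ceil(0.1 * rest_long)
        n_val_non = math.ceil(0.1 * n_nonlong) if n_nonlong else 0
        assert _counts(split) == (
            (rest_long - n_val_long, n_nonlong - n_val_non),
            (n_val_long, n_val_non),
            (n_test, 0),
        )

    def test_same_seed_reproduces_membership(self):
        cohort = make_tiny_cohort(10, 20, seed=5)
        a = split_cohort(cohort, seed=7)
        b = split_cohort(cohort, seed=7)
        for ca, cb in ((a.train, b.train), (a.validation, b.validation),
                       (a.test, b.test)):
            assert [r.patient_id for r in ca] == [r.patient_id for r in cb]

    def test_too_few_longitudinal_errors(self):
        recs = [PatientRecord("P0", [0.0], [0.0], []),
                PatientRecord("P1", [0.0], None, [])]
        with pytest.raises(ValueError, match="longitudinal"):
            split_cohort(Cohort(recs, ["f"], []))

    def test_test_records_always_have_real_followup(self):
        cohort = make_tiny_cohort(6, 10, seed=3)
        # one record carries a synthetic follow-up; it must not reach test
        cohort.records[0].i2_is_synthetic = True
        split = split_cohort(cohort, seed=0)
        assert all(r.has_real_followup for r in split.test)
        ids = {r.patient_id for r in split.test}
        assert cohort.records[0].patient_id not in ids
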