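import math

import numpy as np
import pytest
from scipy import stats

from tsallisseg import (
    BinaryMask,
    LesionRecord,
    PatientRecord,
    REFERENCE_ADC_GROUPS,
    adc_group_test,
    compute_adc,
    mann_whitney_u,
    reference_cohort,
    roi_statistics,
    summarize,
)
from tsallisseg.cohort import read_cohort_tsv, write_cohort_tsv
from tsallisseg.errors import ContractError, StatisticsError, ValidationError


class TestComputeADC:
    def test_e_fold_decay(self):
        adc = compute_adc(np.array([[1000.0]]), np.array([[367.879441]]), 0, 1000)
        assert adc[0, 0] == pytest.approx(1.0, rel=1e-6)

    def test_equal_signals_zero(self):
        adc = compute_adc(np.array([[500.0]]), np.array([[500.0]]))
        assert adc[0, 0] == 0.0

    def test_negative_adc_returned(self):
        adc = compute_adc(np.array([[100.0]]), np.array([[200.0]]))
        assert adc[0, 0] < 0

    def test_nonpositive_signal_invalid(self):
        adc = compute_adc(np.array([[0.0, 100.0]]), np.array([[50.0, -1.0]]))
        assert np.isnan(adc).all()

    def test_b_value_validation(self):
        with pytest.raises(ContractError):
            compute_adc(np.ones((2, 2)), np.ones((2, 2)), 1000, 0)


class TestRoiStatistics:
    def test_constant_roi(self):
        adc = np.full((3, 3), 0.62)
        n, mean, sd = roi_statistics(adc, BinaryMask(np.ones((3, 3), dtype=np.uint8)))
        assert (n, mean, sd) == (9, pytest.approx(0.62), 0.0)

    def test_two_point(self):
        n, mean, sd = roi_statistics(
            np.array([[0.5, 0.7]]), BinaryMask(np.array([[1, 1]], dtype=np.uint8))
        )
        assert n == 2 and mean == pytest.approx(0.6) and sd == pytest.approx(0.1414, abs=1e-4)

    def test_invalid_voxels_excluded(self):
        adc = np.array([[0.5, np.nan]])
        n, mean, _ = roi_statistics(adc, BinaryMask(np.array([[1, 1]], dtype=np.uint8)))
        assert n == 1 and mean == 0.5

    def test_all_invalid_raises(self):
        with pytest.raises(StatisticsError):
            roi_statistics(np.array([[np.nan]]), BinaryMask(np.array([[1]], dtype=np.uint8)))


class TestMannWhitney:
    def test_separated_samples_enumeration(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], method="exact")
        assert res.U == 0.0
        assert res.p_two_sided == pytest.approx(2 / 20)

    def test_identical_samples_degenerate(self):
        res = mann_whitney_u([1.0, 1.0], [1.0, 1.0], method="exact")
        assert res.p_two_sided == 1.0 and res.U == 2.0

    def test_symmetry(self, rng):
        x, y = rng.normal(size=6), rng.normal(0.5, 1, size=7)
        a = mann_whitney_u(x, y, method="exact")
        b = mann_whitney_u(y, x, method="exact")
        assert a.U == pytest.approx(a.n1 * a.n2 - b.U)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_matches_scipy_exact_tie_free(self, rng):
        for _ in range(25):
            x, y = rng.normal(size=7), rng.normal(0.3, 1, size=8)
            ours = mann_whitney_u(x, y, method="exact").p_two_sided
            ref = stats.mannwhitneyu(x, y, method="exact", alternative="two-sided").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_enumeration_handles_ties(self):
        # with midranks, enumeration path must agree with a direct count
        x, y = [1.0, 2.0, 2.0], [2.0, 3.0, 4.0]
        res = mann_whitney_u(x, y, method="exact")
        assert 0 < res.p_two_sided <= 1
        assert res.U == stats.mannwhitneyu(x, y, alternative="two-sided").statistic

    def test_exact_vs_normal_agree(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=8), rng.normal(0.4, 1, size=8)
            pe = mann_whitney_u(x, y, method="exact").p_two_sided
            pn = mann_whitney_u(x, y, method="normal_approx").p_two_sided
            assert abs(pe - pn) < 0.02

    def test_exact_limited_to_small_n(self, rng):
        with pytest.raises(ContractError):
            mann_whitney_u(rng.normal(size=11), rng.normal(size=11), method="exact")

    def test_exact_p_values_valid_under_null(self, rng):
        """Permutation p-values control type-I error up to enumeration granularity."""
        alpha = 0.05
        hits = 0
        reps = 500
        for _ in range(reps):
            pooled = rng.normal(size=12)
            if mann_whitney_u(pooled[:6], pooled[6:], method="exact").p_two_sided <= alpha:
                hits += 1
        assert hits / reps <= alpha + 1 / math.comb(12, 6) + 2 * math.sqrt(alpha / reps)


class TestReferenceCohort:
    def test_headline_counts(self):
        patients, lesions = reference_cohort()
        s = summarize(patients, lesions)
        assert s.n_patients == 15
        assert s.n_lesions == 25
        assert s.multiplicity == {"single": 10, "multiple": 5}
        assert s.enhancement == {"mass_nodular": 17, "striped": 4, "patchy": 3, "ring": 1}
        assert s.composition == {"solid": 24, "cystic": 1}
        assert s.n_with_signs == 8
        assert s.n_with_edema == 12
        assert s.sex == {"M": 11, "F": 4}
        assert s.histology == {"DLBCL": 12, "Burkitt": 3}

    def test_imaging_marginals(self):
        s = summarize(*reference_cohort())
        assert s.dwi_signal == {
            "homogeneous_high": 5,
            "uneven_high": 2,
            "intermediate": 3,
            "not_done": 5,
        }
        assert s.mrs_lip_peak == {"present": 2, "absent": 2, "not_done": 11}
        assert s.t1_signal["low"] + s.t1_signal["slightly_low"] == 22
        assert s.t1_signal["intermediate"] == 3
        assert s.t2_signal == {"slightly_high": 20, "intermediate": 3, "mixed_slightly_high": 2}
        # pooled hemisphere + vermis count, with the remaining sites itemized
        assert s.location["cerebellar_hemisphere"] + s.location["cerebellar_vermis"] == 15
        assert s.location["midbrain"] == 2
        assert s.location["cerebellopontine_angle"] == 2
        assert s.location["fourth_ventricle"] == 1
        assert s.location["supratentorial"] == 5
        assert sum(s.location.values()) == s.n_lesions

    def test_reference_adc_groups(self):
        assert REFERENCE_ADC_GROUPS["tumor"] == {"n": 10, "mean": 0.62, "sd": 0.095}
        assert REFERENCE_ADC_GROUPS["contralateral"] == {"n": 10, "mean": 0.73, "sd": 0.038}


class TestSummarize:
    def test_empty_cohort(self):
        s = summarize([], [])
        assert s.n_patients == 0 and s.n_lesions == 0
        assert all(v == 0 for v in s.enhancement.values())

    def test_duplication_doubles_counts(self):
        patients, lesions = reference_cohort()
        doubled_p = patients + [
            PatientRecord(**{**p.__dict__, "patient_id": p.patient_id + "b"}) for p in patients
        ]
        doubled_l = lesions + [
            LesionRecord(**{**l.__dict__, "patient_id": l.patient_id + "b"}) for l in lesions
        ]
        s1, s2 = summarize(patients, lesions), summarize(doubled_p, doubled_l)
        assert s2.n_lesions == 2 * s1.n_lesions
        assert all(s2.enhancement[k] == 2 * v for k, v in s1.enhancement.items())
        assert s2.n_with_edema == 2 * s1.n_with_edema

    def test_multiplicity_inconsistency_detected(self):
        patients, lesions = reference_cohort()
        bad = [
            PatientRecord(**{**patients[0].__dict__, "multiplicity": "multiple"})
        ] + patients[1:]
        with pytest.raises(ValidationError, match="P01"):
            summarize(bad, lesions)

    def test_orphan_lesion_detected(self):
        patients, lesions = reference_cohort()
        orphan = LesionRecord(**{**lesions[0].__dict__, "patient_id": "PXX"})
        with pytest.raises(ValidationError, match="PXX"):
            summarize(patients, lesions + [orphan])

    def test_enum_validation(self):
        with pytest.raises(ValidationError):
            LesionRecord(
                patient_id="P1",
                location="nowhere",
                t1_signal="low",
                t2_signal="slightly_high",
                enhancement="ring",
                composition="solid",
            )


class TestAdcGroupTest:
    def _patients(self, tumor, contra):
        return [
            PatientRecord(
                patient_id=f"P{i}",
                age=50,
                sex="M",
                multiplicity="single",
                adc_tumor=t,
                adc_contralateral=c,
            )
            for i, (t, c) in enumerate(zip(tumor, contra))
        ]

    def test_separated_groups_enumeration(self):
        # distinct within-group values, fully separated between groups
        tumor = [0.50, 0.51, 0.52, 0.53, 0.54]
        contra = [0.90, 0.91, 0.92, 0.93, 0.94]
        res = adc_group_test(self._patients(tumor, contra))
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(2 / 252)

    def test_identical_groups(self):
        vals = [0.6, 0.61, 0.62, 0.63]
        res = adc_group_test(self._patients(vals, vals))
        assert res.p_two_sided == 1.0

    def test_insufficient_data(self):
        with pytest.raises(StatisticsError):
            adc_group_test(self._patients([0.5], [0.7]))

    def test_reference_cohort_has_no_individual_adc(self):
        patients, _ = reference_cohort()
        with pytest.raises(StatisticsError):
            adc_group_test(patients)


class TestTsvIO:
    def test_round_trip(self, tmp_path):
        patients, lesions = reference_cohort()
        write_cohort_tsv(patients, lesions, tmp_path / "p.tsv", tmp_path / "l.tsv")
        rp, rl = read_cohort_tsv(tmp_path / "p.tsv", tmp_path / "l.tsv")
        assert rp == patients and rl == lesions

    def test_malformed_enum_named_by_row(self, tmp_path):
        patients, lesions = reference_cohort()
        write_cohort_tsv(patients, lesions, tmp_path / "p.tsv", tmp_path / "l.tsv")
        text = (tmp_path / "l.tsv").read_text().replace("mass_nodular", "blobby", 1)
        (tmp_path / "l.tsv").write_text(text)
        with pytest.raises(ValidationError, match="row 0"):
            read_cohort_tsv(tmp_path / "p.tsv", tmp_path / "l.tsv")
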