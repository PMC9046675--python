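import numpy as np
import pytest

from metasynopsis import (
    BiasResult,
    GradeTriplet,
    MetaResult,
    combine_evidence,
    fprp,
    fprp_category,
    fprp_from_summary,
    grade_venice,
    power_at_or,
    venice_category,
)
from metasynopsis.bias import SensitivityReport
from metasynopsis.records import AssociationDataset, StudyRecord


class TestVeniceCategory:
    @pytest.mark.parametrize(
        "grade, category",
        [
            ("AAA", "strong"),
            ("ABA", "moderate"),
            ("ABC", "weak"),
            ("ACA", "weak"),
            ("BBB", "moderate"),
            ("B-C", "weak"),
            ("BCC", "weak"),
        ],
    )
    def test_letter_mapping(self, grade, category):
        assert venice_category(GradeTriplet.parse(grade)) == category

    def test_render_roundtrips(self):
        for text in ("AAA", "B-C", "ACA"):
            assert GradeTriplet.parse(text).render() == text


def _meta(i2, k=5, se=0.05):
    return MetaResult(
        k=k, theta_hat=0.2, se_hat=se, ci_low=1.1, ci_high=1.35, p=1e-4,
        Q=4.0, df=k - 1, i2=i2, tau2=0.0, model="fixed",
    )


def _clean_bias(egger_p=0.5, begg_p=0.5):
    return BiasResult(0.1, 0.2, egger_p, 0.1, begg_p)


def _sens(robust=True):
    return SensitivityReport([], None, None, robust)


def _counted_dataset(per_study=(500, 1000, 500), k=5):
    records = [
        StudyRecord(
            study_id=f"s{i}", variant_id="rs1", outcome_name="d",
            theta=0.2, se=0.05, effect_allele="C", other_allele="A",
            case_genotypes=per_study, control_genotypes=per_study,
        )
        for i in range(k)
    ]
    return AssociationDataset("rs1", "d", records)


class TestGradeVenice:
    def test_all_clean_grades_aaa(self):
        ds = _counted_dataset()  # 20,000 effect alleles in total
        triplet = grade_venice(_meta(i2=0.0), _clean_bias(), _sens(), ds)
        assert triplet.render() == "AAA"

    def test_moderate_heterogeneity_downgrades_replication(self):
        ds = _counted_dataset()
        triplet = grade_venice(_meta(i2=40.0), _clean_bias(), _sens(), ds)
        assert triplet.render() == "ABA"

    def test_significant_egger_downgrades_bias_protection(self):
        ds = _counted_dataset()
        triplet = grade_venice(_meta(i2=0.0), _clean_bias(egger_p=0.02), _sens(), ds)
        assert triplet.render() == "AAC"

    def test_fragile_sensitivity_downgrades_bias_protection(self):
        ds = _counted_dataset()
        triplet = grade_venice(_meta(i2=0.0), _clean_bias(), _sens(robust=False), ds)
        assert triplet.bias_protection == "C"

    def test_small_allele_count_grades_c(self):
        ds = _counted_dataset(per_study=(8, 4, 0), k=3)  # 24 effect alleles
        triplet = grade_venice(_meta(i2=0.0, k=3), _clean_bias(), _sens(), ds)
        assert triplet.amount == "C"

    def test_missing_inputs_leave_letters_ungraded(self):
        triplet = grade_venice(_meta(i2=None), None, None, None)
        assert triplet.render() == "---"


class TestPower:
    def test_published_configuration(self):
        assert power_at_or(0.0922, 0.05, 1.2) == pytest.approx(0.50702, abs=1e-5)

    def test_vanishing_se_gives_full_power(self):
        assert power_at_or(1e-6, 0.05, 1.2) == pytest.approx(1.0)

    def test_null_effect_gives_alpha(self):
        assert power_at_or(0.1, 0.05, 1.0000001) == pytest.approx(0.05, abs=1e-4)

    def test_reciprocal_target_is_equivalent(self):
        assert power_at_or(0.1, 0.05, 1.2) == pytest.approx(
            power_at_or(0.1, 0.05, 1 / 1.2)
        )

    def test_monotone_in_se_and_effect(self):
        ses = np.linspace(0.02, 0.5, 20)
        powers = [power_at_or(s, 0.05, 1.2) for s in ses]
        assert all(a >= b - 1e-12 for a, b in zip(powers, powers[1:]))
        targets = np.linspace(1.05, 2.0, 20)
        powers = [power_at_or(0.2, 0.05, t) for t in targets]
        assert all(b >= a - 1e-12 for a, b in zip(powers, powers[1:]))


class TestFPRP:
    def test_closed_form_value(self):
        res = fprp(0.05, 1.0, 0.05)
        assert res.value == pytest.approx(0.05 * 0.95 / (0.05 * 0.95 + 0.05), abs=1e-5)

    def test_no_power_means_certain_false_positive(self):
        assert fprp(0.05, 1e-9, 0.05).value == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize(
        "value, category",
        [(0.040, "strong"), (0.050, "moderate"), (0.150, "moderate"),
         (0.200, "weak"), (0.254, "weak")],
    )
    def test_category_boundaries(self, value, category):
        assert fprp_category(value) == category

    def test_monotone_in_alpha_power_and_prior(self):
        alphas = np.linspace(1e-4, 0.2, 15)
        vals = [fprp(a, 0.5, 0.05).value for a in alphas]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        powers = np.linspace(0.05, 1.0, 15)
        vals = [fprp(0.01, p, 0.05).value for p in powers]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        priors = np.linspace(0.01, 0.5, 15)
        vals = [fprp(0.01, 0.5, pi).value for pi in priors]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_from_summary_reproduces_published_asthma_row(self):
        res = fprp_from_summary(1.053, 1.023, 1.084, 4.86e-4)
        assert round(res.value, 3) == 0.009
        assert res.category == "strong"


class TestCombineEvidence:
    @pytest.mark.parametrize(
        "venice, fprp_cat, final",
        [
            ("weak", "strong", "moderate"),
            ("strong", "weak", "moderate"),
            ("moderate", "strong", "strong"),
            ("strong", "strong", "strong"),
            ("weak", "weak", "weak"),
            ("moderate", "moderate", "moderate"),
        ],
    )
    def test_shift_with_saturation(self, venice, fprp_cat, final):
        res = combine_evidence(venice, fprp_cat)
        assert res.final == final

    def test_final_never_more_than_one_level_away(self):
        levels = ("weak", "moderate", "strong")
        for v in levels:
            for f in levels:
                res = combine_evidence(v, f)
                assert abs(levels.index(res.final) - levels.index(v)) <= 1
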