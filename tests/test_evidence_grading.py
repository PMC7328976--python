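"""Venice letter grades, composite rule, FPRP upgrade, and the full chain."""

import itertools

import pytest

import metacred as mc
from metacred.catalogue import EVIDENCE_GRADES, FPRP_CATEGORIES


class TestLetterGrades:
    @pytest.mark.parametrize(
        "amount, expected", [(1500, "A"), (1001, "A"), (1000, "B"), (100, "B"), (99, "C"), (0, "C")]
    )
    def test_amount(self, amount, expected):
        assert mc.grade_amount(amount) == expected

    @pytest.mark.parametrize(
        "i2, expected",
        [(10.9, "A"), (24.9, "A"), (25.0, "B"), (36.2, "B"), (50.0, "B"), (84.3, "C")],
    )
    def test_replication(self, i2, expected):
        assert mc.grade_replication(i2) == expected


class TestBiasGrade:
    def test_small_or_without_gwas_is_c(self):
        grade, rules = mc.grade_bias(1.10, gwas_replicated=False, harbord_p=0.6)
        assert grade == "C"
        assert "bias:small-or-no-gwas" in rules

    def test_small_or_with_gwas_rescued_to_a(self):
        grade, rules = mc.grade_bias(1.13, gwas_replicated=True, harbord_p=0.6,
                                     sensitivity_stable=True)
        assert grade == "A"

    def test_protective_small_or_symmetric(self):
        # OR 0.90 has magnitude 1/0.90 = 1.11 < 1.15
        grade, _ = mc.grade_bias(0.90, gwas_replicated=False, harbord_p=0.6)
        assert grade == "C"
        grade, _ = mc.grade_bias(0.80, gwas_replicated=False, harbord_p=0.6)
        assert grade == "A"

    def test_harbord_unavailable_is_b(self):
        grade, rules = mc.grade_bias(1.30, harbord_p=None)
        assert grade == "B"
        assert "bias:harbord-unavailable" in rules

    def test_significant_harbord_is_c(self):
        grade, _ = mc.grade_bias(1.30, harbord_p=0.05)
        assert grade == "C"

    def test_unstable_sensitivity_is_c(self):
        grade, _ = mc.grade_bias(1.30, harbord_p=0.6, sensitivity_stable=False)
        assert grade == "C"


class TestCompositeRule:
    def test_exhaustive_table(self):
        for amount, replication, bias in itertools.product("ABC", repeat=3):
            got = mc.composite_venice(amount, replication, bias)
            if "C" in (amount, replication, bias):
                assert got == "weak"
            elif (amount, replication, bias) == ("A", "A", "A"):
                assert got == "strong"
            else:
                assert got == "moderate"


class TestFprpUpgrade:
    def test_exhaustive_table(self):
        for initial, category in itertools.product(EVIDENCE_GRADES, FPRP_CATEGORIES):
            got = mc.apply_fprp_upgrade(initial, category)
            if category == "<0.05":
                expected = {"weak": "moderate", "moderate": "strong", "strong": "strong"}[initial]
            else:
                expected = initial
            assert got == expected


class TestOrderRespecting:
    def test_worsening_any_letter_never_improves_composite(self):
        order = {"weak": 0, "moderate": 1, "strong": 2}
        letters = "ABC"  # A best
        for triple in itertools.product(letters, repeat=3):
            base = mc.composite_venice(*triple)
            for pos in range(3):
                idx = letters.index(triple[pos])
                if idx == 2:
                    continue
                worse = list(triple)
                worse[pos] = letters[idx + 1]
                assert order[mc.composite_venice(*worse)] <= order[base]


def _meta(p=0.001, i2=10.0, or_pooled=1.4, amount=5000):
    import math

    log_or = math.log(or_pooled)
    return mc.MetaResult(
        k=5, pooled_log_or=log_or, pooled_se=0.05, or_pooled=or_pooled,
        ci_low=or_pooled * 0.9, ci_high=or_pooled * 1.1, p_value=p,
        q_stat=4.0, q_p=0.4, i_squared_pct=i2, tau2=0.0, model="fixed",
        evidence_amount=amount,
    )


def _fprp(category="<0.05"):
    return mc.FprpResult(
        observed_p=0.001, se_log_or=0.05, target_or=1.5, power=0.99,
        priors=(0.05,), fprp_values=(0.01,), headline_prior=0.05,
        headline_fprp={"<0.05": 0.01, "0.05–0.20": 0.1, ">0.20": 0.5}[category],
        category=category,
    )


class TestGradeAssociation:
    def test_clean_association_is_strong(self):
        harbord = mc.HarbordResult(0.1, 0.5, 0.2, 0.8, k_used=5)
        sens = mc.SensitivityReport((1.3, 1.5), 1.4, 1.4, stable=True)
        record = mc.grade_association(_meta(), _fprp(), harbord=harbord, sensitivity=sens)
        assert (record.amount_grade, record.replication_grade, record.bias_grade) == ("A", "A", "A")
        assert record.venice_initial == "strong"
        assert record.final_grade == "strong"

    def test_c_amount_still_upgradable(self):
        # 80 test alleles -> amount C -> weak; FPRP < 0.05 upgrades to moderate
        harbord = mc.HarbordResult(0.1, 0.5, 0.2, 0.8, k_used=2)
        record = mc.grade_association(_meta(amount=80), _fprp("<0.05"), harbord=harbord)
        assert record.amount_grade == "C"
        assert record.venice_initial == "weak"
        assert record.final_grade == "moderate"

    def test_non_significant_refused(self):
        with pytest.raises(mc.NotSignificantError):
            mc.grade_association(_meta(p=0.2), _fprp())

    def test_rationale_lists_fired_rules(self):
        record = mc.grade_association(_meta(amount=80), _fprp("<0.05"))
        assert any(r.startswith("amount:C") for r in record.rationale)
        assert "fprp:upgrade" in record.rationale


class TestGradeFromSummary:
    def test_published_partition_reproduced(self, significant_summaries):
        graded = [mc.grade_from_summary(s) for s in significant_summaries]
        finals = [g.final_grade for g in graded]
        assert finals.count("strong") == 6
        assert finals.count("moderate") == 13
        assert finals.count("weak") == 4
        # derived finals agree with the printed final grade entry by entry
        for s, g in zip(significant_summaries, graded):
            assert g.final_grade == s.final_grade

    def test_named_examples(self, significant_summaries):
        by_key = {(s.variant, s.cancer): s for s in significant_summaries}
        bladder = mc.grade_from_summary(by_key[("rs9642880", "bladder")])
        assert bladder.replication_grade == "A"
        assert bladder.final_grade == "strong"
        stomach = mc.grade_from_summary(by_key[("rs1447295", "stomach")])
        assert stomach.replication_grade == "B"
        assert stomach.final_grade == "moderate"
        prostate = mc.grade_from_summary(by_key[("rs7000448", "prostate")])
        assert prostate.venice_initial == "moderate"
        assert prostate.final_grade == "strong"

    def test_non_significant_refused(self, fixture_summaries):
        nonsig = next(s for s in fixture_summaries if not s.significant)
        with pytest.raises(mc.NotSignificantError):
            mc.grade_from_summary(nonsig)
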