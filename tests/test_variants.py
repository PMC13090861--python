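"""Variant-retention filters, effect classification, and TMB."""
import pytest

from tumorhet import (
    EffectClass,
    TmbCategory,
    ValidationError,
    classify_effect,
    classify_tmb,
    compute_tmb,
    filter_variants,
)
from conftest import make_variant


class TestFilterVariants:
    def test_passing_record_retained(self):
        rec = make_variant(depth=12, alt_count=1)  # vaf 0.083 >= 0.05
        result = filter_variants([rec])
        assert result.retained == [rec] and not result.rejected

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            (dict(depth=9, alt_count=2), "depth"),
            (dict(depth=100, alt_count=2), "af"),
            (dict(depth=100, alt_count=20,
                  caller_evidence={"mutect": "KEEP"}), "callers"),
            (dict(depth=100, alt_count=20,
                  caller_evidence={"mutect": "REJECT", "strelka": "PASS"}), "flag"),
        ],
    )
    def test_first_failing_criterion_reported(self, kwargs, reason):
        result = filter_variants([make_variant(**kwargs)])
        assert result.retained == []
        assert result.rejected[0][1] == reason

    def test_empty_input_gives_empty_output(self):
        assert filter_variants([]).retained == []

    def test_flags_enforced_only_for_present_callers(self):
        # varscan2 has no required flag; two callers without mutect/strelka pass
        rec = make_variant(caller_evidence={"varscan2": "whatever", "other": "x"})
        assert filter_variants([rec]).retained == [rec]

    def test_idempotent(self, rng):
        records = [
            make_variant(depth=int(d), alt_count=int(a),
                         caller_evidence=ev, pos=i)
            for i, (d, a, ev) in enumerate(
                zip(
                    rng.integers(5, 50, 30),
                    rng.integers(0, 5, 30),
                    [{"mutect": "KEEP", "strelka": "PASS"},
                     {"mutect": "KEEP"}] * 15,
                )
            )
            if a <= d
        ]
        once = filter_variants(records).retained
        twice = filter_variants(once)
        assert twice.retained == once and not twice.rejected


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "classification,dist,expected",
        [
            ("Silent", None, EffectClass.SILENT),
            ("Missense_Mutation", None, EffectClass.NONSILENT),
            ("Nonsense_Mutation", None, EffectClass.NONSILENT),
            ("Frame_Shift_Del", None, EffectClass.NONSILENT),
            ("In_Frame_Ins", None, EffectClass.NONSILENT),
            ("Translation_Start_Site", None, EffectClass.NONSILENT),
            ("Missense_Mutation", 2, EffectClass.SPLICING),
            ("Silent", 1, EffectClass.SPLICING),
            ("Missense_Mutation", 3, EffectClass.NONSILENT),
            ("3'UTR", None, EffectClass.OTHER),
            ("totally_unknown", None, EffectClass.OTHER),
        ],
    )
    def test_vocabulary_and_splice_distance(self, classification, dist, expected):
        assert classify_effect(classification, dist) == expected


class TestTmb:
    def test_zero_nonsilent(self):
        res = compute_tmb([], 60.0, sample_id="s")
        assert res.tmb == 0.0 and res.category == TmbCategory.LOW

    def test_arithmetic_33_over_60(self):
        records = [make_variant(pos=i) for i in range(33)]
        res = compute_tmb(records, 60.0)
        assert res.tmb == pytest.approx(0.55)
        assert res.n_nonsilent == 33

    def test_150_over_50_is_pediatric_high(self):
        records = [make_variant(pos=i) for i in range(150)]
        res = compute_tmb(records, 50.0)
        assert res.tmb == pytest.approx(3.0)
        assert res.category == TmbCategory.PEDIATRIC_HIGH

    def test_splicing_counts_as_nonsilent_and_silent_does_not(self):
        records = [
            make_variant(pos=1, effect_class="splicing"),
            make_variant(pos=2, effect_class="silent"),
            make_variant(pos=3, effect_class="other"),
            make_variant(pos=4, effect_class="nonsilent"),
        ]
        assert compute_tmb(records, 10.0).n_nonsilent == 2

    def test_linearity_in_mutation_count(self):
        records = [make_variant(pos=i) for i in range(21)]
        single = compute_tmb(records, 60.0).tmb
        double = compute_tmb(records + records, 60.0).tmb
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_invalid_exome_size_raises(self):
        with pytest.raises(ValidationError):
            compute_tmb([], 0.0)


class TestClassifyTmb:
    @pytest.mark.parametrize(
        "tmb,expected",
        [
            (0.54, TmbCategory.LOW),
            (5.0, TmbCategory.PEDIATRIC_HIGH),
            (12.0, TmbCategory.HYPERMUTATOR),
            (2 - 1e-9, TmbCategory.LOW),
            (2.0, TmbCategory.PEDIATRIC_HIGH),
            (10.0, TmbCategory.PEDIATRIC_HIGH),
            (10 + 1e-9, TmbCategory.HYPERMUTATOR),
        ],
    )
    def test_class_boundaries(self, tmb, expected):
        assert classify_tmb(tmb) == expected

    def test_negative_tmb_raises(self):
        with pytest.raises(ValidationError):
            classify_tmb(-0.1)
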