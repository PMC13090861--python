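"""The synthetic-data generators: determinism, mapping expectations, spans."""
import numpy as np
import pandas as pd
import pytest

from tumorhet import (
    CohortSpec,
    ConfigurationError,
    GroupSpec,
    MetricDistribution,
    SubcloneTruth,
    ValidationError,
    cnv_burden,
    compute_tmb,
    filter_variants,
    simulate_cohort,
    simulate_segments,
    simulate_subclonal_tumor,
    simulate_variant_table,
)


class TestSubclonalTumor:
    def test_clonal_diploid_mean_vaf_near_half(self):
        truth = SubcloneTruth([1.0], [1000], purity=1.0, mean_depth=500, seed=42)
        loci, _ = simulate_subclonal_tumor(truth)
        assert loci["vaf"].mean() == pytest.approx(0.5, abs=0.01)

    def test_half_purity_mean_vaf_near_quarter(self):
        truth = SubcloneTruth([1.0], [1000], purity=0.5, mean_depth=500, seed=42)
        loci, _ = simulate_subclonal_tumor(truth)
        assert loci["vaf"].mean() == pytest.approx(0.25, abs=0.01)

    def test_same_seed_identical_tables(self, tmp_path):
        truth = SubcloneTruth([0.9, 0.3], [20, 20], seed=5)
        a, _ = simulate_subclonal_tumor(truth)
        b, _ = simulate_subclonal_tumor(SubcloneTruth([0.9, 0.3], [20, 20], seed=5))
        pd.testing.assert_frame_equal(a, b)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.to_csv(pa, sep="\t", index=False)
        b.to_csv(pb, sep="\t", index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_cluster_ids_match_truth_layout(self):
        truth = SubcloneTruth([0.8, 0.4, 0.2], [3, 4, 5], seed=1)
        loci, _ = simulate_subclonal_tumor(truth)
        assert loci["cluster_id"].value_counts().sort_index().tolist() == [3, 4, 5]

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValidationError):
            SubcloneTruth([0.5, 0.5], [10], seed=1)
        with pytest.raises(ValidationError):
            SubcloneTruth([1.5], [10], seed=1)


class TestSegments:
    def test_zero_fraction_all_neutral(self):
        segs = simulate_segments(1_000_000, 0.0, 5, seed=1)
        assert all(s.total_copy_number == 2 and not s.is_altered for s in segs)

    def test_altered_spans_sum_to_target(self):
        genome, n_seg = 100_000_000, 25
        segs = simulate_segments(genome, 0.3, n_seg, seed=2)
        altered = sum(s.span for s in segs if s.is_altered)
        assert abs(altered - 0.3 * genome) <= n_seg
        res = cnv_burden(segs, genome)
        assert res.burden == pytest.approx(0.3, abs=n_seg / genome)

    def test_full_fraction_whole_genome_altered(self):
        segs = simulate_segments(10_000, 1.0, 4, seed=3)
        assert sum(s.span for s in segs if s.is_altered) == 10_000

    def test_no_overlap_and_length_conserved(self, rng):
        for _ in range(20):
            genome = int(rng.integers(10_000, 1_000_000))
            frac = float(rng.uniform(0, 1))
            segs = simulate_segments(genome, frac, int(rng.integers(1, 30)),
                                     seed=int(rng.integers(2**31)))
            spans = sum(s.span for s in segs)
            assert spans <= genome
            ordered = sorted(segs, key=lambda s: s.start)
            assert all(a.end < b.start for a, b in zip(ordered, ordered[1:]))


class TestVariantTable:
    def test_zero_nonsilent_gives_zero_tmb(self):
        records = simulate_variant_table(0, 5, seed=1)
        kept = filter_variants(records).retained
        assert compute_tmb(kept, 60.0).tmb == 0.0

    def test_tmb_33_over_60(self):
        records = simulate_variant_table(33, 10, exome_size_mb=60.0, seed=2)
        kept = filter_variants(records).retained
        assert compute_tmb(kept, 60.0).tmb == pytest.approx(0.55)

    def test_spiked_failures_all_removed(self):
        records = simulate_variant_table(10, 0, seed=3, spike_failures=4)
        result = filter_variants(records)
        assert len(result.retained) == 10
        assert len(result.rejected) == 4


class TestCohort:
    def test_deterministic_and_shapes(self):
        spec = CohortSpec(
            groups=[
                GroupSpec("a", 5, MetricDistribution("normal", {})),
                GroupSpec("b", 1, MetricDistribution("normal", {"loc": 2})),
            ],
            metric="tmb",
            seed=9,
        )
        t1, t2 = simulate_cohort(spec), simulate_cohort(spec)
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1["group"] == "b").sum() == 1
        assert list(t1.columns) == ["sample_id", "group", "tmb"]

    def test_unknown_distribution_raises(self):
        spec = CohortSpec(
            groups=[GroupSpec("a", 3, MetricDistribution("cauchyish", {}))],
            seed=1,
        )
        with pytest.raises(ConfigurationError):
            simulate_cohort(spec)

    def test_beta_metric_stays_in_shannon_range(self):
        spec = CohortSpec(
            groups=[GroupSpec("a", 200, MetricDistribution(
                "beta", {"a": 2, "b": 6, "scale": float(np.log(6))}))],
            seed=4,
        )
        values = simulate_cohort(spec)["ith"]
        assert (values >= 0).all() and (values <= np.log(6)).all()
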