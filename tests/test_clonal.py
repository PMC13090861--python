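"""The ITH pipeline: CP mapping, clustering, merging, Shannon scoring."""
import numpy as np
import pytest

from tumorhet import (
    MissingPurityError,
    SubcloneTruth,
    ValidationError,
    builtin_cluster,
    merge_stage1,
    merge_stage2,
    run_ith_pipeline,
    shannon_ith,
    simulate_subclonal_tumor,
    vaf_to_cp,
)
from tumorhet.clonal import expected_vaf
from conftest import make_cluster


class TestVafCpMapping:
    @pytest.mark.parametrize(
        "vaf,purity,cn,expected",
        [
            (0.5, 1.0, 2, 1.0),
            (0.25, 0.5, 2, 1.0),
            (0.0, 0.7, 2, 0.0),
            (0.25, 1.0, 2, 0.5),
        ],
    )
    def test_vaf_to_cp(self, vaf, purity, cn, expected):
        assert vaf_to_cp(vaf, purity, cn) == pytest.approx(expected)

    def test_round_trip_with_expected_vaf(self, rng):
        for _ in range(50):
            cp = rng.uniform(0.05, 1.0)
            purity = rng.uniform(0.2, 1.0)
            v = expected_vaf(cp, purity)
            assert vaf_to_cp(v, purity) == pytest.approx(cp, rel=1e-12)

    def test_invalid_purity_raises(self):
        with pytest.raises(ValidationError):
            vaf_to_cp(0.3, 0.0)


class TestShannon:
    def test_single_cluster_scores_zero(self):
        s = shannon_ith([make_cluster("a", [0.8, 0.9])])
        assert s.ith_score == 0.0

    def test_two_equal_clusters_score_ln2(self):
        s = shannon_ith([make_cluster("a", [0.4]), make_cluster("b", [0.4])])
        assert s.ith_score == pytest.approx(np.log(2), abs=1e-9)

    def test_unequal_proportions(self):
        s = shannon_ith([make_cluster("a", [0.8]), make_cluster("b", [0.2])])
        expected = -(0.8 * np.log(0.8) + 0.2 * np.log(0.2))
        assert s.ith_score == pytest.approx(expected, abs=1e-9)

    def test_proportions_sum_to_one_and_bounded_by_ln_k(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 7))
            clusters = [
                make_cluster(i, rng.uniform(0.05, 1.0, size=rng.integers(1, 6)))
                for i in range(k)
            ]
            s = shannon_ith(clusters)
            assert s.proportions.sum() == pytest.approx(1.0, abs=1e-9)
            assert -1e-12 <= s.ith_score <= np.log(k) + 1e-9

    def test_zero_cp_clusters_dropped_then_error_when_all_zero(self):
        s = shannon_ith([make_cluster("a", [0.5]), make_cluster("z", [0.0])])
        assert len(s.clusters) == 1 and s.ith_score == 0.0
        with pytest.raises(ValidationError):
            shannon_ith([make_cluster("z", [0.0])])


class TestMergeStage1:
    def test_single_cluster_unchanged(self):
        c = make_cluster("a", [0.5])
        assert merge_stage1([c]) == [c]

    def test_close_centroids_merged(self):
        a = make_cluster("a", [0.50], [0.25])
        b = make_cluster("b", [0.52, 0.52], [0.26, 0.26])
        # centroid distance = hypot(0.02, 0.01) ~ 0.0224 < 0.05
        merged = merge_stage1([a, b], cutoff=0.05)
        assert len(merged) == 1 and len(merged[0]) == 3

    def test_distant_centroids_unchanged(self):
        a = make_cluster("a", [0.2], [0.1])
        b = make_cluster("b", [0.8], [0.4])  # distance ~ 0.6708
        assert len(merge_stage1([a, b], cutoff=0.05)) == 2

    def test_singletons_only_scope_keeps_nonsingletons_apart(self):
        a = make_cluster("a", [0.50, 0.50], [0.25, 0.25])
        b = make_cluster("b", [0.52, 0.52], [0.26, 0.26])
        s = make_cluster("s", [0.51], [0.255])
        merged = merge_stage1([a, b, s], cutoff=0.05, scope="singletons_only")
        assert len(merged) == 2  # singleton absorbed, a and b stay separate
        assert sum(len(c) for c in merged) == 5

    def test_member_conservation(self, rng):
        clusters = [
            make_cluster(i, rng.uniform(0, 1, size=rng.integers(1, 5)))
            for i in range(8)
        ]
        total = sum(len(c) for c in clusters)
        merged = merge_stage1(clusters)
        assert sum(len(c) for c in merged) == total
        assert len(merged) <= len(clusters)


class TestMergeStage2:
    def test_identical_distributions_merged(self):
        a = make_cluster("a", [0.3, 0.4, 0.5])
        b = make_cluster("b", [0.3, 0.4, 0.5])
        log = []
        merged = merge_stage2([a, b], merge_log=log)
        assert len(merged) == 1
        assert log[0].p_cp == 1.0 and log[0].p_vaf == 1.0

    def test_separated_distributions_not_merged(self):
        a = make_cluster("a", 0.10 + 0.01 * np.arange(8))
        b = make_cluster("b", 0.80 + 0.01 * np.arange(8))
        assert len(merge_stage2([a, b])) == 2  # p ~ 1.55e-4 <= 0.05

    def test_single_cluster_unchanged(self):
        c = make_cluster("a", [0.5, 0.6])
        assert merge_stage2([c]) == [c]

    def test_idempotent_and_conserving(self, rng):
        for _ in range(20):
            clusters = [
                make_cluster(i, rng.uniform(0, 1, size=rng.integers(1, 9)))
                for i in range(int(rng.integers(2, 6)))
            ]
            total = sum(len(c) for c in clusters)
            once = merge_stage2(clusters)
            assert sum(len(c) for c in once) == total
            log = []
            twice = merge_stage2(once, merge_log=log)
            assert len(twice) == len(once) and log == []


class TestBuiltinCluster:
    def test_single_subclone_recovered(self):
        loci, _ = simulate_subclonal_tumor(
            SubcloneTruth([0.9], [100], mean_depth=500, seed=11)
        )
        assert len(builtin_cluster(loci, seed=1)) == 1

    def test_two_subclones_recovered_with_high_assignment_accuracy(self):
        loci, _ = simulate_subclonal_tumor(
            SubcloneTruth([0.9, 0.3], [50, 50], mean_depth=500, seed=12)
        )
        clusters = builtin_cluster(loci, seed=1)
        assert len(clusters) == 2
        # map each fitted cluster to the dominant true label
        correct = 0
        truth = dict(zip(loci["mutation_id"], loci["cluster_id"]))
        for c in clusters:
            labels = [truth[m.mutation_id] for m in c.members]
            correct += max(labels.count(0), labels.count(1))
        assert correct / len(loci) >= 0.95

    def test_single_locus_gives_singleton(self):
        loci, _ = simulate_subclonal_tumor(SubcloneTruth([0.5], [1], seed=3))
        clusters = builtin_cluster(loci, seed=1)
        assert len(clusters) == 1 and clusters[0].is_singleton

    def test_deterministic_given_seed(self):
        loci, _ = simulate_subclonal_tumor(
            SubcloneTruth([0.9, 0.4], [30, 30], seed=5)
        )
        a = builtin_cluster(loci, seed=7)
        b = builtin_cluster(loci, seed=7)
        assert [sorted(m.mutation_id for m in c.members) for c in a] == [
            sorted(m.mutation_id for m in c.members) for c in b
        ]


class TestPipeline:
    def test_preassigned_single_cluster_scores_zero(self):
        loci, _ = simulate_subclonal_tumor(SubcloneTruth([0.8], [30], seed=2))
        s = run_ith_pipeline(loci, purity=1.0)
        assert s.ith_score == 0.0 and s.provenance == "ingested"

    def test_three_subclone_recovery_within_tolerance(self):
        truth = SubcloneTruth([1.0, 0.6, 0.2], [40, 40, 40], purity=1.0,
                              mean_depth=500, seed=21)
        loci, truth = simulate_subclonal_tumor(truth)
        s = run_ith_pipeline(loci, purity=1.0, use_ingested_clusters=False, seed=4)
        assert len(s.clusters) == 3
        assert abs(s.ith_score - truth.true_ith()) <= 0.1

    def test_missing_purity_excluded_with_report(self):
        loci, _ = simulate_subclonal_tumor(SubcloneTruth([0.8], [10], seed=2))
        with pytest.raises(MissingPurityError, match="excluded"):
            run_ith_pipeline(loci, purity=None)

    def test_relabeling_and_reordering_invariance(self):
        truth = SubcloneTruth([0.9, 0.4], [25, 25], seed=8)
        loci, _ = simulate_subclonal_tumor(truth)
        base = run_ith_pipeline(loci, 1.0).ith_score
        shuffled = loci.sample(frac=1.0, random_state=0).reset_index(drop=True)
        shuffled["cluster_id"] = shuffled["cluster_id"].map({0: 7, 1: 3})
        assert run_ith_pipeline(shuffled, 1.0).ith_score == pytest.approx(
            base, abs=1e-12
        )

    def test_cluster_counts_never_increase_and_loci_conserved(self):
        truth = SubcloneTruth([0.95, 0.55, 0.25], [20, 20, 20], seed=13)
        loci, _ = simulate_subclonal_tumor(truth)
        s = run_ith_pipeline(loci, 1.0)
        assert s.n_clusters_initial >= s.n_after_stage1 >= s.n_after_stage2
        assert sum(len(c) for c in s.clusters) == len(loci)
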