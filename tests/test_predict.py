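import numpy as np
import pytest

from oracles import random_nested_structure
from probefold.aggregate import AggregatedProfile
from probefold.fold_engine import StructureSample
from probefold.formats_io import SecondaryStructure, parse_dotbracket
from probefold.predict import (
    MsaCondition,
    bp_distance,
    centroid,
    cluster_pool,
    predict_structures,
    score_cluster,
)


def sample(db, condition="c", index=0, energy=0.0, length=None):
    structure = parse_dotbracket(db) if isinstance(db, str) else db
    return StructureSample(structure, energy, condition, index)


class TestBpDistance:
    def test_identical(self):
        s = parse_dotbracket("((...))")
        assert bp_distance(s, s) == 0

    def test_symmetric_difference(self):
        assert bp_distance(parse_dotbracket("((...))"), parse_dotbracket(".......")) == 2

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(30):
            structs = [
                SecondaryStructure(25, random_nested_structure(25, rng)) for _ in range(3)
            ]
            a, b, c = structs
            assert bp_distance(a, b) == bp_distance(b, a)
            assert bp_distance(a, c) <= bp_distance(a, b) + bp_distance(b, c)
            assert bp_distance(a, a) == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bp_distance(parse_dotbracket("...."), parse_dotbracket("....."))


class TestClusterPool:
    def test_identical_samples_single_cluster(self):
        pool = [sample("((...))", index=i) for i in range(20)]
        clusters = cluster_pool(pool)
        assert len(clusters) == 1
        assert clusters[0].size == 20

    def test_well_separated_sets_two_clusters(self):
        a = parse_dotbracket("((((((....))))))....................")
        b = parse_dotbracket("....................((((((....))))))")
        pool = [sample(a, index=i) for i in range(15)] + [
            sample(b, index=i) for i in range(10)
        ]
        clusters = cluster_pool(pool)
        assert len(clusters) == 2
        sizes = sorted(c.size for c in clusters)
        assert sizes == [10, 15]

    def test_permutation_invariance(self, rng):
        structs = [
            SecondaryStructure(30, random_nested_structure(30, rng)) for _ in range(8)
        ]
        pool = [sample(structs[i % 8], index=i) for i in range(60)]
        base = cluster_pool(pool)
        base_partition = {frozenset(c.members) for c in base}
        for _ in range(3):
            perm = rng.permutation(len(pool))
            shuffled = [pool[i] for i in perm]
            clusters = cluster_pool(shuffled)
            mapped = {
                frozenset(int(perm[m]) for m in c.members) for c in clusters
            }
            assert mapped == base_partition

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            cluster_pool([])


class TestScoreCluster:
    def test_single_condition_score(self):
        pool = [sample("((...))", index=i) for i in range(60)] + [
            sample(".......", index=100 + i) for i in range(40)
        ]
        members = list(range(60))
        assert score_cluster(members, pool) == pytest.approx(0.61)

    def test_cross_condition_support_beats_single_condition_dominance(self):
        # 50%/50% across two conditions scores (0.51)^2 = 0.2601, while
        # 100%/0% scores (1.01)(0.01) = 0.0101
        pool = [sample("((...))", "c1", i) for i in range(10)] + [
            sample("((...))", "c2", i) for i in range(10)
        ]
        shared = score_cluster(list(range(5)) + list(range(10, 15)), pool)
        dominant = score_cluster(list(range(10)), pool)
        assert shared == pytest.approx(0.51**2)
        assert dominant == pytest.approx(1.01 * 0.01)
        assert shared > dominant

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            score_cluster([], [])


class TestCentroid:
    def test_identical_structures(self):
        pool = [sample("((...))", index=i) for i in range(5)]
        assert centroid([0, 1, 2, 3, 4], pool).pairs == {(1, 7), (2, 6)}

    def test_majority_rule(self):
        pool = [sample("((...))"), sample("(.....)"), sample(".......")]
        result = centroid([0, 1, 2], pool)
        assert result.pairs == {(1, 7)}  # 2/3 > 0.5; (2,6) at 1/3 dropped

    def test_exact_half_excluded(self):
        pool = [sample("((...))"), sample("((...))"), sample("......."), sample(".......")]
        assert centroid([0, 1, 2, 3], pool).pairs == frozenset()

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            centroid([], [])


def _aggregated_from_values(values, condition="c", rna="x"):
    values = np.asarray(values, dtype=float)
    flags = np.where(values == -10.0, "undetermined", "accepted").astype(object)
    return AggregatedProfile(
        rna, condition,
        mean=values,
        std=np.zeros(values.size),
        flag=flags,
        n_valid=np.where(values == -10.0, 0, 3),
    )


class TestPredictStructures:
    SEQ = "GGGCGCAAAGCGCCCAAACC"

    def test_deterministic_under_seed(self):
        cond = {"c1": _aggregated_from_values(np.full(len(self.SEQ), 0.2))}
        a = predict_structures(cond, self.SEQ, n_samples=100, seed=5)
        b = predict_structures(cond, self.SEQ, n_samples=100, seed=5)
        assert a.best.pairs == b.best.pairs
        assert [c.members for c in a.clusters] == [c.members for c in b.clusters]

    def test_best_and_second_from_different_clusters(self):
        cond = {"c1": _aggregated_from_values(np.full(len(self.SEQ), 0.3))}
        result = predict_structures(cond, self.SEQ, n_samples=200, seed=1)
        if result.second is not None:
            assert result.best.pairs != result.second.pairs or len(result.clusters) == 1

    def test_unconstrained_warning_when_nothing_accepted(self):
        values = np.full(len(self.SEQ), -10.0)
        cond = {"c1": _aggregated_from_values(values)}
        with pytest.warns(UserWarning, match="unconstrained"):
            result = predict_structures(cond, self.SEQ, n_samples=50, seed=2)
        assert result.best is not None

    def test_length_mismatch_rejected(self):
        cond = {"c1": _aggregated_from_values(np.full(5, 0.2))}
        with pytest.raises(ValueError, match="length"):
            predict_structures(cond, self.SEQ, n_samples=10, seed=0)

    def test_msa_condition_joins_pool(self):
        cond = {
            "c1": _aggregated_from_values(np.full(len(self.SEQ), 0.2)),
            "msa": MsaCondition([("ref", self.SEQ), ("other", self.SEQ)]),
        }
        result = predict_structures(cond, self.SEQ, n_samples=50, seed=9)
        assert set(result.condition_ids) == {"c1", "msa"}
        total = sum(c.size for c in result.clusters)
        assert total == 100
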