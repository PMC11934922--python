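import itertools

import numpy as np
import pytest

from oracles import aggregation_flag
from probefold.aggregate import (
    AggregatedProfile,
    aggregate_replicates,
    concatenate_primers,
    replicate_correlations,
)
from probefold.formats_io import SENTINEL, ReactivityProfile


def profiles_from_matrix(matrix, rna_id="x", condition_id="c"):
    return [
        ReactivityProfile(rna_id, condition_id, f"rep{i+1}", np.asarray(row, dtype=float))
        for i, row in enumerate(matrix)
    ]


class TestAggregateReplicates:
    def test_tight_replicates_accepted(self):
        agg = aggregate_replicates(profiles_from_matrix([[0.50], [0.52], [0.48]]))
        assert agg.flag[0] == "accepted"
        assert agg.mean[0] == pytest.approx(0.50)
        assert agg.std[0] == pytest.approx(0.02, abs=1e-12)

    def test_wide_spread_nonconsistent(self):
        # pairwise means 0.30/0.50/0.70 span low and medium classes
        agg = aggregate_replicates(profiles_from_matrix([[0.10], [0.50], [0.90]]))
        assert agg.flag[0] == "nonconsistent"

    def test_warning_unreachable_with_interval_classes(self, rng):
        # The total mean is a convex combination of the pairwise means, so if
        # every pairwise mean falls in one class interval the mean's class
        # matches and the position is accepted instead; rejected positions
        # therefore always span several classes (nonconsistent).
        for _ in range(200):
            triple = rng.uniform(0, 1.2, size=3)
            assert aggregation_flag(list(triple)) != "warning"
        agg = aggregate_replicates(profiles_from_matrix([[0.43], [0.68], [1.01]]))
        assert agg.flag[0] == "nonconsistent"

    def test_single_replicate_runs(self):
        agg = aggregate_replicates(profiles_from_matrix([[0.6]]))
        assert agg.flag[0] == "accepted"
        assert agg.mean[0] == 0.6
        assert agg.std[0] == 0.0

    def test_two_replicate_guard(self):
        # single pairwise mean equals the total mean, so acceptance falls
        # back to class agreement of the raw values
        agg = aggregate_replicates(profiles_from_matrix([[0.40, 0.45], [0.90, 0.62]]))
        assert agg.flag[0] == "nonconsistent"  # 0.40 medium vs 0.90 high, std > min_std
        assert agg.flag[1] == "accepted"       # both medium despite std 0.12 < .15

    def test_undetermined_when_too_few_valid(self):
        agg = aggregate_replicates(profiles_from_matrix([[SENTINEL], [SENTINEL], [0.4]]))
        assert agg.flag[0] == "undetermined"
        assert agg.mean[0] == SENTINEL
        assert agg.modeling_values()[0] == SENTINEL

    def test_flags_match_brute_force_on_grid(self):
        grid = np.round(np.arange(0.0, 0.81, 0.2), 10)
        triples = list(itertools.product(grid, repeat=3))
        values = np.array(triples)
        agg = aggregate_replicates(profiles_from_matrix(values.T))
        for pos, triple in enumerate(triples):
            assert agg.flag[pos] == aggregation_flag(list(triple)), triple

    def test_replicate_order_irrelevant(self, rng):
        matrix = rng.uniform(0, 1.2, size=(4, 30))
        matrix[rng.random(matrix.shape) < 0.1] = SENTINEL
        base = aggregate_replicates(profiles_from_matrix(matrix))
        for _ in range(5):
            perm = rng.permutation(4)
            shuffled = aggregate_replicates(profiles_from_matrix(matrix[perm]))
            assert (shuffled.flag == base.flag).all()
            assert np.allclose(shuffled.mean, base.mean)

    def test_accepted_implies_enough_data(self, rng):
        matrix = rng.uniform(0, 1.2, size=(3, 50))
        matrix[rng.random(matrix.shape) < 0.4] = SENTINEL
        agg = aggregate_replicates(profiles_from_matrix(matrix))
        assert (agg.n_valid[agg.flag == "accepted"] >= 2).all()
        assert set(agg.flag) <= {"accepted", "warning", "nonconsistent", "undetermined"}

    def test_length_mismatch_rejected(self):
        profs = [
            ReactivityProfile("x", "c", "a", np.array([0.1, 0.2])),
            ReactivityProfile("x", "c", "b", np.array([0.1])),
        ]
        with pytest.raises(ValueError, match="length"):
            aggregate_replicates(profs)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([])


class TestReplicateCorrelations:
    def test_identical_profiles(self, rng):
        values = rng.uniform(0, 1, size=40)
        profs = profiles_from_matrix([values, values])
        report = replicate_correlations(profs)
        assert report.loc[0, "pearson"] == pytest.approx(1.0)
        assert report.loc[0, "spearman"] == pytest.approx(1.0)

    def test_rank_reversal(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        report = replicate_correlations(profiles_from_matrix([x, x[::-1]]))
        assert report.loc[0, "spearman"] == pytest.approx(-1.0)

    def test_disjoint_valid_positions_undefined(self):
        a = np.array([0.1, SENTINEL, 0.3, SENTINEL])
        b = np.array([SENTINEL, 0.2, SENTINEL, 0.4])
        report = replicate_correlations(profiles_from_matrix([a, b]))
        assert report.loc[0, "n_common"] == 0
        assert np.isnan(report.loc[0, "pearson"])


class TestConcatenatePrimers:
    def _segment(self, means, flags, rna="x", cond="c"):
        n = len(means)
        return AggregatedProfile(
            rna, cond,
            mean=np.asarray(means, dtype=float),
            std=np.zeros(n),
            flag=np.asarray(flags, dtype=object),
            n_valid=np.full(n, 2),
        )

    def test_disjoint_segments_concatenate(self):
        s1 = self._segment([0.1, 0.2], ["accepted"] * 2)
        s2 = self._segment([0.3, 0.4], ["accepted"] * 2)
        merged = concatenate_primers([(s1, 1, 2), (s2, 3, 4)])
        assert merged.mean.tolist() == [0.1, 0.2, 0.3, 0.4]

    def test_uncovered_positions_undetermined(self):
        s1 = self._segment([0.1], ["accepted"])
        merged = concatenate_primers([(s1, 2, 2)], rna_length=4)
        assert merged.flag.tolist() == ["undetermined", "accepted", "undetermined", "undetermined"]

    def test_overlap_both_accepted_averages(self):
        s1 = self._segment([0.4], ["accepted"])
        s2 = self._segment([0.6], ["accepted"])
        merged = concatenate_primers([(s1, 5, 5), (s2, 5, 5)])
        assert merged.mean[4] == pytest.approx(0.5)

    def test_overlap_one_undetermined_keeps_other(self):
        s1 = self._segment([SENTINEL], ["undetermined"])
        s2 = self._segment([0.7], ["accepted"])
        merged = concatenate_primers([(s1, 1, 1), (s2, 1, 1)])
        assert merged.mean[0] == pytest.approx(0.7)
        assert merged.flag[0] == "accepted"

    def test_conflicting_rna_rejected(self):
        s1 = self._segment([0.1], ["accepted"], rna="a")
        s2 = self._segment([0.1], ["accepted"], rna="b")
        with pytest.raises(ValueError, match="rna_id"):
            concatenate_primers([(s1, 1, 1), (s2, 2, 2)])
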