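"""Multi-condition structure prediction.

Samples drawn under every probing condition (and, optionally, from an
alignment-derived pseudo-condition) are pooled and clustered by base-pair
distance.  Clusters are scored multiplicatively across conditions so that
structures supported by several experiments outrank structures dominating a
single one, and the best / second-best cluster centroids become the predicted
models.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .aggregate import AggregatedProfile
from .fold_engine import (
    EnergyModel,
    PseudoEnergyParams,
    StructureSample,
    consensus_sample_from_msa,
    pseudo_energy_vector,
    sample_structures,
)
from .formats_io import SecondaryStructure

#: Occupancy offset; a cluster absent from one condition is penalized but not
#: zeroed out.
OCCUPANCY_EPSILON = 0.01


@dataclass
class MsaCondition:
    """An alignment used as one more pseudo-condition."""

    rows: Sequence[tuple[str, str]]
    reference_id: Optional[str] = None
    covariation_bonus: float = -1.0
    inconsistency_penalty: float = 0.5


@dataclass
class ClusterResult:
    members: list
    occupancy: dict
    score: float
    centroid: SecondaryStructure
    mean_energy: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class PredictionResult:
    clusters: list
    best: SecondaryStructure
    second: Optional[SecondaryStructure]
    condition_ids: list
    config: dict = field(default_factory=dict)


def bp_distance(s1: SecondaryStructure, s2: SecondaryStructure) -> int:
    """Base-pair distance: size of the symmetric difference of pair sets."""
    if s1.length != s2.length:
        raise ValueError("structures must share one length")
    return len(s1.pairs ^ s2.pairs)


def _distance_matrix(pool: Sequence[StructureSample]) -> np.ndarray:
    """All-vs-all base-pair distances, via a binary pair-indicator encoding."""
    pair_index: dict = {}
    for sample in pool:
        for pair in sample.structure.pairs:
            pair_index.setdefault(pair, len(pair_index))
    n = len(pool)
    if not pair_index:
        return np.zeros((n, n))
    X = np.zeros((n, len(pair_index)))
    for row, sample in enumerate(pool):
        for pair in sample.structure.pairs:
            X[row, pair_index[pair]] = 1.0
    counts = X.sum(axis=1)
    D = counts[:, None] + counts[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def centroid(members: Sequence[int], pool: Sequence[StructureSample]) -> SecondaryStructure:
    """Cluster representative keeping pairs with intra-cluster frequency
    > 0.5.

    Majority pairs of nested structures can neither share endpoints nor
    cross, so the centroid is always a valid structure.
    """
    if not members:
        raise ValueError("empty cluster")
    counts: Counter = Counter()
    for idx in members:
        counts.update(pool[idx].structure.pairs)
    cutoff = len(members) / 2.0
    pairs = frozenset(p for p, c in counts.items() if c > cutoff)
    template = pool[members[0]].structure
    return SecondaryStructure(template.length, pairs, template.sequence)


def score_cluster(
    members: Sequence[int],
    pool: Sequence[StructureSample],
    epsilon: float = OCCUPANCY_EPSILON,
) -> float:
    """Multiplicative cross-condition support score: prod_c (occupancy_c +
    epsilon)."""
    condition_totals = Counter(s.condition_id for s in pool)
    if not condition_totals:
        raise ValueError("empty pool")
    member_conditions = Counter(pool[idx].condition_id for idx in members)
    score = 1.0
    for cond, total in sorted(condition_totals.items()):
        score *= member_conditions.get(cond, 0) / total + epsilon
    return score


def _choose_k(D: np.ndarray, Z, max_k: int) -> tuple[int, np.ndarray]:
    n = D.shape[0]
    best_k, best_sil, best_labels = 1, -np.inf, np.ones(n, dtype=int)
    for k in range(2, min(max_k, n - 1) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(D, labels, metric="precomputed")
        if sil > best_sil + 1e-12:
            best_k, best_sil, best_labels = k, sil, labels
    return best_k, best_labels


def cluster_pool(
    pool: Sequence[StructureSample],
    max_k: int = 10,
    seed: Optional[int] = None,
) -> list[ClusterResult]:
    """Agglomerative (average-linkage) clustering of pooled samples on
    base-pair distance; k maximizes the mean silhouette over 2..max_k, with a
    single cluster for near-degenerate pools (mean pairwise distance < 2).

    Deterministic and invariant under pool permutation: samples are clustered
    in a canonical order keyed by their dot-bracket strings.
    """
    if not pool:
        raise ValueError("empty pool")
    n = len(pool)
    canonical = sorted(
        range(n),
        key=lambda i: (pool[i].structure.to_dotbracket(), pool[i].condition_id, pool[i].sample_index),
    )
    ordered = [pool[i] for i in canonical]
    D = _distance_matrix(ordered)
    if n == 1 or D.sum() / (n * (n - 1)) < 2.0:
        labels = np.ones(n, dtype=int)
    else:
        Z = linkage(squareform(D, checks=False), method="average")
        _, labels = _choose_k(D, Z, max_k)
    clusters = []
    condition_totals = Counter(s.condition_id for s in pool)
    for label in np.unique(labels):
        members = [canonical[i] for i in np.flatnonzero(labels == label)]
        occupancy = {
            cond: Counter(pool[idx].condition_id for idx in members).get(cond, 0) / total
            for cond, total in sorted(condition_totals.items())
        }
        clusters.append(
            ClusterResult(
                members=sorted(members),
                occupancy=occupancy,
                score=score_cluster(members, pool),
                centroid=centroid(members, pool),
                mean_energy=float(np.mean([pool[idx].energy for idx in members])),
            )
        )
    # Rank: score desc, then total occupancy desc, then lower mean energy,
    # then dot-bracket for full determinism.
    clusters.sort(
        key=lambda c: (
            -c.score,
            -sum(c.occupancy.values()),
            c.mean_energy,
            c.centroid.to_dotbracket(),
        )
    )
    return clusters


ConditionInput = Union[AggregatedProfile, MsaCondition]


def predict_structures(
    conditions: Mapping[str, ConditionInput],
    sequence: str,
    n_samples: int = 1000,
    model: EnergyModel | None = None,
    pseudo_params: PseudoEnergyParams | None = None,
    max_k: int = 10,
    seed: Optional[int] = None,
) -> PredictionResult:
    """Pool per-condition Boltzmann samples, cluster, score, and emit the
    best and second-best centroid models.

    Probing conditions contribute samples constrained by their accepted
    reactivities (non-accepted positions carry zero pseudo-energy); an
    :class:`MsaCondition` contributes covariation-scored consensus samples in
    the same way as an additional probing condition.  One RNG stream per
    condition is derived from the master seed.
    """
    if not conditions:
        raise ValueError("need at least one condition")
    model = model or EnergyModel()
    pseudo_params = pseudo_params or PseudoEnergyParams()
    sequence = sequence.upper().replace("T", "U")

    names = sorted(conditions)
    seeds = np.random.SeedSequence(seed).spawn(len(names))
    pool: list[StructureSample] = []
    any_constraint = False
    for name, child_seed in zip(names, seeds):
        cond = conditions[name]
        if isinstance(cond, MsaCondition):
            samples = consensus_sample_from_msa(
                cond.rows,
                model=model,
                covariation_bonus=cond.covariation_bonus,
                inconsistency_penalty=cond.inconsistency_penalty,
                n=n_samples,
                seed=child_seed,
                reference_id=cond.reference_id,
                condition_id=name,
            )
            if samples and samples[0].structure.length != len(sequence):
                raise ValueError(
                    "alignment reference length does not match the RNA sequence"
                )
            any_constraint = True
        else:
            values = cond.modeling_values()
            if values.size != len(sequence):
                raise ValueError(
                    f"condition {name!r} length {values.size} != sequence length {len(sequence)}"
                )
            pseudo = pseudo_energy_vector(values, pseudo_params)
            if cond.accepted_mask().any():
                any_constraint = True
            samples = sample_structures(
                sequence,
                pseudo=pseudo,
                model=model,
                n=n_samples,
                seed=child_seed,
                condition_id=name,
            )
        pool.extend(samples)
    if not any_constraint:
        warnings.warn(
            "no accepted reactivities in any condition; prediction proceeds "
            "unconstrained",
            stacklevel=2,
        )
    return rank_pool(pool, names, max_k=max_k, config={
        "n_samples": n_samples,
        "seed": seed,
        "max_k": max_k,
        "m": pseudo_params.m,
        "b": pseudo_params.b,
    })


def rank_pool(
    pool: Sequence[StructureSample],
    condition_ids: Sequence[str],
    max_k: int = 10,
    config: Optional[dict] = None,
) -> PredictionResult:
    """Cluster and rank an already-sampled pool (the tail of
    :func:`predict_structures`, reusable when samples are precomputed)."""
    clusters = cluster_pool(pool, max_k=max_k)
    best = clusters[0].centroid
    second = clusters[1].centroid if len(clusters) > 1 else None
    return PredictionResult(
        clusters=clusters,
        best=best,
        second=second,
        condition_ids=list(condition_ids),
        config=dict(config or {}),
    )
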