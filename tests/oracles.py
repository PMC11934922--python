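"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (exhaustive enumeration,
plain-python statistics) and deliberately shares no code with the package
internals it checks.
"""

from __future__ import annotations

import math
import statistics
from itertools import combinations

import numpy as np

# Watson-Crick + wobble energies, mirroring the engine's published defaults.
PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}
RT = 0.616
MIN_HAIRPIN = 3


def enumerate_structures(seq: str, min_hairpin: int = MIN_HAIRPIN):
    """All nested structures of ``seq`` as frozensets of 1-based pairs."""

    def rec(i, j):
        if j - i < min_hairpin + 1:
            yield frozenset()
            return
        yield from rec(i + 1, j)
        for k in range(i + min_hairpin + 1, j + 1):
            if (seq[i - 1], seq[k - 1]) not in PAIR_ENERGY:
                continue
            for inner in rec(i + 1, k - 1):
                for outer in rec(k + 1, j):
                    yield inner | outer | {(i, k)}

    return list(rec(1, len(seq)))


def structure_energy(seq: str, pairs, pseudo=None) -> float:
    g = [0.0] * len(seq) if pseudo is None else list(pseudo)
    return sum(
        PAIR_ENERGY[(seq[i - 1], seq[j - 1])] + g[i - 1] + g[j - 1] for i, j in pairs
    )


def boltzmann_distribution(seq: str, pseudo=None):
    """Exact structure probabilities by enumeration: {pairs: probability}."""
    structures = enumerate_structures(seq)
    weights = [math.exp(-structure_energy(seq, s, pseudo) / RT) for s in structures]
    Z = sum(weights)
    return {s: w / Z for s, w in zip(structures, weights)}, Z


def pair_probability_matrix(seq: str, pseudo=None):
    dist, Z = boltzmann_distribution(seq, pseudo)
    n = len(seq)
    P = np.zeros((n, n))
    for pairs, p in dist.items():
        for i, j in pairs:
            P[i - 1, j - 1] += p
            P[j - 1, i - 1] += p
    return P, Z


def aggregation_flag(values, min_std=0.15, low=0.4, high=0.7, sentinel=-10.0, min_ndata=2):
    """Independent re-statement of the replicate consistency rules."""

    def klass(v):
        if v == sentinel:
            return "undefined"
        if v < low:
            return "low"
        if v <= high:
            return "medium"
        return "high"

    valid = [v for v in values if v != sentinel]
    if len(valid) < min_ndata:
        return "undetermined"
    if len(valid) == 1:
        return "accepted"
    mean = statistics.fmean(valid)
    if statistics.stdev(valid) <= min_std:
        return "accepted"
    if len(valid) == 2:
        return "accepted" if klass(valid[0]) == klass(valid[1]) else "nonconsistent"
    pair_classes = {klass((a + b) / 2) for a, b in combinations(valid, 2)}
    if pair_classes == {klass(mean)}:
        return "accepted"
    if len(pair_classes) == 1:
        return "warning"
    return "nonconsistent"


def welch_t_p_value(a, b) -> float:
    """Two-sided Welch t-test p-value from the textbook formulas."""
    from scipy.stats import t as t_dist  # distribution function only

    na, nb = len(a), len(b)
    ma, mb = statistics.fmean(a), statistics.fmean(b)
    va, vb = statistics.variance(a), statistics.variance(b)
    se2 = va / na + vb / nb
    t_stat = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * t_dist.sf(abs(t_stat), df)


def random_nested_structure(length: int, rng: np.random.Generator, pair_prob: float = 0.4,
                            min_hairpin: int = MIN_HAIRPIN):
    """Uniform-ish random nested structure built by recursive splitting."""

    def rec(i, j):
        if j - i < min_hairpin + 1:
            return set()
        if rng.random() < pair_prob:
            k = int(rng.integers(i + min_hairpin + 1, j + 1))
            return {(i, k)} | rec(i + 1, k - 1) | rec(k + 1, j)
        return rec(i + 1, j)

    return frozenset(rec(1, length))
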