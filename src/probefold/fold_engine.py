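"""Probing-constrained folding machinery.

The engine converts reactivities into per-nucleotide pseudo-energies (the
Deigan-style ``m * ln(r + 1) + b`` scheme), computes an exact partition
function over all nested secondary structures under a simplified,
stacking-free base-pair energy model, draws i.i.d. structures from the
Boltzmann ensemble by stochastic traceback, and scores a covariation-informed
consensus "sequence" built from a multiple sequence alignment so that
phylogenetic information can enter the pipeline as one more pseudo-condition.

The energy model is deliberately small (per-pair energies for GC/AU/GU plus
the pseudo-energy terms, no stacking or loop terms) so the whole ensemble
machinery is self-contained and exactly testable against exhaustive
enumeration.  Any engine exposing ``partition_function`` and
``sample_structures`` with the same contracts can be plugged in instead; the
downstream prediction stage depends only on the returned samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats_io import SENTINEL, SecondaryStructure

_ALPHABET = set("ACGU")

#: Watson-Crick and wobble pair energies, kcal/mol.
_DEFAULT_PAIR_ENERGIES = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}


@dataclass(frozen=True)
class PseudoEnergyParams:
    """Slope/intercept of the reactivity -> pseudo-energy transform
    (kcal/mol)."""

    m: float = 2.6
    b: float = -0.8

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("slope m must be > 0 to penalize reactive positions")


@dataclass(frozen=True)
class EnergyModel:
    """Simplified stacking-free pair-energy model.

    ``RT`` defaults to 0.616 kcal/mol (37 degrees C).  Only WC + GU pairs are
    allowed and all pair energies are favorable (<= 0).
    """

    pair_energies: dict = field(default_factory=lambda: dict(_DEFAULT_PAIR_ENERGIES))
    min_hairpin: int = 3
    RT: float = 0.616

    def __post_init__(self) -> None:
        if any(e > 0 for e in self.pair_energies.values()):
            raise ValueError("pair energies must be <= 0")
        if self.RT <= 0:
            raise ValueError("RT must be > 0")

    def pair_energy(self, a: str, b: str) -> Optional[float]:
        return self.pair_energies.get((a, b))


@dataclass(frozen=True)
class StructureSample:
    structure: SecondaryStructure
    energy: float
    condition_id: str = ""
    sample_index: int = 0


def pseudo_energy(reactivity: float, params: PseudoEnergyParams | None = None) -> float:
    """Pseudo-energy contribution of pairing one nucleotide.

    Undetermined reactivities (sentinel) contribute nothing.  The term is
    added once per paired nucleotide.
    """
    params = params or PseudoEnergyParams()
    if reactivity == SENTINEL:
        return 0.0
    if reactivity <= -1.0:
        raise ValueError(f"reactivity {reactivity} <= -1 has no pseudo-energy")
    return params.m * math.log(reactivity + 1.0) + params.b


def pseudo_energy_vector(
    values: Sequence[float], params: PseudoEnergyParams | None = None
) -> np.ndarray:
    return np.array([pseudo_energy(float(v), params) for v in values])


def structure_energy(
    structure: SecondaryStructure,
    pseudo: Optional[Sequence[float]] = None,
    model: EnergyModel | None = None,
) -> float:
    """Total energy (pair terms + pseudo terms) of a structure; recomputable
    from the sample alone."""
    model = model or EnergyModel()
    seq = structure.sequence
    if seq is None:
        raise ValueError("structure needs a sequence to evaluate its energy")
    g = np.zeros(structure.length) if pseudo is None else np.asarray(pseudo, dtype=float)
    total = 0.0
    for i, j in structure.pairs:
        e = model.pair_energy(seq[i - 1], seq[j - 1])
        if e is None:
            raise ValueError(f"non-pairable bases at ({i}, {j}): {seq[i-1]}{seq[j-1]}")
        total += e + g[i - 1] + g[j - 1]
    return total


# ---------------------------------------------------------------------------
# Inside / outside dynamic programming
# ---------------------------------------------------------------------------

def _boltzmann_pair_weights(
    sequence: str, pseudo: Optional[Sequence[float]], model: EnergyModel
) -> np.ndarray:
    """(n+2)x(n+2) matrix (1-based) of per-pair Boltzmann factors; zero where
    a pair is chemically or geometrically forbidden."""
    n = len(sequence)
    if n < 1:
        raise ValueError("empty sequence")
    bad = set(sequence) - _ALPHABET
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    g = np.zeros(n) if pseudo is None else np.asarray(pseudo, dtype=float)
    if g.size != n:
        raise ValueError("pseudo-energy vector length mismatch")
    B = np.zeros((n + 2, n + 2))
    for i in range(1, n + 1):
        for j in range(i + model.min_hairpin + 1, n + 1):
            e = model.pair_energy(sequence[i - 1], sequence[j - 1])
            if e is not None:
                B[i, j] = math.exp(-(e + g[i - 1] + g[j - 1]) / model.RT)
    return B


def _inside(B: np.ndarray, n: int, min_hairpin: int) -> np.ndarray:
    """Inside partition-function table.

    ``W[i, j]`` is the Boltzmann sum over nested structures of region
    ``[i, j]`` (1-based, inclusive); empty regions contribute 1.  Recursion:
    position i is unpaired, or paired to some k with the two enclosed /
    following regions independent.
    """
    W = np.ones((n + 2, n + 2))
    for span in range(min_hairpin + 2, n + 1):
        for i in range(1, n - span + 2):
            j = i + span - 1
            kmin = i + min_hairpin + 1
            ks = np.arange(kmin, j + 1)
            contrib = B[i, kmin:j + 1] * W[i + 1, kmin - 1:j] * W[kmin + 1:j + 2, j]
            W[i, j] = W[i + 1, j] + contrib.sum()
    return W


def _outside(B: np.ndarray, W: np.ndarray, n: int) -> np.ndarray:
    """Outside table: ``O[i, j]`` sums Boltzmann weights of all structure
    contexts surrounding a fixed (i, j) pair, excluding the pair's own weight.

    The context either leaves (i, j) external (independent left/right
    regions), or encloses it with an immediate outer pair (p, q); computed for
    decreasing enclosure by increasing-then-decreasing span ordering.
    """
    O = np.zeros((n + 2, n + 2))
    pair_cells = [
        (i, j)
        for span in range(n, 0, -1)
        for i in range(1, n - span + 2)
        for j in [i + span - 1]
        if B[i, j] > 0
    ]
    M = np.zeros((n + 2, n + 2))
    for i, j in pair_cells:
        ext = W[1, i - 1] if i > 1 else 1.0
        ext *= W[j + 1, n] if j < n else 1.0
        total = ext
        if i > 1 and j < n:
            # Sum over immediate enclosing pairs p < i, q > j.
            # inner[p] = sum_q M[p, q] * W[j+1, q-1]
            qs = np.arange(j + 1, n + 1)
            wq = W[j + 1, j:n]  # W[j+1, q-1] for q = j+1..n
            inner = M[1:i, j + 1:n + 1] @ wq
            wp = W[2:i + 1, i - 1]  # W[p+1, i-1] for p = 1..i-1
            total += float(inner @ wp)
        O[i, j] = total
        M[i, j] = B[i, j] * O[i, j]
    return O


def partition_function(
    sequence: str,
    pseudo: Optional[Sequence[float]] = None,
    model: EnergyModel | None = None,
    pair_probabilities: bool = True,
):
    """Exact partition function and base-pair probabilities.

    Returns ``(Z, P)`` where ``Z = sum over all nested structures of
    exp(-E/RT)`` (the empty structure contributes 1) and ``P[i-1, j-1]`` is
    the Boltzmann probability that nucleotides i and j are paired.  Pair
    probabilities come from an exact outside recursion; pass
    ``pair_probabilities=False`` to skip it when only Z is needed.
    """
    model = model or EnergyModel()
    sequence = sequence.upper().replace("T", "U")
    n = len(sequence)
    B = _boltzmann_pair_weights(sequence, pseudo, model)
    W = _inside(B, n, model.min_hairpin)
    Z = float(W[1, n])
    if not pair_probabilities:
        return Z, None
    O = _outside(B, W, n)
    P = np.zeros((n, n))
    for i in range(1, n + 1):
        for j in range(i + model.min_hairpin + 1, n + 1):
            if B[i, j] > 0:
                p = B[i, j] * W[i + 1, j - 1] * O[i, j] / Z
                P[i - 1, j - 1] = P[j - 1, i - 1] = p
    return Z, P


# ---------------------------------------------------------------------------
# Stochastic traceback sampling
# ---------------------------------------------------------------------------

class _Sampler:
    """Caches per-interval decision weights for fast repeated traceback."""

    def __init__(self, sequence: str, B: np.ndarray, W: np.ndarray, min_hairpin: int):
        self.sequence = sequence
        self.B = B
        self.W = W
        self.min_hairpin = min_hairpin
        self._cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def _choices(self, i: int, j: int):
        key = (i, j)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        kmin = i + self.min_hairpin + 1
        ks = np.arange(kmin, j + 1)
        w = self.B[i, kmin:j + 1] * self.W[i + 1, kmin - 1:j] * self.W[kmin + 1:j + 2, j]
        keep = w > 0
        ks = ks[keep]
        weights = np.concatenate(([self.W[i + 1, j]], w[keep]))
        cum = np.cumsum(weights)
        self._cache[key] = (ks, cum)
        return ks, cum

    def draw(self, rng: np.random.Generator) -> frozenset:
        n = len(self.sequence)
        pairs = []
        stack = [(1, n)]
        while stack:
            i, j = stack.pop()
            if j - i < self.min_hairpin + 1:
                continue
            ks, cum = self._choices(i, j)
            u = rng.random() * cum[-1]
            idx = int(np.searchsorted(cum, u, side="right"))
            if idx >= cum.size:  # numerical edge at u == total
                idx = cum.size - 1
            if idx == 0:
                stack.append((i + 1, j))
            else:
                k = int(ks[idx - 1])
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
        return frozenset(pairs)


def sample_structures(
    sequence: str,
    pseudo: Optional[Sequence[float]] = None,
    model: EnergyModel | None = None,
    n: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    condition_id: str = "",
) -> list[StructureSample]:
    """Draw ``n`` i.i.d. structures from the Boltzmann ensemble by stochastic
    traceback of the inside tables; reproducible given ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    model = model or EnergyModel()
    sequence = sequence.upper().replace("T", "U")
    length = len(sequence)
    B = _boltzmann_pair_weights(sequence, pseudo, model)
    W = _inside(B, length, model.min_hairpin)
    sampler = _Sampler(sequence, B, W, model.min_hairpin)
    rng = np.random.default_rng(seed)
    g = np.zeros(length) if pseudo is None else np.asarray(pseudo, dtype=float)
    samples = []
    for index in range(n):
        pairs = sampler.draw(rng)
        structure = SecondaryStructure(length, pairs, sequence)
        energy = sum(
            model.pair_energies[(sequence[i - 1], sequence[j - 1])]
            + g[i - 1]
            + g[j - 1]
            for i, j in pairs
        )
        samples.append(StructureSample(structure, energy, condition_id, index))
    return samples


# ---------------------------------------------------------------------------
# Covariation-scored consensus folding of an alignment
# ---------------------------------------------------------------------------

def _column_pair_score(
    column_a: Sequence[str],
    column_b: Sequence[str],
    model: EnergyModel,
    covariation_bonus: float,
    inconsistency_penalty: float,
) -> Optional[float]:
    """Score pairing two alignment columns; ``None`` when no sequence can
    pair there."""
    energies = []
    pair_types = set()
    cannot = 0
    for x, y in zip(column_a, column_b):
        e = model.pair_energy(x, y) if "-" not in (x, y) else None
        if e is None:
            cannot += 1
        else:
            energies.append(e)
            pair_types.add((x, y))
    if not energies:
        return None
    score = float(np.mean(energies))
    score += covariation_bonus * max(0, len(pair_types) - 1)
    score += inconsistency_penalty * cannot
    return score


def consensus_sample_from_msa(
    msa: Sequence[tuple[str, str]],
    model: EnergyModel | None = None,
    covariation_bonus: float = -1.0,
    inconsistency_penalty: float = 0.5,
    n: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    reference_id: Optional[str] = None,
    condition_id: str = "msa",
) -> list[StructureSample]:
    """Sample consensus structures from an alignment, mapped to reference
    coordinates.

    Each column pair is scored by the mean pair energy over sequences whose
    residues form a WC/GU pair, a (negative) covariation bonus per extra
    distinct pair type observed, and a penalty per sequence that cannot pair
    there (including gapped sequences).  The scored alignment is folded with
    the same ensemble machinery as a single sequence; sampled column pairs
    touching a reference-gap column are dropped when mapping back.
    """
    model = model or EnergyModel()
    if len(msa) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    names = [name for name, _ in msa]
    if reference_id is None:
        ref_index = 0
    else:
        if reference_id not in names:
            raise ValueError(f"reference row {reference_id!r} absent from alignment")
        ref_index = names.index(reference_id)
    rows = [seq.upper().replace("T", "U") for _, seq in msa]
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("alignment rows have unequal lengths")
    columns = ["".join(r[c] for r in rows) for c in range(ncol)]

    B = np.zeros((ncol + 2, ncol + 2))
    for a in range(1, ncol + 1):
        for b in range(a + model.min_hairpin + 1, ncol + 1):
            score = _column_pair_score(
                columns[a - 1], columns[b - 1], model, covariation_bonus, inconsistency_penalty
            )
            if score is not None:
                B[a, b] = math.exp(-score / model.RT)
    W = _inside(B, ncol, model.min_hairpin)
    scores = {}  # for recomputable sample energies
    log = math.log
    RT = model.RT
    sampler = _Sampler("N" * ncol, B, W, model.min_hairpin)
    rng = np.random.default_rng(seed)

    ref_row = rows[ref_index]
    ref_pos = np.full(ncol, -1, dtype=int)
    pos = 0
    for c, char in enumerate(ref_row):
        if char != "-":
            pos += 1
            ref_pos[c] = pos
    ref_len = pos
    if ref_len < 1:
        raise ValueError("reference row is all gaps")
    reference_sequence = ref_row.replace("-", "")

    samples = []
    for index in range(n):
        col_pairs = sampler.draw(rng)
        energy = sum(-RT * log(B[a, b]) for a, b in col_pairs)
        mapped = frozenset(
            (int(ref_pos[a - 1]), int(ref_pos[b - 1]))
            for a, b in col_pairs
            if ref_pos[a - 1] > 0 and ref_pos[b - 1] > 0
        )
        structure = SecondaryStructure(ref_len, mapped, reference_sequence)
        samples.append(StructureSample(structure, energy, condition_id, index))
    return samples
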