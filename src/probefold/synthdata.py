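"""Synthetic probing data with the statistical structure the pipeline
assumes.

Reactivities are generated from a known secondary structure: unpaired
positions draw from a Gamma distribution with mean ~0.8, paired positions
from a Gamma with mean ~0.1 (both nonnegative and right-skewed, like real
normalized reactivities).  Replicates share the per-position base reactivity
and differ by multiplicative log-normal noise; sparse x10 spikes emulate the
intrinsic reverse-transcriptase stops that outlier removal targets, and
random dropouts emulate undetermined nucleotides.  A DMS-like probe observes
only A and C; a SHAPE-like probe observes every nucleotide.

Alignments are simulated by mutating the reference sequence, co-mutating the
partner of a paired position with high probability so that true pairs carry
covariation signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .formats_io import SENTINEL, ReactivityProfile, SecondaryStructure

_PAIR_CHOICES = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
_BASES = "ACGU"


@dataclass(frozen=True)
class ProbeModel:
    """Statistical model of one chemical probe.

    ``observable`` is ``"all"`` (SHAPE-like, ribose chemistry) or ``"AC"``
    (DMS-like, Watson-Crick face of A and C).
    """

    name: str = "shape_like"
    observable: str = "all"
    unpaired_shape: float = 3.0
    unpaired_scale: float = 0.27
    paired_shape: float = 2.0
    paired_scale: float = 0.05
    noise_sigma: float = 0.3
    outlier_rate: float = 0.01
    outlier_factor: float = 10.0
    dropout_rate: float = 0.02

    @classmethod
    def shape_like(cls, **overrides) -> "ProbeModel":
        return cls(name="shape_like", observable="all", **overrides)

    @classmethod
    def dms_like(cls, **overrides) -> "ProbeModel":
        return cls(name="dms_like", observable="AC", **overrides)


def simulate_profiles(
    structure: SecondaryStructure,
    probe: ProbeModel | None = None,
    n_replicates: int = 3,
    seed: int | np.random.SeedSequence | None = None,
    rna_id: str = "synthetic",
    condition_id: str = "",
) -> list[ReactivityProfile]:
    """Simulate replicate reactivity profiles for a known structure."""
    probe = probe or ProbeModel()
    if structure.sequence is None:
        raise ValueError("structure needs a sequence")
    rng = np.random.default_rng(seed)
    n = structure.length
    paired = structure.partner_array() >= 0
    base = np.where(
        paired,
        rng.gamma(probe.paired_shape, probe.paired_scale, size=n),
        rng.gamma(probe.unpaired_shape, probe.unpaired_scale, size=n),
    )
    unobservable = np.zeros(n, dtype=bool)
    if probe.observable == "AC":
        unobservable = np.array([c not in "AC" for c in structure.sequence])
    elif probe.observable != "all":
        raise ValueError(f"unknown observability {probe.observable!r}")
    profiles = []
    cond = condition_id or probe.name
    for rep in range(n_replicates):
        noise = rng.lognormal(mean=0.0, sigma=probe.noise_sigma, size=n) if probe.noise_sigma > 0 else 1.0
        values = base * noise
        spikes = rng.random(n) < probe.outlier_rate
        values = np.where(spikes, values * probe.outlier_factor, values)
        dropouts = rng.random(n) < probe.dropout_rate
        values = np.where(dropouts | unobservable, SENTINEL, values)
        profiles.append(
            ReactivityProfile(
                rna_id=rna_id,
                condition_id=cond,
                replicate_id=f"rep{rep + 1}",
                values=values,
                sequence=structure.sequence,
            )
        )
    return profiles


def simulate_msa(
    structure: SecondaryStructure,
    n_seqs: int = 8,
    mutation_rate: float = 0.1,
    seed: int | np.random.SeedSequence | None = None,
    compensation: float = 0.9,
    gap_rate: float = 0.01,
    reference_id: str = "reference",
) -> list[tuple[str, str]]:
    """Simulate a compensatory-mutation alignment around a reference
    structure.

    Mutations hitting a paired position co-mutate the partner (probability
    ``compensation``) to another WC/GU pair, so true pairs covary; the
    reference row is the unmodified original, listed first.
    """
    if structure.sequence is None:
        raise ValueError("structure needs a sequence")
    rng = np.random.default_rng(seed)
    ref = list(structure.sequence)
    n = structure.length
    partner = structure.partner_array()
    rows = [(reference_id, "".join(ref))]
    for s in range(1, n_seqs):
        seq = list(ref)
        mutate = rng.random(n) < mutation_rate
        handled = np.zeros(n, dtype=bool)
        for pos in range(n):
            if not mutate[pos] or handled[pos]:
                continue
            j = partner[pos]
            if j >= 0 and rng.random() < compensation:
                x, y = _PAIR_CHOICES[rng.integers(len(_PAIR_CHOICES))]
                i, j = (pos, j) if pos < j else (j, pos)
                seq[i], seq[j] = x, y
                handled[i] = handled[j] = True
            else:
                current = seq[pos]
                options = [b for b in _BASES if b != current]
                seq[pos] = options[rng.integers(len(options))]
                handled[pos] = True
        gaps = rng.random(n) < gap_rate
        for pos in np.flatnonzero(gaps):
            seq[pos] = "-"
        rows.append((f"seq{s}", "".join(seq)))
    return rows


def simulate_footprint_pair(
    n_positions: int = 100,
    shifted_positions: Optional[Sequence[int]] = None,
    n_shifted: int = 10,
    shift: float = 0.6,
    sigma: float = 0.1,
    n_replicates: int = 3,
    probe: ProbeModel | None = None,
    seed: int | np.random.SeedSequence | None = None,
    rna_id: str = "synthetic",
):
    """Simulate matched replicate sets for a two-condition footprint.

    Baseline reactivities follow the probe's paired/unpaired mixture (random
    50/50 pairing status).  Differential sites model exposure events --
    protected (paired-like, low) baselines that gain ``shift`` in condition 2,
    as when a ligand-bound helix or junction opens.  Replicate noise is
    additive Gaussian with standard deviation ``sigma``, truncated at zero.

    Returns ``(cond1_profiles, cond2_profiles, shifted_positions)`` with
    1-based shifted positions.
    """
    probe = probe or ProbeModel()
    rng = np.random.default_rng(seed)
    if shifted_positions is None:
        chosen = rng.choice(n_positions, size=n_shifted, replace=False)
        shifted_positions = sorted(int(p) + 1 for p in chosen)
    shifted_idx = np.array([p - 1 for p in shifted_positions], dtype=int)
    paired = rng.random(n_positions) < 0.5
    baseline = np.where(
        paired,
        rng.gamma(probe.paired_shape, probe.paired_scale, size=n_positions),
        rng.gamma(probe.unpaired_shape, probe.unpaired_scale, size=n_positions),
    )
    baseline[shifted_idx] = rng.gamma(
        probe.paired_shape, probe.paired_scale, size=shifted_idx.size
    )
    base2 = baseline.copy()
    base2[shifted_idx] += shift

    def replicate_set(base: np.ndarray, condition: str) -> list[ReactivityProfile]:
        return [
            ReactivityProfile(
                rna_id=rna_id,
                condition_id=condition,
                replicate_id=f"rep{rep + 1}",
                values=np.maximum(base + rng.normal(0.0, sigma, size=n_positions), 0.0),
            )
            for rep in range(n_replicates)
        ]

    return replicate_set(baseline, "cond1"), replicate_set(base2, "cond2"), list(shifted_positions)
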