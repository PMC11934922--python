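"""Replicate aggregation, consistency flagging, correlation QC and
multi-primer concatenation.

Aggregation works position by position and mirrors careful manual practice
with few replicates.  A position is *accepted* (its mean feeds the modeling)
when either the replicate standard deviation is small (<= ``min_std``) or all
pairwise replicate means fall in the same reactivity class as the total mean.
Positions failing both checks are flagged ``warning`` (pairwise means agree on
a single class that differs from the total mean's) or ``nonconsistent``
(pairwise means span several classes); both are excluded from modeling, as are
``undetermined`` positions with too few valid values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import (
    FLAG_ACCEPTED,
    FLAG_NONCONSISTENT,
    FLAG_SEVERITY,
    FLAG_UNDETERMINED,
    FLAG_WARNING,
    SENTINEL,
    ClassScheme,
    ReactivityProfile,
    is_valid,
)


@dataclass(frozen=True)
class ConsistencyConfig:
    min_std: float = 0.15
    min_ndata: int = 2
    scheme: ClassScheme = field(default_factory=ClassScheme)

    def __post_init__(self) -> None:
        if self.min_std <= 0:
            raise ValueError("min_std must be > 0")
        if self.min_ndata < 1:
            raise ValueError("min_ndata must be >= 1")


@dataclass
class AggregatedProfile:
    """Per-position mean / std / consistency flag for one RNA x condition."""

    rna_id: str
    condition_id: str
    mean: np.ndarray
    std: np.ndarray
    flag: np.ndarray
    n_valid: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        self.flag = np.asarray(self.flag, dtype=object)
        self.n_valid = np.asarray(self.n_valid, dtype=int)
        sizes = {a.size for a in (self.mean, self.std, self.flag, self.n_valid)}
        if len(sizes) != 1:
            raise ValueError("aggregated arrays must share one length")

    @property
    def length(self) -> int:
        return int(self.mean.size)

    def accepted_mask(self) -> np.ndarray:
        return self.flag == FLAG_ACCEPTED

    def modeling_values(self) -> np.ndarray:
        """Means where accepted, sentinel everywhere else.

        Only accepted positions constrain structure modeling; warning,
        nonconsistent and undetermined positions behave as missing data.
        """
        values = np.where(self.accepted_mask(), self.mean, SENTINEL)
        return values.astype(float)


def _flag_position(values: np.ndarray, cfg: ConsistencyConfig, min_ndata: int):
    """Return (mean, std, flag, n_valid) for one position's replicate values."""
    valid = values[is_valid(values)]
    n = valid.size
    if n < min_ndata:
        return SENTINEL, 0.0, FLAG_UNDETERMINED, n
    if n == 1:
        return float(valid[0]), 0.0, FLAG_ACCEPTED, 1
    mean = float(np.mean(valid))
    std = float(np.std(valid, ddof=1))
    if std <= cfg.min_std:
        return mean, std, FLAG_ACCEPTED, n
    scheme = cfg.scheme
    mean_class = scheme.classify(mean)
    if n == 2:
        # With two replicates the single pairwise mean equals the total mean,
        # so the class criterion would trivially pass; require instead that the
        # two replicate values themselves agree in class.
        classes = {scheme.classify(float(v)) for v in valid}
        if len(classes) == 1:
            return mean, std, FLAG_ACCEPTED, n
        return mean, std, FLAG_NONCONSISTENT, n
    pair_classes = {
        scheme.classify((float(a) + float(b)) / 2.0)
        for a, b in combinations(valid, 2)
    }
    if pair_classes == {mean_class}:
        return mean, std, FLAG_ACCEPTED, n
    if len(pair_classes) == 1:
        return mean, std, FLAG_WARNING, n
    return mean, std, FLAG_NONCONSISTENT, n


def aggregate_replicates(
    profiles: Sequence[ReactivityProfile],
    cfg: ConsistencyConfig | None = None,
) -> AggregatedProfile:
    """Aggregate replicate profiles of one RNA x condition position by
    position."""
    cfg = cfg or ConsistencyConfig()
    if not profiles:
        raise ValueError("no profiles to aggregate")
    rna_ids = {p.rna_id for p in profiles}
    cond_ids = {p.condition_id for p in profiles}
    lengths = {p.length for p in profiles}
    if len(rna_ids) > 1 or len(cond_ids) > 1:
        raise ValueError("profiles must share rna_id and condition_id")
    if len(lengths) > 1:
        raise ValueError(f"profiles have mismatching lengths {sorted(lengths)}")
    length = lengths.pop()
    # With a single replicate the workflow still runs; clamp min_ndata to 1.
    min_ndata = 1 if len(profiles) == 1 else cfg.min_ndata
    matrix = np.vstack([p.values for p in profiles])
    mean = np.empty(length)
    std = np.empty(length)
    flag = np.empty(length, dtype=object)
    n_valid = np.empty(length, dtype=int)
    for pos in range(length):
        mean[pos], std[pos], flag[pos], n_valid[pos] = _flag_position(
            matrix[:, pos], cfg, min_ndata
        )
    return AggregatedProfile(
        rna_id=profiles[0].rna_id,
        condition_id=profiles[0].condition_id,
        mean=mean,
        std=std,
        flag=flag,
        n_valid=n_valid,
    )


def replicate_correlations(profiles: Sequence[ReactivityProfile]) -> pd.DataFrame:
    """Pairwise Pearson and Spearman correlations between replicates.

    Computed over positions valid in both replicates; pairs with fewer than 3
    common valid positions are reported as undefined (NaN).  The result is a
    QC report only -- it has no automated consequences.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two replicates for correlations")
    rows = []
    for (ia, pa), (ib, pb) in combinations(enumerate(profiles), 2):
        if pa.length != pb.length:
            raise ValueError("profiles have mismatching lengths")
        common = pa.valid_mask() & pb.valid_mask()
        n_common = int(common.sum())
        if n_common < 3:
            pearson = spearman = float("nan")
        else:
            a, b = pa.values[common], pb.values[common]
            with np.errstate(invalid="ignore"):
                pearson = float(stats.pearsonr(a, b).statistic)
                spearman = float(stats.spearmanr(a, b).statistic)
        rows.append(
            {
                "replicate_a": pa.replicate_id or f"rep{ia + 1}",
                "replicate_b": pb.replicate_id or f"rep{ib + 1}",
                "n_common": n_common,
                "pearson": pearson,
                "spearman": spearman,
            }
        )
    return pd.DataFrame(rows)


def concatenate_primers(
    segments: Sequence[tuple[AggregatedProfile, int, int]],
    rna_length: Optional[int] = None,
) -> AggregatedProfile:
    """Merge aggregated profiles from different primers into one full-length
    profile.

    Each segment covers 1-based positions ``primer_start..primer_end``.
    Uncovered positions are undetermined.  Where two segments overlap: if both
    are accepted the means are averaged (std combined conservatively as the
    max); if exactly one is accepted it wins; otherwise the position stays
    excluded with the more severe of the two flags.
    """
    if not segments:
        raise ValueError("no segments to concatenate")
    rna_ids = {seg.rna_id for seg, _, _ in segments}
    cond_ids = {seg.condition_id for seg, _, _ in segments}
    if len(rna_ids) > 1:
        raise ValueError(f"conflicting rna_id in segments: {sorted(rna_ids)}")
    if len(cond_ids) > 1:
        raise ValueError(f"conflicting condition_id in segments: {sorted(cond_ids)}")
    for seg, start, end in segments:
        if start < 1 or end < start:
            raise ValueError(f"invalid primer range {start}..{end}")
        if seg.length != end - start + 1:
            raise ValueError(
                f"segment length {seg.length} does not match range {start}..{end}"
            )
    length = rna_length if rna_length is not None else max(end for _, _, end in segments)
    if length < max(end for _, _, end in segments):
        raise ValueError("rna_length smaller than covered range")
    mean = np.full(length, SENTINEL)
    std = np.zeros(length)
    flag = np.full(length, FLAG_UNDETERMINED, dtype=object)
    n_valid = np.zeros(length, dtype=int)
    for seg, start, end in segments:
        for local, pos in enumerate(range(start - 1, end)):
            new = (seg.mean[local], seg.std[local], seg.flag[local], seg.n_valid[local])
            if flag[pos] == FLAG_UNDETERMINED and n_valid[pos] == 0 and mean[pos] == SENTINEL:
                mean[pos], std[pos], flag[pos], n_valid[pos] = new
                continue
            old = (mean[pos], std[pos], flag[pos], n_valid[pos])
            mean[pos], std[pos], flag[pos], n_valid[pos] = _merge_overlap(old, new)
    return AggregatedProfile(
        rna_id=rna_ids.pop(),
        condition_id=cond_ids.pop(),
        mean=mean,
        std=std,
        flag=flag,
        n_valid=n_valid,
    )


def _merge_overlap(old, new):
    om, os, of, on = old
    nm, ns, nf, nn = new
    if of == FLAG_ACCEPTED and nf == FLAG_ACCEPTED:
        return (om + nm) / 2.0, max(os, ns), FLAG_ACCEPTED, on + nn
    if of == FLAG_ACCEPTED:
        return om, os, of, on
    if nf == FLAG_ACCEPTED:
        return nm, ns, nf, nn
    worse = max(of, nf, key=lambda f: FLAG_SEVERITY[f])
    if worse == FLAG_UNDETERMINED:
        return SENTINEL, 0.0, worse, max(on, nn)
    # Keep the excluded mean of the more severe side for reporting purposes.
    keep = old if FLAG_SEVERITY[of] >= FLAG_SEVERITY[nf] else new
    return keep[0], keep[1], worse, keep[3]
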