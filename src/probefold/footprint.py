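"""Differential-reactivity (footprinting) analysis between two conditions.

A position is called significant when three criteria hold at once: the
absolute difference of the condition means ``dR = |R1 - R2|`` exceeds a
threshold (default 0.2), the relative difference ``dR / (R1 + R2)`` exceeds
the same threshold, and a two-sided Welch t-test on the replicate values
yields ``p < alpha`` (default .05).  The dual threshold discards both small
changes between weakly reactive nucleotides and large but meaningless changes
between highly reactive ones; undetermined positions are excluded outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import (
    ReactivityProfile,
    SecondaryStructure,
    is_valid,
    _fmt,
)

DIRECTION_UP = "up_in_2"
DIRECTION_DOWN = "down_in_2"
DIRECTION_NONE = "none"


@dataclass(frozen=True)
class FootprintConfig:
    diff_threshold: float = 0.2
    alpha: float = 0.05
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if self.diff_threshold <= 0:
            raise ValueError("diff_threshold must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class FootprintRecord:
    position: int
    r1: float
    r2: float
    delta: float
    relative: float
    p_value: float
    significant: bool
    direction: str
    no_test: bool = False


def footprint(
    cond1: Sequence[ReactivityProfile],
    cond2: Sequence[ReactivityProfile],
    cfg: FootprintConfig | None = None,
) -> list[FootprintRecord]:
    """Per-position differential statistics between two replicate sets.

    Only positions with at least one valid replicate value on both sides are
    reported; with fewer than two replicates on either side no test is
    possible and the record carries ``no_test=True`` (never significant).
    """
    cfg = cfg or FootprintConfig()
    if not cond1 or not cond2:
        raise ValueError("both conditions need at least one replicate profile")
    lengths = {p.length for p in list(cond1) + list(cond2)}
    if len(lengths) > 1:
        raise ValueError("all profiles must share the RNA length")
    length = lengths.pop()
    m1 = np.vstack([p.values for p in cond1])
    m2 = np.vstack([p.values for p in cond2])
    records = []
    for pos in range(length):
        v1 = m1[:, pos][is_valid(m1[:, pos])]
        v2 = m2[:, pos][is_valid(m2[:, pos])]
        if v1.size == 0 or v2.size == 0:
            continue  # undetermined on one side: excluded
        r1 = float(np.mean(v1))
        r2 = float(np.mean(v2))
        delta = abs(r1 - r2)
        total = r1 + r2
        relative = delta / total if total != 0 else 0.0
        if v1.size >= 2 and v2.size >= 2:
            p_value = float(stats.ttest_ind(v1, v2, equal_var=False).pvalue)
            no_test = False
        else:
            p_value = float("nan")
            no_test = True
        records.append(
            FootprintRecord(
                position=pos + 1,
                r1=r1,
                r2=r2,
                delta=delta,
                relative=relative,
                p_value=p_value,
                significant=False,
                direction=DIRECTION_NONE,
                no_test=no_test,
            )
        )
    _apply_significance(records, cfg)
    return records


def _apply_significance(records: list[FootprintRecord], cfg: FootprintConfig) -> None:
    p_values = np.array([r.p_value for r in records])
    adjusted = p_values.copy()
    if cfg.bh_correction:
        testable = ~np.isnan(p_values)
        if testable.any():
            adjusted[testable] = stats.false_discovery_control(p_values[testable], method="bh")
    for record, p_adj in zip(records, adjusted):
        significant = (
            not record.no_test
            and not math.isnan(p_adj)
            and record.delta > cfg.diff_threshold
            and record.relative > cfg.diff_threshold
            and p_adj < cfg.alpha
        )
        record.significant = significant
        if significant:
            record.direction = DIRECTION_UP if record.r2 > record.r1 else DIRECTION_DOWN
        else:
            record.direction = DIRECTION_NONE


def records_frame(records: Sequence[FootprintRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position": [r.position for r in records],
            "r1": [r.r1 for r in records],
            "r2": [r.r2 for r in records],
            "delta": [r.delta for r in records],
            "relative": [r.relative for r in records],
            "p_value": [r.p_value for r in records],
            "significant": [r.significant for r in records],
            "direction": [r.direction for r in records],
            "no_test": [r.no_test for r in records],
        }
    )


def footprint_outputs(
    records: Sequence[FootprintRecord],
    out_dir,
    structure: Optional[SecondaryStructure] = None,
    plot: bool = False,
    header: str | None = None,
) -> dict:
    """Write the footprint TSV, the signed-difference histogram data, and an
    optional structure annotation marking significant positions.

    The histogram reports ``R1 - R2`` per position with the significant
    positions flagged by direction (higher / lower reactivity in condition 2).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    table_path = out_dir / "footprint.tsv"
    with table_path.open("w") as handle:
        if header:
            for line in header.splitlines():
                handle.write(f"# {line}\n")
        records_frame(records).to_csv(handle, sep="\t", index=False, float_format="%.6g")
    paths["table"] = table_path

    hist_path = out_dir / "histogram.tsv"
    with hist_path.open("w") as handle:
        if header:
            for line in header.splitlines():
                handle.write(f"# {line}\n")
        handle.write("position\tdiff\tsignificant\tdirection\n")
        for r in records:
            handle.write(
                f"{r.position}\t{_fmt(r.r1 - r.r2)}\t"
                f"{'true' if r.significant else 'false'}\t{r.direction}\n"
            )
    paths["histogram"] = hist_path

    if structure is not None:
        colors_path = out_dir / "colors_footprint.txt"
        by_pos = {r.position: r for r in records}
        with colors_path.open("w") as handle:
            handle.write("# position\tdiff\tcall\n")
            for pos in range(1, structure.length + 1):
                r = by_pos.get(pos)
                if r is None:
                    handle.write(f"{pos}\t0\tundetermined\n")
                elif r.significant:
                    handle.write(f"{pos}\t{_fmt(r.r1 - r.r2)}\t{r.direction}\n")
                else:
                    handle.write(f"{pos}\t0\tnone\n")
        paths["colors"] = colors_path

    if plot:
        paths["plot"] = _plot_histogram(records, out_dir / "histogram.pdf")
    return paths


def _plot_histogram(records: Sequence[FootprintRecord], path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    positions = [r.position for r in records]
    diffs = [r.r1 - r.r2 for r in records]
    colors = [
        "tab:blue" if r.significant and r.direction == DIRECTION_DOWN
        else "tab:red" if r.significant
        else "0.7"
        for r in records
    ]
    fig, ax = plt.subplots(figsize=(max(6, len(records) / 12), 3))
    ax.bar(positions, diffs, color=colors, width=0.8)
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_xlabel("nucleotide position")
    ax.set_ylabel("reactivity difference (R1 - R2)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
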