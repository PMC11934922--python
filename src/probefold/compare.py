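"""Structure-model comparison: per-position three-category classification and
base-pair F1 scoring.

Each position of two equal-length models falls in exactly one category:
``same`` (identical pairing status and, if paired, identical partner),
``paired_both_different_partner`` (paired in both models with different
partners), or ``different_status`` (paired in exactly one model).  The default
annotation colors follow the blue / red / white convention of structure
viewers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .formats_io import SecondaryStructure

CATEGORY_SAME = "same"
CATEGORY_DIFFERENT_PARTNER = "paired_both_different_partner"
CATEGORY_DIFFERENT_STATUS = "different_status"

DEFAULT_COLORS = {
    CATEGORY_SAME: "blue",
    CATEGORY_DIFFERENT_PARTNER: "red",
    CATEGORY_DIFFERENT_STATUS: "white",
}


@dataclass(frozen=True)
class CompareRecord:
    position: int
    category: str


def compare_structures(s1: SecondaryStructure, s2: SecondaryStructure) -> list[CompareRecord]:
    """Classify every position of two models into the three categories."""
    if s1.length != s2.length:
        raise ValueError("structures must share one length")
    p1 = s1.partner_array()
    p2 = s2.partner_array()
    records = []
    for pos in range(s1.length):
        a, b = p1[pos], p2[pos]
        if a == b:
            category = CATEGORY_SAME
        elif a >= 0 and b >= 0:
            category = CATEGORY_DIFFERENT_PARTNER
        else:
            category = CATEGORY_DIFFERENT_STATUS
        records.append(CompareRecord(pos + 1, category))
    return records


def f1_score(model: SecondaryStructure, reference: SecondaryStructure) -> float:
    """Harmonic mean of base-pair precision and recall (exact pair matching,
    no slippage tolerance)."""
    if model.length != reference.length:
        raise ValueError("structures must share one length")
    tp = len(model.pairs & reference.pairs)
    if tp == 0:
        return 0.0
    precision = tp / len(model.pairs)
    recall = tp / len(reference.pairs)
    return 2.0 * precision * recall / (precision + recall)


def write_compare_annotations(
    records: Sequence[CompareRecord],
    common_path,
    categories_path,
    colors: dict | None = None,
) -> None:
    """Write the two comparison outputs: common-structure mask and the full
    three-category color annotation."""
    colors = {**DEFAULT_COLORS, **(colors or {})}
    with Path(common_path).open("w") as handle:
        handle.write("# position\tcommon\n")
        for r in records:
            handle.write(f"{r.position}\t{1 if r.category == CATEGORY_SAME else 0}\n")
    with Path(categories_path).open("w") as handle:
        handle.write("# position\tcategory\tcolor\n")
        for r in records:
            handle.write(f"{r.position}\t{r.category}\t{colors[r.category]}\n")
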