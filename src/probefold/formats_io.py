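"""Data containers and file formats for chemical-probing pipelines.

Everything user-facing is 1-based and inclusive, following the convention of
per-nucleotide reactivity files (column 1 = nucleotide number, column 2 =
reactivity).  Internally values live in 0-indexed numpy arrays.

The reactivity sentinel ``-10`` marks an undetermined position: primer-proximal
nucleotides, removed outliers, or values too negative to be trusted.  Sentinel
positions are carried through every stage and excluded from all statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Reactivity value that marks an undetermined nucleotide.
SENTINEL = -10.0

FLAG_ACCEPTED = "accepted"
FLAG_WARNING = "warning"
FLAG_NONCONSISTENT = "nonconsistent"
FLAG_UNDETERMINED = "undetermined"

#: Severity order used when merging overlapping primer segments.
FLAG_SEVERITY = {
    FLAG_ACCEPTED: 0,
    FLAG_WARNING: 1,
    FLAG_NONCONSISTENT: 2,
    FLAG_UNDETERMINED: 3,
}

CLASS_UNDEFINED = "undefined"
CLASS_LOW = "low"
CLASS_MEDIUM = "medium"
CLASS_HIGH = "high"


class ReactivityIOError(ValueError):
    """Malformed reactivity input (bad row, duplicate position, ...)."""


def is_valid(values: np.ndarray) -> np.ndarray:
    """Boolean mask of determined (non-sentinel) positions."""
    return np.asarray(values) != SENTINEL


# ---------------------------------------------------------------------------
# Reactivity profiles
# ---------------------------------------------------------------------------

@dataclass
class ReactivityProfile:
    """One RNA x condition x replicate reactivity vector.

    ``values[i]`` holds the reactivity of nucleotide ``i + 1``; undetermined
    positions hold :data:`SENTINEL`.
    """

    rna_id: str
    condition_id: str
    replicate_id: str
    values: np.ndarray
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("profile values must be a non-empty 1-D vector")
        if self.sequence is not None and len(self.sequence) != self.values.size:
            raise ValueError("sequence length does not match value vector")

    @property
    def length(self) -> int:
        return int(self.values.size)

    def valid_mask(self) -> np.ndarray:
        return is_valid(self.values)

    def value(self, position: int) -> float:
        """Reactivity at a 1-based nucleotide position."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return float(self.values[position - 1])

    def copy_with(self, values: np.ndarray) -> "ReactivityProfile":
        return replace(self, values=np.asarray(values, dtype=float))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactivityProfile):
            return NotImplemented
        return (
            self.rna_id == other.rna_id
            and self.condition_id == other.condition_id
            and self.replicate_id == other.replicate_id
            and self.sequence == other.sequence
            and np.array_equal(self.values, other.values)
        )


def read_reactivity_tsv(
    path,
    rna_id: str = "",
    condition_id: str = "",
    replicate_id: str = "",
) -> ReactivityProfile:
    """Read a tab-delimited per-nucleotide reactivity file.

    Column 1 is the nucleotide number, column 2 its reactivity; lines starting
    with ``#`` are comments.  Positions missing from the file (within
    ``1..max(position)``) are filled with the sentinel -- probing data
    routinely lacks primer-proximal nucleotides.
    """
    path = Path(path)
    entries: dict[int, float] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise ReactivityIOError(
                    f"{path}: line {lineno}: expected two tab-separated columns"
                )
            try:
                pos = int(fields[0])
            except ValueError as exc:
                raise ReactivityIOError(
                    f"{path}: line {lineno}: nucleotide number {fields[0]!r} "
                    "is not an integer"
                ) from exc
            try:
                val = float(fields[1])
            except ValueError as exc:
                raise ReactivityIOError(
                    f"{path}: line {lineno}: reactivity {fields[1]!r} is not a number"
                ) from exc
            if pos < 1:
                raise ReactivityIOError(
                    f"{path}: line {lineno}: nucleotide number must be >= 1"
                )
            if pos in entries:
                raise ReactivityIOError(
                    f"{path}: line {lineno}: duplicate position {pos}"
                )
            entries[pos] = val
    if not entries:
        raise ReactivityIOError(f"{path}: no data rows")
    length = max(entries)
    values = np.full(length, SENTINEL)
    for pos, val in entries.items():
        values[pos - 1] = val
    return ReactivityProfile(rna_id, condition_id, replicate_id, values)


def write_reactivity_tsv(profile: ReactivityProfile, path, header: str | None = None) -> None:
    """Write a profile back to the two-column tab-delimited format.

    Values are formatted with 6 significant digits so that read(write(p))
    round-trips for preprocessed data.
    """
    path = Path(path)
    with path.open("w") as handle:
        if header:
            for line in header.splitlines():
                handle.write(f"# {line}\n")
        for pos in range(1, profile.length + 1):
            handle.write(f"{pos}\t{_fmt(profile.values[pos - 1])}\n")


def _fmt(value: float) -> str:
    if value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return format(value, ".6g")


# ---------------------------------------------------------------------------
# Secondary structures and dot-bracket
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SecondaryStructure:
    """A nested (pseudoknot-free) set of base pairs on positions 1..length."""

    length: int
    pairs: frozenset
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        if self.length < 1:
            raise ValueError("length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length mismatch")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"invalid pair ({i}, {j}) for length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"position occurs in more than one pair: ({i}, {j})")
            seen.update((i, j))
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for k, l in ordered[a + 1:]:
                if k > j:
                    break
                if i < k <= j < l:
                    raise ValueError(f"crossing pairs ({i},{j}) and ({k},{l})")

    def partner_array(self) -> np.ndarray:
        """0-based partner index per position, -1 for unpaired."""
        partner = np.full(self.length, -1, dtype=int)
        for i, j in self.pairs:
            partner[i - 1] = j - 1
            partner[j - 1] = i - 1
        return partner

    def to_dotbracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    def min_loop_size(self) -> int:
        return min((j - i - 1 for i, j in self.pairs), default=self.length)


def parse_dotbracket(text: str, sequence: Optional[str] = None) -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    Raises ``ValueError`` naming the first offending 1-based index for
    unbalanced strings.
    """
    stack: list[int] = []
    pairs = set()
    for idx, char in enumerate(text, start=1):
        if char == "(":
            stack.append(idx)
        elif char == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket: unmatched ')' at index {idx}")
            pairs.add((stack.pop(), idx))
        elif char != ".":
            raise ValueError(f"invalid dot-bracket character {char!r} at index {idx}")
    if stack:
        raise ValueError(f"unbalanced dot-bracket: unmatched '(' at index {stack[0]}")
    if not text:
        raise ValueError("empty dot-bracket string")
    return SecondaryStructure(len(text), frozenset(pairs), sequence)


def read_dotbracket(path) -> SecondaryStructure:
    """Read a 3-line .dbn file (``>name``, sequence, structure)."""
    lines = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected '>name', sequence and structure lines")
    if lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) == 1:
        return parse_dotbracket(lines[0])
    sequence, structure = lines[0], lines[1]
    if len(sequence) != len(structure):
        raise ValueError(f"{path}: sequence and structure lengths differ")
    return parse_dotbracket(structure, sequence=sequence)


def write_dotbracket(structure: SecondaryStructure, path, name: str = "structure") -> None:
    seq = structure.sequence or "N" * structure.length
    Path(path).write_text(f">{name}\n{seq}\n{structure.to_dotbracket()}\n")


# ---------------------------------------------------------------------------
# Reactivity classes and color annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassScheme:
    """Thresholds splitting reactivities into low / medium / high classes.

    ``medium`` is the closed interval ``[reactivity_medium, reactivity_high]``;
    the sentinel maps to ``undefined``.
    """

    reactivity_medium: float = 0.4
    reactivity_high: float = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.reactivity_medium < self.reactivity_high:
            raise ValueError("require 0 < reactivity_medium < reactivity_high")

    def classify(self, value: float) -> str:
        if value == SENTINEL:
            return CLASS_UNDEFINED
        if value < self.reactivity_medium:
            return CLASS_LOW
        if value <= self.reactivity_high:
            return CLASS_MEDIUM
        return CLASS_HIGH

    def classify_array(self, values: Sequence[float]) -> list[str]:
        return [self.classify(float(v)) for v in np.asarray(values, dtype=float)]


def write_color_annotation(
    values: Sequence[float],
    scheme: ClassScheme,
    path,
    length: Optional[int] = None,
) -> None:
    """Write a per-nucleotide class annotation (position, value, class)."""
    values = np.asarray(values, dtype=float)
    if length is not None and values.size != length:
        raise ValueError(f"annotation length {values.size} != RNA length {length}")
    with Path(path).open("w") as handle:
        handle.write("# position\tvalue\tclass\n")
        for pos, val in enumerate(values, start=1):
            handle.write(f"{pos}\t{_fmt(val)}\t{scheme.classify(float(val))}\n")


def write_color_map(values: Sequence[float], path) -> None:
    """One-column values-only variant loadable by structure viewers."""
    with Path(path).open("w") as handle:
        for val in np.asarray(values, dtype=float):
            handle.write(f"{_fmt(float(val))}\n")


# ---------------------------------------------------------------------------
# Samples table
# ---------------------------------------------------------------------------

SAMPLES_COLUMNS = [
    "rna_id",
    "probe",
    "condition",
    "replicate",
    "primer_start",
    "primer_end",
    "file_path",
    "experimentalist",
    "discarded",
]


@dataclass
class SamplesTable:
    """The central experiment table (samples.tsv).

    One row per RNA x probe x condition x replicate x primer range; arbitrary
    extra annotation columns are preserved.  Rows marked ``discarded`` are
    excluded from every downstream stage.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLES_COLUMNS if c not in self.frame.columns and c != "experimentalist"]
        if missing:
            raise ValueError(f"samples table missing columns: {missing}")
        frame = self.frame.copy()
        if "experimentalist" not in frame.columns:
            frame["experimentalist"] = ""
        frame["discarded"] = frame["discarded"].map(_parse_bool)
        frame["primer_start"] = frame["primer_start"].astype(int)
        frame["primer_end"] = frame["primer_end"].astype(int)
        key = frame[["rna_id", "probe", "condition", "replicate", "primer_start", "primer_end"]]
        dup = key.duplicated()
        if dup.any():
            raise ValueError(
                "duplicate samples rows for key(s): "
                + ", ".join(str(tuple(r)) for r in key[dup].itertuples(index=False))
            )
        self.frame = frame

    def active(self) -> pd.DataFrame:
        """Rows that feed the pipeline (discarded rows removed)."""
        return self.frame[~self.frame["discarded"]].reset_index(drop=True)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"", "0", "false", "no", "n"}:
        return False
    if text in {"1", "true", "yes", "y"}:
        return True
    raise ValueError(f"cannot interpret discarded flag {value!r}")


def read_samples_table(path) -> SamplesTable:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    return SamplesTable(frame)


def write_samples_table(table: SamplesTable, path) -> None:
    frame = table.frame.copy()
    frame["discarded"] = frame["discarded"].map(lambda b: "true" if b else "false")
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA sequences and alignments
# ---------------------------------------------------------------------------

def read_fasta_sequences(path) -> dict[str, str]:
    """Read sequences from FASTA, uppercased with T converted to U."""
    records = {}
    for record in SeqIO.parse(str(path), "fasta"):
        records[record.id] = str(record.seq).upper().replace("T", "U")
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def read_msa_fasta(path) -> list[tuple[str, str]]:
    """Read an aligned FASTA (gaps ``-``); the first record is the reference
    unless the caller selects another row."""
    rows = []
    length = None
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("T", "U")
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(f"{path}: unequal alignment row lengths")
        rows.append((record.id, seq))
    if len(rows) < 1:
        raise ValueError(f"{path}: no alignment records")
    return rows


def write_msa_fasta(rows: Iterable[tuple[str, str]], path) -> None:
    with Path(path).open("w") as handle:
        for name, seq in rows:
            handle.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Aggregated profile I/O (position, mean, std, flag, n_valid)
# ---------------------------------------------------------------------------

def write_aggregated_tsv(aggregated, path, header: str | None = None) -> None:
    with Path(path).open("w") as handle:
        if header:
            for line in header.splitlines():
                handle.write(f"# {line}\n")
        handle.write("position\tmean\tstd\tflag\tn_valid\n")
        for pos in range(aggregated.length):
            handle.write(
                f"{pos + 1}\t{_fmt(float(aggregated.mean[pos]))}\t"
                f"{_fmt(float(aggregated.std[pos]))}\t{aggregated.flag[pos]}\t"
                f"{int(aggregated.n_valid[pos])}\n"
            )


def read_aggregated_tsv(path, rna_id: str = "", condition_id: str = ""):
    from .aggregate import AggregatedProfile  # local import to avoid a cycle

    frame = pd.read_csv(path, sep="\t", comment="#")
    frame = frame.sort_values("position")
    return AggregatedProfile(
        rna_id=rna_id,
        condition_id=condition_id,
        mean=frame["mean"].to_numpy(dtype=float),
        std=frame["std"].to_numpy(dtype=float),
        flag=np.asarray(frame["flag"], dtype=object),
        n_valid=frame["n_valid"].to_numpy(dtype=int),
    )
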