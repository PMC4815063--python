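"""Sequence and alignment containers, file I/O and column statistics.

Conventions used throughout the package:

* 20-letter amino-acid alphabet ``ACDEFGHIKLMNPQRSTVWY``; ``X`` marks an
  unknown residue and ``-`` a gap (alignments only).
* Alignment columns and sequence positions are 1-based, ranges inclusive.
* Input is case-insensitive; residues are stored uppercase.
* ``X`` counts as non-gap for gap fractions but contributes a uniform 1/20
  fractional count to column compositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
#: integer codes: 0..19 amino acids, 20 = X, -1 = gap
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
AA_INDEX[UNKNOWN] = 20

_VALID_ALIGNED = set(AMINO_ACIDS) | {UNKNOWN, GAP}
_VALID_UNALIGNED = set(AMINO_ACIDS) | {UNKNOWN}


class SeqFormatError(ValueError):
    """Raised on malformed sequence/alignment input."""


class AlignmentShapeError(SeqFormatError):
    """Raised when alignment rows are ragged or empty."""


@dataclass
class SequenceRecord:
    """A named protein sequence, aligned (may contain ``-``) or not."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqFormatError("sequence record with empty id")
        self.residues = self.residues.upper()
        if not self.residues:
            raise SeqFormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID_ALIGNED
        if bad:
            pos = min(self.residues.index(c) for c in bad) + 1
            raise SeqFormatError(
                f"sequence {self.id!r}: invalid character {self.residues[pos - 1]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_gapped(self) -> bool:
        return GAP in self.residues

    def ungapped(self) -> "SequenceRecord":
        return SequenceRecord(self.id, self.residues.replace(GAP, ""), self.description)


@dataclass
class Alignment:
    """An ordered set of equal-length rows with optional weights and group labels.

    ``groups`` maps sequence id -> group label (e.g. ``"MAPT_R2"``); ``weights``
    are positive per-sequence reals used by downstream weighted statistics.
    """

    records: list[SequenceRecord]
    weights: np.ndarray | None = None
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentShapeError("alignment with no records")
        L = len(self.records[0])
        for rec in self.records:
            if len(rec) != L:
                raise AlignmentShapeError(
                    f"ragged alignment: record {rec.id!r} has length {len(rec)}, "
                    f"expected {L}"
                )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqFormatError(f"duplicate sequence ids: {dup}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.records),):
                raise SeqFormatError("weights must be one per record")
            if not np.all(self.weights > 0):
                raise SeqFormatError("weights must be positive")
        unknown = set(self.groups) - set(ids)
        if unknown:
            raise SeqFormatError(f"group labels for unknown sequences: {sorted(unknown)}")

    @property
    def L(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def codes(self) -> np.ndarray:
        """Integer-coded residue matrix (n x L): 0..19 aa, 20 X, -1 gap."""
        out = np.empty((len(self), self.L), dtype=np.int8)
        for i, rec in enumerate(self.records):
            out[i] = [AA_INDEX.get(c, -1) for c in rec.residues]
        return out

    def column(self, col: int) -> str:
        self._check_col(col)
        return "".join(rec.residues[col - 1] for rec in self.records)

    def _check_col(self, col: int) -> None:
        if not 1 <= col <= self.L:
            raise IndexError(f"column {col} out of range 1..{self.L}")

    def effective_weights(self) -> np.ndarray:
        if self.weights is not None:
            return self.weights
        return np.ones(len(self))

    def group_labels(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: list[str] = []
        for rec in self.records:
            g = self.groups.get(rec.id)
            if g is not None and g not in seen:
                seen.append(g)
        return seen


# ---------------------------------------------------------------------------
# column statistics
# ---------------------------------------------------------------------------

def column_gap_fraction(aln: Alignment, col: int) -> float:
    """Weighted fraction of gap characters in a 1-based column."""
    aln._check_col(col)
    w = aln.effective_weights()
    is_gap = np.array([c == GAP for c in aln.column(col)])
    return float(w[is_gap].sum() / w.sum())


def column_composition(aln: Alignment, col: int) -> np.ndarray:
    """Weighted residue composition of a column over the 20-letter alphabet.

    Fractions are relative to total (gap-inclusive) weight, so they sum to
    ``1 - column_gap_fraction``.  ``X`` spreads its weight uniformly.
    """
    aln._check_col(col)
    w = aln.effective_weights()
    counts = np.zeros(20)
    for wi, c in zip(w, aln.column(col)):
        if c == GAP:
            continue
        if c == UNKNOWN:
            counts += wi / 20.0
        else:
            counts[AA_INDEX[c]] += wi
    return counts / w.sum()


def subalignment_by_group(aln: Alignment, label: str) -> Alignment:
    """Rows carrying ``label``, columns untouched (no degapping)."""
    keep = [rec for rec in aln.records if aln.groups.get(rec.id) == label]
    if not keep:
        raise KeyError(f"no records with group label {label!r}")
    idx = [i for i, rec in enumerate(aln.records) if aln.groups.get(rec.id) == label]
    w = aln.weights[idx] if aln.weights is not None else None
    groups = {rec.id: label for rec in keep}
    return Alignment([SequenceRecord(r.id, r.residues, r.description) for r in keep],
                     weights=w, groups=groups)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, aligned: bool = False) -> list[SequenceRecord]:
    recs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        recs.append(SequenceRecord(rec.id, str(rec.seq), rec.description))
    if not recs:
        raise SeqFormatError(f"no sequences in {path}")
    if not aligned:
        for r in recs:
            if r.is_gapped:
                raise SeqFormatError(f"unaligned FASTA contains gaps: {r.id!r}")
    return recs


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    if not records:
        raise SeqFormatError("refusing to write empty record list")
    bio = [_BioRecord(Seq(r.residues), id=r.id, description=r.description) for r in records]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


# ---------------------------------------------------------------------------
# Stockholm 1.0 (single-block dialect; '#=GS <seq> GR <label>' carries groups)
# ---------------------------------------------------------------------------

def _read_stockholm(path: str | Path) -> Alignment:
    seqs: dict[str, str] = {}
    order: list[str] = []
    groups: dict[str, str] = {}
    saw_blank_after_seqs = False
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# STOCKHOLM"):
            raise SeqFormatError(f"{path}: missing '# STOCKHOLM' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if line.strip() == "//":
                break
            if not line.strip():
                if seqs:
                    saw_blank_after_seqs = True
                continue
            if line.startswith("#=GS"):
                parts = line.split()
                if len(parts) >= 4 and parts[2] == "GR":
                    groups[parts[1]] = parts[3]
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise SeqFormatError(f"{path}:{lineno}: malformed sequence line")
            name, chunk = parts
            if name in seqs or saw_blank_after_seqs:
                raise SeqFormatError(
                    f"{path}: multi-block Stockholm not supported (sequence lines "
                    f"after a block break at line {lineno})"
                )
            seqs[name] = chunk
            order.append(name)
    if not seqs:
        raise SeqFormatError(f"{path}: no sequences in Stockholm file")
    records = [SequenceRecord(name, seqs[name].replace(".", GAP)) for name in order]
    groups = {k: v for k, v in groups.items() if k in seqs}
    return Alignment(records, groups=groups)


def _write_stockholm(aln: Alignment, path: str | Path) -> None:
    name_w = max(len(r.id) for r in aln.records) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for sid in aln.ids:
            if sid in aln.groups:
                fh.write(f"#=GS {sid} GR {aln.groups[sid]}\n")
        for rec in aln.records:
            fh.write(f"{rec.id:<{name_w}}{rec.residues}\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# format-dispatching alignment I/O
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an alignment; ``format`` is ``fasta`` or ``stockholm``.

    Stockholm ``#=GS <seq> GR <label>`` annotations populate ``groups``.
    """
    if format == "fasta":
        return Alignment(read_fasta(path, aligned=True))
    if format == "stockholm":
        return _read_stockholm(path)
    raise ValueError(f"unknown alignment format {format!r}")


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    if format == "fasta":
        write_fasta(aln.records, path)
    elif format == "stockholm":
        _write_stockholm(aln, path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def guess_format(path: str | Path) -> str:
    p = str(path)
    return "stockholm" if p.endswith((".sto", ".stk", ".stockholm")) else "fasta"
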