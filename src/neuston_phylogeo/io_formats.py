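"""Sequence and table I/O plus alignment-level preprocessing.

Reads FASTA files into :class:`SequenceSet`, group maps (clade + habitat per
sequence) into :class:`GroupMap`, and provides the two site-handling
primitives the downstream statistics depend on: ``dealign`` (remove every
gap, as done before motif counting) and ``complete_deletion`` (keep only
columns where every analyzed sequence has an unambiguous base, the default
site-exclusion convention for the diversity statistics).

Residues are normalized at read time: upper-case, U mapped to T, so every
downstream stage can assume the alphabet {A,C,G,T,N,-} plus IUPAC ambiguity
codes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    DegenerateAlignmentError,
    DuplicateIdError,
    EmptyInputError,
    MissingGroupError,
)

#: Unambiguous bases accepted in analyzed columns.
CANONICAL = frozenset("ACGT")

#: Full residue alphabet after normalization (IUPAC ambiguity codes included).
ALPHABET = frozenset("ACGTN-RYSWKMBDHV")

HABITATS = ("neustonic", "planktonic")


def _normalize(residues: str) -> str:
    return residues.upper().replace("U", "T")


@dataclass(frozen=True)
class NucleotideSequence:
    """One identified nucleotide sequence.

    ``description`` keeps the remainder of the FASTA header line (after the
    first whitespace) so files round-trip; it plays no role in identity.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        norm = _normalize(self.residues)
        bad = set(norm) - ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """Ordered collection of uniquely identified sequences."""

    sequences: list[NucleotideSequence]
    is_alignment: bool = False

    def __post_init__(self):
        ids = [s.id for s in self.sequences]
        if len(ids) != len(set(ids)):
            from collections import Counter

            dupes = sorted(i for i, k in Counter(ids).items() if k > 1)
            raise DuplicateIdError(f"duplicate sequence ids: {dupes}")
        if self.is_alignment and self.sequences:
            lengths = {len(s) for s in self.sequences}
            if len(lengths) > 1:
                raise ValueError(
                    f"alignment flagged but lengths differ: {sorted(lengths)}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def get(self, seq_id: str) -> NucleotideSequence:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise KeyError(seq_id)

    def subset(self, ids: Sequence[str]) -> "SequenceSet":
        """Restrict to ``ids`` (order follows ``ids``)."""
        by_id = {s.id: s for s in self.sequences}
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise KeyError(f"ids not in sequence set: {missing}")
        return SequenceSet([by_id[i] for i in ids], is_alignment=self.is_alignment)


@dataclass
class GroupMap:
    """Sequence id -> (clade label, habitat class)."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        for sid, (clade, habitat) in self.entries.items():
            if habitat not in HABITATS:
                raise ValueError(
                    f"habitat for {sid!r} must be one of {HABITATS}, got {habitat!r}"
                )
            if not clade:
                raise ValueError(f"empty clade label for {sid!r}")

    def clade(self, seq_id: str) -> str:
        return self.entries[seq_id][0]

    def habitat(self, seq_id: str) -> str:
        return self.entries[seq_id][1]

    @property
    def clades(self) -> list[str]:
        return sorted({c for c, _ in self.entries.values()})

    def members(self, clade_label: str) -> list[str]:
        return [i for i, (c, _) in self.entries.items() if c == clade_label]

    def habitat_members(self, habitat: str) -> list[str]:
        return [i for i, (_, h) in self.entries.items() if h == habitat]


def read_fasta(path: str | Path, *, assert_alignment: bool = False) -> SequenceSet:
    """Read a FASTA file.

    ``is_alignment`` is set when all records share one length and either a
    gap character is present or the caller asserts alignment.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    seen: set[str] = set()
    seqs = []
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        seqs.append(NucleotideSequence(rec.id, str(rec.seq), desc))
    lengths = {len(s) for s in seqs}
    has_gap = any("-" in s.residues for s in seqs)
    is_aln = len(lengths) == 1 and (has_gap or assert_alignment)
    return SequenceSet(seqs, is_alignment=is_aln)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_group_map(path: str | Path, sequences: SequenceSet | None = None) -> GroupMap:
    """Read a TSV group map with header columns id, clade, habitat.

    If ``sequences`` is given, every sequence id must be covered.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "clade", "habitat"}
    if not required.issubset(df.columns):
        raise ValueError(f"group map must have columns {sorted(required)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise DuplicateIdError(f"duplicate ids in group map: {dupes}")
    entries = {
        row.id: (row.clade, row.habitat) for row in df.itertuples(index=False)
    }
    gm = GroupMap(entries)
    if sequences is not None:
        missing = [i for i in sequences.ids if i not in entries]
        if missing:
            raise MissingGroupError(f"sequence ids missing from group map: {missing}")
    return gm


def write_group_map(gm: GroupMap, path: str | Path) -> None:
    df = pd.DataFrame(
        [(i, c, h) for i, (c, h) in gm.entries.items()],
        columns=["id", "clade", "habitat"],
    )
    df.to_csv(path, sep="\t", index=False)


def dealign(seqs: SequenceSet) -> SequenceSet:
    """Remove every internal/terminal gap character from every sequence.

    Ids and order are preserved; a sequence that is all gaps is retained as a
    length-0 sequence with a warning (it contributes zero counts downstream).
    """
    out = []
    for s in seqs:
        res = s.residues.replace("-", "")
        if not res and s.residues:
            warnings.warn(f"sequence {s.id!r} is empty after dealignment")
        out.append(NucleotideSequence(s.id, res, s.description))
    return SequenceSet(out, is_alignment=False)


def complete_deletion(aln: SequenceSet) -> SequenceSet:
    """Keep only columns where every sequence has an unambiguous A/C/G/T.

    The standard complete-deletion site-exclusion convention; raised as an
    error when no column survives.
    """
    if not aln.is_alignment:
        raise ValueError("complete_deletion requires an alignment")
    cols = zip(*(s.residues for s in aln))
    kept = [c for c in cols if all(ch in CANONICAL for ch in c)]
    if not kept:
        raise DegenerateAlignmentError("no columns survive complete deletion")
    rows = ["".join(r) for r in zip(*kept)]
    out = [
        NucleotideSequence(s.id, row, s.description)
        for s, row in zip(aln, rows)
    ]
    return SequenceSet(out, is_alignment=True)


def write_report(records, path: str | Path, format: str = "tsv") -> None:
    """Write tabular results as TSV or JSON with >= 6 significant digits."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records) if not isinstance(records, list) else records
        if not records:
            raise ValueError("cannot write an empty report")
        df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("cannot write an empty report")
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2, default=float)
    else:
        raise ValueError(f"unknown report format {format!r}")
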