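"""Lobe-level multiple sequence alignments.

A *lobe alignment* is an aligned set of protein sequences in which each row is
one helix-grip lobe of a TBP-like protein (or a whole single-lobe protein),
annotated with the organism it comes from, its superkingdom of origin, and
which lobe it is.  All downstream statistics — conservation profiles,
signature detection, coevolution — operate on these alignments.

The alphabet is the 20 standard amino acids, ``X`` for any unknown or
nonstandard residue, and ``-`` for a gap.  Nonstandard one-letter codes
(B, Z, J, U, O) are normalised to ``X`` on input so that column geometry is
preserved while the residue stays unscorable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    EmptyInputError,
    EmptySelectionError,
)

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = frozenset(AMINO_ACIDS) | {GAP, UNKNOWN}

SUPERKINGDOMS = frozenset({"eukaryote", "archaea", "bacteria", "virus"})
LOBES = frozenset({"N", "C", "single"})

# One-letter codes with ambiguous or nonstandard meaning map to 'X';
# '.' (Stockholm insert gap) maps to '-'.
_NORMALISE = str.maketrans({c: "X" for c in "BZJUO"} | {".": "-", "*": "-"})


def normalise_residues(raw: str) -> str:
    """Uppercase and map nonstandard codes to 'X', dots to '-'."""
    return raw.upper().translate(_NORMALISE)


@dataclass(frozen=True)
class LobeSequence:
    """One aligned lobe-level sequence with its provenance metadata."""

    seq_id: str
    organism: str
    superkingdom: str
    lobe: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise AlphabetError(f"{self.seq_id}: empty sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise AlphabetError(
                f"{self.seq_id}: illegal residue character(s) {sorted(bad)}"
            )
        if self.superkingdom not in SUPERKINGDOMS:
            raise AlphabetError(
                f"{self.seq_id}: unknown superkingdom {self.superkingdom!r}"
            )
        if self.lobe not in LOBES:
            raise AlphabetError(f"{self.seq_id}: unknown lobe {self.lobe!r}")

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class LobeAlignment:
    """An ordered collection of equal-length :class:`LobeSequence` rows."""

    sequences: tuple[LobeSequence, ...]

    def __post_init__(self):
        if not self.sequences:
            raise EmptyInputError("alignment has no sequences")
        lengths = {len(s.residues) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        ids = [s.seq_id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentShapeError(f"duplicate seq_ids: {dupes}")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0].residues)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[LobeSequence]:
        return iter(self.sequences)

    def column(self, j: int) -> str:
        """Residues of 0-based column *j*, one character per sequence."""
        if not 0 <= j < self.n_columns:
            raise IndexError(f"column {j} outside 0..{self.n_columns - 1}")
        return "".join(s.residues[j] for s in self.sequences)

    def columns(self) -> Iterator[str]:
        for j in range(self.n_columns):
            yield self.column(j)

    def subset(
        self,
        superkingdoms: Iterable[str] | None = None,
        lobes: Iterable[str] | None = None,
    ) -> "LobeAlignment":
        return subset_alignment(self, superkingdoms, lobes)


@dataclass(frozen=True)
class HeaderDialect:
    """How FASTA/Stockholm record names encode the metadata fields.

    The default is pipe-delimited ``id|organism|superkingdom|lobe``.  Records
    whose name cannot be parsed fall back to the declared defaults with a
    logged warning; unknown extra fields are ignored, never fatal.
    """

    sep: str = "|"
    fields: tuple[str, ...] = ("id", "organism", "superkingdom", "lobe")
    default_organism: str = "unknown"
    default_superkingdom: str = "eukaryote"
    default_lobe: str = "single"

    def parse(self, name: str) -> dict[str, str]:
        parts = name.split(self.sep)
        meta = {
            "id": name,
            "organism": self.default_organism,
            "superkingdom": self.default_superkingdom,
            "lobe": self.default_lobe,
        }
        ok = True
        for key, value in zip(self.fields, parts):
            meta[key] = value
        if len(parts) < len(self.fields):
            ok = False
        if meta["superkingdom"] not in SUPERKINGDOMS:
            meta["superkingdom"] = self.default_superkingdom
            ok = False
        if meta["lobe"] not in LOBES:
            meta["lobe"] = self.default_lobe
            ok = False
        if not ok:
            logger.warning(
                "record %r: incomplete/unparsable header, using defaults", name
            )
        return meta

    def format(self, seq: LobeSequence) -> str:
        values = {
            "id": seq.seq_id,
            "organism": seq.organism,
            "superkingdom": seq.superkingdom,
            "lobe": seq.lobe,
        }
        return self.sep.join(values[f] for f in self.fields)


DEFAULT_DIALECT = HeaderDialect()


def _detect_format(path: Path) -> str:
    if path.suffix.lower() in {".sto", ".stk", ".stockholm"}:
        return "stockholm"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "stockholm" if line.startswith("# STOCKHOLM") else "fasta"
    return "fasta"


def read_lobe_alignment(
    path: str | Path,
    dialect: HeaderDialect = DEFAULT_DIALECT,
    fmt: str | None = None,
) -> LobeAlignment:
    """Read an aligned FASTA (or Stockholm) file into a :class:`LobeAlignment`.

    Record names are parsed with *dialect*; records with unparsable metadata
    get the dialect's defaults and a logged warning.  Raises
    :class:`EmptyInputError` on an empty file, :class:`AlignmentShapeError` on
    ragged rows and :class:`AlphabetError` on illegal residues (naming the
    offending record).
    """
    path = Path(path)
    fmt = fmt or _detect_format(path)
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise EmptyInputError(f"{path}: no sequence records")
    seqs = []
    for rec in records:
        meta = dialect.parse(rec.id)
        seqs.append(
            LobeSequence(
                seq_id=meta["id"],
                organism=meta["organism"],
                superkingdom=meta["superkingdom"],
                lobe=meta["lobe"],
                residues=normalise_residues(str(rec.seq)),
            )
        )
    return LobeAlignment(tuple(seqs))


def write_lobe_alignment(
    aln: LobeAlignment,
    path: str | Path,
    dialect: HeaderDialect = DEFAULT_DIALECT,
) -> None:
    """Write the alignment as aligned FASTA (the single canonical output)."""
    records = [
        SeqRecord(Seq(s.residues), id=dialect.format(s), description="")
        for s in aln
    ]
    SeqIO.write(records, str(path), "fasta")


def subset_alignment(
    aln: LobeAlignment,
    superkingdoms: Iterable[str] | None = None,
    lobes: Iterable[str] | None = None,
) -> LobeAlignment:
    """Sequences matching both filters; ``None`` means no constraint.

    Column count is unchanged.  Raises :class:`EmptySelectionError` when the
    filters match nothing — the caller decides whether that is fatal.
    """
    sks = SUPERKINGDOMS if superkingdoms is None else set(superkingdoms)
    lbs = LOBES if lobes is None else set(lobes)
    if not sks <= SUPERKINGDOMS:
        raise AlphabetError(f"unknown superkingdom filter {sorted(sks - SUPERKINGDOMS)}")
    if not lbs <= LOBES:
        raise AlphabetError(f"unknown lobe filter {sorted(lbs - LOBES)}")
    kept = tuple(
        s for s in aln.sequences if s.superkingdom in sks and s.lobe in lbs
    )
    if not kept:
        raise EmptySelectionError(
            f"no sequences match superkingdoms={sorted(sks)} lobes={sorted(lbs)}"
        )
    return LobeAlignment(kept)
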