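"""Substitution matrices and the normalised-score lookup table.

Conservation and coevolution statistics both rest on the *normalised* BLOSUM
score of a residue pair:

    nbs(a, b) = score(a, b) / max(score(a, a), score(b, b))

which lies in [-1, 1] for any matrix whose diagonal dominates its rows (true
of BLOSUM62).  Identical residues score exactly 1.  Pairs involving a gap or
an unknown residue are unscorable (NaN in the numeric table, ``None`` at the
scalar API).

BLOSUM62 is the default matrix, taken from Biopython's copy of the standard
NCBI table; any matrix in NCBI text format can be loaded instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .errors import AlphabetError, ParameterError
from .msa import AMINO_ACIDS, GAP, UNKNOWN

# Residue encoding shared by all vectorised paths: 0..19 standard residues,
# 20 = gap, 21 = unknown.
GAP_CODE = 20
UNKNOWN_CODE = 21
N_CODES = 22

_ENCODER = np.full(128, -1, dtype=np.int8)
for _i, _aa in enumerate(AMINO_ACIDS):
    _ENCODER[ord(_aa)] = _i
_ENCODER[ord(GAP)] = GAP_CODE
_ENCODER[ord(UNKNOWN)] = UNKNOWN_CODE


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as int8 codes (0–19 residues, 20 gap, 21 X)."""
    codes = _ENCODER[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({residues[i] for i in np.where(codes < 0)[0]})
        raise AlphabetError(f"illegal residue character(s) {bad}")
    return codes


@dataclass(frozen=True, eq=False)
class SubstitutionMatrix:
    """A symmetric integer substitution matrix over the 20 standard residues."""

    name: str
    scores: dict[tuple[str, str], int] = field(repr=False)

    def __post_init__(self):
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                if (a, b) not in self.scores:
                    raise ParameterError(f"{self.name}: missing pair ({a},{b})")
                if self.scores[(a, b)] != self.scores[(b, a)]:
                    raise ParameterError(f"{self.name}: asymmetric at ({a},{b})")
            if self.scores[(a, a)] <= 0:
                raise ParameterError(f"{self.name}: non-positive diagonal at {a}")

    def score(self, a: str, b: str) -> int:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise AlphabetError(f"{self.name}: no score for pair ({a},{b})")

    @property
    def normalized_table(self) -> np.ndarray:
        """22x22 float table of normalised scores; NaN for gap/X rows & cols."""
        return _normalized_table(self)

    def is_diagonal_dominant(self) -> bool:
        """True when every off-diagonal entry is below both diagonal entries.

        Guarantees nbs = 1 only for identical residues (holds for BLOSUM62).
        """
        return all(
            self.scores[(a, b)] < max(self.scores[(a, a)], self.scores[(b, b)])
            for a in AMINO_ACIDS
            for b in AMINO_ACIDS
            if a != b
        )


@lru_cache(maxsize=8)
def _normalized_table(matrix: SubstitutionMatrix) -> np.ndarray:
    table = np.full((N_CODES, N_CODES), np.nan)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            table[i, j] = matrix.scores[(a, b)] / max(
                matrix.scores[(a, a)], matrix.scores[(b, b)]
            )
    table.flags.writeable = False
    return table


def _from_biopython(name: str) -> SubstitutionMatrix:
    arr = substitution_matrices.load(name)
    scores = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            scores[(a, b)] = int(arr[a, b])
    return SubstitutionMatrix(name=name, scores=scores)


@lru_cache(maxsize=4)
def blosum62() -> SubstitutionMatrix:
    """The standard BLOSUM62 matrix (the package default)."""
    return _from_biopython("BLOSUM62")


def load_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a named matrix from Biopython's NCBI collection."""
    return _from_biopython(name)


def read_ncbi_matrix(path: str | Path, name: str | None = None) -> SubstitutionMatrix:
    """Read a matrix in the standard NCBI text format (as in the BLAST data dir)."""
    path = Path(path)
    header: list[str] | None = None
    scores: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line or line.lstrip().startswith("#"):
                continue
            if header is None:
                header = line.split()
                continue
            parts = line.split()
            row = parts[0]
            for col, value in zip(header, parts[1:]):
                if row in AMINO_ACIDS and col in AMINO_ACIDS:
                    scores[(row, col)] = int(value)
    if header is None:
        raise ParameterError(f"{path}: not an NCBI matrix file")
    return SubstitutionMatrix(name=name or path.stem, scores=scores)


def write_ncbi_matrix(matrix: SubstitutionMatrix, path: str | Path) -> None:
    """Write the 20x20 standard-residue block in NCBI text format."""
    with open(path, "w") as fh:
        fh.write("   " + "  ".join(AMINO_ACIDS) + "\n")
        for a in AMINO_ACIDS:
            row = " ".join(f"{matrix.scores[(a, b)]:2d}" for b in AMINO_ACIDS)
            fh.write(f"{a} {row}\n")
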