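"""Normalised-BLOSUM conservation profiles and signature detection.

The per-column conservation statistic is the **normalised BLOSUM score**
(NBS): the mean, over all unordered pairs of sequences at one alignment
column, of ``score(a,b) / max(score(a,a), score(b,b))``.  It lies in [-1, 1]
and equals 1 exactly when all scorable residues in the column are identical
(for a diagonal-dominant matrix such as BLOSUM62).

Pairs involving a gap or an unknown residue are excluded and the pair count
renormalised; a column is unscorable when fewer than two standard residues
remain or fewer than half of the m-choose-2 pairs are scorable.

Three detectors are built on this statistic:

* **Universal signatures** — columns of a three-sequence ancestral alignment
  (one reconstructed sequence per superkingdom) whose NBS strictly exceeds
  the profile mean plus one standard deviation.
* **Lobe-specific signatures** — columns conserved in one lobe (NBS above
  that lobe's mean) and either more than ``ratio`` (default 1.5) times the
  other lobe's NBS at the same column, or conserved as a *different* modal
  residue in the two lobes ("residue switch").
* **Conservation fraction** — the share of sequences carrying one particular
  residue at a column (gaps count in the denominator).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import (
    AlignmentShapeError,
    ContextError,
    DegenerateProfileError,
    EmptyInputError,
    InsufficientDepthError,
    ParameterError,
)
from .matrices import GAP_CODE, SubstitutionMatrix, blosum62, encode
from .msa import GAP, LobeAlignment, LobeSequence, UNKNOWN

logger = logging.getLogger(__name__)

# A column is unscorable when fewer than half of its sequences carry a
# standard residue (gaps and X excluded) or fewer than two residues remain.
MIN_RESIDUE_FRACTION = 0.5


def normalized_pair_score(
    a: str, b: str, matrix: SubstitutionMatrix | None = None
) -> float | None:
    """Normalised substitution score of a residue pair, or None if unscorable."""
    if a in (GAP, UNKNOWN) or b in (GAP, UNKNOWN):
        return None
    matrix = matrix or blosum62()
    return matrix.score(a, b) / max(matrix.score(a, a), matrix.score(b, b))


def column_nbs(
    column: Sequence[str], matrix: SubstitutionMatrix | None = None
) -> float | None:
    """NBS of one alignment column: mean normalised score over scorable pairs.

    Returns None when the column is unscorable (fewer than two standard
    residues, or standard residues in fewer than half of the sequences).
    Raises :class:`InsufficientDepthError` for columns of fewer than two
    sequences.
    """
    m = len(column)
    if m < 2:
        raise InsufficientDepthError(f"column depth {m} < 2")
    matrix = matrix or blosum62()
    codes = encode("".join(column))
    return _column_nbs_coded(codes, matrix.normalized_table)


def _column_nbs_coded(codes: np.ndarray, table: np.ndarray) -> float | None:
    m = codes.size
    residues = codes[codes < GAP_CODE]
    k = residues.size
    if k < 2 or k < MIN_RESIDUE_FRACTION * m:
        return None
    iu, ju = np.triu_indices(k, k=1)
    return float(table[residues[iu], residues[ju]].mean())


@dataclass(frozen=True)
class NBSProfile:
    """Per-column NBS values with their mean and standard deviation.

    ``per_column`` holds NaN for unscorable columns; the mean and SD run over
    scorable columns only.  The SD is the population form by default
    (divide by the count), configurable at computation time.
    """

    per_column: np.ndarray
    mean_nbs: float
    sd_nbs: float
    n_scorable: int
    sd_mode: str = "population"

    @property
    def n_columns(self) -> int:
        return self.per_column.size

    def value(self, column: int) -> float | None:
        v = self.per_column[column]
        return None if math.isnan(v) else float(v)

    def mean_of(self, columns: Iterable[int]) -> float:
        """Mean NBS of a caller-supplied column set (scorable members only).

        Used to compare e.g. interface columns against the whole profile.
        """
        values = self.per_column[np.fromiter(columns, dtype=int)]
        values = values[~np.isnan(values)]
        if values.size == 0:
            raise DegenerateProfileError("no scorable columns in the given set")
        return float(values.mean())


def profile_stats(
    aln: LobeAlignment,
    matrix: SubstitutionMatrix | None = None,
    sd_mode: Literal["population", "sample"] = "population",
) -> NBSProfile:
    """NBS for every column of the alignment plus mean/SD over scorable ones."""
    matrix = matrix or blosum62()
    table = matrix.normalized_table
    coded = np.stack([encode(s.residues) for s in aln])
    values = np.full(aln.n_columns, np.nan)
    for j in range(aln.n_columns):
        v = _column_nbs_coded(coded[:, j], table)
        if v is not None:
            values[j] = v
    scorable = values[~np.isnan(values)]
    if scorable.size == 0:
        raise DegenerateProfileError("profile has zero scorable columns")
    ddof = 0 if sd_mode == "population" else 1
    sd = float(scorable.std(ddof=ddof)) if scorable.size > ddof else 0.0
    return NBSProfile(
        per_column=values,
        mean_nbs=float(scorable.mean()),
        sd_nbs=sd,
        n_scorable=int(scorable.size),
        sd_mode=sd_mode,
    )


def modal_residue(column: Sequence[str]) -> tuple[str | None, frozenset[str]]:
    """Most frequent non-gap residue and the full argmax set.

    Ties break lexicographically for the representative.  Returns
    ``(None, frozenset())`` for an all-gap column.
    """
    counts: dict[str, int] = {}
    for ch in column:
        if ch != GAP:
            counts[ch] = counts.get(ch, 0) + 1
    if not counts:
        return None, frozenset()
    best = max(counts.values())
    winners = frozenset(r for r, c in counts.items() if c == best)
    return min(winners), winners


def ancestral_consensus(
    aln: LobeAlignment,
    method: Literal["consensus", "import"] = "consensus",
    imported: str | None = None,
) -> str:
    """One reconstructed sequence of alignment length (gaps allowed).

    ``consensus``: per column, a gap when gaps exceed half the sequences,
    otherwise the modal non-gap residue with lexicographic tie-break.  This
    is the star-tree limit of marginal maximum-likelihood reconstruction.
    ``import``: validate and pass through an externally reconstructed
    sequence (e.g. from a maximum-likelihood program).
    """
    if method == "import":
        if imported is None:
            raise ParameterError("method='import' requires an imported sequence")
        if len(imported) != aln.n_columns:
            raise AlignmentShapeError(
                f"imported ancestral sequence length {len(imported)} != "
                f"alignment width {aln.n_columns}"
            )
        return imported
    if method != "consensus":
        raise ParameterError(f"unknown ancestral method {method!r}")
    out = []
    m = len(aln)
    for j in range(aln.n_columns):
        col = aln.column(j)
        if col.count(GAP) > m / 2:
            out.append(GAP)
        else:
            residue, _ = modal_residue(col)
            out.append(residue if residue is not None else GAP)
    return "".join(out)


@dataclass(frozen=True)
class AncestralSet:
    """One reconstructed sequence per superkingdom context, alignment-length."""

    sequences: dict[str, str]
    method: str

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"ancestral sequences of unequal length {sorted(lengths)}"
            )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    def as_alignment(self) -> LobeAlignment:
        return LobeAlignment(
            tuple(
                LobeSequence(
                    seq_id=f"ancestor_{name}",
                    organism=name,
                    superkingdom="eukaryote" if name not in
                    {"archaea", "bacteria", "virus"} else name,
                    lobe="single",
                    residues=seq,
                )
                for name, seq in sorted(self.sequences.items())
            )
        )


def ancestral_set_by_superkingdom(
    aln: LobeAlignment,
    superkingdoms: Sequence[str] = ("archaea", "bacteria", "eukaryote"),
    method: Literal["consensus", "import"] = "consensus",
    imported: dict[str, str] | None = None,
) -> AncestralSet:
    """Reconstruct one ancestral sequence per superkingdom subset."""
    sequences = {}
    for sk in superkingdoms:
        sub = aln.subset(superkingdoms={sk})
        sequences[sk] = ancestral_consensus(
            sub, method=method, imported=(imported or {}).get(sk)
        )
    return AncestralSet(sequences=sequences, method=method)


@dataclass(frozen=True)
class LobeSignature:
    """One lobe-specific signature position with its rule provenance."""

    column: int  # 0-based
    lobe: str  # 'N' or 'C'
    rule_tag: str  # 'ratio' or 'residue-switch'
    nbs: float
    other_nbs: float


@dataclass(frozen=True)
class SignatureSet:
    """Flagged signature positions with the context that produced them."""

    universal: frozenset[int] = frozenset()
    lobe_specific: frozenset[LobeSignature] = frozenset()
    context: str = ""

    def lobe_columns(self, lobe: str) -> frozenset[int]:
        return frozenset(s.column for s in self.lobe_specific if s.lobe == lobe)


def universal_signatures(
    ancestors: AncestralSet,
    matrix: SubstitutionMatrix | None = None,
    context: str = "",
) -> SignatureSet:
    """Columns whose ancestral-triplet NBS strictly exceeds mean + SD.

    The profile runs over the three reconstructed superkingdom sequences;
    each column's NBS is the mean over the three ancestral pairs.  The strict
    inequality means a perfectly uniform profile flags nothing.
    """
    if len(ancestors.sequences) != 3:
        raise ContextError(
            f"universal-signature test needs exactly 3 ancestral sequences, "
            f"got {len(ancestors.sequences)}"
        )
    profile = profile_stats(ancestors.as_alignment(), matrix)
    threshold = profile.mean_nbs + profile.sd_nbs
    flagged = frozenset(
        int(j)
        for j in range(profile.n_columns)
        if not math.isnan(profile.per_column[j])
        and profile.per_column[j] > threshold
    )
    return SignatureSet(universal=flagged, context=context or f"ancestral:{ancestors.method}")


def lobe_specific_signatures(
    c_aln: LobeAlignment,
    n_aln: LobeAlignment,
    matrix: SubstitutionMatrix | None = None,
    ratio: float = 1.5,
    context: str = "",
) -> SignatureSet:
    """Signature positions specific to the C- or N-terminal lobe.

    For each lobe in turn, a column is flagged when its NBS exceeds that
    lobe's mean NBS and either (a) exceeds ``ratio`` times the other lobe's
    NBS at the same column (tag ``ratio`` — the test is applied literally
    even when the other lobe's NBS is negative, making it trivially true),
    or (b) the ratio test fails but the modal residues of the two lobes
    differ (tag ``residue-switch``; sharing any modal residue counts as
    not different).  Columns unscorable in either lobe are skipped.
    """
    if c_aln.n_columns != n_aln.n_columns:
        raise AlignmentShapeError(
            f"lobe alignments differ in width: {c_aln.n_columns} vs {n_aln.n_columns}"
        )
    matrix = matrix or blosum62()
    prof = {"C": profile_stats(c_aln, matrix), "N": profile_stats(n_aln, matrix)}
    aln = {"C": c_aln, "N": n_aln}
    flagged: set[LobeSignature] = set()
    for target, other in (("C", "N"), ("N", "C")):
        for j in range(c_aln.n_columns):
            nbs_t = prof[target].value(j)
            nbs_o = prof[other].value(j)
            if nbs_t is None or nbs_o is None:
                continue
            if nbs_t <= prof[target].mean_nbs:
                continue
            if nbs_t > ratio * nbs_o:
                tag = "ratio"
            else:
                _, winners_t = modal_residue(aln[target].column(j))
                _, winners_o = modal_residue(aln[other].column(j))
                if winners_t and winners_o and not (winners_t & winners_o):
                    tag = "residue-switch"
                else:
                    continue
            flagged.add(
                LobeSignature(
                    column=j, lobe=target, rule_tag=tag, nbs=nbs_t, other_nbs=nbs_o
                )
            )
    return SignatureSet(lobe_specific=frozenset(flagged), context=context)


def conservation_fraction(column: Sequence[str], residue: str) -> float:
    """Fraction of sequences carrying *residue* at the column (gaps in the denominator)."""
    if len(column) == 0:
        raise EmptyInputError("empty column")
    return sum(1 for ch in column if ch == residue) / len(column)
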