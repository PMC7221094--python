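"""Coevolution between columns of two organism-paired family alignments.

The statistic follows the substitution-similarity approach: at a column,
collect the normalised BLOSUM score of every unordered pair of sequences
into a vector of length n-choose-2 (fixed lexicographic pair order).  The
coevolution of a column *r* in family A with a column *s* in family B is the
Pearson correlation (PC) of the two vectors, computed over the entries where
both are scorable.

Significance comes from a composition-preserving permutation null: both
columns are independently shuffled within themselves (residue composition
unchanged) and PC recomputed; the empirical p-value is the fraction of
rounds whose PC is greater than or equal to the observed PC.  A zero count
is reported as a bound, "< 1/n_perm".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    InsufficientPairsError,
    ParameterError,
    TargetColumnError,
    UndefinedCorrelationError,
)
from .matrices import SubstitutionMatrix, blosum62, encode
from .msa import LobeAlignment

logger = logging.getLogger(__name__)

# Numerical guard when comparing permuted PCs with the observed PC: the
# identity permutation must count as ">= observed" despite float roundoff.
_PC_TIE_TOL = 1e-12


@dataclass(frozen=True)
class PairedAlignment:
    """Two family alignments with rows matched one-to-one by organism."""

    family_a: LobeAlignment
    family_b: LobeAlignment
    pairing: tuple[tuple[str, str], ...]

    def __post_init__(self):
        ids_a = {s.seq_id for s in self.family_a}
        ids_b = {s.seq_id for s in self.family_b}
        for ia, ib in self.pairing:
            if ia not in ids_a or ib not in ids_b:
                raise ParameterError(f"pairing references unknown sequence ({ia},{ib})")
        if len(self.pairing) < 3:
            raise InsufficientPairsError(
                f"need >= 3 organism-matched pairs, got {len(self.pairing)}"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    def column_a(self, j: int) -> str:
        index = {s.seq_id: s.residues for s in self.family_a}
        return "".join(index[ia][j] for ia, _ in self.pairing)

    def column_b(self, j: int) -> str:
        index = {s.seq_id: s.residues for s in self.family_b}
        return "".join(index[ib][j] for _, ib in self.pairing)


def pair_alignments(a: LobeAlignment, b: LobeAlignment) -> PairedAlignment:
    """Match sequences of the two families by exact organism name.

    One pair per organism (the first sequence in row order wins, with a
    warning on duplicates); unpaired sequences are dropped with a warning.
    Pairs are ordered deterministically by organism name.
    """

    def by_organism(aln: LobeAlignment) -> dict[str, str]:
        index: dict[str, str] = {}
        for s in aln:
            if s.organism in index:
                logger.warning(
                    "duplicate organism %r: keeping first sequence", s.organism
                )
            else:
                index[s.organism] = s.seq_id
        return index

    orgs_a, orgs_b = by_organism(a), by_organism(b)
    shared = sorted(set(orgs_a) & set(orgs_b))
    dropped = (set(orgs_a) | set(orgs_b)) - set(shared)
    for org in sorted(dropped):
        logger.warning("organism %r present in only one family: dropped", org)
    if len(shared) < 3:
        raise InsufficientPairsError(
            f"only {len(shared)} organisms shared between the families"
        )
    return PairedAlignment(
        family_a=a,
        family_b=b,
        pairing=tuple((orgs_a[org], orgs_b[org]) for org in shared),
    )


def substitution_vector(
    column: Sequence[str], matrix: SubstitutionMatrix | None = None
) -> np.ndarray:
    """Normalised pair scores over all unordered sequence pairs at a column.

    Length n-choose-2, in lexicographic pair order (1,2), (1,3), ..., (n-1,n);
    entries involving a gap or unknown residue are NaN.
    """
    n = len(column)
    if n < 3:
        raise ParameterError(f"need >= 3 sequences for a pair vector, got {n}")
    matrix = matrix or blosum62()
    codes = encode("".join(column))
    iu, ju = np.triu_indices(n, k=1)
    return matrix.normalized_table[codes[iu], codes[ju]]


def pearson_pc(br: np.ndarray, bs: np.ndarray) -> float:
    """Pearson correlation of two substitution-similarity vectors.

    Entries missing (NaN) in either vector are dropped pairwise.  Raises
    :class:`UndefinedCorrelationError` when fewer than 3 joint entries remain
    or either vector has zero variance.
    """
    br = np.asarray(br, dtype=float)
    bs = np.asarray(bs, dtype=float)
    if br.shape != bs.shape:
        raise ParameterError(f"vector lengths differ: {br.size} vs {bs.size}")
    valid = ~(np.isnan(br) | np.isnan(bs))
    x, y = br[valid], bs[valid]
    if x.size < 3:
        raise UndefinedCorrelationError(
            f"only {x.size} jointly scorable entries (< 3)"
        )
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("zero variance in a substitution vector")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


@dataclass(frozen=True)
class CoevolutionResult:
    """Observed PC with its permutation-test summary."""

    pc: float
    count_ge: int  # permutation rounds with PC_random >= PC_observed
    n_perm: int
    seed: int
    n_pairs_used: int  # jointly scorable pair-entries behind the observed PC

    @property
    def p_value(self) -> float:
        """count/n_perm; 0.0 means the observed PC exceeded every round."""
        return self.count_ge / self.n_perm

    def format_p(self) -> str:
        """p as printed in reports; a zero count reports the resolution bound."""
        if self.count_ge == 0:
            return f"<{1 / self.n_perm:g}"
        return f"{self.p_value:g}"


def _permuted_codes(
    codes: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """n_perm independent within-column shuffles (rows) of a coded column."""
    tiled = np.tile(codes, (n_perm, 1))
    return rng.permuted(tiled, axis=1)


def _pc_rows(br: np.ndarray, bs: np.ndarray) -> np.ndarray:
    """Row-wise PC of two (rounds x N) matrices with NaN-aware pairwise drop.

    Rows with fewer than 3 joint entries or zero variance yield -inf so they
    never count as exceeding an observed PC.
    """
    valid = ~(np.isnan(br) | np.isnan(bs))
    x = np.where(valid, br, 0.0)
    y = np.where(valid, bs, 0.0)
    k = valid.sum(axis=1)
    sx, sy = x.sum(axis=1), y.sum(axis=1)
    sxx, syy = (x * x).sum(axis=1), (y * y).sum(axis=1)
    sxy = (x * y).sum(axis=1)
    num = k * sxy - sx * sy
    var_x = k * sxx - sx**2
    var_y = k * syy - sy**2
    with np.errstate(invalid="ignore", divide="ignore"):
        pc = num / np.sqrt(var_x * var_y)
    pc[(k < 3) | (var_x <= 0) | (var_y <= 0)] = -np.inf
    return pc


def permutation_pvalue(
    col_a: Sequence[str],
    col_b: Sequence[str],
    matrix: SubstitutionMatrix | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    plus_one: bool = False,
) -> CoevolutionResult:
    """Composition-preserving permutation test of PC between two columns.

    Both columns are shuffled independently each round, preserving their
    residue compositions; the p-value is the fraction of rounds whose PC is
    >= the observed PC.  With ``plus_one`` the conservative (count+1)/(n+1)
    estimator is reported instead of the raw fraction.  Fully determined by
    *seed*.
    """
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    if len(col_a) != len(col_b):
        raise ParameterError("columns must be aligned to the same pairing")
    matrix = matrix or blosum62()
    table = matrix.normalized_table
    br = substitution_vector(col_a, matrix)
    bs = substitution_vector(col_b, matrix)
    pc_obs = pearson_pc(br, bs)  # raises UndefinedCorrelationError if degenerate
    n_used = int((~(np.isnan(br) | np.isnan(bs))).sum())

    n = len(col_a)
    rng = np.random.default_rng(seed)
    codes_a = _permuted_codes(encode("".join(col_a)), n_perm, rng)
    codes_b = _permuted_codes(encode("".join(col_b)), n_perm, rng)
    iu, ju = np.triu_indices(n, k=1)
    br_mat = table[codes_a[:, iu], codes_a[:, ju]]
    bs_mat = table[codes_b[:, iu], codes_b[:, ju]]
    pc_rand = _pc_rows(br_mat, bs_mat)
    count = int((pc_rand >= pc_obs - _PC_TIE_TOL).sum())
    if plus_one:
        count = count + 1
        n_perm_eff = n_perm + 1
    else:
        n_perm_eff = n_perm
    return CoevolutionResult(
        pc=pc_obs, count_ge=count, n_perm=n_perm_eff, seed=seed, n_pairs_used=n_used
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (monotone q-values)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def coevolution_scan(
    pa: PairedAlignment,
    target_col: int,
    matrix: SubstitutionMatrix | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[CoevolutionResult | None]:
    """Test one family-A column against every column of family B.

    Returns one result per family-B column, ``None`` for columns where PC is
    undefined (constant or too gapped).  Each column uses an independent
    seed derived deterministically from *seed* so results do not depend on
    which other columns are scanned.  Multiple-testing adjustment is opt-in
    at the report layer (:func:`bh_adjust`); raw results always carry
    unadjusted p.
    """
    matrix = matrix or blosum62()
    col_a = pa.column_a(target_col)
    try:
        _check = pearson_pc(
            substitution_vector(col_a, matrix), substitution_vector(col_a, matrix)
        )
    except UndefinedCorrelationError as exc:
        raise TargetColumnError(f"target column {target_col} unscorable: {exc}")
    results: list[CoevolutionResult | None] = []
    seed_stream = np.random.SeedSequence(seed).spawn(pa.family_b.n_columns)
    for j in range(pa.family_b.n_columns):
        col_b = pa.column_b(j)
        child_seed = int(seed_stream[j].generate_state(1)[0] % (2**31))
        try:
            results.append(
                permutation_pvalue(
                    col_a, col_b, matrix, n_perm=n_perm, seed=child_seed
                )
            )
        except UndefinedCorrelationError:
            results.append(None)
    return results
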