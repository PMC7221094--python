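"""Synthetic alignments, coupled alignment pairs, and variant tables.

Every generator is a pure function of its spec and seed, so planted truth is
exactly recoverable and reruns are byte-identical.

The alignment model is a star tree: each column draws an ancestral residue
from a background distribution; each sequence keeps it with probability
1 - theta (the column's divergence level) and otherwise draws a replacement
from the background excluding the ancestral residue.  theta = 0 gives a
perfectly conserved column (NBS = 1); theta near 1 gives near-background
divergence.

Coevolving column pairs are generated by *event mirroring*: with probability
kappa an organism's substitution decision (and its replacement draw) is
shared between the two coupled columns, so kappa = 1 with equal theta makes
the two columns substitute in the same organisms with coordinated
replacements, driving the coevolution statistic toward 1, while kappa = 0
reduces to two independent simulations.

Variant tables draw per-region, per-source counts from a Poisson law with
the specified rate per residue and place them uniformly within the region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .coevolution import PairedAlignment
from .errors import ParameterError
from .msa import AMINO_ACIDS, LobeAlignment, LobeSequence
from .variation import Region, VariantRecord

_N_AA = len(AMINO_ACIDS)


@dataclass(frozen=True)
class AlignmentSpec:
    """Parameters of one synthetic lobe alignment.

    ``theta`` may be a scalar (shared by all columns) or one value per
    column; ``n_seqs`` maps superkingdom names to sequence counts.

    ``lineage_divergence`` (scalar or per-column, default 0) is the
    probability that a superkingdom's *lineage ancestor* departs from the
    root residue at a column.  Diverged lineage ancestors are drawn to be
    mutually non-conservative (pairwise normalised BLOSUM62 score at most
    ``max_lineage_similarity``, and distinct from the root and each other):
    under a substitution-matrix scoring model a conservative replacement is
    itself a form of conservation, so an honestly diverged background must
    avoid it or planted truth becomes ill-defined.  Sequences then diverge
    from their own lineage ancestor with probability ``theta``.
    """

    n_seqs: Mapping[str, int]
    n_columns: int
    theta: float | Sequence[float] = 0.5
    background: Sequence[float] | None = None  # length-20; uniform if None
    lobe: str = "single"
    seed: int = 0
    organism_prefix: str = "org"
    lineage_divergence: float | Sequence[float] = 0.0
    max_lineage_similarity: float = 0.3

    def theta_vector(self) -> np.ndarray:
        theta = np.broadcast_to(np.asarray(self.theta, float), (self.n_columns,))
        if ((theta < 0) | (theta > 1)).any():
            raise ParameterError("theta must lie in [0,1]")
        return np.array(theta)

    def lineage_divergence_vector(self) -> np.ndarray:
        d = np.broadcast_to(
            np.asarray(self.lineage_divergence, float), (self.n_columns,)
        )
        if ((d < 0) | (d > 1)).any():
            raise ParameterError("lineage_divergence must lie in [0,1]")
        return np.array(d)

    def background_vector(self) -> np.ndarray:
        if self.background is None:
            return np.full(_N_AA, 1.0 / _N_AA)
        bg = np.asarray(self.background, float)
        if bg.size != _N_AA or (bg < 0).any() or bg.sum() <= 0:
            raise ParameterError("background must be 20 nonnegative weights")
        return bg / bg.sum()

    def validate(self) -> None:
        if self.n_columns < 1:
            raise ParameterError("n_columns must be >= 1")
        if not self.n_seqs or any(v < 2 for v in self.n_seqs.values()):
            raise ParameterError("need >= 2 sequences per superkingdom context")
        self.theta_vector()
        self.background_vector()
        self.lineage_divergence_vector()

    def organisms(self) -> list[tuple[str, str]]:
        """Deterministic (organism, superkingdom) roster."""
        roster = []
        for sk in sorted(self.n_seqs):
            for i in range(self.n_seqs[sk]):
                roster.append((f"{self.organism_prefix}_{sk}_{i:03d}", sk))
        return roster


@dataclass(frozen=True)
class CouplingSpec:
    """Coupled column pairs between two families: (col_a, col_b, kappa)."""

    pairs: tuple[tuple[int, int, float], ...] = ()

    def validate(self, n_cols_a: int, n_cols_b: int) -> None:
        seen_a, seen_b = set(), set()
        for ca, cb, kappa in self.pairs:
            if not (0 <= ca < n_cols_a and 0 <= cb < n_cols_b):
                raise ParameterError(f"coupled column ({ca},{cb}) out of range")
            if not 0 <= kappa <= 1:
                raise ParameterError(f"kappa must lie in [0,1], got {kappa}")
            if ca in seen_a or cb in seen_b:
                raise ParameterError("each column may appear in one coupling only")
            seen_a.add(ca)
            seen_b.add(cb)


def _draw_background(bg: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw of residue codes from the background, u in [0,1)."""
    cdf = np.cumsum(bg)
    return np.searchsorted(cdf, u, side="right").clip(max=_N_AA - 1)


def _replacement(bg: np.ndarray, ancestral: int, u: np.ndarray) -> np.ndarray:
    """Draw replacement codes from the background excluding the ancestral residue."""
    weights = bg.copy()
    weights[ancestral] = 0.0
    weights /= weights.sum()
    return _draw_background(weights, u)


def _column_codes(
    ancestral: int,
    theta: float,
    bg: np.ndarray,
    v: np.ndarray,
    w: np.ndarray,
) -> np.ndarray:
    """Residue codes for one column given per-sequence event/replacement draws."""
    codes = np.full(v.size, ancestral)
    hit = v < theta
    if hit.any():
        codes[hit] = _replacement(bg, ancestral, w[hit])
    return codes


def _codes_to_rows(codes: np.ndarray) -> list[str]:
    lookup = np.array(list(AMINO_ACIDS))
    return ["".join(lookup[row]) for row in codes]


def _nonconservative_pool(
    taken: Sequence[int], max_similarity: float
) -> np.ndarray:
    """Residue codes non-conservative (and distinct) w.r.t. all *taken* codes."""
    from .matrices import blosum62

    table = blosum62().normalized_table
    ok = np.ones(_N_AA, dtype=bool)
    for code in taken:
        ok &= table[np.arange(_N_AA), code] <= max_similarity
        ok[code] = False
    return np.where(ok)[0]


def _lineage_ancestors(
    spec: AlignmentSpec,
    root: np.ndarray,
    superkingdoms: Sequence[str],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-superkingdom ancestral codes: root, or a mutually diverged residue."""
    d = spec.lineage_divergence_vector()
    ancestors = {sk: root.copy() for sk in superkingdoms}
    for j in range(spec.n_columns):
        if d[j] == 0:
            continue
        diverged = [sk for sk in superkingdoms if rng.random() < d[j]]
        taken = [int(root[j])]
        for sk in diverged:
            pool = _nonconservative_pool(taken, spec.max_lineage_similarity)
            if pool.size == 0:  # alphabet exhausted; fall back to any new residue
                pool = np.setdiff1d(np.arange(_N_AA), taken)
            choice = int(rng.choice(pool))
            ancestors[sk][j] = choice
            taken.append(choice)
    return ancestors


def simulate_alignment(
    spec: AlignmentSpec, rng: np.random.Generator | None = None
) -> LobeAlignment:
    """Generate a lobe alignment under the star-tree divergence model."""
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed)
    theta = spec.theta_vector()
    bg = spec.background_vector()
    roster = spec.organisms()
    m = len(roster)
    root = _draw_background(bg, rng.random(spec.n_columns))
    sks = sorted(spec.n_seqs)
    lineage = _lineage_ancestors(spec, root, sks, rng)
    ancestral_rows = np.stack([lineage[sk] for _, sk in roster])
    codes = np.empty((m, spec.n_columns), dtype=int)
    for j in range(spec.n_columns):
        v, w = rng.random(m), rng.random(m)
        col = np.empty(m, dtype=int)
        for anc in np.unique(ancestral_rows[:, j]):
            rows = ancestral_rows[:, j] == anc
            col[rows] = _column_codes(int(anc), theta[j], bg, v[rows], w[rows])
        codes[:, j] = col
    rows = _codes_to_rows(codes)
    return LobeAlignment(
        tuple(
            LobeSequence(
                seq_id=f"sim_{org}",
                organism=org,
                superkingdom=sk,
                lobe=spec.lobe,
                residues=row,
            )
            for (org, sk), row in zip(roster, rows)
        )
    )


def simulate_coevolving_pair(
    spec_a: AlignmentSpec,
    spec_b: AlignmentSpec,
    coupling: CouplingSpec = CouplingSpec(),
) -> PairedAlignment:
    """Two organism-matched alignments with planted coevolving column pairs.

    Both families share the organism roster of ``spec_a`` (``spec_b`` must
    declare the same sequence counts).  For a coupled pair with strength
    kappa, each organism mirrors its substitution event and replacement draw
    between the two columns with probability kappa; kappa = 0 is exactly two
    independent simulations.  All randomness comes from ``spec_a.seed``.
    """
    spec_a.validate()
    spec_b.validate()
    if dict(spec_a.n_seqs) != dict(spec_b.n_seqs):
        raise ParameterError("both families need the same organism roster")
    coupling.validate(spec_a.n_columns, spec_b.n_columns)
    rng = np.random.default_rng(spec_a.seed)
    roster = spec_a.organisms()
    m = len(roster)
    theta_a, theta_b = spec_a.theta_vector(), spec_b.theta_vector()
    bg_a, bg_b = spec_a.background_vector(), spec_b.background_vector()
    anc_a = _draw_background(bg_a, rng.random(spec_a.n_columns))
    anc_b = _draw_background(bg_b, rng.random(spec_b.n_columns))

    # Independent event/replacement streams for every column of each family.
    v_a, w_a = rng.random((m, spec_a.n_columns)), rng.random((m, spec_a.n_columns))
    v_b, w_b = rng.random((m, spec_b.n_columns)), rng.random((m, spec_b.n_columns))
    for ca, cb, kappa in coupling.pairs:
        mirrored = rng.random(m) < kappa
        v_b[mirrored, cb] = v_a[mirrored, ca]
        w_b[mirrored, cb] = w_a[mirrored, ca]

    def build(spec, anc, theta, bg, v, w, prefix):
        codes = np.empty((m, spec.n_columns), dtype=int)
        for j in range(spec.n_columns):
            codes[:, j] = _column_codes(anc[j], theta[j], bg, v[:, j], w[:, j])
        rows = _codes_to_rows(codes)
        return LobeAlignment(
            tuple(
                LobeSequence(
                    seq_id=f"{prefix}_{org}",
                    organism=org,
                    superkingdom=sk,
                    lobe=spec.lobe,
                    residues=row,
                )
                for (org, sk), row in zip(roster, rows)
            )
        )

    fam_a = build(spec_a, anc_a, theta_a, bg_a, v_a, w_a, "famA")
    fam_b = build(spec_b, anc_b, theta_b, bg_b, v_b, w_b, "famB")
    pairing = tuple(
        (f"famA_{org}", f"famB_{org}") for org, _ in sorted(roster)
    )
    return PairedAlignment(family_a=fam_a, family_b=fam_b, pairing=pairing)


@dataclass(frozen=True)
class VariantSpec:
    """Per-region, per-source Poisson rates (mutations per residue)."""

    protein: str
    protein_length: int
    regions: tuple[Region, ...]
    rates: Mapping[str, Mapping[str, float]]  # region name -> source -> rate
    seed: int = 0

    def validate(self) -> None:
        for region in self.regions:
            if region.end > self.protein_length:
                raise ParameterError(
                    f"region {region.name!r} exceeds protein length "
                    f"{self.protein_length}"
                )
        for name, per_source in self.rates.items():
            if name not in {r.name for r in self.regions}:
                raise ParameterError(f"rate for unknown region {name!r}")
            for source, rate in per_source.items():
                if source not in {"natural", "cancer"}:
                    raise ParameterError(f"unknown source {source!r}")
                if rate < 0:
                    raise ParameterError(f"negative rate for {name}/{source}")


def simulate_variant_table(spec: VariantSpec) -> list[VariantRecord]:
    """Missense variant records with planted per-region density contrasts."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[VariantRecord] = []
    for region in spec.regions:
        for source in ("natural", "cancer"):
            rate = spec.rates.get(region.name, {}).get(source, 0.0)
            count = int(rng.poisson(rate * region.length))
            positions = rng.integers(region.start, region.end + 1, size=count)
            records.extend(
                VariantRecord(
                    protein=spec.protein,
                    position=int(pos),
                    consequence="missense",
                    source=source,
                )
                for pos in positions
            )
    return records
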