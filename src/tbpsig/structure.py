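"""Structure-derived contacts, column mapping, and interface enrichment.

Contacts between two molecules (protein-protein or protein-nucleic-acid) are
extracted from PDB/mmCIF coordinates with a heavy-atom distance rule: two
residues are in contact when any pair of their heavy atoms lies within the
cutoff (default 4.5 Å).  An optional rule uses per-element van der Waals
radius sums plus 0.5 Å instead of a flat cutoff; every contact set records
which rule produced it.  Hydrogens and waters are excluded; alternate
locations resolve to the highest-occupancy conformer.

Contact residues are mapped onto alignment columns through the ungapped
index of the structure's sequence within its aligned row (author residue
numbering is used verbatim; a sequence mismatch is fatal, because silent
renumbering is the classic source of off-by-one interface errors).

Enrichment of a signature position set in an interface position set is
tested with the upper tail of the hypergeometric distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import hypergeom

from .errors import EmptyInputError, MappingMismatchError, ParameterError
from .msa import GAP

logger = logging.getLogger(__name__)

# Bondi van der Waals radii (Å) for the optional per-element rule.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "ZN": 1.39, "FE": 1.63, "MN": 1.61, "CA": 2.31,
    "K": 2.75, "NA": 2.27,
}
_DEFAULT_VDW = 1.70
VDW_SLACK = 0.5


@dataclass(frozen=True)
class ResidueCoords:
    """Heavy-atom coordinates of one residue (author numbering)."""

    chain: str
    residue_number: int
    residue_name: str
    heavy_atoms: tuple[tuple[float, float, float], ...]
    elements: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.heavy_atoms:
            raise ParameterError(
                f"{self.chain}/{self.residue_number}: residue with no heavy atoms"
            )
        if not np.isfinite(np.asarray(self.heavy_atoms)).all():
            raise ParameterError(
                f"{self.chain}/{self.residue_number}: non-finite coordinates"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.residue_number)


def load_residues(
    path: str | Path, chains: Iterable[str] | None = None
) -> list[ResidueCoords]:
    """Read heavy-atom residue coordinates from a PDB or mmCIF file.

    Waters and hydrogens are dropped; alternate locations are reduced to the
    highest-occupancy conformer.  Nucleic-acid residues are returned exactly
    like protein residues.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_hydrogens()
    st.remove_waters()
    wanted = set(chains) if chains is not None else None
    out: list[ResidueCoords] = []
    model = st[0]
    for chain in model:
        if wanted is not None and chain.name not in wanted:
            continue
        for res in chain:
            # resolve alternate locations to the highest-occupancy conformer
            best: dict[str, gemmi.Atom] = {}
            for a in res:
                prev = best.get(a.name)
                if prev is None or a.occ > prev.occ:
                    best[a.name] = a
            atoms = [
                ((a.pos.x, a.pos.y, a.pos.z), a.element.name.upper())
                for a in best.values()
            ]
            if not atoms:
                continue
            out.append(
                ResidueCoords(
                    chain=chain.name,
                    residue_number=res.seqid.num,
                    residue_name=res.name,
                    heavy_atoms=tuple(xyz for xyz, _ in atoms),
                    elements=tuple(el for _, el in atoms),
                )
            )
    if not out:
        raise EmptyInputError(f"{path}: no residues in requested chains")
    return out


@dataclass(frozen=True)
class ContactSet:
    """Unordered residue-residue contact pairs with the rule that made them."""

    pairs: frozenset[tuple[tuple[str, int], tuple[str, int]]]
    cutoff_rule: str

    def __post_init__(self):
        for a, b in self.pairs:
            if a == b:
                raise ParameterError(f"self-contact {a}")

    def residues(self) -> frozenset[tuple[str, int]]:
        return frozenset(r for pair in self.pairs for r in pair)


def extract_contacts(
    chains_a: Sequence[ResidueCoords],
    chains_b: Sequence[ResidueCoords],
    cutoff: float = 4.5,
    rule: str = "heavy-distance",
) -> ContactSet:
    """Residue pairs across the two chain sets within the contact criterion.

    ``rule='heavy-distance'``: any heavy-atom pair within *cutoff* Å.
    ``rule='vdw'``: any heavy-atom pair within the sum of the two elements'
    van der Waals radii plus 0.5 Å (*cutoff* ignored).
    """
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be positive, got {cutoff}")
    if not chains_a or not chains_b:
        raise EmptyInputError("both chain sets must be nonempty")
    if rule not in {"heavy-distance", "vdw"}:
        raise ParameterError(f"unknown contact rule {rule!r}")

    coords_a = np.concatenate([np.asarray(r.heavy_atoms) for r in chains_a])
    coords_b = np.concatenate([np.asarray(r.heavy_atoms) for r in chains_b])
    owner_a = np.concatenate(
        [np.full(len(r.heavy_atoms), i) for i, r in enumerate(chains_a)]
    )
    owner_b = np.concatenate(
        [np.full(len(r.heavy_atoms), i) for i, r in enumerate(chains_b)]
    )

    if rule == "vdw":
        radii_a = np.concatenate(
            [
                [VDW_RADII.get(el, _DEFAULT_VDW) for el in (r.elements or ("C",) * len(r.heavy_atoms))]
                for r in chains_a
            ]
        )
        radii_b = np.concatenate(
            [
                [VDW_RADII.get(el, _DEFAULT_VDW) for el in (r.elements or ("C",) * len(r.heavy_atoms))]
                for r in chains_b
            ]
        )
        search = float(radii_a.max() + radii_b.max() + VDW_SLACK)
        rule_text = f"vdw-sum+{VDW_SLACK}A"
    else:
        search = float(cutoff)
        rule_text = f"heavy-atom<= {cutoff}A".replace(" ", "")

    tree_b = cKDTree(coords_b)
    pairs: set[tuple[tuple[str, int], tuple[str, int]]] = set()
    neighbours = tree_b.query_ball_point(coords_a, search)
    for ia, hits in enumerate(neighbours):
        if not hits:
            continue
        ra = chains_a[owner_a[ia]]
        for ib in hits:
            rb = chains_b[owner_b[ib]]
            if ra.key == rb.key:
                continue
            if rule == "vdw":
                limit = radii_a[ia] + radii_b[ib] + VDW_SLACK
                if np.linalg.norm(coords_a[ia] - coords_b[ib]) > limit:
                    continue
            pairs.add(tuple(sorted((ra.key, rb.key))))
    return ContactSet(pairs=frozenset(pairs), cutoff_rule=rule_text)


@dataclass(frozen=True)
class PositionSet:
    """A named set of 0-based alignment columns."""

    name: str
    columns: frozenset[int]


def column_map_from_aligned_row(
    aligned_row: str,
    residue_numbers: Sequence[int],
    structure_sequence: str | None = None,
) -> dict[int, int]:
    """Map author residue numbers to alignment columns via the ungapped row.

    The i-th non-gap character of *aligned_row* corresponds to
    ``residue_numbers[i]``.  When *structure_sequence* (one-letter) is given
    it must match the ungapped row exactly; a mismatch raises
    :class:`MappingMismatchError` rather than guessing a register.
    """
    ungapped_cols = [j for j, ch in enumerate(aligned_row) if ch != GAP]
    if len(residue_numbers) != len(ungapped_cols):
        raise MappingMismatchError(
            f"{len(residue_numbers)} residue numbers for "
            f"{len(ungapped_cols)} non-gap columns"
        )
    if structure_sequence is not None:
        ungapped = aligned_row.replace(GAP, "")
        if structure_sequence.upper() != ungapped:
            raise MappingMismatchError(
                "structure sequence does not match the ungapped aligned row"
            )
    return dict(zip(residue_numbers, ungapped_cols))


def map_contacts_to_columns(
    contacts: ContactSet,
    seq_to_column: Mapping[int, int],
    chain: str | None = None,
    name: str = "interface",
) -> PositionSet:
    """Columns of the residues participating in at least one contact.

    *seq_to_column* maps author residue numbers of the molecule of interest
    (optionally restricted to *chain*) to 0-based columns; residues absent
    from the mapping are logged and skipped, never fatal.
    """
    columns: set[int] = set()
    for ch, resnum in contacts.residues():
        if chain is not None and ch != chain:
            continue
        if resnum in seq_to_column:
            columns.add(seq_to_column[resnum])
        else:
            logger.warning("residue %s/%d not in the column mapping", ch, resnum)
    return PositionSet(name=name, columns=frozenset(columns))


def hypergeometric_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    *N* columns total, *K* of them in the interface, *n* signature columns
    drawn, *k* of those in the interface.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ParameterError(
            f"inconsistent hypergeometric parameters N={N} K={K} n={n} k={k}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))
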