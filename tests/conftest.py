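"""Shared fixtures: toy alignments, a tiny synthetic structure, matrices."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pytest
from hypothesis import settings

from tbpsig import LobeAlignment, LobeSequence, blosum62

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_alignment(rows, superkingdom="eukaryote", lobe="single"):
    """Build a LobeAlignment from aligned strings (metadata optional per row).

    Each row is either a residue string or a (residues, organism,
    superkingdom, lobe) tuple.
    """
    seqs = []
    for i, row in enumerate(rows):
        if isinstance(row, str):
            row = (row, f"org{i}", superkingdom, lobe)
        residues, organism, sk, lb = row
        seqs.append(
            LobeSequence(
                seq_id=f"seq{i}", organism=organism, superkingdom=sk,
                lobe=lb, residues=residues,
            )
        )
    return LobeAlignment(tuple(seqs))


@pytest.fixture(scope="session")
def matrix():
    return blosum62()


@pytest.fixture
def toy_fasta(tmp_path: Path) -> Path:
    path = tmp_path / "toy.fasta"
    path.write_text(
        textwrap.dedent(
            """\
            >P20226|Homo_sapiens|eukaryote|C
            MKDFEWACD
            >Q12345|Pyrococcus_sp|archaea|N
            MKEFEW-CD
            >X99999|Escherichia_coli|bacteria|single
            MRDFEWACE
            """
        )
    )
    return path


def _pdb_atom(serial, name, altloc, resname, chain, resnum, x, y, z, occ, element):
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc:1s}{resname:>3s} {chain:1s}"
        f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


# A minimal two-chain structure: chain A = four "residues" at known positions,
# chain B = one residue, plus a water, a hydrogen and an altloc pair that must
# be reduced to the higher-occupancy conformer.  Distances to B/10 at
# (0,0,2.5): A/1 -> 2.5, A/2 -> 12.8, A/3 -> 3.91, A/4 (occ 0.7 conformer
# at (0,4,0)) -> 4.72 (the occ 0.3 conformer would be 47.5 away).
def synthetic_pdb_text() -> str:
    lines = [
        _pdb_atom(1, "CA", " ", "ALA", "A", 1, 0.0, 0.0, 0.0, 1.0, "C"),
        _pdb_atom(2, "CA", " ", "GLY", "A", 2, 10.0, 0.0, 8.0, 1.0, "C"),
        _pdb_atom(3, "CA", " ", "SER", "A", 3, 0.0, 3.0, 0.0, 1.0, "C"),
        _pdb_atom(4, "CB", "A", "LEU", "A", 4, 0.0, 0.0, 50.0, 0.3, "C"),
        _pdb_atom(5, "CB", "B", "LEU", "A", 4, 0.0, 4.0, 0.0, 0.7, "C"),
        _pdb_atom(6, "H", " ", "ALA", "A", 1, 0.0, 0.0, 0.5, 1.0, "H"),
        _pdb_atom(7, "CA", " ", "PHE", "B", 10, 0.0, 0.0, 2.5, 1.0, "C"),
        _pdb_atom(8, "O", " ", "HOH", "B", 100, 0.0, 0.0, 1.0, 1.0, "O"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def synthetic_pdb(tmp_path: Path) -> Path:
    """Synthetic coordinate fixture (hand-placed atoms, not a real structure)."""
    path = tmp_path / "synthetic.pdb"
    path.write_text(synthetic_pdb_text())
    return path
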