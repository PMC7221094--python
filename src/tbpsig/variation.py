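"""Region-wise mutation densities and the cancer-vs-natural enrichment ratio.

For a named protein region, the mutation density (MD) is the number of
missense variants falling in the region divided by the region's length in
residues.  The mutational density-enrichment ratio compares the two variant
sources:

    MDR = log2( MD_cancer / MD_natural )

Variants are counted with allele multiplicity by default (each reported
record counts, even at a repeated position); unique-site counting is
available as an option.  When either missense count is zero, 0.5 is added to
both counts (Haldane–Anscombe style) before the densities are formed, and
the result is flagged.  Indels and frameshifts are tallied per region for
reporting but never enter MD/MDR, which are missense-only by definition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParameterError, RowError, SchemaError, UndefinedMDRError

logger = logging.getLogger(__name__)

CONSEQUENCES = ("missense", "indel", "frameshift", "other")
SOURCES = ("natural", "cancer")


@dataclass(frozen=True)
class VariantRecord:
    protein: str
    position: int  # 1-based residue index
    consequence: str
    source: str

    def __post_init__(self):
        if self.position < 1:
            raise ParameterError(f"position must be >= 1, got {self.position}")
        if self.consequence not in CONSEQUENCES:
            raise ParameterError(f"unknown consequence {self.consequence!r}")
        if self.source not in SOURCES:
            raise ParameterError(f"unknown source {self.source!r}")


@dataclass(frozen=True)
class Region:
    """A named 1-based inclusive residue interval."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ParameterError(
                f"region {self.name!r}: need 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def load_variants(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV with columns protein, position, consequence, source.

    Unknown consequences are mapped to ``other`` with a warning; a
    non-integer position raises :class:`RowError` with its line number, a
    missing column raises :class:`SchemaError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein", "position", "consequence", "source"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            position = int(str(row.position))
        except ValueError:
            raise RowError(f"non-integer position {row.position!r}", line=line)
        consequence = str(row.consequence)
        if consequence not in CONSEQUENCES:
            logger.warning(
                "line %d: consequence %r mapped to 'other'", line, consequence
            )
            consequence = "other"
        source = str(row.source)
        if source not in SOURCES:
            raise RowError(f"unknown source {source!r}", line=line)
        records.append(
            VariantRecord(
                protein=str(row.protein),
                position=position,
                consequence=consequence,
                source=source,
            )
        )
    return records


def load_regions(path: str | Path) -> list[Region]:
    """Read a region TSV with columns name, start, end."""
    df = pd.read_csv(path, sep="\t")
    missing = {"name", "start", "end"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        Region(name=str(r.name), start=int(r.start), end=int(r.end))
        for r in df.itertuples(index=False)
    ]


def _count(
    records: Iterable[VariantRecord],
    region: Region,
    source: str,
    consequence: str,
    unique_sites: bool,
) -> int:
    hits = [
        r.position
        for r in records
        if r.source == source
        and r.consequence == consequence
        and region.contains(r.position)
    ]
    return len(set(hits)) if unique_sites else len(hits)


def mutation_density(
    records: Sequence[VariantRecord],
    region: Region,
    source: str,
    consequence: str = "missense",
    unique_sites: bool = False,
    protein_length: int | None = None,
) -> float:
    """Matching-variant count divided by the region length in residues."""
    if source not in SOURCES:
        raise ParameterError(f"unknown source {source!r}")
    if protein_length is not None and region.end > protein_length:
        logger.warning(
            "region %s (%d..%d) extends beyond protein length %d",
            region.name, region.start, region.end, protein_length,
        )
    return _count(records, region, source, consequence, unique_sites) / region.length


def mdr(
    records: Sequence[VariantRecord],
    region: Region,
    unique_sites: bool = False,
) -> tuple[float, bool]:
    """log2 cancer-to-natural missense-density ratio for a region.

    Returns ``(value, pseudocount_flag)``; the flag marks that a zero count
    forced the symmetric 0.5 pseudocount.  Raises
    :class:`UndefinedMDRError` when the input contains no record of either
    source at all.
    """
    has_natural = any(r.source == "natural" for r in records)
    has_cancer = any(r.source == "cancer" for r in records)
    if not has_natural and not has_cancer:
        raise UndefinedMDRError("no natural and no cancer records in the input")
    n_cancer = _count(records, region, "cancer", "missense", unique_sites)
    n_natural = _count(records, region, "natural", "missense", unique_sites)
    pseudo = n_cancer == 0 or n_natural == 0
    if pseudo:
        n_cancer += 0.5
        n_natural += 0.5
    md_cancer = n_cancer / region.length
    md_natural = n_natural / region.length
    return math.log2(md_cancer / md_natural), pseudo


def density_report(
    records: Sequence[VariantRecord],
    regions: Sequence[Region],
    unique_sites: bool = False,
) -> pd.DataFrame:
    """Per-region MD (both sources), MDR and auxiliary indel/frameshift counts."""
    rows = []
    for region in regions:
        value, pseudo = mdr(records, region, unique_sites=unique_sites)
        rows.append(
            {
                "region": region.name,
                "start": region.start,
                "end": region.end,
                "length": region.length,
                "md_natural": mutation_density(
                    records, region, "natural", unique_sites=unique_sites
                ),
                "md_cancer": mutation_density(
                    records, region, "cancer", unique_sites=unique_sites
                ),
                "mdr": value,
                "pseudocount_flag": pseudo,
                "n_indel_natural": _count(records, region, "natural", "indel", unique_sites),
                "n_indel_cancer": _count(records, region, "cancer", "indel", unique_sites),
                "n_frameshift_natural": _count(records, region, "natural", "frameshift", unique_sites),
                "n_frameshift_cancer": _count(records, region, "cancer", "frameshift", unique_sites),
            }
        )
    return pd.DataFrame(rows)
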