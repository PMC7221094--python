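"""Common TBP Numbering (CTN).

The CTN scheme names every alignment column with a three-field label
``lobe.element.index``: the lobe (N or C; omitted for single-lobe contexts),
the consensus secondary-structure element (strands S1–S5, helices H1–H2,
loops L1–L6) and the 1-based position within that element.  ``C.L3.2`` is the
second position of loop 3 in the C-terminal lobe.

The map between columns and labels is built from an ordered
secondary-structure template — a list of ``(element, length)`` runs covering
the alignment left to right.  A run whose element is ``-`` is a spacer:
its columns consume alignment width but carry no label (the scheme does not
define how columns outside consensus elements are numbered, so the map leaves
them unassigned and reports them).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import GrammarError, TemplateOverflowError
from .msa import LobeAlignment

ELEMENTS = tuple(
    [f"S{i}" for i in range(1, 6)]
    + [f"H{i}" for i in range(1, 3)]
    + [f"L{i}" for i in range(1, 7)]
)
_ELEMENT_SET = frozenset(ELEMENTS)
SPACER = "-"

_LABEL_RE = re.compile(
    r"^(?:(?P<lobe>[NC])\.)?(?P<element>[SHL]\d+)\.(?P<index>\d+)$"
)


@dataclass(frozen=True, order=True)
class CTNLabel:
    """A single CTN position label."""

    lobe_field: str  # 'N', 'C', or 'none'
    element: str
    index: int  # 1-based within the element

    def __post_init__(self):
        if self.lobe_field not in {"N", "C", "none"}:
            raise GrammarError(f"invalid lobe field {self.lobe_field!r}")
        if self.element not in _ELEMENT_SET:
            raise GrammarError(f"unknown secondary-structure element {self.element!r}")
        if self.index < 1:
            raise GrammarError(f"CTN index must be >= 1, got {self.index}")

    def __str__(self) -> str:
        return format_ctn(self)


def format_ctn(label: CTNLabel) -> str:
    """Dotted text form, e.g. ``C.L3.2`` (``L3.2`` when lobe_field is none)."""
    if label.lobe_field == "none":
        return f"{label.element}.{label.index}"
    return f"{label.lobe_field}.{label.element}.{label.index}"


def parse_ctn(label_text: str) -> CTNLabel:
    """Parse dotted text into a :class:`CTNLabel`; inverse of :func:`format_ctn`."""
    m = _LABEL_RE.match(label_text.strip())
    if not m:
        raise GrammarError(f"cannot parse CTN label {label_text!r}")
    return CTNLabel(
        lobe_field=m.group("lobe") or "none",
        element=m.group("element"),
        index=int(m.group("index")),
    )


@dataclass(frozen=True)
class CTNMap:
    """Injective mapping from 0-based alignment columns to CTN labels."""

    assignments: dict[int, CTNLabel]
    sse_template: tuple[tuple[str, int], ...]
    lobe_field: str
    n_columns: int

    def __post_init__(self):
        labels = list(self.assignments.values())
        if len(set(labels)) != len(labels):
            raise GrammarError("CTN assignments are not injective")

    @property
    def unassigned_columns(self) -> tuple[int, ...]:
        return tuple(
            j for j in range(self.n_columns) if j not in self.assignments
        )

    def label(self, column: int) -> CTNLabel | None:
        return self.assignments.get(column)

    def label_text(self, column: int) -> str:
        """Dotted label, or the 1-based column as ``col<k>`` when unassigned."""
        lab = self.assignments.get(column)
        return format_ctn(lab) if lab is not None else f"col{column + 1}"

    def column_of(self, label: CTNLabel | str) -> int:
        if isinstance(label, str):
            label = parse_ctn(label)
        for col, lab in self.assignments.items():
            if lab == label:
                return col
        raise KeyError(f"label {format_ctn(label)} not assigned in this map")


def _validate_template(sse_template: Sequence[tuple[str, int]]) -> None:
    named = [e for e, _ in sse_template if e != SPACER]
    unknown = set(named) - _ELEMENT_SET
    if unknown:
        raise GrammarError(f"unknown template element(s) {sorted(unknown)}")
    if len(set(named)) != len(named):
        raise GrammarError("template elements must be unique")
    if any(length < 1 for _, length in sse_template):
        raise GrammarError("template lengths must be >= 1")


def build_ctn_map(
    aln: LobeAlignment | int,
    sse_template: Sequence[tuple[str, int]],
    lobe_field: str = "none",
) -> CTNMap:
    """Assign CTN labels to alignment columns, left to right in template order.

    *aln* may be an alignment or just its column count.  Columns beyond the
    template, and columns under a ``-`` spacer run, remain unassigned.
    Raises :class:`TemplateOverflowError` when the template is longer than the
    alignment.
    """
    n_columns = aln if isinstance(aln, int) else aln.n_columns
    _validate_template(sse_template)
    total = sum(length for _, length in sse_template)
    if total > n_columns:
        raise TemplateOverflowError(
            f"template covers {total} columns but alignment has {n_columns}"
        )
    assignments: dict[int, CTNLabel] = {}
    col = 0
    for element, length in sse_template:
        for idx in range(1, length + 1):
            if element != SPACER:
                assignments[col] = CTNLabel(lobe_field, element, idx)
            col += 1
    return CTNMap(
        assignments=assignments,
        sse_template=tuple((e, int(l)) for e, l in sse_template),
        lobe_field=lobe_field,
        n_columns=n_columns,
    )


def read_sse_template(path: str | Path) -> tuple[tuple[str, int], ...]:
    """Read a two-column TSV template: element, length (in order; '#' comments)."""
    rows: list[tuple[str, int]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if len(row) < 2:
                raise GrammarError(f"template row needs 2 fields, got {row!r}")
            rows.append((row[0].strip(), int(row[1])))
    template = tuple(rows)
    _validate_template(template)
    return template
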