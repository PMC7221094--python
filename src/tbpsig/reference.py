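"""Reproduction of the reference-alignment analysis, when the data is present.

The reference multiple sequence alignment (RefMSA) of TBP-lobe sequences and
the paired viral TBP/TFIIB alignments are distributed as supplementary data
of the original resource and are not bundled here.  When a user places them
under a data directory, :func:`reference_reproduction` re-runs the census,
signature detection, L5.1 conservation and the viral coevolution statistic
on them.

Expected layout (file names configurable through ``reference.yaml`` in the
same directory):

    refmsa.fasta          aligned FASTA, headers ``id|organism|superkingdom|lobe``
    sse_template.tsv      CTN secondary-structure template (element, length)
    viral_tbp.fasta       viral TBP-like alignment (organism-matched headers)
    viral_tfiib.fasta     viral TFIIB-like alignment
    reference.yaml        optional: {tbp_target_column: <1-based>,
                          tfiib_partner_column: <1-based>, ...}
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .coevolution import pair_alignments, pearson_pc, substitution_vector
from .conservation import (
    ancestral_set_by_superkingdom,
    conservation_fraction,
    lobe_specific_signatures,
    universal_signatures,
)
from .ctn import build_ctn_map, parse_ctn, read_sse_template
from .errors import EmptyInputError, EmptySelectionError
from .msa import read_lobe_alignment

DEFAULT_FILES = {
    "refmsa": "refmsa.fasta",
    "sse_template": "sse_template.tsv",
    "viral_tbp": "viral_tbp.fasta",
    "viral_tfiib": "viral_tfiib.fasta",
}


def reference_reproduction(data_dir: str | Path) -> dict[str, Any]:
    """Recompute the reference analysis' headline quantities from local data.

    Returns a dict with the lobe-sequence census, alignment width, universal
    and lobe-specific signature counts, the L5.1 Phe conservation fraction in
    cellular and viral contexts, and (when the viral pair alignments are
    present) the TBP-TFIIB coevolution PC at the configured column pair.
    Raises :class:`EmptyInputError` when the alignment file is absent.
    """
    data_dir = Path(data_dir)
    cfg: dict[str, Any] = dict(DEFAULT_FILES)
    cfg_path = data_dir / "reference.yaml"
    if cfg_path.exists():
        cfg.update(yaml.safe_load(cfg_path.read_text()) or {})

    refmsa_path = data_dir / cfg["refmsa"]
    if not refmsa_path.exists():
        raise EmptyInputError(
            f"reference alignment not found at {refmsa_path}; place the "
            "supplementary RefMSA files under this directory to reproduce "
            "the reference analysis"
        )
    aln = read_lobe_alignment(refmsa_path)
    viral = [s for s in aln if s.superkingdom == "virus"]
    out: dict[str, Any] = {
        "n_lobe_sequences": len(aln),
        "n_viral_lobe_sequences": len(viral),
        "n_viruses": len({s.organism for s in viral}),
        "n_columns": aln.n_columns,
    }

    cellular = aln.subset(superkingdoms={"archaea", "bacteria", "eukaryote"})
    ancestors = ancestral_set_by_superkingdom(cellular)
    universal = universal_signatures(ancestors)
    out["n_universal"] = len(universal.universal)

    lobes_present = {s.lobe for s in cellular}
    if {"C", "N"} <= lobes_present:
        sigs = lobe_specific_signatures(
            cellular.subset(lobes={"C"}), cellular.subset(lobes={"N"})
        )
        out["n_lobe_specific_C"] = len(sigs.lobe_columns("C"))
        out["n_lobe_specific_N"] = len(sigs.lobe_columns("N"))
        out["n_signatures_total"] = (
            out["n_universal"] + out["n_lobe_specific_C"] + out["n_lobe_specific_N"]
        )

    template_path = data_dir / cfg["sse_template"]
    if template_path.exists():
        ctn = build_ctn_map(aln.n_columns, read_sse_template(template_path))
        l5_col = ctn.column_of(parse_ctn(str(cfg.get("l5_label", "L5.1"))))
        out["l5_phe_fraction_cellular"] = conservation_fraction(
            cellular.column(l5_col), "F"
        )
        try:
            viral_sub = aln.subset(superkingdoms={"virus"})
            out["l5_phe_fraction_viral"] = conservation_fraction(
                viral_sub.column(l5_col), "F"
            )
        except EmptySelectionError:
            pass

    tbp_path = data_dir / cfg["viral_tbp"]
    tfiib_path = data_dir / cfg["viral_tfiib"]
    if tbp_path.exists() and tfiib_path.exists():
        pa = pair_alignments(
            read_lobe_alignment(tbp_path), read_lobe_alignment(tfiib_path)
        )
        target = int(cfg.get("tbp_target_column", 1)) - 1
        partner = int(cfg.get("tfiib_partner_column", 1)) - 1
        out["viral_coevolution_pc"] = pearson_pc(
            substitution_vector(pa.column_a(target)),
            substitution_vector(pa.column_b(partner)),
        )
    return out
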