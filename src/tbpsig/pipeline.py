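"""Config-driven orchestration with manifests and deterministic reports.

A run is described by a YAML (or dict) config naming the inputs, the
spatio-temporal context (which superkingdoms and lobes each stage looks at),
the matrix and thresholds, and a seed for stochastic stages.  Every stage
writes TSV tables, JSON scalars and a ``manifest.json`` that echoes every
parameter in force — defaulted or not — so two runs are comparable.  On any
stage error, partial outputs are removed and the error is re-raised with the
stage name.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .coevolution import bh_adjust, coevolution_scan, pair_alignments
from .conservation import (
    ancestral_set_by_superkingdom,
    lobe_specific_signatures,
    profile_stats,
    universal_signatures,
)
from .ctn import CTNMap, build_ctn_map, read_sse_template
from .errors import ConfigError, TbpsigError
from .matrices import load_matrix
from .msa import read_lobe_alignment
from .variation import density_report, load_regions, load_variants

logger = logging.getLogger(__name__)


def load_config(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, dict):
            raise ConfigError(f"{config}: config must be a mapping")
        return loaded
    return dict(config)


def _require_paths(cfg: Mapping[str, Any], keys: list[str], stage: str) -> None:
    for key in keys:
        value = cfg.get(key)
        if value is None:
            raise ConfigError(f"{stage}: config key {key!r} is required")
        if not Path(value).exists():
            raise ConfigError(f"{stage}: input path does not exist: {value}")


class _Stage:
    """Tracks written outputs so a failed stage leaves no partial files."""

    def __init__(self, name: str, out_dir: str | Path):
        self.name = name
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.written: list[Path] = []

    def path(self, filename: str) -> Path:
        p = self.out_dir / filename
        self.written.append(p)
        return p

    def cleanup(self) -> None:
        for p in self.written:
            p.unlink(missing_ok=True)

    def manifest(self, inputs: dict, parameters: dict) -> None:
        payload = {
            "stage": self.name,
            "tbpsig_version": __version__,
            "inputs": inputs,
            "parameters": parameters,
            "outputs": [p.name for p in self.written],
        }
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _ctn_map_from_config(cfg: Mapping[str, Any], n_columns: int) -> CTNMap | None:
    template_path = cfg.get("sse_template")
    if template_path is None:
        return None
    template = read_sse_template(template_path)
    return build_ctn_map(n_columns, template, cfg.get("lobe_field", "none"))


def run_signatures(
    config: str | Path | Mapping[str, Any], out_dir: str | Path
) -> dict[str, Any]:
    """Subset -> profile -> ancestral -> universal -> lobe-specific signatures.

    Config keys: ``alignment`` (aligned FASTA, required); ``superkingdoms`` /
    ``lobes`` context filters; ``ancestral_superkingdoms`` (default archaea,
    bacteria, eukaryote); ``matrix`` (default BLOSUM62); ``ratio`` (default
    1.5); optional ``sse_template`` + ``lobe_field`` for CTN labels.
    """
    cfg = load_config(config)
    _require_paths(cfg, ["alignment"], "signatures")
    if cfg.get("sse_template") and not Path(cfg["sse_template"]).exists():
        raise ConfigError(f"signatures: missing sse_template {cfg['sse_template']}")

    stage = _Stage("signatures", out_dir)
    parameters = {
        "matrix": cfg.get("matrix", "BLOSUM62"),
        "superkingdoms": sorted(cfg.get("superkingdoms", [])) or "all",
        "lobes": sorted(cfg.get("lobes", [])) or "all",
        "ancestral_superkingdoms": list(
            cfg.get("ancestral_superkingdoms", ["archaea", "bacteria", "eukaryote"])
        ),
        "ancestral_method": cfg.get("ancestral_method", "consensus"),
        "ratio": float(cfg.get("ratio", 1.5)),
        "sd_mode": cfg.get("sd_mode", "population"),
        "lobe_field": cfg.get("lobe_field", "none"),
    }
    try:
        matrix = load_matrix(parameters["matrix"])
        aln = read_lobe_alignment(cfg["alignment"])
        if cfg.get("superkingdoms") or cfg.get("lobes"):
            aln = aln.subset(
                superkingdoms=cfg.get("superkingdoms") or None,
                lobes=cfg.get("lobes") or None,
            )
        ctn = _ctn_map_from_config(cfg, aln.n_columns)
        label = (lambda j: ctn.label_text(j)) if ctn else (lambda j: f"col{j + 1}")

        profile = profile_stats(aln, matrix, sd_mode=parameters["sd_mode"])
        prof_df = pd.DataFrame(
            {
                "ctn_label": [label(j) for j in range(profile.n_columns)],
                "column_index_1based": range(1, profile.n_columns + 1),
                "nbs": profile.per_column,
            }
        )
        prof_df.to_csv(stage.path("profile.tsv"), sep="\t", index=False)

        ancestors = ancestral_set_by_superkingdom(
            aln,
            superkingdoms=parameters["ancestral_superkingdoms"],
            method=parameters["ancestral_method"],
        )
        anc_df = pd.DataFrame(
            sorted(ancestors.sequences.items()), columns=["superkingdom", "sequence"]
        )
        anc_df.to_csv(stage.path("ancestral.tsv"), sep="\t", index=False)

        universal = universal_signatures(ancestors, matrix)
        anc_profile = profile_stats(ancestors.as_alignment(), matrix)

        rows = [
            {
                "ctn_label": label(j),
                "column_index_1based": j + 1,
                "context": "universal",
                "nbs": anc_profile.per_column[j],
                "lobe_mean": anc_profile.mean_nbs,
                "lobe_sd": anc_profile.sd_nbs,
                "rule_tag": "universal",
            }
            for j in sorted(universal.universal)
        ]

        lobes_present = {s.lobe for s in aln}
        if {"C", "N"} <= lobes_present:
            c_aln = aln.subset(lobes={"C"})
            n_aln = aln.subset(lobes={"N"})
            lobe_sigs = lobe_specific_signatures(
                c_aln, n_aln, matrix, ratio=parameters["ratio"]
            )
            lobe_prof = {"C": profile_stats(c_aln, matrix), "N": profile_stats(n_aln, matrix)}
            rows += [
                {
                    "ctn_label": label(s.column),
                    "column_index_1based": s.column + 1,
                    "context": f"lobe:{s.lobe}",
                    "nbs": s.nbs,
                    "lobe_mean": lobe_prof[s.lobe].mean_nbs,
                    "lobe_sd": lobe_prof[s.lobe].sd_nbs,
                    "rule_tag": s.rule_tag,
                }
                for s in sorted(
                    lobe_sigs.lobe_specific, key=lambda s: (s.lobe, s.column)
                )
            ]
        sig_df = pd.DataFrame(
            rows,
            columns=[
                "ctn_label", "column_index_1based", "context",
                "nbs", "lobe_mean", "lobe_sd", "rule_tag",
            ],
        )
        sig_df.to_csv(stage.path("signatures.tsv"), sep="\t", index=False)

        summary = {
            "n_sequences": len(aln),
            "n_columns": aln.n_columns,
            "mean_nbs": profile.mean_nbs,
            "sd_nbs": profile.sd_nbs,
            "n_scorable": profile.n_scorable,
            "n_universal": len(universal.universal),
            "n_lobe_specific": int((sig_df["context"] != "universal").sum()),
        }
        with open(stage.path("summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        stage.manifest({"alignment": str(cfg["alignment"])}, parameters)
        return summary
    except TbpsigError as exc:
        stage.cleanup()
        raise type(exc)(f"[signatures] {exc}") from exc


def run_coevolution(
    config: str | Path | Mapping[str, Any], out_dir: str | Path
) -> pd.DataFrame:
    """Organism pairing -> scan -> permutation p-values, with manifest.

    Config keys: ``family_a``/``family_b`` (aligned FASTA); ``target_column``
    (1-based in family A) or ``target_ctn`` with ``sse_template``; ``n_perm``
    (default 1000); ``seed`` (required); ``bh`` (default false).
    """
    cfg = load_config(config)
    _require_paths(cfg, ["family_a", "family_b"], "coevolution")
    if "seed" not in cfg:
        raise ConfigError("coevolution: 'seed' is mandatory for stochastic stages")
    n_perm = int(cfg.get("n_perm", 1000))
    if n_perm < 1:
        raise ConfigError(f"coevolution: n_perm must be >= 1, got {n_perm}")

    stage = _Stage("coevolution", out_dir)
    parameters = {
        "matrix": cfg.get("matrix", "BLOSUM62"),
        "n_perm": n_perm,
        "seed": int(cfg["seed"]),
        "bh": bool(cfg.get("bh", False)),
    }
    try:
        matrix = load_matrix(parameters["matrix"])
        fam_a = read_lobe_alignment(cfg["family_a"])
        fam_b = read_lobe_alignment(cfg["family_b"])
        pa = pair_alignments(fam_a, fam_b)
        ctn = _ctn_map_from_config(cfg, fam_b.n_columns)
        label = (lambda j: ctn.label_text(j)) if ctn else (lambda j: f"col{j + 1}")
        if "target_ctn" in cfg:
            if ctn is None:
                raise ConfigError("coevolution: target_ctn needs an sse_template")
            target = ctn.column_of(cfg["target_ctn"])
        else:
            target = int(cfg.get("target_column", 1)) - 1
        parameters["target_column_1based"] = target + 1

        results = coevolution_scan(
            pa, target, matrix, n_perm=n_perm, seed=parameters["seed"]
        )
        rows = []
        for j, res in enumerate(results):
            rows.append(
                {
                    "ctn_label": label(j),
                    "column_index_1based": j + 1,
                    "pc": res.pc if res else float("nan"),
                    "p_value": res.p_value if res else float("nan"),
                    "p_report": res.format_p() if res else "NA",
                    "n_perm": n_perm,
                    "n_pairs_used": res.n_pairs_used if res else 0,
                    "seed": res.seed if res else parameters["seed"],
                }
            )
        df = pd.DataFrame(rows)
        if parameters["bh"]:
            defined = df["p_value"].notna()
            q = pd.Series(float("nan"), index=df.index)
            if defined.any():
                q[defined] = bh_adjust(df.loc[defined, "p_value"].to_numpy())
            df["q_value"] = q
        df.to_csv(stage.path("coevolution.tsv"), sep="\t", index=False)
        stage.manifest(
            {"family_a": str(cfg["family_a"]), "family_b": str(cfg["family_b"]),
             "n_pairs": pa.n_pairs},
            parameters,
        )
        return df
    except TbpsigError as exc:
        stage.cleanup()
        raise type(exc)(f"[coevolution] {exc}") from exc


def run_variation(
    config: str | Path | Mapping[str, Any], out_dir: str | Path
) -> pd.DataFrame:
    """Variant table + regions -> per-region MD/MDR report."""
    cfg = load_config(config)
    _require_paths(cfg, ["variants", "regions"], "variation")
    stage = _Stage("variation", out_dir)
    parameters = {"unique_sites": bool(cfg.get("unique_sites", False))}
    try:
        records = load_variants(cfg["variants"])
        regions = load_regions(cfg["regions"])
        df = density_report(records, regions, unique_sites=parameters["unique_sites"])
        df.to_csv(stage.path("variation.tsv"), sep="\t", index=False)
        with open(stage.path("variation.json"), "w") as fh:
            json.dump(
                df.set_index("region")[["md_natural", "md_cancer", "mdr"]]
                .round(6)
                .to_dict(orient="index"),
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
        stage.manifest(
            {"variants": str(cfg["variants"]), "regions": str(cfg["regions"])},
            parameters,
        )
        return df
    except TbpsigError as exc:
        stage.cleanup()
        raise type(exc)(f"[variation] {exc}") from exc
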