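"""Orchestration: scan -> conserve -> crossref (-> structures) in one run.

Mirrors the narrative order of the analysis: annotate k-turns and GAC targets
in the input snoRNAs, measure -1n conservation per ortholog family, map A1n
positions to the genome and intersect with the m6A site table, and optionally
classify base-pair geometry in any supplied structures.  Emits per-stage TSVs
plus a single machine-readable JSON summary; a stage failure is recorded and
its dependents are skipped with provenance, never aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as kio
from .conservation import group_compare, minus1n_conservation
from .modsite_crossref import crossref, map_a1n_to_genome, summarize
from .motif_annotation import (SnoRNASequence, annotate_kturn, best_outer_pair,
                               scan_sequence_set)
from .structure_geometry import classify_structure, read_structure

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta: str | None = None
    alignment_dir: str | None = None
    sites_tsv: str | None = None
    genes_bed: str | None = None
    genes_fasta: str | None = None
    structures: list[str] = field(default_factory=list)
    methylated_families: dict[str, bool] = field(default_factory=dict)
    max_mismatch: int = 0
    internal_max_mismatch: int = 1
    slack: int = 0
    output_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        for p in [self.fasta, self.alignment_dir, self.sites_tsv, self.genes_bed,
                  self.genes_fasta, *self.structures]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _sha1(path: str) -> str:
    return hashlib.sha1(Path(path).read_bytes()).hexdigest()[:12]


def run_all(cfg: RunConfig) -> dict:
    """Execute all configured stages; returns the summary dict (also written
    to <output_dir>/summary.json)."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}, "seed": cfg.seed}

    scan_tab = None
    if cfg.fasta is not None:
        try:
            logger.info("stage=scan input=%s sha1=%s", cfg.fasta, _sha1(cfg.fasta))
            seqs = kio.read_fasta(cfg.fasta)
            scan_tab = scan_sequence_set(seqs, cfg.max_mismatch, cfg.internal_max_mismatch)
            scan_tab.to_csv(out / "scan.tsv", sep="\t", index=False)
            ok = scan_tab[scan_tab["status"].astype(str).str.startswith("ok")]
            summary["stages"]["scan"] = {
                "n_sequences": len(seqs),
                "n_kturns": int(len(ok)),
                "n_gac_targets": int(ok["is_gac"].fillna(False).astype(bool).sum()),
            }
        except Exception as err:  # recorded, not raised: downstream skipped
            summary["stages"]["scan"] = {"error": str(err)}

    if cfg.alignment_dir is not None:
        try:
            reports = []
            for path in sorted(Path(cfg.alignment_dir).iterdir()):
                if path.suffix.lower() not in (".fa", ".fasta", ".afa", ".sto", ".stk"):
                    continue
                logger.info("stage=conserve input=%s sha1=%s", path, _sha1(str(path)))
                aln = kio.read_alignment(path)
                ref_id, ref_gapped = aln.rows[0]
                ref_seq = SnoRNASequence(ref_id, ref_gapped.replace("-", "").replace(".", ""))
                spans = best_outer_pair(ref_seq, cfg.max_mismatch)
                if spans is None:
                    reports.append({"family_id": aln.family_id, "error": "no k-turn in reference"})
                    continue
                ann = annotate_kturn(ref_seq, *spans)
                rep = minus1n_conservation(
                    aln, ann, ref_id,
                    methylated=cfg.methylated_families.get(aln.family_id),
                )
                reports.append({
                    "family_id": rep.family_id, "n_sequences": rep.n_sequences,
                    "minus1n_c_percent": rep.minus1n_c_percent,
                    "methylated": rep.methylated,
                })
            rep_df = pd.DataFrame(reports)
            rep_df.to_csv(out / "conservation.tsv", sep="\t", index=False)
            summary["stages"]["conserve"] = {"n_families": len(reports)}
            if cfg.methylated_families:
                from .conservation import ConservationReport

                good = [ConservationReport(r["family_id"], r["n_sequences"],
                                           r["minus1n_c_percent"], r["methylated"])
                        for r in reports if "error" not in r and r["methylated"] is not None]
                summary["stages"]["conserve"]["group_compare"] = group_compare(good)
        except Exception as err:
            summary["stages"]["conserve"] = {"error": str(err)}

    if cfg.sites_tsv is not None and cfg.genes_bed is not None and cfg.genes_fasta is not None:
        if scan_tab is None and cfg.fasta is not None:
            summary["stages"]["crossref"] = {"skipped": "scan stage failed"}
        else:
            try:
                logger.info("stage=crossref sites=%s sha1=%s", cfg.sites_tsv, _sha1(cfg.sites_tsv))
                genes = kio.read_gene_models(cfg.genes_bed, cfg.genes_fasta)
                sites = kio.read_sites(cfg.sites_tsv)
                targets = []
                for g in genes:
                    gseq = SnoRNASequence(g.gene_name, g.sequence)
                    spans = best_outer_pair(gseq, cfg.max_mismatch)
                    if spans is None:
                        continue
                    ann = annotate_kturn(gseq, *spans)
                    chrom, pos, strand = map_a1n_to_genome(g, ann)
                    targets.append({"gene_name": g.gene_name, "chromosome": chrom,
                                    "position": pos, "strand": strand,
                                    "kturn_position_label": f"{ann.dbox_role} 1n"})
                joined = crossref(pd.DataFrame(
                    targets, columns=["gene_name", "chromosome", "position", "strand",
                                      "kturn_position_label"]), sites, cfg.slack)
                joined.to_csv(out / "crossref.tsv", sep="\t", index=False)
                meth = joined[joined["methylated"]]
                summary["stages"]["crossref"] = {
                    "n_targets": len(targets),
                    "n_methylated": int(joined["methylated"].sum()),
                    "summary": summarize(meth).as_dict() if len(meth) else None,
                }
            except Exception as err:
                summary["stages"]["crossref"] = {"error": str(err)}

    if cfg.structures:
        results = {}
        for spath in cfg.structures:
            try:
                logger.info("stage=structures input=%s sha1=%s", spath, _sha1(spath))
                residues = read_structure(spath)
                pairs = classify_structure(residues)
                results[Path(spath).name] = {
                    "n_residues": len(residues),
                    "classes": sorted(p.class_label for p in pairs if p.paired),
                }
            except Exception as err:
                results[Path(spath).name] = {"error": str(err)}
        summary["stages"]["structures"] = results

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
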