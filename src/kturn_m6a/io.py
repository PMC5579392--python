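"""Readers and writers for the package's external formats.

FASTA and Stockholm go through Biopython; tables through pandas.  Site tables
are accepted either with RMBase-style column names or as 6-column BED
(chrom, start0, end, name, score=support, strand).  Titration series are TSV
with ``# key=value`` header comments carrying the scalar metadata.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding_models import FretTitration, ITCExperiment
from .conservation import MultipleAlignment
from .modsite_crossref import SITE_COLUMNS, GeneModel, ModSite
from .motif_annotation import SnoRNASequence


def read_fasta(path: str | Path) -> list[SnoRNASequence]:
    return [
        SnoRNASequence(rec.id, str(rec.seq), source=str(path))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: list[SnoRNASequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def _alignment_format(path: Path) -> str:
    return "stockholm" if path.suffix.lower() in (".sto", ".stk", ".stockholm") else "fasta"


def read_alignment(path: str | Path, family_id: str | None = None) -> MultipleAlignment:
    path = Path(path)
    aln = AlignIO.read(str(path), _alignment_format(path))
    rows = [(rec.id, str(rec.seq)) for rec in aln]
    return MultipleAlignment(family_id or path.stem, rows)


def write_stockholm(rows: list[tuple[str, str]], path: str | Path, family_id: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        if family_id:
            fh.write(f"#=GF ID {family_id}\n")
        width = max(len(rid) for rid, _ in rows) + 2
        for rid, seq in rows:
            fh.write(f"{rid:<{width}}{seq.replace('-', '.')}\n")
        fh.write("//\n")


def read_sites(path: str | Path) -> list[ModSite]:
    """Site table from TSV (RMBase-style columns) or 6-column BED."""
    path = Path(path)
    head = path.read_text().lstrip().splitlines()[0]
    if "\t" in head and not head.split("\t")[1].isdigit() and "position" in head.lower().replace("_", ""):
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.strip().lower() for c in df.columns]
        rename = {"genename": "gene_name", "modid": "mod_id", "supportnum": "support_num"}
        df = df.rename(columns=rename)
        if "kturn_position_label" not in df:
            df["kturn_position_label"] = ""
        return [ModSite(**{k: row[k] for k in SITE_COLUMNS}) for _, row in df.iterrows()]
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start0", "end", "name", "score", "strand"])
    return [
        ModSite(gene_name=str(r["name"]), mod_id=f"{r['name']}@{r.chrom}:{r.end}",
                chromosome=str(r.chrom), position=int(r["end"]), strand=str(r.strand),
                support_num=int(r.score))
        for _, r in bed.iterrows()
    ]


def read_gene_models(bed_path: str | Path, fasta_path: str | Path) -> list[GeneModel]:
    """Gene models from a BED file plus a FASTA keyed by gene name."""
    seqs = {s.id: s.seq for s in read_fasta(fasta_path)}
    bed = pd.read_csv(bed_path, sep="\t", header=None,
                      names=["chrom", "start0", "end", "name", "score", "strand"])
    genes = []
    for _, r in bed.iterrows():
        name = str(r["name"])
        if name not in seqs:
            raise KeyError(f"gene {name} in BED has no FASTA record")
        genes.append(GeneModel(name, str(r.chrom), int(r.start0) + 1, int(r["end"]),
                               str(r.strand), seqs[name]))
    return genes


def write_gene_models(genes: list[GeneModel], bed_path: str | Path, fasta_path: str | Path) -> None:
    with open(bed_path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_name}\t0\t{g.strand}\n")
    write_fasta([SnoRNASequence(g.gene_name, g.sequence) for g in genes], fasta_path)


def write_sites_tsv(sites: list[ModSite], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in sites])[SITE_COLUMNS].to_csv(path, sep="\t", index=False)


def _read_kv_tsv(path: str | Path) -> tuple[dict, pd.DataFrame]:
    meta, lines = {}, []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = float(v)
        elif line.strip():
            lines.append(line)
    return meta, pd.read_csv(_io.StringIO("\n".join(lines)), sep="\t")


def read_fret_tsv(path: str | Path) -> FretTitration:
    meta, df = _read_kv_tsv(path)
    return FretTitration(df["p_total_molar"].to_numpy(), df["efret"].to_numpy(),
                         meta["r_total_molar"])


def write_fret_tsv(data: FretTitration, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# r_total_molar = {float(data.r_total)!r}\n")
        fh.write("p_total_molar\tefret\n")
        for p, e in zip(data.p_total, data.efret):
            fh.write(f"{float(p)!r}\t{float(e)!r}\n")


def read_itc_tsv(path: str | Path) -> ITCExperiment:
    meta, df = _read_kv_tsv(path)
    return ITCExperiment(
        df["injection_volume_l"].to_numpy(), df["heat_cal"].to_numpy(),
        meta["cell_rna_m"], meta["syringe_protein_m"], meta["cell_volume_l"],
        meta.get("temperature_k", 298.0),
    )


def write_itc_tsv(exp: ITCExperiment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k in ("cell_rna_m", "syringe_protein_m", "cell_volume_l", "temperature_k"):
            fh.write(f"# {k} = {float(getattr(exp, k))!r}\n")
        fh.write("injection_volume_l\theat_cal\n")
        for v, h in zip(exp.injection_volumes_l, exp.heats_cal):
            fh.write(f"{float(v)!r}\t{float(h)!r}\n")
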