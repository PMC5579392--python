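"""Genomic mapping of A1n positions and intersection with m6A site tables.

Site tables follow the RMBase record shape: gene name, modification id,
chromosome, 1-based position, strand, and the number of supporting
experiments.  Coordinates are 1-based inclusive throughout this module; the
conversion from the package's internal 0-based indices happens here, at the
boundary.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass

import pandas as pd

from .motif_annotation import KTurnAnnotation

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["gene_name", "mod_id", "chromosome", "position", "strand",
                "support_num", "kturn_position_label"]


@dataclass(frozen=True)
class GeneModel:
    """Single-exon snoRNA gene: genomic span plus spliced sequence in
    transcript orientation."""

    gene_name: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    sequence: str

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"{self.gene_name}: end < start")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_name}: strand must be + or -")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"{self.gene_name}: sequence length {len(self.sequence)} != span "
                f"{self.end - self.start + 1}"
            )


@dataclass(frozen=True)
class ModSite:
    gene_name: str
    mod_id: str
    chromosome: str
    position: int  # 1-based
    strand: str
    support_num: int
    kturn_position_label: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"{self.mod_id}: position must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"{self.mod_id}: strand must be + or -")
        if self.support_num < 0:
            raise ValueError(f"{self.mod_id}: support_num must be >= 0")


@dataclass(frozen=True)
class CrossrefSummary:
    n_sites: int
    n_unique_positions: int
    n_unique_genes: int
    n_boxD_genes: int
    n_boxDprime_genes: int
    max_support: tuple[str, int] | None

    def as_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "n_unique_positions": self.n_unique_positions,
            "n_unique_genes": self.n_unique_genes,
            "n_boxD_genes": self.n_boxD_genes,
            "n_boxDprime_genes": self.n_boxDprime_genes,
            "max_support": list(self.max_support) if self.max_support else None,
        }


def map_a1n_to_genome(gene: GeneModel, annotation: KTurnAnnotation) -> tuple[str, int, str]:
    """Genomic (chromosome, 1-based position, strand) of the annotated A1n.

    On the plus strand transcript position i (0-based) maps to start + i; on
    the minus strand transcript 5'->3' runs down the genomic coordinate, so it
    maps to end - i.
    """
    idx = annotation.position_map.nonbulged["1n"][1]
    span = gene.end - gene.start + 1
    if not 0 <= idx < span:
        raise ValueError(f"{gene.gene_name}: A1n index {idx} outside span of {span} nt")
    pos = gene.start + idx if gene.strand == "+" else gene.end - idx
    return gene.chromosome, pos, gene.strand


def invert_genomic_position(gene: GeneModel, position: int) -> int:
    """Transcript 0-based index of a genomic position (round trip of
    :func:`map_a1n_to_genome`)."""
    if not gene.start <= position <= gene.end:
        raise ValueError(f"{gene.gene_name}: position {position} outside gene span")
    return position - gene.start if gene.strand == "+" else gene.end - position


def crossref(targets: pd.DataFrame, sites: list[ModSite], slack: int = 0) -> pd.DataFrame:
    """Join mapped A1n targets against an m6A site table.

    ``targets`` needs columns gene_name, chromosome, position, strand (and
    optionally kturn_position_label).  A target matches a site when chromosome
    and strand agree and |position difference| <= slack (default 0: exact,
    single-nucleotide resolution).  Unmatched targets are retained with
    methylated=False; a target matching several sites yields one row per site.
    """
    if slack < 0:
        raise ValueError("slack must be >= 0")
    mod_ids = [s.mod_id for s in sites]
    dupes = {m for m in mod_ids if mod_ids.count(m) > 1}
    if dupes:
        raise ValueError(f"duplicate mod_id: {sorted(dupes)}")

    rows = []
    for tgt in targets.to_dict("records"):
        hits = [
            s for s in sites
            if s.chromosome == tgt["chromosome"]
            and s.strand == tgt["strand"]
            and abs(s.position - tgt["position"]) <= slack
        ]
        if hits:
            for s in sorted(hits, key=lambda s: (abs(s.position - tgt["position"]), s.mod_id)):
                rows.append(tgt | {
                    "methylated": True, "mod_id": s.mod_id,
                    "site_position": s.position, "support_num": s.support_num,
                })
        else:
            rows.append(tgt | {"methylated": False, "mod_id": pd.NA,
                               "site_position": pd.NA, "support_num": pd.NA})
    cols = list(targets.columns) + ["methylated", "mod_id", "site_position", "support_num"]
    return pd.DataFrame(rows, columns=cols)


_PARALOG_RE = re.compile(r"^(.*\d)([A-Z])$")


def collapse_paralog_name(name: str, all_names: set[str]) -> str:
    """Strip a single trailing capital letter when the stem is shared.

    SNORD62A/SNORD62B count as one RNA name family; a trailing letter is
    stripped only when another record carries the same stem (bare or with a
    different letter), so a lone suffixed name is left untouched.
    """
    m = _PARALOG_RE.match(name)
    if not m:
        return name
    stem, letter = m.groups()
    siblings = {n for n in all_names if n != name and (n == stem or
                (_PARALOG_RE.match(n) and _PARALOG_RE.match(n).group(1) == stem))}
    if siblings:
        logger.info("collapsing paralog %s -> %s (shared with %s)", name, stem, sorted(siblings))
        return stem
    return name


def summarize(table: pd.DataFrame) -> CrossrefSummary:
    """Table-level counts: sites, unique positions, unique RNAs and their
    box D / box D' split, and the best-supported gene.

    The table needs columns chromosome, position, strand, gene_name,
    kturn_position_label and support_num (the shape of an RMBase extract or of
    a :func:`crossref` join restricted to methylated rows).
    """
    if table.empty:
        return CrossrefSummary(0, 0, 0, 0, 0, None)
    n_sites = len(table)
    n_pos = table[["chromosome", "position", "strand"]].drop_duplicates().shape[0]

    names = set(table["gene_name"])
    collapsed = {n: collapse_paralog_name(n, names) for n in names}
    gene_of = table["gene_name"].map(collapsed)

    roles = {}
    for gene, label in zip(gene_of, table["kturn_position_label"]):
        role = "boxD'" if "D'" in str(label) else "boxD"
        if roles.setdefault(gene, role) != role:
            raise ValueError(f"conflicting k-turn roles for gene {gene}")
    n_dprime = sum(1 for r in roles.values() if r == "boxD'")

    best = table.sort_values(["support_num", "gene_name"], ascending=[False, True]).iloc[0]
    return CrossrefSummary(
        n_sites=n_sites,
        n_unique_positions=n_pos,
        n_unique_genes=len(roles),
        n_boxD_genes=len(roles) - n_dprime,
        n_boxDprime_genes=n_dprime,
        max_support=(str(best["gene_name"]), int(best["support_num"])),
    )


def load_site_table(species: str = "human") -> pd.DataFrame:
    """The bundled A1n m6A site table (19 human rows, 1 mouse row)."""
    ref = importlib.resources.files("kturn_m6a.data").joinpath("rmbase_m6a_sites.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df = df[df["species"] == species].drop(columns="species").reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no rows for species {species!r}")
    return df


def sites_from_table(df: pd.DataFrame) -> list[ModSite]:
    return [ModSite(**{k: row[k] for k in SITE_COLUMNS}) for _, row in df.iterrows()]
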