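"""Column statistics over snoRNA ortholog alignments.

Covers the logo-style per-column base frequencies, the joint distribution of
two named k-turn positions (e.g. the -1b/-1n pair) across an annotated
sequence set, gap-aware projection of the reference -1n column through an
alignment, and a rank-based comparison of -1n=C conservation between
methylated and unmethylated families.  Gaps are excluded from denominators by
default (logo convention); an inclusive mode is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .motif_annotation import KTurnAnnotation

BASES = ("A", "C", "G", "U")
GAP_CHARS = set("-.")

_VALID_PAIR_LABELS = ("-2b", "-1b", "L1", "L2", "L3", "1b", "2b", "3b",
                      "3n", "2n", "1n", "-1n", "-2n")


@dataclass(frozen=True)
class MultipleAlignment:
    family_id: str
    rows: list[tuple[str, str]]  # (species_or_seq_id, gapped sequence)

    def __post_init__(self):
        if not self.rows:
            raise ValueError(f"{self.family_id}: alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"{self.family_id}: ragged alignment rows {sorted(lengths)}")
        norm = [(rid, s.upper().replace("T", "U")) for rid, s in self.rows]
        for rid, s in norm:
            bad = [(j, ch) for j, ch in enumerate(s) if ch not in BASES and ch not in GAP_CHARS]
            if bad:
                j, ch = bad[0]
                raise ValueError(f"{self.family_id}: invalid character {ch!r} in row {rid} column {j + 1}")
        object.__setattr__(self, "rows", norm)

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1])

    def row(self, row_id: str) -> str:
        for rid, s in self.rows:
            if rid == row_id:
                return s
        raise KeyError(f"{self.family_id}: no row {row_id!r}")


@dataclass(frozen=True)
class ColumnFrequencies:
    counts: pd.DataFrame  # index = column (0-based), columns = A,C,G,U
    fractions: pd.DataFrame
    effective_n: np.ndarray  # non-gap count per column


@dataclass(frozen=True)
class ConservationReport:
    family_id: str
    n_sequences: int
    minus1n_c_percent: float
    methylated: bool | None = None


def column_frequencies(aln: MultipleAlignment, include_gaps: bool = False) -> ColumnFrequencies:
    """Per-column base counts and fractions.

    With ``include_gaps`` the denominator is the row count; otherwise it is the
    number of non-gap characters (effective n).  Columns with effective n = 0
    get fraction 0 for every base.
    """
    mat = np.array([list(s) for _, s in aln.rows])
    counts = pd.DataFrame(
        {b: (mat == b).sum(axis=0) for b in BASES}, index=np.arange(aln.column_count)
    )
    eff_n = counts.sum(axis=1).to_numpy()
    denom = np.full(aln.column_count, len(aln.rows)) if include_gaps else eff_n
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts.div(np.where(denom > 0, denom, 1), axis=0)
    return ColumnFrequencies(counts=counts, fractions=frac, effective_n=eff_n)


def pair_frequencies(
    annotations: list[KTurnAnnotation], posA: str, posB: str
) -> tuple[pd.DataFrame, int]:
    """Joint percent distribution of the bases at two named k-turn positions.

    Returns (table, n_excluded): the table has one row per observed base pair
    (e.g. 'CG' for posA=C, posB=G) with count and percent of the *resolved*
    annotations; annotations missing either position are excluded and counted.
    """
    for p in (posA, posB):
        if p not in _VALID_PAIR_LABELS:
            raise ValueError(f"unknown position label {p!r}; valid: {_VALID_PAIR_LABELS}")
    pairs, excluded = [], 0
    for ann in annotations:
        a = ann.position_map.get(posA)
        b = ann.position_map.get(posB)
        if a is None or b is None:
            excluded += 1
        else:
            pairs.append(a[0] + b[0])
    if not pairs:
        return pd.DataFrame(columns=["pair", "count", "percent"]), excluded
    ser = pd.Series(pairs).value_counts()
    tab = pd.DataFrame(
        {"pair": ser.index, "count": ser.to_numpy(),
         "percent": 100.0 * ser.to_numpy() / len(pairs)}
    ).sort_values(["count", "pair"], ascending=[False, True], ignore_index=True)
    return tab, excluded


def reference_index_to_column(aln: MultipleAlignment, row_id: str, seq_index: int) -> int:
    """Alignment column holding the reference row's ``seq_index``-th residue
    (both 0-based)."""
    gapped = aln.row(row_id)
    k = -1
    for col, ch in enumerate(gapped):
        if ch not in GAP_CHARS:
            k += 1
            if k == seq_index:
                return col
    raise ValueError(f"{aln.family_id}: row {row_id} has fewer than {seq_index + 1} residues")


def minus1n_conservation(
    aln: MultipleAlignment,
    anchor: KTurnAnnotation,
    reference_id: str,
    methylated: bool | None = None,
) -> ConservationReport:
    """Percent of rows with C at the column holding the reference -1n.

    The anchor annotation maps -1n to an ungapped index of the reference row;
    that index is projected through the reference row's gaps to an alignment
    column.  Rows with a gap in that column are excluded from the denominator.
    """
    m1n = anchor.position_map.nonbulged.get("-1n")
    if m1n is None:
        raise ValueError(f"{aln.family_id}: anchor annotation has no -1n position")
    col = reference_index_to_column(aln, reference_id, m1n[1])
    column = [s[col] for _, s in aln.rows]
    non_gap = [ch for ch in column if ch not in GAP_CHARS]
    if not non_gap:
        raise ValueError(f"{aln.family_id}: -1n projects to an all-gap column {col + 1}")
    pct = 100.0 * non_gap.count("C") / len(non_gap)
    return ConservationReport(aln.family_id, len(aln.rows), pct, methylated)


def group_compare(reports: list[ConservationReport]) -> dict:
    """Methylated vs unmethylated -1n=C conservation.

    Reports per-group mean/median and a two-sided Mann-Whitney U with normal
    approximation.  The rank test is an addition of this package: the original
    comparison was presented graphically, without a statistic.
    """
    meth = [r.minus1n_c_percent for r in reports if r.methylated]
    unmeth = [r.minus1n_c_percent for r in reports if r.methylated is False]
    out: dict = {
        "note": "Mann-Whitney comparison added by this package; the source analysis was visual only.",
        "methylated": _group_summary(meth),
        "unmethylated": _group_summary(unmeth),
        "U": None,
        "p_two_sided": None,
    }
    if meth and unmeth:
        res = stats.mannwhitneyu(meth, unmeth, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        out["U"] = float(res.statistic)
        out["p_two_sided"] = float(res.pvalue)
    return out


def _group_summary(vals: list[float]) -> dict:
    if not vals:
        return {"n": 0, "mean": None, "median": None}
    return {"n": len(vals), "mean": float(np.mean(vals)), "median": float(np.median(vals))}
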