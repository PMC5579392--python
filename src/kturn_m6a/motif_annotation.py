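"""Box C/D and C'/D' annotation of snoRNA sequences with k-turn position maps.

Box C/D snoRNAs carry two conserved elements, box C (consensus RUGAUGA, R = A/G)
near the 5' end and box D (consensus CUGA) near the 3' end, which fold back on
each other into a kink-turn (k-turn).  Internal copies (box C'/D') sit between
them, usually closing a k-loop.  Positions are numbered outward from the
three-nucleotide bulge: b = bulged strand, n = non-bulged strand, so the core
sheared pairs are G1b.A1n and A2b.G2n, flanked by the canonical (C) helix at
-1b/-1n and the non-canonical (NC) helix at 3b/3n.

Strand assignment: box D's CUGA lies on the *non-bulged* strand contributing
(reading 5'->3') the NC-helix C, 3n=U, 2n=G, 1n=A, with -1n the nucleotide
immediately 3' of box D; box C's RUGAUGA lies on the bulged strand contributing
L2, L3, 1b=G, 2b=A, 3b plus two NC-helix nucleotides.  When -1n is a cytosine,
the non-bulged strand reads GAC across (2n, 1n, -1n): a target for N6-adenine
methyl transferases, whose preferred motif is DRACH (D = A/G/U, R = A/G,
H = A/C/U) with GAC as its most common core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

BOX_C_CONSENSUS = "RUGAUGA"
BOX_D_CONSENSUS = "CUGA"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

#: Watson-Crick plus G.U wobble pairs, used for C-helix / k-loop calls.
WC_WOBBLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

# Named k-turn positions as offsets from the box starts (0-based).
_BULGED_OFFSETS = {"-2b": -3, "-1b": -2, "L1": -1, "L2": 0, "L3": 1, "1b": 2, "2b": 3, "3b": 4}
_NONBULGED_OFFSETS = {"3n": 1, "2n": 2, "1n": 3, "-1n": 4, "-2n": 5}


class AnnotationError(ValueError):
    """Raised when box spans cannot be assembled into a valid k-turn."""

    def __init__(self, message: str, violated_positions: list[str] | None = None):
        super().__init__(message)
        self.violated_positions = violated_positions or []


@dataclass(frozen=True)
class SnoRNASequence:
    """A snoRNA sequence over {A,C,G,U}; T and lowercase are normalized on input."""

    id: str
    seq: str
    source: str = ""

    def __post_init__(self):
        norm = self.seq.upper().replace("T", "U")
        if not norm:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(norm) - set("ACGU")
        if bad:
            raise ValueError(f"{self.id}: non-RNA characters {sorted(bad)}")
        object.__setattr__(self, "seq", norm)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SnoRNASequence":
        return SnoRNASequence(self.id + "_rc", self.seq.translate(_COMPLEMENT)[::-1], self.source)


@dataclass(frozen=True)
class BoxPairCandidate:
    """A (box C-like, box D-like) pairing; for internal elements the C' box lies
    downstream of the D' box."""

    role: str  # "boxCD" or "boxC'D'"
    boxC_span: tuple[int, int]  # half-open, 0-based; the 7-mer RUGAUGA-like box
    boxD_span: tuple[int, int]  # half-open, 0-based; the 4-mer CUGA-like box
    mismatches: int


@dataclass(frozen=True)
class KTurnPositionMap:
    """Map from k-turn position labels to (nucleotide, 0-based index).

    role is 'boxCD', "boxC'D'" or 'kloop'; positions absent from a truncated
    sequence are omitted from the maps.
    """

    role: str
    bulged: dict[str, tuple[str, int]]
    nonbulged: dict[str, tuple[str, int]]
    minus1_pair_is_wc: bool

    def get(self, label: str) -> tuple[str, int] | None:
        return self.bulged.get(label) or self.nonbulged.get(label)

    @property
    def all_positions(self) -> dict[str, tuple[str, int]]:
        return {**self.bulged, **self.nonbulged}


@dataclass(frozen=True)
class KTurnAnnotation:
    sequence_id: str
    position_map: KTurnPositionMap
    boxC_span: tuple[int, int]
    boxD_span: tuple[int, int]
    score: int  # total mismatches to the two box consensi

    @property
    def dbox_role(self) -> str:
        """Which D box hosts the A1n: 'boxD' for the outer C/D k-turn, "boxD'"
        for the internal element."""
        return "boxD" if self.position_map.role == "boxCD" else "boxD'"


@dataclass(frozen=True)
class MethylTarget:
    annotation: KTurnAnnotation
    a1n_index: int
    context5: str  # 5-mer 3n,2n,1n,-1n,-2n read 5'->3' on the non-bulged strand
    core_triplet: str  # 2n,1n,-1n
    is_gac: bool
    is_drach: bool
    truncated: bool = False  # -1n and/or -2n beyond the sequence end


def matches_iupac(seq: str, pattern: str) -> bool:
    """True when seq matches the IUPAC degenerate pattern (equal lengths)."""
    return len(seq) == len(pattern) and all(s in IUPAC[p] for s, p in zip(seq, pattern))


def _mismatches(window: str, consensus: str) -> int:
    return sum(1 for s, p in zip(window, consensus) if s not in IUPAC[p])


def _motif_hits(seq: str, consensus: str, max_mismatch: int) -> list[tuple[int, int]]:
    k = len(consensus)
    return [
        (i, m)
        for i in range(len(seq) - k + 1)
        if (m := _mismatches(seq[i : i + k], consensus)) <= max_mismatch
    ]


def find_boxes(
    seq: SnoRNASequence,
    max_mismatch: int = 0,
    internal_max_mismatch: int = 1,
) -> list[BoxPairCandidate]:
    """Enumerate (box C, box D) pairings and internal (C', D') candidates.

    Outer pairings require the D box to start >= 8 nt after the C box start so
    the NC helix can close.  Internal candidates are sought between the
    outermost C/D pairing, with the D' box upstream of the C' box, using a
    (usually looser) mismatch budget.  Candidates are ordered by total
    mismatches, then leftmost box C, then leftmost box D; internal candidates
    follow the outer ones.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    s = seq.seq
    c_hits = _motif_hits(s, BOX_C_CONSENSUS, max_mismatch)
    d_hits = _motif_hits(s, BOX_D_CONSENSUS, max_mismatch)
    outer = [
        BoxPairCandidate("boxCD", (ci, ci + 7), (di, di + 4), cm + dm)
        for ci, cm in c_hits
        for di, dm in d_hits
        if di >= ci + 8
    ]
    outer.sort(key=lambda c: (c.mismatches, c.boxC_span[0], c.boxD_span[0]))

    internal: list[BoxPairCandidate] = []
    if outer:
        ci, di = _outermost(outer)
        lo, hi = ci + 7, di
        region = s[lo:hi]
        dp_hits = _motif_hits(region, BOX_D_CONSENSUS, internal_max_mismatch)
        cp_hits = _motif_hits(region, BOX_C_CONSENSUS, internal_max_mismatch)
        internal = [
            BoxPairCandidate(
                "boxC'D'", (lo + cj, lo + cj + 7), (lo + dj, lo + dj + 4), cm + dm
            )
            for dj, dm in dp_hits
            for cj, cm in cp_hits
            if cj >= dj + 5
        ]
        internal.sort(key=lambda c: (c.mismatches, c.boxC_span[0], c.boxD_span[0]))
    return outer + internal


def best_outer_pair(
    seq: SnoRNASequence, max_mismatch: int = 0
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Spans of the outermost best-scoring (box C, box D) pairing, or None.

    Among the minimal-mismatch pairings this takes the leftmost box C with
    its rightmost box D, so an internal D' box is never mistaken for the
    terminal box D.
    """
    outer = [c for c in find_boxes(seq, max_mismatch) if c.role == "boxCD"]
    if not outer:
        return None
    ci, di = _outermost(outer)
    return (ci, ci + 7), (di, di + 4)


def _outermost(outer: list[BoxPairCandidate]) -> tuple[int, int]:
    """Start indices of the outermost best-scoring C/D pairing."""
    best = min(c.mismatches for c in outer)
    pool = [c for c in outer if c.mismatches == best]
    ci = min(c.boxC_span[0] for c in pool)
    di = max(c.boxD_span[0] for c in pool if c.boxC_span[0] == ci)
    return ci, di


def annotate_kturn(
    seq: SnoRNASequence,
    boxC_span: tuple[int, int],
    boxD_span: tuple[int, int],
) -> KTurnAnnotation:
    """Build the k-turn position map for one (box C, box D) pairing.

    The 7-mer span is the C-like box on the bulged strand, the 4-mer span the
    D-like box on the non-bulged strand; their order in the sequence decides
    whether this is the outer C/D k-turn or an internal C'/D' element.  Fails
    with :class:`AnnotationError` naming the violated positions when the
    conserved core (1b=G, 2b=A on the bulged strand; 2n=G, 1n=A on the
    non-bulged strand) is not satisfied.
    """
    s = seq.seq
    for span in (boxC_span, boxD_span):
        if not (0 <= span[0] < span[1] <= len(s)):
            raise AnnotationError(f"span {span} outside sequence of length {len(s)}")
    if boxC_span[1] - boxC_span[0] != 7 or boxD_span[1] - boxD_span[0] != 4:
        raise AnnotationError("box C span must be 7 nt and box D span 4 nt")
    if max(boxC_span[0], boxD_span[0]) < min(boxC_span[1], boxD_span[1]):
        raise AnnotationError(f"box spans {boxC_span} and {boxD_span} overlap")

    c0, d0 = boxC_span[0], boxD_span[0]
    internal = c0 > d0  # box D' precedes box C' in the internal element

    bulged = {
        lab: (s[c0 + off], c0 + off)
        for lab, off in _BULGED_OFFSETS.items()
        if 0 <= c0 + off < len(s)
    }
    nonbulged = {
        lab: (s[d0 + off], d0 + off)
        for lab, off in _NONBULGED_OFFSETS.items()
        if 0 <= d0 + off < len(s)
    }

    core_expect = {"1b": "G", "2b": "A", "2n": "G", "1n": "A"}
    violated = [
        lab
        for lab, want in core_expect.items()
        if (bulged.get(lab) or nonbulged.get(lab, (None,)))[0] not in (want, None)
    ]
    if violated:
        raise AnnotationError(
            f"{seq.id}: conserved k-turn core unsatisfiable at {','.join(sorted(violated))}",
            violated_positions=sorted(violated),
        )

    m1b, m1n = bulged.get("-1b"), nonbulged.get("-1n")
    minus1_wc = bool(m1b and m1n and (m1b[0], m1n[0]) in WC_WOBBLE)

    role = "boxCD"
    if internal:
        role = "boxC'D'"
        m2b, m2n = bulged.get("-2b"), nonbulged.get("-2n")
        minus2_wc = bool(m2b and m2n and (m2b[0], m2n[0]) in WC_WOBBLE)
        between = c0 - (d0 + 4)  # nt between the paired strands
        if between <= 8 and not (minus1_wc and minus2_wc):
            role = "kloop"

    pmap = KTurnPositionMap(role=role, bulged=bulged, nonbulged=nonbulged,
                            minus1_pair_is_wc=minus1_wc)
    score = _mismatches(s[c0 : c0 + 7], BOX_C_CONSENSUS) + _mismatches(
        s[d0 : d0 + 4], BOX_D_CONSENSUS
    )
    return KTurnAnnotation(seq.id, pmap, boxC_span, boxD_span, score)


def classify_context(context5: str) -> tuple[bool, bool]:
    """(is_gac, is_drach) for a 5-mer centered on the 1n adenine.

    ``is_drach`` is a plain IUPAC match of DRACH; ``is_gac`` flags a
    methyl-transferase GAC target — the (2n, 1n, -1n) core reads GAC *and*
    the flanks complete a DRACH motif — so every GAC target is a DRACH
    instance by construction.
    """
    is_drach = matches_iupac(context5, "DRACH")
    return (context5[1:4] == "GAC") and is_drach, is_drach


def scan_gac_target(annotation: KTurnAnnotation, seq: SnoRNASequence) -> MethylTarget:
    """Read the (2n, 1n, -1n) triplet and the 5-mer context around A1n.

    ``is_gac`` flags a methyl-transferase GAC target: the core triplet is GAC
    *and* the surrounding 5-mer satisfies DRACH (so every GAC target is also a
    DRACH instance).  The raw triplet is reported separately.
    """
    pmap = annotation.position_map
    a1n = pmap.nonbulged["1n"]
    d0 = annotation.boxD_span[0]
    context5 = seq.seq[d0 + 1 : d0 + 6]
    truncated = len(context5) < 5
    core = context5[1:4]
    is_gac, is_drach = classify_context(context5)
    return MethylTarget(
        annotation=annotation,
        a1n_index=a1n[1],
        context5=context5,
        core_triplet=core,
        is_gac=is_gac,
        is_drach=is_drach,
        truncated=truncated,
    )


_SCAN_COLUMNS = [
    "id", "role", "boxC_start", "boxC_end", "boxD_start", "boxD_end",
    "a1n_pos", "minus1n_base", "context5", "is_gac", "is_drach", "score",
    "kturn_form", "status",
]


def scan_sequence_set(
    seqs: list[SnoRNASequence],
    max_mismatch: int = 0,
    internal_max_mismatch: int = 1,
) -> pd.DataFrame:
    """find_boxes -> annotate_kturn -> scan_gac_target over a sequence set.

    One row per detected k-turn (outer C/D and internal C'/D'), in input order
    with the outer element first.  Per-sequence failures become rows with a
    status message; coordinates in the output are 1-based inclusive.
    """
    ids = [q.id for q in seqs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate sequence ids: {sorted(dupes)}")

    rows = []
    for sq in seqs:
        cands = find_boxes(sq, max_mismatch, internal_max_mismatch)
        outer = [c for c in cands if c.role == "boxCD"]
        if not outer:
            rows.append(_failure_row(sq.id, "no box C/D pairing found"))
            continue
        ci, di = _outermost(outer)
        chosen = [BoxPairCandidate("boxCD", (ci, ci + 7), (di, di + 4), 0)]
        internal = [c for c in cands if c.role == "boxC'D'"]
        if internal:
            chosen.append(internal[0])
        for cand in chosen:
            try:
                ann = annotate_kturn(sq, cand.boxC_span, cand.boxD_span)
                tgt = scan_gac_target(ann, sq)
            except AnnotationError as err:
                rows.append(_failure_row(sq.id, str(err)))
                continue
            m1n = ann.position_map.nonbulged.get("-1n")
            rows.append(
                {
                    "id": sq.id,
                    "role": ann.dbox_role,
                    "boxC_start": ann.boxC_span[0] + 1,
                    "boxC_end": ann.boxC_span[1],
                    "boxD_start": ann.boxD_span[0] + 1,
                    "boxD_end": ann.boxD_span[1],
                    "a1n_pos": tgt.a1n_index + 1,
                    "minus1n_base": m1n[0] if m1n else "",
                    "context5": tgt.context5,
                    "is_gac": tgt.is_gac,
                    "is_drach": tgt.is_drach,
                    "score": ann.score,
                    "kturn_form": ann.position_map.role,
                    "status": "ok" if not tgt.truncated else "ok(truncated context)",
                }
            )
    return pd.DataFrame(rows, columns=_SCAN_COLUMNS)


def _failure_row(seq_id: str, reason: str) -> dict:
    return {col: pd.NA for col in _SCAN_COLUMNS} | {"id": seq_id, "status": reason}
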