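"""Base-pair geometry from 3D coordinates.

Implements the pieces needed to show why N6-methylation of adenine disrupts
sheared (trans sugar-Hoogsteen) G.A pairs but not Watson-Crick pairs:
hydrogen-bond detection from donor/acceptor geometry, Leontis-Westhof
edge/orientation classification, detection of tandem sheared G.A pairs,
idealized N6-methyl placement with a clash check against the partner ribose,
and Kabsch least-squares superposition.

Crystal structures at the relevant resolutions carry no hydrogen positions,
so H-bonds are called from heavy-atom distance (default <= 3.5 A, the minimal
cutoff consistent with the longest bond treated as real here, 3.4 A) plus a
donor-antecedent angle floor standing in for H-atom collinearity.

Edges follow the Leontis-Westhof atom sets.  Exocyclic C6/C4 substituents
(adenine N6, guanine O6, cytosine N4, uracil O4) sit on the boundary between
the Watson-Crick and Hoogsteen (CH) edges; they are treated as shared and
resolved toward whichever of the two edges the unambiguous atoms support,
with ties broken toward the edge of the shortest H-bond and flagged.  The
cis/trans orientation is the sign-free dihedral test on the glycosidic
attachment atoms: |dihedral(N_gly1, C1'_1, C1'_2, N_gly2)| < 90 deg means the
glycosidic bonds lie on the same side of the C1'-C1' axis (cis).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

# ---------------------------------------------------------------------------
# residues and structure reading

_BASE_TYPE_ALIASES = {
    "A": "A", "ADE": "A", "RA": "A", "DA": "A",
    "G": "G", "GUA": "G", "RG": "G", "DG": "G",
    "C": "C", "CYT": "C", "RC": "C", "DC": "C",
    "U": "U", "URA": "U", "URI": "U", "RU": "U",
    "6MA": "6MA", "6MZ": "6MA", "M6A": "6MA", "A2M": "A",
    "5BC": "5BC", "CBR": "5BC", "C5B": "5BC",
    "5BU": "U", "BRU": "U",
}
#: modified bases classify with the parent base's edge sets
_PARENT_BASE = {"6MA": "A", "5BC": "C"}

_PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

_RIBOSE_ATOMS = ("C1'", "C2'", "C3'", "C4'", "C5'", "O2'", "O3'", "O4'", "O5'",
                 "P", "OP1", "OP2")

_ATOM_NAME_FIXES = {"O1P": "OP1", "O2P": "OP2"}


@dataclass(frozen=True)
class NucleotideResidue:
    chain: str
    number: int
    base_type: str  # A, C, G, U, 6MA, 5BC
    atoms: dict[str, np.ndarray]
    incomplete: bool = False

    @property
    def parent_base(self) -> str:
        return _PARENT_BASE.get(self.base_type, self.base_type)

    @property
    def is_purine(self) -> bool:
        return self.parent_base in ("A", "G")

    @property
    def glycosidic_n(self) -> str:
        return "N9" if self.is_purine else "N1"

    def coord(self, name: str) -> np.ndarray:
        return self.atoms[name]

    def label(self) -> str:
        return f"{self.chain}{self.number}{self.base_type}"


def _required_atoms(base: str) -> tuple[str, ...]:
    ring = _PURINE_RING if base in ("A", "G") else _PYRIMIDINE_RING
    return ring + ("C1'",)


def read_structure(path: str, model_index: int = 0) -> list[NucleotideResidue]:
    """Parse nucleotide residues from a PDB or mmCIF file via gemmi.

    Atom-name dialects are unified (O2* -> O2', O1P -> OP1); for alternate
    locations the highest occupancy wins, ties by altloc letter.  Residues
    missing required base atoms are kept but flagged incomplete (and excluded
    from classification downstream).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    model = st[model_index]
    out: list[NucleotideResidue] = []
    for chain in model:
        for res in chain:
            base = _BASE_TYPE_ALIASES.get(res.name.strip().upper())
            if base is None:
                continue
            picked: dict[str, tuple[float, str, np.ndarray]] = {}
            for atom in res:
                name = atom.name.strip().replace("*", "'")
                name = _ATOM_NAME_FIXES.get(name, name)
                key = (round(-atom.occ, 6), atom.altloc or "~")
                if name not in picked or key < picked[name][:2]:
                    picked[name] = (key[0], key[1],
                                    np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
            atoms = {n: v[2] for n, v in picked.items()}
            parent = _PARENT_BASE.get(base, base)
            missing = [a for a in _required_atoms(parent) if a not in atoms]
            out.append(NucleotideResidue(chain.name, res.seqid.num, base, atoms,
                                         incomplete=bool(missing)))
    return out


# ---------------------------------------------------------------------------
# hydrogen bonds

#: donor atom -> covalently bonded heavy antecedents (for the angle test)
_DONORS = {
    "A": {"N6": ("C6",)},
    "G": {"N1": ("C2", "C6"), "N2": ("C2",)},
    "C": {"N4": ("C4",)},
    "U": {"N3": ("C2", "C4")},
}
_ACCEPTORS = {
    "A": ("N1", "N3", "N7"),
    "G": ("O6", "N3", "N7"),
    "C": ("O2", "N3"),
    "U": ("O2", "O4"),
}
_BACKBONE_ACCEPTORS = ("O2'", "O4'", "O3'", "O5'", "OP1", "OP2")


@dataclass(frozen=True)
class HBond:
    donor_res: NucleotideResidue
    donor_atom: str
    acceptor_res: NucleotideResidue
    acceptor_atom: str
    distance: float
    donor_angle: float | None = None

    @property
    def base_base(self) -> bool:
        return (self.donor_atom not in _RIBOSE_ATOMS
                and self.acceptor_atom not in _RIBOSE_ATOMS)


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def _donor_map(res: NucleotideResidue) -> dict[str, tuple[str, ...]]:
    d = dict(_DONORS.get(res.parent_base, {}))
    if "O2'" in res.atoms and "C2'" in res.atoms:
        d["O2'"] = ("C2'",)
    return d


def _acceptor_list(res: NucleotideResidue) -> list[str]:
    acc = [a for a in _ACCEPTORS.get(res.parent_base, ()) if a in res.atoms]
    acc += [a for a in _BACKBONE_ACCEPTORS if a in res.atoms]
    return acc


def find_hbonds(
    residues: list[NucleotideResidue],
    d_max: float = 3.5,
    angle_min: float = 110.0,
) -> list[HBond]:
    """Donor-acceptor contacts between distinct residues, sorted by distance.

    A contact qualifies when the heavy-atom distance is <= d_max and every
    donor-antecedent angle (antecedent-donor-acceptor) is >= angle_min, the
    proxy for a roughly linear N/O-H...acceptor geometry when hydrogens are
    absent from the model.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    bonds: list[HBond] = []
    for i, r1 in enumerate(residues):
        donors = _donor_map(r1)
        for j, r2 in enumerate(residues):
            if i == j:
                continue
            for datom, antecedents in donors.items():
                if datom not in r1.atoms:
                    continue
                dpos = r1.atoms[datom]
                for aatom in _acceptor_list(r2):
                    apos = r2.atoms[aatom]
                    dist = float(np.linalg.norm(dpos - apos))
                    if dist > d_max:
                        continue
                    angles = [
                        _angle(r1.atoms[ant], dpos, apos)
                        for ant in antecedents
                        if ant in r1.atoms
                    ]
                    if angles and min(angles) < angle_min:
                        continue
                    bonds.append(HBond(r1, datom, r2, aatom, dist,
                                       min(angles) if angles else None))
    bonds.sort(key=lambda b: b.distance)
    return bonds


# ---------------------------------------------------------------------------
# Leontis-Westhof classification

#: unambiguous edge atoms per parent base; O2' joins the sugar edge
_EDGE_CORE = {
    "A": {"WatsonCrick": ("N1",), "Hoogsteen": ("N7", "C8"), "Sugar": ("N3", "O2'")},
    "G": {"WatsonCrick": ("N1",), "Hoogsteen": ("N7", "C8"), "Sugar": ("N3", "N2", "O2'")},
    "C": {"WatsonCrick": ("N3",), "Hoogsteen": ("C5", "C6"), "Sugar": ("O2", "O2'")},
    "U": {"WatsonCrick": ("N3",), "Hoogsteen": ("C5", "C6"), "Sugar": ("O2", "O2'")},
}
#: boundary atoms shared between the WC and Hoogsteen edges
_EDGE_SHARED = {"A": ("N6",), "G": ("O6",), "C": ("N4",), "U": ("O4",)}

#: base atoms whose mean marks each edge's direction (for the geometric vote)
_EDGE_REPS = {
    "A": {"WatsonCrick": ("N1", "N6"), "Hoogsteen": ("N7", "N6"), "Sugar": ("N3", "C2")},
    "G": {"WatsonCrick": ("N1", "O6"), "Hoogsteen": ("N7", "O6"), "Sugar": ("N3", "N2")},
    "C": {"WatsonCrick": ("N3", "N4"), "Hoogsteen": ("C5", "N4"), "Sugar": ("O2",)},
    "U": {"WatsonCrick": ("N3", "O4"), "Hoogsteen": ("C5", "O4"), "Sugar": ("O2",)},
}


def _base_centroid(res: NucleotideResidue) -> np.ndarray:
    ring = _PURINE_RING if res.is_purine else _PYRIMIDINE_RING
    return np.mean([res.atoms[a] for a in ring if a in res.atoms], axis=0)


def _geometric_edge(res: NucleotideResidue, partner: NucleotideResidue) -> str:
    """Edge whose representative direction best aligns with the partner.

    Robust against individual H-bonds dropping in and out of the detection
    window: uses only base centroids and fixed representative atoms.
    """
    c = _base_centroid(res)
    d = _base_centroid(partner) - c
    d /= np.linalg.norm(d)
    best, best_cos = "WatsonCrick", -2.0
    for edge, reps in _EDGE_REPS[res.parent_base].items():
        v = np.mean([res.atoms[a] for a in reps if a in res.atoms], axis=0) - c
        cosv = float(np.dot(v, d) / np.linalg.norm(v))
        if cosv > best_cos:
            best, best_cos = edge, cosv
    return best


@dataclass(frozen=True)
class BasePair:
    res1: NucleotideResidue
    res2: NucleotideResidue
    hbonds: list[HBond]
    paired: bool
    edge1: str | None = None
    edge2: str | None = None
    orientation: str | None = None  # cis / trans
    class_label: str = "unpaired"
    ambiguous: bool = False


def _edge_for_residue(
    res: NucleotideResidue, bonds: list[HBond], partner: NucleotideResidue
) -> tuple[str | None, bool]:
    """Majority edge of a residue's H-bonded atoms; returns (edge, ambiguous).

    Core atoms vote for their edge; the partner-direction geometric vote is
    added with unit weight (it stabilizes the call when a marginal H-bond
    falls out of the detection window); shared boundary atoms (N6/O6/N4/O4)
    then join whichever of WC/Hoogsteen leads.  Remaining ties break toward
    the edge holding the shortest H-bond and are flagged ambiguous.
    """
    core = _EDGE_CORE[res.parent_base]
    shared = _EDGE_SHARED[res.parent_base]
    seen: dict[str, float] = {}
    for b in bonds:
        if b.donor_res is res:
            seen[b.donor_atom] = min(b.distance, seen.get(b.donor_atom, np.inf))
        if b.acceptor_res is res:
            seen[b.acceptor_atom] = min(b.distance, seen.get(b.acceptor_atom, np.inf))
    if not seen:
        return None, False
    atoms = sorted(seen.items(), key=lambda t: t[1])
    votes = {"WatsonCrick": 0.0, "Hoogsteen": 0.0, "Sugar": 0.0}
    shared_atoms = []
    for name, dist in atoms:
        placed = False
        for edge, members in core.items():
            if name in members:
                votes[edge] += 1
                placed = True
        if not placed and name in shared:
            shared_atoms.append((name, dist))
    votes[_geometric_edge(res, partner)] += 1.5
    ambiguous = False
    if shared_atoms:
        if votes["WatsonCrick"] != votes["Hoogsteen"]:
            winner = max(("WatsonCrick", "Hoogsteen"), key=lambda e: votes[e])
        else:
            winner, ambiguous = "WatsonCrick", True
        votes[winner] += len(shared_atoms)
    best = max(votes.values())
    winners = [e for e, v in votes.items() if v == best and v > 0]
    if len(winners) == 1:
        return winners[0], ambiguous
    # equal votes: tie toward the edge holding the shortest H-bond
    for name, _ in sorted(atoms, key=lambda t: t[1]):
        for edge in winners:
            if name in core[edge]:
                return edge, True
    return winners[0], True


def _cis_trans(r1: NucleotideResidue, r2: NucleotideResidue) -> str:
    # base-centroid -> C1' stands in for the glycosidic bond direction: same
    # side of the C1'-C1' axis, but with a ~4.7 A lever arm and an averaged
    # endpoint, so the call is stable against coordinate error
    a1, b1 = _base_centroid(r1), r1.atoms["C1'"]
    b2, a2 = r2.atoms["C1'"], _base_centroid(r2)
    return "cis" if abs(_dihedral(a1, b1, b2, a2)) < 90.0 else "trans"


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))


_EDGE_SHORT = {"WatsonCrick": "WC", "Hoogsteen": "Hoogsteen", "Sugar": "Sugar"}


def classify_pair(
    r1: NucleotideResidue,
    r2: NucleotideResidue,
    hbonds: list[HBond] | None = None,
    d_max: float = 3.6,
) -> BasePair:
    """Leontis-Westhof classification of two residues.

    ``paired`` requires at least one base-base H-bond; edge votes also count
    O2' contacts (sugar edge).  The vote-gathering contacts are taken on
    distance alone (slightly beyond the reporting cutoff, no angle filter):
    the donor-angle test guards *reported* H-bond lists against spurious
    contacts, but dropping a marginal bond from the vote would destabilize
    the classification, which the geometric vote and the distance window keep
    robust to coordinate error.  The class label reads e.g.
    'trans Sugar/Hoogsteen G·A' with the residues in (res1, res2) order.
    """
    if r1.incomplete or r2.incomplete:
        raise ValueError("cannot classify incomplete residues")
    if hbonds is None:
        hbonds = find_hbonds([r1, r2], d_max=d_max, angle_min=0.0)
    else:
        hbonds = [
            b for b in hbonds
            if {id(b.donor_res), id(b.acceptor_res)} == {id(r1), id(r2)}
        ]
    if not any(b.base_base for b in hbonds):
        return BasePair(r1, r2, hbonds, paired=False)
    e1, amb1 = _edge_for_residue(r1, hbonds, r2)
    e2, amb2 = _edge_for_residue(r2, hbonds, r1)
    orientation = _cis_trans(r1, r2)
    label = (f"{orientation} {_EDGE_SHORT[e1]}/{_EDGE_SHORT[e2]} "
             f"{r1.parent_base}·{r2.parent_base}")
    return BasePair(r1, r2, hbonds, True, e1, e2, orientation, label, amb1 or amb2)


def classify_structure(
    residues: list[NucleotideResidue], d_max: float = 3.5, angle_min: float = 110.0
) -> list[BasePair]:
    """All base pairs among complete residues.

    Pair *discovery* uses the strict H-bond criteria (distance and donor
    angle), so stacking contacts do not spawn spurious pairs; each discovered
    pair is then classified with the robust vote of :func:`classify_pair`.
    """
    complete = [r for r in residues if not r.incomplete]
    bonds = find_hbonds(complete, d_max=d_max, angle_min=angle_min)
    seen: set[tuple[int, int]] = set()
    index = {id(r): k for k, r in enumerate(complete)}
    for b in bonds:
        if b.base_base:
            seen.add(tuple(sorted((index[id(b.donor_res)], index[id(b.acceptor_res)]))))
    return [classify_pair(complete[i], complete[j]) for i, j in sorted(seen)]


def detect_sheared_GA(pairs: list[BasePair]) -> tuple[list[BasePair], int]:
    """Sheared pairs (trans, G on the sugar edge, A on the Hoogsteen edge) and
    the number of tandem (chain-adjacent) occurrences among them."""
    sheared = []
    for p in pairs:
        if not p.paired or p.orientation != "trans":
            continue
        ga = {(p.res1.parent_base, p.edge1), (p.res2.parent_base, p.edge2)}
        if ga == {("G", "Sugar"), ("A", "Hoogsteen")}:
            sheared.append(p)
    tandem = 0
    for i in range(len(sheared)):
        for j in range(i + 1, len(sheared)):
            if _adjacent(sheared[i], sheared[j]):
                tandem += 1
    return sheared, tandem


def _adjacent(p: BasePair, q: BasePair) -> bool:
    def near(a: NucleotideResidue, b: NucleotideResidue) -> bool:
        return a.chain == b.chain and abs(a.number - b.number) == 1

    return (near(p.res1, q.res1) and near(p.res2, q.res2)) or (
        near(p.res1, q.res2) and near(p.res2, q.res1)
    )


# ---------------------------------------------------------------------------
# N6-methyl placement and clash check

def base_plane_normal(res: NucleotideResidue) -> np.ndarray:
    ring = _PURINE_RING if res.is_purine else _PYRIMIDINE_RING
    pts = np.array([res.atoms[a] for a in ring if a in res.atoms])
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def add_n6_methyl(res: NucleotideResidue, rotamer: str = "anti") -> NucleotideResidue:
    """Place an idealized N6-methyl carbon (atom CN6) on an adenine.

    sp2 geometry in the base plane, 1.45 A from N6, with the C6-N6-CN6 angle
    at 120 deg; 'anti' puts the methyl trans to N1 across the C6-N6 bond (the
    rotamer compatible with Watson-Crick pairing), 'syn' cis to N1.
    """
    if res.parent_base != "A":
        raise ValueError("N6-methyl placement requires an adenine")
    for need in ("N6", "C6", "N1"):
        if need not in res.atoms:
            raise ValueError(f"{res.label()}: missing anchor atom {need}")
    if rotamer not in ("anti", "syn"):
        raise ValueError("rotamer must be 'anti' or 'syn'")
    n6, c6, n1 = res.atoms["N6"], res.atoms["C6"], res.atoms["N1"]
    normal = base_plane_normal(res)
    u = n6 - c6
    u -= normal * np.dot(u, normal)
    u /= np.linalg.norm(u)
    w = np.cross(normal, u)
    cand = [n6 + 1.45 * (np.cos(np.radians(60)) * u + s * np.sin(np.radians(60)) * w)
            for s in (+1.0, -1.0)]
    # anti: maximize distance to N1 across the C6-N6 bond
    cand.sort(key=lambda p: np.linalg.norm(p - n1), reverse=(rotamer == "anti"))
    atoms = dict(res.atoms)
    atoms["CN6"] = cand[0]
    return replace(res, base_type="6MA", atoms=atoms)


def forced_methyl_rotamer(res: NucleotideResidue, acceptor_position: np.ndarray) -> str:
    """Rotamer a methyl must adopt when N6's remaining H donates to an acceptor.

    The N6 hydrogen that points at the acceptor occupies one sp2 slot; the
    methyl is forced into the other.  Returns 'anti' or 'syn' — the slot
    farther from the acceptor.
    """
    return max(
        ("anti", "syn"),
        key=lambda r: float(
            np.linalg.norm(add_n6_methyl(res, r).atoms["CN6"] - acceptor_position)
        ),
    )


def clash_check(
    res_aug: NucleotideResidue,
    partner: NucleotideResidue,
    cutoff: float = 3.0,
    probe_atom: str = "CN6",
) -> tuple[float, bool, tuple[str, str]]:
    """Minimum distance from the methyl carbon to the partner's ribose atoms.

    Returns (min_distance, clashing, (probe atom, closest ribose atom));
    clashing when the minimum falls below the cutoff (default 3.0 A, about a
    C/O van der Waals contact).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    probe = res_aug.atoms[probe_atom]
    ribose = [(a, partner.atoms[a]) for a in _RIBOSE_ATOMS if a in partner.atoms]
    if not ribose:
        raise ValueError(f"{partner.label()}: no ribose atoms present")
    name, dist = min(
        ((a, float(np.linalg.norm(probe - pos))) for a, pos in ribose),
        key=lambda t: t[1],
    )
    return dist, dist < cutoff, (probe_atom, name)


# ---------------------------------------------------------------------------
# superposition

@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray  # 3x3, proper
    translation: np.ndarray
    rmsd: float
    atom_selection: str = ""

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray, atom_selection: str = "") -> Superposition:
    """Kabsch least-squares rigid-body fit of mobile onto reference."""
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3 or mob.shape[0] < 3:
        raise ValueError("need matched (n, 3) coordinate arrays with n >= 3")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    a, b = mob - cm, ref - cr
    if min(np.linalg.matrix_rank(a, tol=1e-8), np.linalg.matrix_rank(b, tol=1e-8)) < 2:
        raise ValueError("degenerate (collinear) atom selection")
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    fitted = a @ rot.T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return Superposition(rot, trans, rmsd, atom_selection)


def rmsd_between(sup: Superposition, mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD over a separately chosen atom selection after applying ``sup``."""
    moved = sup.apply(np.asarray(mobile, dtype=float))
    diff = moved - np.asarray(reference, dtype=float)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
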