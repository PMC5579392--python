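"""Synthetic inputs with recorded ground truth for every analysis stage.

Each generator emulates one experimental input: snoRNA sequences with planted
box C/D (and optional C'/D') elements, ortholog alignments with configured
per-column conservation, RMBase-style m6A site tables over synthetic gene
models, FRET titration curves from the two-state isotherm, one-site ITC
injection series, and idealized duplex coordinates with planted base-pair
geometry.  Every artifact comes with a machine-readable truth record, so each
analysis stage can be tested closed-loop without any download.

Generators draw from independent seeded streams (seed spawned per generator),
so adding or re-running one generator never perturbs another.  Defaults
follow the study conditions: 200 nM RNA FRET titrations plateauing at
E_FRET = 0.6, the 0.4 ul + 19 x 2 ul ITC schedule with 20 uM RNA in a 200 ul
cell and 200 uM protein in the syringe at 298 K, -1b/-1n pair frequencies
led by CG at 65.27%, and A-form duplexes (rise 2.81 A, twist 32.7 deg —
conventional fiber values) carrying either Watson-Crick steps, a planted
sheared G.A step realizing the GN2-AN7 2.8 A / AN6-GN3 3.4 A contacts with
the opposing ribose O2' about 3 A from AN6, or a displaced G/6MA step with
the former H-bond distances pushed beyond 6 A and AN6 donating to G O2' at
2.8 A.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .binding_models import FretTitration, ITCExperiment, itc_one_site_heats, FretFitParams
from .modsite_crossref import GeneModel, ModSite
from .motif_annotation import SnoRNASequence
from .structure_geometry import NucleotideResidue

_STREAMS = {"snorna": 1, "alignment": 2, "modsites": 3, "fret": 4, "itc": 5, "duplex": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# sequences

#: -1b/-1n pair frequencies observed across human box C/D k-turns; the five
#: named pairs carry the bulk of the distribution, the remainder is spread
#: uniformly over the other combinations.
DEFAULT_MINUS1_PAIR_PROBS = {"CG": 0.6527, "AU": 0.0878, "UA": 0.0496,
                             "UG": 0.0420, "GC": 0.0382}

BOX_C = "_UGAUGA"  # leading R filled per sequence
BOX_D = "CUGA"


@dataclass(frozen=True)
class SnoRNAConfig:
    n_sequences: int = 20
    prefix_len: int = 6
    guide_len: int = 10
    suffix_len: int = 6
    p_internal: float = 0.5  # probability of planting a box C'/D' element
    internal_loop_len: int = 3
    internal_kloop: bool = True
    minus1_pair_probs: dict = field(default_factory=lambda: dict(DEFAULT_MINUS1_PAIR_PROBS))
    #: override: force the -1n base with this probability table instead of the
    #: joint pair distribution (keys A/C/G/U); None keeps the pair table
    minus1n_probs: dict | None = None
    #: force the -2n base (e.g. 'U' to guarantee a DRACH-compatible context);
    #: None draws it uniformly
    minus2n: str | None = None


_PAIRS = [a + b for a in "ACGU" for b in "ACGU"]
_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _pair_distribution(cfg: SnoRNAConfig) -> tuple[list[str], np.ndarray]:
    probs = dict.fromkeys(_PAIRS, 0.0)
    named = cfg.minus1_pair_probs
    rest = (1.0 - sum(named.values())) / (len(_PAIRS) - len(named))
    for p in _PAIRS:
        probs[p] = named.get(p, rest)
    v = np.array([probs[p] for p in _PAIRS])
    return _PAIRS, v / v.sum()


def _draw_minus1(cfg: SnoRNAConfig, rng: np.random.Generator) -> tuple[str, str]:
    """(-1b, -1n) draw."""
    if cfg.minus1n_probs is not None:
        bases, pv = zip(*sorted(cfg.minus1n_probs.items()))
        n = rng.choice(bases, p=np.array(pv) / sum(pv))
        return _WC_PARTNER[n], str(n)
    pairs, pv = _pair_distribution(cfg)
    pair = pairs[rng.choice(len(pairs), p=pv)]
    return pair[0], pair[1]


def _random_run(rng: np.random.Generator, k: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=k))


def _has_spurious_boxes(seq: str, allowed_c: set[int], allowed_d: set[int]) -> bool:
    for i in range(len(seq) - 6):
        if seq[i + 1 : i + 7] == "UGAUGA" and seq[i] in "AG" and i not in allowed_c:
            return True
    for i in range(len(seq) - 3):
        if seq[i : i + 4] == BOX_D and i not in allowed_d:
            return True
    return False


def gen_snorna_set(cfg: SnoRNAConfig, seed: int) -> tuple[list[SnoRNASequence], pd.DataFrame]:
    """Sequences with planted boxes plus a truth table of spans and -1n bases.

    Flanks and guide segments are resampled until the assembled sequence
    contains no spurious box motifs, so the planted spans are the unique
    best-scoring annotation by construction (truth stays unambiguous).
    Coordinates in the truth table are 0-based half-open.
    """
    if cfg.prefix_len < 3 or cfg.guide_len < 1 or cfg.internal_loop_len > 7:
        raise ValueError("impossible length constraints")
    rng = _rng(seed, "snorna")
    seqs, rows = [], []
    for k in range(cfg.n_sequences):
        for _attempt in range(200):
            r = rng.choice(["A", "G"])
            box_c = r + BOX_C[1:]
            m1b, m1n = _draw_minus1(cfg, rng)
            internal = bool(rng.random() < cfg.p_internal)
            prefix = _random_run(rng, cfg.prefix_len - 2) + m1b + _random_run(rng, 1)
            parts = [prefix, box_c]
            c0 = len(prefix)
            dp0 = cp0 = a1n_p = None
            m1n_p = ""
            if internal:
                parts.append(_random_run(rng, cfg.guide_len))
                dp0 = sum(map(len, parts))
                m1n_p = str(rng.choice(list("ACGU")))
                loop = _random_run(rng, cfg.internal_loop_len)
                if cfg.internal_kloop:
                    # spoil the would-be C-helix pairs so the element k-loops
                    loop = loop[:-1] + ("A" if m1n_p != "U" else "C")
                rp = rng.choice(["A", "G"])
                parts += [BOX_D, m1n_p, loop, rp + BOX_C[1:]]
                cp0 = dp0 + 4 + 1 + len(loop)
                a1n_p = dp0 + 3
            parts.append(_random_run(rng, cfg.guide_len))
            d0 = sum(map(len, parts))
            m2n = cfg.minus2n or _random_run(rng, 1)
            parts += [BOX_D, m1n, m2n, _random_run(rng, cfg.suffix_len)]
            seq = "".join(parts)
            allowed_c = {c0} | ({cp0} if cp0 is not None else set())
            allowed_d = {d0} | ({dp0} if dp0 is not None else set())
            if not _has_spurious_boxes(seq, allowed_c, allowed_d):
                break
        else:
            raise RuntimeError("could not assemble a motif-clean sequence")
        sid = f"syn{k:04d}"
        seqs.append(SnoRNASequence(sid, seq, source="synthetic"))
        rows.append({
            "id": sid, "length": len(seq),
            "boxC_start": c0, "boxC_end": c0 + 7,
            "boxD_start": d0, "boxD_end": d0 + 4,
            "a1n_index": d0 + 3, "minus1n": m1n, "minus1b": m1b,
            "has_internal": internal,
            "boxDp_start": dp0, "boxCp_start": cp0,
            "a1n_internal_index": a1n_p, "minus1n_internal": m1n_p or None,
        })
    return seqs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# alignments

@dataclass(frozen=True)
class AlignmentConfig:
    family_id: str = "SYNFAM"
    n_rows: int = 20
    substitution_rate: float = 0.05  # per non-conserved column, per row
    minus1n_conservation: float = 0.9  # P(row keeps C at the -1n column)
    deletion_rate: float = 0.0  # per row: one random flank position gapped


def gen_alignment(
    cfg: AlignmentConfig, seed: int, snorna_cfg: SnoRNAConfig | None = None
) -> tuple[list[tuple[str, str]], dict]:
    """Ortholog alignment rows from a synthetic root snoRNA.

    The root (reference) sequence is row 0, ungapped, with -1n forced to C.
    Box columns are copied verbatim; other columns substitute at the
    configured rate; the -1n column is C with the configured conservation and
    a random other base otherwise.  Truth carries the reference annotation
    spans and the -1n column.
    """
    if cfg.n_rows < 1:
        raise ValueError("alignment needs at least one row")
    scfg = snorna_cfg or SnoRNAConfig(n_sequences=1, p_internal=0.0)
    scfg = dataclass_replace(scfg, n_sequences=1, minus1n_probs={"C": 1.0})
    seqs, truth = gen_snorna_set(scfg, seed)
    root = seqs[0].seq
    t = truth.iloc[0]
    boxed = set(range(t.boxC_start, t.boxC_end)) | set(range(t.boxD_start, t.boxD_end))
    m1n_col = int(t.boxD_end)  # -1n sits immediately 3' of box D

    rng = _rng(seed, "alignment")
    rows = [("ref", root)]
    for r in range(1, cfg.n_rows):
        chars = list(root)
        for j in range(len(chars)):
            if j in boxed:
                continue
            if j == m1n_col:
                if rng.random() >= cfg.minus1n_conservation:
                    chars[j] = rng.choice([b for b in "AGU"])
            elif rng.random() < cfg.substitution_rate:
                chars[j] = rng.choice([b for b in "ACGU" if b != chars[j]])
        if cfg.deletion_rate and rng.random() < cfg.deletion_rate:
            flank = [j for j in range(len(chars)) if j not in boxed and j != m1n_col]
            chars[int(rng.choice(flank))] = "-"
        rows.append((f"sp{r:03d}", "".join(chars)))
    truth_info = {
        "family_id": cfg.family_id,
        "reference_id": "ref",
        "boxC_span": (int(t.boxC_start), int(t.boxC_end)),
        "boxD_span": (int(t.boxD_start), int(t.boxD_end)),
        "a1n_index": int(t.a1n_index),
        "minus1n_index": m1n_col,
        "minus1n_conservation": cfg.minus1n_conservation,
    }
    return rows, truth_info


def dataclass_replace(obj, **kw):
    from dataclasses import replace

    return replace(obj, **kw)


# ---------------------------------------------------------------------------
# gene models and modification sites

@dataclass(frozen=True)
class ModsiteConfig:
    methylated_fraction: float = 0.6
    n_decoys: int = 10
    support_poisson_mean: float = 2.0
    n_chromosomes: int = 5
    chrom_len: int = 1_000_000


def gen_gene_models(
    seqs: list[SnoRNASequence], cfg: ModsiteConfig, seed: int
) -> list[GeneModel]:
    """Place each snoRNA at a random single-exon locus."""
    rng = _rng(seed, "modsites")
    genes = []
    for sq in seqs:
        chrom = f"chr{int(rng.integers(1, cfg.n_chromosomes + 1))}"
        start = int(rng.integers(1000, cfg.chrom_len))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(sq.id, chrom, start, start + len(sq.seq) - 1,
                               strand, sq.seq))
    return genes


def gen_modsites(
    genes: list[GeneModel], truth: pd.DataFrame, cfg: ModsiteConfig, seed: int
) -> tuple[list[ModSite], pd.DataFrame]:
    """RMBase-style site table: true A1n sites for a subset of genes plus
    off-target decoys; truth records which genes were methylated."""
    rng = _rng(seed, "modsites")
    rng.integers(0, 1 << 16, size=len(genes) * 3)  # advance past the gene-placement draws
    truth_by_id = truth.set_index("id")
    sites, rows = [], []
    for g in genes:
        idx = int(truth_by_id.loc[g.gene_name, "a1n_index"])
        pos = g.start + idx if g.strand == "+" else g.end - idx
        meth = bool(rng.random() < cfg.methylated_fraction)
        if meth:
            sites.append(ModSite(g.gene_name, f"m6A_syn_{g.gene_name}", g.chromosome,
                                 pos, g.strand, int(1 + rng.poisson(cfg.support_poisson_mean)),
                                 "boxD 1n"))
        rows.append({"gene_name": g.gene_name, "chromosome": g.chromosome,
                     "a1n_genomic": pos, "strand": g.strand, "methylated": meth})
    a1n_loci = {(r["chromosome"], r["a1n_genomic"], r["strand"]) for r in rows}
    k = 0
    while k < cfg.n_decoys:
        chrom = f"chr{int(rng.integers(1, cfg.n_chromosomes + 1))}"
        pos = int(rng.integers(1, cfg.chrom_len))
        strand = "+" if rng.random() < 0.5 else "-"
        if (chrom, pos, strand) in a1n_loci:
            continue
        sites.append(ModSite("decoy", f"m6A_syn_decoy{k:03d}", chrom, pos, strand,
                             int(1 + rng.poisson(cfg.support_poisson_mean)), ""))
        k += 1
    return sites, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binding data

@dataclass(frozen=True)
class FretConfig:
    e0: float = 0.30
    de: float = 0.30  # plateau at E0 + dE = 0.6
    k_assoc: float = 1.0e8  # M^-1; effectively stoichiometric at 200 nM RNA
    r_total: float = 200e-9  # M
    p_max: float = 600e-9
    n_points: int = 12
    sigma: float = 0.01


def gen_fret_curve(cfg: FretConfig, seed: int) -> tuple[FretTitration, FretFitParams]:
    """Noisy titration from the two-state isotherm; truth = the parameters."""
    if cfg.sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    from .binding_models import efret_model

    rng = _rng(seed, "fret")
    p = np.linspace(0.0, cfg.p_max, cfg.n_points)
    params = FretFitParams(e0=cfg.e0, de=cfg.de, k_assoc=cfg.k_assoc)
    e = efret_model(p, params, cfg.r_total)
    if cfg.sigma:
        e = e + rng.normal(0.0, cfg.sigma, size=e.shape)
    return FretTitration(p, e, cfg.r_total), params


@dataclass(frozen=True)
class ITCConfig:
    dh: float = -10_000.0  # cal/mol, exothermic
    k_assoc: float = 1.0e7  # M^-1
    n_sites: float = 1.0
    cell_rna_m: float = 20e-6
    syringe_protein_m: float = 200e-6
    cell_volume_l: float = 200e-6
    first_injection_l: float = 0.4e-6
    later_injection_l: float = 2.0e-6
    n_injections: int = 20
    temperature_k: float = 298.0
    sigma_cal: float = 0.0


def gen_itc_series(cfg: ITCConfig, seed: int) -> tuple[ITCExperiment, dict]:
    """One-site injection heats on the standard schedule; truth = parameters."""
    if cfg.sigma_cal < 0:
        raise ValueError("noise sigma must be non-negative")
    if cfg.n_injections < 1:
        raise ValueError("need at least one injection")
    rng = _rng(seed, "itc")
    vols = np.r_[cfg.first_injection_l,
                 np.full(cfg.n_injections - 1, cfg.later_injection_l)]
    base = ITCExperiment(vols, np.zeros_like(vols), cfg.cell_rna_m,
                         cfg.syringe_protein_m, cfg.cell_volume_l, cfg.temperature_k)
    heats = itc_one_site_heats(base, cfg.dh, cfg.k_assoc, cfg.n_sites)
    if cfg.sigma_cal:
        heats = heats + rng.normal(0.0, cfg.sigma_cal, size=heats.shape)
    exp = ITCExperiment(vols, heats, cfg.cell_rna_m, cfg.syringe_protein_m,
                        cfg.cell_volume_l, cfg.temperature_k)
    truth = {"dh": cfg.dh, "k_assoc": cfg.k_assoc, "n_sites": cfg.n_sites}
    return exp, truth


# ---------------------------------------------------------------------------
# duplex coordinates

#: nucleobase heavy atoms in the base-pair standard reference frame (x, y, z=0);
#: in this frame the Watson-Crick partner is the 180 deg rotation about x.
BASE_COORDS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498, 0.0), "C8": (0.024, 4.897, 0.0), "N7": (0.877, 3.902, 0.0),
        "C5": (0.071, 2.771, 0.0), "C6": (0.369, 1.398, 0.0), "N6": (1.611, 0.909, 0.0),
        "N1": (-0.668, 0.532, 0.0), "C2": (-1.912, 1.023, 0.0), "N3": (-2.320, 2.290, 0.0),
        "C4": (-1.267, 3.124, 0.0),
    },
    "G": {
        "N9": (-1.289, 4.551, 0.0), "C8": (0.023, 4.962, 0.0), "N7": (0.870, 3.969, 0.0),
        "C5": (0.071, 2.833, 0.0), "C6": (0.424, 1.460, 0.0), "O6": (1.554, 0.955, 0.0),
        "N1": (-0.700, 0.641, 0.0), "C2": (-1.999, 1.087, 0.0), "N2": (-2.949, 0.139, 0.0),
        "N3": (-2.342, 2.364, 0.0), "C4": (-1.265, 3.177, 0.0),
    },
    "C": {
        "N1": (-1.285, 4.542, 0.0), "C2": (-1.472, 3.158, 0.0), "O2": (-2.628, 2.709, 0.0),
        "N3": (-0.391, 2.344, 0.0), "C4": (0.837, 2.868, 0.0), "N4": (1.875, 2.027, 0.0),
        "C5": (1.056, 4.275, 0.0), "C6": (-0.023, 5.068, 0.0),
    },
    "U": {
        "N1": (-1.284, 4.500, 0.0), "C2": (-1.462, 3.131, 0.0), "O2": (-2.563, 2.608, 0.0),
        "N3": (-0.302, 2.397, 0.0), "C4": (0.989, 2.884, 0.0), "O4": (1.935, 2.094, 0.0),
        "C5": (1.089, 4.311, 0.0), "C6": (-0.024, 5.053, 0.0),
    },
}

#: simplified ribose in the same frame (idealized, fixed pucker)
RIBOSE_COORDS = {
    "C1'": (-2.477, 5.399, 0.0),
    "O4'": (-3.377, 4.599, 0.800),
    "C2'": (-3.577, 5.899, 0.910),
    "O2'": (-4.077, 6.999, 1.510),
    "C3'": (-3.777, 4.699, 1.810),
}

A_FORM_RISE = 2.81  # Angstrom per step
A_FORM_TWIST = 32.7  # degrees per step


def nucleotide_template(base: str) -> dict[str, np.ndarray]:
    return {k: np.array(v) for k, v in (BASE_COORDS[base] | RIBOSE_COORDS).items()}


def _flip(atoms: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: v * np.array([1.0, -1.0, -1.0]) for k, v in atoms.items()}


def _transform(atoms, rot: np.ndarray, trans: np.ndarray):
    return {k: rot @ v + trans for k, v in atoms.items()}


def _pack(atoms: dict[str, np.ndarray]) -> tuple[list[str], np.ndarray]:
    names = sorted(atoms)
    return names, np.array([atoms[n] for n in names])


def _chi_rotate(atoms: dict[str, np.ndarray], glyc_n: str, chi_deg: float):
    """Rotate the ribose about the glycosidic N - C1' axis (sugar orientation)."""
    axis_a, axis_b = atoms[glyc_n], atoms["C1'"]
    axis = axis_b - axis_a
    rot = Rotation.from_rotvec(np.radians(chi_deg) * axis / np.linalg.norm(axis))
    out = dict(atoms)
    for name in RIBOSE_COORDS:
        if name != "C1'":
            out[name] = axis_b + rot.apply(atoms[name] - axis_b)
    return out


_POLAR = {"N", "O"}


def _base_polar_atoms(atoms: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: v for k, v in atoms.items() if k[0] in _POLAR and k not in RIBOSE_COORDS}


@functools.lru_cache(maxsize=None)
def sheared_ga_geometry() -> tuple[tuple, tuple]:
    """Solved trans sugar-Hoogsteen G.A pair geometry.

    Adenine sits in the standard frame; guanine (base + ribose) is placed by a
    rigid transform plus a sugar torsion, optimized against the target
    contacts GN2-AN7 = 2.8 A, AN6-GN3 = 3.4 A and AN6-GO2' = 3.0 A with
    donor-angle plausibility, a trans glycosidic orientation, steric floors
    and a soft coplanarity term.  The solve is deterministic (fixed
    multistart) and cached; returns ((names_G, coords_G), (names_A, coords_A)).
    """
    from .structure_geometry import _dihedral

    a_atoms = nucleotide_template("A")
    a_n7, a_n6, a_c6 = a_atoms["N7"], a_atoms["N6"], a_atoms["C6"]
    a_clash = np.array([v for k, v in a_atoms.items() if k not in RIBOSE_COORDS])

    def place(template, x):
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        g = _chi_rotate(template, "N9", x[6])
        return _transform(g, rot, x[3:6])

    def cost(x, template):
        g = place(template, x)
        c = 0.0
        c += 100.0 * (np.linalg.norm(g["N2"] - a_n7) - 2.8) ** 2
        c += 100.0 * (np.linalg.norm(a_n6 - g["N3"]) - 3.4) ** 2
        c += 10.0 * (np.linalg.norm(a_n6 - g["O2'"]) - 3.0) ** 2
        # donor-angle plausibility: C2-N2...N7 and C6-N6...N3 roughly linear
        for ant, don, acc in ((g["C2"], g["N2"], a_n7), (a_c6, a_n6, g["N3"])):
            u, v = ant - don, acc - don
            ang = np.degrees(np.arccos(np.clip(
                np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))
            c += 0.5 * max(0.0, 125.0 - ang) ** 2
        # firmly trans glycosidic orientation (margin against coordinate noise)
        dih = _dihedral(g["N9"], g["C1'"], a_atoms["C1'"], a_atoms["N9"])
        c += 20.0 * max(0.0, np.cos(np.radians(dih)) + 0.65) ** 2
        # steric floor between the two bases
        g_base = np.array([v for k, v in g.items() if k not in RIBOSE_COORDS])
        d = np.linalg.norm(g_base[:, None, :] - a_clash[None, :, :], axis=2)
        c += 30.0 * np.sum(np.maximum(0.0, 2.7 - d) ** 2)
        # keep the guanine base near the adenine plane
        c += 0.02 * np.sum(g_base[:, 2] ** 2)
        return c

    # small fixed multistart around the sugar-edge-to-Hoogsteen-edge approach
    template = nucleotide_template("G")
    best = None
    for rotz in (0.0, 270.0):
        r0 = Rotation.from_euler("z", rotz, degrees=True).as_rotvec()
        for chi in (120.0, 240.0):
            x0 = np.r_[r0, 4.5, 1.5, 0.0, chi]
            res = minimize(cost, x0, args=(template,), method="Nelder-Mead",
                           options={"maxiter": 3000, "xatol": 1e-7, "fatol": 1e-9})
            if best is None or res.fun < best[0]:
                best = (res.fun, res.x)
    return _pack(place(template, best[1])), _pack(a_atoms)


@functools.lru_cache(maxsize=None)
def displaced_g6ma_geometry() -> tuple[tuple, tuple]:
    """Non-paired G / N6-methyladenine arrangement.

    Starts from the sheared geometry and translates/rotates the adenine so the
    former H-bond distances exceed 6 A while AN6 donates to the guanine O2' at
    2.8 A, with no remaining base-base polar contact within 3.6 A — the
    disrupted arrangement adopted when the adenine carries an N6-methyl group.
    """
    (g_names, g_xyz), (a_names, a_xyz) = sheared_ga_geometry()
    g = dict(zip(g_names, g_xyz))
    a0 = dict(zip(a_names, a_xyz))
    g_polar = _base_polar_atoms(g)

    def place(x):
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        return _transform(a0, rot, x[3:6])

    def cost(x):
        a = place(x)
        c = 10.0 * (np.linalg.norm(a["N6"] - g["O2'"]) - 2.8) ** 2
        # just past the broken-contact mark: a large but minimal translation
        c += 0.5 * (np.linalg.norm(g["N2"] - a["N7"]) - 6.6) ** 2
        c += 0.5 * (np.linalg.norm(a["N6"] - g["N3"]) - 6.6) ** 2
        c += 20.0 * max(0.0, 6.4 - np.linalg.norm(g["N2"] - a["N7"])) ** 2
        c += 20.0 * max(0.0, 6.4 - np.linalg.norm(a["N6"] - g["N3"])) ** 2
        a_polar = _base_polar_atoms(a)
        for gp in g_polar.values():
            for ap in a_polar.values():
                c += 30.0 * max(0.0, 3.8 - np.linalg.norm(gp - ap)) ** 2
        # stay roughly in plane: large in-plane translation, little lift
        c += 0.05 * np.sum(np.array([v[2] for v in a_polar.values()]) ** 2)
        return c

    best = None
    for dx, dy in ((4.0, -3.0), (5.0, 0.0), (3.0, -5.0), (6.0, -2.0)):
        x0 = np.r_[np.zeros(3), dx, dy, 0.0]
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x)
    a = place(best[1])
    return _pack(g), _pack(a)


@dataclass(frozen=True)
class DuplexConfig:
    seq1: str = "CGCAGUCG"  # strand 1, 5'->3'; partner derived per step
    planted_step: int = 3  # step index carrying the special pair
    planted_class: str = "wc"  # wc | sheared_GA | tandem_sheared | displaced_G6MA
    noise_sigma: float = 0.0  # Gaussian coordinate noise, A
    random_orientation: bool = False  # apply a random global rigid transform
    rise: float = A_FORM_RISE
    twist: float = A_FORM_TWIST


def gen_duplex_coords(
    cfg: DuplexConfig, seed: int
) -> tuple[list[NucleotideResidue], pd.DataFrame]:
    """Idealized duplex with an optionally planted non-canonical central step.

    Strand 1 is chain A (residues 1..n, 5'->3'), strand 2 chain B (numbered so
    that paired residues share the step order).  The planted step places the
    solved sheared or displaced geometry; all other steps are Watson-Crick.
    Truth lists the intended class per step.
    """
    n = len(cfg.seq1)
    if not 0 <= cfg.planted_step < n:
        raise ValueError("planted_step outside the duplex")
    if cfg.planted_class not in ("wc", "sheared_GA", "tandem_sheared", "displaced_G6MA"):
        raise ValueError(f"unknown planted class {cfg.planted_class!r}")
    if cfg.noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    if cfg.planted_class != "wc" and cfg.seq1[cfg.planted_step] != "A":
        raise ValueError("planted G.A step requires an A in strand 1 at that step")
    if cfg.planted_class == "tandem_sheared" and (
        cfg.planted_step + 1 >= n or cfg.seq1[cfg.planted_step + 1] != "G"
    ):
        raise ValueError("tandem sheared pairs require A then G in strand 1")

    rng = _rng(seed, "duplex")
    residues: list[NucleotideResidue] = []
    truth_rows = []
    for i, b1 in enumerate(cfg.seq1):
        ang = np.radians(cfg.twist * i)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                        [np.sin(ang), np.cos(ang), 0.0],
                        [0.0, 0.0, 1.0]])
        trans = np.array([0.0, 0.0, cfg.rise * i])
        planted = cfg.planted_class != "wc" and (
            i == cfg.planted_step
            or (cfg.planted_class == "tandem_sheared" and i == cfg.planted_step + 1)
        )
        if planted:
            if cfg.planted_class == "displaced_G6MA":
                (gn, gx), (an, ax) = displaced_g6ma_geometry()
                klass = "unpaired"
            else:
                (gn, gx), (an, ax) = sheared_ga_geometry()
                klass = "trans Sugar/Hoogsteen"
            g_atoms, a_atoms = dict(zip(gn, gx)), dict(zip(an, ax))
            if i == cfg.planted_step:
                atoms1, atoms2 = a_atoms, g_atoms
                b2, bt1 = "G", ("6MA" if cfg.planted_class == "displaced_G6MA" else "A")
            else:  # second tandem step: strands swap roles (G.A over A.G)
                atoms1, atoms2 = g_atoms, a_atoms
                b2, bt1 = "A", "G"
        else:
            b2 = _WC_PARTNER[b1]
            atoms1 = nucleotide_template(b1)
            atoms2 = _flip(nucleotide_template(b2))
            klass, bt1 = "cis WC/WC", b1
        atoms1 = _transform(atoms1, rot, trans)
        atoms2 = _transform(atoms2, rot, trans)
        residues.append(NucleotideResidue("A", i + 1, bt1, atoms1))
        residues.append(NucleotideResidue("B", n - i, b2, atoms2))
        truth_rows.append({"step": i, "chain1_resnum": i + 1, "chain2_resnum": n - i,
                           "base1": bt1, "base2": b2, "true_class": klass})

    if cfg.noise_sigma or cfg.random_orientation:
        rot_g = (Rotation.random(random_state=np.random.RandomState(int(rng.integers(1 << 31))))
                 .as_matrix() if cfg.random_orientation else np.eye(3))
        trans_g = rng.uniform(-20, 20, 3) if cfg.random_orientation else np.zeros(3)
        noisy = []
        for r in residues:
            atoms = {
                k: rot_g @ (v + (rng.normal(0, cfg.noise_sigma, 3) if cfg.noise_sigma else 0.0))
                + trans_g
                for k, v in r.atoms.items()
            }
            noisy.append(NucleotideResidue(r.chain, r.number, r.base_type, atoms))
        residues = noisy
    return residues, pd.DataFrame(truth_rows)


def write_pdb(residues: list[NucleotideResidue], path: str) -> None:
    """Write residues as a minimal PDB file (via gemmi)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for r in residues:
        ch = chains.setdefault(r.chain, gemmi.Chain(r.chain))
        res = gemmi.Residue()
        res.name = {"6MA": "6MA", "5BC": "5BC"}.get(r.base_type, r.base_type)
        res.seqid = gemmi.SeqId(r.number, " ")
        for name, xyz in r.atoms.items():
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(name[0])
            at.pos = gemmi.Position(*xyz)
            at.occ = 1.0
            res.add_atom(at)
        ch.add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
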