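# Methods

`kturn_m6a` reimplements, as a tested pipeline, the chain of analyses behind a
simple regulatory claim: a subset of human box C/D snoRNAs carry a cytosine at
the k-turn -1n position, which turns the conserved non-bulged-strand 2n,1n
dinucleotide (GA) into a GAC methyl-transferase target; N6-methylation of the
A1n adenine is incompatible with the trans sugar-Hoogsteen (sheared) G·A pair
at the k-turn core, so the 15.5-kDa protein cannot induce the kinked fold and
snoRNP assembly is blocked at its first step. The package covers motif
annotation, ortholog conservation, modification-site cross-referencing,
binding-isotherm fitting, and 3D base-pair geometry, each testable closed-loop
against a synthetic-data generator.

## k-turn annotation

Box C (consensus RUGAUGA, R = A/G) and box D (CUGA) are located by IUPAC-aware
window scanning with a per-box mismatch budget (default 0 for the outer boxes,
1 for the internal C'/D' copies, which are known to be degenerate). A valid
outer pairing requires the D box to start at least 8 nt after the C box start,
so the non-canonical (NC) helix can close; candidates are ordered by total
mismatches, then leftmost box C, then leftmost box D. Because an internal D'
box would otherwise pair with the outer box C at equal score, the primary C/D
k-turn is the *outermost* minimal-mismatch pairing (leftmost C with its
rightmost D); internal C'/D' candidates are then sought strictly between the
outer boxes, with the D' box upstream of the C' box.

The position map follows the standard k-turn nomenclature, with the strand
assignment fixed by the architecture of the motif itself: box D's CUGA lies on
the non-bulged strand and reads (5'→3') NC-helix C, 3n=U, 2n=G, 1n=A, with -1n
the nucleotide immediately 3' of the box — which is why -1n=C yields the GAC
target reading 2n,1n,-1n along that strand, and why site tables label the
methylated adenine "boxD 1n". Box C's RUGAUGA supplies the bulged strand: L2,
L3, 1b=G, 2b=A, 3b, plus two NC-helix nucleotides; L1 and the -1b/-2b
positions are the nucleotides 5' of the box. The conserved core (1b=G, 2b=A,
2n=G, 1n=A) is enforced; an annotation that cannot satisfy it fails with the
violated position named, which doubles as the rejection rule for unreliable D'
boxes (flagged in output, never silently dropped). An internal element whose
inter-strand segment is ≤ 8 nt and cannot form both the -1 and -2
Watson-Crick/wobble pairs is labelled a k-loop — the common situation for box
C'/D'.

A methylation target is reported from the 5-mer 3n,2n,1n,-1n,-2n. `is_drach`
is a plain IUPAC match of DRACH (D = A/G/U, R = A/G, H = A/C/U). `is_gac`
flags a methyl-transferase GAC target: the core triplet (2n,1n,-1n) is GAC
*and* the flanks complete DRACH. Defining the flag this way (rather than from
the bare triplet) makes "GAC target ⇒ DRACH instance" true by construction,
which is the biologically meaningful reading — a GAC core in a non-DRACH
context is not a preferred substrate; the raw triplet is reported separately
so no information is lost.

## Conservation statistics

Column frequencies exclude gaps from the denominator (the logo convention; an
inclusive mode sits behind a flag). The -1n column of an ortholog alignment is
found by projecting the annotated reference index through the reference row's
gaps; the conservation report is the percent of (non-gap) rows with C there.
The -1b/-1n joint distribution is tabulated over annotated sets as percents of
resolved rows, with unresolved rows excluded and counted. The
methylated-vs-unmethylated group comparison adds a two-sided Mann-Whitney U
with normal approximation (no continuity correction, so identical groups give
p = 1 exactly); the original comparison was purely visual, and the output says
the test is an addition.

## Site cross-referencing

Coordinates are 1-based inclusive throughout this module, converting from the
package's internal 0-based indices at the boundary. A1n maps to the genome as
`start + i` on the plus strand and `end − i` on the minus strand (transcript
5'→3' descends the genomic coordinate there). The join against an m6A site
table matches on chromosome and strand with |Δposition| ≤ slack (default 0:
the site tables are single-nucleotide resolution). Summaries count distinct
(chromosome, position, strand) as unique positions and collapse paralog
names — a single trailing capital letter is stripped exactly when another
record shares the stem (SNORD62A/SNORD62B → SNORD62), logged, never silent.
This is the rule that makes 19 sites resolve to 14 unique RNAs; a lone
suffixed name is left untouched. The 19 human + 1 mouse printed site records
ship as a package fixture.

## Binding models

**Folding isotherm.** Protein P binding RNA R two-state, with complex
concentration C the physically meaningful (smaller) root of
C² − C(P_T + R_T + 1/K_A) + P_T·R_T = 0 and E = E0 + ΔE·C/R_T. The printed
form of this equation is typographically garbled in its source (the
discriminant appears with no operators); the implementation is the
algebraically consistent two-state solution, which reproduces both stated
limits — E(0) = E0 and E → E0 + ΔE at saturation — and is evaluated in a
cancellation-free form (2PR / (b + √(b² − 4PR))) that stays exact in the
stoichiometric K_A → ∞ regime. The fitter is unweighted least squares (no
per-point σ is available) over (E0, ΔE, log10 K_A), initialized at the first
datum, last-minus-first, and K_A = 2/R_T, with E0, ΔE ∈ [−0.5, 1.5]. Because
L7Ae-family proteins bind k-turns with picomolar affinity, titrations at
200 nM RNA are essentially stoichiometric and K_A is weakly identified; the
fit reports an identifiability flag (standard error of log10 K_A < 1 decade
and |ΔE| bounded away from 0) instead of pretending otherwise.

**ITC.** The one-set-of-sites (Wiseman) model with explicit
displaced-volume bookkeeping: each injection of volume v into cell volume V0
dilutes every cell species by (1 − v/V0) and adds titrant at X0·v/V0; the
bound concentration is recomputed from the same quadratic with n sites per
RNA, and heat_i = ΔH·V0·(B_i − B_{i−1}(1 − v/V0)). The first (priming)
injection is excluded from the fit by default. Derived quantities use
ΔG = −RT ln K with R = 1.9872 cal mol⁻¹ K⁻¹, ΔS = (ΔH − ΔG)/T, Kd = 1/K.
Default schedule: 0.4 µl + 19 × 2 µl into 200 µl of 20 µM RNA with 200 µM
protein at 298 K.

## Structure geometry

Structures are read through gemmi (PDB or mmCIF), with atom-name dialects
unified (O2* → O2', O1P → OP1) and alternate locations resolved by highest
occupancy (ties by altloc letter); residues missing required base atoms are
flagged incomplete and excluded from classification. N6-methyladenine residue
codes (6MA/6MZ/M6A) classify as adenine, 5-bromocytosine codes as cytosine.

Crystal structures at the relevant resolutions have no hydrogens, so H-bonds
are called from heavy-atom donor-acceptor distance (default ≤ 3.5 Å — the
minimal cutoff consistent with the longest contact treated as a bond here,
3.4 Å) plus a donor-antecedent angle floor of 110° standing in for N/O-H
collinearity.

Edges follow the Leontis-Westhof atom sets. Two deliberate choices:

- The exocyclic C6/C4 substituents (A N6, G O6, C N4, U O4) sit on the
  boundary between the Watson-Crick and Hoogsteen edges. They are treated as
  shared and resolved toward whichever of the two edges the unambiguous atoms
  support; the unambiguous ("core") sets are disjoint per base.
- Votes are gathered per unique H-bonded atom over a distance-only window
  (≤ 3.6 Å, no angle filter), and a geometric vote — the edge whose
  representative direction best aligns with the partner's base centroid —
  is added with weight 1.5. The strict angle criterion guards *reported*
  H-bond lists; using it to gate the classification vote would let a single
  marginal bond dropping out of the window flip the call, whereas the
  centroid-based vote averages ~10 atoms and is stable. This is what makes
  classification exact under 0.2 Å coordinate noise. Pair *discovery* in
  whole-structure scans still uses the strict criteria, so stacking contacts
  do not spawn spurious pairs.

cis/trans is the sign-free dihedral test on (base centroid₁, C1'₁, C1'₂, base
centroid₂): below 90° the glycosidic attachments lie on the same side of the
C1'–C1' axis (cis). The centroid stands in for the glycosidic nitrogen to gain
a ~4.7 Å lever arm; on clean geometry the two definitions agree.

A sheared pair is a trans pair with G on the sugar edge and A on the
Hoogsteen edge; tandem occurrences are chain-adjacent sheared pairs. The
N6-methyl is placed in the base plane, 1.45 Å from N6 at the sp2 angle, anti
or syn to N1 across the C6–N6 bond; when the remaining N6-H must donate to an
acceptor (G N3 in the sheared pair), the methyl is forced into the other
slot — the geometric heart of the disruption. The clash check reports the
minimum heavy-atom distance from the methyl carbon to the partner's ribose
atoms against a 3.0 Å cutoff (≈ C/O van der Waals contact). Superposition is
a plain Kabsch SVD fit with a separately reportable RMSD selection; the fit
and report selections are explicit because the published superposition frame
is not stated.

## Synthetic data

Each generator draws from its own seeded stream (seed spawned per generator),
so outputs are bit-reproducible and adding a generator never perturbs
another. Defaults are the study conditions: FRET titrations at 200 nM RNA
plateauing at E_FRET = 0.6 with σ = 0.01; the ITC schedule above; -1b/-1n
pairs drawn at CG 65.27%, AU 8.78%, UA 4.96%, UG 4.20%, GC 3.82% with the
remainder uniform over the other eleven combinations.

Sequence flanks are rejection-sampled so the assembled snoRNA contains no
spurious box motifs; planted spans are therefore the unique best-scoring
annotation and recall against truth is a meaningful 100%-or-bug check. Real
snoRNAs are messier (degenerate boxes, pseudogenes, overlapping motifs), so
passing recall here demonstrates correctness of the annotation logic, not
performance on genomic data.

Duplexes are idealized A-form stacks (rise 2.81 Å, twist 32.7° — conventional
fiber values, constants of this package) of standard-frame bases, in which
the Watson-Crick partner is the 180° rotation about x. Ribose atoms are a
simplified fixed-pucker five-atom set. The planted sheared G·A geometry is
*solved*, not copied from any deposited file: a rigid-body-plus-sugar-torsion
optimization places guanine against the adenine Hoogsteen edge to realize the
target contacts GN2–AN7 = 2.8 Å, AN6–GN3 = 3.4 Å and AN6–G O2' = 3.0 Å with
plausible donor angles, a firmly trans glycosidic orientation and steric
floors (deterministic fixed multistart, Nelder-Mead, cached). The displaced
G/6MA arrangement starts from it and translates the adenine, mostly in plane,
until the former H-bond distances just exceed 6 Å while A N6 donates to the
guanosine O2' at 2.8 Å with no base-base polar contact within H-bond range.
These are synthetic stand-ins constructed to the published contact distances;
they are not the deposited coordinates, and the deposited-structure test in
the suite runs only when the real files are placed under `data/structures/`.

Generated duplexes do not emulate crystallographic disorder, solvent, or
sequence-dependent helical parameters; classifier accuracy on them bounds
logic errors, not performance on refined experimental models.

## Problem sizes

The test suite and acceptance script use: 100 FRET titrations of 12 points
for the recovery median; a 20-injection noise-free ITC series; 200-row
alignments for conservation recovery; 600 planted sequences for the pair
table; 6-8 duplexes of 8 bp per classifier condition (σ = 0.2 Å, random
rigid orientation); the full 1,024-context enumeration for the GAC/DRACH
invariant. These sizes give sampling errors well inside the asserted bounds
while keeping any single run in seconds.

## Known limitations

- The database-wide numbers of the original analysis (27 candidate snoRNAs,
  the exact 65.27% CG frequency, 100% SNORD71 conservation) depend on
  snoRNABase/snOPY/RMBase extracts that are not redistributable here; they
  are exercised as property-based checks on synthetic data plus the printed
  site-table fixture.
- Box C'/D' annotation uses a fixed mismatch budget and the core constraint
  as its rejection rule; truly degenerate D' boxes are reported as failures
  rather than recovered.
- The edge classifier targets the pair classes relevant here (WC, wobble,
  sheared G·A, unpaired); it is not a full annotation-parity replacement for
  comprehensive RNA structure annotators, and bifurcated or water-mediated
  pairs are out of scope.
- The ITC dilution bookkeeping is the explicit displacement model described
  above; instrument-specific correction conventions differ in the third
  decimal and are not emulated.
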