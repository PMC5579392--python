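# kturn-m6a

Analysis toolkit for a question in RNA epigenetics: can N6-methyladenine
(m6A) switch off the assembly of box C/D snoRNPs?

Box C/D snoRNAs fold their conserved box C (RUGAUGA) and box D (CUGA)
elements into a kink-turn (k-turn), whose core is two tandem sheared — trans
sugar-Hoogsteen — G·A base pairs (G1b·A1n and A2b·G2n). Binding of the
15.5-kDa protein to this k-turn is the first, obligatory step of snoRNP
assembly. When the -1n position is a cytosine, the non-bulged strand reads
**GAC** across (2n, 1n, -1n): the most common core of the METTL3/METTL14
target motif DRACH (D = A/G/U, R = A/G, H = A/C/U), putting the essential
A1n adenine at risk of N6-methylation. The package implements the full chain
of analyses that makes the case:

1. **Motif annotation** — locate box C/D and internal C'/D' elements, build
   the standard k-turn position map (-2b…3b, -2n…3n, L1-L3), and flag
   GAC/DRACH targets at A1n.
2. **Conservation** — column statistics over ortholog alignments; percent
   conservation of -1n = C with a methylated-vs-unmethylated comparison.
3. **Site cross-referencing** — map A1n to genomic coordinates and intersect
   with RMBase-style m6A site tables (the printed 19-site human table and the
   mouse record ship as a fixture).
4. **Binding models** — the protein-induced folding FRET isotherm
   E = E0 + ΔE·C/R_T, with C the smaller root of
   C² − C(P_T + R_T + 1/K_A) + P_T·R_T = 0, and the one-set-of-sites ITC
   model with ΔG = −RT ln K (R = 1.9872 cal mol⁻¹ K⁻¹), ΔS = (ΔH − ΔG)/T,
   Kd = 1/K.
5. **Structure geometry** — H-bond detection, Leontis-Westhof edge/orientation
   classification, sheared-G·A detection, idealized N6-methyl placement with
   a ribose clash check, and Kabsch superposition — showing *why* the methyl
   breaks the sheared pair (the N6-H slot that should carry the methyl is
   needed for the A N6 → G N3 bond, and the alternative slot collides with
   the opposing ribose) while Watson-Crick A-U pairs accommodate it.
6. **Synthetic data** — seeded generators for every input, with ground truth,
   so the whole pipeline is testable offline.

## Worked example

Generate a synthetic snoRNA set and scan it:

```bash
kturn-m6a simulate --what snorna --seed 11 --out-dir sim
kturn-m6a scan sim/snorna.fasta | head -3
```

```
id       role  boxC_start  boxC_end  boxD_start  boxD_end  a1n_pos  minus1n_base  context5  is_gac  is_drach  score  kturn_form  status
syn0000  boxD  7           13        24          27        27       A             UGAAC     False   False     0      boxCD       ok
syn0001  boxD  7           13        24          27        27       A             UGAAG     False   False     0      boxCD       ok
```

Each row is one detected k-turn (coordinates 1-based inclusive): `a1n_pos` is
the conserved adenine of the D box, `context5` the 5-mer 3n,2n,1n,-1n,-2n on
the non-bulged strand, and `is_gac` marks a GAC methylation target (which is
always also a DRACH instance). Fit a simulated titration:

```bash
kturn-m6a simulate --what fret --seed 3 --out-dir sim
kturn-m6a fitfret sim/fret.tsv
```

```json
{
  "E0": 0.3082858173865934,
  "dE_FRET": 0.2913366123660239,
  "K_A_per_M": 116737812.50876908,
  "E0_se": 0.009866000996685881,
  "dE_se": 0.013173368459049373,
  "log10_KA_se": 0.2579168042631251,
  "K_A_identifiable": true
}
```

E0 + ΔE ≈ 0.60 is the folded-state plateau at 200 nM RNA; in the
stoichiometric regime the fit flags K_A as weakly identified rather than
reporting a meaningless affinity.

The numbered scripts under `analysis/` run the complete narrative —
simulation, scanning, conservation, site cross-referencing, binding fits,
and base-pair geometry — writing tables under `results/` and printing what
each stage found, e.g. (from `analysis/06_structure_geometry.py`):

```
sheared pair: trans Hoogsteen/Sugar A·G; GN2-AN7 2.80 A, AN6-GN3 3.40 A, AN6-G O2' 3.00 A
N6-methyl (syn slot, the H-bonding slot is occupied): 1.71 A to G ribose O2' -> steric clash
Watson-Crick A-U with anti methyl: 8.90 A to partner ribose -> accommodated
```

## Layout

```
src/kturn_m6a/     library: motif_annotation, conservation, modsite_crossref,
                   binding_models, structure_geometry, synthetic_data,
                   pipeline, io, cli
analysis/          numbered narrative drivers over the library
tests/             pytest suite, including tests/test_acceptance.py
docs/methods.md    models, conventions, numerical choices, limitations
```
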