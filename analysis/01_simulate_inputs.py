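"""Generate the full synthetic input bundle used by the downstream analyses.

Writes snoRNA sequences with planted box C/D elements (plus truth), gene
models and an RMBase-style m6A site table over them, an ortholog alignment,
FRET and ITC titration series at the study conditions, and an idealized
duplex with a planted sheared G·A step.  Everything is seeded: re-running
reproduces the bundle byte for byte.
"""

import json
from pathlib import Path

from kturn_m6a import io as kio
from kturn_m6a import synthetic_data as syn

SEED = 20170616
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    scfg = syn.SnoRNAConfig(n_sequences=40)
    seqs, truth = syn.gen_snorna_set(scfg, SEED)
    kio.write_fasta(seqs, OUT / "snorna.fasta")
    truth.to_csv(OUT / "snorna_truth.tsv", sep="\t", index=False)
    n_c = int((truth.minus1n == "C").sum())
    print(f"snoRNA set: {len(seqs)} sequences, {n_c} with -1n=C "
          f"({int(truth.has_internal.sum())} carry a C'/D' element)")

    mcfg = syn.ModsiteConfig()
    genes = syn.gen_gene_models(seqs, mcfg, SEED)
    sites, site_truth = syn.gen_modsites(genes, truth, mcfg, SEED)
    kio.write_gene_models(genes, OUT / "genes.bed", OUT / "genes.fasta")
    kio.write_sites_tsv(sites, OUT / "sites.tsv")
    site_truth.to_csv(OUT / "sites_truth.tsv", sep="\t", index=False)
    print(f"site table: {len(sites)} records "
          f"({int(site_truth.methylated.sum())} true A1n sites, "
          f"{mcfg.n_decoys} decoys)")

    rows, atruth = syn.gen_alignment(syn.AlignmentConfig(n_rows=30), SEED)
    kio.write_stockholm(rows, OUT / "alignment.sto", atruth["family_id"])
    (OUT / "alignment_truth.json").write_text(json.dumps(atruth, indent=2))
    print(f"alignment: {len(rows)} rows, -1n conservation set to "
          f"{atruth['minus1n_conservation']}")

    fret, fparams = syn.gen_fret_curve(syn.FretConfig(), SEED)
    kio.write_fret_tsv(fret, OUT / "fret.tsv")
    itc, itruth = syn.gen_itc_series(syn.ITCConfig(sigma_cal=5e-8), SEED)
    kio.write_itc_tsv(itc, OUT / "itc.tsv")
    print("binding data: 12-point FRET titration (plateau "
          f"{fparams.e0 + fparams.de:.2f}), 20-injection ITC series")

    residues, dtruth = syn.gen_duplex_coords(
        syn.DuplexConfig(planted_class="sheared_GA"), SEED)
    syn.write_pdb(residues, OUT / "duplex_sheared.pdb")
    dtruth.to_csv(OUT / "duplex_truth.tsv", sep="\t", index=False)
    print("duplex: 8 bp with one planted sheared G·A step")


if __name__ == "__main__":
    main()
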