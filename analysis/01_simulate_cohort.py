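"""Generate the synthetic cohort all downstream scripts analyze.

Emits genome, gene models, replication-timing track, SNVs (with kataegis
foci injected), SVs, CNV segments, translocation labels, expression and
clinical tables — plus the planted truth — under results/cohort/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from config import COHORT, COHORT_DIR

from myelosig import synthetic as syn
from myelosig.sv import write_sv_table


def main() -> None:
    out = COHORT_DIR
    (out / "truth").mkdir(parents=True, exist_ok=True)
    rngs = syn.substreams(COHORT.seed)

    genome = syn.simulate_genome(COHORT, rngs["genome"])
    muts, true_exp = syn.simulate_mutations(COHORT, genome, rngs["mutations"])
    muts, foci_truth = syn.inject_kataegis(muts, COHORT, genome,
                                           rngs["kataegis"])
    ids = list(true_exp.index)
    svs, true_rs = syn.simulate_svs(COHORT, ids, rng=rngs["sv"])
    cnv, hd_truth, tra = syn.simulate_cnv(COHORT, ids, rng=rngs["cnv"])
    clinical = syn.simulate_clinical(COHORT, ids, rng=rngs["clinical"])
    fpkm = syn.simulate_expression(COHORT, genome.genes, ids,
                                   rngs["expression"])

    syn.write_fasta(genome.contigs, out / "genome.fa")
    genome.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    genome.timing.bins[["chrom", "start", "end", "signal"]].to_csv(
        out / "timing.bedgraph", sep="\t", header=False, index=False)
    muts.to_csv(out / "mutations.tsv", sep="\t", index=False)
    write_sv_table(svs, out / "svs.tsv")
    cnv.to_csv(out / "cnv.tsv", sep="\t", index=False)
    tra.rename_axis("sample_id").to_frame().to_csv(
        out / "translocations.tsv", sep="\t")
    clinical.to_csv(out / "clinical.tsv", sep="\t")
    fpkm.rename_axis("gene").to_csv(out / "fpkm.tsv", sep="\t")
    true_exp.to_csv(out / "truth" / "exposures.tsv", sep="\t")
    true_rs.to_csv(out / "truth" / "rs_exposures.tsv", sep="\t")
    foci_truth.to_csv(out / "truth" / "kataegis_foci.tsv", sep="\t",
                      index=False)
    hd_truth.rename_axis("sample_id").to_frame().to_csv(
        out / "truth" / "hyperdiploidy.tsv", sep="\t")
    COHORT.signatures().write_tsv(out / "truth" / "signatures.tsv")
    COHORT.rs_profiles().write_tsv(out / "truth" / "rs_profiles.tsv")

    print(f"cohort written to {out}")
    print(f"  {len(ids)} samples, {len(muts)} SNVs, {len(svs)} SVs, "
          f"{len(foci_truth)} injected kataegis foci, "
          f"{int(hd_truth.sum())} hyperdiploid samples")


if __name__ == "__main__":
    main()
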