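"""End-to-end pipeline over a synthetic cohort.

Runs every analysis stage on one simulated cohort and writes its tables
under an output directory: cohort emission, catalog construction with the
immune/clonality filters, de novo extraction and reference assignment,
per-mutation attribution, regional contrast, replication/transcription
analyses, kataegis, rearrangement signatures, karyotype and subgroup
enrichment, and consensus clustering with survival staging. Outputs are
plain TSV/JSON with fixed float formatting, byte-reproducible per seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    catalog as cat_mod,
    cluster_survival as cs,
    kataegis as kat_mod,
    regional,
    replitrans as rt,
    signatures as sig_mod,
    subgroups as sg,
    sv as sv_mod,
    synthetic as syn,
)

FLOAT_FMT = "%.6g"


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def run_pipeline(config: syn.SimulationConfig, outdir) -> dict:
    """Run the full analysis chain; returns a summary dict (also written
    as summary.json under ``outdir``)."""
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    rngs = syn.substreams(config.seed)

    # ---- cohort -----------------------------------------------------------
    genome = syn.simulate_genome(config, rngs["genome"])
    muts, true_exp = syn.simulate_mutations(config, genome, rngs["mutations"])
    muts, foci_truth = syn.inject_kataegis(muts, config, genome, rngs["kataegis"])
    sample_ids = list(true_exp.index)
    svs, true_rs_exp = syn.simulate_svs(config, sample_ids, rng=rngs["sv"])
    cnv, hd_truth, tra = syn.simulate_cnv(config, sample_ids, rng=rngs["cnv"])
    clinical = syn.simulate_clinical(config, sample_ids, rng=rngs["clinical"])
    fpkm = syn.simulate_expression(config, genome.genes, sample_ids,
                                   rngs["expression"])

    syn.write_fasta(genome.contigs, out / "genome.fa")
    _write(genome.genes, out / "genes.tsv", index=False)
    genome.timing.bins[["chrom", "start", "end", "signal"]].to_csv(
        out / "timing.bedgraph", sep="\t", header=False, index=False,
        float_format=FLOAT_FMT)
    _write(muts, out / "mutations.tsv", index=False)
    sv_mod.write_sv_table(svs, out / "svs.tsv")
    _write(cnv, out / "cnv.tsv", index=False)
    _write(clinical, out / "clinical.tsv")
    _write(fpkm.rename_axis("gene"), out / "fpkm.tsv")
    _write(true_exp, out / "truth" / "exposures.tsv")
    _write(true_rs_exp, out / "truth" / "rs_exposures.tsv")
    _write(foci_truth, out / "truth" / "kataegis_foci.tsv", index=False)
    true_sigs = config.signatures()
    true_sigs.write_tsv(out / "truth" / "signatures.tsv")

    # ---- catalog with filters --------------------------------------------
    # a small immune-like exclusion zone at the start of chr1, pre-extended
    immune = cat_mod.RegionSet.from_intervals(
        "immune", [("chr1", 0, 5_000)]).extend(2_000)
    mut_objs = syn.mutations_frame_to_objects(muts)
    kept = cat_mod.filter_immune_regions(mut_objs, immune)
    catalog = cat_mod.build_catalog(kept, genome.contigs, samples=sample_ids)
    cat_mod.write_catalog(catalog, out / "catalog.tsv")

    # ---- signatures -------------------------------------------------------
    k_range = range(2, min(config.n_signatures + 3, len(sample_ids)))
    de_novo, _, diag = sig_mod.extract_de_novo(
        catalog, k_range=k_range, n_restarts=8, seed=config.seed)
    assignment = sig_mod.assign_to_reference(de_novo, true_sigs)
    exposures = sig_mod.fit_exposures(catalog, true_sigs)
    _write(exposures, out / "exposures.tsv")
    _write(diag.table, out / "rank_diagnostics.tsv", index=False)
    pd.DataFrame(
        [{"de_novo": k, "reference": v[0], "cosine": v[1]}
         for k, v in assignment.items()]
    ).to_csv(out / "assignment.tsv", sep="\t", index=False,
             float_format=FLOAT_FMT)

    # ---- attribution ------------------------------------------------------
    frame = muts.reset_index(drop=True)
    attribution = sig_mod.attribute_mutations(
        frame["category"], frame["sample_id"], exposures, true_sigs)
    _write(attribution, out / "attribution.tsv", index=False)

    # ---- regional contrast: genic vs intergenic --------------------------
    genic = cat_mod.RegionSet.from_intervals(
        "genic", [(r.chrom, r.start, r.end) for r in genome.genes.itertuples()])
    inter_ivals = []
    for chrom, seq in genome.contigs.items():
        arr = genic.intervals.get(chrom)
        prev = 0
        if arr is not None:
            for s, e in arr:
                if s > prev:
                    inter_ivals.append((chrom, prev, int(s)))
                prev = int(e)
        if prev < len(seq):
            inter_ivals.append((chrom, prev, len(seq)))
    intergenic = cat_mod.RegionSet.from_intervals("intergenic", inter_ivals)
    contrast = regional.compare_regions(
        frame, attribution, intergenic, genic, genome.contigs, seed=config.seed)
    _write(contrast, out / "region_contrast.tsv", index=False)

    drivers = sorted(frame["gene"].dropna().value_counts().head(5).index)
    driver_res = regional.driver_contrast(frame, attribution, drivers)
    _write(driver_res, out / "driver_contrast.tsv", index=False)

    # ---- replication / transcription -------------------------------------
    deciles = rt.assign_timing(frame, genome.timing)
    rates = rt.rate_by_decile(frame, genome.timing, deciles)
    slope, slope_p = rt.permutation_slope_test(rates, n_perm=2_000,
                                               seed=config.seed)
    rep_strand = rt.assign_replication_strand(frame, genome.timing)
    rep_asym = rt.strand_asymmetry(frame, rep_strand, attribution,
                                   axis="replication")
    txn_strand = rt.assign_transcription_strand(frame, genome.genes)
    txn_asym = rt.strand_asymmetry(frame, txn_strand, attribution,
                                   axis="transcription")
    pent = rt.expression_pentiles(fpkm)
    gene_lengths = pd.Series(
        (genome.genes["end"] - genome.genes["start"]).to_numpy(),
        index=genome.genes["gene"].to_numpy())
    expr_rates = rt.rate_by_expression(frame, pent, gene_lengths)
    _write(rates.to_frame(), out / "decile_rates.tsv")
    _write(rep_asym, out / "replication_asymmetry.tsv", index=False)
    _write(txn_asym, out / "transcription_asymmetry.tsv", index=False)
    _write(expr_rates, out / "expression_rates.tsv", index=False)

    # ---- kataegis ---------------------------------------------------------
    foci = kat_mod.detect_kataegis(frame)
    enrich = kat_mod.focus_enrichment(frame, foci, attribution)
    frac_foci_near_sv, frac_sv_near_foci = kat_mod.colocalize_sv(foci, svs)
    _write(kat_mod.foci_to_bed(foci), out / "kataegis.bed", index=False)
    _write(enrich, out / "kataegis_enrichment.tsv", index=False)

    # ---- rearrangement signatures ----------------------------------------
    sv_catalog = sv_mod.build_sv_catalog(svs, samples=sample_ids)
    rs_sigs, rs_exp, rs_diag = sv_mod.extract_rs(
        sv_catalog, k_range=range(2, config.n_rs + 3), n_restarts=8,
        seed=config.seed)
    rs_corr = sv_mod.correlate_rs_snv(rs_exp, exposures)
    _write(sv_catalog, out / "sv_catalog.tsv")
    _write(rs_exp, out / "rs_exposures.tsv")
    _write(rs_corr, out / "rs_snv_correlation.tsv", index=False)

    # ---- karyotype + subgroup enrichment ---------------------------------
    segs_by_sample: dict[str, list] = {sid: [] for sid in sample_ids}
    for r in cnv.itertuples():
        segs_by_sample[r.sample_id].append(
            sg.CNVSegment(r.sample_id, r.chrom, int(r.start), int(r.end),
                          float(r.log2_ratio)))
    karyo = sg.karyotype_table(
        segs_by_sample, syn.default_chrom_sizes(),
        sg.cytoband_regions(syn.cytoband_fixture()), translocations=tra)
    subgroup_label = karyo["translocation"].where(
        ~karyo["hyperdiploid"] | (karyo["translocation"] != "none"), "HD")
    enr = sg.enrichment_test(exposures, subgroup_label)
    _write(karyo, out / "karyotype.tsv")
    _write(enr, out / "subgroup_enrichment.tsv", index=False)

    # ---- clustering + survival -------------------------------------------
    snv_prop = sig_mod.normalize_exposures(
        exposures[sig_mod.major_signatures(exposures)])
    rs_prop = sig_mod.normalize_exposures(rs_exp)
    features = pd.concat([snv_prop, rs_prop], axis=1).fillna(0.0)
    model = cs.consensus_cluster(
        features, k_range=range(2, 5),
        n_resamples=60, seed=config.seed)
    lr_stat, lr_p = cs.logrank(model.labels, clinical["pfs_time"],
                               clinical["pfs_event"])
    tiers = cs.delineate_risk(model.labels, clinical["pfs_time"],
                              clinical["pfs_event"])
    _write(model.labels.to_frame().join(
        tiers.rename("risk_tier"), on="cluster"), out / "clusters.tsv")

    summary = {
        "n_samples": len(sample_ids),
        "n_mutations": int(len(frame)),
        "n_svs": len(svs),
        "chosen_k_snv": int(diag.chosen_k),
        "chosen_k_rs": int(rs_diag.chosen_k),
        "n_assigned_signatures": sum(1 for v in assignment.values()
                                     if v[0] != "novel"),
        "timing_slope": round(float(slope), 6),
        "timing_slope_p": round(float(slope_p), 6),
        "n_kataegis_foci": len(foci),
        "frac_foci_near_sv": (None if np.isnan(frac_foci_near_sv)
                              else round(frac_foci_near_sv, 4)),
        "frac_sv_near_foci": (None if np.isnan(frac_sv_near_foci)
                              else round(frac_sv_near_foci, 4)),
        "n_clusters": int(model.chosen_k),
        "logrank_p": round(float(lr_p), 6),
        "n_significant_subgroup_pairs": int(enr["significant"].sum()),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
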