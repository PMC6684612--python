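"""Synthetic cohort generator: planted structure and determinism."""

import numpy as np
import pandas as pd
import pytest

from myelosig.catalog import build_catalog
from myelosig.replitrans import (
    assign_replication_strand,
    assign_timing,
    permutation_slope_test,
    rate_by_decile,
)
from myelosig.signatures import cosine_similarity
from myelosig.subgroups import CNVSegment, call_hyperdiploidy
from myelosig.kataegis import detect_kataegis
from myelosig.sv import build_sv_catalog
from myelosig.synthetic import (
    SimulationConfig,
    block_signatures,
    default_chrom_sizes,
    inject_kataegis,
    mutations_frame_to_objects,
    read_fasta,
    simulate_clinical,
    simulate_cnv,
    simulate_genome,
    simulate_mutations,
    simulate_svs,
    substreams,
    write_fasta,
)


class TestGenome:
    def test_gc_content_within_binomial_bound(self):
        cfg = SimulationConfig(seed=1, contig_sizes={"chr1": 1_000_000},
                               gc_content=0.5, n_genes=0)
        g = simulate_genome(cfg)
        seq = g.contigs["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01

    def test_zero_genes_gives_empty_table(self):
        cfg = SimulationConfig(seed=1, n_genes=0)
        assert simulate_genome(cfg).genes.empty

    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=9, contig_sizes={"chr1": 50_000})
        a, b = simulate_genome(cfg), simulate_genome(cfg)
        write_fasta(a.contigs, tmp_path / "a.fa")
        write_fasta(b.contigs, tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert read_fasta(tmp_path / "a.fa") == a.contigs

    def test_short_contig_rejected(self):
        with pytest.raises(ValueError, match="10 kb"):
            simulate_genome(SimulationConfig(contig_sizes={"c": 5_000}))


class TestMutations:
    def test_single_signature_catalog_converges_to_profile(self):
        cfg = SimulationConfig(seed=2, n_samples=1, n_signatures=1,
                               mutations_per_sample=10_000)
        g = simulate_genome(cfg)
        muts, _ = simulate_mutations(cfg, g)
        cat = build_catalog(mutations_frame_to_objects(muts), g.contigs)
        truth = block_signatures(1).matrix()[0]
        assert cosine_similarity(cat.to_numpy()[0], truth) > 0.99

    def test_flat_timing_gives_uniform_decile_p(self):
        cfg = SimulationConfig(seed=3, n_samples=10, mutations_per_sample=400)
        g = simulate_genome(cfg)
        muts, _ = simulate_mutations(cfg, g)
        rates = rate_by_decile(muts, g.timing)
        _, p = permutation_slope_test(rates, n_perm=2_000, seed=0)
        assert p > 0.01

    def test_planted_timing_slope_recovered(self):
        slope = {f"S{i+1}": 1.5 for i in range(5)}
        cfg = SimulationConfig(seed=4, n_samples=10, mutations_per_sample=500,
                               timing_slope=slope)
        g = simulate_genome(cfg)
        muts, _ = simulate_mutations(cfg, g)
        rates = rate_by_decile(muts, g.timing)
        obs, p = permutation_slope_test(rates, n_perm=2_000, seed=0)
        assert obs > 0 and p < 0.01  # more mutations in late deciles

    def test_planted_lagging_bias_recovered(self):
        bias = {f"S{i+1}": 0.7 for i in range(5)}
        cfg = SimulationConfig(seed=5, n_samples=10,
                               mutations_per_sample=1_000, lagging_bias=bias)
        g = simulate_genome(cfg)
        muts, _ = simulate_mutations(cfg, g)
        strand = assign_replication_strand(muts, g.timing)
        n_lag = (strand == "lagging").sum()
        n_lead = (strand == "leading").sum()
        imb = (n_lag - n_lead) / (n_lag + n_lead)
        assert imb == pytest.approx(0.4, abs=0.05)

    def test_exposures_match_mutation_counts(self):
        cfg = SimulationConfig(seed=6, n_samples=8)
        g = simulate_genome(cfg)
        muts, exp = simulate_mutations(cfg, g)
        per_sample = muts.groupby("sample_id").size()
        assert (exp.sum(axis=1).sort_index() == per_sample.sort_index()).all()


class TestKataegisInjection:
    def test_injected_foci_are_detected(self):
        cfg = SimulationConfig(seed=7, n_samples=10, mutations_per_sample=30,
                               kataegis_rate=0.8, kataegis_signature="S2")
        g = simulate_genome(cfg)
        muts, _ = simulate_mutations(cfg, g)
        muts, truth = inject_kataegis(muts, cfg, g)
        assert len(truth) >= 5
        foci = detect_kataegis(muts)
        hits = 0
        for t in truth.itertuples():
            hits += any(f.sample_id == t.sample_id and f.chrom == t.chrom
                        and f.start <= t.end and t.start <= f.end
                        for f in foci)
        assert hits >= len(truth) - 1  # nearly all truth foci rediscovered

    def test_zero_rate_injects_nothing(self):
        cfg = SimulationConfig(seed=8, n_samples=5, mutations_per_sample=30,
                               kataegis_rate=0.0, kataegis_signature="S1")
        g = simulate_genome(cfg)
        muts, _ = simulate_mutations(cfg, g)
        out, truth = inject_kataegis(muts, cfg, g)
        assert len(out) == len(muts) and truth.empty
        # sparse background alone produces (almost) no foci
        assert len(detect_kataegis(muts)) == 0

    def test_injected_records_consistent_with_genome(self):
        cfg = SimulationConfig(seed=9, n_samples=4, mutations_per_sample=20,
                               kataegis_rate=1.0, kataegis_signature="S3")
        g = simulate_genome(cfg)
        muts, _ = simulate_mutations(cfg, g)
        out, _ = inject_kataegis(muts, cfg, g)
        for r in out.itertuples():
            assert g.contigs[r.chrom][r.pos - 1] == r.ref


class TestSVCNVClinical:
    def test_sv_catalog_counts_conserved(self):
        cfg = SimulationConfig(seed=10, sv_per_sample=30)
        ids = [f"MM{i:04d}" for i in range(1, 21)]
        svs, true_exp = simulate_svs(cfg, ids)
        cat = build_sv_catalog(svs, samples=ids)
        assert (cat.sum(axis=1).to_numpy() ==
                true_exp.sum(axis=1).to_numpy()).all()

    def test_planted_hd_samples_called(self):
        cfg = SimulationConfig(seed=11, hd_fraction=0.5)
        ids = [f"MM{i:04d}" for i in range(1, 31)]
        cnv, hd_truth, tra = simulate_cnv(cfg, ids)
        sizes = default_chrom_sizes()
        agree = 0
        for sid in ids:
            segs = [CNVSegment(r.sample_id, r.chrom, int(r.start), int(r.end),
                               float(r.log2_ratio))
                    for r in cnv[cnv["sample_id"] == sid].itertuples()]
            agree += call_hyperdiploidy(segs, sizes) == hd_truth[sid]
        assert agree == len(ids)
        assert set(tra.index) == set(ids)

    def test_planted_hr_shifts_survival(self):
        cfg = SimulationConfig(seed=12, group_hrs={"hi": 3.0})
        ids = [f"s{i}" for i in range(400)]
        groups = pd.Series(["hi"] * 200 + ["lo"] * 200, index=ids)
        clin = simulate_clinical(cfg, ids, group_labels=groups)
        med_hi = clin.loc[groups == "hi", "pfs_time"].median()
        med_lo = clin.loc[groups == "lo", "pfs_time"].median()
        assert med_hi < med_lo

    def test_zero_svs_give_empty_list(self):
        cfg = SimulationConfig(seed=13, sv_per_sample=0.0)
        svs, exp = simulate_svs(cfg, ["a", "b"])
        assert svs == [] and exp.to_numpy().sum() == 0


def test_substreams_are_named_and_independent():
    s1 = substreams(123)
    s2 = substreams(123)
    a = s1["mutations"].random(3)
    # consuming the genome stream does not shift the mutations stream
    s2["genome"].random(1000)
    b = s2["mutations"].random(3)
    np.testing.assert_array_equal(a, b)
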