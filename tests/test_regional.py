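"""Trinucleotide-composition normalization and region/driver contrasts."""

import numpy as np
import pandas as pd
import pytest

from myelosig.catalog import RegionSet
from myelosig.regional import (
    compare_regions,
    count_opportunities,
    driver_contrast,
    exclude_recurrent,
    mutations_to_frame,
    normalize_counts,
)
from myelosig.signatures import attribute_mutations, fit_exposures
from myelosig.synthetic import (
    SimulationConfig,
    block_signatures,
    mutations_frame_to_objects,
    simulate_genome,
    simulate_mutations,
)
from myelosig.catalog import build_catalog


class TestOpportunities:
    def test_hand_enumerated_4mer(self):
        ref = {"c": "ACGT"}
        region = RegionSet.from_intervals("r", [("c", 0, 4)])
        V, W = count_opportunities(region, ref)
        # interior positions: ACG (C-centered) and CGT -> revcomp ACG
        assert W == 4
        assert V["ACG"] == 2
        assert sum(V.values()) == 2

    def test_homopolymer_counts_only_reverse_complement_class(self):
        # poly-A offers opportunities solely through the minus strand:
        # every interior AAA 3-mer collapses to the TTT pyrimidine class
        ref = {"c": "A" * 50}
        V, W = count_opportunities(RegionSet.from_intervals("r", [("c", 0, 50)]),
                                   ref)
        assert V["TTT"] == 48
        assert sum(V.values()) == 48
        assert W == 50

    def test_totals_equal_scannable_positions(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
        ref = {"c": seq}
        V, W = count_opportunities(RegionSet.from_intervals("r", [("c", 0, 10_000)]),
                                   ref)
        assert W == 10_000
        assert sum(V.values()) == 9_998  # every interior position is unambiguous

    def test_interval_beyond_contig_raises(self):
        with pytest.raises(ValueError, match="beyond contig"):
            count_opportunities(RegionSet.from_intervals("r", [("c", 0, 10)]),
                                {"c": "ACGT"})


class TestNormalizeCounts:
    def test_printed_example(self):
        assert normalize_counts(12, V_CX=60, V_CY=30, W_X=900, W_Y=300) == 18

    def test_identity_under_equal_composition(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            U = int(rng.integers(0, 500))
            V = int(rng.integers(1, 5_000))
            W = int(rng.integers(V, 50_000))
            assert normalize_counts(U, V, V, W, W) == U

    def test_zero_count_stays_zero(self):
        assert normalize_counts(0, 1, 99, 5, 7) == 0

    def test_homogeneity_before_rounding(self):
        a = normalize_counts(100, 60, 30, 900, 300)
        b = normalize_counts(200, 60, 30, 900, 300)
        assert b == 2 * a

    def test_rounds_half_away_from_zero(self):
        # 1 * (1 * 3) / (2 * 1) = 1.5 -> 2
        assert normalize_counts(1, 2, 1, 3, 1) == 2

    def test_impossible_context_raises(self):
        with pytest.raises(ValueError, match="zero opportunities"):
            normalize_counts(5, 0, 10, 100, 100)


@pytest.fixture(scope="module")
def attributed_cohort():
    cfg = SimulationConfig(seed=13, n_samples=40, mutations_per_sample=400,
                           contig_sizes={"chr1": 500_000}, n_genes=60)
    genome = simulate_genome(cfg)
    muts, _ = simulate_mutations(cfg, genome)
    sigs = cfg.signatures()
    catalog = build_catalog(mutations_frame_to_objects(muts), genome.contigs)
    exposures = fit_exposures(catalog, sigs)
    attribution = attribute_mutations(muts["category"], muts["sample_id"],
                                      exposures, sigs)
    return cfg, genome, muts, attribution


class TestCompareRegions:
    def _halves(self, genome):
        size = len(genome.contigs["chr1"])
        x = RegionSet.from_intervals("x", [("chr1", 0, int(size * 0.6))])
        y = RegionSet.from_intervals("y", [("chr1", int(size * 0.6), size)])
        return x, y

    def test_null_regions_not_flagged(self, attributed_cohort):
        cfg, genome, muts, attribution = attributed_cohort
        x, y = self._halves(genome)
        out = compare_regions(muts, attribution, x, y, genome.contigs, seed=0)
        assert out["significant"].sum() == 0

    def test_overlapping_regions_raise(self, attributed_cohort):
        cfg, genome, muts, attribution = attributed_cohort
        x = RegionSet.from_intervals("x", [("chr1", 0, 300_000)])
        y = RegionSet.from_intervals("y", [("chr1", 200_000, 500_000)])
        with pytest.raises(ValueError, match="overlap"):
            compare_regions(muts, attribution, x, y, genome.contigs)

    def test_planted_enrichment_is_flagged(self):
        """A signature active only inside region X must be detected."""
        cfg = SimulationConfig(seed=14, n_samples=40,
                               mutations_per_sample=300,
                               contig_sizes={"chr1": 500_000})
        genome = simulate_genome(cfg)
        muts, _ = simulate_mutations(cfg, genome)
        sigs = cfg.signatures()
        catalog = build_catalog(mutations_frame_to_objects(muts),
                                genome.contigs)
        exposures = fit_exposures(catalog, sigs)
        attribution = attribute_mutations(muts["category"], muts["sample_id"],
                                          exposures, sigs)
        # relocate S1-generated mutations into the first 60% of the contig
        # (the larger region, so it keeps the X designation)
        x_end = 300_000
        pos = muts["pos"].to_numpy().copy()
        is_s1 = (muts["true_signature"] == "S1").to_numpy()
        pos[is_s1] = pos[is_s1] % (x_end - 10) + 5
        muts = muts.assign(pos=pos)
        x = RegionSet.from_intervals("x", [("chr1", 0, x_end)])
        y = RegionSet.from_intervals("y", [("chr1", x_end, 500_000)])
        out = compare_regions(muts, attribution, x, y, genome.contigs, seed=0)
        assert out["region_x"].iloc[0] == "x"
        row = out.set_index("signature").loc["S1"]
        assert row["significant"]
        assert row["mean_prop_x"] > row["mean_prop_y"]

    def test_swapping_labels_reproduces_q_values(self, attributed_cohort):
        cfg, genome, muts, attribution = attributed_cohort
        x, y = self._halves(genome)
        a = compare_regions(muts, attribution, x, y, genome.contigs, seed=0)
        b = compare_regions(muts, attribution, y, x, genome.contigs, seed=0)
        np.testing.assert_allclose(a["q"], b["q"])


class TestDriverContrast:
    def test_recurrent_exclusion_noop_without_recurrence(self, attributed_cohort):
        cfg, genome, muts, attribution = attributed_cohort
        no_recurrent = exclude_recurrent(muts)
        if len(no_recurrent) == len(muts):
            drivers = list(muts["gene"].dropna().unique())[:3]
            a = driver_contrast(muts, attribution, drivers,
                                mode="include_recurrent")
            b = driver_contrast(muts, attribution, drivers,
                                mode="exclude_recurrent")
            pd.testing.assert_frame_equal(a, b)

    def test_exclude_recurrent_drops_shared_positions(self):
        muts = pd.DataFrame({
            "sample_id": ["a", "b", "a"],
            "chrom": ["chr1"] * 3,
            "pos": [100, 100, 200],
            "alt": ["T", "T", "G"],
            "sample": ["a", "b", "a"],
        })
        out = exclude_recurrent(muts)
        assert list(out["pos"]) == [200]

    def test_planted_driver_signature_flagged(self, attributed_cohort):
        cfg, genome, muts, attribution = attributed_cohort
        # fabricate a driver gene whose mutations are purely S2-generated
        muts = muts.copy()
        is_s2 = muts["true_signature"] == "S2"
        target = is_s2 & (np.arange(len(muts)) % 3 == 0)
        muts.loc[target, "gene"] = "DRV1"
        out = driver_contrast(muts, attribution, ["DRV1"])
        row = out.set_index(["gene", "signature"]).loc[("DRV1", "S2")]
        assert row["significant"]
        assert row["mean_gene"] > row["mean_rest"]

    def test_absent_gene_skipped(self, attributed_cohort):
        cfg, genome, muts, attribution = attributed_cohort
        out = driver_contrast(muts, attribution, ["NOT_A_GENE"])
        assert out.empty


def test_mutations_to_frame_annotates_categories(attributed_cohort):
    cfg, genome, muts, _ = attributed_cohort
    objs = mutations_frame_to_objects(muts.head(50))
    frame = mutations_to_frame(objs, genome.contigs)
    assert (frame["category"].to_numpy() ==
            muts.head(50)["category"].to_numpy()).all()
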