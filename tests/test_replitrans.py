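"""Replication timing, strand asymmetry and expression-rate analyses."""

import numpy as np
import pandas as pd
import pytest

from myelosig.replitrans import (
    TimingTrack,
    assign_replication_strand,
    assign_timing,
    assign_transcription_strand,
    expression_pentiles,
    permutation_slope_test,
    rate_by_decile,
    rate_by_expression,
    strand_asymmetry,
)


@pytest.fixture(scope="module")
def track():
    """100 bins of 10 kb with a linear signal: decile boundaries exact."""
    bins = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(100) * 10_000,
        "end": (np.arange(100) + 1) * 10_000,
        "signal": np.linspace(100, 1, 100),
    })
    return TimingTrack(bins)


class TestTrack:
    def test_deciles_have_equal_bp_mass(self, track):
        bp = track.decile_bp()
        assert (abs(bp - bp.mean()) / bp.mean() <= 0.02).all()

    def test_highest_signal_is_decile_one(self, track):
        b = track.bins
        assert b.loc[b["signal"].idxmax(), "decile"] == 1
        assert b.loc[b["signal"].idxmin(), "decile"] == 10

    def test_overlapping_bins_rejected(self):
        bins = pd.DataFrame({"chrom": "chr1", "start": [0, 500],
                             "end": [1000, 1500], "signal": [1.0, 2.0]})
        with pytest.raises(ValueError, match="overlapping"):
            TimingTrack(bins)


class TestAssignTiming:
    def test_position_maps_to_containing_bin(self, track):
        muts = pd.DataFrame({"chrom": ["chr1"], "pos": [5]})
        assert assign_timing(muts, track).iloc[0] == 1

    def test_gap_is_unassigned(self, track):
        muts = pd.DataFrame({"chrom": ["chr1", "chr2"],
                             "pos": [2_000_000, 100]})
        out = assign_timing(muts, track)
        assert out.isna().all()

    def test_matches_naive_scan(self, track):
        rng = np.random.default_rng(0)
        muts = pd.DataFrame({"chrom": "chr1",
                             "pos": rng.integers(1, 1_200_000, 300)})
        fast = assign_timing(muts, track)
        b = track.bins
        for i, (c, p) in enumerate(zip(muts["chrom"], muts["pos"])):
            hit = b[(b["chrom"] == c) & (b["start"] <= p - 1) & (p - 1 < b["end"])]
            expect = float(hit["decile"].iloc[0]) if len(hit) else np.nan
            assert (np.isnan(expect) and np.isnan(fast.iloc[i])) or \
                fast.iloc[i] == expect


class TestRates:
    def test_uniform_mutations_give_equal_rates(self, track):
        # one mutation per bin -> equal counts per equal-mass decile
        muts = pd.DataFrame({"chrom": "chr1",
                             "pos": np.arange(100) * 10_000 + 5_000})
        rates = rate_by_decile(muts, track)
        assert rates.nunique() == 1

    def test_all_mutations_in_one_decile(self, track):
        late = track.bins[track.bins["decile"] == 10].iloc[0]
        muts = pd.DataFrame({"chrom": "chr1",
                             "pos": [late["start"] + 10] * 7})
        rates = rate_by_decile(muts, track)
        assert rates[10] > 0
        assert rates.drop(10).sum() == 0

    def test_planted_gradient_is_monotone(self, track):
        rng = np.random.default_rng(1)
        pos = []
        for _, b in track.bins.iterrows():
            lam = 2 * (b["decile"] - 1) + 1
            pos.extend(rng.integers(b["start"] + 1, b["end"], rng.poisson(lam)))
        muts = pd.DataFrame({"chrom": "chr1", "pos": sorted(pos)})
        rates = rate_by_decile(muts, track)
        assert rates.corr(pd.Series(rates.index, index=rates.index),
                          method="spearman") > 0.9


class TestSlopeTest:
    def test_constant_rates_give_p_one(self):
        rates = pd.Series(2.0, index=range(1, 11))
        slope, p = permutation_slope_test(rates, n_perm=100, seed=0)
        assert slope == 0.0 and p == 1.0

    def test_strong_gradient_hits_resolution_floor(self):
        rates = pd.Series(np.arange(10, dtype=float) * 5, index=range(1, 11))
        slope, p = permutation_slope_test(rates, n_perm=10_000, seed=0)
        assert slope == pytest.approx(5.0)
        assert p == pytest.approx(1 / 10_001)

    def test_add_one_p_never_zero_and_bounded(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            rates = pd.Series(rng.gamma(3, 1, 10), index=range(1, 11))
            _, p = permutation_slope_test(rates, n_perm=200, seed=3)
            assert 1 / 201 <= p <= 1.0

    def test_too_few_deciles_raise(self):
        with pytest.raises(ValueError):
            permutation_slope_test(pd.Series([1.0, 2.0]), n_perm=10, seed=0)


class TestReplicationStrand:
    def single_peak_track(self):
        # signal rises then falls: peak at the center
        sig = np.concatenate([np.linspace(1, 50, 25), np.linspace(50, 1, 25)])
        bins = pd.DataFrame({"chrom": "chr1",
                             "start": np.arange(50) * 1_000,
                             "end": (np.arange(50) + 1) * 1_000,
                             "signal": sig})
        return TimingTrack(bins)

    def test_fork_polarity_flips_at_peak(self):
        track = self.single_peak_track()
        muts = pd.DataFrame({"chrom": "chr1", "pos": [5_000, 45_000],
                             "ref": ["C", "C"]})
        out = assign_replication_strand(muts, track)
        assert set(out) == {"leading", "lagging"}

    def test_complement_recording_flips_strand_call(self):
        track = self.single_peak_track()
        muts = pd.DataFrame({"chrom": "chr1", "pos": [5_000, 5_000],
                             "ref": ["C", "G"]})
        out = assign_replication_strand(muts, track)
        assert {out.iloc[0], out.iloc[1]} == {"leading", "lagging"}

    def test_positions_at_extrema_unassigned(self):
        track = self.single_peak_track()
        peak_bin = track.bins.loc[track.bins["fork_dir"] == 0].iloc[0]
        muts = pd.DataFrame({"chrom": "chr1",
                             "pos": [peak_bin["start"] + 1], "ref": ["C"]})
        assert assign_replication_strand(muts, track).iloc[0] == "unassigned"


class TestAsymmetry:
    def _frame(self, n_samples=12, n=40, bias=0.5, seed=0):
        rng = np.random.default_rng(seed)
        rows, strands = [], []
        for j in range(n_samples):
            for _ in range(n):
                rows.append({"sample_id": f"s{j}"})
                strands.append("lagging" if rng.random() < bias else "leading")
        muts = pd.DataFrame(rows)
        strand = pd.Series(strands, index=muts.index)
        attribution = pd.DataFrame({"A": 1.0, "signature": "A"},
                                   index=muts.index)
        return muts, strand, attribution

    def test_imbalance_arithmetic_70_30(self):
        muts, strand, attribution = self._frame(bias=1.0)
        strand.iloc[: int(0.3 * len(strand))] = "leading"
        out = strand_asymmetry(muts, strand, attribution)
        assert out["imbalance"].iloc[0] == pytest.approx(0.4, abs=0.01)

    def test_planted_bias_flagged_and_symmetric_not(self):
        muts, strand, attribution = self._frame(n_samples=30, n=100, bias=0.75,
                                                seed=1)
        out = strand_asymmetry(muts, strand, attribution)
        assert bool(out["significant"].iloc[0])
        muts2, strand2, attr2 = self._frame(n_samples=30, n=100, bias=0.5,
                                            seed=2)
        out2 = strand_asymmetry(muts2, strand2, attr2)
        assert not out2["significant"].any()

    def test_unassigned_axis_raises(self):
        muts, strand, attribution = self._frame()
        with pytest.raises(ValueError, match="transcription"):
            strand_asymmetry(muts, pd.Series("unassigned", index=muts.index),
                             attribution, axis="transcription")


class TestTranscriptionStrand:
    GENES = pd.DataFrame({
        "gene": ["g1", "g2", "g3"],
        "chrom": ["chr1", "chr1", "chr1"],
        "start": [0, 5_000, 9_000],
        "end": [2_000, 7_000, 11_000],
        "strand": ["+", "-", "+"],
    })

    def test_pyrimidine_on_coding_strand_is_non_transcribed(self):
        muts = pd.DataFrame({"chrom": ["chr1"] * 4,
                             "pos": [100, 100, 5_500, 3_000],
                             "ref": ["C", "G", "C", "C"]})
        out = assign_transcription_strand(muts, self.GENES)
        assert list(out) == ["non-transcribed", "transcribed",
                             "transcribed", "unassigned"]

    def test_overlapping_opposite_genes_ambiguous(self):
        genes = pd.concat([self.GENES, pd.DataFrame([{
            "gene": "g4", "chrom": "chr1", "start": 0, "end": 2_000,
            "strand": "-"}])])
        muts = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "ref": ["C"]})
        assert assign_transcription_strand(muts, genes).iloc[0] == "unassigned"


class TestExpression:
    def test_ten_distinct_genes_make_bins_of_two(self):
        fpkm = pd.DataFrame({"s1": np.arange(10, dtype=float)},
                            index=[f"g{i}" for i in range(10)])
        pent = expression_pentiles(fpkm, excluded_genes=())
        assert sorted(np.bincount(pent["s1"])[1:].tolist()) == [2] * 5

    def test_zero_ties_produce_balanced_bins(self):
        fpkm = pd.DataFrame({"s1": [0.0] * 37 + [5.0, 6.0, 7.0]},
                            index=[f"g{i}" for i in range(40)])
        pent = expression_pentiles(fpkm, excluded_genes=())
        sizes = np.bincount(pent["s1"])[1:]
        assert sizes.max() - sizes.min() <= 1

    def test_excluded_genes_never_binned(self):
        fpkm = pd.DataFrame({"s1": [1.0, 2.0, 3.0, 4.0, 5.0]},
                            index=["MYC", "IGHV1", "a", "b", "c"])
        pent = expression_pentiles(fpkm)
        assert "MYC" not in pent.index and "IGHV1" not in pent.index

    def test_rate_by_expression_monotone_for_planted_rate(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(50)]
        fpkm = pd.DataFrame({"s1": np.linspace(0.1, 100, 50)}, index=genes)
        pent = expression_pentiles(fpkm, excluded_genes=())
        lengths = pd.Series(1_000.0, index=genes)
        rows = []
        for g, q in pent["s1"].items():
            for _ in range(rng.poisson(3 * q)):
                rows.append({"sample_id": "s1", "gene": g})
        muts = pd.DataFrame(rows)
        out = rate_by_expression(muts, pent, lengths)
        rates = out.set_index("pentile")["mean_rate_per_mb"]
        assert rates.is_monotonic_increasing

    def test_zero_length_gene_excluded(self):
        pent = pd.DataFrame({"s1": [1, 2]}, index=["a", "b"])
        lengths = pd.Series([0.0, 1000.0], index=["a", "b"])
        muts = pd.DataFrame({"sample_id": ["s1"], "gene": ["b"]})
        out = rate_by_expression(muts, pent, lengths)
        assert 1 not in out["pentile"].tolist()  # pentile of the 0-length gene
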