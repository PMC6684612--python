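"""Replication timing, strand asymmetry and expression-level mutation rates.

Replication timing comes in as a binned signal (bedGraph-like; higher =
earlier). Deciles partition the binned genome into ten near-equal bp-mass
strata, decile 1 earliest. Replication-fork polarity is inferred from the
track: origins fire at signal peaks and forks run downhill toward valleys,
so the local sign of the (smoothed) signal gradient gives fork direction.
For a right-moving fork the reference plus strand is replicated as the
leading strand; the strand of a mutation is the strand carrying its
pyrimidine base.

Strand asymmetry per signature is summarized by the pooled imbalance
|n1 - n2| / (n1 + n2) and a paired Wilcoxon across samples, and called
significant when the imbalance exceeds 0.30 with BH-adjusted Q < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

from .catalog import pyrimidine_strand

logger = logging.getLogger(__name__)

N_DECILES = 10


@dataclass
class TimingTrack:
    """Binned replication-timing signal with derived deciles and fork polarity."""

    bins: pd.DataFrame  # chrom, start, end (0-based half-open), signal
    smooth_bins: int = 5

    def __post_init__(self) -> None:
        b = self.bins.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, g in b.groupby("chrom"):
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping timing bins on {chrom}")
        b["bp"] = b["end"] - b["start"]
        b["decile"] = self._deciles(b)
        b["fork_dir"] = self._fork_direction(b)
        self.bins = b

    @classmethod
    def read_bedgraph(cls, path, **kw) -> "TimingTrack":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "signal"],
                         dtype={"chrom": str})
        return cls(df, **kw)

    def _deciles(self, b: pd.DataFrame) -> np.ndarray:
        """Equal-bp-mass deciles of the signal; decile 1 = earliest (highest)."""
        order = np.lexsort((b.index.to_numpy(), -b["signal"].to_numpy()))
        cum = np.cumsum(b["bp"].to_numpy()[order])
        total = cum[-1]
        # decile of a bin from the midpoint of its cumulative mass
        mid = cum - b["bp"].to_numpy()[order] / 2
        dec_sorted = np.minimum((mid / total * N_DECILES).astype(int) + 1, N_DECILES)
        dec = np.empty(len(b), dtype=int)
        dec[order] = dec_sorted
        return dec

    def _fork_direction(self, b: pd.DataFrame) -> np.ndarray:
        """-1 left-moving, +1 right-moving, 0 at peaks/valleys or chrom edges."""
        out = np.zeros(len(b), dtype=int)
        for chrom, g in b.groupby("chrom"):
            s = g["signal"].to_numpy(dtype=float)
            if len(s) >= self.smooth_bins:
                kernel = np.ones(self.smooth_bins) / self.smooth_bins
                pad = self.smooth_bins // 2
                sp = np.convolve(np.pad(s, pad, mode="edge"), kernel, mode="valid")
            else:
                sp = s
            grad = np.zeros_like(sp)
            grad[1:-1] = sp[2:] - sp[:-2]
            # forks run from early (high signal) to late: downhill
            out[g.index] = -np.sign(grad).astype(int)
        return out

    def decile_bp(self) -> pd.Series:
        return self.bins.groupby("decile")["bp"].sum().reindex(
            range(1, N_DECILES + 1), fill_value=0
        )

    def _lookup(self, chroms: pd.Series, pos: pd.Series, column: str) -> np.ndarray:
        """Value of ``column`` for the bin containing each 1-based position."""
        out = np.zeros(len(chroms), dtype=float)
        out[:] = np.nan
        df = pd.DataFrame({"chrom": chroms.to_numpy(), "pos": pos.to_numpy()})
        for chrom, g in df.groupby("chrom"):
            bins = self.bins[self.bins["chrom"] == chrom]
            if bins.empty:
                continue
            starts = bins["start"].to_numpy()
            ends = bins["end"].to_numpy()
            vals = bins[column].to_numpy()
            p = g["pos"].to_numpy() - 1
            i = np.searchsorted(starts, p, side="right") - 1
            ok = (i >= 0) & (p < ends[np.clip(i, 0, len(ends) - 1)])
            res = np.full(len(p), np.nan)
            res[ok] = vals[i[ok]]
            out[g.index] = res
        return out


def assign_timing(muts: pd.DataFrame, track: TimingTrack) -> pd.Series:
    """Decile (1-10) of the bin containing each mutation; NaN when uncovered."""
    return pd.Series(track._lookup(muts["chrom"], muts["pos"], "decile"),
                     index=muts.index, name="decile")


def rate_by_decile(
    muts: pd.DataFrame, track: TimingTrack, deciles: pd.Series | None = None
) -> pd.Series:
    """Mutation rate (per Mb) in each replication-timing decile."""
    if deciles is None:
        deciles = assign_timing(muts, track)
    counts = deciles.value_counts().reindex(range(1, N_DECILES + 1), fill_value=0)
    bp = track.decile_bp()
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = counts / bp * 1e6
    rate[bp == 0] = np.nan
    rate.index.name = "decile"
    return rate.rename("rate_per_mb")


def permutation_slope_test(
    rates: pd.Series, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Least-squares slope of rate on decile index with a permutation P.

    The decile labels are permuted ``n_perm`` times; the empirical P is the
    add-one-corrected fraction of permutations whose absolute slope is at
    least the observed one: P = (1 + #exceed) / (1 + n_perm), never zero.
    """
    y = rates.dropna()
    if len(y) < 3:
        raise ValueError("need >= 3 deciles with defined rates")
    x = y.index.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    xc = x - x.mean()
    denom = (xc**2).sum()
    obs = float((xc * (yv - yv.mean())).sum() / denom)
    if np.allclose(yv, yv[0]):
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, len(yv))), axis=1)
    slopes = ((yv[perms] - yv.mean()) @ xc) / denom
    exceed = int((np.abs(slopes) >= abs(obs) - 1e-15).sum())
    p = (1 + exceed) / (1 + n_perm)
    return obs, p


def assign_replication_strand(muts: pd.DataFrame, track: TimingTrack) -> pd.Series:
    """'leading'/'lagging'/'unassigned' per mutation.

    Right-moving fork: the plus strand is replicated as leading; the
    mutation sits on the strand carrying its pyrimidine base.
    """
    fork = track._lookup(muts["chrom"], muts["pos"], "fork_dir")
    pyr = muts["ref"].map(pyrimidine_strand).to_numpy()
    prod = fork * pyr
    out = np.where(prod > 0, "leading", np.where(prod < 0, "lagging", "unassigned"))
    out[np.isnan(fork)] = "unassigned"
    return pd.Series(out, index=muts.index, name="replication_strand")


def assign_transcription_strand(
    muts: pd.DataFrame, genes: pd.DataFrame
) -> pd.Series:
    """'transcribed'/'non-transcribed'/'unassigned' per mutation.

    ``genes``: columns gene, chrom, start, end (0-based half-open), strand.
    A pyrimidine on the gene's coding strand is non-transcribed; positions
    covered by genes on both strands are ambiguous, intergenic unassigned.
    """
    out = np.full(len(muts), "unassigned", dtype=object)
    for chrom, g in muts.groupby("chrom"):
        gh = genes[genes["chrom"] == chrom]
        if gh.empty:
            continue
        starts = gh["start"].to_numpy()
        ends = gh["end"].to_numpy()
        strands = gh["strand"].to_numpy()
        for i, pos, ref in zip(g.index, g["pos"], g["ref"]):
            p = pos - 1
            hit = (starts <= p) & (p < ends)
            ss = set(strands[hit])
            if len(ss) != 1:
                continue  # intergenic or genes on both strands
            gene_strand = 1 if ss.pop() == "+" else -1
            same = pyrimidine_strand(ref) == gene_strand
            out[muts.index.get_loc(i)] = "non-transcribed" if same else "transcribed"
    return pd.Series(out, index=muts.index, name="transcription_strand")


def strand_asymmetry(
    muts: pd.DataFrame,
    strand: pd.Series,
    attribution: pd.DataFrame,
    axis: str = "replication",
    imbalance_min: float = 0.30,
    alpha: float = 0.05,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Per-signature strand asymmetry with the >30% & Q<0.05 significance rule.

    Each mutation counts toward its argmax signature. Per sample the two
    strand counts feed a paired Wilcoxon across samples; the imbalance is
    pooled |n1 - n2| / (n1 + n2). BH across signatures.
    """
    pair = {"replication": ("leading", "lagging"),
            "transcription": ("transcribed", "non-transcribed")}[axis]
    assigned = strand.isin(pair)
    if not assigned.any():
        raise ValueError(f"no mutations assigned on the {axis} axis")
    df = pd.DataFrame({
        "sample_id": muts.loc[assigned, "sample_id"],
        "strand": strand[assigned],
        "signature": attribution.loc[assigned, "signature"],
    }).dropna(subset=["signature"])
    n_samples = df["sample_id"].nunique()
    if n_samples < min_samples:
        raise ValueError(f"only {n_samples} samples with assigned mutations")
    rows = []
    for sig, g in df.groupby("signature"):
        tab = (g.groupby(["sample_id", "strand"]).size().unstack(fill_value=0)
               .reindex(columns=pair, fill_value=0))
        n1, n2 = int(tab[pair[0]].sum()), int(tab[pair[1]].sum())
        imbalance = abs(n1 - n2) / (n1 + n2) if (n1 + n2) else 0.0
        d = tab[pair[0]] - tab[pair[1]]
        if len(tab) < 3 or (d == 0).all():
            p = 1.0
        else:
            _, p = wilcoxon(tab[pair[0]], tab[pair[1]])
        rows.append({"signature": sig, f"n_{pair[0]}": n1, f"n_{pair[1]}": n2,
                     "imbalance": imbalance, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = (out["imbalance"] > imbalance_min) & (out["q"] < alpha)
    return out


EXCLUDED_EXPRESSION_GENES = (
    "CCND1", "CCND3", "FGFR3", "MMSET", "MAF", "MAFB", "MYC",
)


def expression_pentiles(
    fpkm: pd.DataFrame, excluded_genes=EXCLUDED_EXPRESSION_GENES
) -> pd.DataFrame:
    """Per-tumor pentile (1 = lowest expression) of each gene's FPKM.

    ``fpkm``: genes x samples. Excluded genes (translocation-upregulated
    and immunoglobulin loci, supplied by the caller) are removed before
    binning. Ties order stably by (FPKM, gene name); bin sizes are within
    one of equal.
    """
    excluded = set(excluded_genes)
    kept = fpkm.loc[[g for g in fpkm.index if g not in excluded
                     and not str(g).startswith("IG")]]
    out = {}
    n = len(kept)
    for sample in kept.columns:
        order = np.lexsort((kept.index.to_numpy(), kept[sample].to_numpy()))
        pent = np.empty(n, dtype=int)
        edges = (np.arange(n) * 5) // n + 1
        pent[order] = edges
        out[sample] = pent
    return pd.DataFrame(out, index=kept.index)


def rate_by_expression(
    muts: pd.DataFrame, pentiles: pd.DataFrame, gene_lengths: pd.Series
) -> pd.DataFrame:
    """Per-pentile mutation rate (per Mb), averaged over tumors with 95% CI."""
    zero_len = gene_lengths[gene_lengths <= 0].index
    if len(zero_len):
        logger.info("excluding %d zero-length genes", len(zero_len))
        gene_lengths = gene_lengths.drop(zero_len)
    per_tumor = []
    for sample in pentiles.columns:
        pent = pentiles[sample]
        g = muts[(muts["sample_id"] == sample) & muts["gene"].isin(pent.index)]
        counts = pent.reindex(g["gene"]).value_counts()
        for q in range(1, 6):
            genes_q = pent.index[pent == q].intersection(gene_lengths.index)
            bp = gene_lengths.loc[genes_q].sum()
            if bp == 0:
                continue
            per_tumor.append({"sample_id": sample, "pentile": q,
                              "rate_per_mb": counts.get(q, 0) / bp * 1e6})
    pt = pd.DataFrame(per_tumor)
    rows = []
    for q, g in pt.groupby("pentile"):
        m = g["rate_per_mb"].mean()
        se = g["rate_per_mb"].std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else 0.0
        rows.append({"pentile": q, "mean_rate_per_mb": m,
                     "ci_low": m - 1.96 * se, "ci_high": m + 1.96 * se,
                     "n_tumors": len(g)})
    return pd.DataFrame(rows)
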