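"""Region contrasts with explicit trinucleotide-composition normalization.

Two genomic regions generally differ in trinucleotide composition, so a
raw comparison of signature activity between them confounds process
intensity with sequence opportunity. Before comparing, the mutation count
of each category C observed in the larger region X is rescaled to the count
expected if X had the composition of the smaller region Y, assuming a
constant per-opportunity mutation rate:

    U_norm(C, X) = U(C, X) * V(C, Y) * W(X) / (V(C, X) * W(Y))

where U is the observed count, V the number of positions at which a
category-C mutation can occur, and W the region size in bp. U_norm is
rounded to the closest integer (half away from zero). Normalization is
applied within each tumor, never pooled.

Opportunities V live on the 32 pyrimidine-centered context classes (any of
three alternate alleles can occur at a position), shared across the three
alt alleles of a context; U lives on the 96 categories.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon
from statsmodels.stats.multitest import multipletests

from .catalog import (
    CONTEXT_CLASSES_32,
    CATEGORIES_96,
    Mutation,
    RegionSet,
    _context_from_reference,
    classify_snv,
    context_class,
)

logger = logging.getLogger(__name__)

#: context class (32) of each of the 96 categories
CATEGORY_TO_CLASS = {c: c[0] + c[2] + c[6] for c in CATEGORIES_96}


def mutations_to_frame(
    muts: Sequence[Mutation], reference: Mapping[str, str]
) -> pd.DataFrame:
    """Tabulate mutations with their 96-category and 32-class annotations.

    Mutations with ambiguous context are dropped (logged count).
    """
    rows = []
    n_dropped = 0
    for m in muts:
        ctx = _context_from_reference(reference, m.chrom, m.pos)
        cat = classify_snv(m, ctx)
        if cat is None:
            n_dropped += 1
            continue
        rows.append(
            {"sample_id": m.sample_id, "chrom": m.chrom, "pos": m.pos,
             "ref": m.ref, "alt": m.alt, "vaf": m.vaf, "gene": m.gene,
             "category": cat, "context_class": CATEGORY_TO_CLASS[cat]}
        )
    if n_dropped:
        logger.info("dropped %d mutations with ambiguous context", n_dropped)
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "vaf",
                       "gene", "category", "context_class"],
    )


def count_opportunities(
    region: RegionSet, reference: Mapping[str, str]
) -> tuple[dict[str, int], int]:
    """Count per-class mutation opportunities V and the region size W.

    A position contributes to class V when its centered reference 3-mer
    (flanks may extend beyond the interval, within the contig) is
    unambiguous; the class is the pyrimidine-collapsed trinucleotide.
    """
    counts = dict.fromkeys(CONTEXT_CLASSES_32, 0)
    total_bp = 0
    for chrom, start, end in region.iter_intervals():
        seq = str(reference[chrom][:]).upper() if not isinstance(
            reference[chrom], str) else reference[chrom].upper()
        if end > len(seq):
            raise ValueError(
                f"interval {chrom}:{start}-{end} beyond contig end ({len(seq)})"
            )
        total_bp += end - start
        lo = max(start, 1)
        hi = min(end, len(seq) - 1)
        for p in range(lo, hi):
            cls = context_class(seq[p - 1 : p + 2])
            if cls is not None:
                counts[cls] += 1
    return counts, total_bp


def normalize_counts(
    U: float, V_CX: int, V_CY: int, W_X: int, W_Y: int
) -> int:
    """Composition-normalized count, rounded half away from zero."""
    if U < 0 or min(V_CX, V_CY, W_X, W_Y) < 0:
        raise ValueError("all inputs must be non-negative")
    if U == 0:
        return 0
    if V_CX == 0:
        raise ValueError(
            "mutation observed in a context with zero opportunities (V_CX == 0)"
        )
    x = U * (V_CY * W_X) / (V_CX * W_Y)
    return int(np.floor(x + 0.5))


def _realized_weights(
    muts: pd.DataFrame, V_X: dict, V_Y: dict, W_X: int, W_Y: int, rng
) -> np.ndarray:
    """Per-mutation weights realizing the normalized category counts.

    When U_norm < U the category's mutations are uniformly subsampled
    (weight 0/1); when U_norm > U existing mutations are upweighted by
    U_norm / U rather than fabricating mutations.
    """
    weights = np.ones(len(muts))
    for cls, idx in muts.groupby("context_class").indices.items():
        U = len(idx)
        u_norm = normalize_counts(U, V_X[cls], V_Y[cls], W_X, W_Y)
        if u_norm < U:
            keep = rng.choice(idx, size=u_norm, replace=False)
            drop = np.setdiff1d(idx, keep)
            weights[drop] = 0.0
        elif u_norm > U:
            weights[idx] = u_norm / U
    return weights


def _in_region(muts: pd.DataFrame, region: RegionSet) -> np.ndarray:
    return np.array(
        [region.contains(c, p) for c, p in zip(muts["chrom"], muts["pos"])]
    )


def compare_regions(
    muts: pd.DataFrame,
    attribution: pd.DataFrame,
    region_x: RegionSet,
    region_y: RegionSet,
    reference: Mapping[str, str],
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Contrast per-signature contributions between two disjoint regions.

    The larger region (by bp) is designated X and its mutation counts are
    normalized per tumor to Y's trinucleotide composition. Contribution of
    a signature in a region is the (weight-realized) sum of per-mutation
    attributed probabilities; the paired Wilcoxon signed-rank test compares
    per-sample proportional contributions across regions, BH-corrected over
    signatures.
    """
    sig_cols = [c for c in attribution.columns if c != "signature"]
    V_a, W_a = count_opportunities(region_x, reference)
    V_b, W_b = count_opportunities(region_y, reference)
    if W_a < W_b:  # the larger region is X
        region_x, region_y = region_y, region_x
        V_a, V_b, W_a, W_b = V_b, V_a, W_b, W_a
    in_x = _in_region(muts, region_x)
    in_y = _in_region(muts, region_y)
    if (in_x & in_y).any():
        raise ValueError("regions X and Y overlap")
    rng = np.random.default_rng(seed)

    rows = []
    for sid, g in muts.groupby("sample_id"):
        gx = g[in_x[g.index]]
        gy = g[in_y[g.index]]
        if gx.empty or gy.empty:
            continue
        wx = _realized_weights(gx, V_a, V_b, W_a, W_b, rng)
        ax = attribution.loc[gx.index, sig_cols].to_numpy(dtype=float)
        ay = attribution.loc[gy.index, sig_cols].to_numpy(dtype=float)
        keep_x = ~np.isnan(ax).any(axis=1)
        keep_y = ~np.isnan(ay).any(axis=1)
        cx = (ax[keep_x] * wx[keep_x, None]).sum(axis=0)
        cy = ay[keep_y].sum(axis=0)
        tx, ty = cx.sum(), cy.sum()
        if tx == 0 or ty == 0:
            continue
        for s, vx, vy in zip(sig_cols, cx, cy):
            rows.append({"sample_id": sid, "signature": s,
                         "contrib_x": vx, "contrib_y": vy,
                         "prop_x": vx / tx, "prop_y": vy / ty})
    per_sample = pd.DataFrame(rows)
    out_rows = []
    for s in sig_cols:
        sub = per_sample[per_sample["signature"] == s]
        d = sub["prop_x"] - sub["prop_y"]
        if len(d) < 3 or np.allclose(d, 0):
            stat, p = np.nan, 1.0
        else:
            stat, p = wilcoxon(sub["prop_x"], sub["prop_y"])
        out_rows.append({"signature": s, "n_samples": len(sub),
                         "mean_prop_x": sub["prop_x"].mean(),
                         "mean_prop_y": sub["prop_y"].mean(),
                         "statistic": stat, "p": p})
    out = pd.DataFrame(out_rows)
    out["q"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    out["region_x"] = region_x.name  # after the larger-is-X designation
    out["region_y"] = region_y.name
    return out


def exclude_recurrent(muts: pd.DataFrame) -> pd.DataFrame:
    """Drop mutations at positions mutated in more than one tumor."""
    key = muts["chrom"].astype(str) + ":" + muts["pos"].astype(str) + ":" + muts["alt"]
    n_tumors = muts.groupby(key)["sample_id"].transform("nunique")
    return muts[n_tumors <= 1]


def driver_contrast(
    muts: pd.DataFrame,
    attribution: pd.DataFrame,
    driver_genes: Sequence[str],
    mode: str = "include_recurrent",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(gene, signature) contrast of attribution probabilities.

    For each driver gene, mutations affecting the gene are compared with
    all other mutations by Wilcoxon rank-sum on per-mutation attributed
    probability of each signature; BH over the full gene x signature
    family. ``mode='exclude_recurrent'`` first drops positions mutated in
    more than one tumor (robustness against positive selection of specific
    sites). Genes absent from the annotation are listed and skipped.
    """
    if mode not in ("include_recurrent", "exclude_recurrent"):
        raise ValueError(f"unknown mode {mode!r}")
    work = muts
    if mode == "exclude_recurrent":
        work = exclude_recurrent(muts)
    attrib = attribution.loc[work.index]
    sig_cols = [c for c in attribution.columns if c != "signature"]
    present = set(work["gene"].dropna())
    skipped = [g for g in driver_genes if g not in present]
    if skipped:
        logger.info("driver genes absent from annotation, skipped: %s", skipped)
    rows = []
    for gene in driver_genes:
        if gene not in present:
            continue
        in_gene = (work["gene"] == gene).to_numpy()
        for s in sig_cols:
            p_gene = attrib.loc[in_gene, s].dropna()
            p_rest = attrib.loc[~in_gene, s].dropna()
            if len(p_gene) == 0 or len(p_rest) == 0:
                continue
            try:
                stat, p = mannwhitneyu(p_gene, p_rest, alternative="two-sided")
            except ValueError:
                stat, p = np.nan, 1.0
            rows.append({"gene": gene, "signature": s, "n_gene": len(p_gene),
                         "mean_gene": p_gene.mean(), "mean_rest": p_rest.mean(),
                         "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
        out["significant"] = out["q"] < alpha
    return out
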