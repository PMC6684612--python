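"""Structural-variant classification and rearrangement signatures.

SVs are classified into a fixed 32-category scheme: clustered status x
{deletion, tandem duplication, inversion in five log-spaced size bins;
translocation unbinned}. Clustered status is a per-sample property of the
breakpoint landscape: a breakpoint run whose spacing is far below the
sample's genome-wide expectation marks a region of concentrated
rearrangement. Rearrangement signatures (RSs) are then extracted from the
32-category catalog with the same NMF machinery used for SNV signatures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .signatures import SignatureSet, extract_de_novo

SV_TYPES = ("DEL", "DUP", "INV", "TRA")

#: Half-open size bins for intra-chromosomal events, in bp.
SIZE_BINS = ((1_000, 10_000), (10_000, 100_000), (100_000, 1_000_000),
             (1_000_000, 10_000_000), (10_000_000, None))
SIZE_BIN_LABELS = ("1-10kb", "10-100kb", "100kb-1Mb", "1-10Mb", ">10Mb")

SV_CATEGORIES_32 = tuple(
    f"{clust}:{t}:{b}"
    for clust in ("clustered", "non-clustered")
    for t in ("DEL", "DUP", "INV")
    for b in SIZE_BIN_LABELS
) + ("clustered:TRA", "non-clustered:TRA")


@dataclass
class SVEvent:
    """One somatic structural variant (breakpoints 1-based)."""

    sample_id: str
    sv_type: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type}")
        if self.sv_type == "TRA":
            if self.chrom1 == self.chrom2:
                raise ValueError("translocation with equal chromosomes")
        elif self.chrom1 != self.chrom2:
            raise ValueError(f"{self.sv_type} with breakends on different chromosomes")

    @property
    def size(self) -> int | None:
        if self.sv_type == "TRA":
            return None
        return abs(self.pos2 - self.pos1)

    def breakends(self) -> list[tuple[str, int]]:
        return [(self.chrom1, self.pos1), (self.chrom2, self.pos2)]


def _size_bin(size: int) -> str:
    for (low, high), label in zip(SIZE_BINS, SIZE_BIN_LABELS):
        if size >= low and (high is None or size < high):
            return label
    return SIZE_BIN_LABELS[0]  # sub-1kb events fall into the smallest bin


def detect_clustered(
    svs: Sequence[SVEvent],
    genome_size: int | None = None,
    density_ratio: float = 0.1,
    min_breakpoints: int = 8,
) -> list[bool]:
    """Flag clustered SVs in one sample.

    All breakends (both ends of intra-chromosomal events; one end per
    chromosome for translocations) are pooled per chromosome and sorted.
    The sample's expected breakpoint spacing is genome_size / n_breakends;
    a maximal run of adjacent gaps each below ``density_ratio`` times that
    expectation, spanning at least ``min_breakpoints`` breakends, is a
    cluster. An event is clustered iff any of its breakends lies in a
    cluster. When ``genome_size`` is not given it is estimated as the sum
    over involved chromosomes of the maximum breakend position.
    """
    if not svs:
        return []
    if any(sv.sample_id != svs[0].sample_id for sv in svs):
        raise ValueError("detect_clustered operates on a single sample")
    by_chrom: dict[str, list[tuple[int, int]]] = {}  # chrom -> [(pos, sv_idx)]
    for i, sv in enumerate(svs):
        for chrom, pos in sv.breakends():
            by_chrom.setdefault(chrom, []).append((pos, i))
    n_bp = sum(len(v) for v in by_chrom.values())
    if genome_size is None:
        genome_size = sum(max(p for p, _ in v) for v in by_chrom.values())
    expected_spacing = genome_size / n_bp
    threshold = density_ratio * expected_spacing

    flags = [False] * len(svs)
    for chrom, bends in by_chrom.items():
        bends.sort()
        pos = np.array([p for p, _ in bends])
        gaps = np.diff(pos)
        close = gaps < threshold
        # maximal runs of close gaps
        start = 0
        while start < len(close):
            if not close[start]:
                start += 1
                continue
            end = start
            while end < len(close) and close[end]:
                end += 1
            # run covers breakends start .. end (inclusive), end-start+1 of them
            if end - start + 1 >= min_breakpoints:
                for _, idx in bends[start : end + 1]:
                    flags[idx] = True
            start = end
    return flags


def classify_sv(sv: SVEvent, clustered: bool) -> str:
    """Category label for one SV given its clustered flag."""
    prefix = "clustered" if clustered else "non-clustered"
    if sv.sv_type == "TRA":
        return f"{prefix}:TRA"
    return f"{prefix}:{sv.sv_type}:{_size_bin(sv.size)}"


def build_sv_catalog(
    svs: Iterable[SVEvent],
    samples: Sequence[str] | None = None,
    genome_size: int | None = None,
) -> pd.DataFrame:
    """Samples x 32 SV-category count matrix (clustered flags computed per sample)."""
    by_sample: dict[str, list[SVEvent]] = {}
    for sv in svs:
        by_sample.setdefault(sv.sample_id, []).append(sv)
    index = list(samples) if samples is not None else sorted(by_sample)
    mat = np.zeros((len(index), len(SV_CATEGORIES_32)), dtype=np.int64)
    cat_idx = {c: i for i, c in enumerate(SV_CATEGORIES_32)}
    for r, sid in enumerate(index):
        events = by_sample.get(sid, [])
        if not events:
            continue
        flags = detect_clustered(events, genome_size=genome_size)
        for sv, fl in zip(events, flags):
            mat[r, cat_idx[classify_sv(sv, fl)]] += 1
    return pd.DataFrame(mat, index=pd.Index(index, name="sample_id"),
                        columns=list(SV_CATEGORIES_32))


def extract_rs(
    sv_catalog: pd.DataFrame, k_range=range(2, 7), n_restarts: int = 20,
    seed: int = 0, **kwargs
) -> tuple[SignatureSet, pd.DataFrame, "object"]:
    """De novo rearrangement-signature extraction on the 32-category space."""
    sigs, exp, diag = extract_de_novo(
        sv_catalog, k_range=k_range, n_restarts=n_restarts, seed=seed, **kwargs
    )
    sigs = SignatureSet.from_matrix(
        [f"RS{i + 1}" for i in range(len(sigs.ids))], sigs.matrix(), sv_catalog.columns
    )
    exp.columns = list(sigs.ids)
    return sigs, exp, diag


def correlate_rs_snv(
    rs_exposures: pd.DataFrame, snv_exposures: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman correlation of each (RS, SNV signature) exposure pair.

    Returns a long table with rho, p, BH-adjusted q and a flag at
    q < ``alpha``, computed over samples present in both matrices.
    """
    shared = rs_exposures.index.intersection(snv_exposures.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared samples; need >= 10")
    rows = []
    for rs in rs_exposures.columns:
        for sig in snv_exposures.columns:
            rho, p = spearmanr(
                rs_exposures.loc[shared, rs], snv_exposures.loc[shared, sig]
            )
            rows.append({"rs": rs, "signature": sig, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    return out


def read_sv_table(path) -> list[SVEvent]:
    """BEDPE-like TSV: sample_id, chrom1, pos1, chrom2, pos2, sv_type."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    return [
        SVEvent(r.sample_id, r.sv_type, r.chrom1, int(r.pos1), r.chrom2, int(r.pos2))
        for r in df.itertuples()
    ]


def write_sv_table(svs: Sequence[SVEvent], path) -> None:
    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "chrom1": s.chrom1, "pos1": s.pos1,
             "chrom2": s.chrom2, "pos2": s.pos2, "sv_type": s.sv_type}
            for s in svs
        ]
    ).to_csv(path, sep="\t", index=False)
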