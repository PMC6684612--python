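"""Myeloma karyotype calls and subgroup enrichment of signatures.

Hyperdiploidy (HD) is called when at least two autosomes are amplified over
at least 90% of their length. Prognostic chromosome-arm events are segments
longer than 1 Mb with |log2 ratio| >= 0.1613 of the correct sign
overlapping one of the five cytobands 1p12, 1p32.3, 1q21.1, 1q23.3, 17p13.
Translocation labels are input metadata (sequencing-FISH derived), never
inferred. Subgroup enrichment is a two-tailed Fisher's exact test of
binarized signature activity against subgroup membership, BH-corrected
over the full signature x subgroup family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .catalog import RegionSet

logger = logging.getLogger(__name__)

LOG2_EVENT_THRESHOLD = 0.1613
ARM_EVENT_MIN_BP = 1_000_000
HD_AMPLIFIED_FRACTION = 0.9
HD_MIN_AUTOSOMES = 2

ARM_EVENT_LOCI = ("1p12", "1p32.3", "1q21.1", "1q23.3", "17p13")
#: sign of the prognostic event at each band (+1 gain, -1 deletion)
ARM_EVENT_SIGN = {"1p12": -1, "1p32.3": -1, "1q21.1": +1, "1q23.3": +1,
                  "17p13": -1}


@dataclass
class CNVSegment:
    sample_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end <= start at {self.chrom}:{self.start}")


def call_hyperdiploidy(
    segments: list[CNVSegment],
    chrom_sizes: dict[str, int],
    gain_threshold: float = LOG2_EVENT_THRESHOLD,
) -> bool:
    """True iff >= 2 autosomes are amplified over >= 90% of their length.

    Amplification uses the same log2 gain cut as arm events. Only
    chromosomes present in ``chrom_sizes`` (the autosome roster) count.
    """
    if not chrom_sizes:
        raise ValueError("chrom_sizes is required")
    amp: dict[str, list] = {}
    for seg in segments:
        if seg.chrom not in chrom_sizes:
            continue
        if seg.log2_ratio >= gain_threshold:
            end = min(seg.end, chrom_sizes[seg.chrom])
            if end > seg.start:
                amp.setdefault(seg.chrom, []).append((seg.start, end))
    n_amp = 0
    for chrom, ivals in amp.items():  # merge so overlaps are not double-counted
        ivals.sort()
        bp, cur_s, cur_e = 0, *ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                bp += cur_e - cur_s
                cur_s, cur_e = s, e
        bp += cur_e - cur_s
        if bp / chrom_sizes[chrom] >= HD_AMPLIFIED_FRACTION:
            n_amp += 1
    return n_amp >= HD_MIN_AUTOSOMES


def call_arm_events(
    segments: list[CNVSegment],
    loci: RegionSet,
    threshold: float = LOG2_EVENT_THRESHOLD,
    min_bp: int = ARM_EVENT_MIN_BP,
) -> set[str]:
    """Prognostic arm events present in one sample.

    ``loci`` must name its intervals after the five cytobands via a
    per-chrom encoding: the RegionSet is built from a band table (see
    :func:`read_cytobands`). An event is called when a segment longer than
    ``min_bp`` with |log2| >= ``threshold`` of the correct sign overlaps
    the band.
    """
    missing = [b for b in ARM_EVENT_LOCI if b not in loci.intervals]
    if missing:
        raise KeyError(f"cytoband coordinates missing for: {missing}")
    events = set()
    for band in ARM_EVENT_LOCI:
        sign = ARM_EVENT_SIGN[band]
        for chrom_start_end in loci.intervals[band]:
            b_start, b_end = int(chrom_start_end[0]), int(chrom_start_end[1])
            band_chrom = loci.band_chrom[band]
            for seg in segments:
                if seg.chrom != band_chrom:
                    continue
                if seg.end - seg.start <= min_bp:
                    continue
                if abs(seg.log2_ratio) < threshold:
                    continue
                if np.sign(seg.log2_ratio) != sign:
                    continue
                if seg.start < b_end and b_start < seg.end:
                    suffix = "gain" if sign > 0 else "del"
                    events.add(f"{band} {suffix}")
    return events


def cytoband_regions(bands: pd.DataFrame) -> RegionSet:
    """RegionSet keyed by band name (not chrom) for :func:`call_arm_events`.

    ``bands``: columns band, chrom, start, end (0-based half-open).
    """
    rs = RegionSet(name="cytobands", intervals={})
    rs.band_chrom = {}
    for r in bands.itertuples():
        rs.intervals[r.band] = np.array([[int(r.start), int(r.end)]], dtype=np.int64)
        rs.band_chrom[r.band] = str(r.chrom)
    return rs


def karyotype_table(
    segments_by_sample: dict[str, list[CNVSegment]],
    chrom_sizes: dict[str, int],
    loci: RegionSet,
    translocations: pd.Series | None = None,
    tp53: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample karyotype calls joined with input translocation labels."""
    rows = []
    for sid, segs in segments_by_sample.items():
        events = call_arm_events(segs, loci)
        rows.append({
            "sample_id": sid,
            "hyperdiploid": call_hyperdiploidy(segs, chrom_sizes),
            "del_1p": any(e.startswith("1p") for e in events),
            "gain_1q": any(e.startswith("1q") for e in events),
            "del_17p": "17p13 del" in events,
            "arm_events": ";".join(sorted(events)),
        })
    out = pd.DataFrame(rows).set_index("sample_id")
    out["translocation"] = (
        translocations.reindex(out.index).fillna("none")
        if translocations is not None else "none"
    )
    out["tp53_mutated"] = (
        tp53.reindex(out.index).fillna(False).astype(bool)
        if tp53 is not None else False
    )
    return out


def binarize_activity(exposures: pd.DataFrame, threshold: float = 0.05
                      ) -> pd.DataFrame:
    """Signature 'active' when its normalized per-sample exposure >= threshold."""
    totals = exposures.sum(axis=1)
    norm = exposures.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return norm >= threshold


def enrichment_test(
    exposures: pd.DataFrame,
    labels: pd.Series,
    activity_threshold: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of binarized signature activity across subgroups.

    One two-tailed Fisher's exact test per (signature, subgroup): subgroup
    membership x signature-active 2x2 table over all samples; BH within the
    full family. Subgroups with < 5 members are still tested but flagged.
    """
    shared = exposures.index.intersection(labels.index)
    active = binarize_activity(exposures.loc[shared], activity_threshold)
    lab = labels.loc[shared]
    groups = sorted(lab.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 subgroups")
    rows = []
    for grp in groups:
        in_grp = (lab == grp).to_numpy()
        for sig in active.columns:
            act = active[sig].to_numpy()
            a = int((in_grp & act).sum())
            b = int((in_grp & ~act).sum())
            c = int((~in_grp & act).sum())
            d = int((~in_grp & ~act).sum())
            odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append({"subgroup": grp, "signature": sig,
                         "n_group": int(in_grp.sum()),
                         "odds_ratio": odds, "p": p,
                         "low_n": bool(in_grp.sum() < 5)})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    return out
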