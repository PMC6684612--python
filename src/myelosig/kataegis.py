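"""Kataegis: localized hypermutation foci.

A focus is a run of six or more consecutive mutations on one chromosome of
one sample whose mean adjacent inter-mutation distance is at most 1 kb
(boundary inclusive). Maximality is defined through qualifying windows:
every contiguous window of >= ``min_mutations`` mutations with mean gap <=
``max_mean_imd`` qualifies, and the reported foci are the connected
components of the union of qualifying windows — so no reported focus can be
extended and no two foci share a mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .sv import SVEvent


@dataclass
class KataegisFocus:
    sample_id: str
    chrom: str
    start: int  # 1-based position of first member mutation
    end: int  # 1-based position of last member mutation
    mutation_ids: list = field(default_factory=list)  # row indices into muts

    @property
    def n(self) -> int:
        return len(self.mutation_ids)


def _qualifying_cover(pos: np.ndarray, min_mutations: int, max_mean_imd: float
                      ) -> np.ndarray:
    """Boolean cover: index is inside some qualifying window.

    For each start i, the window mean gap sum(gaps[i:j]) / (j - i) is
    tracked incrementally while extending j; every qualifying extent marks
    its indices covered. O(n^2) worst case, linear in practice because
    extension stops once the running best mean cannot recover.
    """
    n = len(pos)
    covered = np.zeros(n, dtype=bool)
    if n < min_mutations:
        return covered
    gaps = np.diff(pos)
    cum = np.concatenate([[0], np.cumsum(gaps)])
    budget = max_mean_imd
    for i in range(n - min_mutations + 1):
        best_to = -1
        for j in range(i + min_mutations - 1, n):
            mean_gap = (cum[j] - cum[i]) / (j - i)
            if mean_gap <= budget:
                best_to = j
            elif (cum[j] - cum[i]) - budget * (j - i) > budget * (n - 1 - j):
                # even 0-length future gaps cannot bring the mean back down
                break
        if best_to >= 0:
            covered[i : best_to + 1] = True
    return covered


def detect_kataegis(
    muts: pd.DataFrame,
    min_mutations: int = 6,
    max_mean_imd: float = 1000.0,
) -> list[KataegisFocus]:
    """Detect kataegis foci per (sample, chromosome).

    ``muts`` needs sample_id, chrom, pos columns; row index identifies
    mutations. Returns non-overlapping maximal foci.
    """
    foci: list[KataegisFocus] = []
    for (sid, chrom), g in muts.groupby(["sample_id", "chrom"], sort=True):
        g = g.sort_values("pos")
        pos = g["pos"].to_numpy(dtype=np.int64)
        covered = _qualifying_cover(pos, min_mutations, max_mean_imd)
        i = 0
        while i < len(pos):
            if not covered[i]:
                i += 1
                continue
            j = i
            while j < len(pos) and covered[j]:
                j += 1
            foci.append(
                KataegisFocus(sid, chrom, int(pos[i]), int(pos[j - 1]),
                              list(g.index[i:j]))
            )
            i = j
    return foci


def focus_enrichment(
    muts: pd.DataFrame,
    foci: list[KataegisFocus],
    attribution: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Signature enrichment at kataegis foci, two comparisons per signature.

    Focus mutations are compared by Wilcoxon rank-sum on attributed
    probability (i) against other mutations in kataegis-positive tumors and
    (ii) against mutations in kataegis-negative tumors; BH within each
    comparison. A signature is consistently enriched when both hold at
    Q < ``alpha`` with focus mean exceeding the comparison mean.
    """
    sig_cols = [c for c in attribution.columns if c != "signature"]
    focus_idx = sorted({i for f in foci for i in f.mutation_ids})
    if not focus_idx:
        return pd.DataFrame(
            columns=["signature", "q_within", "q_negative", "consistent"])
    pos_tumors = {f.sample_id for f in foci}
    in_focus = muts.index.isin(focus_idx)
    in_pos = muts["sample_id"].isin(pos_tumors)
    rows = []
    for s in sig_cols:
        pf = attribution.loc[in_focus, s].dropna()
        p_within = attribution.loc[in_pos & ~in_focus, s].dropna()
        p_neg = attribution.loc[~in_pos, s].dropna()
        row = {"signature": s, "mean_focus": pf.mean()}
        for label, other in (("within", p_within), ("negative", p_neg)):
            if len(pf) == 0 or len(other) == 0:
                row[f"p_{label}"] = np.nan
                row[f"mean_{label}"] = np.nan
                continue
            _, p = mannwhitneyu(pf, other, alternative="two-sided")
            row[f"p_{label}"] = p
            row[f"mean_{label}"] = other.mean()
        rows.append(row)
    out = pd.DataFrame(rows)
    for label in ("within", "negative"):
        out[f"q_{label}"] = multipletests(
            out[f"p_{label}"].fillna(1.0), method="fdr_bh")[1]
    out["consistent"] = (
        (out["q_within"] < alpha) & (out["q_negative"] < alpha)
        & (out["mean_focus"] > out["mean_within"])
        & (out["mean_focus"] > out["mean_negative"])
    )
    return out


def colocalize_sv(
    foci: list[KataegisFocus],
    svs: list[SVEvent],
    window: int = 10_000,
) -> tuple[float, float]:
    """Fractions of (foci near an SV breakpoint, SV events near a focus).

    A focus is near an SV when any breakpoint of the same sample and
    chromosome lies within ``window`` bp of [start - window, end + window]
    ... i.e. within ``window`` bp of the focus interval; the SV-side
    fraction counts events with at least one breakend near some focus.
    """
    if not foci:
        return (float("nan"), 0.0 if svs else float("nan"))
    bends: dict[tuple[str, str], list[int]] = {}
    for i, sv in enumerate(svs):
        for chrom, pos in sv.breakends():
            bends.setdefault((sv.sample_id, chrom), []).append((pos, i))
    near_focus = 0
    sv_near: set[int] = set()
    for f in foci:
        hits = bends.get((f.sample_id, f.chrom), [])
        found = False
        for pos, i in hits:
            if f.start - window <= pos <= f.end + window:
                found = True
                sv_near.add(i)
        near_focus += found
    frac_foci = near_focus / len(foci)
    frac_sv = len(sv_near) / len(svs) if svs else float("nan")
    return frac_foci, frac_sv


def foci_to_bed(foci: list[KataegisFocus]) -> pd.DataFrame:
    """BED-like frame: chrom, start (0-based), end, name=sample, score=n."""
    return pd.DataFrame(
        [{"chrom": f.chrom, "start": f.start - 1, "end": f.end,
          "name": f.sample_id, "score": f.n} for f in foci]
    )
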