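"""Synthetic myeloma cohorts with planted ground truth.

Every statistical structure the pipeline assumes is plantable here: known
signature mixtures per sample (Dirichlet exposures over a set of true
96-category profiles), replication-timing-dependent mutation rates,
replicative strand bias, kataegis foci from a designated process, SV
category mixtures per rearrangement signature with materialized clustered
breakpoint runs, a karyotype plan (hyperdiploidy and arm events), subgroup
labels, and proportional-hazards survival — so every downstream stage can
be validated against truth without any external data.

Determinism: one global seed spawns named substreams in a fixed order
(genome, mutations, kataegis, sv, cnv, clinical), so adding draws to one
component never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import (
    BASES,
    CATEGORIES_96,
    COMPLEMENT,
    CONTEXT_CLASSES_32,
    Mutation,
)
from .replitrans import TimingTrack
from .signatures import SignatureSet
from .sv import SV_CATEGORIES_32, SIZE_BINS, SIZE_BIN_LABELS, SVEvent

_SUBSTREAMS = ("genome", "mutations", "kataegis", "sv", "cnv", "clinical",
               "expression")


def substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(_SUBSTREAMS, children)}


# ---------------------------------------------------------------- signatures


def block_signatures(k: int = 5, peak_mass: float = 0.8,
                     categories=CATEGORIES_96, prefix: str = "S") -> SignatureSet:
    """Well-separated synthetic signatures: each concentrates ``peak_mass``
    on its own block of categories with the rest spread uniformly.

    Pairwise cosine is low (~0.2 at default mass), which makes NMF recovery
    identifiable; profiles are deterministic (no RNG).
    """
    n_cat = len(categories)
    if k > n_cat:
        raise ValueError("more signatures than categories")
    block = n_cat // k
    off = n_cat - block
    mat = np.zeros((k, n_cat))
    for i in range(k):
        if off:
            mat[i, :] = (1 - peak_mass) / off
            mat[i, i * block : (i + 1) * block] = peak_mass / block
        else:  # single signature spanning every category
            mat[i, :] = 1.0 / n_cat
    ids = [f"{prefix}{i + 1}" for i in range(k)]
    return SignatureSet.from_matrix(ids, mat, categories)


def block_rs_profiles(k: int = 3, peak_mass: float = 0.8) -> SignatureSet:
    return block_signatures(k, peak_mass, SV_CATEGORIES_32, prefix="RS")


# -------------------------------------------------------------------- genome


@dataclass
class Genome:
    contigs: dict[str, str]
    genes: pd.DataFrame  # gene, chrom, start, end, strand
    timing: TimingTrack

    def size(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the conditions the validation suite runs at: a compact
    two-contig genome, 50 samples of ~300 mutations each from five
    well-separated signatures with sparse Dirichlet mixing (alpha = 0.5),
    no timing tilt or strand bias unless planted.
    """

    seed: int = 0
    n_samples: int = 50
    mutations_per_sample: float = 300.0
    contig_sizes: dict = field(default_factory=lambda: {"chr1": 600_000,
                                                        "chr2": 600_000})
    gc_content: float = 0.42
    n_genes: int = 150
    gene_length: int = 4_000
    timing_bin: int = 5_000
    timing_period: int = 200_000
    n_signatures: int = 5
    dirichlet_alpha: float = 0.5
    timing_slope: dict = field(default_factory=dict)  # sig -> tilt coefficient
    lagging_bias: dict = field(default_factory=dict)  # sig -> P(lagging)
    clonal_fraction: float = 0.7
    kataegis_rate: float = 0.0  # expected foci per sample
    kataegis_signature: str | None = None
    kataegis_n: tuple = (6, 12)
    sv_per_sample: float = 25.0
    n_rs: int = 3
    rs_dirichlet_alpha: float = 0.7
    hd_fraction: float = 0.3
    arm_event_rate: float = 0.15
    translocation_probs: dict = field(default_factory=lambda: {
        "none": 0.4, "t(11;14)": 0.2, "t(4;14)": 0.15, "t(14;16)": 0.1,
        "t(14;20)": 0.05, "t(8;14) MYC": 0.1})
    baseline_hazard: float = 1 / 40.0  # per month
    censoring_rate: float = 1 / 90.0
    group_hrs: dict = field(default_factory=dict)  # cluster label -> HR

    def signatures(self) -> SignatureSet:
        return block_signatures(self.n_signatures)

    def rs_profiles(self) -> SignatureSet:
        return block_rs_profiles(self.n_rs)


def simulate_genome(config: SimulationConfig, rng=None) -> Genome:
    """Random genome with genes and a sinusoidal replication-timing track."""
    rng = rng or substreams(config.seed)["genome"]
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs = {}
    for chrom, size in config.contig_sizes.items():
        if size < 10_000:
            raise ValueError(f"contig {chrom} shorter than 10 kb")
        idx = rng.choice(4, size=size, p=probs)
        contigs[chrom] = "".join(np.array(list("ACGT"))[idx])
    genes = []
    chroms = list(config.contig_sizes)
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        size = config.contig_sizes[chrom]
        start = int(rng.integers(0, max(1, size - config.gene_length)))
        genes.append({"gene": f"G{i + 1:04d}", "chrom": chrom,
                      "start": start, "end": start + config.gene_length,
                      "strand": "+" if rng.random() < 0.5 else "-"})
    genes_df = pd.DataFrame(
        genes, columns=["gene", "chrom", "start", "end", "strand"])
    bins = []
    for chrom, size in config.contig_sizes.items():
        starts = np.arange(0, size, config.timing_bin)
        ends = np.minimum(starts + config.timing_bin, size)
        mids = (starts + ends) / 2
        signal = 50 + 40 * np.sin(2 * np.pi * mids / config.timing_period)
        for s, e, v in zip(starts, ends, signal):
            bins.append({"chrom": chrom, "start": int(s), "end": int(e),
                         "signal": float(v)})
    track = TimingTrack(pd.DataFrame(bins))
    return Genome(contigs, genes_df, track)


# ----------------------------------------------------------------- mutations

_BASE_CODE = {b: i for i, b in enumerate(BASES)}


class _PositionSampler:
    """Genome positions indexed by pyrimidine context class, with per-position
    decile, fork direction and pyrimidine strand for tilted sampling."""

    def __init__(self, genome: Genome):
        self.chrom_names = list(genome.contigs)
        cls_pos: dict[str, list] = {c: [] for c in CONTEXT_CLASSES_32}
        # map 3-mer code -> (class index, pyr strand)
        code_to_cls = np.full(64, -1, dtype=int)
        code_to_pyr = np.zeros(64, dtype=int)
        cls_index = {c: i for i, c in enumerate(CONTEXT_CLASSES_32)}
        for f5 in BASES:
            for c in BASES:
                for f3 in BASES:
                    code = 16 * _BASE_CODE[f5] + 4 * _BASE_CODE[c] + _BASE_CODE[f3]
                    tri = f5 + c + f3
                    if c in "CT":
                        code_to_cls[code] = cls_index[tri]
                        code_to_pyr[code] = 1
                    else:
                        rc = "".join(COMPLEMENT[b] for b in reversed(tri))
                        code_to_cls[code] = cls_index[rc]
                        code_to_pyr[code] = -1
        self.data = {}
        for ci, chrom in enumerate(self.chrom_names):
            seq = genome.contigs[chrom]
            codes = np.array([_BASE_CODE[b] for b in seq], dtype=np.int64)
            tri = 16 * codes[:-2] + 4 * codes[1:-1] + codes[2:]
            cls = code_to_cls[tri]
            pyr = code_to_pyr[tri]
            pos = np.arange(2, len(seq))  # 1-based center positions
            muts = pd.DataFrame({"chrom": pd.Series([chrom] * len(pos)),
                                 "pos": pos})
            dec = genome.timing._lookup(muts["chrom"], muts["pos"], "decile")
            fork = genome.timing._lookup(muts["chrom"], muts["pos"], "fork_dir")
            for k in range(32):
                m = cls == k
                if m.any():
                    cls_pos[CONTEXT_CLASSES_32[k]].append(
                        (np.full(m.sum(), ci), pos[m], pyr[m],
                         dec[m], fork[m]))
        self.index = {}
        for c, chunks in cls_pos.items():
            if chunks:
                self.index[c] = tuple(np.concatenate([ch[i] for ch in chunks])
                                      for i in range(5))
        self._weight_cache: dict = {}

    def sample(self, cls: str, sig_id: str, slope: float, lag_bias: float,
               n: int, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Draw n positions of a class under a signature's timing/strand tilt.

        Returns (chrom index, 1-based position, pyrimidine strand).
        """
        if cls not in self.index:
            raise ValueError(f"no genomic opportunities for context {cls}")
        ci, pos, pyr, dec, fork = self.index[cls]
        key = (cls, sig_id)
        if key not in self._weight_cache:
            w = np.ones(len(pos))
            if slope:
                w *= np.exp(slope * (np.nan_to_num(dec, nan=5.5) - 5.5) / 4.5)
            if lag_bias != 0.5:
                strand = fork * pyr  # >0 leading, <0 lagging
                w *= np.where(strand < 0, lag_bias,
                              np.where(strand > 0, 1 - lag_bias, 0.5))
            cw = np.cumsum(w)
            self._weight_cache[key] = cw / cw[-1]
        cw = self._weight_cache[key]
        idx = np.searchsorted(cw, rng.random(n), side="right")
        return ci[idx], pos[idx], pyr[idx]


def _category_parts(cat: str) -> tuple[str, str, str]:
    """(context class, pyr ref, pyr alt) of a 96-category label."""
    return cat[0] + cat[2] + cat[6], cat[2], cat[4]


def simulate_mutations(
    config: SimulationConfig, genome: Genome, rng=None,
    sampler: _PositionSampler | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort's SNVs from planted signature mixtures.

    Returns (mutations, true_exposures): mutations carry sample_id, chrom,
    pos, ref, alt, vaf, gene, category and the generating true_signature;
    exposures are the realized per-sample mutation counts per signature.
    """
    rng = rng or substreams(config.seed)["mutations"]
    sigs = config.signatures()
    S = sigs.matrix()
    k = S.shape[0]
    sampler = sampler or _PositionSampler(genome)
    gene_lookup = _GeneLookup(genome.genes)
    rows = []
    exposures = np.zeros((config.n_samples, k), dtype=int)
    sample_ids = [f"MM{j + 1:04d}" for j in range(config.n_samples)]
    for j, sid in enumerate(sample_ids):
        p = rng.dirichlet(np.full(k, config.dirichlet_alpha))
        n_mut = rng.poisson(config.mutations_per_sample)
        sig_counts = rng.multinomial(n_mut, p)
        exposures[j] = sig_counts
        for si, n_s in enumerate(sig_counts):
            if n_s == 0:
                continue
            sig_id = sigs.ids[si]
            cat_counts = rng.multinomial(n_s, S[si])
            for cati in np.nonzero(cat_counts)[0]:
                cat = CATEGORIES_96[cati]
                cls, pref, palt = _category_parts(cat)
                n_c = int(cat_counts[cati])
                ci, pos, pyr = sampler.sample(
                    cls, sig_id,
                    config.timing_slope.get(sig_id, 0.0),
                    config.lagging_bias.get(sig_id, 0.5),
                    n_c, rng)
                for cc, pp, st in zip(ci, pos, pyr):
                    if st > 0:
                        ref, alt = pref, palt
                    else:
                        ref, alt = COMPLEMENT[pref], COMPLEMENT[palt]
                    rows.append((sid, sampler.chrom_names[cc], int(pp),
                                 ref, alt, cat, sig_id))
    muts = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref",
                                       "alt", "category", "true_signature"])
    clonal = rng.random(len(muts)) < config.clonal_fraction
    vaf = np.where(clonal, rng.uniform(0.905, 1.0, len(muts)),
                   rng.uniform(0.05, 0.9, len(muts)))
    muts["vaf"] = np.round(vaf, 4)
    muts["gene"] = gene_lookup(muts)
    muts["context_class"] = [
        _category_parts(c)[0] for c in muts["category"]]
    muts = muts.sort_values(["sample_id", "chrom", "pos"]).reset_index(drop=True)
    exp_df = pd.DataFrame(exposures, index=pd.Index(sample_ids, name="sample_id"),
                          columns=list(sigs.ids))
    return muts, exp_df


class _GeneLookup:
    def __init__(self, genes: pd.DataFrame):
        self.genes = genes

    def __call__(self, muts: pd.DataFrame) -> pd.Series:
        out = np.full(len(muts), None, dtype=object)
        for chrom, g in muts.groupby("chrom"):
            gh = self.genes[self.genes["chrom"] == chrom]
            if gh.empty:
                continue
            starts = gh["start"].to_numpy()
            ends = gh["end"].to_numpy()
            names = gh["gene"].to_numpy()
            p = g["pos"].to_numpy() - 1
            for row_i, pp in zip(g.index, p):
                hit = np.nonzero((starts <= pp) & (pp < ends))[0]
                if len(hit):
                    out[row_i] = names[hit[0]]
        return pd.Series(out, index=muts.index)


def inject_kataegis(
    muts: pd.DataFrame, config: SimulationConfig, genome: Genome, rng=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add tight hypermutation runs from the configured generating signature.

    Each focus picks 6+ positions inside a dense window (window span keeps
    the mean inter-mutation distance well under 1 kb), weighting position
    choice by the generating signature's context-class marginal — the way a
    context-specific mutator concentrates on its preferred motifs — and
    then draws the alt allele from the signature's conditional distribution
    given the local context. Emitted records therefore stay consistent with
    the genome sequence while the focus catalog matches the generating
    profile. Returns (augmented mutations, truth table of injected foci).
    """
    rng = rng or substreams(config.seed)["kataegis"]
    if config.kataegis_rate <= 0 or config.kataegis_signature is None:
        return muts, pd.DataFrame(columns=["sample_id", "chrom", "start",
                                           "end", "n"])
    sigs = config.signatures()
    si = list(sigs.ids).index(config.kataegis_signature)
    S = sigs.matrix()[si]
    cat_class = np.array([_category_parts(c)[0] for c in CATEGORIES_96])
    cls_index = {c: i for i, c in enumerate(CONTEXT_CLASSES_32)}
    class_marginal = np.zeros(32)
    for cat_i, cls in enumerate(cat_class):
        class_marginal[cls_index[cls]] += S[cat_i]
    chroms = list(genome.contigs)
    new_rows, truth = [], []
    for sid in sorted(muts["sample_id"].unique()):
        n_foci = rng.poisson(config.kataegis_rate)
        for _ in range(n_foci):
            n_mut = int(rng.integers(config.kataegis_n[0],
                                     config.kataegis_n[1] + 1))
            chrom = chroms[int(rng.integers(len(chroms)))]
            seq = genome.contigs[chrom]
            span = n_mut * 250  # dense window: any subset has mean IMD << 1 kb
            anchor = int(rng.integers(2, len(seq) - span - 2))
            window = np.arange(anchor, anchor + span)
            cls_ids = np.full(len(window), -1)
            pyr = np.zeros(len(window), dtype=int)
            for k, p in enumerate(window):
                tri = seq[p - 2 : p + 1].upper()
                if "N" in tri:
                    continue
                if tri[1] in "CT":
                    cls_ids[k] = cls_index[tri]
                    pyr[k] = 1
                else:
                    rc = "".join(COMPLEMENT[b] for b in reversed(tri))
                    cls_ids[k] = cls_index[rc]
                    pyr[k] = -1
            valid = cls_ids >= 0
            w = np.where(valid, class_marginal[np.clip(cls_ids, 0, 31)], 0.0)
            if (w > 0).sum() < n_mut:
                continue
            picked = rng.choice(len(window), size=n_mut, replace=False,
                                p=w / w.sum())
            positions = []
            for k in sorted(picked):
                p = int(window[k])
                cls = CONTEXT_CLASSES_32[cls_ids[k]]
                cats = np.nonzero(cat_class == cls)[0]
                cw = S[cats]
                if cw.sum() == 0:
                    cw = np.ones(len(cats))
                alt_i = int(rng.choice(cats, p=cw / cw.sum()))
                _, pref, palt = _category_parts(CATEGORIES_96[alt_i])
                if pyr[k] > 0:
                    ref, alt = pref, palt
                else:
                    ref, alt = COMPLEMENT[pref], COMPLEMENT[palt]
                new_rows.append({
                    "sample_id": sid, "chrom": chrom, "pos": p,
                    "ref": ref, "alt": alt,
                    "category": CATEGORIES_96[alt_i],
                    "true_signature": config.kataegis_signature,
                    "vaf": round(float(rng.uniform(0.905, 1.0)), 4),
                    "gene": None,
                    "context_class": cls})
                positions.append(p)
            if len(positions) >= 6:
                truth.append({"sample_id": sid, "chrom": chrom,
                              "start": min(positions), "end": max(positions),
                              "n": len(positions)})
    if not new_rows:
        return muts, pd.DataFrame(truth)
    out = pd.concat([muts, pd.DataFrame(new_rows)], ignore_index=True)
    out = out.sort_values(["sample_id", "chrom", "pos"]).reset_index(drop=True)
    return out, pd.DataFrame(truth)


# ------------------------------------------------------------ SV / CNV / OS


def _materialize_sv(sid: str, cat: str, chroms: list, sizes: dict, rng,
                    cluster_state: dict) -> SVEvent:
    clustered = cat.startswith("clustered")
    parts = cat.split(":")
    sv_type = parts[1]
    if sv_type == "TRA":
        if clustered:
            c1, p1 = _cluster_pos(cluster_state, chroms, sizes, rng)
            c2 = chroms[int(rng.integers(len(chroms)))]
            while c2 == c1:
                c2 = chroms[int(rng.integers(len(chroms)))]
        else:
            i1, i2 = rng.choice(len(chroms), size=2, replace=False)
            c1, c2 = chroms[int(i1)], chroms[int(i2)]
            p1 = int(rng.integers(1, sizes[c1]))
        p2 = int(rng.integers(1, sizes[c2]))
        return SVEvent(sid, "TRA", c1, p1, c2, p2)
    low, high = SIZE_BINS[SIZE_BIN_LABELS.index(parts[2])]
    high = high or 50_000_000
    size = int(np.exp(rng.uniform(np.log(low), np.log(high))))
    if clustered:
        chrom, p1 = _cluster_pos(cluster_state, chroms, sizes, rng)
    else:
        chrom = chroms[int(rng.integers(len(chroms)))]
        p1 = int(rng.integers(1, max(2, sizes[chrom] - min(size, sizes[chrom] - 2))))
    size = min(size, sizes[chrom] - 2)
    p2 = min(p1 + size, sizes[chrom] - 1)
    if p2 == p1:
        p2 = p1 + 1
    return SVEvent(sid, sv_type, chrom, p1, chrom, p2)


def _cluster_pos(state: dict, chroms: list, sizes: dict, rng) -> tuple[str, int]:
    """All clustered draws of one sample walk a single tight window (gaps of
    0.5-2 kb), so a genuine breakpoint run materializes on one chromosome."""
    if "chrom" not in state:
        state["chrom"] = chroms[int(rng.integers(len(chroms)))]
        state["pos"] = int(rng.integers(1, max(2, sizes[state["chrom"]] // 2)))
    state["pos"] += int(rng.integers(500, 2_000))
    return state["chrom"], state["pos"]


def simulate_svs(
    config: SimulationConfig,
    sample_ids: list,
    chrom_sizes: dict | None = None,
    rng=None,
) -> tuple[list[SVEvent], pd.DataFrame]:
    """SV events drawn from planted rearrangement-signature mixtures.

    Clustered-category events are materialized as tight breakpoint runs.
    Returns (events, true RS exposures as realized counts).
    """
    rng = rng or substreams(config.seed)["sv"]
    rs = config.rs_profiles()
    R = rs.matrix()
    chrom_sizes = chrom_sizes or {f"chr{i}": 100_000_000 for i in range(1, 11)}
    chroms = list(chrom_sizes)
    events: list[SVEvent] = []
    exposures = np.zeros((len(sample_ids), R.shape[0]), dtype=int)
    for j, sid in enumerate(sample_ids):
        p = rng.dirichlet(np.full(R.shape[0], config.rs_dirichlet_alpha))
        n_sv = rng.poisson(config.sv_per_sample)
        rs_counts = rng.multinomial(n_sv, p)
        exposures[j] = rs_counts
        cluster_state: dict = {}
        for ri, n_r in enumerate(rs_counts):
            cat_counts = rng.multinomial(n_r, R[ri])
            for cati in np.nonzero(cat_counts)[0]:
                for _ in range(int(cat_counts[cati])):
                    events.append(_materialize_sv(
                        sid, SV_CATEGORIES_32[cati], chroms, chrom_sizes,
                        rng, cluster_state))
    exp_df = pd.DataFrame(exposures,
                          index=pd.Index(sample_ids, name="sample_id"),
                          columns=list(rs.ids))
    return events, exp_df


def simulate_cnv(
    config: SimulationConfig, sample_ids: list, rng=None,
    chrom_sizes: dict | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """CNV segments realizing the hyperdiploidy / arm-event plan.

    Returns (segments table, planted HD truth, translocation labels per
    sample). Chromosome sizes default to a compact 22-autosome model;
    arm-event bands live on chr1 and chr17 at fixed fixture coordinates
    (see ``cytoband_fixture``).
    """
    rng = rng or substreams(config.seed)["cnv"]
    chrom_sizes = chrom_sizes or default_chrom_sizes()
    bands = cytoband_fixture()
    rows = []
    hd_truth = {}
    tra_labels = {}
    tra_names = list(config.translocation_probs)
    tra_p = np.array(list(config.translocation_probs.values()), dtype=float)
    tra_p = tra_p / tra_p.sum()
    autosomes = list(chrom_sizes)
    for sid in sample_ids:
        tra_labels[sid] = tra_names[int(rng.choice(len(tra_names), p=tra_p))]
        is_hd = rng.random() < config.hd_fraction
        hd_truth[sid] = bool(is_hd)
        if is_hd:
            n_amp = int(rng.integers(2, 6))
            amped = rng.choice(autosomes, size=n_amp, replace=False)
            for chrom in amped:
                size = chrom_sizes[chrom]
                frac = rng.uniform(0.92, 1.0)
                rows.append({"sample_id": sid, "chrom": chrom, "start": 0,
                             "end": int(size * frac),
                             "log2_ratio": round(rng.uniform(0.3, 0.6), 3)})
        for r in bands.itertuples():
            if rng.random() < config.arm_event_rate:
                sign = 1 if "q2" in r.band else -1
                mid = (r.start + r.end) // 2
                half = int(rng.integers(700_000, 3_000_000))
                rows.append({
                    "sample_id": sid, "chrom": r.chrom,
                    "start": max(0, mid - half), "end": mid + half,
                    "log2_ratio": round(sign * rng.uniform(0.2, 0.5), 3)})
    return (pd.DataFrame(rows), pd.Series(hd_truth, name="hd_truth"),
            pd.Series(tra_labels, name="translocation"))


def default_chrom_sizes() -> dict[str, int]:
    return {f"chr{i}": 60_000_000 for i in range(1, 23)}


def cytoband_fixture() -> pd.DataFrame:
    """Synthetic cytoband coordinates for the five prognostic bands.

    These are fixture positions on the compact default chromosome model,
    not genome-build coordinates.
    """
    return pd.DataFrame([
        {"band": "1p12", "chrom": "chr1", "start": 18_000_000, "end": 20_000_000},
        {"band": "1p32.3", "chrom": "chr1", "start": 8_000_000, "end": 9_500_000},
        {"band": "1q21.1", "chrom": "chr1", "start": 32_000_000, "end": 34_000_000},
        {"band": "1q23.3", "chrom": "chr1", "start": 40_000_000, "end": 41_500_000},
        {"band": "17p13", "chrom": "chr17", "start": 1_000_000, "end": 3_000_000},
    ])


def simulate_clinical(
    config: SimulationConfig,
    sample_ids: list,
    group_labels: pd.Series | None = None,
    rng=None,
) -> pd.DataFrame:
    """Clinical records with exponential proportional-hazards survival.

    Each sample's hazard is ``baseline_hazard`` times its group's HR (from
    ``config.group_hrs``, default 1); censoring is independent exponential
    plus administrative cutoff. Times in months, event flag 1 = observed.
    """
    rng = rng or substreams(config.seed)["clinical"]
    rows = []
    for sid in sample_ids:
        grp = group_labels.get(sid, "none") if group_labels is not None else "none"
        hr = config.group_hrs.get(grp, 1.0)
        t_event = rng.exponential(1 / (config.baseline_hazard * hr))
        t_cens = min(rng.exponential(1 / config.censoring_rate), 120.0)
        t = min(t_event, t_cens)
        rows.append({
            "sample_id": sid,
            "age": int(rng.integers(40, 85)),
            "sex": "F" if rng.random() < 0.45 else "M",
            "group": grp,
            "pfs_time": round(t, 2), "pfs_event": int(t_event <= t_cens),
            "os_time": round(min(t * rng.uniform(1.0, 2.0), 120.0), 2),
            "os_event": int(t_event <= t_cens),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_clustered_cohort(
    n_samples: int = 800,
    n_clusters: int = 4,
    n_features: int = 8,
    separation: float = 0.35,
    noise: float = 0.04,
    high_risk_cluster: int = 3,
    hr: float = 2.0,
    baseline_hazard: float = 1 / 40.0,
    censoring_target: float = 0.30,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Signature-proportion cohort with planted clusters and survival.

    Each cluster has its own simplex centroid (mass ``separation`` moved
    onto cluster-specific features); samples scatter around it with
    truncated Gaussian noise and renormalization. One cluster carries a
    planted PFS hazard ratio ``hr``; censoring is tuned to the target
    fraction under the baseline hazard. Returns (features, true labels,
    clinical table).
    """
    rng = np.random.default_rng(seed)
    base = np.full(n_features, 1.0 / n_features)
    centroids = []
    for c in range(n_clusters):
        cen = base * (1 - separation)
        own = [c % n_features, (c + n_clusters) % n_features]
        for f in set(own):
            cen[f] += separation / len(set(own))
        centroids.append(cen / cen.sum())
    labels = rng.integers(0, n_clusters, size=n_samples)
    X = np.empty((n_samples, n_features))
    for i, lab in enumerate(labels):
        v = np.clip(centroids[lab] + rng.normal(0, noise, n_features), 1e-6, None)
        X[i] = v / v.sum()
    ids = [f"MM{i + 1:04d}" for i in range(n_samples)]
    features = pd.DataFrame(X, index=pd.Index(ids, name="sample_id"),
                            columns=[f"F{j + 1}" for j in range(n_features)])
    truth = pd.Series([chr(ord("A") + int(c)) for c in labels], index=features.index,
                      name="true_cluster")
    # censoring hazard giving roughly the target censored fraction
    cens_hazard = baseline_hazard * censoring_target / (1 - censoring_target)
    rows = []
    for sid, lab in zip(ids, labels):
        h = baseline_hazard * (hr if lab == high_risk_cluster else 1.0)
        t_event = rng.exponential(1 / h)
        t_cens = rng.exponential(1 / cens_hazard)
        rows.append({"sample_id": sid,
                     "pfs_time": round(min(t_event, t_cens), 3),
                     "pfs_event": int(t_event <= t_cens),
                     "age": int(rng.integers(40, 85)),
                     "sex": int(rng.random() < 0.45),
                     "high_risk_truth": int(lab == high_risk_cluster)})
    clinical = pd.DataFrame(rows).set_index("sample_id")
    return features, truth, clinical


def simulate_expression(
    config: SimulationConfig, genes: pd.DataFrame, sample_ids: list, rng=None,
) -> pd.DataFrame:
    """Log-normal FPKM table (genes x samples) with gene-level means.

    Each gene has a fixed latent mean expression; per-sample values jitter
    around it, and ~15% of genes are silent (FPKM 0) to exercise
    tie-handling in the pentile construction.
    """
    rng = rng or substreams(config.seed)["expression"]
    n_genes = len(genes)
    mean = rng.normal(1.0, 1.5, size=n_genes)
    silent = rng.random(n_genes) < 0.15
    vals = np.exp(mean[:, None] + rng.normal(0, 0.4, size=(n_genes, len(sample_ids))))
    vals[silent] = 0.0
    return pd.DataFrame(np.round(vals, 4), index=genes["gene"].to_numpy(),
                        columns=list(sample_ids))


# ------------------------------------------------------------------ writers


def write_fasta(contigs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA into an in-memory chrom -> sequence mapping."""
    import pyfaidx

    with pyfaidx.Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def mutations_frame_to_objects(muts: pd.DataFrame) -> list[Mutation]:
    return [
        Mutation(r.sample_id, r.chrom, int(r.pos), r.ref, r.alt,
                 vaf=None if pd.isna(r.vaf) else float(r.vaf),
                 gene=None if pd.isna(r.gene) else r.gene)
        for r in muts.itertuples()
    ]
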