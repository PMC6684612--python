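"""Planted-truth recovery harnesses and independent brute-force oracles.

Each harness regenerates a synthetic cohort under the documented study
conditions, runs the corresponding pipeline stage, and measures recovery
of the planted structure. The oracles here are deliberately naive
(exhaustive window scoring, per-base tallies, all-pairs scans) and fully
independent of the implementations they check.
"""

from __future__ import annotations

import hashlib
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import (
    catalog as cat_mod,
    cluster_survival as cs,
    kataegis as kat_mod,
    regional,
    replitrans as rt,
    signatures as sig_mod,
    subgroups as sg,
    synthetic as syn,
)

# --------------------------------------------------------------- oracles


def kataegis_bruteforce(positions, min_mutations: int = 6,
                        max_mean_imd: float = 1000.0) -> list[tuple[int, int]]:
    """Exhaustive-window kataegis oracle: score every contiguous window,
    merge maximal qualifying windows; returns merged (i, j) index spans."""
    pos = sorted(positions)
    n = len(pos)
    covered = [False] * n
    for i in range(n):
        for j in range(i + min_mutations - 1, n):
            gaps = [pos[t + 1] - pos[t] for t in range(i, j)]
            if sum(gaps) / len(gaps) <= max_mean_imd:
                for t in range(i, j + 1):
                    covered[t] = True
    spans = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            spans.append((i, j - 1))
            i = j
        else:
            i += 1
    return spans


def hyperdiploidy_bruteforce(segments, chrom_sizes,
                             gain_threshold: float = sg.LOG2_EVENT_THRESHOLD,
                             frac: float = sg.HD_AMPLIFIED_FRACTION,
                             min_autosomes: int = sg.HD_MIN_AUTOSOMES) -> bool:
    """Per-base tally oracle for the hyperdiploidy call."""
    n_amp = 0
    for chrom, size in chrom_sizes.items():
        base = np.zeros(size, dtype=bool)
        for s in segments:
            if s.chrom == chrom and s.log2_ratio >= gain_threshold:
                base[s.start : min(s.end, size)] = True
        if base.sum() / size >= frac:
            n_amp += 1
    return n_amp >= min_autosomes


def arm_events_bruteforce(segments, bands: pd.DataFrame,
                          threshold: float = sg.LOG2_EVENT_THRESHOLD,
                          min_bp: int = sg.ARM_EVENT_MIN_BP) -> set[str]:
    """Per-base oracle for prognostic arm events."""
    events = set()
    for r in bands.itertuples():
        sign = sg.ARM_EVENT_SIGN[r.band]
        width = r.end - r.start
        base = np.zeros(width, dtype=bool)
        for s in segments:
            if (s.chrom == r.chrom and s.end - s.start > min_bp
                    and abs(s.log2_ratio) >= threshold
                    and np.sign(s.log2_ratio) == sign):
                lo = max(s.start, r.start) - r.start
                hi = min(s.end, r.end) - r.start
                if hi > lo:
                    base[lo:hi] = True
        if base.any():
            events.add(f"{r.band} {'gain' if sign > 0 else 'del'}")
    return events


# ------------------------------------------------------------- harnesses


def signature_recovery(seed: int, n_samples: int = 200,
                       muts_per_sample: float = 500.0,
                       n_restarts: int = 10) -> dict:
    """Validation harness: de novo extraction on a five-signature cohort.

    Returns the selected rank, the worst matched cosine between true and
    extracted profiles, and the mean absolute error of fitted exposure
    proportions against the planted ones.
    """
    cfg = syn.SimulationConfig(seed=seed, n_samples=n_samples,
                               mutations_per_sample=muts_per_sample,
                               dirichlet_alpha=0.5, n_signatures=5)
    genome = syn.simulate_genome(cfg)
    muts, true_exp = syn.simulate_mutations(cfg, genome)
    catalog = cat_mod.build_catalog(
        syn.mutations_frame_to_objects(muts), genome.contigs,
        samples=list(true_exp.index))
    sig_hat, exp_hat, diag = sig_mod.extract_de_novo(
        catalog, k_range=range(2, 9), n_restarts=n_restarts, seed=seed)
    T = cfg.signatures().matrix()
    H = sig_hat.matrix()
    k = min(len(T), len(H))
    sim = np.array([[sig_mod.cosine_similarity(t, h) for h in H] for t in T])
    ri, ci = linear_sum_assignment(-sim)
    matched = sim[ri, ci]
    prop_hat = sig_mod.normalize_exposures(exp_hat).to_numpy()
    prop_true = sig_mod.normalize_exposures(true_exp).to_numpy()
    if H.shape[0] == T.shape[0]:
        mae = float(np.abs(prop_hat[:, ci] - prop_true[:, ri]).mean())
    else:
        mae = float("nan")
    return {"chosen_k": int(diag.chosen_k),
            "min_cosine": float(matched.min()),
            "exposure_mae": mae,
            "n": n_samples}


def normalization_check(seed: int, n_random: int = 1000) -> dict:
    """Validation harness: the worked normalization example plus the
    composition-identity property on random inputs."""
    example = regional.normalize_counts(12, V_CX=60, V_CY=30, W_X=900, W_Y=300)
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_random):
        U = int(rng.integers(0, 1000))
        V = int(rng.integers(1, 10_000))
        W = int(rng.integers(V, 100_000))
        if regional.normalize_counts(U, V, V, W, W) != U:
            violations += 1
    return {"worked_example": example, "identity_violations": violations,
            "n": n_random}


def kataegis_agreement(seed: int, n_instances: int = 1000) -> dict:
    """Validation harness: detector vs exhaustive-window oracle on random
    per-sample instances, plus the inclusive 1-kb boundary case."""
    rng = np.random.default_rng(seed)
    agree = 0
    for inst in range(n_instances):
        n_bg = int(rng.integers(0, 30))
        pos = list(rng.integers(1, 2_000_000, size=n_bg))
        if rng.random() < 0.6:  # plant 1-2 dense runs with near-1kb gaps
            for _ in range(int(rng.integers(1, 3))):
                start = int(rng.integers(1, 1_900_000))
                k = int(rng.integers(4, 12))
                gaps = rng.integers(50, 1500, size=k)
                pos.extend(start + np.cumsum(gaps))
        pos = sorted(set(int(p) for p in pos))
        muts = pd.DataFrame({"sample_id": "s", "chrom": "chr1", "pos": pos})
        found = {tuple(f.mutation_ids) for f in kat_mod.detect_kataegis(muts)}
        oracle = {tuple(range(i, j + 1)) for i, j in kataegis_bruteforce(pos)}
        agree += found == oracle
    boundary = pd.DataFrame({
        "sample_id": "s", "chrom": "chr1",
        "pos": 10_000 + 1_000 * np.arange(6)})
    boundary_foci = kat_mod.detect_kataegis(boundary)
    return {"agreement_fraction": agree / n_instances,
            "boundary_detected": int(len(boundary_foci) == 1
                                     and boundary_foci[0].n == 6),
            "n": n_instances}


def slope_calibration(seed: int, n_reps: int = 1000,
                      n_perm: int = 1000, alpha: float = 0.05) -> dict:
    """Validation harness: permutation slope test under an exchangeable null
    (iid decile rates); reports the rejection rate at alpha."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for rep in range(n_reps):
        rates = pd.Series(rng.gamma(5.0, 2.0, size=10),
                          index=range(1, 11))
        _, p = rt.permutation_slope_test(
            rates, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1)))
        rejections += p <= alpha
    rate = rejections / n_reps
    half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_reps)
    return {"rejection_rate": rate, "ci_low": alpha - half,
            "ci_high": alpha + half, "n": n_reps}


def strand_asymmetry_check(seed: int, n_samples: int = 50,
                           muts_per_sample: float = 500.0,
                           n_null_runs: int = 20) -> dict:
    """Validation harness: planted 70/30 lagging bias recovery plus null
    calibration (fraction of symmetric runs with zero flags)."""

    def run(seed_i: int, bias: dict) -> tuple[pd.DataFrame, syn.SimulationConfig]:
        cfg = syn.SimulationConfig(seed=seed_i, n_samples=n_samples,
                                   mutations_per_sample=muts_per_sample,
                                   lagging_bias=bias)
        genome = syn.simulate_genome(cfg)
        muts, true_exp = syn.simulate_mutations(cfg, genome)
        catalog = cat_mod.build_catalog(
            syn.mutations_frame_to_objects(muts), genome.contigs,
            samples=list(true_exp.index))
        sigs = cfg.signatures()
        exposures = sig_mod.fit_exposures(catalog, sigs)
        attribution = sig_mod.attribute_mutations(
            muts["category"], muts["sample_id"], exposures, sigs)
        strand = rt.assign_replication_strand(muts, genome.timing)
        return rt.strand_asymmetry(muts, strand, attribution,
                                   axis="replication"), cfg

    bias = {f"S{i + 1}": 0.7 for i in range(5)}  # lagging-biased mutagenesis
    planted, cfg = run(seed, bias)
    n_lead = planted[[c for c in planted.columns if c == "n_leading"]].sum().sum()
    n_lag = planted[[c for c in planted.columns if c == "n_lagging"]].sum().sum()
    pooled = abs(n_lead - n_lag) / (n_lead + n_lag)
    null_clean = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_null_runs):
        null_res, _ = run(int(rng.integers(0, 2**31 - 1)), {})
        null_clean += int(null_res["significant"].sum() == 0)
    return {"planted_imbalance": float(pooled),
            "planted_max_q": float(planted["q"].max()),
            "planted_flagged_fraction": float(planted["significant"].mean()),
            "null_clean_fraction": null_clean / n_null_runs,
            "n": n_samples}


def karyotype_agreement(seed: int, n_cases: int = 500) -> dict:
    """Validation harness: HD and arm-event calls vs per-base oracles on
    random segment sets, with threshold-boundary segments injected."""
    rng = np.random.default_rng(seed)
    chrom_sizes = {"chr1": 5_000_000, "chr2": 4_000_000, "chr17": 3_000_000}
    bands = pd.DataFrame([
        {"band": "1p12", "chrom": "chr1", "start": 1_000_000, "end": 1_200_000},
        {"band": "1p32.3", "chrom": "chr1", "start": 400_000, "end": 500_000},
        {"band": "1q21.1", "chrom": "chr1", "start": 3_000_000, "end": 3_200_000},
        {"band": "1q23.3", "chrom": "chr1", "start": 3_800_000, "end": 3_900_000},
        {"band": "17p13", "chrom": "chr17", "start": 100_000, "end": 300_000},
    ])
    loci = sg.cytoband_regions(bands)
    hd_agree = arm_agree = 0
    boundary_log2 = [sg.LOG2_EVENT_THRESHOLD, -sg.LOG2_EVENT_THRESHOLD,
                     0.16, -0.16]
    for case in range(n_cases):
        segs = []
        for _ in range(int(rng.integers(1, 12))):
            chrom = list(chrom_sizes)[int(rng.integers(3))]
            size = chrom_sizes[chrom]
            start = int(rng.integers(0, size - 10))
            end = int(rng.integers(start + 1, size))
            if rng.random() < 0.2:
                lr = float(boundary_log2[int(rng.integers(4))])
            else:
                lr = float(np.round(rng.normal(0, 0.4), 4))
            if rng.random() < 0.1:  # exact 1 Mb segment at the size boundary
                end = min(start + 1_000_000, size)
            segs.append(sg.CNVSegment("s", chrom, start, end, lr))
        hd_agree += (sg.call_hyperdiploidy(segs, chrom_sizes)
                     == hyperdiploidy_bruteforce(segs, chrom_sizes))
        arm_agree += (sg.call_arm_events(segs, loci)
                      == arm_events_bruteforce(segs, bands))
    return {"hd_agreement_fraction": hd_agree / n_cases,
            "arm_agreement_fraction": arm_agree / n_cases,
            "n": n_cases}


def cluster_survival_recovery(seed: int, n_reps: int = 20,
                              n_resamples: int = 100) -> dict:
    """Validation harness: consensus clustering + survival staging over
    seeded replicates of the 4-cluster planted-hazard cohort."""
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(seed)
    ok_ari = ok_lr = ok_cox = ok_tier = 0
    hrs = []
    for rep in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        feat, truth, clin = syn.simulate_clustered_cohort(seed=rep_seed)
        model = cs.consensus_cluster(feat, k_range=range(2, 7),
                                     n_resamples=n_resamples, seed=rep_seed)
        ari = adjusted_rand_score(truth, model.labels)
        _, lr_p = cs.logrank(model.labels, clin["pfs_time"], clin["pfs_event"])
        df = clin.join(model.labels)
        high_lab = df.groupby("cluster")["high_risk_truth"].mean().idxmax()
        df["high_risk_cluster"] = (df["cluster"] == high_lab).astype(int)
        cox = cs.cox_multivariate(df, "pfs_time", "pfs_event",
                                  ["age", "sex", "high_risk_cluster"])
        hr = float(cox.loc["high_risk_cluster", "hr"])
        hrs.append(hr)
        tiers = cs.delineate_risk(df["cluster"], df["pfs_time"],
                                  df["pfs_event"])
        ok_ari += ari > 0.9
        ok_lr += lr_p < 0.01
        ok_cox += 1.7 <= hr <= 2.35
        ok_tier += tiers.get(high_lab) == "high"
    return {"ari_fraction": ok_ari / n_reps,
            "logrank_fraction": ok_lr / n_reps,
            "cox_in_band_fraction": ok_cox / n_reps,
            "high_tier_fraction": ok_tier / n_reps,
            "median_hr": float(np.median(hrs)),
            "n": n_reps}


def determinism_check(seed: int) -> dict:
    """Validation harness: the full pipeline twice with one seed; 1 iff all
    written files are byte-identical."""
    from .pipeline import run_pipeline

    cfg = syn.SimulationConfig(seed=seed, n_samples=25,
                               mutations_per_sample=200,
                               kataegis_rate=0.3, kataegis_signature="S2")

    def run_and_hash() -> dict:
        with tempfile.TemporaryDirectory() as tmp:
            run_pipeline(cfg, tmp)
            return {
                str(p.relative_to(tmp)): hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(Path(tmp).rglob("*")) if p.is_file()
            }

    h1, h2 = run_and_hash(), run_and_hash()
    return {"identical": int(h1 == h2), "n_files": len(h1), "n": len(h1)}
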