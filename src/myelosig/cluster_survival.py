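"""Consensus clustering of signature activities and survival staging.

Patients are clustered on per-sample proportional contributions of the de
novo rearrangement signatures plus the major SNV signatures. Consensus
clustering: for each candidate k, the cohort is repeatedly subsampled (80%
by default) and hierarchically clustered (average linkage, Euclidean); the
consensus matrix holds, per sample pair, the fraction of co-subsampled runs
in which the pair co-clustered. Final labels come from average-linkage
clustering of 1 - consensus; k maximizes the mean intra-cluster consensus
penalized linearly in k.

Survival staging: global log-rank across clusters, pairwise log-rank with
BH for the low/high-risk delineation, and multivariate Cox for adjusted
hazard ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ClusterModel:
    features: pd.DataFrame
    consensus: pd.DataFrame  # chosen-k consensus, samples x samples
    chosen_k: int
    labels: pd.Series  # sample -> cluster label "A", "B", ...
    k_scores: pd.DataFrame = field(default_factory=pd.DataFrame)
    risk_tiers: pd.Series | None = None


def _consensus_matrix(
    X: np.ndarray, k: int, n_resamples: int, subsample_frac: float, rng
) -> np.ndarray:
    n = X.shape[0]
    m = max(2, int(round(subsample_frac * n)))
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        idx.sort()
        Z = linkage(X[idx], method="average", metric="euclidean")
        lab = fcluster(Z, t=k, criterion="maxclust")
        same = lab[:, None] == lab[None, :]
        sampled[np.ix_(idx, idx)] += 1
        together[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        cons = np.where(sampled > 0, together / sampled, 0.0)
    np.fill_diagonal(cons, 1.0)
    return (cons + cons.T) / 2


def consensus_cluster(
    features: pd.DataFrame,
    k_range=range(2, 8),
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    area_gain_min: float = 0.1,
) -> ClusterModel:
    """Consensus hierarchical clustering with explicit k selection.

    k selection follows the consensus-CDF area criterion: with pairwise
    consensus values c_ij, the area under their empirical CDF is
    A(k) = 1 - mean(c_ij). Splitting a genuine cluster pair cleanly moves
    its consensus from 1 to 0 and grows A(k); once additional components
    only split stable clusters arbitrarily, the gain collapses. Scanning k
    upward, k is accepted while the relative gain
    (A(k) - A(k-1)) / A(k-1) stays >= ``area_gain_min``. If every pairwise
    consensus at the chosen k is ~1 the cohort is effectively one cluster
    and k collapses to 1 with a warning. Deterministic given ``seed``.
    """
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    ks = sorted(k_range)
    if ks[-1] > n:
        raise ValueError(f"k_max={ks[-1]} exceeds sample count {n}")
    rng = np.random.default_rng(seed)
    k_seeds = {k: int(rng.integers(0, 2**31 - 1)) for k in ks}

    results = {}
    rows = []
    for k in ks:
        cons = _consensus_matrix(
            X, k, n_resamples, subsample_frac, np.random.default_rng(k_seeds[k])
        )
        Z = linkage(squareform(1 - cons, checks=False), method="average")
        lab = fcluster(Z, t=k, criterion="maxclust")
        iu = np.triu_indices(n, 1)
        same = (lab[:, None] == lab[None, :])[iu]
        cv = cons[iu]
        intra = float(cv[same].mean()) if same.any() else 1.0
        area = float(1.0 - cv.mean())
        results[k] = (cons, lab)
        rows.append({"k": k, "mean_intra_consensus": intra, "cdf_area": area})
    k_scores = pd.DataFrame(rows)
    areas = dict(zip(k_scores["k"], k_scores["cdf_area"]))
    chosen = ks[0]
    for prev, k in zip(ks, ks[1:]):
        gain = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
        if gain >= area_gain_min:
            chosen = k
        else:
            break
    cons, lab = results[chosen]

    off_diag = cons[np.triu_indices(n, 1)]
    if len(off_diag) and off_diag.min() > 0.999:
        logger.warning("all samples co-cluster; collapsing to a single cluster")
        chosen = 1
        lab = np.ones(n, dtype=int)

    # relabel clusters A, B, ... by decreasing size (stable tie-break on
    # first-sample order) so labels are deterministic
    order = sorted(np.unique(lab),
                   key=lambda c: (-(lab == c).sum(), np.argmax(lab == c)))
    letter = {c: chr(ord("A") + i) for i, c in enumerate(order)}
    labels = pd.Series([letter[c] for c in lab], index=features.index,
                       name="cluster")
    cons_df = pd.DataFrame(cons, index=features.index, columns=features.index)
    return ClusterModel(features, cons_df, chosen, labels, k_scores)


def logrank(
    groups: pd.Series, times: pd.Series, events: pd.Series
) -> tuple[float, float]:
    """Global k-group log-rank test; returns (statistic, P)."""
    df = pd.DataFrame({"g": groups, "t": times, "e": events}).dropna()
    if len(df["g"].unique()) < 2:
        raise ValueError("log-rank needs >= 2 non-empty groups")
    res = multivariate_logrank_test(df["t"], df["g"], df["e"])
    return float(res.test_statistic), float(res.p_value)


def cox_multivariate(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit.

    Returns per-covariate hazard ratio, 95% CI and Wald P. Constant
    covariates raise; separation/non-convergence surfaces as an error
    naming the model.
    """
    cols = [duration_col, event_col] + covariates
    df = data[cols].dropna().copy()
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant across samples")
    n_events = int(df[event_col].sum())
    if n_events < 10 * len(covariates):
        logger.warning(
            "only %d events for %d coefficients", n_events, len(covariates)
        )
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines raises various convergence errors
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    out = cph.summary[["exp(coef)", "exp(coef) lower 95%",
                       "exp(coef) upper 95%", "p"]].copy()
    out.columns = ["hr", "hr_low", "hr_high", "p"]
    return out


def _km_median(times: pd.Series, events: pd.Series) -> float:
    km = KaplanMeierFitter()
    km.fit(times, events)
    return float(km.median_survival_time_)


def delineate_risk(
    labels: pd.Series,
    times: pd.Series,
    events: pd.Series,
    alpha: float = 0.05,
) -> pd.Series:
    """Split clusters into low/high-risk tiers by pairwise survival tests.

    Clusters are ordered by Kaplan-Meier median survival; all pairwise
    log-rank P values are BH-corrected; the tier boundary is the largest
    adjacent median gap whose across-boundary pair is significant. With no
    significant boundary every cluster is one (low) tier.
    """
    df = pd.DataFrame({"g": labels, "t": times, "e": events}).dropna()
    clusters = sorted(df["g"].unique())
    if len(clusters) < 2:
        return pd.Series("low", index=clusters, name="risk_tier")
    med = {
        c: _km_median(df.loc[df["g"] == c, "t"], df.loc[df["g"] == c, "e"])
        for c in clusters
    }
    pairs, pvals = [], []
    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            res = logrank_test(
                df.loc[df["g"] == a, "t"], df.loc[df["g"] == b, "t"],
                df.loc[df["g"] == a, "e"], df.loc[df["g"] == b, "e"],
            )
            pairs.append((a, b))
            pvals.append(res.p_value)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    qmap = {frozenset(p): q for p, q in zip(pairs, qvals)}

    ordered = sorted(clusters, key=lambda c: (med[c], c))  # shortest first
    best_gap, boundary = -np.inf, None
    for i in range(len(ordered) - 1):
        a, b = ordered[i], ordered[i + 1]
        if qmap[frozenset((a, b))] < alpha:
            gap = med[b] - med[a]
            if gap > best_gap:
                best_gap, boundary = gap, i
    tiers = {}
    for i, c in enumerate(ordered):
        if boundary is None:
            tiers[c] = "low"
        else:
            tiers[c] = "high" if i <= boundary else "low"
    return pd.Series(tiers, name="risk_tier")
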