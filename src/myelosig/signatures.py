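"""Signature extraction, assignment, exposure fitting and attribution.

De novo extraction factorizes a samples x categories count matrix as
``catalog ~ Exposures @ Signatures`` with non-negativity on both factors
(NMF, Frobenius loss). Signature rows are normalized to probability
distributions; the scale is absorbed into the exposures, so an exposure is
interpretable as a number of mutations attributed to that process.

Rank selection is explicit: for each candidate rank the factorization is
restarted ``n_restarts`` times from random initializations; the best-of run
is kept, and restart stability (mean cosine of matched signatures across
restarts) plus the reconstruction-error elbow choose the rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.decomposition import NMF

FLAT_SIGNATURES = ("3", "5", "8")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two non-negative profiles, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class SignatureSet:
    """Signature ids and a (signatures x categories) probability matrix."""

    ids: list
    profiles: pd.DataFrame  # rows: ids, columns: categories, rows sum to 1

    def __post_init__(self) -> None:
        p = self.profiles.to_numpy(dtype=float)
        if (p < -1e-12).any():
            raise ValueError("signature profiles must be non-negative")
        sums = p.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("signature rows must sum to 1")

    @classmethod
    def from_matrix(cls, ids, matrix, categories) -> "SignatureSet":
        m = np.asarray(matrix, dtype=float)
        m = m / m.sum(axis=1, keepdims=True)
        return cls(list(ids), pd.DataFrame(m, index=list(ids), columns=list(categories)))

    @classmethod
    def read_tsv(cls, path) -> "SignatureSet":
        """Reference table: rows = categories in fixed order, columns = ids."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        prof = df.T
        prof = prof.div(prof.sum(axis=1), axis=0)
        return cls(list(prof.index.astype(str)), prof.set_axis(prof.index.astype(str)))

    def write_tsv(self, path) -> None:
        self.profiles.T.to_csv(path, sep="\t")

    @property
    def categories(self) -> list:
        return list(self.profiles.columns)

    def matrix(self) -> np.ndarray:
        return self.profiles.to_numpy(dtype=float)


@dataclass
class RankDiagnostics:
    """Per-rank reconstruction error and restart stability."""

    table: pd.DataFrame  # columns: k, rel_error, stability
    chosen_k: int


def _match_signatures(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Optimal one-to-one matching of rows of a to rows of b by cosine."""
    k = a.shape[0]
    sim = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            sim[i, j] = cosine_similarity(a[i], b[j])
    ri, ci = linear_sum_assignment(-sim)
    return sim[ri, ci]


def _nmf_once(X: np.ndarray, k: int, seed: int, max_iter: int = 1000):
    model = NMF(
        n_components=k,
        init="random",
        solver="cd",
        beta_loss="frobenius",
        max_iter=max_iter,
        random_state=seed,
        tol=1e-6,
    )
    W = model.fit_transform(X)
    H = model.components_
    err = np.linalg.norm(X - W @ H)
    return W, H, err


def nmf_best_of(
    X: np.ndarray, k: int, n_restarts: int, seed: int
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Best-of-restarts NMF; returns (W, H, rel_error, stability).

    Stability is the mean cosine of optimally matched signatures between
    each restart and the best run.
    """
    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    runs = [_nmf_once(X, k, int(s)) for s in restart_seeds]
    best = min(range(n_restarts), key=lambda i: runs[i][2])
    W, H, err = runs[best]
    xnorm = np.linalg.norm(X)
    sims = []
    for i, (_, Hi, _) in enumerate(runs):
        if i == best:
            continue
        sims.append(_match_signatures(H, Hi).mean())
    stability = float(np.mean(sims)) if sims else 1.0
    return W, H, err / xnorm if xnorm > 0 else 0.0, stability


def extract_de_novo(
    catalog: pd.DataFrame,
    k_range=range(2, 9),
    n_restarts: int = 20,
    seed: int = 0,
    stability_min: float = 0.9,
    elbow_gain: float = 0.05,
) -> tuple[SignatureSet, pd.DataFrame, RankDiagnostics]:
    """De novo NMF extraction with explicit rank selection.

    The rank is the largest k in ``k_range`` that is stable across restarts
    (mean matched cosine >= ``stability_min``) and still earns its extra
    component: going from k-1 to k must reduce relative reconstruction
    error by at least ``elbow_gain`` of the k-1 error. Deterministic given
    ``seed`` (one pipeline seed fans out to per-rank, per-restart seeds).

    Returns the signature set (rows normalized to 1), the exposure matrix
    on the count scale, and per-rank diagnostics.
    """
    X = catalog.to_numpy(dtype=float)
    ks = sorted(k_range)
    n_nonzero = int((X.sum(axis=1) > 0).sum())
    if ks[-1] > min(X.shape[1], n_nonzero):
        raise ValueError(
            f"k_max={ks[-1]} infeasible for catalog with {n_nonzero} "
            f"nonzero samples and {X.shape[1]} categories"
        )
    rng = np.random.default_rng(seed)
    rank_seeds = {k: int(rng.integers(0, 2**31 - 1)) for k in ks}

    results = {}
    rows = []
    for k in ks:
        W, H, rel_err, stab = nmf_best_of(X, k, n_restarts, rank_seeds[k])
        results[k] = (W, H)
        rows.append({"k": k, "rel_error": rel_err, "stability": stab})
    diag = pd.DataFrame(rows)

    # elbow: accept the next rank only while it is restart-stable and still
    # reduces relative error by >= elbow_gain of the previous rank's error
    chosen = ks[0]
    err = dict(zip(diag["k"], diag["rel_error"]))
    stab = dict(zip(diag["k"], diag["stability"]))
    for prev, k in zip(ks, ks[1:]):
        gain = (err[prev] - err[k]) / err[prev] if err[prev] > 0 else 0.0
        if stab[k] >= stability_min and gain >= elbow_gain:
            chosen = k
        else:
            break

    W, H = results[chosen]
    scale = H.sum(axis=1)
    scale[scale == 0] = 1.0
    S = H / scale[:, None]
    E = W * scale[None, :]
    # order signatures by total exposure, largest first, for stable output
    order = np.argsort(-E.sum(axis=0))
    S, E = S[order], E[:, order]
    ids = [f"N{i + 1}" for i in range(chosen)]
    sigset = SignatureSet.from_matrix(ids, S, catalog.columns)
    exposures = pd.DataFrame(E, index=catalog.index, columns=ids)
    return sigset, exposures, RankDiagnostics(diag, chosen)


def assign_to_reference(
    de_novo: SignatureSet, reference: SignatureSet, threshold: float = 0.75
) -> dict[str, tuple[str, float]]:
    """Map each de novo signature to its best reference by cosine.

    A reference is assigned only when cosine similarity is strictly above
    ``threshold``; otherwise the signature is "novel". Among references
    above threshold the most similar wins; exact ties break toward the
    earlier reference id in table order.
    """
    if list(de_novo.categories) != list(reference.categories):
        raise ValueError("category spaces differ between de novo and reference")
    R = reference.matrix()
    out = {}
    for i, sid in enumerate(de_novo.ids):
        sims = np.array([cosine_similarity(de_novo.matrix()[i], R[j])
                         for j in range(R.shape[0])])
        best = int(np.argmax(sims))  # argmax takes the first maximum: id-order tie-break
        if sims[best] > threshold:
            out[sid] = (str(reference.ids[best]), float(sims[best]))
        else:
            out[sid] = ("novel", float(sims[best]))
    return out


def fit_exposures(catalog: pd.DataFrame, signatures: SignatureSet) -> pd.DataFrame:
    """Per-sample non-negative least-squares projection onto fixed signatures.

    Exposures are on the mutation-count scale; normalize rows for the
    proportional view.
    """
    if list(catalog.columns) != list(signatures.categories):
        raise ValueError("catalog and signature category spaces differ")
    S = signatures.matrix()  # k x c
    A = S.T  # c x k
    E = np.zeros((catalog.shape[0], S.shape[0]))
    X = catalog.to_numpy(dtype=float)
    for j in range(X.shape[0]):
        E[j], _ = nnls(A, X[j])
    return pd.DataFrame(E, index=catalog.index, columns=list(signatures.ids))


def normalize_exposures(exposures: pd.DataFrame) -> pd.DataFrame:
    """Row-normalized (proportional) view; all-zero rows stay zero."""
    totals = exposures.sum(axis=1)
    out = exposures.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return out


def major_signatures(exposures: pd.DataFrame, min_mean_contribution: float = 0.01):
    """Signatures with mean proportional contribution above the cut (>1%)."""
    norm = normalize_exposures(exposures)
    means = norm.mean(axis=0)
    return list(means.index[means > min_mean_contribution])


def collapse_flat(
    exposures: pd.DataFrame, flat_ids=FLAT_SIGNATURES, name: str = "flat"
) -> pd.DataFrame:
    """Sum the flat signatures (3, 5, 8) into one combined activity column."""
    flat_ids = [str(i) for i in flat_ids]
    missing = [i for i in flat_ids if i not in exposures.columns]
    if missing:
        raise KeyError(f"flat signature ids absent from exposures: {missing}")
    rest = exposures.drop(columns=flat_ids)
    rest[name] = exposures[flat_ids].sum(axis=1)
    return rest


def attribute_mutations(
    categories: pd.Series,
    sample_ids: pd.Series,
    exposures: pd.DataFrame,
    signatures: SignatureSet,
) -> pd.DataFrame:
    """Per-mutation posterior probability over signatures.

    For a mutation of category c in sample j:
    ``P(s | c, j) = E_js * S_sc / sum_t E_jt * S_tc``.
    Rows with a zero denominator (category impossible under every active
    signature of the sample) are returned as all-NaN and should be excluded
    from attribution-based analyses. A ``signature`` column carries the
    argmax assignment (ties break to the earlier signature id).
    """
    S = signatures.matrix()  # k x c
    cat_idx = pd.Index(signatures.categories)
    ci = cat_idx.get_indexer(categories)
    if (ci < 0).any():
        bad = sorted(set(categories[ci < 0]))
        raise KeyError(f"unknown categories: {bad[:5]}")
    E = exposures.reindex(sample_ids).to_numpy(dtype=float)
    if np.isnan(E).any():
        missing = sorted(set(sample_ids) - set(exposures.index))
        raise KeyError(f"samples without fitted exposures: {missing[:5]}")
    num = E * S[:, ci].T  # n x k
    denom = num.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(denom > 0, num / denom, np.nan)
    out = pd.DataFrame(probs, columns=list(signatures.ids))
    valid = denom[:, 0] > 0
    argmax = np.full(len(out), None, dtype=object)
    if valid.any():
        idx = np.argmax(probs[valid], axis=1)
        argmax[valid] = np.asarray(list(signatures.ids), dtype=object)[idx]
    out["signature"] = argmax
    return out
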