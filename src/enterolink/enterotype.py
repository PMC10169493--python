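"""Enterotype stratification.

Samples are clustered on the square root of the Jensen-Shannon divergence
(the metric form, natural log) with Partitioning Around Medoids; the number
of clusters is chosen by the Calinski-Harabasz index computed on the full
PCoA embedding of the distance matrix. Bray-Curtis distances, PCoA and
between-class analysis (BCA) ordination support the beta-diversity views.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.metrics import calinski_harabasz_score, silhouette_samples

from .datatypes import AbundanceTable, DistanceMatrix, ValidationError

log = logging.getLogger("enterolink")

__all__ = [
    "jsd_distance",
    "bray_curtis",
    "pam",
    "ch_index",
    "pcoa",
    "bca",
    "select_enterotypes",
    "EnterotypeResult",
]


def jsd_distance(table: AbundanceTable, pseudocount: float = 1e-6) -> DistanceMatrix:
    """Root Jensen-Shannon divergence between all sample pairs.

    D_ij = sqrt( KL(P_i || M)/2 + KL(P_j || M)/2 ) with M the midpoint
    distribution and natural logarithms, so the maximum distance is
    sqrt(ln 2). A pseudocount is added (and rows renormalized) because KL is
    undefined at zeros.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    P = table.values + pseudocount
    if np.any(P.sum(axis=1) <= 0):
        raise ValidationError("sample with all-zero abundances")
    P = P / P.sum(axis=1, keepdims=True)
    n = P.shape[0]
    D = np.zeros((n, n))
    logP = np.log(P)
    for i in range(n):
        M = (P[i] + P[i:]) / 2.0
        logM = np.log(M)
        kl_i = np.sum(P[i] * (logP[i] - logM), axis=1)
        kl_j = np.sum(P[i:] * (logP[i:] - logM), axis=1)
        jsd = np.clip(0.5 * kl_i + 0.5 * kl_j, 0.0, None)
        D[i, i:] = np.sqrt(jsd)
    D = D + D.T
    np.fill_diagonal(D, 0.0)
    ids = table.sample_ids
    return DistanceMatrix(pd.DataFrame(D, index=ids, columns=ids), metric_tag="sqrt_jsd")


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, D_ij = sum|x-y| / sum(x+y), in [0, 1]."""
    X = table.values if hasattr(table, "values") and not isinstance(table, np.ndarray) else np.asarray(table)
    ids = table.sample_ids if hasattr(table, "sample_ids") else [str(i) for i in range(len(X))]
    zero_rows = np.where(X.sum(axis=1) == 0)[0]
    with np.errstate(invalid="ignore"):
        D = squareform(pdist(X, metric="braycurtis"))
    if len(zero_rows):
        warnings.warn("all-zero sample(s); their mutual Bray-Curtis set to 0", UserWarning, stacklevel=2)
        D = np.nan_to_num(D, nan=0.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(pd.DataFrame(D, index=ids, columns=ids), metric_tag="bray_curtis")


def _assign(D: np.ndarray, medoids: list[int]) -> np.ndarray:
    return np.asarray(medoids)[np.argmin(D[:, medoids], axis=1)]


def _cost(D: np.ndarray, medoids: list[int]) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def pam(D: DistanceMatrix | np.ndarray, k: int, max_swaps: int = 200, method: str = "auto"):
    """Partitioning Around Medoids, deterministic.

    For small problems (``method='auto'`` and C(n, k) <= 1000, which covers
    every cohort this pipeline targets) the exact optimum is found by
    enumerating medoid sets. Larger problems use the classic BUILD + SWAP
    heuristic: greedy seeding, then repeated best-improvement medoid /
    non-medoid exchanges to a local optimum of the total within-cluster
    distance. Ties always break toward the lowest sample index, so results
    are deterministic.

    Returns ``(labels, medoid_indices)`` with labels in 1..k numbered by
    medoid order (medoids sorted ascending).
    """
    Dm = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    n = Dm.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (got k={k}, n={n})")
    from math import comb

    if method not in ("auto", "build_swap", "exhaustive"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exhaustive" or (method == "auto" and comb(n, k) <= 1000):
        medoids = None
        best = np.inf
        for combo in itertools.combinations(range(n), k):
            c = _cost(Dm, list(combo))
            if c < best - 1e-15:
                best, medoids = c, list(combo)
        return _finalize_pam(Dm, medoids)

    # BUILD
    medoids = [int(np.argmin(Dm.sum(axis=0)))]
    while len(medoids) < k:
        current = Dm[:, medoids].min(axis=1)
        gains = np.array([np.maximum(current - Dm[:, c], 0.0).sum() if c not in medoids else -1.0 for c in range(n)])
        medoids.append(int(np.argmax(gains)))

    # SWAP: best-improvement steepest descent
    best = _cost(Dm, medoids)
    for _ in range(max_swaps):
        improved = False
        best_swap, best_cost = None, best
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = h
                c = _cost(Dm, cand)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, h)
        if best_swap is not None:
            medoids[best_swap[0]] = best_swap[1]
            best = best_cost
            improved = True
        if not improved:
            break

    return _finalize_pam(Dm, medoids)


def _finalize_pam(Dm: np.ndarray, medoids: list[int]):
    medoids = sorted(medoids)
    assign = _assign(Dm, medoids)
    labels = np.array([medoids.index(a) + 1 for a in assign])
    # medoids must sit in their own cluster
    for j, m in enumerate(medoids):
        labels[m] = j + 1
    return labels, medoids


def pam_exhaustive(D, k: int):
    """Exhaustive k-medoids optimum (oracle for small n)."""
    Dm = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    n = Dm.shape[0]
    best_cost, best_medoids = np.inf, None
    for combo in itertools.combinations(range(n), k):
        c = _cost(Dm, list(combo))
        if c < best_cost - 1e-15:
            best_cost, best_medoids = c, list(combo)
    return best_cost, best_medoids


def pcoa(D: DistanceMatrix, n_axes: int | None = None):
    """Classical scaling (principal coordinates) of a distance matrix.

    Gower-centers -D^2/2 and eigendecomposes; axes with negative eigenvalues
    are dropped (their absolute mass is logged). Returns a coordinates
    DataFrame (samples x axes, ordered by eigenvalue) and the positive
    eigenvalues.
    """
    Dm = D.values
    n = Dm.shape[0]
    A = -0.5 * Dm**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    neg_mass = float(np.abs(evals[evals < 0]).sum())
    if neg_mass > 1e-10:
        log.info("pcoa: dropping negative-eigenvalue axes (total mass %.4g)", neg_mass)
    keep = evals > 1e-10
    evals, evecs = evals[keep], evecs[:, keep]
    coords = evecs * np.sqrt(evals)
    if n_axes is not None:
        coords, evals = coords[:, :n_axes], evals[:n_axes]
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=D.sample_ids, columns=cols), evals


def ch_index(D: DistanceMatrix, labels) -> float:
    """Calinski-Harabasz index of a clustering of a distance matrix.

    Computed as [B/(k-1)] / [W/(n-k)] on the full positive-axis PCoA
    embedding, which makes the between/within sum-of-squares decomposition
    well-defined for non-Euclidean metrics.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n = len(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters")
    if len(uniq) == n:
        raise ValueError("CH undefined when every cluster is a singleton")
    coords, _ = pcoa(D)
    return float(calinski_harabasz_score(coords.to_numpy(), labels))


def bca(table, labels, n_axes: int | None = None):
    """Between-class analysis: principal axes of the class-mean matrix.

    Columns are centered; class means are weighted by class size; samples are
    projected onto the k-1 leading axes of the weighted between-class
    covariance. Returns (sample scores DataFrame, axis eigenvalues).
    """
    X = np.asarray(table.values if hasattr(table, "values") else table, dtype=float)
    ids = table.sample_ids if hasattr(table, "sample_ids") else [str(i) for i in range(len(X))]
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("bca needs >= 2 classes")
    if np.any(counts == 0):
        raise ValueError("empty class")
    Xc = X - X.mean(axis=0)
    n = len(labels)
    G = np.vstack([Xc[labels == u].mean(axis=0) for u in uniq])
    w = counts / n
    Bcov = (G * w[:, None]).T @ G
    evals, evecs = np.linalg.eigh((Bcov + Bcov.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k_axes = len(uniq) - 1 if n_axes is None else n_axes
    evals, evecs = evals[:k_axes], evecs[:, :k_axes]
    if np.all(evals < 1e-12):
        warnings.warn("identical class means: zero between-class variance", UserWarning, stacklevel=2)
    scores = Xc @ evecs
    cols = [f"BCA{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=ids, columns=cols), evals


@dataclass
class EnterotypeResult:
    """Outcome of enterotype model selection."""

    labels: pd.Series
    medoids: list[str]
    k_best: int
    ch_curve: dict[int, float]
    silhouette: pd.Series
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    metric: str = "sqrt_jsd"
    strong_stratification: bool = True
    notes: list = field(default_factory=list)

    def group_sizes(self) -> dict[int, int]:
        return self.labels.value_counts().sort_index().to_dict()


def select_enterotypes(
    table: AbundanceTable,
    metric: str = "jsd",
    k_max: int = 6,
    pseudocount: float = 1e-6,
    n_null: int = 199,
    seed: int = 0,
) -> EnterotypeResult:
    """Cluster samples into enterotypes with PAM and pick k by the CH index.

    Runs PAM for k = 2..k_max on the chosen distance, scores each k with the
    Calinski-Harabasz index on the PCoA embedding, and keeps the argmax.
    Stratification strength is screened against a permutation null in which
    each taxon column is shuffled independently (destroying sample structure
    but keeping marginal abundances) and the whole distance + PAM + CH
    pipeline is re-run; a CH(k_best) that does not beat the null's 95th
    percentile is flagged as "no strong stratification".
    """
    n = len(table.sample_ids)
    if n < 4:
        raise ValueError("need at least 4 samples")
    if k_max >= n:
        warnings.warn(f"k_max clipped from {k_max} to {n - 1}", UserWarning, stacklevel=2)
        k_max = n - 1
    D = jsd_distance(table, pseudocount) if metric == "jsd" else bray_curtis(table)

    ch_curve, labelings, medoid_sets = {}, {}, {}
    for k in range(2, k_max + 1):
        labels, medoids = pam(D, k)
        ch_curve[k] = ch_index(D, labels)
        labelings[k], medoid_sets[k] = labels, medoids
    k_best = max(ch_curve, key=lambda k: (ch_curve[k], -k))
    labels = labelings[k_best]

    coords, evals = pcoa(D)
    sil = silhouette_samples(D.values, labels, metric="precomputed")

    # permutation null for stratification strength: shuffle each taxon
    # column independently and re-run the clustering pipeline
    rng = np.random.default_rng(seed)
    vals = table.values
    null = np.empty(n_null)
    for b in range(n_null):
        perm = np.column_stack([rng.permutation(vals[:, j]) for j in range(vals.shape[1])])
        perm /= perm.sum(axis=1, keepdims=True)
        ptable = AbundanceTable(
            pd.DataFrame(perm, index=table.sample_ids, columns=table.taxon_ids)
        )
        Dp = jsd_distance(ptable, pseudocount) if metric == "jsd" else bray_curtis(ptable)
        plabels, _ = pam(Dp, k_best)
        null[b] = ch_index(Dp, plabels)
    strong = ch_curve[k_best] > np.quantile(null, 0.95)
    notes = [] if strong else ["no strong stratification: CH within permutation null range"]

    ids = table.sample_ids
    return EnterotypeResult(
        labels=pd.Series(labels, index=ids, name="enterotype"),
        medoids=[ids[m] for m in medoid_sets[k_best]],
        k_best=k_best,
        ch_curve=ch_curve,
        silhouette=pd.Series(sil, index=ids, name="silhouette"),
        coordinates=coords,
        eigenvalues=evals,
        metric=D.metric_tag,
        strong_stratification=bool(strong),
        notes=notes,
    )
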