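"""Weighted co-expression module detection (WGCNA-style), from scratch.

The construction follows the signed-hybrid recipe: Pearson correlations with
negative values zeroed are raised to a soft power chosen for approximate
scale-free topology, converted to a topological overlap matrix (TOM),
clustered by average-linkage on the TOM dissimilarity, and cut into modules
with a static quantile cut plus a minimum module size (a deliberate,
reproducible simplification of adaptive branch cutting). Modules are
summarized by eigengenes (first principal component of the standardized
member features), merged when their eigengenes are highly correlated, and
related to traits by Pearson correlation with Student-t p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "WgcnaParams",
    "ModuleSet",
    "pick_soft_power",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengenes",
    "merge_modules",
    "module_trait_correlation",
    "cor_pvalue_student",
    "fit_modules",
]

#: soft powers used per layer in the reference analysis
DEFAULT_POWERS = {"rumen_micro": 7, "rumen_metab": 18, "serum_metab": 16, "milk_metab": 20}


@dataclass
class WgcnaParams:
    """Tuning parameters for module detection.

    ``beta`` is the soft-thresholding power; ``cut_quantile`` sets the static
    dendrogram cut at that quantile of the merge heights; branches smaller
    than ``min_module_size`` fall into module 0 (unassigned); module pairs
    with eigengene correlation above ``merge_cor`` are merged.
    """

    beta: int = 7
    network_type: str = "signed_hybrid"
    min_module_size: int = 5
    cut_quantile: float = 0.90
    merge_cor: float = 0.75
    scale_free_r2_target: float = 0.8

    def __post_init__(self) -> None:
        if self.beta < 1 or int(self.beta) != self.beta:
            raise ValueError("beta must be an integer >= 1")
        if not 0 < self.merge_cor < 1:
            raise ValueError("merge_cor must lie in (0, 1)")


@dataclass
class ModuleSet:
    """Feature->module assignment with eigengenes and fit diagnostics."""

    assignment: pd.Series  # feature -> module int, 0 = unassigned
    eigengenes: pd.DataFrame  # samples x ME<k>
    beta: int
    scale_free_r2: pd.DataFrame | None = None
    var_explained: pd.Series | None = None
    params: WgcnaParams | None = None
    notes: list = field(default_factory=list)

    @property
    def module_sizes(self) -> pd.Series:
        return self.assignment[self.assignment > 0].value_counts().sort_index()

    @property
    def n_modules(self) -> int:
        return int((self.assignment.unique() > 0).sum())

    def members(self, module: int) -> list[str]:
        return list(self.assignment.index[self.assignment == module])


def _corr(X: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(X, rowvar=False)
    return c


def adjacency(matrix: pd.DataFrame, beta: int, network_type: str = "signed_hybrid") -> pd.DataFrame:
    """Signed-hybrid soft adjacency: a_ij = cor_ij^beta if cor_ij > 0 else 0.

    ``network_type='unsigned'`` uses |cor| instead. Constant features get
    zero correlations (with a warning) rather than NaNs.
    """
    X = matrix.to_numpy(dtype=float)
    c = _corr(X)
    if np.isnan(c).any():
        warnings.warn("constant feature(s): correlations set to 0", UserWarning, stacklevel=2)
        c = np.nan_to_num(c, nan=0.0)
    if network_type == "signed_hybrid":
        a = np.where(c > 0, c, 0.0) ** beta
    elif network_type == "unsigned":
        a = np.abs(c) ** beta
    else:
        raise ValueError(f"unknown network_type {network_type!r}")
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=matrix.columns, columns=matrix.columns)


def pick_soft_power(
    matrix: pd.DataFrame,
    candidate_powers=tuple(range(1, 21)),
    r2_target: float = 0.8,
    network_type: str = "signed_hybrid",
    n_bins: int = 10,
):
    """Choose the soft power by the scale-free topology criterion.

    For each candidate power the connectivity k_i = sum_j a_ij (diagonal
    excluded) is binned into ``n_bins`` bins; the fit index is the r^2 of the
    regression of log10 p(k) on log10 mean(k), signed negative when the slope
    is positive (anti-scale-free). The chosen beta is the smallest power
    reaching ``r2_target``, else the argmax with a warning.
    """
    rows = []
    for power in candidate_powers:
        a = adjacency(matrix, int(power), network_type).to_numpy()
        k = a.sum(axis=1) - 1.0
        r2, slope = _scale_free_fit(k, n_bins)
        rows.append((int(power), r2, slope, float(k.mean()), float(np.median(k)), float(k.max())))
    diag = pd.DataFrame(rows, columns=["power", "sft_r2", "slope", "mean_k", "median_k", "max_k"])
    ok = diag[diag["sft_r2"] >= r2_target]
    if len(ok):
        beta = int(ok["power"].iloc[0])
    else:
        beta = int(diag.loc[diag["sft_r2"].idxmax(), "power"])
        warnings.warn(
            f"no candidate power reaches scale-free R^2 {r2_target}; using argmax (beta={beta})",
            UserWarning,
            stacklevel=2,
        )
    return beta, diag


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) == 0:
        raise ValueError("all connectivities zero")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 2:
        raise ValueError("fewer than 2 occupied connectivity bins")
    slope, _, r, _, _ = st.linregress(xs, ys)
    r2 = float(r**2)
    return (-r2 if slope > 0 else r2), float(slope)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a symmetric adjacency in [0, 1].

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_{u != i,j} a_iu a_uj and k_i the connectivity; diagonal 1.
    """
    A = adj.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    Ad = A.copy()
    np.fill_diagonal(Ad, 0.0)
    k = Ad.sum(axis=1)
    L = Ad @ Ad  # zeroed diagonal excludes the u = i and u = j terms
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + Ad) / (kmin + 1.0 - Ad)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def detect_modules(tom_dissim: pd.DataFrame, params: WgcnaParams) -> pd.Series:
    """Average-linkage clustering of the TOM dissimilarity into modules.

    The dendrogram is cut at the ``cut_quantile`` quantile of its merge
    heights; branches below ``min_module_size`` go to module 0. Modules are
    numbered 1.. by decreasing size.
    """
    D = tom_dissim.to_numpy(dtype=float)
    feats = list(tom_dissim.index)
    if len(feats) < 2:
        return pd.Series([1] * len(feats), index=feats)
    Z = linkage(squareform((D + D.T) / 2.0, checks=False), method="average")
    heights = Z[:, 2]
    cut = float(np.quantile(heights, params.cut_quantile))
    raw = fcluster(Z, t=cut, criterion="distance")
    if len(np.unique(raw)) == 1:
        warnings.warn("all features fall in a single branch", UserWarning, stacklevel=2)
    return _relabel_by_size(pd.Series(raw, index=feats), params.min_module_size)


def _relabel_by_size(raw: pd.Series, min_size: int) -> pd.Series:
    sizes = raw.value_counts()
    keep = sizes[sizes >= min_size].sort_values(ascending=False)
    mapping = {old: new for new, old in enumerate(keep.index, start=1)}
    return raw.map(lambda m: mapping.get(m, 0)).astype(int)


def module_eigengenes(matrix: pd.DataFrame, assignment: pd.Series):
    """Module eigengenes: first PC of each module's z-scored features.

    Each eigengene is unit-norm over samples and sign-oriented so that its
    mean correlation with the member features is positive. Returns the
    eigengene DataFrame (samples x ME<k>) and the per-module variance
    explained (first squared singular value share).
    """
    modules = sorted(m for m in assignment.unique() if m > 0)
    if not modules:
        raise ValueError("no assigned modules")
    eg, ve = {}, {}
    n = matrix.shape[0]
    for m in modules:
        members = assignment.index[assignment == m]
        sub = matrix[members].to_numpy(dtype=float)
        mu, sd = sub.mean(axis=0), sub.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = (sub - mu) / sd
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        u = U[:, 0]
        cors = np.array([np.corrcoef(u, Z[:, j])[0, 1] for j in range(Z.shape[1])])
        if np.nanmean(cors) < 0:
            u = -u
        eg[f"ME{m}"] = u
        ve[f"ME{m}"] = float(S[0] ** 2 / (S**2).sum()) if (S**2).sum() > 0 else 0.0
    eigen = pd.DataFrame(eg, index=matrix.index)
    return eigen, pd.Series(ve)


def merge_modules(matrix: pd.DataFrame, assignment: pd.Series, merge_cor: float = 0.75) -> pd.Series:
    """Iteratively merge module pairs whose eigengenes correlate above
    ``merge_cor``, recomputing eigengenes after each merge, to a fixed point."""
    assignment = assignment.copy()
    for _ in range(max(assignment.max(), 1)):
        modules = sorted(m for m in assignment.unique() if m > 0)
        if len(modules) < 2:
            break
        eigen, _ = module_eigengenes(matrix, assignment)
        C = eigen.corr().to_numpy()
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] <= merge_cor:
            break
        mi, mj = modules[i], modules[j]
        assignment[assignment == mj] = mi
    # renumber by decreasing size
    return _relabel_by_size(assignment[assignment > 0], 1).reindex(assignment.index, fill_value=0)


def cor_pvalue_student(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided Student-t p-value for a Pearson correlation at sample size n."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    return 2.0 * st.t.sf(t, df=n - 2)


def module_trait_correlation(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each trait, with Student-t p."""
    if len(eigengenes) < 4:
        raise ValueError("need n >= 4 samples")
    if not eigengenes.index.equals(traits.index):
        raise ValueError("eigengene and trait samples are not aligned")
    n = len(eigengenes)
    rows = []
    for me in eigengenes.columns:
        for tr in traits.columns:
            r = float(np.corrcoef(eigengenes[me], traits[tr])[0, 1])
            rows.append((me, tr, r, float(cor_pvalue_student(np.array([r]), n)[0])))
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p"])


def fit_modules(matrix: pd.DataFrame, params: WgcnaParams | None = None, pick_power: bool = False) -> ModuleSet:
    """Full module-detection pipeline for one omics layer.

    adjacency -> TOM -> average-linkage modules -> eigengenes -> merge.
    With ``pick_power=True`` the soft power is chosen by the scale-free
    criterion instead of ``params.beta``.
    """
    params = params or WgcnaParams()
    diag = None
    beta = params.beta
    if pick_power:
        beta, diag = pick_soft_power(matrix, r2_target=params.scale_free_r2_target, network_type=params.network_type)
    adj = adjacency(matrix, beta, params.network_type)
    tom = tom_similarity(adj)
    assignment = detect_modules(1.0 - tom, params)
    notes = []
    if (assignment > 0).sum() == 0:
        notes.append("no module reached min_module_size; all features unassigned")
        return ModuleSet(assignment=assignment, eigengenes=pd.DataFrame(index=matrix.index),
                         beta=beta, scale_free_r2=diag, params=params, notes=notes)
    assignment = merge_modules(matrix, assignment, params.merge_cor)
    eigen, ve = module_eigengenes(matrix, assignment)
    return ModuleSet(
        assignment=assignment,
        eigengenes=eigen,
        beta=beta,
        scale_free_r2=diag,
        var_explained=ve,
        params=params,
        notes=notes,
    )
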