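"""Metabolome preprocessing, OPLS-DA and differential analysis.

Preprocessing applies, in order: an 80% detection rule (feature-wise within
at least one group), minimum-value imputation, a QC relative-standard-
deviation filter, per-sample sum normalization, and a log transform with a
half-minimum offset for zeros. Group discrimination uses orthogonal
projections to latent structures (OPLS-DA) with a single predictive
component; per-feature importance is the VIP score (mean VIP^2 = 1).
Differential metabolites combine a Student t-test with BH FDR, a group-mean
ratio on the pre-log scale, and the VIP gate. Pathway enrichment is the
one-sided Fisher/hypergeometric test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .datatypes import DifferentialTable

__all__ = [
    "PreprocessParams",
    "PreprocessResult",
    "preprocess",
    "OPLSDA",
    "OplsResults",
    "opls_da",
    "vip",
    "DifferentialCriteria",
    "differential_metabolites",
    "pathway_enrichment",
]


@dataclass
class PreprocessParams:
    detection_frac: float = 0.8
    qc_rsd_max: float = 0.30
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.detection_frac <= 1:
            raise ValueError("detection_frac must lie in (0, 1]")
        if self.qc_rsd_max <= 0:
            raise ValueError("qc_rsd_max must be positive")


@dataclass
class PreprocessResult:
    data: pd.DataFrame  # sum-normalized, pre-log scale
    log_data: pd.DataFrame
    dropped_detection: list = field(default_factory=list)
    dropped_qc: list = field(default_factory=list)
    params: PreprocessParams | None = None


def preprocess(
    raw: pd.DataFrame,
    qc: pd.DataFrame | None = None,
    params: PreprocessParams | None = None,
    labels=None,
) -> PreprocessResult:
    """Run the metabolome preprocessing chain on a samples x features matrix.

    Missing values are NaN. A feature is retained when detected in at least
    ``detection_frac`` of the samples of at least one group (all samples when
    no labels are given); remaining missing values are imputed with the
    feature minimum; features whose QC RSD exceeds ``qc_rsd_max`` are
    dropped; samples are sum-normalized (scaled to the mean sample total);
    the log matrix uses a per-feature half-minimum offset for zeros.
    """
    params = params or PreprocessParams()
    X = raw.astype(float).copy()
    if labels is None:
        groups = [np.ones(len(X), dtype=bool)]
    else:
        lab = np.asarray(labels)
        groups = [lab == u for u in np.unique(lab)]

    detected = X.notna()
    keep_mask = np.zeros(X.shape[1], dtype=bool)
    for mask in groups:
        keep_mask |= detected.loc[mask].mean(axis=0).to_numpy() >= params.detection_frac
    dropped_detection = list(X.columns[~keep_mask])
    X = X.loc[:, keep_mask]

    # minimum-value imputation for remaining missing entries
    mins = X.min(axis=0, skipna=True)
    X = X.fillna(mins)

    dropped_qc: list = []
    if qc is not None:
        common = [c for c in X.columns if c in qc.columns]
        qc_sub = qc[common].astype(float)
        mean = qc_sub.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rsd = qc_sub.std(axis=0, ddof=1) / mean.replace(0, np.nan)
        dropped_qc = list(rsd.index[(rsd > params.qc_rsd_max).fillna(False)])
        X = X.drop(columns=dropped_qc)
    if X.shape[1] == 0:
        raise ValueError("preprocessing dropped all features")

    sums = X.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("sample(s) with nonpositive total intensity")
    X = X.div(sums, axis=0) * float(sums.mean())

    logX = X.copy()
    for c in logX.columns:
        col = logX[c].to_numpy()
        pos = col[col > 0]
        offset = pos.min() / 2.0 if len(pos) else 1.0
        col = np.where(col <= 0, offset, col)
        logX[c] = np.log(col) / np.log(params.log_base)
    return PreprocessResult(
        data=X, log_data=logX, dropped_detection=dropped_detection, dropped_qc=dropped_qc, params=params
    )


class OPLSDA:
    """Orthogonal PLS discriminant analysis with one predictive component.

    Columns are mean-centered and unit-variance scaled; y is the centered
    +/-1 class code. ``n_ortho`` orthogonal-signal-correction components are
    removed before the predictive component is fit. With ``n_ortho=0`` the
    model reduces to one-component PLS-DA.
    """

    def __init__(self, X: pd.DataFrame, y, n_ortho: int = 1):
        self.X = X.astype(float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("OPLS-DA needs exactly two classes")
        if min((y == c).sum() for c in classes) < 2:
            raise ValueError("each class needs >= 2 samples")
        self.classes_ = classes
        self.y_code = np.where(y == classes[0], -1.0, 1.0)
        self.n_ortho = int(n_ortho)

    @staticmethod
    def _scale(X: np.ndarray, mu=None, sd=None):
        if mu is None:
            mu = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1)
            sd = np.where(sd == 0, 1.0, sd)
        return (X - mu) / sd, mu, sd

    def _decompose(self, Xs: np.ndarray, yc: np.ndarray):
        """Return (w, W_o, P_o, t, p_load, q) of the OSC-filtered model."""
        w = Xs.T @ yc
        w /= np.linalg.norm(w)
        Xf = Xs.copy()
        W_o, P_o = [], []
        for _ in range(self.n_ortho):
            t = Xf @ w
            p = Xf.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            norm = np.linalg.norm(w_o)
            if norm < 1e-12:
                break
            w_o /= norm
            t_o = Xf @ w_o
            p_o = Xf.T @ t_o / (t_o @ t_o)
            Xf = Xf - np.outer(t_o, p_o)
            W_o.append(w_o)
            P_o.append(p_o)
        t = Xf @ w
        p_load = Xf.T @ t / (t @ t)
        q = (yc @ t) / (t @ t)
        return w, W_o, P_o, Xf, t, p_load, q

    def fit(self, cv_folds: int = 7, seed: int = 0) -> "OplsResults":
        Xs, mu, sd = self._scale(self.X.to_numpy())
        yc = self.y_code - self.y_code.mean()
        w, W_o, P_o, Xf, t, p_load, q = self._decompose(Xs, yc)

        ssx = (Xs**2).sum()
        X_res = Xf - np.outer(t, p_load)
        r2x = 1.0 - (X_res**2).sum() / ssx
        y_hat = t * q
        r2y = 1.0 - ((yc - y_hat) ** 2).sum() / (yc**2).sum()
        q2y = self._q2y(cv_folds, seed)

        p_feats = Xs.shape[1]
        vip_vals = np.sqrt(p_feats) * np.abs(w)  # single predictive component
        return OplsResults(
            model=self,
            weights=pd.Series(w, index=self.X.columns, name="w"),
            scores=pd.Series(t, index=self.X.index, name="t_pred"),
            loadings=pd.Series(p_load, index=self.X.columns, name="p"),
            ortho_weights=np.array(W_o),
            ortho_scores=np.array([Xs @ wo for wo in W_o]) if W_o else np.empty((0, len(t))),
            r2x=float(r2x),
            r2y=float(r2y),
            q2y=float(q2y),
            vip=pd.Series(vip_vals, index=self.X.columns, name="vip"),
            q=float(q),
        )

    def _q2y(self, cv_folds: int, seed: int) -> float:
        """Stratified k-fold cross-validated Q2 = 1 - PRESS/SS."""
        X = self.X.to_numpy()
        y = self.y_code
        n = len(y)
        rng = np.random.default_rng(seed)
        folds = np.empty(n, dtype=int)
        for cls in (-1.0, 1.0):
            idx = np.where(y == cls)[0]
            rng.shuffle(idx)
            k = min(cv_folds, len(idx))
            folds[idx] = np.arange(len(idx)) % k
        press, ss = 0.0, ((y - y.mean()) ** 2).sum()
        for f in np.unique(folds):
            test = folds == f
            train = ~test
            if len(np.unique(y[train])) < 2:
                continue
            Xs_tr, mu, sd = self._scale(X[train])
            yc_tr = y[train] - y[train].mean()
            try:
                w, W_o, P_o, _, t_tr, p_load, q = self._decompose(Xs_tr, yc_tr)
            except (np.linalg.LinAlgError, ZeroDivisionError):
                continue
            Xs_te = (X[test] - mu) / sd
            for w_o, p_o in zip(W_o, P_o):
                t_o = Xs_te @ w_o
                Xs_te = Xs_te - np.outer(t_o, p_o)
            y_pred = (Xs_te @ w) * q + y[train].mean()
            press += ((y[test] - y_pred) ** 2).sum()
        return 1.0 - press / ss


@dataclass
class OplsResults:
    """Fitted OPLS-DA model: scores, loadings, fit statistics and VIP."""

    model: OPLSDA
    weights: pd.Series
    scores: pd.Series
    loadings: pd.Series
    ortho_weights: np.ndarray
    ortho_scores: np.ndarray
    r2x: float
    r2y: float
    q2y: float
    vip: pd.Series
    q: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": [self.r2x, self.r2y, self.q2y, len(self.ortho_weights)],
            },
            index=["R2X", "R2Y", "Q2Y", "n_ortho"],
        )


def opls_da(X: pd.DataFrame, y, n_ortho: int = 1, cv_folds: int = 7, seed: int = 0) -> OplsResults:
    """Functional wrapper: fit an OPLS-DA model and return its results."""
    return OPLSDA(X, y, n_ortho=n_ortho).fit(cv_folds=cv_folds, seed=seed)


def vip(results: OplsResults) -> pd.Series:
    """Variable importance in projection of the fitted model (mean VIP^2 = 1)."""
    return results.vip


@dataclass
class DifferentialCriteria:
    """Thresholds defining a differential metabolite.

    The default ("methods") preset requires VIP >= 1, a fold-change ratio
    >= 2 or <= 1/2, and BH q <= 0.05; the "results" preset drops the ratio
    gate (t-test FDR < 0.05 and VIP > 1).
    """

    vip_min: float = 1.0
    ratio_min: float | None = 2.0
    q_max: float = 0.05
    vip_strict: bool = False  # True: VIP > vip_min rather than >=

    @classmethod
    def preset(cls, name: str) -> "DifferentialCriteria":
        if name == "methods":
            return cls()
        if name == "results":
            return cls(ratio_min=None, vip_strict=True)
        raise ValueError(f"unknown criteria preset {name!r}")

    def evaluate(self, vip_v, ratio, q) -> bool:
        ok = (vip_v > self.vip_min) if self.vip_strict else (vip_v >= self.vip_min)
        ok = ok and q <= self.q_max
        if self.ratio_min is not None:
            ok = ok and (ratio >= self.ratio_min or ratio <= 1.0 / self.ratio_min)
        return bool(ok)


def differential_metabolites(
    X_log: pd.DataFrame,
    labels,
    vip_scores: pd.Series,
    criteria: DifferentialCriteria | None = None,
    X_prelog: pd.DataFrame | None = None,
    log_base: float = 10.0,
) -> DifferentialTable:
    """Score every metabolite against the differential criteria.

    Student's t-test runs on the log matrix; the group-mean ratio is taken on
    the pre-log (sum-normalized) scale, reconstructed from the log matrix if
    not supplied. A zero denominator yields ratio = +inf with a flag.
    """
    criteria = criteria or DifferentialCriteria()
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("differential analysis requires exactly two groups")
    g1, g2 = labels == uniq[0], labels == uniq[1]
    if X_prelog is None:
        X_prelog = pd.DataFrame(
            np.power(log_base, X_log.to_numpy()), index=X_log.index, columns=X_log.columns
        )
    rows = []
    for feat in X_log.columns:
        a, b = X_log.loc[g1, feat].to_numpy(), X_log.loc[g2, feat].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            t_stat, p = np.nan, 1.0
        else:
            t_stat, p = st.ttest_ind(a, b, equal_var=True)
        m1, m2 = X_prelog.loc[g1, feat].mean(), X_prelog.loc[g2, feat].mean()
        ratio = np.inf if m2 == 0 else m1 / m2
        rows.append((feat, m1, m2, float(t_stat) if np.isfinite(t_stat) else np.nan, float(p), ratio))
    df = pd.DataFrame(rows, columns=["feature", "mean_g1", "mean_g2", "stat", "p", "ratio"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["vip"] = vip_scores.reindex(df["feature"]).to_numpy()
    df["pass"] = [
        criteria.evaluate(v, r, q) for v, r, q in zip(df["vip"], df["ratio"], df["q"])
    ]
    crit_dict = {
        "vip_min": criteria.vip_min,
        "ratio_min": criteria.ratio_min,
        "q_max": criteria.q_max,
        "vip_strict": criteria.vip_strict,
    }
    return DifferentialTable(df, criteria=crit_dict)


def pathway_enrichment(diff_ids, universe_ids, pathway_map: pd.DataFrame) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric) enrichment of pathways in the
    differential set.

    For each pathway with members in the universe: N = universe size, K =
    pathway members in the universe, n = differential set size, k = overlap;
    p = P(X >= k) under the hypergeometric null. BH q-values are reported
    alongside. Pathways with no universe members are skipped with a note.
    """
    diff = set(diff_ids)
    universe = set(universe_ids)
    if not diff <= universe:
        raise ValueError("differential ids must be a subset of the universe")
    N, n = len(universe), len(diff)
    rows, skipped = [], []
    name_col = "pathway_name" if "pathway_name" in pathway_map.columns else "pathway_id"
    for pid, sub in pathway_map.groupby("pathway_id"):
        members = set(sub["metabolite_id"]) & universe
        K = len(members)
        if K == 0:
            skipped.append(pid)
            continue
        k = len(members & diff)
        p = float(st.hypergeom.sf(k - 1, N, K, n))
        rows.append((pid, sub[name_col].iloc[0], K, k, p))
    out = pd.DataFrame(rows, columns=["pathway_id", "pathway_name", "n_in_universe", "n_diff", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    if skipped:
        out.attrs["skipped_pathways"] = skipped
        warnings.warn(f"{len(skipped)} pathway(s) had no universe members; skipped", UserWarning, stacklevel=2)
    return out
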