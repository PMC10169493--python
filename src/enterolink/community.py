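"""Community-level statistics.

Rarefaction, alpha diversity (Shannon, Gini-Simpson, Chao1, ACE), ANOSIM on a
distance matrix, two-group Mann-Whitney testing with Benjamini-Hochberg FDR,
prevalence/abundance filtering, and VFA/phenotype group summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.stats import rankdata
from skbio.diversity.alpha import ace as _ace, chao1 as _chao1, shannon as _shannon, simpson as _simpson
from statsmodels.stats.multitest import multipletests

from .datatypes import DifferentialTable, DistanceMatrix, PhenotypeTable

__all__ = [
    "rarefy",
    "alpha_diversity",
    "anosim",
    "AnosimResult",
    "mann_whitney_bh",
    "prevalence_abundance_filter",
    "vfa_summary",
    "VfaSummary",
]

VFA_ACIDS = ["acetate", "propionate", "isobutyrate", "butyrate", "isovalerate", "valerate"]


def rarefy(counts: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Subsample each sample's counts to a common depth without replacement."""
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("rarefy requires integer counts")
        arr = arr.astype(np.int64)
    totals = arr.sum(axis=1)
    short = np.where(totals < depth)[0]
    if len(short):
        raise ValueError(f"sample(s) below rarefaction depth {depth}: {list(counts.index[short])}")
    rng = np.random.default_rng(seed)
    out = np.vstack([rng.multivariate_hypergeometric(row, depth) for row in arr])
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


_ALPHA_METRICS = ("shannon", "simpson", "chao1", "ace")


def alpha_diversity(counts: pd.DataFrame, metric: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity.

    Shannon uses natural log; Simpson is reported as the Gini-Simpson form
    1 - sum(p^2); Chao1 is bias-corrected; ACE uses the standard rare-species
    cutoff of 10.
    """
    if metric not in _ALPHA_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {_ALPHA_METRICS}")
    fns = {
        "shannon": lambda c: _shannon(c, base=np.e),
        "simpson": _simpson,
        "chao1": lambda c: _chao1(c, bias_corrected=True),
        "ace": _ace,
    }
    vals = []
    for sid, row in counts.iterrows():
        c = row.to_numpy()
        if c.sum() <= 0:
            raise ValueError(f"empty sample {sid!r}")
        vals.append(float(fns[metric](c.astype(np.int64) if metric in ("chao1", "ace") else c)))
    return pd.Series(vals, index=counts.index, name=metric)


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    seed: int


def _anosim_r(ranks: np.ndarray, within_mask: np.ndarray) -> float:
    n_pairs = len(ranks)
    r_within = ranks[within_mask].mean()
    r_between = ranks[~within_mask].mean()
    return float((r_between - r_within) / (n_pairs / 2.0))


def anosim(D: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0) -> AnosimResult:
    """ANOSIM: rank-based contrast of between- vs within-group distances.

    R = (mean between-rank - mean within-rank) / (M/2), M = n(n-1)/2, with a
    one-sided permutation p-value p = (1 + #{R_perm >= R_obs}) / (1 + n_perm).
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("anosim needs >= 2 groups")
    if np.any(counts < 2):
        raise ValueError("anosim groups must each have >= 2 samples")
    Dm = D.values if isinstance(D, DistanceMatrix) else np.asarray(D)
    iu = np.triu_indices(Dm.shape[0], 1)
    ranks = rankdata(Dm[iu])
    same = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranks, same)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        same_p = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, same_p) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return AnosimResult(R=r_obs, p=float(p), n_permutations=n_perm, seed=seed)


def mann_whitney_bh(
    matrix: pd.DataFrame,
    labels,
    alpha: float = 0.05,
    method: str = "auto",
) -> DifferentialTable:
    """Per-feature two-group Mann-Whitney U tests with BH adjustment.

    ``method='auto'`` uses the exact U distribution when the combined sample
    size is <= 20 and the feature has no ties, otherwise the tie-corrected
    normal approximation. Constant features get p = 1 and a flag.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("mann_whitney_bh requires exactly two groups")
    g1, g2 = (labels == uniq[0]), (labels == uniq[1])
    rows = []
    for feat in matrix.columns:
        x, y = matrix.loc[g1, feat].to_numpy(), matrix.loc[g2, feat].to_numpy()
        constant = np.all(np.concatenate([x, y]) == x[0])
        if constant:
            rows.append((feat, x.mean(), y.mean(), np.nan, 1.0, True))
            continue
        if method == "exact" or (method == "auto" and len(x) + len(y) <= 20 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)):
            res = st.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        else:
            res = st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        rows.append((feat, x.mean(), y.mean(), float(res.statistic), float(res.pvalue), False))
    df = pd.DataFrame(rows, columns=["feature", "mean_g1", "mean_g2", "stat", "p", "constant"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["pass"] = df["q"] < alpha
    return DifferentialTable(df, criteria={"q_max": alpha, "test": "mann_whitney", "adjust": "fdr_bh"})


def prevalence_abundance_filter(
    matrix: pd.DataFrame,
    min_value: float,
    min_frac: float,
    per_group_labels=None,
) -> pd.DataFrame:
    """Keep features exceeding ``min_value`` in at least ``min_frac`` of the
    samples of every group (all samples if no grouping is given)."""
    if per_group_labels is None:
        groups = [np.ones(len(matrix), dtype=bool)]
    else:
        lab = np.asarray(per_group_labels)
        groups = [lab == u for u in np.unique(lab)]
    keep = np.ones(matrix.shape[1], dtype=bool)
    for mask in groups:
        sub = matrix.loc[mask]
        frac = (sub.to_numpy() > min_value).mean(axis=0)
        keep &= frac >= min_frac
    return matrix.loc[:, keep]


@dataclass
class VfaSummary:
    """Group summary of volatile fatty acid concentrations.

    TVFA per group is the sum of the six acid group means; A/P is the group
    mean of per-sample acetate/propionate ratios; SEM is the pooled value
    sqrt(MS_within / harmonic-mean group size).
    """

    group_means: pd.DataFrame  # items x groups
    sem: pd.Series  # pooled SEM per item
    anova_p: pd.Series
    flags: dict

    def to_frame(self) -> pd.DataFrame:
        out = self.group_means.copy()
        out["SEM"] = self.sem
        out["P"] = self.anova_p
        return out


def _anova_p(groups: list[np.ndarray]) -> float:
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return 1.0
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        return 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = st.f_oneway(*groups)
    return float(p) if np.isfinite(p) else 1.0


def vfa_summary(vfa_table: PhenotypeTable | pd.DataFrame, labels) -> VfaSummary:
    """Summarize the six VFA concentrations by group, plus TVFA and A/P."""
    df = vfa_table.data if isinstance(vfa_table, PhenotypeTable) else vfa_table
    missing = [a for a in VFA_ACIDS if a not in df.columns]
    if missing:
        raise ValueError(f"missing VFA column(s): {missing}")
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    flags = {}

    items = VFA_ACIDS + ["TVFA", "A/P"]
    work = df[VFA_ACIDS].copy()
    work["TVFA"] = work[VFA_ACIDS].sum(axis=1)
    work["A/P"] = df["acetate"] / df["propionate"]

    means = pd.DataFrame(index=items, columns=[f"group{u}" for u in uniq], dtype=float)
    sems, ps = {}, {}
    n_h = len(uniq) / np.sum(1.0 / np.array([np.sum(labels == u) for u in uniq]))
    for item in items:
        groups = [work.loc[labels == u, item].to_numpy() for u in uniq]
        for u, g in zip(uniq, groups):
            means.loc[item, f"group{u}"] = g.mean()
        n, k = len(labels), len(uniq)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        ms_within = ss_within / (n - k) if n > k else 0.0
        sems[item] = float(np.sqrt(ms_within / n_h))
        p = _anova_p(groups)
        if sems[item] == 0.0:
            flags[item] = "zero within-group variance; p reported as 1"
            p = 1.0
        ps[item] = p
    # TVFA group means must equal the sum of acid group means (identity check)
    for col in means.columns:
        assert abs(means.loc["TVFA", col] - means.loc[VFA_ACIDS, col].sum()) < 1e-9
    return VfaSummary(
        group_means=means,
        sem=pd.Series(sems).reindex(items),
        anova_p=pd.Series(ps).reindex(items),
        flags=flags,
    )
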