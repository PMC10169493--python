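"""Recursive path analysis (observed-variable SEM) by maximum likelihood.

A :class:`PathModel` is specified with lavaan-like lines (``y ~ x1 + x2``
for regressions, ``x ~~ y`` for free exogenous covariances), validated as
acyclic, and fitted to data by minimizing the ML discrepancy

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

with Sigma(theta) = (I - B)^-1 Psi (I - B)^-T. The fitted
:class:`PathResults` carries estimates, standard errors (observed
information), standardized coefficients, per-equation R^2, the model and
independence-baseline chi-square statistics, RMSEA and CFI.
``chain_search`` screens every one-module-per-layer chain from microbiome
modules to the phenotype and ranks the candidate models by fit.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize as opt
import scipy.stats as st

__all__ = ["PathModel", "PathResults", "specify_model", "fit_indices", "chain_search"]


def _parse(path_strings) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    if isinstance(path_strings, str):
        path_strings = [s for s in path_strings.splitlines() if s.strip()]
    paths, covs = [], []
    for line in path_strings:
        line = line.split("#")[0].strip()
        if not line:
            continue
        if "~~" in line:
            lhs, rhs = (s.strip() for s in line.split("~~"))
            covs.append((lhs, rhs))
            continue
        m = re.match(r"^(\S+)\s*~\s*(.+)$", line)
        if not m:
            raise ValueError(f"cannot parse model line: {line!r}")
        y = m.group(1)
        for x in re.split(r"\+", m.group(2)):
            paths.append((y, x.strip()))
    return paths, covs


class PathModel:
    """A recursive (acyclic) path model over observed variables.

    Parameters
    ----------
    path_strings : str or sequence of str
        Model syntax, one relation per line: ``y ~ x1 + x2`` declares
        directed paths, ``x1 ~~ x2`` frees a covariance between exogenous
        variables. Every variable gets a free (residual) variance.
    """

    def __init__(self, path_strings):
        self.paths, self.covariances = _parse(path_strings)
        variables: list[str] = []
        for y, x in self.paths:
            for v in (x, y):
                if v not in variables:
                    variables.append(v)
        for a, b in self.covariances:
            for v in (a, b):
                if v not in variables:
                    variables.append(v)
        self.variables = variables
        self._check_acyclic()
        self.endogenous = sorted({y for y, _ in self.paths})
        self.exogenous = [v for v in variables if v not in self.endogenous]
        for a, b in self.covariances:
            if a in self.endogenous or b in self.endogenous:
                raise ValueError(f"free covariance {a}~~{b} involves an endogenous variable")

    def _check_acyclic(self) -> None:
        children: dict[str, set] = {}
        for y, x in self.paths:
            children.setdefault(x, set()).add(y)
        seen, stack = set(), set()

        def visit(v):
            if v in stack:
                raise ValueError(f"cyclic model specification at {v!r}")
            if v in seen:
                return
            stack.add(v)
            for c in children.get(v, ()):
                visit(c)
            stack.discard(v)
            seen.add(v)

        for v in self.variables:
            visit(v)

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def n_free(self) -> int:
        return len(self.paths) + self.p + len(self.covariances)

    @property
    def df(self) -> int:
        d = self.p * (self.p + 1) // 2 - self.n_free
        if d < 0:
            raise ValueError(f"model is over-parameterized (df = {d})")
        return d

    # -- parameter packing ---------------------------------------------------
    def _unpack(self, theta: np.ndarray):
        p = self.p
        idx = {v: i for i, v in enumerate(self.variables)}
        B = np.zeros((p, p))
        for k, (y, x) in enumerate(self.paths):
            B[idx[y], idx[x]] = theta[k]
        Psi = np.zeros((p, p))
        off = len(self.paths)
        for i in range(p):
            Psi[i, i] = theta[off + i]
        off += p
        for k, (a, b) in enumerate(self.covariances):
            Psi[idx[a], idx[b]] = Psi[idx[b], idx[a]] = theta[off + k]
        return B, Psi

    def implied_cov(self, theta: np.ndarray) -> np.ndarray:
        B, Psi = self._unpack(theta)
        A = np.linalg.inv(np.eye(self.p) - B)
        return A @ Psi @ A.T

    def _start(self, S: pd.DataFrame) -> np.ndarray:
        """Per-equation OLS start values (exact ML for diagonal-Psi models)."""
        idx = {v: i for i, v in enumerate(self.variables)}
        Sm = S.to_numpy()
        theta = np.zeros(self.n_free)
        resid_var = {v: Sm[idx[v], idx[v]] for v in self.variables}
        eq: dict[str, list[str]] = {}
        for y, x in self.paths:
            eq.setdefault(y, []).append(x)
        for y, xs in eq.items():
            xi = [idx[x] for x in xs]
            Sxx = Sm[np.ix_(xi, xi)]
            sxy = Sm[xi, idx[y]]
            beta = np.linalg.solve(Sxx, sxy)
            for x, b in zip(xs, beta):
                theta[self.paths.index((y, x))] = b
            resid_var[y] = max(Sm[idx[y], idx[y]] - beta @ sxy, 1e-8)
        off = len(self.paths)
        for i, v in enumerate(self.variables):
            theta[off + i] = max(resid_var[v], 1e-8)
        off += self.p
        for k, (a, b) in enumerate(self.covariances):
            theta[off + k] = Sm[idx[a], idx[b]]
        return theta

    def discrepancy(self, theta: np.ndarray, S: np.ndarray) -> float:
        Sigma = self.implied_cov(theta)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return 1e10
        _, logdet_s = np.linalg.slogdet(S)
        return float(logdet + np.trace(S @ np.linalg.inv(Sigma)) - logdet_s - self.p)

    # -- fitting -------------------------------------------------------------
    def fit(self, data: pd.DataFrame | None = None, S: pd.DataFrame | None = None, n: int | None = None, gtol: float = 1e-8) -> "PathResults":
        """Fit by ML from raw data (samples x variables) or a covariance S with n."""
        if data is not None:
            data = data[self.variables]
            if data.isna().any().any():
                raise ValueError("missing values in data")
            n = len(data)
            S = data.cov()
        elif S is None or n is None:
            raise ValueError("provide data, or S together with n")
        else:
            S = S.loc[self.variables, self.variables]
        if n <= self.p:
            raise ValueError(f"need n > p (n={n}, p={self.p})")
        Sm = S.to_numpy()
        sign, _ = np.linalg.slogdet(Sm)
        if sign <= 0 or np.linalg.eigvalsh(Sm).min() <= 0:
            raise ValueError("sample covariance not positive definite; more samples or fewer variables needed")

        # optimize on the correlation scale (well-conditioned; F_ML and the
        # fit statistics are invariant under variable rescaling), then map
        # the solution back to the original scale
        sd = np.sqrt(np.diag(Sm))
        R = Sm / np.outer(sd, sd)
        Rdf = pd.DataFrame(R, index=S.index, columns=S.columns)
        theta0 = self._start(Rdf)
        theta = theta0
        # for recursive models with diagonal Psi the per-equation OLS start is
        # the exact ML optimum; only polish numerically when it is not
        grad_norm = float(np.max(np.abs(_num_grad(lambda t: self.discrepancy(t, R), theta0))))
        if grad_norm > 1e-6:
            res = opt.minimize(self.discrepancy, theta0, args=(R,), method="BFGS", options={"gtol": gtol, "maxiter": 500})
            if self.discrepancy(res.x, R) < self.discrepancy(theta0, R):
                theta = res.x
        grad_norm = float(np.max(np.abs(_num_grad(lambda t: self.discrepancy(t, R), theta))))
        if grad_norm > 1e-4:
            raise RuntimeError(f"ML fit did not converge (gradient inf-norm {grad_norm:.3g})")

        f_min = self.discrepancy(theta, R)
        chi2 = max((n - 1) * f_min, 0.0)
        H = _num_hess(lambda t: self.discrepancy(t, R), theta)
        se = np.full(self.n_free, np.nan)
        try:
            cov_theta = 2.0 / (n - 1) * np.linalg.pinv(H)
            d = np.diag(cov_theta)
            se = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            pass
        scale = self._scale_factors(sd)
        return PathResults(
            model=self, theta=theta * scale, se=se * scale, S=S, n=n, chi2=float(chi2), f_min=float(f_min)
        )

    def _scale_factors(self, sd: np.ndarray) -> np.ndarray:
        """Per-parameter factors mapping a correlation-scale solution back to
        the covariance scale: s_y/s_x for paths, s_i^2 for variances,
        s_a*s_b for covariances."""
        idx = {v: i for i, v in enumerate(self.variables)}
        scale = np.empty(self.n_free)
        for k, (y, x) in enumerate(self.paths):
            scale[k] = sd[idx[y]] / sd[idx[x]]
        off = len(self.paths)
        for i in range(self.p):
            scale[off + i] = sd[i] ** 2
        off += self.p
        for k, (a, b) in enumerate(self.covariances):
            scale[off + k] = sd[idx[a]] * sd[idx[b]]
        return scale


def specify_model(path_strings) -> PathModel:
    """Build and validate a :class:`PathModel` from model syntax lines."""
    return PathModel(path_strings)


def _num_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = eps
        g[i] = (f(x + e) - f(x - e)) / (2 * eps)
    return g


def _num_hess(f, x, eps=1e-5):
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros_like(x); ei[i] = eps
            ej = np.zeros_like(x); ej[j] = eps
            H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)) / (4 * eps**2)
    return H


@dataclass
class PathResults:
    """ML estimates and fit statistics of a recursive path model."""

    model: PathModel
    theta: np.ndarray
    se: np.ndarray
    S: pd.DataFrame
    n: int
    chi2: float
    f_min: float
    _baseline: tuple | None = field(default=None, repr=False)

    @property
    def df(self) -> int:
        return self.model.df

    @property
    def estimates(self) -> pd.DataFrame:
        """Per-path estimate, SE, z, p, standardized estimate."""
        m = self.model
        Sigma = m.implied_cov(self.theta)
        idx = {v: i for i, v in enumerate(m.variables)}
        sd = np.sqrt(np.diag(Sigma))
        rows = []
        for k, (y, x) in enumerate(m.paths):
            est, se = self.theta[k], self.se[k]
            z = est / se if se and np.isfinite(se) and se > 0 else np.nan
            p = 2 * st.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            std = est * sd[idx[x]] / sd[idx[y]]
            rows.append((y, x, est, se, z, p, std))
        return pd.DataFrame(rows, columns=["lhs", "rhs", "estimate", "se", "z", "p", "std_estimate"])

    @property
    def residual_variances(self) -> pd.Series:
        off = len(self.model.paths)
        return pd.Series(self.theta[off : off + self.model.p], index=self.model.variables)

    @property
    def r_squared(self) -> pd.Series:
        """R^2 per endogenous variable from the implied covariance."""
        Sigma = self.model.implied_cov(self.theta)
        idx = {v: i for i, v in enumerate(self.model.variables)}
        psi = self.residual_variances
        out = {}
        for y in self.model.endogenous:
            total = Sigma[idx[y], idx[y]]
            out[y] = 1.0 - psi[y] / total if total > 0 else np.nan
        return pd.Series(out)

    def baseline(self) -> tuple[float, int]:
        """Independence-model chi-square and df (free variances only)."""
        if self._baseline is None:
            Sm = self.S.to_numpy()
            sign, logdet_s = np.linalg.slogdet(Sm)
            f0 = float(np.sum(np.log(np.diag(Sm))) - logdet_s)
            chi2_0 = max((self.n - 1) * f0, 0.0)
            df_0 = self.model.p * (self.model.p + 1) // 2 - self.model.p
            self._baseline = (chi2_0, df_0)
        return self._baseline

    @property
    def chi2_p(self) -> float:
        if self.df == 0:
            return 1.0
        return float(st.chi2.sf(self.chi2, self.df))

    @property
    def rmsea(self) -> float:
        if self.df == 0:
            return 0.0
        return float(np.sqrt(max(self.chi2 - self.df, 0.0) / (self.df * (self.n - 1))))

    @property
    def cfi(self) -> float:
        chi2_0, df_0 = self.baseline()
        num = max(self.chi2 - self.df, 0.0)
        den = max(chi2_0 - df_0, self.chi2 - self.df, 0.0)
        if den == 0.0:
            return 1.0
        return float(1.0 - num / den)

    def summary(self) -> str:
        lines = [
            "Recursive path model (ML)",
            f"  n = {self.n}, variables = {self.model.p}, free parameters = {self.model.n_free}",
            f"  chi2 = {self.chi2:.3f}, df = {self.df}, p = {self.chi2_p:.3f}",
            f"  RMSEA = {self.rmsea:.3f}, CFI = {self.cfi:.3f}",
            "",
            "Paths:",
        ]
        for _, row in self.estimates.iterrows():
            stars = "".join("*" for thr in (0.05, 0.01, 0.001) if row["p"] < thr) if np.isfinite(row["p"]) else ""
            lines.append(
                f"  {row['lhs']:>12s} ~ {row['rhs']:<12s} {row['estimate']:+8.3f} (se {row['se']:.3f})"
                f"  std {row['std_estimate']:+6.3f}  p={row['p']:.4f} {stars}"
            )
        lines.append("")
        lines.append("R-squared:")
        for v, r2 in self.r_squared.items():
            lines.append(f"  {v:>12s}  {r2:.3f}")
        return "\n".join(lines)


def fit_indices(fit: PathResults) -> dict:
    """RMSEA, CFI and baseline statistics of a fitted path model."""
    chi2_0, df_0 = fit.baseline()
    return {
        "chi2": fit.chi2,
        "df": fit.df,
        "p": fit.chi2_p,
        "rmsea": fit.rmsea,
        "cfi": fit.cfi,
        "baseline_chi2": chi2_0,
        "baseline_df": df_0,
    }


@dataclass
class ChainSearchResult:
    winner: dict | None
    ranking: pd.DataFrame
    n_candidates: int


def chain_search(
    module_scores: dict[str, pd.DataFrame],
    phenotype: pd.Series,
    layer_order: tuple = ("rumen_micro", "rumen_metab", "serum_metab", "milk_metab"),
    alpha: float = 0.05,
) -> ChainSearchResult:
    """Screen all one-module-per-layer causal chains ending at the phenotype.

    Every combination of one eigengene per layer (in ``layer_order``) defines
    a pure chain model layer1 -> layer2 -> ... -> phenotype; each is fitted
    by ML and ranked by (CFI desc, RMSEA asc, weakest-path p asc — the last
    breaks the frequent CFI = 1 ties at small n toward the chain with the
    strongest evidence on its weakest link). The winner is the best-ranked
    chain whose every path is significant at ``alpha``; if none qualifies the
    ranking is returned with an empty winner.
    """
    for layer in layer_order:
        if layer not in module_scores or module_scores[layer].shape[1] == 0:
            raise ValueError(f"no module scores for layer {layer!r}")
    pheno_name = phenotype.name or "MPY"
    combos = list(itertools.product(*[module_scores[l].columns for l in layer_order]))
    rows = []
    for combo in combos:
        cols = {}
        names = []
        for layer, me in zip(layer_order, combo):
            vname = f"{layer}_{me}"
            cols[vname] = module_scores[layer][me]
            names.append(vname)
        data = pd.DataFrame(cols)
        data[pheno_name] = phenotype
        spec_lines = [f"{b} ~ {a}" for a, b in zip(names, names[1:] + [pheno_name])]
        model = PathModel(spec_lines)
        try:
            row = _fast_chain_stats(model, data, alpha)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            continue
        row["chain"] = "-".join(list(combo) + [pheno_name])
        row["modules"] = combo
        row["_data"] = data
        row["_model"] = model
        rows.append(row)
    ranking = pd.DataFrame(rows)
    if len(ranking):
        ranking = ranking.sort_values(
            ["cfi", "rmsea", "max_path_p"], ascending=[False, True, True], kind="mergesort"
        ).reset_index(drop=True)
    winners = ranking[ranking["all_paths_significant"]] if len(ranking) else ranking
    winner = None
    if len(winners):
        winner = winners.iloc[0].to_dict()
        winner["fit"] = winner.pop("_model").fit(data=winner.pop("_data"))
    if len(ranking):
        ranking = ranking.drop(columns=["_data", "_model"])
    return ChainSearchResult(winner=winner, ranking=ranking, n_candidates=len(combos))


def _fast_chain_stats(model: PathModel, data: pd.DataFrame, alpha: float) -> dict:
    """Fit statistics of a pure-chain model without the full ML machinery.

    Exploits the ML = per-equation-OLS identity for recursive models: chi2
    comes from the discrepancy at the OLS solution, per-path p-values are the
    OLS slope t-tests (each chain equation is a simple regression).
    """
    data = data[model.variables]
    n = len(data)
    S = data.cov()
    Sm = S.to_numpy()
    if np.linalg.eigvalsh(Sm).min() <= 0:
        raise ValueError("sample covariance not positive definite")
    theta = model._start(S)
    chi2 = max((n - 1) * model.discrepancy(theta, Sm), 0.0)
    ps = []
    for y, x in model.paths:
        ps.append(float(st.pearsonr(data[x], data[y]).pvalue))
    sign, logdet_s = np.linalg.slogdet(Sm)
    f0 = float(np.sum(np.log(np.diag(Sm))) - logdet_s)
    chi2_0 = max((n - 1) * f0, 0.0)
    df_0 = model.p * (model.p + 1) // 2 - model.p
    df = model.df
    num = max(chi2 - df, 0.0)
    den = max(chi2_0 - df_0, num, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    rmsea = 0.0 if df == 0 else float(np.sqrt(num / (df * (n - 1))))
    return {
        "cfi": float(cfi),
        "rmsea": rmsea,
        "chi2": float(chi2),
        "df": df,
        "max_path_p": max(ps),
        "all_paths_significant": bool(max(ps) < alpha),
    }
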