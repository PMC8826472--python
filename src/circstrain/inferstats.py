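"""Group comparisons and prevalence-ratio regression.

Implements the study's statistical toolkit:

* Kruskal-Wallis tests (tie-corrected) across BMI categories, followed by
  Dunn's pairwise z-tests with Sidak adjustment within each variable's
  pairwise family;
* rank effect sizes epsilon-squared = H*(n+1)/(n^2-1) and
  eta-squared = (H-k+1)/(n-k) with seeded percentile-bootstrap CIs;
* "modified Poisson" regression for prevalence ratios (PR): a Poisson
  GLM with log link fitted by IRLS on a binary outcome, with the HC0
  sandwich covariance (bread = inverse Fisher information, meat = outer
  product of per-subject score residuals).  On a saturated two-group
  design the PR is exactly the ratio of stratum proportions and the robust
  SE has the binomial closed form — both are exercised by the tests;
* variance-inflation factors (VIF) with a >5 severity flag;
* a Wald check of log-linearity for a continuous term, by testing the
  joint significance of quartile-bin deviations from the linear trend
  (the route by which social jetlag ends up categorized at >1 h).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class StatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn's test

@dataclass
class PairwiseResult:
    pair: tuple
    z: float
    p_raw: float
    p_sidak: float


@dataclass
class GroupComparison:
    variable: str
    k: int
    n: int
    H: float
    df: int
    p: float
    epsilon_sq: float
    epsilon_sq_ci: tuple
    eta_sq: float
    eta_sq_ci: tuple
    pairwise: list


def _exact_kw_p(groups: list, h_obs: float) -> float:
    """Exact permutation p-value of the tie-corrected H by enumerating all
    distinct assignments of the pooled ranks to groups of the given sizes."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float((counts ** 3 - counts).sum()) / (N ** 3 - N)
    if tie <= 0:
        raise StatError("all values identical; H undefined")

    def h_from_sums(rank_sums):
        h = 12.0 / (N * (N + 1)) * sum(r * r / s for r, s in zip(rank_sums, sizes))
        return (h - 3.0 * (N + 1)) / tie

    n_ge = n_tot = 0
    def recurse(avail: tuple, gi: int, sums: list):
        nonlocal n_ge, n_tot
        if gi == len(sizes) - 1:
            sums.append(ranks[list(avail)].sum())
            n_tot += 1
            if h_from_sums(sums) >= h_obs - 1e-12:
                n_ge += 1
            sums.pop()
            return
        for pick in combinations(avail, sizes[gi]):
            sums.append(ranks[list(pick)].sum())
            recurse(tuple(i for i in avail if i not in pick), gi + 1, sums)
            sums.pop()

    recurse(tuple(range(N)), 0, [])
    return n_ge / n_tot


def kruskal_wallis(groups: Sequence[np.ndarray], method: str = "auto",
                   exact_max_n: int = 8) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H, its df and the p-value.

    The p-value comes from the chi-square distribution with k-1 df, except
    for very small samples (total n <= ``exact_max_n`` under ``method=
    'auto'``, or always under ``method='exact'``), where the exact
    permutation null of H is enumerated -- the chi-square approximation is
    off by far more than rounding there.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise StatError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise StatError("all values identical; H undefined")
    h, p = stats.kruskal(*groups)
    if method == "exact" or (method == "auto" and len(pooled) <= exact_max_n):
        p = _exact_kw_p(groups, float(h))
    elif method not in ("auto", "chi2"):
        raise ValueError(f"unknown method {method!r}")
    return float(h), len(groups) - 1, float(p)


def dunn_sidak(groups: Sequence[np.ndarray],
               labels: Optional[Sequence] = None) -> list[PairwiseResult]:
    """Dunn's pairwise z-tests from pooled mid-ranks with tie correction.

    Sidak adjustment: p_adj = 1 - (1 - p)^m over the m = k(k-1)/2
    comparisons of this variable's family.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise StatError("need >= 2 groups")
    labels = list(labels) if labels is not None else list(range(k))
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    idx = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [ranks[idx[i]:idx[i + 1]].mean() for i in range(k)]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (12.0 * (N - 1))) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term
    m = k * (k - 1) // 2
    out = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(base_var * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        p_sidak = min(1.0, 1.0 - (1.0 - p) ** m)
        out.append(PairwiseResult((labels[i], labels[j]), float(z), float(p), float(p_sidak)))
    return out


def _effect_sizes_point(h: float, n: int, k: int) -> tuple[float, float]:
    eps = h * (n + 1) / (n ** 2 - 1)
    eta = max(0.0, (h - k + 1) / (n - k))
    return eps, eta


def effect_sizes(groups: Sequence[np.ndarray], B: int = 2000,
                 seed: int = 0) -> tuple[float, tuple, float, tuple]:
    """epsilon^2 and eta^2 for a Kruskal-Wallis design, with percentile
    bootstrap CIs resampling subjects within groups (B replicates)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n = sum(len(g) for g in groups)
    if n <= k:
        raise StatError("effect sizes need n > k")
    h, _, _ = kruskal_wallis(groups)
    eps, eta = _effect_sizes_point(h, n, k)
    rng = np.random.default_rng(seed)
    eps_b, eta_b = [], []
    for _ in range(B):
        resampled = [g[rng.integers(0, len(g), len(g))] for g in groups]
        try:
            hb, _, _ = kruskal_wallis(resampled)
        except StatError:
            continue
        e1, e2 = _effect_sizes_point(hb, n, k)
        eps_b.append(e1)
        eta_b.append(e2)
    def ci(v):
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))) if v else (np.nan, np.nan)
    return eps, ci(eps_b), eta, ci(eta_b)


def compare_groups(variable: str, groups: Sequence[np.ndarray],
                   labels: Optional[Sequence] = None, B: int = 2000,
                   seed: int = 0) -> GroupComparison:
    h, df, p = kruskal_wallis(groups)
    n = sum(len(g) for g in groups)
    eps, eps_ci, eta, eta_ci = effect_sizes(groups, B=B, seed=seed)
    pairs = dunn_sidak(groups, labels)
    return GroupComparison(variable, len(groups), n, h, df, p, eps, eps_ci,
                           eta, eta_ci, pairs)


# ---------------------------------------------------------------------------
# Modified Poisson regression (prevalence ratios)

@dataclass
class RegressionResult:
    terms: list
    coef: np.ndarray          # log scale
    pr: np.ndarray            # exp(coef)
    se_robust: np.ndarray     # HC0
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    vif: dict
    n: int
    converged: bool
    n_iter: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms, "PR": self.pr,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p, "coef": self.coef, "se_robust": self.se_robust,
            "VIF": [self.vif.get(t, np.nan) for t in self.terms],
        })


def fit_modified_poisson(y: np.ndarray, X: np.ndarray, terms: Sequence[str],
                         max_iter: int = 100, tol: float = 1e-10) -> RegressionResult:
    """Poisson log-link GLM on a binary outcome with HC0 robust covariance.

    Fitted by iteratively reweighted least squares.  exp(coef) is the
    prevalence ratio; 95% CIs are exp(coef +/- 1.96 * robust SE).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise StatError("outcome must be binary 0/1")
    if np.linalg.matrix_rank(X) < p:
        raise StatError("design matrix is rank deficient")
    beta = np.zeros(p)
    beta[list(terms).index("intercept")] = np.log(max(y.mean(), 1e-6)) \
        if "intercept" in terms else 0.0
    converged = False
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        W = mu
        z = eta + (y - mu) / mu
        XtW = X.T * W
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as e:
            raise StatError(f"IRLS failed: {e}") from e
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
        if np.max(np.abs(beta)) > 25:
            raise StatError("coefficients diverging; separation suspected "
                            "(a stratum with all or no events)")
    if not converged:
        raise StatError(f"IRLS did not converge in {max_iter} iterations")

    mu = np.exp(np.clip(X @ beta, -30, 30))
    bread = np.linalg.inv((X.T * mu) @ X)       # inverse Fisher information
    score = X * (y - mu)[:, None]               # per-subject score residuals
    meat = score.T @ score
    cov = bread @ meat @ bread
    se = np.sqrt(np.diag(cov))
    zval = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    vifs = vif(X, terms)
    return RegressionResult(list(terms), beta, np.exp(beta), se,
                            np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se),
                            pval, vifs, n, converged, it)


def vif(X: np.ndarray, terms: Sequence[str], flag_threshold: float = 5.0) -> dict:
    """VIF_j = 1/(1 - R^2_j) from regressing each non-intercept column on
    the others (with intercept); perfect collinearity reports inf."""
    X = np.asarray(X, dtype=float)
    terms = list(terms)
    non_int = [j for j, t in enumerate(terms) if t != "intercept"]
    out = {}
    if len(non_int) < 2:
        return {terms[j]: 1.0 for j in non_int}
    for j in non_int:
        others = [c for c in range(X.shape[1]) if c != j]
        Xo = X[:, others]
        if "intercept" not in terms:
            Xo = np.column_stack([np.ones(len(X)), Xo])
        yj = X[:, j]
        coef, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ coef
        sst = float(((yj - yj.mean()) ** 2).sum())
        if sst == 0:
            out[terms[j]] = np.inf
            continue
        r2 = 1.0 - float((resid ** 2).sum()) / sst
        out[terms[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# ---------------------------------------------------------------------------
# Wald linearity check

@dataclass
class WaldLinearity:
    term: str
    statistic: float
    df: int
    p: float
    recommend_categorize: bool
    skipped: bool = False
    message: str = ""


def wald_linearity(y: np.ndarray, X: np.ndarray, terms: Sequence[str],
                   term: str, n_bins: int = 4, alpha: float = 0.05) -> WaldLinearity:
    """Joint Wald test that quartile-bin deviations from a linear trend in
    ``term`` are zero, under the modified-Poisson model.

    The continuous term is kept linear and quartile-bin indicator columns
    (reference = lowest bin) are added; their joint significance signals a
    departure from log-linearity, recommending categorization.
    """
    terms = list(terms)
    j = terms.index(term)
    x = np.asarray(X, dtype=float)[:, j]
    q = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    if len(q) - 1 < 2:
        return WaldLinearity(term, np.nan, 0, np.nan, False, skipped=True,
                             message="too few distinct values to bin")
    codes = np.clip(np.searchsorted(q, x, side="right") - 1, 0, len(q) - 2)
    dummies = np.column_stack([(codes == b).astype(float)
                               for b in range(1, len(q) - 1)])
    # drop dummy columns collinear with the existing design
    Xa = np.column_stack([X, dummies])
    names = terms + [f"{term}_bin{b}" for b in range(1, dummies.shape[1] + 1)]
    keep = []
    for c in range(X.shape[1], Xa.shape[1]):
        trial = Xa[:, [i for i in range(X.shape[1])] + keep + [c]]
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(c)
    if not keep:
        return WaldLinearity(term, np.nan, 0, np.nan, False, skipped=True,
                             message="bin indicators collinear with design")
    Xa = Xa[:, list(range(X.shape[1])) + keep]
    names = terms + [names[c] for c in keep]
    fit = fit_modified_poisson(y, Xa, names)
    idx = list(range(X.shape[1], Xa.shape[1]))
    # Wald statistic on the extra coefficients with HC0 covariance
    mu = np.exp(np.clip(Xa @ fit.coef, -30, 30))
    bread = np.linalg.inv((Xa.T * mu) @ Xa)
    score = Xa * (y - mu)[:, None]
    cov = bread @ (score.T @ score) @ bread
    b = fit.coef[idx]
    V = cov[np.ix_(idx, idx)]
    try:
        w = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        return WaldLinearity(term, np.nan, 0, np.nan, False, skipped=True,
                             message="singular covariance for bin terms")
    df = len(idx)
    p = float(stats.chi2.sf(w, df))
    return WaldLinearity(term, w, df, p, p < alpha)


# ---------------------------------------------------------------------------
# Design-matrix assembly

def build_design(df: pd.DataFrame, continuous: Sequence[str] = (),
                 binary: Sequence[str] = (), categorical: dict | None = None,
                 standardize: Sequence[str] = ()) -> tuple[np.ndarray, list]:
    """Design matrix with intercept from a tidy per-subject frame.

    ``categorical`` maps column -> reference level; the remaining levels
    enter as indicator columns named col[level].  Columns listed in
    ``standardize`` are z-scored (used for 'per SD' prevalence ratios).
    """
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for c in continuous:
        v = df[c].to_numpy(dtype=float)
        if c in standardize:
            sd = v.std(ddof=0)
            if sd == 0:
                raise StatError(f"cannot standardize constant column {c}")
            v = (v - v.mean()) / sd
        cols.append(v)
        names.append(c)
    for c in binary:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    for c, ref in (categorical or {}).items():
        levels = [l for l in pd.unique(df[c]) if l != ref]
        for l in sorted(map(str, levels)):
            cols.append((df[c].astype(str) == l).to_numpy(dtype=float))
            names.append(f"{c}[{l}]")
    return np.column_stack(cols), names
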