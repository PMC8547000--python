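"""Shared statistical machinery: correlations, OLS, Mantel, single-factor
PERMANOVA, rank tests.  Every permutation test takes a seed and uses the
``(#extreme + 1)/(N + 1)`` estimator, so p-values are in (0, 1] and exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TestResult:
    statistic: float
    p: float
    n: int
    method: str
    n_permutations: int | None = None
    seed: int | None = None
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic, "p": self.p, "n": self.n,
            "method": self.method,
        }


def _undefined(method: str, n: int) -> TestResult:
    return TestResult(np.nan, np.nan, n, method, defined=False)


def pearson(x, y) -> TestResult:
    """Pearson correlation with two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("pearson requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return _undefined("pearson", len(x))
    r, p = stats.pearsonr(x, y)
    return TestResult(float(r), float(p), len(x), "pearson")


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("spearman requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return _undefined("spearman", len(x))
    rho, p = stats.spearmanr(x, y)
    return TestResult(float(rho), float(p), len(x), "spearman")


def _upper(d: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(d.shape[0], k=1)
    return d[i, j]


def _check_square_symmetric(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    return d


def mantel_test(d1, d2, method: str = "pearson", n_perm: int = 999,
                seed: int | None = None) -> TestResult:
    """Mantel correlation between two distance matrices.

    The statistic is the correlation of the vectorized upper triangles; the
    permutation null simultaneously permutes rows and columns of ``d2``.
    ``method='spearman'`` ranks the triangles first (permutation of a
    symmetric matrix permutes its off-diagonal multiset, so ranking commutes
    with the permutation step).
    """
    d1 = _check_square_symmetric(d1, "d1")
    d2 = _check_square_symmetric(d2, "d2")
    n = d1.shape[0]
    if n < 4:
        raise ValueError("mantel requires n >= 4 samples")
    if method == "spearman":
        v1 = stats.rankdata(_upper(d1))
        m2 = np.zeros_like(d2)
        iu = np.triu_indices(n, k=1)
        ranked = stats.rankdata(d2[iu])
        m2[iu] = ranked
        m2 = m2 + m2.T
        d2v = m2
    elif method == "pearson":
        v1 = _upper(d1)
        d2v = d2
    else:
        raise ValueError(f"unknown method {method!r}")
    v2 = _upper(d2v)
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        return _undefined(f"mantel-{method}", n)
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = _upper(d2v[np.ix_(perm, perm)])
        r = np.corrcoef(v1, vp)[0, 1]
        if r >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return TestResult(r_obs, p, n, f"mantel-{method}", n_perm, seed)


def permanova(distance, covariate, n_perm: int = 999,
              seed: int | None = None) -> dict:
    """Single-factor PERMANOVA of a distance matrix on one covariate.

    The distance matrix is Gower-centered (G = -(1/2) J D^2 J); the covariate
    (continuous, or categorical via dummy coding) yields a hat matrix H, and

        pseudo-F = [tr(HGH)/df1] / [tr((I-H)G(I-H))/df2]

    with significance from permuting sample labels of the distance matrix.
    """
    d = _check_square_symmetric(distance, "distance")
    n = d.shape[0]
    if n < 4:
        raise ValueError("permanova requires n >= 4")
    cov = np.asarray(covariate)
    if cov.shape[0] != n:
        raise ValueError("covariate length mismatch")
    if cov.dtype.kind in "OUS":  # categorical
        levels = np.unique(cov)
        if len(levels) < 2:
            raise ValueError("constant covariate")
        X = np.column_stack(
            [np.ones(n)] + [(cov == lv).astype(float) for lv in levels[1:]])
    else:
        cov = cov.astype(float)
        if np.ptp(cov) == 0:
            raise ValueError("constant covariate")
        X = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(X)
    df1, df2 = rank - 1, n - rank
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (d ** 2) @ J
    H = X @ np.linalg.pinv(X.T @ X) @ X.T

    def _f(Gm):
        ss_model = np.sum(H * Gm)  # tr(HG), H idempotent symmetric
        ss_resid = np.trace(Gm) - ss_model
        return (ss_model / df1) / (ss_resid / df2)

    f_obs = _f(G)
    r2 = float(np.sum(H * G) / np.trace(G))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _f(G[np.ix_(perm, perm)]) >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return {"pseudo_F": float(f_obs), "R2": r2, "p": float(p), "n": n,
            "df1": df1, "df2": df2, "n_permutations": n_perm, "seed": seed}


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum test (two-sided by default).

    Exact p when the smaller group has <= 8 observations and there are no
    ties; normal approximation with tie correction otherwise.  The reported
    statistic is the rank sum of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    w = float(res.statistic + len(x) * (len(x) + 1) / 2)  # U -> rank sum
    return TestResult(w, float(res.pvalue), len(x) + len(y),
                      f"wilcoxon-{method}")


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction and chi-square p (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    n = sum(len(g) for g in groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return _undefined("kruskal-wallis", n)
    h, p = stats.kruskal(*groups)
    return TestResult(float(h), float(p), n, "kruskal-wallis")


def ols_regression(x, y) -> dict:
    """Simple least squares of y on x: slope, intercept, R^2, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("ols requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope), "intercept": float(res.intercept),
        "R2": float(res.rvalue ** 2), "p": float(res.pvalue), "n": len(x),
    }
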