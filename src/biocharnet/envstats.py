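"""Two-group soil-variable statistics, Spearman grids and Mantel tests.

Group comparisons check normality (Shapiro-Wilk per group) and variance
homogeneity (Levene); the t-test is pooled-variance when Levene's p >= 0.05
and Welch otherwise.  The Mantel statistic is the Pearson correlation of the
two lower-triangle distance vectors; its null distribution permutes rows and
columns of the second matrix jointly, exhaustively for n <= 6.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform


def compare_groups(
    env: pd.DataFrame, labels: pd.Series, reference: str = "NB", treated: str = "AB"
) -> pd.DataFrame:
    """Per-variable two-group comparison with assumption checks.

    Percent change is (mean_treated - mean_reference)/mean_reference x 100,
    undefined (NaN) when the reference mean is zero.
    """
    labels = labels.reindex(env.index)
    a = env[labels == reference]
    b = env[labels == treated]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    rows = {}
    for var in env.columns:
        x, y = a[var].to_numpy(), b[var].to_numpy()
        sw_ref = stats.shapiro(x).pvalue if np.ptp(x) > 0 else np.nan
        sw_trt = stats.shapiro(y).pvalue if np.ptp(y) > 0 else np.nan
        lev = stats.levene(x, y).pvalue if np.ptp(np.r_[x, y]) > 0 else np.nan
        equal_var = bool(np.isnan(lev) or lev >= 0.05)
        if np.ptp(np.r_[x, y]) == 0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(y, x, equal_var=equal_var)
        pct = (
            (y.mean() - x.mean()) / x.mean() * 100.0 if x.mean() != 0 else np.nan
        )
        rows[var] = {
            f"mean_{reference}": x.mean(),
            f"mean_{treated}": y.mean(),
            "percent_change": pct,
            f"shapiro_p_{reference}": sw_ref,
            f"shapiro_p_{treated}": sw_trt,
            "levene_p": lev,
            "test": "student" if equal_var else "welch",
            "t": float(t_stat),
            "p": float(p),
            "significant": bool(p < 0.05),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def pairwise_env_corr(env: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation matrix (with p-values) between variables.

    Constant variables yield NaN rows/columns (rho undefined).
    """
    if len(env) < 4:
        raise ValueError("need at least 4 samples")
    cols = list(env.columns)
    rho = pd.DataFrame(np.nan, index=cols, columns=cols)
    pval = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, u in enumerate(cols):
        for j, v in enumerate(cols):
            if env[u].std() == 0 or env[v].std() == 0:
                continue
            if i == j:
                rho.loc[u, v], pval.loc[u, v] = 1.0, 0.0
                continue
            r, p = stats.spearmanr(env[u], env[v])
            rho.loc[u, v], pval.loc[u, v] = r, p
    return rho, pval


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    method: str
    exhaustive: bool
    seed: int | None = None


def _tri(d: np.ndarray) -> np.ndarray:
    return d[np.triu_indices(d.shape[0], 1)]


def mantel_test(
    dist_a: pd.DataFrame | np.ndarray,
    dist_b: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "pearson",
    exhaustive_max_n: int = 6,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    The statistic correlates the lower-triangle vectors (Pearson by default,
    Spearman via ``method``).  The two-sided p counts permutations with
    |r_perm| >= |r_obs| after jointly permuting rows and columns of the
    second matrix: exhaustively over all n! relabellings when n <=
    ``exhaustive_max_n``, otherwise over ``n_perm`` seeded random draws with
    the add-one correction p = (1 + hits)/(1 + n_perm).
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrices must be square and of equal size")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("distance matrices must be symmetric")
    n = a.shape[0]
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    va = _tri(a)

    def stat(perm: np.ndarray) -> float:
        return float(corr(va, _tri(b[np.ix_(perm, perm)]))[0])

    r_obs = stat(np.arange(n))
    if n <= exhaustive_max_n:
        rs = np.array([stat(np.array(p)) for p in _permutations(range(n))])
        p_value = float(np.mean(np.abs(rs) >= abs(r_obs) - 1e-12))
        return MantelResult(r_obs, p_value, len(rs), method, True, seed)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if abs(stat(rng.permutation(n))) >= abs(r_obs) - 1e-12:
            hits += 1
    return MantelResult(
        r_obs, (1 + hits) / (1 + n_perm), n_perm, method, False, seed
    )


def env_distance(env: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Euclidean distance between samples on one z-scored variable."""
    v = env[variable].to_numpy(dtype=float)
    sd = v.std(ddof=1)
    z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    d = squareform(pdist(z[:, None]))
    return pd.DataFrame(d, index=env.index, columns=env.index)


def mantel_grid(
    community_dist: pd.DataFrame,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mantel r and p of a community distance matrix against every variable."""
    rows = {}
    rng = np.random.default_rng(seed)
    for var in env.columns:
        sub_seed = int(rng.integers(2**31 - 1))
        res = mantel_test(
            community_dist, env_distance(env, var), n_perm=n_perm, seed=sub_seed
        )
        rows[var] = {"mantel_r": res.r, "p": res.p_value, "n_perm": res.n_perm}
    return pd.DataFrame.from_dict(rows, orient="index")
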