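"""Ordination and gradient inference: soil PCA, CCA, Mantel tests, and
regression of dispersion indices on gradient scores.

The soil PCA reduces the measured soil parameters to orthogonal gradient
axes; CCA relates community composition to those parameters directly with
permutation tests per constrained axis; Mantel tests relate similarity
matrices (functional, phylogenetic, environmental); and simple least-squares
regression quantifies how dispersion indices (NRI, ZFDis) track the leading
soil axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CommunityMatrix, DistanceMatrix

__all__ = [
    "OrdinationResult", "MantelResult", "RegressionResult",
    "soil_pca", "cca", "cca_axis_test", "mantel", "regress_ses_on_axis",
    "soil_distance",
]


@dataclass
class OrdinationResult:
    method: str
    scores: pd.DataFrame          # unit x axis
    loadings: pd.DataFrame        # variable x axis
    explained: np.ndarray         # fraction of variance / inertia per axis
    total: float                  # total variance (PCA) or inertia (CCA)
    axis_p: np.ndarray | None = None


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# PCA of soil parameters
# ---------------------------------------------------------------------------

def soil_pca(soil: pd.DataFrame) -> OrdinationResult:
    """PCA of z-scored soil parameters (correlation-matrix PCA).

    Axis k explains lambda_k / sum(lambda); with unit-variance scaling the
    total variance equals the number of parameters.
    """
    if soil.isna().any().any():
        raise ValueError("soil table has missing values")
    if soil.shape[0] < 2 or soil.shape[1] < 2:
        raise ValueError("need >= 2 plots and >= 2 soil variables")
    sd = soil.std(axis=0, ddof=1)
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance soil column(s): {dead}")
    z = (soil - soil.mean(axis=0)) / sd
    corr = np.cov(z.to_numpy(float), rowvar=False, ddof=1)
    lam, vec = np.linalg.eigh(corr)
    order = np.argsort(lam)[::-1]
    lam, vec = np.maximum(lam[order], 0.0), vec[:, order]
    # deterministic sign: largest-|loading| entry positive
    for k in range(vec.shape[1]):
        j = np.argmax(np.abs(vec[:, k]))
        if vec[j, k] < 0:
            vec[:, k] *= -1
    scores = z.to_numpy(float) @ vec
    axes = [f"PCA{k + 1}" for k in range(len(lam))]
    return OrdinationResult(
        method="PCA",
        scores=pd.DataFrame(scores, index=soil.index, columns=axes),
        loadings=pd.DataFrame(vec, index=soil.columns, columns=axes),
        explained=lam / lam.sum(),
        total=float(lam.sum()),
    )


# ---------------------------------------------------------------------------
# Canonical correspondence analysis
# ---------------------------------------------------------------------------

def _chi_square_standardized(y):
    total = y.sum()
    p = y / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if np.any(r <= 0) or np.any(c <= 0):
        raise ValueError("community rows and columns must have positive sums")
    qbar = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return qbar, r, c


def _weighted_standardize(x, r):
    mean = r @ x
    xc = x - mean
    sd = np.sqrt(r @ xc ** 2)
    if np.any(sd <= 0):
        raise ValueError("zero-variance environmental column")
    return xc / sd


def _check_rank(z, names):
    rank = int(np.linalg.matrix_rank(z))
    if rank < z.shape[1]:
        from scipy.linalg import qr as sqr
        _, _, piv = sqr(z, pivoting=True, mode="economic")
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"collinear environmental columns: {bad}")


def _cca_fit(y, x, env_names=None):
    qbar, r, c = _chi_square_standardized(y)
    xs = _weighted_standardize(x, r)
    z = np.sqrt(r)[:, None] * xs
    _check_rank(z, env_names if env_names is not None else list(range(x.shape[1])))
    beta, *_ = np.linalg.lstsq(z, qbar, rcond=None)
    fitted = z @ beta
    u, sv, vt = np.linalg.svd(fitted, full_matrices=False)
    total = float((qbar ** 2).sum())
    return qbar, r, z, fitted, u, sv, vt, total


def cca(community, env: pd.DataFrame) -> OrdinationResult:
    """Canonical correspondence analysis of abundances against environment.

    The chi-square-standardized community matrix is projected onto the
    row-weighted standardized environmental space; singular values of the
    projection give the constrained eigenvalues.  ``explained`` is eigenvalue
    over total inertia (sum of squared chi-square residuals).
    """
    if isinstance(community, CommunityMatrix):
        y = np.asarray(community.abundance, float)
        units = community.units
    elif isinstance(community, pd.DataFrame):
        y = community.to_numpy(float)
        units = list(community.index)
    else:
        y = np.asarray(community, float)
        units = list(range(y.shape[0]))
    if np.any(y < 0):
        raise ValueError("abundances must be nonnegative")
    units_str = [str(u) for u in units]
    env_idx = list(env.index.astype(str))
    if env_idx != units_str and set(units_str) <= set(env_idx):
        env = env.set_axis(env_idx).loc[units_str]
    x = env.to_numpy(float)
    qbar, r, z, fitted, u, sv, vt, total = _cca_fit(y, x, list(env.columns))
    tol = sv.max() * 1e-10 if sv.size else 0.0
    keep = sv > tol
    sv, u = sv[keep], u[:, keep]
    eig = sv ** 2
    axes = [f"CCA{k + 1}" for k in range(len(eig))]
    site = u * sv / np.sqrt(r)[:, None]  # weighted site scores (LC)
    # env loadings: weighted correlation of standardized env with site scores
    xs = _weighted_standardize(x, r)
    lc_std = site / np.sqrt((r @ (site ** 2)) - (r @ site) ** 2)
    loadings = (xs * r[:, None]).T @ lc_std
    return OrdinationResult(
        method="CCA",
        scores=pd.DataFrame(site, index=units, columns=axes),
        loadings=pd.DataFrame(loadings, index=env.columns, columns=axes),
        explained=eig / total,
        total=total,
    )


def cca_axis_test(community, env: pd.DataFrame, n_perm: int = 999,
                  seed: int = 0, n_axes: int | None = None) -> np.ndarray:
    """Sequential permutation test of the constrained axes.

    Axis k is tested by permuting whole rows of the environment table while
    conditioning on the previously fitted axes (their fitted components are
    projected out of both the community and the permuted environment);
    p-values use the add-one rule.
    """
    if isinstance(community, CommunityMatrix):
        y = np.asarray(community.abundance, float)
    elif isinstance(community, pd.DataFrame):
        y = community.to_numpy(float)
    else:
        y = np.asarray(community, float)
    x = env.to_numpy(float)
    qbar, r, z, fitted, u, sv, vt, total = _cca_fit(y, x, list(env.columns))
    tol = sv.max() * 1e-10 if sv.size else 0.0
    n_constrained = int(np.sum(sv > tol))
    n_axes = n_constrained if n_axes is None else min(n_axes, n_constrained)
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_axes)
    sqrt_r = np.sqrt(r)

    def first_eig(q_res, x_rows, u_prev):
        xs = _weighted_standardize(x_rows, r)
        zz = sqrt_r[:, None] * xs
        if u_prev is not None:
            zz = zz - u_prev @ (u_prev.T @ zz)
        beta, *_ = np.linalg.lstsq(zz, q_res, rcond=None)
        s = np.linalg.svd(zz @ beta, compute_uv=False)
        return s[0] ** 2 if s.size else 0.0

    for k in range(n_axes):
        u_prev = u[:, :k] if k > 0 else None
        q_res = qbar if k == 0 else qbar - u[:, :k] @ (u[:, :k].T @ qbar)
        obs = sv[k] ** 2
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(r))
            count += first_eig(q_res, x[perm], u_prev) >= obs - 1e-12
        pvals[k] = (1.0 + count) / (n_perm + 1.0)
    return pvals


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def soil_distance(soil: pd.DataFrame, standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance between plots in (z-scored) soil-parameter space."""
    x = soil.to_numpy(float)
    if standardize:
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    from scipy.spatial.distance import pdist, squareform
    return DistanceMatrix(list(soil.index.astype(str)), squareform(pdist(x)))


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed: int = 0, alternative: str = "greater",
           exhaustive: bool = False) -> MantelResult:
    """Mantel correlation between two unit distance matrices.

    r is the Pearson correlation of the upper-triangle entries; the p-value
    permutes rows and columns of the second matrix simultaneously (add-one
    rule, one-tailed 'greater' by default).  With ``exhaustive`` all n!
    permutations are enumerated (small n only) and the p-value is the exact
    fraction of permutations at least as extreme as the identity.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels and order")
    n = len(d1)
    if n < 3:
        raise ValueError("Mantel test needs >= 3 units")
    ii, jj = np.triu_indices(n, 1)
    a = d1.values[ii, jj]
    m2 = d2.values
    a_c = a - a.mean()
    a_ss = np.sqrt((a_c ** 2).sum())

    def corr(b_rows):
        b_c = b_rows - b_rows.mean(axis=-1, keepdims=True)
        denom = a_ss * np.sqrt((b_c ** 2).sum(axis=-1))
        return (b_c @ a_c) / denom

    r_obs = float(corr(m2[ii, jj][None, :])[0])
    if exhaustive:
        import itertools
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        perms = np.array(list(itertools.permutations(range(n))))
        b = m2[perms[:, ii], perms[:, jj]]
        r_perm = corr(b)
        if alternative == "greater":
            count = int(np.sum(r_perm >= r_obs - 1e-12))
        elif alternative == "less":
            count = int(np.sum(r_perm <= r_obs + 1e-12))
        else:
            count = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
        return MantelResult(r=r_obs, p_value=count / len(perms),
                            n_perm=len(perms))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    b = m2[perms[:, ii], perms[:, jj]]  # (n_perm, n_pairs)
    r_perm = corr(b)
    if alternative == "greater":
        count = int(np.sum(r_perm >= r_obs - 1e-12))
    elif alternative == "less":
        count = int(np.sum(r_perm <= r_obs + 1e-12))
    else:
        count = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    return MantelResult(r=r_obs, p_value=(1.0 + count) / (n_perm + 1.0),
                        n_perm=n_perm)


# ---------------------------------------------------------------------------
# Dispersion vs gradient regression
# ---------------------------------------------------------------------------

def regress_ses_on_axis(ses, scores) -> RegressionResult:
    """OLS of a per-unit dispersion index on a gradient axis score.

    Returns the slope with its two-sided t-test p-value and the Pearson r.
    Non-finite pairs are dropped; at least three are required.
    """
    ses = np.asarray(ses, float)
    scores = np.asarray(scores, float)
    mask = np.isfinite(ses) & np.isfinite(scores)
    ses, scores = ses[mask], scores[mask]
    if len(ses) < 3:
        raise ValueError("need >= 3 finite (index, score) pairs")
    if np.ptp(scores) == 0:
        raise ValueError("zero-variance predictor")
    fit = stats.linregress(scores, ses)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r=float(fit.rvalue), p_value=float(fit.pvalue),
                            n=len(ses))
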