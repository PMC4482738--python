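"""Blomberg's K statistic and its tip-permutation significance test.

K compares the observed ratio of cross-species trait variance to the
phylogenetically corrected variance against the ratio expected if the trait
had evolved by Brownian motion along the supplied branch lengths.  K near 1
matches Brownian evolution, K < 1 indicates a convergent/labile trait and
K > 1 a conserved one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data_model import Phylogeny
from .null_models import tip_shuffle

__all__ = ["SignalResult", "blomberg_k", "blomberg_k_many", "k_test"]


@dataclass
class SignalResult:
    trait: str
    k: float
    p_value: float
    n_tips: int
    n_perm: int


def _prepare(tree: Phylogeny):
    c = tree.vcv()
    n = c.shape[0]
    try:
        factor = cho_factor(c)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular phylogenetic covariance matrix") from e
    w = cho_solve(factor, np.ones(n))  # C^-1 1
    sum_cinv = float(w.sum())          # 1' C^-1 1
    denom_expected = (np.trace(c) - n / sum_cinv) / (n - 1)
    return factor, w, sum_cinv, denom_expected, n


def _mse_terms(x_rows, factor, w, sum_cinv):
    """MSE0 and C^-1-weighted MSE for each row of x_rows (rows x tips)."""
    x = np.atleast_2d(np.asarray(x_rows, float))
    n = x.shape[1]
    ahat = (x @ w) / sum_cinv
    r = x - ahat[:, None]
    mse0 = (r ** 2).sum(axis=1) / (n - 1)
    s = cho_solve(factor, r.T)  # C^-1 r'
    mse = (r.T * s).sum(axis=0) / (n - 1)
    return mse0, mse


def blomberg_k(tree: Phylogeny, x) -> float:
    """Blomberg's K for one trait vector (tip-label order of the tree)."""
    x = np.asarray(x, float)
    if tree.n_tips < 4:
        raise ValueError("K requires >= 4 tips")
    if len(x) != tree.n_tips:
        raise ValueError("trait vector length must equal number of tips")
    if np.ptp(x) == 0:
        raise ValueError("constant trait: K undefined")
    factor, w, sum_cinv, denom_expected, _ = _prepare(tree)
    mse0, mse = _mse_terms(x, factor, w, sum_cinv)
    return float((mse0[0] / mse[0]) / denom_expected)


def blomberg_k_many(tree: Phylogeny, x_rows) -> np.ndarray:
    """Vectorized K over many trait vectors (rows x tips)."""
    factor, w, sum_cinv, denom_expected, _ = _prepare(tree)
    mse0, mse = _mse_terms(x_rows, factor, w, sum_cinv)
    return (mse0 / mse) / denom_expected


def k_test(tree: Phylogeny, x, n_perm: int = 999, seed: int = 0,
           trait: str = "trait") -> SignalResult:
    """Permutation test of phylogenetic signal.

    Trait values are shuffled across tips; the add-one permutation p-value is
    the fraction of shuffles whose phylogenetically weighted mean squared
    error is at most the observed one (a low MSE means the trait fits the
    tree structure well).
    """
    x = np.asarray(x, float)
    k = blomberg_k(tree, x)  # validates inputs
    factor, w, sum_cinv, _, _ = _prepare(tree)
    _, mse_obs = _mse_terms(x, factor, w, sum_cinv)
    perms = tip_shuffle(x, n_reps=n_perm, seed=seed)
    _, mse_perm = _mse_terms(perms, factor, w, sum_cinv)
    p = (1.0 + np.sum(mse_perm <= mse_obs[0])) / (n_perm + 1.0)
    return SignalResult(trait=trait, k=k, p_value=float(p),
                        n_tips=tree.n_tips, n_perm=n_perm)
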