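"""Trait screening, trait space construction, and functional dispersion.

The trait pipeline mirrors the phylogenetic one: species are placed in a
Euclidean trait space (after log10 transformation), a complete-linkage
dendrogram summarizes overall trait similarity, and per-community functional
dispersion (FDis) is standardized against the same individual-randomization
null used for MPD/NRI (giving ZFDis).
"""

from __future__ import annotations

from dataclasses import dataclass, field  # noqa: F401

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .data_model import CommunityMatrix, DistanceMatrix, Phylogeny, normalize_name
from .null_models import NullEnsemble
from .phylo_structure import dispersion_frame, phylosor_ses_matrix

__all__ = [
    "allometric_slope", "TraitScreenReport", "screen_traits", "trait_distance",
    "Dendrogram", "build_dendrogram", "fdis", "fdis_coords", "zfdis",
    "trait_sor_ses_matrix",
]


# ---------------------------------------------------------------------------
# Derived allometric traits and trait screening
# ---------------------------------------------------------------------------

def allometric_slope(individuals: pd.DataFrame, response: str) -> pd.Series:
    """Per-species OLS slope of a size-dependent trait (H or CW) on DBH.

    ``individuals`` holds one row per measured tree with columns
    ``species``, ``dbh`` and the response.  Removing the shared dependence
    on stem diameter turns height and crown width into size-corrected
    traits.  Species with fewer than two usable individuals, or with no dbh
    variation, get NaN.
    """
    if response not in individuals.columns:
        raise KeyError(f"response column {response!r} not present")
    out = {}
    for sp, grp in individuals.groupby("species"):
        sub = grp[["dbh", response]].dropna()
        if len(sub) < 2 or sub["dbh"].nunique() < 2:
            out[normalize_name(sp)] = np.nan
            continue
        x = sub["dbh"].to_numpy(float)
        y = sub[response].to_numpy(float)
        out[normalize_name(sp)] = float(np.polyfit(x, y, 1)[0])
    return pd.Series(out, name=f"dbh_{response}_slope")


@dataclass
class TraitScreenReport:
    correlations: pd.DataFrame
    selected: list
    dropped: dict = field(default_factory=dict)  # trait -> conflicting kept trait
    threshold: float = 0.50


def screen_traits(traits: pd.DataFrame, threshold: float = 0.50,
                  priority=None) -> TraitScreenReport:
    """Greedy selection of mutually weakly correlated traits.

    Traits are scanned in ``priority`` order (default: column order); a trait
    is kept iff its pairwise Pearson |r| (pairwise-complete observations)
    with every already-kept trait is below ``threshold``.
    """
    cols = list(traits.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 traits to screen")
    priority = list(priority) if priority else cols
    unknown = [t for t in priority if t not in cols]
    if unknown:
        raise KeyError(f"priority traits not in table: {unknown}")
    corr = traits.corr(method="pearson")
    kept, dropped = [], {}
    for t in priority:
        conflict = next((k for k in kept
                         if abs(corr.loc[t, k]) >= threshold), None)
        if conflict is None:
            kept.append(t)
        else:
            dropped[t] = conflict
    return TraitScreenReport(correlations=corr, selected=kept,
                             dropped=dropped, threshold=threshold)


def trait_distance(traits: pd.DataFrame, columns=None, log10: bool = True,
                   standardize: bool = False) -> DistanceMatrix:
    """Euclidean distance between species in (log10) trait space.

    Species with any missing value among the chosen columns are excluded;
    their names are attached to the result as ``excluded_species``.
    """
    cols = list(columns) if columns is not None else list(traits.columns)
    sub = traits[cols]
    complete = sub.dropna()
    excluded = sorted(set(sub.index) - set(complete.index))
    if len(complete) < 2:
        raise ValueError("fewer than 2 species with complete trait data")
    x = complete.to_numpy(float)
    if log10:
        if np.any(x <= 0):
            i, j = np.argwhere(x <= 0)[0]
            raise ValueError(
                f"nonpositive value for trait {cols[j]!r} of species "
                f"{complete.index[i]!r}: log10 transform undefined")
        x = np.log10(x)
    if standardize:
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    dm = DistanceMatrix(list(complete.index), squareform(pdist(x)))
    dm.excluded_species = excluded
    return dm


# ---------------------------------------------------------------------------
# Trait dendrogram
# ---------------------------------------------------------------------------

class Dendrogram:
    """Ultrametric species tree from agglomerative clustering.

    Wraps a scipy linkage matrix; heights are in the units of the input
    distances.  Convertible to a Phylogeny so that branch-length-based
    similarity (PhyloSor) can run on trait space unchanged.
    """

    def __init__(self, linkage_matrix: np.ndarray, labels):
        self.linkage = np.asarray(linkage_matrix, float)
        self.labels = [str(l) for l in labels]
        if np.any(np.diff(self.linkage[:, 2]) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    def cophenetic_matrix(self) -> DistanceMatrix:
        coph = hierarchy.cophenet(self.linkage)
        return DistanceMatrix(self.labels, squareform(coph))

    def to_phylogeny(self) -> Phylogeny:
        """Ultrametric tree whose tip-to-tip path length equals the
        cophenetic distance (edge length = half the height difference)."""
        root, nodes = hierarchy.to_tree(self.linkage, rd=True)
        parent, length, labels = [], [], []
        index = {}

        def build(node, parent_idx, parent_h):
            idx = len(parent)
            index[node.id] = idx
            parent.append(parent_idx)
            length.append(0.0 if parent_idx == -1 else (parent_h - node.dist) / 2.0)
            if node.is_leaf():
                labels.append(self.labels[node.id])
            else:
                build(node.left, idx, node.dist)
                build(node.right, idx, node.dist)

        build(root, -1, root.dist)
        return Phylogeny(parent, length, labels)


def build_dendrogram(d: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a species distance matrix.

    Complete linkage is the default; ties are broken by scipy's
    deterministic nearest-pair ordering, so repeated runs agree.
    """
    if len(d) < 2:
        raise ValueError("need >= 2 species")
    if not np.all(np.isfinite(d.values)):
        raise ValueError("distance matrix contains non-finite values")
    z = hierarchy.linkage(d.condensed(), method=linkage)
    return Dendrogram(z, d.labels)


# ---------------------------------------------------------------------------
# Functional dispersion
# ---------------------------------------------------------------------------

def fdis_coords(coords, weights) -> float:
    """FDis computed directly in coordinate space.

    Weighted mean distance of the points to their weighted centroid;
    the geometric form of FDis, exact whenever the distance matrix is
    Euclidean-embeddable.
    """
    x = np.atleast_2d(np.asarray(coords, float))
    if x.shape[0] == 1:
        x = x.T
    a = np.asarray(weights, float)
    mask = a > 0
    if mask.sum() < 2:
        return 0.0
    x, a = x[mask], a[mask]
    a = a / a.sum()
    c = a @ x
    return float(a @ np.sqrt(((x - c) ** 2).sum(axis=1)))


def fdis(distances, weights) -> float:
    """FDis from an arbitrary species distance matrix via PCoA.

    The Gower-centered matrix of the present species is eigendecomposed;
    positive- and negative-eigenvalue axes are kept separately and the
    squared distance of species j to the weighted centroid is the positive
    part minus the negative part (absolute value taken before the square
    root).  Single-species communities return 0 by convention.
    """
    d = distances.values if isinstance(distances, DistanceMatrix) else np.asarray(distances, float)
    a = np.asarray(weights, float)
    mask = a > 0
    if mask.sum() < 2:
        return 0.0
    d = d[np.ix_(mask, mask)]
    a = a[mask]
    a = a / a.sum()
    n = len(a)
    g = -0.5 * d ** 2
    g = g - g.mean(axis=0) - g.mean(axis=1)[:, None] + g.mean()
    lam, vec = np.linalg.eigh((g + g.T) / 2)
    tol = max(abs(lam).max(), 1.0) * 1e-10
    pos = lam > tol
    neg = lam < -tol
    xp = vec[:, pos] * np.sqrt(lam[pos])
    xn = vec[:, neg] * np.sqrt(-lam[neg])
    d2p = ((xp - a @ xp) ** 2).sum(axis=1) if pos.any() else np.zeros(n)
    d2n = ((xn - a @ xn) ** 2).sum(axis=1) if neg.any() else np.zeros(n)
    z = np.sqrt(np.abs(d2p - d2n))
    return float(a @ z)


def _fdis_rows(weight_rows, d=None, coords=None):
    if coords is not None:
        return np.array([fdis_coords(coords, w) for w in weight_rows])
    return np.array([fdis(d, w) for w in weight_rows])


def zfdis(community: CommunityMatrix, distances, ensemble: NullEnsemble,
          weighting: str = "abundance", coords=None,
          metric_name: str = "FDis") -> pd.DataFrame:
    """Standardized effect size of FDis per unit (ZFDis).

    The ``ses`` column is the raw (FDis_obs - mean FDis_null)/sd FDis_null;
    the ``index`` column is the sign-flipped clustering index, positive when
    trait dispersion is smaller than the null expectation.  Significance is
    |ses| > 1.96.  When ``coords`` is given (an exact Euclidean embedding of
    ``distances``) the geometric fast path is used.
    """
    # species lacking trait data are excluded from the FDis computation
    cols = np.arange(len(community.species))
    d = None
    if coords is None:
        if isinstance(distances, DistanceMatrix):
            have = set(distances.labels)
            cols = np.array([j for j, s in enumerate(community.species) if s in have])
            if len(cols) < 2:
                raise ValueError("fewer than 2 community species in trait space")
            d = distances.submatrix([community.species[j] for j in cols])
        else:
            d = DistanceMatrix(community.species, np.asarray(distances, float))
    obs = _fdis_rows(community.layer(weighting)[:, cols], d=d, coords=coords)
    n_u = community.n_units
    sums = np.zeros(n_u)
    sq = np.zeros(n_u)
    count = 0
    for ab, ba in ensemble.replicate_layers():
        layer = ab if weighting == "abundance" else ba
        for rep in layer:
            vals = _fdis_rows(rep[:, cols], d=d, coords=coords)
            sums += vals
            sq += vals ** 2
            count += 1
    mean = sums / count
    var = np.maximum(sq / count - mean ** 2, 0.0)
    sd = np.sqrt(var * count / max(count - 1, 1))
    out = dispersion_frame(community.units, metric_name, weighting,
                           community.scale, obs, mean, sd, flip_sign=True)
    return out.rename(columns={"index": "zfdis_clustering"})


def trait_sor_ses_matrix(community: CommunityMatrix, dendrogram: Dendrogram,
                         ensemble: NullEnsemble) -> pd.DataFrame:
    """PhyloSor SES matrix computed on the trait dendrogram.

    Identical contract to the phylogenetic version, with the complete-linkage
    trait tree supplying the branch lengths.
    """
    return phylosor_ses_matrix(community, dendrogram.to_phylogeny(), ensemble)
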