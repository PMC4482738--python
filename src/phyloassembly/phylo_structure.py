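"""Phylogenetic community structure: MPD, NRI and PhyloSor.

MPD is the abundance- (or basal-area-) weighted mean pairwise distance among
the species of one community.  NRI standardizes observed MPD against an
individual-randomization null ensemble, sign-flipped so that positive values
mean phylogenetic clustering.  PhyloSor is the Sorensen-type fraction of
branch length shared by the spanning subtrees of two communities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conventions import Z_CRIT
from .data_model import CommunityMatrix, DistanceMatrix, Phylogeny
from .null_models import NullEnsemble

__all__ = [
    "mpd", "mpd_per_unit", "nri", "phylosor", "phylosor_matrix",
    "phylosor_ses_matrix", "dispersion_frame",
]


# ---------------------------------------------------------------------------
# MPD / NRI
# ---------------------------------------------------------------------------

def mpd(weights, distances) -> float:
    """Weighted mean pairwise distance for one community.

    MPD = sum_{i != j} w_i w_j d_ij / sum_{i != j} w_i w_j.  The diagonal
    (intraspecific distance 0) never enters.  Returns NaN when fewer than two
    species carry positive weight.
    """
    w = np.asarray(weights, dtype=float)
    d = distances.values if isinstance(distances, DistanceMatrix) else np.asarray(distances, float)
    if np.count_nonzero(w > 0) < 2:
        return float("nan")
    denom = w.sum() ** 2 - (w ** 2).sum()
    return float(w @ d @ w / denom)


def mpd_per_unit(weight_matrix, distances) -> np.ndarray:
    """Vectorized MPD over stacked weight rows (..., n_species)."""
    w = np.asarray(weight_matrix, dtype=float)
    d = distances.values if isinstance(distances, DistanceMatrix) else np.asarray(distances, float)
    num = np.einsum("...i,ij,...j->...", w, d, w)
    denom = w.sum(axis=-1) ** 2 - (w ** 2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / denom
    out = np.where((w > 0).sum(axis=-1) >= 2, out, np.nan)
    return out


def dispersion_frame(units, metric, weighting, scale, observed, null_mean,
                     null_sd, flip_sign=True) -> pd.DataFrame:
    """Assemble per-unit dispersion rows from observed and null summaries.

    ``ses`` is (observed - null_mean)/null_sd; ``index`` is the clustering
    index (-ses when flip_sign, so clustering, i.e. a small metric, is
    positive).  Units with zero or undefined null SD are flagged undefined.
    """
    observed = np.asarray(observed, float)
    null_mean = np.asarray(null_mean, float)
    null_sd = np.asarray(null_sd, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = (observed - null_mean) / null_sd
    ses = np.where((null_sd > 0) & np.isfinite(observed), ses, np.nan)
    index = -ses if flip_sign else ses
    return pd.DataFrame({
        "unit": list(units),
        "metric": metric,
        "weighting": weighting,
        "scale": scale,
        "observed": observed,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "ses": ses,
        "index": index,
        "significant": np.abs(ses) > Z_CRIT,
    })


def nri(community: CommunityMatrix, distances: DistanceMatrix,
        ensemble: NullEnsemble, weighting: str = "abundance",
        printed_formula: bool = False) -> pd.DataFrame:
    """Net Relatedness Index per community unit.

    Default definition: NRI = -(MPD_obs - mean MPD_null) / sd MPD_null, so
    positive values indicate phylogenetic clustering and |NRI| > 1.96 marks
    two-sided significance at P < 0.05.  With ``printed_formula`` an extra
    column reports the variant that divides the centered MPD by the observed
    MPD instead of the null SD.
    """
    d = distances.submatrix(community.species)
    obs = mpd_per_unit(community.layer(weighting), d)
    sums = np.zeros_like(obs)
    sq = np.zeros_like(obs)
    count = 0
    for ab, ba in ensemble.replicate_layers():
        layer = ab if weighting == "abundance" else ba
        vals = mpd_per_unit(layer, d)
        sums += np.nansum(vals, axis=0)
        sq += np.nansum(vals ** 2, axis=0)
        count += vals.shape[0]
    mean = sums / count
    var = np.maximum(sq / count - mean ** 2, 0.0)
    sd = np.sqrt(var * count / max(count - 1, 1))
    out = dispersion_frame(community.units, "MPD", weighting, community.scale,
                           obs, mean, sd, flip_sign=True)
    out = out.rename(columns={"index": "nri"})
    if printed_formula:
        with np.errstate(divide="ignore", invalid="ignore"):
            out["nri_printed"] = -(obs - mean) / obs
    return out


# ---------------------------------------------------------------------------
# PhyloSor
# ---------------------------------------------------------------------------

def _incidence(tree: Phylogeny, species):
    """Branch lengths and branch-by-species incidence, restricted and ordered
    to ``species`` (which must all be tips of ``tree``)."""
    lens, inc = tree.branch_incidence()
    idx = {l: k for k, l in enumerate(tree.tip_labels)}
    cols = [idx[s] for s in species]
    return lens, inc[:, cols]


def spanning_branch_lengths(tree: Phylogeny, presence, species=None):
    """Total branch length of the spanning subtree per presence row.

    The spanning subtree of a community includes every branch on the path
    from its tips to the root of the tree (PD convention).
    """
    species = species if species is not None else tree.tip_labels
    lens, inc = _incidence(tree, species)
    p = np.atleast_2d(np.asarray(presence, bool))
    on = p @ inc.T > 0  # (rows, branches)
    return on @ lens


def phylosor(tree: Phylogeny, species_a, species_b) -> float:
    """PhyloSor similarity of two species sets on a common tree.

    BL_shared / (0.5 (BL_a + BL_b)) where BL_x is the branch length of the
    subtree spanning set x (including the path to the root) and BL_shared the
    branch length lying on both spanning subtrees.  1 for identical sets.
    """
    for name, s in (("a", species_a), ("b", species_b)):
        if len(s) < 1:
            raise ValueError(f"community {name} is empty")
        missing = [x for x in s if x not in tree]
        if missing:
            raise KeyError(f"species not on tree: {missing}")
    lens, inc = tree.branch_incidence()
    idx = {l: k for k, l in enumerate(tree.tip_labels)}
    pa = np.zeros(tree.n_tips, bool)
    pb = np.zeros(tree.n_tips, bool)
    from .data_model import normalize_name
    pa[[idx[normalize_name(s)] for s in species_a]] = True
    pb[[idx[normalize_name(s)] for s in species_b]] = True
    on_a = inc @ pa > 0
    on_b = inc @ pb > 0
    bl_a = lens[on_a].sum()
    bl_b = lens[on_b].sum()
    shared = lens[on_a & on_b].sum()
    return float(shared / (0.5 * (bl_a + bl_b)))


def phylosor_matrix(tree: Phylogeny, presence, species=None) -> np.ndarray:
    """Pairwise PhyloSor for presence rows (units x species, boolean)."""
    species = species if species is not None else tree.tip_labels
    lens, inc = _incidence(tree, species)
    p = np.asarray(presence, bool)
    on = (p @ inc.T > 0).astype(float)  # units x branches
    bl = on @ lens
    shared = (on * lens) @ on.T
    denom = 0.5 * (bl[:, None] + bl[None, :])
    return shared / denom


def phylosor_ses_matrix(community: CommunityMatrix, tree: Phylogeny,
                        ensemble: NullEnsemble) -> pd.DataFrame:
    """Standardized effect size of pairwise PhyloSor against the null.

    Off-diagonal cells hold (obs - null mean)/null sd for each unit pair;
    the diagonal is NaN.  Works for a trait dendrogram converted to a tree
    just as for the phylogeny.
    """
    species = community.species
    obs = phylosor_matrix(tree, community.abundance > 0, species)
    n_u = community.n_units
    sums = np.zeros((n_u, n_u))
    sq = np.zeros((n_u, n_u))
    count = 0
    lens, inc = _incidence(tree, species)
    ens_species = ensemble.observed.species
    cols = np.array([ens_species.index(s) for s in species])
    for ab, _ in ensemble.replicate_layers():
        pres = ab[:, :, cols] > 0
        on = (pres @ inc.T > 0).astype(float)  # (reps, units, branches)
        bl = on @ lens
        shared = np.einsum("rub,b,rvb->ruv", on, lens, on)
        denom = 0.5 * (bl[:, :, None] + bl[:, None, :])
        vals = shared / denom
        sums += vals.sum(axis=0)
        sq += (vals ** 2).sum(axis=0)
        count += vals.shape[0]
    mean = sums / count
    var = np.maximum(sq / count - mean ** 2, 0.0)
    sd = np.sqrt(var * count / max(count - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = (obs - mean) / sd
    ses[sd == 0] = np.nan
    np.fill_diagonal(ses, np.nan)
    ses = (ses + ses.T) / 2  # numerically symmetric
    return pd.DataFrame(ses, index=community.units, columns=community.units)
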