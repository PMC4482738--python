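"""Randomization engines shared by the dispersion and similarity tests.

The workhorse is the individual-based null (Hardy's model 1s): stems keep
their species identity and basal area, but the sampling-unit labels are
randomly permuted across the multiset of stems.  Every replicate therefore
preserves each unit's stem total and each species' community-wide abundance
exactly, and basal-area weights travel with the stems they belong to.

A second, independent engine (`tip_shuffle`) permutes a trait vector across
tree tips; it backs the phylogenetic-signal permutation test.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data_model import CommunityMatrix, StemTable, aggregate_stems

__all__ = ["NullEnsemble", "randomize_1s", "tip_shuffle"]


class NullEnsemble:
    """Reproducible stream of individual-randomized community replicates.

    The ensemble is defined by (observed community, n_reps, seed); replicate
    matrices are regenerated on demand, so two passes over the same ensemble
    see identical replicates (the dispersion and similarity analyses share
    one set of null communities).
    """

    model = "individuals_to_units_1s"

    def __init__(self, observed: CommunityMatrix, stem_units, stem_species,
                 stem_basal, n_reps: int, seed: int):
        if n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if observed.n_units < 2:
            raise ValueError("need >= 2 units to randomize")
        self.observed = observed
        self._u = np.asarray(stem_units, dtype=np.int64)
        self._s = np.asarray(stem_species, dtype=np.int64)
        self._w = np.asarray(stem_basal, dtype=float)
        self.n_reps = int(n_reps)
        self.seed = int(seed)

    @property
    def n_stems(self) -> int:
        return len(self._u)

    def _matrices_from_units(self, units):
        n_u = self.observed.n_units
        n_s = len(self.observed.species)
        flat = units * n_s + self._s
        ab = np.bincount(flat, minlength=n_u * n_s).astype(float)
        ba = np.bincount(flat, weights=self._w, minlength=n_u * n_s)
        return ab.reshape(n_u, n_s), ba.reshape(n_u, n_s)

    def replicate_layers(self, batch_size: int = 256):
        """Yield (abundance, basal_area) stacks of shape (b, units, species)."""
        rng = np.random.default_rng(self.seed)
        done = 0
        while done < self.n_reps:
            b = min(batch_size, self.n_reps - done)
            ab = np.empty((b, self.observed.n_units, len(self.observed.species)))
            ba = np.empty_like(ab)
            for k in range(b):
                units = rng.permutation(self._u)
                ab[k], ba[k] = self._matrices_from_units(units)
            done += b
            yield ab, ba

    def all_layers(self):
        """All replicates stacked; convenient when n_reps is moderate."""
        abs_, bas = [], []
        for ab, ba in self.replicate_layers():
            abs_.append(ab)
            bas.append(ba)
        return np.concatenate(abs_), np.concatenate(bas)

    def iter_matrices(self):
        """Yield replicates as CommunityMatrix objects (audit/dump path)."""
        rng = np.random.default_rng(self.seed)
        obs = self.observed
        for _ in range(self.n_reps):
            units = rng.permutation(self._u)
            ab, ba = self._matrices_from_units(units)
            yield CommunityMatrix(obs.units, obs.species, ab, ba, scale=obs.scale)


def _stems_from_matrix(community: CommunityMatrix):
    """Expand an aggregated matrix into pseudo-stems.

    Each cell with count k becomes k individuals, each carrying an equal
    1/k share of the cell's basal area (per-stem dbh is unrecoverable from
    the aggregate).
    """
    ab = community.abundance.astype(int)
    ii, jj = np.nonzero(ab)
    counts = ab[ii, jj]
    units = np.repeat(ii, counts)
    species = np.repeat(jj, counts)
    per_stem = community.basal_area[ii, jj] / counts
    basal = np.repeat(per_stem, counts)
    return units, species, basal


def randomize_1s(community, n_reps: int = 999, seed: int = 0,
                 scale: str | None = None) -> NullEnsemble:
    """Individual-randomization null (model 1s).

    ``community`` may be a StemTable (stems carry their true basal area; the
    target scale must be given) or a CommunityMatrix (cells are expanded to
    pseudo-stems with equal basal-area shares).
    """
    if isinstance(community, StemTable):
        if scale is None:
            raise ValueError("scale required when randomizing a StemTable")
        observed = aggregate_stems(community, scale=scale)
        df = community.df
        if scale == "plot":
            unit_lbl = df["plot_id"].astype(str)
        else:
            unit_lbl = df["plot_id"].astype(str) + ":" + df["subplot_id"].astype(str)
        ui = {u: i for i, u in enumerate(observed.units)}
        si = {s: j for j, s in enumerate(observed.species)}
        units = unit_lbl.map(ui).to_numpy()
        species = df["species"].map(si).to_numpy()
        basal = df["basal_area"].to_numpy()
    elif isinstance(community, CommunityMatrix):
        observed = community
        units, species, basal = _stems_from_matrix(community)
    else:
        raise TypeError("community must be a StemTable or CommunityMatrix")
    return NullEnsemble(observed, units, species, basal, n_reps, seed)


def tip_shuffle(values, n_reps: int = 999, seed: int = 0) -> np.ndarray:
    """Uniform random permutations of a trait vector across tips.

    Returns an (n_reps, n_tips) array; row k is replicate k.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("tip shuffle needs >= 3 tips")
    if np.ptp(values) == 0:
        warnings.warn("constant trait vector: permutation test is degenerate")
    rng = np.random.default_rng(seed)
    return rng.permuted(np.tile(values, (n_reps, 1)), axis=1)
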