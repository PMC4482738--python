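"""Core data containers and file I/O.

The analysis operates on four linked inputs: a rooted phylogeny with branch
lengths, a stem table of individually enumerated trees (plot, subplot,
species, dbh), a species-by-trait table, and a plot-by-soil table.  This
module defines the in-memory containers for each, the CSV/Newick readers and
writers, stem-to-community aggregation at the two sampling scales, and the
reconciliation step that restricts tree, traits and community to their
common species set.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "DistanceMatrix",
    "StemTable",
    "CommunityMatrix",
    "ReconcileReport",
    "read_newick",
    "parse_newick",
    "write_newick",
    "read_stem_table",
    "read_trait_table",
    "read_soil_table",
    "read_community_matrix",
    "aggregate_stems",
    "basal_area",
    "cophenetic_distance",
    "reconcile",
    "normalize_name",
    "TRAIT_COLUMNS",
    "SOIL_COLUMNS",
]

#: the eleven measured traits plus the two allometric slopes derived from them
TRAIT_COLUMNS = [
    "SLA", "LA", "LT", "LVD", "WD", "H", "DBH", "CW", "C", "N", "P",
    "dbh_H_slope", "dbh_CW_slope",
]

SOIL_COLUMNS = ["pH", "OM", "N", "P", "K2O", "sand", "silt", "clay"]


def normalize_name(name: str) -> str:
    """Canonical species name: trimmed, underscores mapped to spaces."""
    return " ".join(str(name).replace("_", " ").split())


def basal_area(dbh):
    """Cross-sectional stem area at breast height, pi*(dbh/2)^2, in cm^2."""
    dbh = np.asarray(dbh, dtype=float)
    return np.pi * (dbh / 2.0) ** 2


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

class Phylogeny:
    """Rooted tree with branch lengths, stored as flat parent/length arrays.

    Nodes are indexed in preorder (root first).  ``length[i]`` is the length
    of the edge above node ``i``; the root's entry is 0 unless the source
    Newick carried a root edge.  Tip labels are unique.
    """

    def __init__(self, parent, length, labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        n = len(self.parent)
        if len(self.length) != n:
            raise ValueError("parent and length must have equal size")
        child_count = np.zeros(n, dtype=int)
        for i, p in enumerate(self.parent):
            if p >= 0:
                child_count[p] += 1
        self.is_tip = child_count == 0
        tips = np.flatnonzero(self.is_tip)
        if len(labels) != len(tips):
            raise ValueError("one label per tip required")
        labels = [normalize_name(l) for l in labels]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")
        self.tip_nodes = tips
        self.tip_labels = list(labels)
        self._tip_index = {l: k for k, l in enumerate(self.tip_labels)}
        if np.any(self.length[1:] < 0) or not np.all(np.isfinite(self.length)):
            raise ValueError("branch lengths must be finite and >= 0")

    # -- basic properties ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def total_branch_length(self) -> float:
        """Sum of all edge lengths (root edge excluded)."""
        return float(self.length[1:].sum())

    def __contains__(self, label) -> bool:
        return normalize_name(label) in self._tip_index

    # -- derived structures -------------------------------------------------

    def children(self):
        ch = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            ch[self.parent[i]].append(i)
        return ch

    def branch_incidence(self):
        """(lengths, incidence) for every non-root edge.

        ``incidence[b, t]`` is True when tip ``t`` descends through edge
        ``b``; the edge order follows node order 1..n_nodes-1.
        """
        n = self.n_nodes
        inc = np.zeros((n, self.n_tips), dtype=bool)
        for k, node in enumerate(self.tip_nodes):
            inc[node, k] = True
        # postorder accumulation: reversed preorder visits children first
        for i in range(n - 1, 0, -1):
            inc[self.parent[i]] |= inc[i]
        return self.length[1:].copy(), inc[1:]

    def vcv(self) -> np.ndarray:
        """Tip variance-covariance matrix under Brownian motion.

        C[i, j] is the shared root-to-MRCA path length; the root's own edge
        does not contribute.
        """
        lens, inc = self.branch_incidence()
        incf = inc.astype(float)
        return (incf * lens[:, None]).T @ incf

    def depths(self) -> np.ndarray:
        """Root-to-tip path length per tip (tip-label order)."""
        return np.diag(self.vcv()).copy()

    def cophenetic_matrix(self) -> "DistanceMatrix":
        if self.n_tips < 2:
            raise ValueError("cophenetic distance requires >= 2 tips")
        c = self.vcv()
        d = np.diag(c)
        out = d[:, None] + d[None, :] - 2.0 * c
        np.fill_diagonal(out, 0.0)
        out = np.maximum(out, 0.0)
        return DistanceMatrix(self.tip_labels, (out + out.T) / 2.0)

    # -- pruning ------------------------------------------------------------

    def prune_to(self, labels) -> "Phylogeny":
        """Subtree spanning ``labels``: unifurcations are suppressed and the
        new root is the MRCA of the retained tips (its stem edge is dropped).
        """
        keep_labels = [normalize_name(l) for l in labels]
        missing = [l for l in keep_labels if l not in self._tip_index]
        if missing:
            raise KeyError(f"tips not in tree: {missing}")
        if len(set(keep_labels)) < 1:
            raise ValueError("no tips to retain")
        keep_tip = np.zeros(self.n_tips, dtype=bool)
        for l in keep_labels:
            keep_tip[self._tip_index[l]] = True

        n = self.n_nodes
        n_desc = np.zeros(n, dtype=int)
        for k, node in enumerate(self.tip_nodes):
            if keep_tip[k]:
                n_desc[node] = 1
        for i in range(n - 1, 0, -1):
            n_desc[self.parent[i]] += n_desc[i]

        ch = self.children()

        def live_children(i):
            return [c for c in ch[i] if n_desc[c] > 0]

        # new root = deepest node with all retained tips below it
        root = 0
        while not self.is_tip[root]:
            lc = live_children(root)
            if len(lc) == 1:
                root = lc[0]
            else:
                break

        new_parent, new_length, new_labels = [], [], []
        tip_label_of = {int(t): self.tip_labels[k] for k, t in enumerate(self.tip_nodes)}

        def build(i, parent_new, acc_len):
            if self.is_tip[i] or len(live_children(i)) >= 2 or parent_new == -1:
                idx = len(new_parent)
                new_parent.append(parent_new)
                new_length.append(0.0 if parent_new == -1 else acc_len + self.length[i])
                if self.is_tip[i]:
                    new_labels.append(tip_label_of[i])
                for c in live_children(i):
                    build(c, idx, 0.0)
            else:  # unifurcation: fold edge length into the single child
                (c,) = live_children(i)
                build(c, parent_new, acc_len + self.length[i])

        build(root, -1, 0.0)
        return Phylogeny(new_parent, new_length, new_labels)

    # -- serialization ------------------------------------------------------

    def newick(self) -> str:
        ch = self.children()
        tip_label_of = {int(t): self.tip_labels[k] for k, t in enumerate(self.tip_nodes)}

        def fmt(i):
            if self.is_tip[i]:
                body = tip_label_of[i].replace(" ", "_")
            else:
                body = "(" + ",".join(fmt(c) for c in ch[i]) + ")"
            if self.parent[i] == -1:
                return body
            return f"{body}:{self.length[i]:.17g}"

        return fmt(0) + ";"

    def __repr__(self):
        return f"<Phylogeny {self.n_tips} tips, {self.n_nodes} nodes>"


def _from_dendropy(tree: dendropy.Tree) -> Phylogeny:
    parent, length, labels = [], [], []
    index = {}
    for node in tree.preorder_node_iter():
        idx = len(parent)
        index[id(node)] = idx
        if node.parent_node is None:
            parent.append(-1)
            length.append(float(node.edge.length or 0.0))
        else:
            parent.append(index[id(node.parent_node)])
            if node.edge.length is None:
                name = node.taxon.label if node.taxon else f"internal node #{idx}"
                raise ValueError(f"missing branch length on edge above {name!r}")
            length.append(float(node.edge.length))
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise ValueError("unlabeled tip in Newick input")
            labels.append(node.taxon.label)
    return Phylogeny(parent, length, labels)


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required on all non-root edges)."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
    except Exception as e:  # dendropy's reader errors vary by cause
        raise ValueError(f"invalid Newick ({'duplicate taxon' if 'uplicate' in str(e) else e})") from e
    return _from_dendropy(tree)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with named rows/columns."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")
        self._index = {l: i for i, l in enumerate(self.labels)}

    def __len__(self):
        return len(self.labels)

    def get(self, a, b) -> float:
        return float(self.values[self._index[str(a)], self._index[str(b)]])

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self._index[str(l)] for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def reorder(self, labels) -> "DistanceMatrix":
        return self.submatrix(labels)

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def cophenetic_distance(tree: Phylogeny) -> DistanceMatrix:
    """Patristic (path-length) distance between every pair of tips."""
    return tree.cophenetic_matrix()


# ---------------------------------------------------------------------------
# StemTable
# ---------------------------------------------------------------------------

class StemTable:
    """Individually enumerated stems: plot, subplot, species and dbh (cm).

    Basal area is always recomputed from dbh as pi*(dbh/2)^2 in cm^2 and is
    never stored independently.
    """

    REQUIRED = ["stem_id", "plot_id", "subplot_id", "species", "dbh"]

    def __init__(self, df: pd.DataFrame, n_subplots: int = 25):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"StemTable missing columns: {missing}")
        df = df.copy()
        df["species"] = df["species"].map(normalize_name)
        df["dbh"] = df["dbh"].astype(float)
        if len(df) and (df["dbh"] <= 0).any():
            bad = df.loc[df["dbh"] <= 0, "stem_id"].tolist()[:5]
            raise ValueError(f"nonpositive dbh for stems {bad}")
        sub = pd.to_numeric(df["subplot_id"], errors="coerce")
        if len(df) and (sub.isna() | (sub < 1) | (sub > n_subplots)).any():
            bad = df.loc[sub.isna() | (sub < 1) | (sub > n_subplots), "subplot_id"]
            raise ValueError(f"subplot ids outside 1..{n_subplots}: {sorted(set(bad))[:5]}")
        df["subplot_id"] = sub.astype(int) if len(df) else sub
        df["basal_area"] = basal_area(df["dbh"])
        self.df = df.reset_index(drop=True)
        self.n_subplots = n_subplots

    def __len__(self):
        return len(self.df)

    @property
    def species(self):
        return sorted(self.df["species"].unique())

    def restrict_to_species(self, keep) -> "StemTable":
        keep = {normalize_name(s) for s in keep}
        return StemTable(self.df[self.df["species"].isin(keep)].drop(columns="basal_area"),
                         n_subplots=self.n_subplots)

    def to_csv(self, path):
        self.df.drop(columns="basal_area").to_csv(path, index=False)


def read_stem_table(path, n_subplots: int = 25) -> StemTable:
    return StemTable(pd.read_csv(path), n_subplots=n_subplots)


# ---------------------------------------------------------------------------
# CommunityMatrix
# ---------------------------------------------------------------------------

class CommunityMatrix:
    """Unit x species community table with two weight layers.

    ``abundance`` holds stem counts and ``basal_area`` the summed per-stem
    basal areas (cm^2); the two layers share a support (a cell has positive
    basal area iff it has positive abundance).
    """

    def __init__(self, units, species, abundance, basal_area, scale="plot"):
        self.units = [str(u) for u in units]
        self.species = [normalize_name(s) for s in species]
        self.abundance = np.asarray(abundance, dtype=float)
        self.basal_area = np.asarray(basal_area, dtype=float)
        if scale not in ("plot", "subplot"):
            raise ValueError("scale must be 'plot' or 'subplot'")
        self.scale = scale
        shape = (len(self.units), len(self.species))
        if self.abundance.shape != shape or self.basal_area.shape != shape:
            raise ValueError("layer shapes must be units x species")
        if np.any(self.abundance < 0) or np.any(self.basal_area < 0):
            raise ValueError("negative weights")
        if not np.allclose(self.abundance, np.round(self.abundance)):
            raise ValueError("abundance must be integer counts")
        if np.any((self.abundance > 0) != (self.basal_area > 0)):
            raise ValueError("abundance/basal-area support mismatch")
        self._unit_index = {u: i for i, u in enumerate(self.units)}
        self._sp_index = {s: j for j, s in enumerate(self.species)}

    @property
    def n_units(self):
        return len(self.units)

    def layer(self, weighting: str) -> np.ndarray:
        if weighting not in ("abundance", "basal_area"):
            raise ValueError("weighting must be 'abundance' or 'basal_area'")
        return self.abundance if weighting == "abundance" else self.basal_area

    def restrict_to_species(self, keep) -> "CommunityMatrix":
        keep = [s for s in self.species if s in {normalize_name(k) for k in keep}]
        idx = [self._sp_index[s] for s in keep]
        return CommunityMatrix(self.units, keep, self.abundance[:, idx],
                               self.basal_area[:, idx], scale=self.scale)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, u in enumerate(self.units):
            for j, s in enumerate(self.species):
                if self.abundance[i, j] > 0:
                    rows.append((u, s, int(self.abundance[i, j]), self.basal_area[i, j]))
        return pd.DataFrame(rows, columns=["unit", "species", "abundance", "basal_area"])

    def to_csv(self, path):
        self.to_long().to_csv(path, index=False)


def read_community_matrix(path, scale="plot") -> CommunityMatrix:
    long = pd.read_csv(path)
    units = sorted(long["unit"].astype(str).unique())
    species = sorted(long["species"].map(normalize_name).unique())
    ui = {u: i for i, u in enumerate(units)}
    si = {s: j for j, s in enumerate(species)}
    ab = np.zeros((len(units), len(species)))
    ba = np.zeros_like(ab)
    for _, r in long.iterrows():
        i, j = ui[str(r["unit"])], si[normalize_name(r["species"])]
        ab[i, j] += r["abundance"]
        ba[i, j] += r["basal_area"]
    return CommunityMatrix(units, species, ab, ba, scale=scale)


def aggregate_stems(stems: StemTable, scale: str = "plot") -> CommunityMatrix:
    """Collapse a stem table to a unit x species matrix at the chosen scale.

    Plot units are the plot ids; subplot units are ``plot:subplot`` labels.
    Stem counts and summed basal area are conserved exactly.
    """
    if scale not in ("plot", "subplot"):
        raise ValueError("scale must be 'plot' or 'subplot'")
    df = stems.df
    if scale == "plot":
        unit = df["plot_id"].astype(str)
    else:
        unit = df["plot_id"].astype(str) + ":" + df["subplot_id"].astype(str)
    if len(df) == 0:
        return CommunityMatrix([], [], np.zeros((0, 0)), np.zeros((0, 0)), scale=scale)
    if scale == "plot":
        units = sorted(unit.unique())
    else:
        # every subplot of an enumerated plot is a sampling unit, stems or not
        units = [f"{p}:{q}" for p in sorted(df["plot_id"].astype(str).unique())
                 for q in range(1, stems.n_subplots + 1)]
    species = sorted(df["species"].unique())
    ui = unit.map({u: i for i, u in enumerate(units)}).to_numpy()
    si = df["species"].map({s: j for j, s in enumerate(species)}).to_numpy()
    flat = ui * len(species) + si
    ab = np.bincount(flat, minlength=len(units) * len(species)).astype(float)
    ba = np.bincount(flat, weights=df["basal_area"].to_numpy(),
                     minlength=len(units) * len(species))
    shape = (len(units), len(species))
    return CommunityMatrix(units, species, ab.reshape(shape), ba.reshape(shape),
                           scale=scale)


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------

@dataclass
class ReconcileReport:
    kept_species: list
    dropped_from_tree: list
    dropped_from_traits: list
    dropped_from_community: list
    excluded_individual_fraction: float

    def summary(self) -> str:
        return (f"kept {len(self.kept_species)} species; dropped "
                f"{len(self.dropped_from_community)} community species "
                f"({self.excluded_individual_fraction:.1%} of individuals)")


def reconcile(tree: Phylogeny, traits: pd.DataFrame, community):
    """Restrict tree, trait table and community to their shared species.

    ``traits`` is indexed by species name; ``community`` is a StemTable or a
    CommunityMatrix.  Returns (pruned tree, filtered traits, filtered
    community, report); the report records dropped names per source and the
    fraction of individuals excluded from the community.
    """
    tree_sp = set(tree.tip_labels)
    trait_sp = {normalize_name(s) for s in traits.index}
    if isinstance(community, StemTable):
        comm_sp = set(community.species)
        weights = community.df.groupby("species").size()
    else:
        comm_sp = set(community.species)
        weights = pd.Series(community.abundance.sum(axis=0), index=community.species)
    common = tree_sp & trait_sp & comm_sp
    if len(common) < 2:
        raise ValueError("fewer than 2 species shared by tree, traits and community")
    total = float(weights.sum())
    excluded = float(weights[~weights.index.isin(common)].sum())
    frac = excluded / total if total > 0 else 0.0

    traits_out = traits.loc[[s for s in traits.index if normalize_name(s) in common]].copy()
    traits_out.index = [normalize_name(s) for s in traits_out.index]
    report = ReconcileReport(
        kept_species=sorted(common),
        dropped_from_tree=sorted(tree_sp - common),
        dropped_from_traits=sorted(trait_sp - common),
        dropped_from_community=sorted(comm_sp - common),
        excluded_individual_fraction=frac,
    )
    pruned = tree.prune_to(sorted(common)) if tree_sp != common else tree
    comm_out = community.restrict_to_species(common)
    return pruned, traits_out, comm_out, report


# ---------------------------------------------------------------------------
# Trait / soil tables
# ---------------------------------------------------------------------------

def read_trait_table(path) -> pd.DataFrame:
    """Species x trait CSV; first column is the species name.

    Missing values stay as NaN — they are never silently zeroed.
    """
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    df.index = [normalize_name(s) for s in df.index]
    df.index.name = "species"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate species in trait table: {dup}")
    return df.astype(float)


def read_soil_table(path) -> pd.DataFrame:
    """Plot x soil-parameter CSV; first column is the plot id."""
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "plot_id"
    if df.index.duplicated().any():
        raise ValueError("duplicate plot ids in soil table")
    tex = [c for c in ("sand", "silt", "clay") if c in df.columns]
    if len(tex) == 3:
        tot = df[tex].sum(axis=1)
        ok = tot.isna() | ((tot >= 99.0) & (tot <= 101.0))
        if not ok.all():
            bad = df.index[~ok].tolist()
            raise ValueError(f"sand+silt+clay outside [99, 101] for plots {bad}")
    return df.astype(float)
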