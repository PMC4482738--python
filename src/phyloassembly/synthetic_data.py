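"""Synthetic forest communities under known assembly processes.

The generator produces the full input bundle the analysis pipeline expects —
a Yule phylogeny, species trait values evolved as conserved (Brownian) or
convergent (Brownian signal destroyed by large tip noise), a one-dimensional
soil gradient expressed through correlated soil parameters, and a stem table
of individual trees assembled into plots by one of three processes:

* environmental filtering — each plot has a trait optimum mapped from the
  soil gradient; a stem's species is drawn with probability proportional to
  a Gaussian kernel around that optimum;
* competitive exclusion (limiting similarity) — plot membership is built
  sequentially, rejecting candidates whose assembly-trait distance to any
  resident is below a threshold; stems are then spread over the residents;
* neutral — species are drawn uniformly from the pool.

Defaults mirror an 11-plot, 25-subplots-per-plot survey of ~1200 stems from
a pool of 123 species, so that the generated bundle exercises every stage of
the pipeline at realistic size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import Phylogeny, StemTable, write_newick

__all__ = [
    "ScenarioConfig", "SyntheticDataset", "SCENARIOS",
    "simulate_tree", "simulate_bm", "simulate_traits", "simulate_soil",
    "assemble", "generate",
]

#: the six process x trait-evolution cells
SCENARIOS = {
    "filtering_conserved": ("environmental_filtering", "conserved"),
    "filtering_convergent": ("environmental_filtering", "convergent"),
    "competition_conserved": ("competitive_exclusion", "conserved"),
    "competition_convergent": ("competitive_exclusion", "convergent"),
    "neutral_conserved": ("neutral", "conserved"),
    "neutral_convergent": ("neutral", "convergent"),
}


@dataclass
class ScenarioConfig:
    process: str = "neutral"            # environmental_filtering | competitive_exclusion | neutral
    trait_mode: str = "conserved"       # conserved | convergent
    n_species_pool: int = 123
    n_plots: int = 11
    subplots_per_plot: int = 25
    stems_per_plot: int = 111           # 11 x 111 = 1221 stems
    filtering_width: float = 0.4        # sigma_f, in pool-trait-SD units
    filtering_width_range: tuple | None = None  # per-plot sigma_f linear in the gradient
    limiting_similarity: float = 0.5    # delta, in pool-trait-SD units
    target_richness: int = 10           # residents per plot under competition
    gradient_range: tuple = (-1.5, 1.5) # plot optima, in pool-trait-SD units
    n_decoys: int = 3
    bm_rate: float = 1.0
    convergent_noise_factor: float = 10.0
    dbh_meanlog: float = np.log(20.0)
    dbh_sdlog: float = 0.5
    dbh_min: float = 10.0
    seed: int = 0

    @classmethod
    def from_scenario(cls, name: str, **kwargs) -> "ScenarioConfig":
        if name not in SCENARIOS:
            raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
        process, trait_mode = SCENARIOS[name]
        return cls(process=process, trait_mode=trait_mode, **kwargs)


@dataclass
class SyntheticDataset:
    tree: Phylogeny
    traits: pd.DataFrame
    soil: pd.DataFrame
    stems: StemTable
    truth: dict

    def write(self, outdir):
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_newick(self.tree, out / "tree.nwk")
        self.traits.to_csv(out / "traits.csv")
        self.soil.to_csv(out / "soil.csv")
        self.stems.to_csv(out / "stems.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# Tree and trait simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree.

    Starting from two lineages, waiting times between splits are exponential
    with rate k*birth_rate while k lineages are extant; after the last split
    one more exponential interval is appended, so the tree is ultrametric
    with expected tip depth sum_{k=2..n} 1/(k*birth_rate).
    """
    if n_tips < 4:
        raise ValueError("simulate_tree requires n_tips >= 4")
    rng = np.random.default_rng(seed)
    parent = [-1, 0, 0]
    length = [0.0, 0.0, 0.0]
    active = [1, 2]
    k = 2
    while True:
        t = rng.exponential(1.0 / (birth_rate * k))
        for i in active:
            length[i] += t
        if k == n_tips:
            break
        j = active[rng.integers(len(active))]
        for _ in range(2):
            parent.append(j)
            length.append(0.0)
            active.append(len(parent) - 1)
        active.remove(j)
        k += 1
    # relabel into preorder and name tips
    order = _preorder(parent)
    remap = {old: new for new, old in enumerate(order)}
    new_parent = [remap[parent[old]] if parent[old] != -1 else -1 for old in order]
    new_length = [length[old] for old in order]
    n_nodes = len(new_parent)
    is_tip = np.ones(n_nodes, bool)
    for p in new_parent:
        if p >= 0:
            is_tip[p] = False
    labels = [f"sp{k + 1:03d}" for k in range(int(is_tip.sum()))]
    return Phylogeny(new_parent, new_length, labels)


def _preorder(parent):
    children = {}
    root = None
    for i, p in enumerate(parent):
        if p == -1:
            root = i
        else:
            children.setdefault(p, []).append(i)
    order = []
    stack = [root]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(reversed(children.get(i, [])))
    return order


def simulate_bm(tree: Phylogeny, rate: float = 1.0, seed: int = 0,
                n_traits: int = 1) -> np.ndarray:
    """Brownian-motion trait values at the tips (n_traits x n_tips).

    Each edge adds a normal increment with variance rate * branch length.
    """
    rng = np.random.default_rng(seed)
    n = tree.n_nodes
    vals = np.zeros((n_traits, n))
    for i in range(1, n):  # preorder: parents precede children
        sd = np.sqrt(rate * tree.length[i])
        vals[:, i] = vals[:, tree.parent[i]] + rng.normal(0.0, sd, size=n_traits)
    return vals[:, tree.tip_nodes]


def simulate_traits(tree: Phylogeny, mode: str = "conserved",
                    bm_rate: float = 1.0, n_decoys: int = 3,
                    convergent_noise_factor: float = 10.0,
                    seed: int = 0) -> pd.DataFrame:
    """Species trait table with one assembly trait and decoy traits.

    T1 is the assembly trait: Brownian under 'conserved'; under 'convergent'
    the Brownian values are swamped by iid tip noise scaled to
    ``convergent_noise_factor`` times their SD, destroying the phylogenetic
    signal while keeping a comparable scale.  Decoys are iid normal, and the
    final pair of columns is built with |r| > 0.8 so that trait screening has
    something to drop.
    """
    if mode not in ("conserved", "convergent"):
        raise ValueError("mode must be 'conserved' or 'convergent'")
    rng = np.random.default_rng(seed)
    bm = simulate_bm(tree, rate=bm_rate, seed=rng.integers(2 ** 31))[0]
    if mode == "convergent":
        noise = rng.normal(0.0, convergent_noise_factor * max(bm.std(), 1e-12),
                           size=len(bm))
        t1 = bm + noise
    else:
        t1 = bm
    cols = {"T1": t1}
    for k in range(n_decoys):
        cols[f"T{k + 2}"] = rng.normal(0.0, 1.0, tree.n_tips)
    base = rng.normal(0.0, 1.0, tree.n_tips)
    cols[f"T{n_decoys + 2}"] = base
    cols[f"T{n_decoys + 3}"] = 0.9 * base + np.sqrt(1 - 0.9 ** 2) * rng.normal(0.0, 1.0, tree.n_tips)
    return pd.DataFrame(cols, index=pd.Index(tree.tip_labels, name="species"))


# ---------------------------------------------------------------------------
# Soil gradient
# ---------------------------------------------------------------------------

def simulate_soil(n_plots: int, gradient_range=(-1.5, 1.5), seed: int = 0,
                  jitter: float = 0.05, noise: float = 0.03):
    """Soil table whose leading PCA axis is a known latent gradient.

    Plots sit at equally spaced (jittered) positions g on the gradient.
    Sand and pH rise with g; P, K2O, silt and clay fall; OM and N vary
    independently (they load on the second axis).  Returns (soil table, g).
    """
    if n_plots < 2:
        raise ValueError("need >= 2 plots")
    rng = np.random.default_rng(seed)
    lo, hi = gradient_range
    g = np.linspace(lo, hi, n_plots) + rng.normal(0.0, jitter * (hi - lo), n_plots)
    gs = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
    eps = lambda scale=1.0: rng.normal(0.0, noise * scale, n_plots)
    om = 4.0 + 1.2 * rng.normal(0.0, 1.0, n_plots)
    sand = 45.0 + 12.0 * gs + eps(10.0)
    sand = np.clip(sand, 5.0, 90.0)
    rest = 100.0 - sand
    silt_frac = 0.55 + eps(0.3)
    soil = pd.DataFrame({
        "pH": 5.2 + 0.5 * gs + eps(5.0),
        "OM": np.maximum(om, 0.5),
        "N": np.maximum(0.05 + 0.04 * om + eps(0.5), 0.01),
        "P": np.maximum(30.0 - 8.0 * gs + eps(40.0), 1.0),
        "K2O": np.maximum(80.0 - 20.0 * gs + eps(80.0), 5.0),
        "sand": sand,
        "silt": rest * silt_frac,
        "clay": rest * (1.0 - silt_frac),
    }, index=pd.Index([f"P{i + 1:02d}" for i in range(n_plots)], name="plot_id"))
    return soil, g


# ---------------------------------------------------------------------------
# Community assembly
# ---------------------------------------------------------------------------

def _draw_dbh(rng, n, cfg: ScenarioConfig):
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(cfg.dbh_meanlog, cfg.dbh_sdlog, size=2 * (n - filled))
        draw = draw[draw >= cfg.dbh_min]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _assign_subplots(rng, species_idx, n_subplots, cluster_prob=0.5):
    """Mildly clustered subplot labels: each species has a home subplot that
    attracts a fraction of its stems (Thomas-process flavor)."""
    home = {}
    out = np.empty(len(species_idx), dtype=int)
    for i, s in enumerate(species_idx):
        if s not in home:
            home[s] = rng.integers(1, n_subplots + 1)
        if rng.random() < cluster_prob:
            out[i] = home[s]
        else:
            out[i] = rng.integers(1, n_subplots + 1)
    return out


def assemble(config: ScenarioConfig, tree: Phylogeny, traits: pd.DataFrame,
             gradient, assembly_trait: str = "T1", seed=None) -> StemTable:
    """Draw individual stems per plot under the configured process.

    ``gradient`` gives one latent soil score per plot; it is mapped linearly
    onto trait optima spanning ``gradient_range`` (in pool-trait SD units)
    so that filtering strength and direction track the soil axis.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    species = list(traits.index)
    t = traits[assembly_trait].to_numpy(float)
    t_mean, t_sd = t.mean(), t.std()
    g = np.asarray(gradient, float)
    if len(g) != config.n_plots:
        raise ValueError("gradient length must equal n_plots")
    lo, hi = config.gradient_range
    span = g.max() - g.min()
    rel = (g - g.min()) / span if span > 0 else np.full_like(g, 0.5)
    optima = t_mean + t_sd * (lo + (hi - lo) * rel)
    if config.filtering_width_range is not None:
        w_lo, w_hi = config.filtering_width_range
        sigma_f_per_plot = (w_lo + (w_hi - w_lo) * rel) * t_sd
    else:
        sigma_f_per_plot = np.full(config.n_plots, config.filtering_width * t_sd)
    delta = config.limiting_similarity * t_sd

    rows = []
    stem_id = 0
    for u in range(config.n_plots):
        plot = f"P{u + 1:02d}"
        if config.process == "neutral":
            probs = np.full(len(species), 1.0 / len(species))
            sp_idx = rng.choice(len(species), size=config.stems_per_plot, p=probs)
        elif config.process == "environmental_filtering":
            logw = -((t - optima[u]) ** 2) / (2.0 * sigma_f_per_plot[u] ** 2)
            w = np.exp(logw - logw.max())
            probs = w / w.sum()
            sp_idx = rng.choice(len(species), size=config.stems_per_plot, p=probs)
        elif config.process == "competitive_exclusion":
            residents = []
            attempts = 0
            max_attempts = 400 * config.target_richness
            order = rng.permutation(len(species))
            ptr = 0
            while len(residents) < config.target_richness and attempts < max_attempts:
                if ptr == len(order):
                    order = rng.permutation(len(species))
                    ptr = 0
                cand = order[ptr]
                ptr += 1
                attempts += 1
                if cand in residents:
                    continue
                if all(abs(t[cand] - t[r]) >= delta for r in residents):
                    residents.append(cand)
            if len(residents) < 2:
                raise ValueError(
                    "limiting similarity threshold infeasible: fewer than two "
                    "species can coexist")
            residents = np.array(residents)
            sp_idx = residents[rng.integers(len(residents), size=config.stems_per_plot)]
        else:
            raise ValueError(f"unknown process {config.process!r}")
        dbh = _draw_dbh(rng, len(sp_idx), config)
        subplots = _assign_subplots(rng, sp_idx, config.subplots_per_plot)
        for s, d, q in zip(sp_idx, dbh, subplots):
            stem_id += 1
            rows.append((f"s{stem_id:05d}", plot, int(q), species[s], float(d)))
    df = pd.DataFrame(rows, columns=["stem_id", "plot_id", "subplot_id",
                                     "species", "dbh"])
    return StemTable(df, n_subplots=config.subplots_per_plot)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def generate(config: ScenarioConfig) -> SyntheticDataset:
    """Full synthetic bundle: tree, traits, soil, stems and truth record."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]
    tree = simulate_tree(config.n_species_pool, seed=seeds[0])
    traits = simulate_traits(tree, mode=config.trait_mode, bm_rate=config.bm_rate,
                             n_decoys=config.n_decoys,
                             convergent_noise_factor=config.convergent_noise_factor,
                             seed=seeds[1])
    # the latent soil gradient has its own fixed span; config.gradient_range
    # only controls how wide the TRAIT optima are spread along it
    soil, gradient = simulate_soil(config.n_plots, seed=seeds[2])
    stems = assemble(config, tree, traits, gradient, seed=seeds[3])
    truth = {
        "process": config.process,
        "trait_mode": config.trait_mode,
        "assembly_trait": "T1",
        "gradient": list(map(float, gradient)),
        "plot_ids": list(soil.index),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    return SyntheticDataset(tree=tree, traits=traits, soil=soil, stems=stems,
                            truth=truth)
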