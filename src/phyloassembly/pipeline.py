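"""End-to-end orchestration of the assembly analysis.

``run_all`` reproduces the full analysis sequence on any dataset, real or
synthetic: reconciliation, trait screening, trait distances and dendrogram,
the shared individual-randomization null, NRI and ZFDis (both weightings,
both scales, per-trait and multivariate), Blomberg's K per trait, soil PCA,
CCA with axis permutation tests, PhyloSor / trait-dendrogram SES matrices,
Mantel tests against soil distance, and regressions of the dispersion
indices on the soil PCA axes.  One JSON-serializable report collects every
number; per-unit tables are returned as DataFrames (and written as CSV by
the CLI).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import data_model as dm
from .conventions import DEFAULT_N_REPS
from .gradient_stats import (cca, cca_axis_test, mantel, regress_ses_on_axis,
                             soil_distance, soil_pca)
from .null_models import randomize_1s
from .phylo_signal import k_test
from .phylo_structure import nri, phylosor_matrix, phylosor_ses_matrix
from .trait_structure import (build_dendrogram, screen_traits, trait_distance,
                              trait_sor_ses_matrix, zfdis)

__all__ = ["AnalysisConfig", "run_all"]


@dataclass
class AnalysisConfig:
    tree_path: str = ""
    stems_path: str = ""
    traits_path: str = ""
    soil_path: str = ""
    weightings: tuple = ("abundance", "basal_area")
    scales: tuple = ("plot", "subplot")
    n_reps: int = DEFAULT_N_REPS
    seed: int = 0
    trait_threshold: float = 0.50
    trait_priority: tuple = ()       # empty = column order
    log10_traits: bool = True
    multivariate: bool = True
    per_trait: bool = True
    # CCA cannot take the full compositional texture triplet (sand+silt+clay
    # is constant); default to five parameters, overridable per dataset
    cca_soil_columns: tuple = ("pH", "OM", "N", "P", "K2O")
    printed_nri_formula: bool = False
    fdis_space: str = "dendrogram"   # multivariate FDis distances: dendrogram | euclidean

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        for key in ("weightings", "scales", "trait_priority", "cca_soil_columns"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _bh(pvals):
    p = np.asarray(pvals, float)
    mask = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def run_all(config: AnalysisConfig, tree=None, stems=None, traits=None,
            soil=None):
    """Run the whole analysis; returns (report dict, tables dict).

    Inputs may be passed as objects (overriding the config paths) — the
    synthetic generator's outputs plug in directly.
    """
    tree = tree if tree is not None else dm.read_newick(config.tree_path)
    stems = stems if stems is not None else dm.read_stem_table(config.stems_path)
    traits = traits if traits is not None else dm.read_trait_table(config.traits_path)
    soil = soil if soil is not None else dm.read_soil_table(config.soil_path)

    tree, traits, stems, rec_report = dm.reconcile(tree, traits, stems)

    screen = screen_traits(traits, threshold=config.trait_threshold,
                           priority=list(config.trait_priority) or None)
    selected = screen.selected
    tdist = trait_distance(traits, columns=selected, log10=config.log10_traits)
    dendro = build_dendrogram(tdist)
    # multivariate FDis runs on the dendrogram's cophenetic distances by
    # default (trait-dendrogram FDis); 'euclidean' uses raw trait distances
    if config.fdis_space == "dendrogram":
        fdis_dist = dendro.cophenetic_matrix()
    elif config.fdis_space == "euclidean":
        fdis_dist = tdist
    else:
        raise ValueError("fdis_space must be 'dendrogram' or 'euclidean'")
    pdist_matrix = dm.cophenetic_distance(tree)

    report = {
        "seed": config.seed,
        "n_reps": config.n_reps,
        "reconciliation": {
            "n_species": len(rec_report.kept_species),
            "dropped_from_community": rec_report.dropped_from_community,
            "excluded_individual_fraction": rec_report.excluded_individual_fraction,
        },
        "trait_screening": {
            "selected": selected,
            "dropped": screen.dropped,
            "threshold": screen.threshold,
        },
    }
    tables = {}

    # --- phylogenetic signal ------------------------------------------------
    k_rows = []
    for j, trait in enumerate(traits.columns):
        vec = traits[trait].reindex(tree.tip_labels)
        if vec.isna().any() or vec.nunique() < 2:
            continue
        res = k_test(tree, vec.to_numpy(), n_perm=config.n_reps,
                     seed=config.seed + 101 + j, trait=trait)
        k_rows.append({"trait": trait, "K": res.k, "p_value": res.p_value,
                       "n_tips": res.n_tips, "n_perm": res.n_perm})
    k_table = pd.DataFrame(k_rows)
    tables["k_table"] = k_table
    report["phylo_signal"] = k_rows

    # --- dispersion at both scales, both weightings --------------------------
    disp_frames = []
    plot_ensemble = None
    for si, scale in enumerate(config.scales):
        ensemble = randomize_1s(stems, n_reps=config.n_reps,
                                seed=config.seed + 11 * (si + 1), scale=scale)
        if scale == "plot":
            plot_ensemble = ensemble
        community = ensemble.observed
        d_phy = pdist_matrix.submatrix(community.species)
        per_trait_dist = {t: trait_distance(traits, columns=[t],
                                            log10=config.log10_traits)
                          for t in selected} if config.per_trait else {}
        for weighting in config.weightings:
            disp_frames.append(nri(community, d_phy, ensemble, weighting,
                                   printed_formula=config.printed_nri_formula))
            if config.multivariate:
                f = zfdis(community, fdis_dist, ensemble, weighting,
                          metric_name="FDis_multivariate")
                disp_frames.append(f.rename(columns={"zfdis_clustering": "nri"}))
            for trait, dt in per_trait_dist.items():
                f = zfdis(community, dt, ensemble, weighting,
                          metric_name=f"FDis_{trait}")
                disp_frames.append(f.rename(columns={"zfdis_clustering": "nri"}))
    dispersion = pd.concat(disp_frames, ignore_index=True)
    dispersion = dispersion.rename(columns={"nri": "clustering_index"})
    tables["dispersion"] = dispersion
    report["dispersion_summary"] = (
        dispersion.groupby(["metric", "weighting", "scale"])
        .agg(n_units=("unit", "count"),
             n_significant=("significant", "sum"),
             mean_index=("clustering_index", "mean"))
        .reset_index()
        .assign(n_significant=lambda d: d["n_significant"].astype(int))
        .to_dict(orient="records")
    )

    # --- soil gradients -----------------------------------------------------
    pca = soil_pca(soil)
    report["soil_pca"] = {
        "explained": [float(v) for v in pca.explained[:4]],
        "loadings_pca1": pca.loadings["PCA1"].to_dict(),
    }
    tables["soil_scores"] = pca.scores

    plot_comm = plot_ensemble.observed if plot_ensemble is not None else None
    cca_cols = [c for c in (config.cca_soil_columns or soil.columns)
                if c in soil.columns]
    if len(cca_cols) < 2:
        cca_cols = list(soil.columns)
    if plot_comm is not None and len(cca_cols) > plot_comm.n_units - 1:
        # a saturated constraint set leaves no residual degrees of freedom
        cca_cols = cca_cols[:plot_comm.n_units - 1]
    if plot_comm is not None:
        soil_al = soil.loc[[str(u) for u in plot_comm.units], cca_cols]
        ord_res = cca(plot_comm, soil_al)
        axis_p = cca_axis_test(plot_comm, soil_al, n_perm=config.n_reps,
                               seed=config.seed + 71, n_axes=min(2, len(ord_res.explained)))
        report["cca"] = {
            "explained": [float(v) for v in ord_res.explained[:4]],
            "axis_p": [float(v) for v in axis_p],
            "total_inertia": ord_res.total,
        }

        # --- similarity and Mantel -------------------------------------------
        plot_comm_tr = plot_comm.restrict_to_species(tdist.labels)
        phylo_ses = phylosor_ses_matrix(plot_comm, tree, plot_ensemble)
        trait_ses = trait_sor_ses_matrix(plot_comm_tr, dendro, plot_ensemble)
        tables["phylosor_ses"] = phylo_ses
        tables["traitsor_ses"] = trait_ses

        d_soil = soil_distance(soil.loc[[str(u) for u in plot_comm.units]])
        phylo_sim = phylosor_matrix(tree, plot_comm.abundance > 0,
                                    plot_comm.species)
        trait_sim = phylosor_matrix(dendro.to_phylogeny(),
                                    plot_comm_tr.abundance > 0,
                                    plot_comm_tr.species)
        d_phylo = dm.DistanceMatrix(plot_comm.units, _sim_to_dist(phylo_sim))
        d_trait = dm.DistanceMatrix(plot_comm.units, _sim_to_dist(trait_sim))
        m_tr = mantel(d_trait, d_soil, n_perm=config.n_reps, seed=config.seed + 81)
        m_ph = mantel(d_phylo, d_soil, n_perm=config.n_reps, seed=config.seed + 82)
        report["mantel"] = {
            "trait_vs_soil": {"r": m_tr.r, "p": m_tr.p_value},
            "phylo_vs_soil": {"r": m_ph.r, "p": m_ph.p_value},
        }

        # --- dispersion vs gradient regressions ------------------------------
        reg_rows = []
        plot_disp = dispersion[dispersion["scale"] == "plot"]
        for (metric, weighting), grp in plot_disp.groupby(["metric", "weighting"]):
            idx = grp.set_index("unit")["clustering_index"]
            for axis in ("PCA1", "PCA2"):
                if axis not in pca.scores.columns:
                    continue
                scores = pca.scores[axis].reindex(idx.index.astype(str))
                try:
                    fit = regress_ses_on_axis(idx.to_numpy(), scores.to_numpy())
                except ValueError:
                    continue
                reg_rows.append({"metric": metric, "weighting": weighting,
                                 "axis": axis, "slope": fit.slope, "r": fit.r,
                                 "p_value": fit.p_value, "n": fit.n})
        reg = pd.DataFrame(reg_rows)
        if len(reg):
            reg["q_value_bh"] = _bh(reg["p_value"])  # extension, labeled as such
        tables["regressions"] = reg
        report["regressions"] = reg.to_dict(orient="records")

    return report, tables


def _sim_to_dist(sim):
    d = 1.0 - np.asarray(sim, float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return d


def write_outputs(report, tables, outdir):
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    for name, tab in tables.items():
        tab.to_csv(out / f"{name}.csv")
    return out / "report.json"


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
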