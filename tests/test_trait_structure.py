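"""Trait screening, dendrogram, FDis/ZFDis against geometric oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import phyloassembly as pa
from phyloassembly.data_model import DistanceMatrix
from phyloassembly.null_models import randomize_1s
from phyloassembly.trait_structure import (allometric_slope, build_dendrogram,
                                           fdis, fdis_coords, screen_traits,
                                           trait_distance, zfdis)

from conftest import make_stems


class TestAllometricSlope:
    def test_two_points_exact(self):
        df = pd.DataFrame({"species": ["a", "a"], "dbh": [10.0, 20.0],
                           "H": [5.0, 10.0]})
        assert allometric_slope(df, "H")["a"] == pytest.approx(0.5)

    def test_constant_dbh_gives_missing(self):
        df = pd.DataFrame({"species": ["a", "a"], "dbh": [10.0, 10.0],
                           "H": [5.0, 9.0]})
        assert np.isnan(allometric_slope(df, "H")["a"])

    def test_recovers_known_slope_from_noisy_data(self):
        rng = np.random.default_rng(6)
        dbh = rng.uniform(10, 60, 200)
        h = 2.0 + 0.4 * dbh + rng.normal(0, 0.5, 200)
        df = pd.DataFrame({"species": "a", "dbh": dbh, "CW": h})
        slope = allometric_slope(df, "CW")["a"]
        assert slope == pytest.approx(0.4, abs=0.02)


class TestScreenTraits:
    def test_correlated_pair_drops_second(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        df = pd.DataFrame({"t1": x, "t2": 0.95 * x + 0.05 * rng.normal(size=200),
                           "t3": rng.normal(size=200)})
        rep = screen_traits(df)
        assert rep.selected == ["t1", "t3"]
        assert rep.dropped == {"t2": "t1"}

    def test_all_weakly_correlated_kept(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        rep = screen_traits(df)
        assert rep.selected == list("abcd")

    def test_reproduces_fieldlike_selection(self):
        # trait table with an allometric trio (r > 0.63) and a leaf-chemistry
        # trio (r > 0.80); priority scan should retain exactly one per block
        rng = np.random.default_rng(2)
        n = 400
        size = rng.normal(size=n)
        chem = rng.normal(size=n)
        df = pd.DataFrame({
            "WD": rng.normal(size=n),
            "LA": rng.normal(size=n),
            "SLA": rng.normal(size=n),
            "LVD": rng.normal(size=n),
            "dbh_H_slope": rng.normal(size=n),
            "C": chem + 0.3 * rng.normal(size=n),
            "DBH": size + 0.5 * rng.normal(size=n),
            "H": size + 0.5 * rng.normal(size=n),
            "CW": size + 0.5 * rng.normal(size=n),
            "N": chem + 0.3 * rng.normal(size=n),
            "P": chem + 0.3 * rng.normal(size=n),
        })
        priority = ["WD", "LA", "SLA", "LVD", "dbh_H_slope", "C",
                    "DBH", "H", "CW", "N", "P"]
        rep = screen_traits(df, priority=priority)
        assert rep.selected[:6] == ["WD", "LA", "SLA", "LVD", "dbh_H_slope", "C"]
        assert {"N", "P"}.isdisjoint(rep.selected)


class TestTraitDistance:
    def test_identical_rows_zero(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}, index=["x", "y"])
        assert trait_distance(df).get("x", "y") == 0.0

    def test_log10_one_decade_is_one(self):
        df = pd.DataFrame({"a": [10.0, 100.0]}, index=["x", "y"])
        assert trait_distance(df).get("x", "y") == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(1, 50, size=(5, 3)),
                          index=list("abcde"), columns=["t1", "t2", "t3"])
        dm = trait_distance(df)
        direct = squareform(pdist(np.log10(df.to_numpy())))
        assert np.allclose(dm.values, direct, atol=1e-12)

    def test_nonpositive_under_log_names_culprit(self):
        df = pd.DataFrame({"t": [1.0, -2.0]}, index=["ok", "bad"])
        with pytest.raises(ValueError, match="bad"):
            trait_distance(df)

    def test_missing_species_excluded_with_report(self):
        df = pd.DataFrame({"t": [1.0, np.nan, 3.0]}, index=["a", "b", "c"])
        dm = trait_distance(df)
        assert dm.labels == ["a", "c"]
        assert dm.excluded_species == ["b"]


class TestDendrogram:
    def test_merge_order_and_heights(self):
        d = DistanceMatrix(list("ABC"),
                           [[0, 1, 10], [1, 0, 10], [10, 10, 0]])
        dend = build_dendrogram(d)
        heights = dend.linkage[:, 2]
        assert heights[0] == pytest.approx(1.0)
        assert heights[1] == pytest.approx(10.0)

    def test_cophenetic_matches_merge_reconstruction(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 3))
        d = DistanceMatrix(list("abcdefgh"), squareform(pdist(pts)))
        dend = build_dendrogram(d)
        coph = dend.cophenetic_matrix()
        # oracle: replay the linkage merges, recording the height at which
        # each pair first shares a cluster
        n = 8
        members = {i: {i} for i in range(n)}
        expect = np.zeros((n, n))
        for k, (a, b, h, _) in enumerate(dend.linkage):
            ma, mb = members.pop(int(a)), members.pop(int(b))
            for i in ma:
                for j in mb:
                    expect[i, j] = expect[j, i] = h
            members[n + k] = ma | mb
        assert np.allclose(coph.values, expect, atol=1e-12)

    def test_complete_linkage_dominates_input(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 2))
        d = DistanceMatrix([str(i) for i in range(10)], squareform(pdist(pts)))
        coph = build_dendrogram(d).cophenetic_matrix()
        assert np.all(coph.values >= d.values - 1e-12)

    def test_to_phylogeny_preserves_cophenetic(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 2))
        d = DistanceMatrix(list("abcdef"), squareform(pdist(pts)))
        dend = build_dendrogram(d)
        tree = dend.to_phylogeny()
        coph_tree = tree.cophenetic_matrix().submatrix(d.labels)
        assert np.allclose(coph_tree.values, dend.cophenetic_matrix().values,
                           atol=1e-9)


class TestFDis:
    def test_coincident_points_zero(self):
        d = np.zeros((3, 3))
        assert fdis(d, [1.0, 2.0, 3.0]) == 0.0

    def test_two_species_half_distance(self):
        d = np.array([[0.0, 4.0], [4.0, 0.0]])
        assert fdis(d, [1.0, 1.0]) == pytest.approx(2.0)

    def test_single_species_zero_by_convention(self):
        d = np.array([[0.0, 4.0], [4.0, 0.0]])
        assert fdis(d, [1.0, 0.0]) == 0.0

    def test_pcoa_equals_geometry_on_euclidean_input(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            pts = rng.normal(size=(7, 3))
            w = rng.uniform(0.1, 5.0, size=7)
            d = squareform(pdist(pts))
            assert fdis(d, w) == pytest.approx(fdis_coords(pts, w), abs=1e-9)

    def test_invariances(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        w = rng.uniform(0.5, 2.0, 6)
        assert fdis(d, w) == pytest.approx(fdis(d, 7 * w), rel=1e-12)
        assert fdis(3 * d, w) == pytest.approx(3 * fdis(d, w), rel=1e-9)

    def test_noneuclidean_uses_negative_axes(self):
        # a metric that violates Euclidean embeddability: PCoA has negative
        # eigenvalues, and the corrected z must stay real and nonnegative
        d = np.array([[0, 3, 1, 1],
                      [3, 0, 1, 1],
                      [1, 1, 0, 3],
                      [1, 1, 3, 0]], float)
        v = fdis(d, np.array([1.0, 1.0, 2.0, 1.0]))
        assert np.isfinite(v) and v > 0


class TestZFDis:
    def test_enumerable_two_plot_toy(self):
        # 4 stems, 2 plots: compare to exhaustive enumeration of C(4,2)
        stems = make_stems([("s1", "P1", 1, "A", 10), ("s2", "P1", 2, "B", 10),
                            ("s3", "P2", 1, "C", 10), ("s4", "P2", 2, "D", 10)])
        vals = {"A": 0.0, "B": 1.0, "C": 4.0, "D": 9.0}
        sp = ["A", "B", "C", "D"]
        coords = np.array([[vals[s]] for s in sp])
        d = DistanceMatrix(sp, squareform(pdist(coords)))
        null_fdis = []
        for pair in itertools.combinations(range(4), 2):
            w = np.zeros(4)
            w[list(pair)] = 1.0
            null_fdis.append(fdis(d.values, w))
        exp_mean, exp_sd = np.mean(null_fdis), np.std(null_fdis)
        obs = fdis(d.values, np.array([1.0, 1.0, 0, 0]))
        ens = randomize_1s(stems, n_reps=4000, seed=11, scale="plot")
        out = zfdis(ens.observed, d, ens, "abundance").set_index("unit")
        assert out.loc["P1", "null_mean"] == pytest.approx(exp_mean, rel=0.02)
        expected_index = -(obs - exp_mean) / exp_sd
        assert out.loc["P1", "zfdis_clustering"] == pytest.approx(expected_index,
                                                                  abs=0.12)

    def test_zero_when_observed_equals_null_mean(self):
        from phyloassembly.phylo_structure import dispersion_frame
        f = dispersion_frame(["u"], "FDis", "abundance", "plot",
                             [1.0], [1.0], [0.3])
        assert f["ses"].iloc[0] == 0.0

    def test_strong_filtering_clusters_most_units(self):
        # narrow trait samples per plot: clustering index > 0 nearly always
        from phyloassembly.synthetic_data import ScenarioConfig, generate
        hits = tot = 0
        for seed in range(5):
            cfg = ScenarioConfig(process="environmental_filtering",
                                 trait_mode="conserved", filtering_width=0.25,
                                 n_species_pool=60, n_plots=8,
                                 stems_per_plot=60, seed=seed)
            ds = generate(cfg)
            comm = pa.aggregate_stems(ds.stems, "plot")
            ens = randomize_1s(ds.stems, n_reps=99, seed=100 + seed, scale="plot")
            tv = ds.traits["T1"].reindex(comm.species).to_numpy()[:, None]
            out = zfdis(comm, None, ens, "abundance", coords=tv)
            hits += int((out["zfdis_clustering"] > 0).sum())
            tot += len(out)
        assert hits / tot >= 0.95

    def test_coords_fast_path_matches_distance_path(self, neutral_dataset):
        comm = pa.aggregate_stems(neutral_dataset.stems, "plot")
        ens = randomize_1s(neutral_dataset.stems, n_reps=49, seed=3, scale="plot")
        tv = neutral_dataset.traits["T1"].reindex(comm.species).to_numpy()
        d = DistanceMatrix(comm.species, squareform(pdist(tv[:, None])))
        a = zfdis(comm, d, ens, "abundance")
        b = zfdis(comm, None, ens, "abundance", coords=tv[:, None])
        assert np.allclose(a["ses"], b["ses"], atol=1e-9)
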