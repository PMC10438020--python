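"""Contiguity weights, global/local autocorrelation, classification,
ADCM and constrained regionalization."""

import itertools

import numpy as np
import pytest
from shapely.geometry import box

import caedec as cd
from caedec.spatial import (
    ClassificationError,
    GeometryError,
    SpatialLattice,
    classify_choropleth,
    CLASSIFIERS,
)
from conftest import random_lattice


# ---------------------------------------------------------------------------
# double-loop oracles


def moran_oracle(y, w):
    z = y - y.mean()
    n = len(y)
    num = sum(z[i] * z[j] for i, nb in enumerate(w.neighbors) for j in nb)
    return n / w.s0 * num / np.sum(z**2)


def geary_oracle(y, w):
    z = y - y.mean()
    num = sum((y[i] - y[j]) ** 2 for i, nb in enumerate(w.neighbors) for j in nb)
    return (len(y) - 1) * num / (2 * w.s0 * np.sum(z**2))


def g_oracle(y, w):
    num = sum(y[i] * y[j] for i, nb in enumerate(w.neighbors) for j in nb)
    den = sum(y[i] * y[j] for i in range(len(y)) for j in range(len(y)) if i != j)
    return num / den


class TestContiguityWeights:
    def test_2x2_rook(self, grid_2x2):
        w = cd.contiguity_weights(grid_2x2, "rook")
        assert all(len(nb) == 2 for nb in w.neighbors)
        assert w.s0 == 8

    def test_2x2_queen_includes_diagonals(self, grid_2x2):
        w = cd.contiguity_weights(grid_2x2, "queen")
        assert all(len(nb) == 3 for nb in w.neighbors)
        assert w.s0 == 12

    def test_disjoint_squares_flagged_islands(self):
        lat = SpatialLattice(("a", "b"), (box(0, 0, 1, 1), box(5, 5, 6, 6)),
                             np.array([1.0, 2.0]))
        with pytest.warns(UserWarning, match="island"):
            w = cd.contiguity_weights(lat)
        assert w.islands == (0, 1)

    def test_symmetry_and_sorted_lists(self):
        lat = random_lattice(4, seed=0)
        w = cd.contiguity_weights(lat)
        for i, nb in enumerate(w.neighbors):
            assert list(nb) == sorted(nb)
            for j in nb:
                assert i in w.neighbors[j]
                assert i != j

    def test_invalid_geometry_named(self, grid_2x2):
        from shapely.geometry import Polygon

        bad = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])  # self-intersecting bowtie
        lat = SpatialLattice(("u",) + grid_2x2.ids[1:], (bad,) + grid_2x2.geometry[1:],
                             grid_2x2.values)
        with pytest.raises(GeometryError, match="'u'"):
            cd.contiguity_weights(lat)


class TestGlobalStatistics:
    def test_checkerboard_moran_is_minus_one(self, grid_2x2):
        w = cd.contiguity_weights(grid_2x2, "rook")
        assert cd.morans_I(grid_2x2.values, w, 99, 0).statistic == pytest.approx(-1.0)

    def test_checkerboard_geary(self, grid_2x2):
        w = cd.contiguity_weights(grid_2x2, "rook")
        assert cd.gearys_C(grid_2x2.values, w, 99, 0).statistic == pytest.approx(1.5)

    def test_constant_attribute_rejected(self, grid_2x2):
        w = cd.contiguity_weights(grid_2x2, "rook")
        for fn in (cd.morans_I, cd.gearys_C, cd.getis_ord_G):
            with pytest.raises(ValueError):
                fn(np.ones(4), w, 9, 0)

    def test_getis_ord_uniform_values(self, grid_2x2):
        w = cd.contiguity_weights(grid_2x2, "rook")
        y = np.ones(4) + np.arange(4) * 1e-12  # non-constant, effectively uniform
        assert cd.getis_ord_G(y, w, 9, 0).statistic == pytest.approx(8 / 12, abs=1e-9)

    def test_getis_ord_negative_rejected(self, grid_2x2):
        w = cd.contiguity_weights(grid_2x2, "rook")
        with pytest.raises(ValueError, match="non-negative"):
            cd.getis_ord_G(np.array([1.0, -1, 1, 1]), w, 9, 0)

    def test_g_prefers_adjacent_concentration(self, grid_2x2):
        w = cd.contiguity_weights(grid_2x2, "rook")
        adjacent = np.array([5.0, 5.0, 0.1, 0.1])   # cells (0,0),(0,1) share an edge
        opposite = np.array([5.0, 0.1, 0.1, 5.0])   # diagonal cells, no rook edge
        ga = cd.getis_ord_G(adjacent, w, 9, 0).statistic
        go = cd.getis_ord_G(opposite, w, 9, 0).statistic
        assert ga > go

    @pytest.mark.parametrize("seed", range(4))
    def test_all_globals_match_double_loop_oracles(self, seed):
        lat = random_lattice(np.random.default_rng(seed).integers(3, 6), seed=seed)
        y = np.abs(lat.values) + 0.1  # keep G's domain
        w = cd.contiguity_weights(lat, "queen")
        assert cd.morans_I(y, w, 9, 0).statistic == pytest.approx(moran_oracle(y, w), abs=1e-10)
        assert cd.gearys_C(y, w, 9, 0).statistic == pytest.approx(geary_oracle(y, w), abs=1e-10)
        assert cd.getis_ord_G(y, w, 9, 0).statistic == pytest.approx(g_oracle(y, w), abs=1e-10)

    def test_permutation_null_expectations(self):
        lat = random_lattice(5, seed=2)
        w = cd.contiguity_weights(lat, "rook")
        res_i = cd.morans_I(lat.values, w, 499, 3)
        assert res_i.perm_mean == pytest.approx(-1 / (lat.n - 1), abs=0.02)
        res_c = cd.gearys_C(lat.values, w, 499, 3)
        assert res_c.perm_mean == pytest.approx(1.0, abs=0.05)


class TestLocalMorans:
    def test_checkerboard_local_values_and_quadrants(self, grid_2x2):
        w = cd.contiguity_weights(grid_2x2, "rook")
        lisa = cd.local_morans(grid_2x2.values, w, 99, 0)
        assert np.allclose(lisa.local_i, -1.0)
        for v, raw in zip(grid_2x2.values, lisa.raw_quadrants):
            assert raw == ("HL" if v > 0 else "LH")

    def test_block_interior_classified_high_high(self):
        lat = cd.simulate_lattice(
            cd.LatticeSpec(5, 5, "block", n_blocks=2, contrast=10.0, noise_sd=0.2, seed=4)
        )
        w = cd.contiguity_weights(lat, "queen")
        lisa = cd.local_morans(lat.values, w, 999, 1)
        # interior column of the high band: rows 1-3, col 4 has neighbours col 3 also high
        high_units = [i for i in range(lat.n) if lat.values[i] > 5]
        hh = [lisa.raw_quadrants[i] for i in high_units]
        assert hh.count("HH") == len(hh)

    def test_ns_exactly_when_p_above_threshold(self):
        lat = random_lattice(5, seed=9)
        w = cd.contiguity_weights(lat, "queen")
        lisa = cd.local_morans(lat.values, w, 199, 0)
        for p, q, raw in zip(lisa.p_values, lisa.quadrants, lisa.raw_quadrants):
            if p > lisa.significance:
                assert q == "ns"
            else:
                assert q == raw

    def test_sum_of_locals_consistent_with_global(self):
        lat = random_lattice(5, seed=6)
        w = cd.contiguity_weights(lat, "queen")
        lisa = cd.local_morans(lat.values, w, 9, 0)
        global_rowstd = cd.morans_I(lat.values, w, 9, 0, row_standardized=True)
        assert lisa.local_i.sum() / lat.n == pytest.approx(global_rowstd.statistic, abs=1e-10)


class TestChoropleth:
    def test_fisher_jenks_bimodal(self):
        y = np.array([1.0, 2, 3, 100, 101, 102])
        c = classify_choropleth(y, 2, "fisher_jenks")
        assert np.array_equal(c.labels, [0, 0, 0, 1, 1, 1])

    def test_single_class(self):
        y = np.arange(5.0)
        c = classify_choropleth(y, 1, "equal_interval")
        assert c.k == 1 and set(c.labels) == {0}

    def test_equal_interval_break_at_midpoint(self):
        y = np.array([0.0, 2.0, 5.0, 7.0, 10.0])
        c = classify_choropleth(y, 2, "equal_interval")
        assert c.bins[0] == pytest.approx(5.0)

    def test_too_many_classes_rejected(self):
        with pytest.raises(ClassificationError):
            classify_choropleth(np.array([1.0, 1.0, 2.0]), 3, "quantiles")

    @pytest.mark.parametrize("method", CLASSIFIERS)
    def test_every_method_partitions_all_units(self, method):
        y = np.sort(np.random.default_rng(0).lognormal(0, 1, 40))
        c = classify_choropleth(y, 4, method)
        assert len(c.labels) == 40
        assert set(c.labels) == set(range(c.k))
        # class membership respects the value ordering
        assert (np.diff(c.labels[np.argsort(y)]) >= 0).all()

    @pytest.mark.parametrize("n,k", [(6, 2), (8, 3), (10, 4), (12, 4), (12, 2)])
    def test_fisher_jenks_is_exhaustive_optimum(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        for _ in range(5):
            y = np.sort(rng.normal(size=n))

            def ssq(part):
                return sum(float(np.sum((p - p.mean()) ** 2)) for p in part)

            best = min(
                ssq([y[a:b] for a, b in zip((0,) + cuts, cuts + (n,))])
                for cuts in itertools.combinations(range(1, n), k - 1)
            )
            c = classify_choropleth(y, k, "fisher_jenks")
            got = ssq([y[c.labels == j] for j in range(k)])
            assert got == pytest.approx(best, abs=1e-10)


class TestAdcm:
    def test_two_block_partition(self):
        y = np.array([1.0, 2, 3, 100, 101, 102])
        c = classify_choropleth(y, 2, "fisher_jenks")
        assert cd.adcm(y, c) == pytest.approx(4.0)

    def test_singleton_classes_zero(self):
        y = np.array([1.0, 5.0, 9.0])
        c = classify_choropleth(y, 3, "quantiles")
        assert cd.adcm(y, c) == pytest.approx(0.0)

    def test_single_class_direct(self):
        y = np.array([0.0, 10.0])
        c = classify_choropleth(y, 1, "equal_interval")
        assert cd.adcm(y, c) == pytest.approx(10.0)


class TestSelectClassifier:
    def test_fisher_jenks_beats_equal_intervals_on_bimodal(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(50, 1, 10)])
        ranking = cd.select_classifier(y, 2, ["fisher_jenks", "equal_interval"])
        fj = float(ranking.loc[ranking.method == "fisher_jenks", "adcm"].iloc[0])
        ei = float(ranking.loc[ranking.method == "equal_interval", "adcm"].iloc[0])
        assert fj <= ei

    def test_ranking_is_permutation_of_methods(self):
        y = np.random.default_rng(1).lognormal(0, 1, 30)
        ranking = cd.select_classifier(y, 3)
        assert sorted(ranking.method) == sorted(CLASSIFIERS)
        assert (ranking.adcm.diff().dropna() >= 0).all()

    def test_identical_classifications_identical_adcm(self):
        y = np.array([1.0, 2, 3, 100, 101, 102])
        a = cd.adcm(y, classify_choropleth(y, 2, "fisher_jenks"))
        b = cd.adcm(y, classify_choropleth(y, 2, "maximum_breaks"))
        assert a == pytest.approx(b)


class TestRegionalize:
    def test_two_block_recovery(self, grid_4x4_blocks):
        w = cd.contiguity_weights(grid_4x4_blocks, "rook")
        labels = cd.regionalize(grid_4x4_blocks, w, 2)
        left = labels[grid_4x4_blocks.values < 5]
        right = labels[grid_4x4_blocks.values >= 5]
        assert len(set(left)) == 1 and len(set(right)) == 1
        assert set(left) != set(right)

    def test_single_region(self, grid_4x4_blocks):
        w = cd.contiguity_weights(grid_4x4_blocks, "rook")
        assert set(cd.regionalize(grid_4x4_blocks, w, 1)) == {0}

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_regions_always_connected(self, k):
        lat = random_lattice(5, seed=k)
        w = cd.contiguity_weights(lat, "rook")
        labels = cd.regionalize(lat, w, k)
        g = w.to_graph()
        import networkx as nx

        for region in set(labels):
            sub = g.subgraph(np.where(labels == region)[0])
            assert nx.is_connected(sub)

    def test_more_regions_than_units_rejected(self, grid_2x2):
        w = cd.contiguity_weights(grid_2x2, "rook")
        with pytest.raises(ValueError):
            cd.regionalize(grid_2x2, w, 5)


class TestSelectNRegions:
    def test_silhouette_maximized_at_true_k(self, grid_4x4_blocks):
        w = cd.contiguity_weights(grid_4x4_blocks, "rook")
        diag = cd.select_n_regions(grid_4x4_blocks, w, range(2, 6))
        assert int(diag.loc[diag.silhouette.idxmax(), "k"]) == 2

    def test_within_variance_nonincreasing(self, grid_4x4_blocks):
        w = cd.contiguity_weights(grid_4x4_blocks, "rook")
        diag = cd.select_n_regions(grid_4x4_blocks, w, range(2, 7))
        assert (diag.within_ss.diff().dropna() <= 1e-9).all()

    def test_one_row_per_candidate_k(self, grid_4x4_blocks):
        w = cd.contiguity_weights(grid_4x4_blocks, "rook")
        assert len(cd.select_n_regions(grid_4x4_blocks, w, [2, 3, 4])) == 3


class TestRegionCoherence:
    def test_circle_compactness_near_one(self):
        from shapely.geometry import Point

        circle = Point(0, 0).buffer(1.0, quad_segs=256)
        lat = SpatialLattice(("c", "d"), (circle, box(5, 5, 6, 6)),
                             np.array([1.0, 2.0]))
        df, _ = cd.region_coherence(lat, np.array([0, 1]))
        assert df.loc[df.region == 0, "compactness"].iloc[0] == pytest.approx(1.0, abs=1e-3)

    def test_thin_strip_compactness_small(self):
        lat = SpatialLattice(("s", "q"), (box(0, 0, 100, 0.5), box(200, 0, 201, 1)),
                             np.array([1.0, 2.0]))
        df, _ = cd.region_coherence(lat, np.array([0, 1]))
        assert df.loc[df.region == 0, "compactness"].iloc[0] < 0.05

    def test_truth_labels_high_feature_fit(self, grid_4x4_blocks):
        truth = (grid_4x4_blocks.values >= 5).astype(int)
        _, fit = cd.region_coherence(grid_4x4_blocks, truth)
        assert fit > 0.9


class TestGeoJsonRoundtrip:
    def test_lattice_io(self, tmp_path, grid_2x2):
        p = tmp_path / "lat.geojson"
        grid_2x2.to_geojson(p, extra={"quadrant": ["HL", "LH", "LH", "HL"]})
        back = SpatialLattice.from_geojson(p, "value")
        assert back.ids == grid_2x2.ids
        assert np.allclose(back.values, grid_2x2.values)
        w1 = cd.contiguity_weights(grid_2x2, "rook")
        w2 = cd.contiguity_weights(back, "rook")
        assert w1.neighbors == w2.neighbors
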