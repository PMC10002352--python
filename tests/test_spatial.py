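"""Spatial weights construction and Moran statistics against brute-force oracles."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from lvcoupling import spatial
from lvcoupling.errors import (
    CodingError,
    ConstantValuesError,
    EmptyWeightsError,
    GeometryError,
    IsolateError,
    LabelError,
)
from lvcoupling.spatial import (
    SpatialWeights,
    build_weights,
    classify_clusters,
    encode_ranks,
    expected_moran,
    global_moran,
    local_moran,
    permutation_test_global,
    queen_contiguity,
    region_block_weights,
)


def brute_force_global(values, w):
    """Independent double-sum implementation of global Moran's I."""
    x = np.asarray(values, float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w.matrix[i, j] * z[i] * z[j]
            s0 += w.matrix[i, j]
    return n / s0 * num / sum(zi * zi for zi in z)


def brute_force_local(values, w):
    """Independent per-site double-sum of the LISA decomposition."""
    x = np.asarray(values, float)
    n = len(x)
    z = x - x.mean()
    m2 = sum(zi * zi for zi in z) / n
    out = []
    for i in range(n):
        lag = sum(w.matrix[i, j] * z[j] for j in range(n))
        out.append(z[i] / m2 * lag)
    return np.array(out)


def random_weights(rng, n, scheme="row_standardized"):
    """Random connected-ish symmetric binary graph as SpatialWeights."""
    while True:
        mat = rng.random((n, n)) < 0.45
        mat = np.triu(mat, 1)
        mat = (mat + mat.T).astype(float)
        if mat.sum(axis=1).min() > 0:
            break
    labels = tuple(f"n{i}" for i in range(n))
    return SpatialWeights(labels, spatial._apply_scheme(mat, scheme), scheme)


def rook_lattice(k, m, scheme="binary"):
    labels = [f"c{r}_{c}" for r in range(k) for c in range(m)]
    idx = {lbl: i for i, lbl in enumerate(labels)}
    mat = np.zeros((k * m, k * m))
    for r in range(k):
        for c in range(m):
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < k and cc < m:
                    i, j = idx[f"c{r}_{c}"], idx[f"c{rr}_{cc}"]
                    mat[i, j] = mat[j, i] = 1.0
    return SpatialWeights(tuple(labels), spatial._apply_scheme(mat, scheme),
                          scheme)


def checkerboard(k, m):
    return np.array([1.0 if (r + c) % 2 == 0 else -1.0
                     for r in range(k) for c in range(m)])


class TestQueenContiguity:
    def test_2x2_grid_fully_connected(self):
        polys = {f"sq{i}": box(x, y, x + 1, y + 1)
                 for i, (x, y) in enumerate([(0, 0), (1, 0), (0, 1), (1, 1)])}
        edges = queen_contiguity(polys)
        assert len(edges) == 6  # diagonal pairs touch at the shared corner

    def test_disjoint_squares(self):
        polys = {"a": box(0, 0, 1, 1), "b": box(5, 5, 6, 6)}
        assert queen_contiguity(polys) == set()

    def test_no_self_pairs(self):
        polys = {"a": box(0, 0, 1, 1), "b": box(1, 0, 2, 1)}
        assert all(a != b for a, b in queen_contiguity(polys))

    def test_invalid_geometry_named(self):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        with pytest.raises(GeometryError, match="bad"):
            queen_contiguity({"bad": bowtie, "ok": box(5, 5, 6, 6)})

    def test_geojson_round_trip(self, tmp_path):
        import json

        from shapely.geometry import mapping

        from lvcoupling.spatial import load_geojson_polygons

        doc = {"type": "FeatureCollection", "features": [
            {"type": "Feature", "properties": {"name": lbl},
             "geometry": mapping(box(x, 0, x + 1, 1))}
            for lbl, x in (("west", 0), ("east", 1), ("far", 9))]}
        path = tmp_path / "units.geojson"
        path.write_text(json.dumps(doc))
        polys = load_geojson_polygons(path, "name")
        assert queen_contiguity(polys) == {("east", "west")}


class TestBuildWeights:
    def test_matrix_matches_edges(self):
        w = build_weights([("a", "b"), ("b", "c")], ["a", "b", "c"],
                          scheme="binary")
        expect = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        assert np.array_equal(w.matrix, expect)

    def test_extra_links_add_symmetric_pair(self):
        w = build_weights([("a", "b")], ["a", "b", "island"],
                          extra_links=[("island", "a")], scheme="binary")
        assert w.matrix[2, 0] == 1.0 and w.matrix[0, 2] == 1.0

    def test_row_standardization(self):
        w = build_weights([("a", "b"), ("b", "c")], ["a", "b", "c"],
                          scheme="row_standardized")
        assert np.allclose(w.matrix[1], [0.5, 0, 0.5])
        assert np.allclose(w.matrix.sum(axis=1), 1.0)

    def test_unknown_label_rejected(self):
        with pytest.raises(LabelError, match="ghost"):
            build_weights([("a", "ghost")], ["a", "b"])

    def test_isolate_strict_mode(self):
        with pytest.raises(IsolateError):
            build_weights([("a", "b")], ["a", "b", "island"], strict=True)

    def test_zero_diagonal_invariant(self):
        w = build_weights([("a", "b")], ["a", "b"], scheme="binary")
        assert np.all(np.diag(w.matrix) == 0)


class TestRegionBlockWeights:
    def test_same_region_pairs_only(self):
        w = region_block_weights({"x": "A", "y": "A", "z": "B"},
                                 ["x", "y", "z"], scheme="binary")
        expect = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], float)
        assert np.array_equal(w.matrix, expect)

    def test_single_region_complete_graph(self):
        w = region_block_weights({c: "A" for c in "abcd"}, list("abcd"),
                                 scheme="binary")
        assert w.matrix.sum() == 12  # 4*3 directed pairs

    def test_missing_region_rejected(self):
        with pytest.raises(LabelError, match="z"):
            region_block_weights({"x": "A", "y": "A"}, ["x", "y", "z"])

    def test_union_with_contiguity_edges(self):
        w = region_block_weights({"x": "A", "y": "A", "z": "B"},
                                 ["x", "y", "z"], scheme="binary",
                                 union_edges=[("y", "z")])
        assert w.matrix[1, 2] == 1.0 and w.matrix[2, 1] == 1.0


class TestEncodeRanks:
    def test_default_coding(self):
        assert encode_ranks(["S", "E", "B"]).tolist() == [6.0, 1.0, 4.0]

    def test_custom_coding(self):
        assert encode_ranks(["S", "E"], {"S": 10, "E": 0}).tolist() == [10.0, 0.0]

    def test_unknown_letter(self):
        with pytest.raises(CodingError):
            encode_ranks(["S", "Z"])

    def test_affine_codings_give_identical_moran(self, rng):
        w = random_weights(rng, 8)
        letters = rng.choice(list("SABCDE"), size=8).tolist()
        base = global_moran(encode_ranks(letters), w)
        shifted = {k: 3 * v + 7 for k, v in spatial.DEFAULT_RANK_CODING.items()}
        assert global_moran(encode_ranks(letters, shifted), w) == pytest.approx(
            base, abs=1e-12)


class TestGlobalMoran:
    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 11))
            scheme = "binary" if rng.random() < 0.5 else "row_standardized"
            w = random_weights(rng, n, scheme)
            values = rng.normal(size=n)
            assert global_moran(values, w) == pytest.approx(
                brute_force_global(values, w), rel=1e-12)

    @pytest.mark.parametrize("scheme", ["binary", "row_standardized"])
    def test_2x2_checkerboard_is_minus_one(self, scheme):
        w = rook_lattice(2, 2, scheme)
        assert global_moran([1, -1, -1, 1], w) == pytest.approx(-1.0)

    @pytest.mark.parametrize("k,m", [(2, 4), (4, 4), (3, 5)])
    def test_checkerboard_bound_on_lattices(self, k, m):
        w = rook_lattice(k, m, "row_standardized")
        assert global_moran(checkerboard(k, m), w) == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        w = random_weights(rng, 7)
        x = rng.normal(size=7)
        assert global_moran(3 * x + 7, w) == pytest.approx(
            global_moran(x, w), abs=1e-12)

    def test_null_expectation(self):
        assert expected_moran(31) == pytest.approx(-1 / 30)

    def test_constant_values_rejected(self, rng):
        w = random_weights(rng, 5)
        with pytest.raises(ConstantValuesError):
            global_moran([2.0] * 5, w)

    def test_empty_weights_rejected(self):
        w = SpatialWeights(("a", "b"), np.zeros((2, 2)), "binary")
        with pytest.raises(EmptyWeightsError):
            global_moran([1.0, 2.0], w)


class TestPermutationTestGlobal:
    def test_reproducible_given_seed(self, rng):
        w = random_weights(rng, 9)
        x = rng.normal(size=9)
        r1 = permutation_test_global(x, w, n_perm=199, seed=11)
        r2 = permutation_test_global(x, w, n_perm=199, seed=11)
        assert r1 == r2

    def test_different_seeds_similar_p(self, rng):
        w = rook_lattice(3, 3, "row_standardized")
        x = rng.normal(size=9)
        p1 = permutation_test_global(x, w, n_perm=999, seed=1).pseudo_p
        p2 = permutation_test_global(x, w, n_perm=999, seed=2).pseudo_p
        assert abs(p1 - p2) < 0.1

    def test_plus_one_floor(self, rng):
        w = rook_lattice(2, 2, "binary")
        r = permutation_test_global([1, -1, -1, 1], w, n_perm=999, seed=0)
        assert r.pseudo_p >= 1 / 1000
        assert r.pseudo_p <= 1.0

    def test_strong_pattern_is_significant(self):
        w = rook_lattice(4, 4, "row_standardized")
        r = permutation_test_global(checkerboard(4, 4), w, n_perm=999, seed=5)
        assert r.observed_i == pytest.approx(-1.0)
        assert r.significant(0.1)


class TestLocalMoran:
    def test_matches_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 11))
            w = random_weights(rng, n, "row_standardized")
            x = rng.normal(size=n)
            res = local_moran(x, w, n_perm=9, seed=0)
            assert np.allclose(res.local_i, brute_force_local(x, w),
                               rtol=1e-12)

    def test_aggregation_identity_row_standardized(self, rng):
        for _ in range(10):
            w = random_weights(rng, 8, "row_standardized")
            x = rng.normal(size=8)
            res = local_moran(x, w, n_perm=9, seed=0)
            assert res.local_i.sum() == pytest.approx(
                8 * global_moran(x, w), rel=1e-10)

    def test_mean_entity_has_zero_local_i(self):
        w = rook_lattice(1, 3, "row_standardized")
        res = local_moran([2.0, 0.0, -2.0], w, n_perm=9, seed=0)
        assert res.local_i[1] == pytest.approx(0.0)

    def test_isolate_gets_zero_and_p_one(self):
        mat = np.zeros((3, 3))
        mat[0, 1] = mat[1, 0] = 1.0
        w = SpatialWeights(("a", "b", "c"), mat, "binary")
        res = local_moran([1.0, 2.0, 3.0], w, n_perm=99, seed=0)
        assert res.local_i[2] == 0.0
        assert res.pseudo_p[2] == 1.0

    def test_reproducible(self, rng):
        w = random_weights(rng, 7)
        x = rng.normal(size=7)
        a = local_moran(x, w, n_perm=99, seed=3)
        b = local_moran(x, w, n_perm=99, seed=3)
        assert np.array_equal(a.pseudo_p, b.pseudo_p)


class TestClassifyClusters:
    def test_quadrant_labels(self):
        w = rook_lattice(4, 4, "row_standardized")
        x = checkerboard(4, 4)
        lisa = local_moran(x, w, n_perm=999, seed=0)
        cats = classify_clusters(x, w, lisa, alpha=0.1)
        for i, c in enumerate(cats):
            if c == "not_significant":
                continue
            assert c == ("high_low" if x[i] > 0 else "low_high")

    def test_insignificant_everywhere(self, rng):
        w = random_weights(rng, 6)
        x = rng.normal(size=6)
        lisa = local_moran(x, w, n_perm=9, seed=0)
        forced = spatial.LisaResult(lisa.labels, lisa.local_i,
                                    np.full(6, 0.5), 0, 9)
        assert set(classify_clusters(x, w, forced, 0.1)) == {"not_significant"}

    def test_high_high_detected(self):
        # two tight clusters of high and low values on a path graph
        mat = np.zeros((6, 6))
        for i in range(5):
            mat[i, i + 1] = mat[i + 1, i] = 1.0
        w = SpatialWeights(tuple("abcdef"),
                           spatial._apply_scheme(mat, "row_standardized"),
                           "row_standardized")
        x = np.array([5.0, 5.2, 4.8, 1.0, 1.2, 0.8])
        lisa = local_moran(x, w, n_perm=999, seed=1)
        cats = classify_clusters(x, w, lisa, alpha=0.2)
        sig = [c for c in cats if c != "not_significant"]
        assert sig and set(sig) <= {"high_high", "low_low"}
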