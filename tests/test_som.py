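import numpy as np
import pytest

from cdsom import (
    CDSpectrum,
    ReferenceEntry,
    ReferenceSet,
    SOMConfig,
    StructureFractions5,
    WavelengthGrid,
    assign_node_structures,
    find_bmus,
    load_map,
    map_layout,
    predict,
    save_map,
    train_som,
)
from cdsom.som import TrainedMap


def _tiny_refset(grid, structures, seed=0):
    rng = np.random.default_rng(seed)
    entries = []
    for i, s5 in enumerate(structures, start=1):
        entries.append(
            ReferenceEntry(
                spectrum=CDSpectrum(grid=grid, values=rng.normal(size=len(grid)),
                                    label=f"ref_{i}"),
                structure=StructureFractions5(*s5),
                name=f"ref_{i}",
                index=i,
            )
        )
    return ReferenceSet(entries=tuple(entries), grid=grid)


def _manual_map(grid, weights, structures, occupancy, names, k_bmu=5, rows=None,
                cols=None, neighbour_radius=3.0):
    """Hand-assembled TrainedMap for oracle tests."""
    weights = np.asarray(weights, dtype=float)
    rows = rows or weights.shape[0]
    cols = cols or weights.shape[1]
    cfg = SOMConfig(rows=rows, cols=cols, k_bmu=min(k_bmu, rows * cols),
                    neighbour_radius=neighbour_radius)
    return TrainedMap(
        config=cfg,
        grid=grid,
        node_weights=weights,
        node_structures=np.asarray(structures, dtype=float) if structures is not None else None,
        occupancy=np.asarray(occupancy, dtype=int),
        ref_names=tuple(names),
        ref_beta2=tuple(False for _ in names),
    )


class TestTraining:
    def test_deterministic_given_seed(self, grid):
        rs = _tiny_refset(grid, [(0.5, 0.2, 0.1, 0.1, 0.1)] * 3)
        cfg = SOMConfig(rows=4, cols=4, epochs=20, seed=11)
        a = train_som(rs, cfg)
        b = train_som(rs, cfg)
        np.testing.assert_array_equal(a.node_weights, b.node_weights)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)
        np.testing.assert_array_equal(a.node_structures, b.node_structures)

    def test_1x1_map_converges_to_refset_mean(self, grid):
        rs = _tiny_refset(grid, [(1, 0, 0, 0, 0), (0, 1, 0, 0, 0),
                                 (0, 0, 1, 0, 0)])
        cfg = SOMConfig(rows=1, cols=1, k_bmu=1, epochs=500, seed=3,
                        n_structure_neighbours=3, radius_initial=0.5,
                        radius_final=0.1)
        m = train_som(rs, cfg)
        mean = rs.spectra_matrix().mean(axis=0)
        # single node is pulled toward the mean of the set
        assert np.abs(m.node_weights[0, 0] - mean).max() < 0.2
        assert np.all(m.occupancy == 0)

    def test_single_spectrum_attractor(self, grid):
        rs = _tiny_refset(grid, [(0.7, 0.1, 0.1, 0.05, 0.05)])
        cfg = SOMConfig(rows=3, cols=3, k_bmu=1, epochs=300, seed=5,
                        n_structure_neighbours=1, lr_final=1e-3)
        m = train_som(rs, cfg)
        d = np.linalg.norm(
            m.flat_weights() - rs.entries[0].spectrum.values, axis=1
        ).min()
        assert d < 1e-2

    def test_empty_refset_rejected(self, grid):
        with pytest.raises(ValueError):
            ReferenceSet(entries=(), grid=grid)


class TestNodeStructures:
    def test_hosting_node_gets_reference_structure_exactly(self, grid):
        rs = _tiny_refset(grid, [(0.6, 0.2, 0.1, 0.05, 0.05)])
        m = _manual_map(
            grid,
            weights=np.zeros((2, 2, len(grid))),
            structures=None,
            occupancy=[[0, 0]],
            names=["ref_1"],
        )
        m2 = assign_node_structures(m, rs, n_neighbours=1)
        np.testing.assert_allclose(m2.node_structures[0, 0],
                                   rs.entries[0].structure.as_array())

    def test_equidistant_references_average_equally(self, grid):
        rs = _tiny_refset(grid, [(1, 0, 0, 0, 0), (0, 1, 0, 0, 0)])
        m = _manual_map(
            grid,
            weights=np.zeros((1, 3, len(grid))),
            structures=None,
            occupancy=[[0, 0], [0, 2]],
            names=["ref_1", "ref_2"],
            rows=1, cols=3,
        )
        m2 = assign_node_structures(m, rs, n_neighbours=2)
        np.testing.assert_allclose(m2.node_structures[0, 1],
                                   [0.5, 0.5, 0, 0, 0], atol=1e-12)

    def test_inverse_distance_average_matches_brute_force(self, grid):
        structures = [(1, 0, 0, 0, 0), (0, 1, 0, 0, 0), (0, 0, 0.5, 0.3, 0.2)]
        rs = _tiny_refset(grid, structures, seed=4)
        occ = np.array([[0, 0], [1, 1], [0, 1]])
        rng = np.random.default_rng(9)
        W = rng.normal(size=(2, 2, len(grid)))
        m = _manual_map(grid, W, None, occ, ["ref_1", "ref_2", "ref_3"],
                        rows=2, cols=2)
        m2 = assign_node_structures(m, rs, n_neighbours=2)
        S = rs.structures_matrix()
        coords = [(r, c) for r in range(2) for c in range(2)]
        for node, (r, c) in enumerate(coords):
            dmap = np.linalg.norm(occ - np.array([r, c]), axis=1)
            dspec = np.linalg.norm(
                rs.spectra_matrix() - W[r, c], axis=1
            )
            order = sorted(range(3), key=lambda i: (dmap[i], dspec[i]))[:2]
            d = dmap[order]
            w = (d < 1e-12).astype(float) if (d < 1e-12).any() else 1.0 / d
            w = w / w.sum()
            expected = w @ S[order]
            np.testing.assert_allclose(m2.node_structures[r, c], expected,
                                       atol=1e-12)

    def test_n_neighbours_exceeding_refset_rejected(self, grid, small_map, refset):
        with pytest.raises(ValueError):
            assign_node_structures(small_map, refset, n_neighbours=len(refset) + 1)


class TestBMUs:
    def test_exact_node_weight_is_rank1_with_zero_distance(self, small_map, grid):
        q = CDSpectrum(grid=grid, values=small_map.node_weights[3, 4])
        bmus = find_bmus(small_map, q, 3)
        assert bmus[0].node == (3, 4) and bmus[0].distance == 0.0
        assert [b.rank for b in bmus] == [1, 2, 3]

    def test_k_equal_node_count_returns_all_sorted(self, small_map, grid):
        q = CDSpectrum(grid=grid, values=np.zeros(51))
        bmus = find_bmus(small_map, q, small_map.n_nodes)
        d = [b.distance for b in bmus]
        assert d == sorted(d) and len(bmus) == small_map.n_nodes

    def test_matches_exhaustive_sort_on_random_maps(self, grid):
        """BMU search equals a brute-force sort of all node distances."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            rows, cols = rng.integers(1, 6, size=2)
            W = rng.normal(size=(rows, cols, len(grid)))
            m = _manual_map(grid, W, None, [[0, 0]], ["r1"],
                            rows=int(rows), cols=int(cols))
            q = CDSpectrum(grid=grid, values=rng.normal(size=len(grid)))
            k = int(rng.integers(1, rows * cols + 1))
            got = find_bmus(m, q, k)
            flat = W.reshape(-1, len(grid))
            d = np.linalg.norm(flat - q.values, axis=1)
            expected = sorted(
                ((d[i], i // cols, i % cols) for i in range(len(d)))
            )[:k]
            for b, (dist, r, c) in zip(got, expected):
                assert b.node == (r, c)
                assert b.distance == pytest.approx(dist)


class TestPredict:
    def test_query_on_node_weight_returns_node_exactly(self, grid):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(2, 2, len(grid)))
        S = np.tile(np.array([0.2, 0.2, 0.2, 0.2, 0.1]), (2, 2, 1))
        S[1, 1] = [0.9, 0.0, 0.05, 0.03, 0.02]
        m = _manual_map(grid, W, S, [[0, 0]], ["r1"], k_bmu=2)
        q = CDSpectrum(grid=grid, values=W[1, 1])
        fit = predict(m, q)
        assert fit.nrmsd_value == 0.0
        np.testing.assert_allclose(fit.predicted_spectrum.values, W[1, 1])
        np.testing.assert_allclose(fit.structure5.as_array(), S[1, 1])

    def test_equidistant_bmus_average_structures(self, grid):
        base = np.full(len(grid), 3.0)
        W = np.stack([base + 1.0, base - 1.0])[None, :, :]  # 1x2 map
        S = np.array([[[1, 0, 0, 0, 0], [0, 0, 0, 0, 1]]], dtype=float)
        m = _manual_map(grid, W, S, [[0, 0]], ["r1"], k_bmu=2, rows=1, cols=2)
        q = CDSpectrum(grid=grid, values=base)  # equidistant from both nodes
        fit = predict(m, q)
        np.testing.assert_allclose(fit.structure5.as_array(),
                                   [0.5, 0, 0, 0, 0.5], atol=1e-12)

    def test_weighted_average_matches_hand_arithmetic(self, grid):
        L = len(grid)
        W = np.zeros((2, 2, L))
        W[0, 0] = 4.0   # distance to the flat query at 3: sqrt(51)
        W[0, 1] = 5.0   # 2*sqrt(51)
        W[1, 0] = 30.0
        W[1, 1] = 30.0
        S = np.zeros((2, 2, 5))
        S[0, 0] = [1, 0, 0, 0, 0]
        S[0, 1] = [0, 1, 0, 0, 0]
        m = _manual_map(grid, W, S, [[0, 0]], ["r1"], k_bmu=2)
        q = CDSpectrum(grid=grid, values=np.full(L, 3.0))
        fit = predict(m, q)
        # weights 1/d: (1/1) vs (1/2) -> 2/3 and 1/3
        np.testing.assert_allclose(fit.structure5.as_array(),
                                   [2 / 3, 1 / 3, 0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fit.predicted_spectrum.values,
                                   (2 / 3) * 4.0 + (1 / 3) * 5.0, atol=1e-12)

    def test_prediction_weights_stay_in_convex_hull(self, small_map, refset, grid):
        rng = np.random.default_rng(8)
        q = CDSpectrum(grid=grid, values=rng.normal(size=51) * 5)
        fit = predict(small_map, q)
        idx = [b.node for b in fit.bmus]
        S = np.array([small_map.node_structures[r, c] for r, c in idx])
        s5 = fit.structure5.as_array()
        assert np.all(s5 >= S.min(axis=0) - 1e-12)
        assert np.all(s5 <= S.max(axis=0) + 1e-12)

    def test_grid_mismatch_rejected(self, small_map):
        other = WavelengthGrid(250, 200, 1.0)
        q = CDSpectrum(grid=other, values=np.zeros(len(other)))
        with pytest.raises(Exception):
            predict(small_map, q)


class TestLayoutAndPersistence:
    def test_layout_counts(self, small_map, refset, grid):
        q = refset.entries[0].spectrum
        fit = predict(small_map, q)
        layout = map_layout(small_map, fit)
        assert len(layout["references"]) == len(refset)
        assert [r[0] for r in layout["references"]] == list(range(1, len(refset) + 1))
        assert len(layout["bmus"]) == small_map.config.k_bmu
        assert layout["extent"] == (10, 10)
        assert map_layout(small_map, None)["bmus"] == []

    def test_save_load_roundtrip(self, small_map, tmp_path, grid, refset):
        path = tmp_path / "map.json"
        save_map(small_map, path)
        back = load_map(path)
        np.testing.assert_array_equal(back.node_weights, small_map.node_weights)
        np.testing.assert_array_equal(back.node_structures, small_map.node_structures)
        np.testing.assert_array_equal(back.occupancy, small_map.occupancy)
        assert back.config == small_map.config
        # loaded map predicts identically
        q = refset.entries[3].spectrum
        a, b = predict(small_map, q), predict(back, q)
        assert a.nrmsd_value == b.nrmsd_value
        assert a.bmus == b.bmus
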