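import math

import numpy as np
import pytest

from wph.geometry import OSMOLYTE, WATER, Configuration, cross_distance_matrix
from wph.iph import (
    build_global_iph_matrix,
    build_local_iph_matrix,
    global_prdf_pipeline,
    iph_betti0,
    iph_betti1_check,
    iph_pbn_bpe_pipeline,
    local_prdf_pipeline,
)
from wph.rips import betti0_union_find
from wph.descriptors import prdf_from_barcode
from wph.synthetic import Trajectory, gen_solvated, gen_trajectory, gen_uniform

from oracles import bipartite_mst_deaths


def mixed_config(n_osm, n_wat, box=30.0, seed=0):
    osmo = gen_uniform(n_osm, box, seed=seed)
    return gen_solvated(osmo, n_wat, shell_fraction=0.0, seed=seed + 1)


class TestMatrixConstruction:
    def test_global_shape_and_infinite_pattern(self):
        cfg = mixed_config(1, 2)
        m = build_global_iph_matrix(cfg, int(cfg.indices_of(OSMOLYTE)[0]))
        assert m.matrix.shape == (3, 3)
        assert math.isinf(m.matrix[1, 2]) and math.isinf(m.matrix[2, 1])
        assert np.all(np.isfinite(m.matrix[0, 1:]))
        assert np.all(np.diagonal(m.matrix) == 0.0)

    def test_global_requires_osmolyte_index(self):
        cfg = mixed_config(1, 2)
        water = int(cfg.indices_of(WATER)[0])
        with pytest.raises(ValueError, match="not OSMOLYTE"):
            build_global_iph_matrix(cfg, water)

    def test_global_entries_match_min_image_distances(self):
        cfg = mixed_config(3, 10)
        osm = int(cfg.indices_of(OSMOLYTE)[1])
        m = build_global_iph_matrix(cfg, osm)
        expected = cross_distance_matrix(cfg, [osm], cfg.indices_of(WATER))[0]
        assert np.allclose(m.matrix[0, 1:], expected)

    def test_local_shape_and_same_type_infinities(self):
        cfg = mixed_config(2, 3)
        m = build_local_iph_matrix(cfg)
        assert m.matrix.shape == (5, 5)
        assert math.isinf(m.matrix[0, 1])  # osmolyte-osmolyte
        same = m.types[:, None] == m.types[None, :]
        off = ~np.eye(5, dtype=bool)
        assert np.all(np.isinf(m.matrix[same & off]))
        assert np.all(np.isfinite(m.matrix[~same]))

    def test_local_requires_both_species(self):
        cfg = gen_uniform(4, 20.0, seed=0)
        with pytest.raises(ValueError, match="both species"):
            build_local_iph_matrix(cfg)


class TestBetti0:
    def test_global_fast_path_deaths_are_distances(self):
        cfg = mixed_config(1, 40, seed=3)
        osm = int(cfg.indices_of(OSMOLYTE)[0])
        m = build_global_iph_matrix(cfg, osm)
        bc = iph_betti0(m)
        assert np.allclose(np.sort(bc.finite(0)[:, 1]), np.sort(m.matrix[0, 1:]))
        assert bc.n_infinite(0) == 1

    def test_global_fast_path_equals_union_find(self, rng):
        for seed in range(5):
            cfg = mixed_config(1, 25, seed=seed)
            m = build_global_iph_matrix(cfg, int(cfg.indices_of(OSMOLYTE)[0]))
            fast = iph_betti0(m)
            uf = betti0_union_find(m.matrix)
            assert np.allclose(
                np.sort(fast.finite(0)[:, 1]), np.sort(uf.finite(0)[:, 1])
            )
            assert fast.n_infinite(0) == uf.n_infinite(0)

    def test_local_deaths_are_bipartite_mst_weights(self, rng):
        for seed in range(4):
            cfg = mixed_config(5, 30, seed=10 + seed)
            m = build_local_iph_matrix(cfg)
            bc = iph_betti0(m)
            assert np.allclose(
                np.sort(bc.finite(0)[:, 1]), bipartite_mst_deaths(m.matrix, m.types)
            )

    def test_single_pair(self):
        cfg = Configuration(
            coords=np.array([[1.0, 1, 1], [4.0, 1, 1]]),
            box=np.full(3, 20.0),
            types=np.array([OSMOLYTE, WATER]),
        )
        bc = iph_betti0(build_local_iph_matrix(cfg))
        assert bc.finite(0)[:, 1].tolist() == [3.0]


class TestBetti1Check:
    def test_no_triangle_at_any_threshold(self):
        cfg = mixed_config(3, 8)
        report = iph_betti1_check(build_local_iph_matrix(cfg))
        assert report["analytic_bipartite"]
        assert report["verified_by_reduction"]
        assert report["n_triangles"] == 0
        assert report["all_dim1_deaths_infinite"]

    def test_four_cycle_loop_persists_forever(self):
        # 2 osmolytes + 2 waters alternating around a square: one eternal loop
        coords = np.array(
            [[0.0, 0, 0], [1.0, 1, 0], [1.0, 0, 0], [0.0, 1, 0]]
        ) + 5.0
        cfg = Configuration(
            coords=coords,
            box=np.full(3, 20.0),
            types=np.array([OSMOLYTE, OSMOLYTE, WATER, WATER]),
        )
        m = build_local_iph_matrix(cfg)
        from wph.rips import build_rips_filtration, compute_persistence

        bc = compute_persistence(build_rips_filtration(m.matrix, max_dim=2))
        dim1 = bc.get(1)
        assert len(dim1) == 1 and math.isinf(dim1[0, 1])

    def test_single_finite_edge_no_loops(self):
        cfg = Configuration(
            coords=np.array([[1.0, 1, 1], [2.0, 1, 1]]),
            box=np.full(3, 10.0),
            types=np.array([OSMOLYTE, WATER]),
        )
        m = build_local_iph_matrix(cfg)
        report = iph_betti1_check(m)
        assert report["all_dim1_deaths_infinite"]
        from wph.rips import build_rips_filtration, compute_persistence

        bc = compute_persistence(build_rips_filtration(m.matrix, max_dim=2))
        assert bc.n_bars(1) == 0


class TestPipelines:
    def test_single_frame_single_osmolyte_reduces_to_prdf(self):
        cfg = mixed_config(1, 60, box=24.0, seed=6)
        traj = Trajectory(frames=[cfg])
        pipeline = global_prdf_pipeline(traj, bin_width=0.5)
        m = build_global_iph_matrix(cfg, int(cfg.indices_of(OSMOLYTE)[0]))
        bc = iph_betti0(m)
        direct = prdf_from_barcode(
            bc, bin_width=0.5, rho=pipeline.rho, r_max=12.0
        )
        assert np.allclose(pipeline.values, direct.values)

    def test_local_curve_zero_beyond_largest_death(self):
        traj = gen_trajectory(mixed_config(4, 40, seed=8), 2, frame_jitter=0.3, seed=9)
        curve = local_prdf_pipeline(traj, bin_width=0.25)
        beyond = curve.bin_centers > curve.x_t
        assert np.all(curve.values[beyond] == 0.0)

    def test_one_frame_local_pipeline_is_identity(self):
        cfg = mixed_config(4, 40, seed=12)
        one = local_prdf_pipeline(Trajectory(frames=[cfg]), bin_width=0.25)
        bc = iph_betti0(build_local_iph_matrix(cfg))
        rho = 40 / float(np.prod(cfg.box))
        direct = prdf_from_barcode(bc, bin_width=0.25, rho=rho, r_max=15.0)
        assert np.allclose(one.values, direct.values)

    def test_denser_osmolytes_shrink_largest_death(self):
        box = 30.0
        sparse = Trajectory(frames=[mixed_config(3, 60, box=box, seed=20)])
        dense = Trajectory(frames=[mixed_config(30, 60, box=box, seed=20)])
        assert (
            local_prdf_pipeline(dense, 0.25).x_t < local_prdf_pipeline(sparse, 0.25).x_t
        )

    def test_pbn_bpe_pipeline_shapes_and_vertex_count(self):
        traj = gen_trajectory(mixed_config(3, 27, seed=14), 4, frame_jitter=0.2, seed=15)
        pbn, bpes = iph_pbn_bpe_pipeline(traj)
        assert len(bpes) == 4
        assert pbn.values[0] == pytest.approx(30)  # N_w + N_s vertices born at 0

    def test_frozen_trajectory_zero_bpe_variance(self):
        traj = gen_trajectory(mixed_config(3, 20, seed=16), 3, frame_jitter=0.0, seed=17)
        _, bpes = iph_pbn_bpe_pipeline(traj)
        assert np.ptp(bpes) == 0.0
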