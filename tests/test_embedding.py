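"""Coalescent embedding: RA weights, projection, angles, radii."""

import numpy as np
import pytest

from hypdisp import EmbeddingParams, embed, generate_base_connectome, ra_weight
from hypdisp.embedding import (
    classical_mds_2d,
    degree_ranks,
    equidistant_angles,
    geodesic_matrix,
    project_2d,
    radial_coordinates,
)
from hypdisp.geometry import circular_correlation
from hypdisp.io import ValidationError

from conftest import SMALL_CONFIG, connectome_from_edges


class TestRAWeights:
    def test_path_graph_hand_values(self, path_graph):
        w = ra_weight(path_graph)
        # (d_A + d_B + d_A*d_B) / (1 + CN) = (1 + 2 + 2) / 1 = 5
        assert w[0, 1] == pytest.approx(5.0)
        assert w[1, 2] == pytest.approx(5.0)
        assert w[0, 2] == 0.0

    def test_triangle_hand_values(self, triangle_graph):
        w = ra_weight(triangle_graph)
        # every edge: (2 + 2 + 4) / (1 + 1) = 4
        for i, j in [(0, 1), (1, 2), (0, 2)]:
            assert w[i, j] == pytest.approx(4.0)

    def test_star_hand_values(self, star_graph):
        w = ra_weight(star_graph)
        # hub-leaf: (3 + 1 + 3) / 1 = 7
        for leaf in (1, 2, 3):
            assert w[0, leaf] == pytest.approx(7.0)

    def test_symmetry_and_support(self, path_graph):
        w = ra_weight(path_graph)
        assert np.array_equal(w > 0, path_graph.adjacency > 0)
        np.testing.assert_array_equal(w, w.T)

    def test_edgeless_graph_rejected(self):
        net = connectome_from_edges([], "AB")
        with pytest.raises(ValidationError, match="edgeless"):
            ra_weight(net)


class TestProjection:
    def test_path_graph_collinear_equal_spacing(self, path_graph):
        # geodesics 5, 5, 10 form a line metric; classical MDS places the
        # three points collinear with equal spacing on the leading axis
        xy = project_2d(ra_weight(path_graph), node_ids=path_graph.node_ids)
        assert abs(abs(xy[0, 0] - xy[1, 0]) - abs(xy[1, 0] - xy[2, 0])) < 1e-6
        assert np.allclose(xy[:, 1], 0.0, atol=1e-6)

    def test_coordinates_are_centered(self, triangle_graph):
        xy = project_2d(ra_weight(triangle_graph), node_ids=triangle_graph.node_ids)
        np.testing.assert_allclose(xy.mean(axis=0), 0.0, atol=1e-9)

    def test_four_cycle_forms_rectangle(self):
        net = connectome_from_edges(
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")], "ABCD"
        )
        xy = project_2d(ra_weight(net), node_ids=net.node_ids)
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
        # opposite corners (A,C) and (B,D) at equal diagonal distance
        assert d[0, 2] == pytest.approx(d[1, 3], abs=1e-9)
        # opposite sides equal
        assert d[0, 1] == pytest.approx(d[2, 3], abs=1e-9)
        assert d[1, 2] == pytest.approx(d[3, 0], abs=1e-9)

    def test_disconnected_graph_reported(self):
        net = connectome_from_edges([("A", "B"), ("C", "D")], "ABCD")
        with pytest.raises(ValidationError, match="disconnected"):
            project_2d(ra_weight(net), node_ids=net.node_ids)

    def test_bridged_geodesics_finite(self):
        net = connectome_from_edges([("A", "B"), ("C", "D")], "ABCD")
        d = geodesic_matrix(ra_weight(net))
        assert np.isfinite(d).all()
        finite_max = d[np.isfinite(d)].max()
        assert finite_max == pytest.approx(1.05 * 3.0)  # 1.05 x max in-component


class TestEquidistantAngles:
    def test_respacing_preserves_cyclic_order(self):
        raw = np.deg2rad([10, 80, 200, 300])
        xy = np.column_stack([np.cos(raw), np.sin(raw)])
        th = equidistant_angles(xy)
        np.testing.assert_allclose(th, [0, np.pi / 2, np.pi, 3 * np.pi / 2], atol=1e-12)

    def test_gaps_all_equal(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0, 2 * np.pi, 17)
        xy = np.column_stack([np.cos(raw), np.sin(raw)])
        th = np.sort(equidistant_angles(xy))
        gaps = np.diff(np.concatenate([th, [th[0] + 2 * np.pi]]))
        np.testing.assert_allclose(gaps, 2 * np.pi / 17, atol=1e-12)

    def test_rotation_shifts_assignment_cyclically(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(0, 2 * np.pi, 12)
        xy = np.column_stack([np.cos(raw), np.sin(raw)])
        th1 = equidistant_angles(xy)
        rot = (raw + 0.4) % (2 * np.pi)
        xy2 = np.column_stack([np.cos(rot), np.sin(rot)])
        th2 = equidistant_angles(xy2)
        # same cyclic order: pairwise angular ordering retained up to shift
        shift = (th2 - th1) % (2 * np.pi)
        assert len(np.unique(np.round(shift, 9))) == 1


class TestRadii:
    @pytest.mark.parametrize("n", [4, 23, 114])
    @pytest.mark.parametrize("beta", [0.5, 0.9])
    def test_rank1_rescaled_radius_is_one_minus_beta(self, n, beta):
        hub = "a0"
        net = connectome_from_edges([(hub, f"a{i}") for i in range(1, n)],
                                    [f"a{i}" for i in range(n)])
        _, rescaled, rank = radial_coordinates(net, EmbeddingParams(beta=beta))
        assert rescaled[rank == 1][0] == pytest.approx(1 - beta)

    def test_rescaled_extremes(self, star_graph):
        native, rescaled, rank = radial_coordinates(star_graph)
        assert rescaled[rank == star_graph.n_nodes][0] == pytest.approx(1.0)
        assert rescaled[rank == 1][0] == pytest.approx(0.1)  # 1 - beta at zeta=1

    def test_native_values_for_114_nodes(self):
        net, _ = generate_base_connectome(
            SMALL_CONFIG.__class__(n_nodes=114, seed=3), 3
        )
        native, _, rank = radial_coordinates(net)
        assert native[rank == 1][0] == pytest.approx(0.2 * np.log(114))
        assert native[rank == 114][0] == pytest.approx(2 * np.log(114))

    def test_degree_rank_ties_break_by_node_id(self, path_graph):
        rank = degree_ranks(path_graph.degrees, path_graph.node_ids)
        # B (degree 2) first, then A and C (degree 1) in id order
        assert rank.tolist() == [2, 1, 3]


class TestEmbed:
    def test_deterministic(self, small_cohort):
        net = small_cohort["patients"][0].pre
        e1 = embed(net)
        e2 = embed(net)
        np.testing.assert_array_equal(e1.radius, e2.radius)
        np.testing.assert_array_equal(e1.theta, e2.theta)

    def test_radius_antimonotone_in_degree(self, small_cohort):
        net = small_cohort["patients"][0].pre
        e = embed(net)
        order = np.argsort(-e.degree, kind="stable")
        assert np.all(np.diff(e.radius[order]) >= -1e-12)

    def test_theta_is_permutation_of_uniform_grid(self, small_cohort):
        net = small_cohort["patients"][0].pre
        e = embed(net)
        n = net.n_nodes
        expected = 2 * np.pi * np.arange(n) / n
        np.testing.assert_allclose(np.sort(e.theta), expected, atol=1e-12)

    def test_radii_within_unit_disk_band(self, small_cohort):
        e = embed(small_cohort["patients"][0].pre)
        assert e.radius.min() >= 1 - e.params.beta - 1e-12
        assert e.radius.max() == pytest.approx(1.0)

    def test_recovers_generative_angles(self):
        cfg = SMALL_CONFIG.__class__(n_nodes=114, seed=5)
        net, truth = generate_base_connectome(cfg, 77)
        e = embed(net)
        assert abs(circular_correlation(e.theta, truth.true_angle)) >= 0.7

    def test_isolated_nodes_flagged_and_placed_at_fallback(self, small_cohort):
        net = small_cohort["patients"][0].pre
        adj = net.adjacency.copy()
        adj[3, :] = adj[:, 3] = 0
        cut = net.with_adjacency(adj)
        fallback = embed(net).theta
        e = embed(cut, theta_fallback=fallback)
        assert e.isolated[3]
        assert e.theta[3] == pytest.approx(fallback[3])
        assert e.rank[3] == net.n_nodes  # degree-0 sinks to the last rank

    def test_align_to_reference_recovers_rotated_copy(self, small_cohort):
        from hypdisp import align_to_reference
        from hypdisp.geometry import wrap_angle

        ref = embed(small_cohort["patients"][0].pre)
        rotated = ref.rotated(theta=wrap_angle(ref.theta + 0.8))
        aligned, result = align_to_reference(rotated, ref)
        assert result.loss < 1e-6
        diff = np.abs(aligned.theta - ref.theta)
        diff = np.minimum(diff, 2 * np.pi - diff)
        assert diff.max() < 1e-6
        np.testing.assert_array_equal(aligned.radius, ref.radius)

    def test_hubs_sit_in_inner_radii(self):
        cfg = SMALL_CONFIG.__class__(n_nodes=114, seed=9)
        net, _ = generate_base_connectome(cfg, 9)
        e = embed(net)
        hub = e.degree >= np.quantile(e.degree, 0.9)
        assert e.radius[hub].max() <= np.quantile(e.radius, 0.15)
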