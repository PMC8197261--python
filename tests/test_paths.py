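"""Path layers: hand-computed scalar examples, loop-oracle agreement,
equivariance and coordinate-invariance properties."""

import numpy as np
import pytest

from conftest import (edge_path_loop, node_path_loop, random_graph,
                      threed_path_loop)
from molpath._tensor import Tensor
from molpath.molgraph import BondType, MolecularGraph, build_adjacency
from molpath.paths import (FIXED_EDGE_WEIGHTS, EdgePathParams, NodePathParams,
                           ThreeDPathParams, edge_parameter_matrix,
                           edge_path_update, neighbor_sets, node_path_update,
                           relative_coords, threed_path_update)


def scalar_node_params(w_np=(1.0, 1.0), b_np=0.0, w_n=1.0, b_n=0.0):
    return NodePathParams(W_np=Tensor([list(w_np)], True), B_np=Tensor([b_np], True),
                          W_n=Tensor([[w_n]], True), B_n=Tensor([b_n], True))


def rand_node_params(rng, M):
    return NodePathParams(W_np=Tensor(rng.standard_normal((M, 2 * M)), True),
                          B_np=Tensor(rng.standard_normal(M), True),
                          W_n=Tensor(rng.standard_normal((M, M)), True),
                          B_n=Tensor(rng.standard_normal(M), True))


def rand_edge_params(rng, M, fixed=False):
    w = FIXED_EDGE_WEIGHTS.copy() if fixed else rng.standard_normal(5)
    c = 0.0 if fixed else float(rng.standard_normal())
    return EdgePathParams(W_ep=Tensor(rng.standard_normal((M, 2 * M)), True),
                          B_ep=Tensor(rng.standard_normal(M), True),
                          W_e=Tensor(rng.standard_normal((M, M)), True),
                          B_e=Tensor(rng.standard_normal(M), True),
                          w=Tensor(w, not fixed), c=Tensor(c, not fixed),
                          fixed_mode=fixed)


def rand_threed_params(rng, M, include_self=True):
    return ThreeDPathParams(W_tp=Tensor(rng.standard_normal((M, 2 * M)), True),
                            B_tp=Tensor(rng.standard_normal(M), True),
                            W_tq=Tensor(rng.standard_normal((M, M)), True),
                            B_tq=Tensor(rng.standard_normal(M), True),
                            W_t=Tensor(rng.standard_normal((M, 2 * M)), True),
                            W_ns=Tensor(rng.standard_normal((M, M)), True),
                            include_self=include_self)


class TestNodePath:
    def test_two_bonded_nodes_hand_example(self, two_atom_graph):
        out = node_path_update(Tensor(two_atom_graph.H_init), two_atom_graph,
                               scalar_node_params())
        np.testing.assert_allclose(out.data.ravel(), [5.0, 7.0], atol=1e-9)

    def test_all_zero_weights_give_zero_output(self, two_atom_graph):
        p = scalar_node_params(w_np=(0, 0), w_n=0)
        out = node_path_update(Tensor(two_atom_graph.H_init), two_atom_graph, p)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_isolated_node_self_only_neighborhood(self):
        g = MolecularGraph(elements=("C",), A=build_adjacency([], 1),
                           H_init=np.array([[3.0]]))
        out = node_path_update(Tensor(g.H_init), g, scalar_node_params())
        np.testing.assert_allclose(out.data.ravel(), [6.0], atol=1e-9)

    def test_shape_mismatch_reports_expected_width(self, two_atom_graph):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="width"):
            node_path_update(Tensor(two_atom_graph.H_init), two_atom_graph,
                             rand_node_params(rng, 3))


class TestEdgeParameterMatrix:
    def test_fixed_categorical_values_on_single_bond(self, two_atom_graph):
        E = edge_parameter_matrix(two_atom_graph.A, FIXED_EDGE_WEIGHTS, 0.0)
        np.testing.assert_array_equal(E, [[1, 2], [2, 1]])

    def test_zero_weights_zero_bias_gives_zero(self, two_atom_graph):
        E = edge_parameter_matrix(two_atom_graph.A, np.zeros(5), 0.0)
        np.testing.assert_array_equal(E, 0.0)

    def test_self_channel_only_gives_identity(self, two_atom_graph):
        E = edge_parameter_matrix(two_atom_graph.A, np.array([1., 0, 0, 0, 0]), 0.0)
        np.testing.assert_array_equal(E, np.eye(2))

    def test_symmetric_when_adjacency_is(self):
        rng = np.random.default_rng(1)
        g = random_graph(rng, n_atoms=6)
        E = edge_parameter_matrix(g.A, rng.standard_normal(5), 0.3)
        np.testing.assert_allclose(E, E.T)


class TestEdgePath:
    def test_fixed_mode_hand_example(self, two_atom_graph):
        p = EdgePathParams(W_ep=Tensor([[1.0, 1.0]], True), B_ep=Tensor([0.0], True),
                           W_e=Tensor([[1.0]], True), B_e=Tensor([0.0], True),
                           w=Tensor(FIXED_EDGE_WEIGHTS), c=Tensor(0.0),
                           fixed_mode=True)
        out = edge_path_update(Tensor(two_atom_graph.H_init), two_atom_graph, p)
        np.testing.assert_allclose(out.data.ravel(), [8.0, 10.0], atol=1e-9)

    def test_unit_edge_parameters_reduce_to_node_path(self):
        # E == 1 on a SELF+SINGLE-only graph with shared weights
        rng = np.random.default_rng(5)
        M = 4
        g = random_graph(rng, n_atoms=6, M=M)
        bonds = {(i, j, BondType.SINGLE) for i, j, _ in g.bonds}
        g.A = build_adjacency(bonds, g.n_atoms)
        np_params = rand_node_params(rng, M)
        ep = EdgePathParams(W_ep=np_params.W_np, B_ep=np_params.B_np,
                            W_e=np_params.W_n, B_e=np_params.B_n,
                            w=Tensor(np.array([1.0, 1.0, 0, 0, 0])),
                            c=Tensor(0.0), fixed_mode=True)
        H = Tensor(g.H_init)
        np.testing.assert_array_equal(edge_path_update(H, g, ep).data,
                                      node_path_update(H, g, np_params).data)

    def test_all_zero_weights_give_zeros(self, two_atom_graph):
        p = EdgePathParams(W_ep=Tensor([[0.0, 0.0]], True), B_ep=Tensor([0.0], True),
                           W_e=Tensor([[0.0]], True), B_e=Tensor([0.0], True),
                           w=Tensor(FIXED_EDGE_WEIGHTS), c=Tensor(0.0),
                           fixed_mode=True)
        out = edge_path_update(Tensor(two_atom_graph.H_init), two_atom_graph, p)
        np.testing.assert_array_equal(out.data, 0.0)


class TestRelativeCoords:
    def test_direct_subtraction(self):
        R = relative_coords(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        np.testing.assert_array_equal(R[0], [[0, -1], [1, 0]])
        np.testing.assert_array_equal(R[1], 0.0)
        np.testing.assert_array_equal(R[2], 0.0)

    def test_zero_diagonal_and_antisymmetry(self):
        rng = np.random.default_rng(2)
        C = rng.standard_normal((7, 3))
        R = relative_coords(C)
        for k in range(3):
            np.testing.assert_array_equal(np.diag(R[k]), 0.0)
            np.testing.assert_allclose(R[k], -R[k].T)

    def test_translation_cancels(self):
        rng = np.random.default_rng(3)
        C = rng.standard_normal((5, 3))
        np.testing.assert_allclose(relative_coords(C),
                                   relative_coords(C + 10.0), atol=1e-12)

    def test_missing_coordinates_instructive_error(self):
        with pytest.raises(ValueError, match="embed|SDF"):
            relative_coords(None)


class TestThreeDPath:
    def _scalar_params(self, include_self):
        return ThreeDPathParams(W_tp=Tensor([[1.0, 1.0]], True),
                                B_tp=Tensor([0.0], True),
                                W_tq=Tensor([[1.0]], True), B_tq=Tensor([0.0], True),
                                W_t=Tensor([[1.0, 1.0]], True),
                                W_ns=Tensor([[1.0]], True),
                                include_self=include_self)

    def test_hand_example_with_self(self, two_atom_graph):
        out = threed_path_update(Tensor(two_atom_graph.H_init), two_atom_graph,
                                 self._scalar_params(True))
        np.testing.assert_allclose(out.data.ravel(), [1.0, 5.0], atol=1e-9)

    def test_hand_example_without_self(self, two_atom_graph):
        out = threed_path_update(Tensor(two_atom_graph.H_init), two_atom_graph,
                                 self._scalar_params(False))
        np.testing.assert_allclose(out.data.ravel(), [0.0, 3.0], atol=1e-9)

    def test_translation_invariance_exact(self):
        rng = np.random.default_rng(7)
        g = random_graph(rng, n_atoms=6)
        p = rand_threed_params(rng, 4)
        out1 = threed_path_update(Tensor(g.H_init), g, p).data
        g.C = g.C + np.array([3.0, -2.0, 11.0])
        out2 = threed_path_update(Tensor(g.H_init), g, p).data
        # exact up to floating-point rounding of the coordinate differences
        np.testing.assert_allclose(out1, out2, atol=1e-9)

    def test_rotation_changes_some_output(self):
        rng = np.random.default_rng(8)
        g = random_graph(rng, n_atoms=6)
        p = rand_threed_params(rng, 4)
        out1 = threed_path_update(Tensor(g.H_init), g, p).data
        theta = 0.7  # generic rotation about z
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        g.C = g.C @ rot.T
        out2 = threed_path_update(Tensor(g.H_init), g, p).data
        assert np.abs(out1 - out2).max() > 1e-6

    def test_missing_coordinates_raise(self, benzene_like_graph):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            threed_path_update(Tensor(benzene_like_graph.H_init),
                               benzene_like_graph, rand_threed_params(rng, 1))


class TestOracleAgreementAndProperties:
    """Vectorized implementations vs the naive double-loop oracles, plus
    permutation equivariance and nonnegativity on random graphs."""

    @pytest.mark.parametrize("seed", range(20))
    def test_all_paths_match_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(1, 8))
        g = random_graph(rng, M=M)
        H = rng.standard_normal((g.n_atoms, M))
        npar = rand_node_params(rng, M)
        np.testing.assert_allclose(
            node_path_update(Tensor(H), g, npar).data,
            node_path_loop(H, g, npar.W_np.data, npar.B_np.data,
                           npar.W_n.data, npar.B_n.data), atol=1e-6)
        epar = rand_edge_params(rng, M)
        np.testing.assert_allclose(
            edge_path_update(Tensor(H), g, epar).data,
            edge_path_loop(H, g, epar.W_ep.data, epar.B_ep.data,
                           epar.W_e.data, epar.B_e.data,
                           epar.w.data, float(epar.c.data)), atol=1e-6)
        for include_self in (True, False):
            tpar = rand_threed_params(rng, M, include_self)
            np.testing.assert_allclose(
                threed_path_update(Tensor(H), g, tpar).data,
                threed_path_loop(H, g, tpar.W_tp.data, tpar.B_tp.data,
                                 tpar.W_tq.data, tpar.B_tq.data,
                                 tpar.W_t.data, tpar.W_ns.data, include_self),
                atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(100 + seed)
        M = 4
        g = random_graph(rng, M=M)
        perm = rng.permutation(g.n_atoms)
        gp = g.permuted(perm)
        npar, epar = rand_node_params(rng, M), rand_edge_params(rng, M)
        tpar = rand_threed_params(rng, M)
        for update, par in ((node_path_update, npar),
                            (edge_path_update, epar),
                            (threed_path_update, tpar)):
            out = update(Tensor(g.H_init), g, par).data
            out_p = update(Tensor(gp.H_init), gp, par).data
            np.testing.assert_allclose(out_p, out[_inverse(perm)], atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_outputs_are_nonnegative(self, seed):
        rng = np.random.default_rng(200 + seed)
        M = 3
        g = random_graph(rng, M=M)
        H = Tensor(rng.standard_normal((g.n_atoms, M)))
        assert node_path_update(H, g, rand_node_params(rng, M)).data.min() >= 0
        assert edge_path_update(H, g, rand_edge_params(rng, M)).data.min() >= 0
        assert threed_path_update(H, g, rand_threed_params(rng, M)).data.min() >= 0

    def test_neighbor_sets_include_self_and_are_symmetric(self):
        rng = np.random.default_rng(11)
        g = random_graph(rng)
        ns = neighbor_sets(g)
        for i in range(g.n_atoms):
            assert i in ns[i]
            for j in ns[i]:
                assert i in ns[j]


def _inverse(perm):
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return inv
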