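import numpy as np
import pytest

from afloc.atrial_sim.geometry import AtrialMesh
from afloc.forward_ecg import (
    TransferMatrix,
    build_gradient_operator,
    build_transfer_matrix,
    default_vest,
    dipole_potential,
    fit_quadratic_gradient,
    forward_bsp,
    load_transfer_matrix,
    save_transfer_matrix,
    wct_correct,
    wct_reference,
)


@pytest.fixture(scope="module")
def vest():
    return default_vest()


@pytest.fixture(scope="module")
def tm_small(small_mesh_module, vest):
    torso, _ = vest
    return build_transfer_matrix(small_mesh_module, torso)


@pytest.fixture(scope="module")
def small_mesh_module():
    from afloc.atrial_sim import build_synthetic_atria

    return build_synthetic_atria(256, rng_seed=7)


class TestQuadraticGradient:
    def test_linear_field_exact(self, small_mesh_module):
        mesh = small_mesh_module
        vm = 2 * mesh.node_coords[:, 0] + 3 * mesh.node_coords[:, 1] + 4 * mesh.node_coords[:, 2]
        g, diag = fit_quadratic_gradient(mesh, vm, node=17)
        np.testing.assert_allclose(g, [2.0, 3.0, 4.0], atol=1e-8)
        assert diag.n_stencil >= 9

    def test_constant_field_zero(self, small_mesh_module):
        vm = np.full(small_mesh_module.n_nodes, 3.25)
        g, _ = fit_quadratic_gradient(small_mesh_module, vm, node=40)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_quadratic_field_vs_normal_equations(self, small_mesh_module):
        # oracle: independent normal-equations solve of the same fit
        mesh = small_mesh_module
        node = 11
        vm = mesh.node_coords[:, 0] ** 2
        g, diag = fit_quadratic_gradient(mesh, vm, node)

        seen, frontier, stencil = {node}, {node}, []
        while len(stencil) < 9:
            nxt = set()
            for f in frontier:
                for nb in mesh.neighbors[f]:
                    nb = int(nb)
                    if nb not in seen:
                        seen.add(nb)
                        nxt.add(nb)
                        stencil.append(nb)
            frontier = nxt
        st = np.array(sorted(stencil))
        d = mesh.node_coords[st] - mesh.node_coords[node]
        x, y, z = d.T
        design = np.column_stack([x, y, z, x * x, y * y, z * z, x * y, y * z, x * z])
        b = vm[st] - vm[node]
        coef = np.linalg.solve(design.T @ design, design.T @ b)
        np.testing.assert_allclose(g, coef[:3], atol=1e-6)
        # exact answer for a field that is itself quadratic
        x0 = mesh.node_coords[node, 0]
        np.testing.assert_allclose(g, [2 * x0, 0.0, 0.0], atol=1e-6)

    def test_gradient_operator_matches_pointwise(self, small_mesh_module):
        mesh = small_mesh_module
        g_op, diags = build_gradient_operator(mesh)
        rng = np.random.default_rng(0)
        vm = rng.standard_normal(mesh.n_nodes)
        full = (g_op @ vm).reshape(mesh.n_nodes, 3)
        for node in (0, 50, 123):
            g, _ = fit_quadratic_gradient(mesh, vm, node)
            np.testing.assert_allclose(full[node], g, atol=1e-10)
        assert len(diags) == mesh.n_nodes


class TestDipolePotential:
    def test_zero_gradient_zero_potential(self, small_mesh_module):
        grad = np.zeros((small_mesh_module.n_nodes, 3))
        assert dipole_potential(small_mesh_module, grad, [300.0, 0, 0]) == 0.0

    def test_inverse_square_decay(self, small_mesh_module):
        mesh = small_mesh_module
        grad = np.zeros((mesh.n_nodes, 3))
        k = 10
        grad[k] = [1.0, 0.5, -0.2]
        direction = np.array([1.0, 0.0, 0.0])
        p1 = dipole_potential(mesh, grad, mesh.node_coords[k] + 200 * direction)
        p2 = dipole_potential(mesh, grad, mesh.node_coords[k] + 400 * direction)
        assert p1 != 0
        assert p1 / p2 == pytest.approx(4.0, rel=1e-12)

    def test_mirror_symmetric_sources_cancel(self):
        coords = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
        mesh = AtrialMesh(
            node_coords=coords,
            triangles=np.empty((0, 3), dtype=np.int64),
            fiber_dir=np.array([[1.0, 0, 0], [1.0, 0, 0]]),
            region_id=np.array([1, 2]),
            d_long=1.0,
            d_trans=0.5,
        )
        # gradients parallel to the symmetry plane, equal and opposite
        grad = np.array([[1.0, 0.5, 0.0], [-1.0, -0.5, 0.0]])
        v = dipole_potential(mesh, grad, [5.0, 3.0, 0.0], weights=np.ones(2))
        assert abs(v) < 1e-14

    def test_guard_radius(self, small_mesh_module):
        mesh = small_mesh_module
        grad = np.ones((mesh.n_nodes, 3))
        with pytest.raises(ValueError, match="guard"):
            dipole_potential(mesh, grad, mesh.node_coords[0] + 0.01, guard_radius=1.0)


class TestTransferMatrix:
    def test_uniform_vm_maps_to_zero(self, tm_small):
        out = forward_bsp(tm_small, np.full(tm_small.shape[1], 7.5), referenced=False)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_matches_direct_dipole_summation(self, small_mesh_module, tm_small, vest):
        # oracle: per-electrode loop without matrix assembly
        mesh = small_mesh_module
        torso, _ = vest
        rng = np.random.default_rng(5)
        vm = rng.standard_normal(mesh.n_nodes)
        grads = np.stack([fit_quadratic_gradient(mesh, vm, k)[0] for k in range(mesh.n_nodes)])
        direct = np.array(
            [dipole_potential(mesh, grads, torso.electrode_coords[m])
             for m in range(torso.n_electrodes)]
        )
        via_matrix = tm_small.a @ vm
        scale = np.abs(direct).max()
        assert np.abs(via_matrix - direct).max() / scale < 1e-10

    def test_shape_default_mesh(self, mesh2048, vest):
        torso, _ = vest
        tm = build_transfer_matrix(mesh2048, torso)
        assert tm.a.shape == (torso.n_electrodes, 2048)
        assert tm.a.shape[1] == 2048

    def test_linearity(self, tm_small, rng):
        x = rng.standard_normal(tm_small.shape[1])
        y = rng.standard_normal(tm_small.shape[1])
        lhs = forward_bsp(tm_small, 2.0 * x + 3.0 * y)
        rhs = 2.0 * forward_bsp(tm_small, x) + 3.0 * forward_bsp(tm_small, y)
        assert np.abs(lhs - rhs).max() / np.abs(rhs).max() < 1e-12

    def test_electrode_in_guard_rejected(self, small_mesh_module):
        torso, _ = default_vest(radius_mm=120.0)
        coords = torso.electrode_coords.copy()
        coords[5] = small_mesh_module.node_coords[0] * 1.001
        bad = type(torso)(coords, torso.electrode_names, torso.wct_indices)
        with pytest.raises(ValueError, match=torso.electrode_names[5]):
            build_transfer_matrix(small_mesh_module, bad)

    def test_torso_must_enclose(self, small_mesh_module):
        torso, _ = default_vest(radius_mm=120.0)
        shifted = type(torso)(
            torso.electrode_coords + np.array([500.0, 0, 0]),
            torso.electrode_names, torso.wct_indices,
        )
        with pytest.raises(ValueError, match="enclose"):
            build_transfer_matrix(small_mesh_module, shifted)

    def test_far_field_decay(self, small_mesh_module, rng):
        vm = rng.standard_normal(small_mesh_module.n_nodes)
        peaks = []
        for radius in (120.0, 160.0, 200.0, 260.0):
            torso, _ = default_vest(radius_mm=radius)
            tm = build_transfer_matrix(small_mesh_module, torso)
            peaks.append(np.abs(tm.a_wct @ vm).max())
        assert all(a > b for a, b in zip(peaks, peaks[1:]))

    def test_h5_roundtrip(self, tm_small, tmp_path):
        save_transfer_matrix(tm_small, tmp_path / "tm.h5")
        back = load_transfer_matrix(tmp_path / "tm.h5")
        np.testing.assert_array_equal(back.a, tm_small.a)
        np.testing.assert_array_equal(back.a_wct, tm_small.a_wct)
        np.testing.assert_array_equal(back.wct_indices, tm_small.wct_indices)


class TestWctReferencing:
    def test_wct_rows_average_to_zero(self, tm_small, rng):
        x = rng.standard_normal(tm_small.shape[1])
        out = wct_reference(tm_small, x)
        scale = np.abs(out).max()
        assert abs(out[tm_small.wct_indices].mean()) / scale < 1e-12

    def test_identical_rows_all_wct_gives_zero(self):
        a = np.tile(np.arange(5.0), (4, 1))
        a_wct = wct_correct(a, [0, 1, 2, 3])
        x = np.array([1.0, -2.0, 0.5, 3.0, 1.5])
        np.testing.assert_allclose(a_wct @ x, 0.0, atol=1e-12)

    def test_two_step_oracle(self, tm_small, rng):
        # oracle: subtract the mean of the WCT rows of (a @ x) explicitly
        x = rng.standard_normal(tm_small.shape[1])
        y = tm_small.a @ x
        expected = y - y[tm_small.wct_indices].mean()
        got = tm_small.a_wct @ x
        assert np.abs(got - expected).max() / np.abs(expected).max() < 1e-12

    def test_idempotence(self, tm_small):
        twice = wct_correct(tm_small.a_wct, tm_small.wct_indices)
        np.testing.assert_allclose(twice, tm_small.a_wct, atol=1e-12)

    def test_empty_wct_rejected(self, tm_small):
        with pytest.raises(ValueError):
            wct_correct(tm_small.a, [])
        bad = TransferMatrix(tm_small.a, tm_small.a_wct, np.array([], dtype=np.int64))
        with pytest.raises(ValueError):
            wct_reference(bad, np.zeros(tm_small.shape[1]))


class TestDefaultVest:
    def test_counts_and_table(self, vest):
        torso, table = vest
        assert torso.n_electrodes == 64
        assert len(table) == 64
        assert set(table.panel) == {"front", "back", "side"}
        assert (table.groupby("panel").size()[["front", "back", "side"]] == [24, 24, 16]).all()
        assert torso.wct_indices.size == 3

    def test_table_roundtrip(self, vest, tmp_path):
        import pandas as pd

        from afloc.forward_ecg import load_electrode_table, save_electrode_table

        _, table = vest
        save_electrode_table(table, tmp_path / "vest.csv")
        back = load_electrode_table(tmp_path / "vest.csv")
        pd.testing.assert_frame_equal(
            back, table.reset_index(drop=True), check_dtype=False
        )
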