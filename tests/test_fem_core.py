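import numpy as np
import pytest

from vcfem import fem_core as fc
from vcfem import meshkit as mk
from vcfem.interface_models import (ChargeTransferParams, InterfaceModel,
                                    charge_transfer_resistance_area)

from conftest import dense_stiffness_oracle

FARADAIC = InterfaceModel(mode="faradaic", ct=ChargeTransferParams(j0=0.05))
G_FARADAIC = 1.0 / charge_transfer_resistance_area(FARADAIC.ct)


def two_tet_mesh():
    nodes = np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                      [0.9, 0.9, 0.9]])
    tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
    return mk.TetMesh(nodes, tets, np.array([1, 2]))


class TestStiffnessAssembly:
    def test_unit_tet_element_matrix(self):
        nodes = np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        mesh = mk.TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([1]))
        A = fc.assemble_stiffness(mesh, {1: 1.0}).operator.toarray()
        G = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        assert np.allclose(A, G @ G.T / 6.0, atol=1e-14)
        assert np.abs(A.sum(axis=1)).max() < 1e-14

    def test_two_tet_dense_oracle(self):
        mesh = two_tet_mesh()
        A = fc.assemble_stiffness(mesh, {1: 0.7, 2: 1.3}).operator.toarray()
        oracle = dense_stiffness_oracle(mesh.nodes, mesh.tets, [0.7, 1.3]).real
        assert np.abs(A - oracle).max() < 1e-14

    def test_constants_in_nullspace(self, sphere_four_layer):
        system = fc.assemble_stiffness(
            sphere_four_layer, {1: 0.33, 2: 1.79, 3: 0.01, 4: 0.33})
        ones = np.ones(system.ndof)
        scale = np.abs(system.operator.data).max()
        assert np.abs(system.operator @ ones).max() < 1e-12 * scale

    def test_tensor_conductivity(self, box):
        # diag(2, 1, 1) tensor equals scalar assembly stretched along x
        T = np.diag([2.0, 1.0, 1.0])
        a_t = fc.assemble_stiffness(box, {1: T}).operator
        a_1 = fc.assemble_stiffness(box, {1: 1.0}).operator
        a_2 = fc.assemble_stiffness(box, {1: 2.0}).operator
        # tensor matrix lies between the two isotropic ones (quadratic forms)
        rng = np.random.default_rng(0)
        for _ in range(5):
            v = rng.normal(size=a_t.shape[0])
            qt = v @ (a_t @ v)
            assert v @ (a_1 @ v) <= qt + 1e-12
            assert qt <= v @ (a_2 @ v) + 1e-12

    def test_unmapped_marker_raises(self, box):
        with pytest.raises(KeyError, match="marker 1"):
            fc.assemble_stiffness(box, {99: 1.0})

    def test_complex_material_rejected_in_real_mode(self, box):
        with pytest.raises(ValueError, match="complex"):
            fc.assemble_stiffness(box, {1: 1.0 + 0.5j})


class TestComplexBlock:
    def test_zero_imag_matches_real_solve(self, ball_tiny):
        src = fc.SourceSpec.dipole((0, 0, 0.01), (1, 0, 0), 1e-4, 5e-3)
        s_real = fc.assemble_stiffness(ball_tiny, {1: 0.8})
        fc.assemble_source_rhs(s_real, src)
        f_real = fc.solve(s_real, method="cg", tol=1e-12,
                          preconditioner="jacobi")
        s_cplx = fc.assemble_complex_block(ball_tiny, {1: 0.8 + 0j})
        fc.assemble_source_rhs(s_cplx, src)
        f_cplx = fc.solve(s_cplx, method="gmres", tol=1e-12,
                          preconditioner="jacobi")
        assert np.abs(f_cplx.values.imag).max() < 1e-10 * np.abs(
            f_real.values).max()
        assert np.allclose(f_cplx.values.real, f_real.values, atol=1e-9)

    def test_dense_complex_oracle_small_mesh(self, ball_tiny):
        assert ball_tiny.num_nodes <= 300
        y = 0.9 + 0.4j
        system = fc.assemble_complex_block(ball_tiny, {1: y})
        src = fc.SourceSpec.dipole((0, 0, 0.012), (0, 1, 1), 1e-4, 4e-3)
        fc.assemble_source_rhs(system, src)
        fld = fc.solve(system, method="gmres", tol=1e-13,
                       preconditioner="jacobi")
        # dense direct solve of (A_r + j A_j) u = b with a zero-mean
        # Lagrange row as independent oracle
        A = system.full_matrix().toarray()
        b = system.full_rhs()
        c = system.volume_weights()
        n = len(b)
        Ab = np.zeros((n + 1, n + 1), dtype=complex)
        Ab[:n, :n] = A
        Ab[:n, n] = c
        Ab[n, :n] = c
        x = np.linalg.solve(Ab, np.concatenate([b, [0.0]]))[:n]
        assert np.abs(fld.values - x).max() < 1e-10 * np.abs(x).max()

    def test_block_operator_structure(self, ball_tiny):
        y = 0.5 + 0.25j
        system = fc.assemble_complex_block(ball_tiny, {1: y})
        block, _ = system.to_block_operator()
        n = system.ndof
        Ar = system.operator.real.toarray()
        Aj = system.operator.imag.toarray()
        B = block.toarray()
        assert np.allclose(B[:n, :n], Ar)
        assert np.allclose(B[:n, n:], -Aj)
        assert np.allclose(B[n:, :n], Aj)
        assert np.allclose(B[n:, n:], Ar)

    def test_block_solve_equals_complex_solve(self, ball_tiny):
        import scipy.sparse.linalg as spla

        y = 0.6 + 0.3j
        system = fc.assemble_complex_block(ball_tiny, {1: y})
        src = fc.SourceSpec.dipole((0, 0, 0.01), (1, 0, 0), 1e-4, 5e-3)
        fc.assemble_source_rhs(system, src)
        fld = fc.solve(system, method="gmres", tol=1e-13,
                       preconditioner="jacobi")
        block, rhs = system.to_block_operator()
        n = system.ndof
        # pin the constant nullspace of the doubled system
        c = system.volume_weights()
        import scipy.sparse as sp

        rows = [block, sp.csr_matrix(np.concatenate([c, np.zeros(n)])[None]),
                sp.csr_matrix(np.concatenate([np.zeros(n), c])[None])]
        lhs = sp.vstack(rows).tocsc()
        x, *_ = spla.lsqr(lhs, np.concatenate([rhs, [0.0, 0.0]]),
                          atol=1e-14, btol=1e-14, iter_lim=20000)[:1]
        u = x[:n] + 1j * x[n:]
        assert np.abs(u - fld.values).max() < 1e-7 * np.abs(u).max()

    def test_conjugated_admittivity_conjugates_solution(self, ball_tiny):
        src = fc.SourceSpec.dipole((0, 0, 0.01), (1, 0, 0), 1e-4, 5e-3)
        vals = {}
        for y in (0.6 + 0.3j, 0.6 - 0.3j):
            system = fc.assemble_complex_block(ball_tiny, {1: y})
            fc.assemble_source_rhs(system, src)
            vals[y] = fc.solve(system, method="gmres", tol=1e-12,
                               preconditioner="jacobi").values
        assert np.allclose(vals[0.6 + 0.3j].conj(), vals[0.6 - 0.3j],
                           atol=1e-9)


class TestRobinInterface:
    def test_zero_admittance_is_identity(self, box):
        s0 = fc.assemble_stiffness(box, {1: 1.0})
        s1 = fc.assemble_stiffness(box, {1: 1.0})
        tiny = InterfaceModel(mode="faradaic",
                              ct=ChargeTransferParams(j0=1e-30))
        fc.add_robin_interface(
            s1, fc.ElectrodeSpec(mk.BOX_FACE_MARKERS["xmin"], "stimulating",
                                 tiny, phi_metal=1.0), 0.0)
        diff = (s1.operator - s0.operator)
        assert np.abs(diff.data).max() < 1e-20 * np.abs(s0.operator.data).max()
        assert np.abs(s1.rhs).max() < 1e-20

    def test_dirichlet_limit(self, box):
        big = InterfaceModel(mode="faradaic", ct=ChargeTransferParams(j0=1e10))
        system = fc.assemble_stiffness(box, {1: 0.5})
        fc.add_robin_interface(system, fc.ElectrodeSpec(
            mk.BOX_FACE_MARKERS["xmin"], "stimulating", big, phi_metal=1.0), 0.0)
        fc.add_robin_interface(system, fc.ElectrodeSpec(
            mk.BOX_FACE_MARKERS["xmax"], "ground", big), 0.0)
        fld = fc.solve(system, method="cg", tol=1e-13,
                       preconditioner="jacobi", max_iter=20000)
        surf = np.unique(box.facets[box.facet_markers
                                    == mk.BOX_FACE_MARKERS["xmin"]])
        assert np.abs(fld.values[surf] - 1.0).max() < 1e-4

    def test_series_circuit(self, box):
        sigma = 0.5
        L, W, H = 0.02, 0.01, 0.01
        system = fc.assemble_stiffness(box, {1: sigma})
        fc.add_robin_interface(system, fc.ElectrodeSpec(
            mk.BOX_FACE_MARKERS["xmin"], "stimulating", FARADAIC,
            phi_metal=1.0), 0.0)
        fc.add_robin_interface(system, fc.ElectrodeSpec(
            mk.BOX_FACE_MARKERS["xmax"], "ground", FARADAIC), 0.0)
        fld = fc.solve(system, method="cg", tol=1e-12,
                       preconditioner="jacobi")
        currents = fc.interface_currents(system, fld)
        area = W * H
        r_int = 1.0 / (G_FARADAIC * area)
        r_bulk = L / (sigma * area)
        expected = 1.0 / (2 * r_int + r_bulk)
        measured = abs(currents[mk.BOX_FACE_MARKERS["xmin"]])
        assert measured == pytest.approx(expected, rel=0.02)

    def test_kirchhoff_current_balance(self, box):
        system = fc.assemble_stiffness(box, {1: 0.5})
        for marker, role, phi in ((mk.BOX_FACE_MARKERS["xmin"], "stimulating", 1.0),
                                  (mk.BOX_FACE_MARKERS["xmax"], "ground", 0.0),
                                  (mk.BOX_FACE_MARKERS["ymin"], "ground", 0.0)):
            fc.add_robin_interface(system, fc.ElectrodeSpec(
                marker, role, FARADAIC, phi_metal=phi), 0.0)
        fld = fc.solve(system, method="cg", tol=1e-12,
                       preconditioner="jacobi")
        currents = fc.interface_currents(system, fld)
        total = sum(currents.values())
        assert abs(total) < 1e-6 * max(abs(v) for v in currents.values())

    def test_recording_role_delegates_to_floating(self, box):
        system = fc.assemble_stiffness(box, {1: 0.5})
        fc.add_robin_interface(system, fc.ElectrodeSpec(
            mk.BOX_FACE_MARKERS["ymax"], "recording", FARADAIC), 0.0)
        assert len(system.floating) == 1

    def test_p2_robin_not_implemented(self, box):
        system = fc.assemble_stiffness(box, {1: 0.5}, order=2)
        with pytest.raises(NotImplementedError):
            fc.add_robin_interface(system, fc.ElectrodeSpec(
                mk.BOX_FACE_MARKERS["xmin"], "stimulating", FARADAIC, 1.0), 0.0)


@pytest.fixture(scope="module")
def floating_setup(box):
    """Stimulated box with one small floating electrode on the top face."""
    fmk = box.facet_markers.copy()
    cent = box.nodes[box.facets].mean(axis=1)
    sel = ((fmk == mk.BOX_FACE_MARKERS["zmax"])
           & (np.abs(cent[:, 0] - 0.005) < 0.002)
           & (np.abs(cent[:, 1] - 0.005) < 0.003))
    assert sel.any()
    fmk[sel] = 50
    mesh = mk.TetMesh(box.nodes, box.tets, box.cell_markers, box.facets, fmk,
                      {**box.marker_names, 50: "rec"})
    system = fc.assemble_stiffness(mesh, {1: 0.5})
    fc.add_robin_interface(system, fc.ElectrodeSpec(
        mk.BOX_FACE_MARKERS["xmin"], "stimulating", FARADAIC, phi_metal=1.0),
        0.0)
    fc.add_robin_interface(system, fc.ElectrodeSpec(
        mk.BOX_FACE_MARKERS["xmax"], "ground", FARADAIC), 0.0)
    fc.add_floating_electrode(system, fc.ElectrodeSpec(50, "recording",
                                                       FARADAIC), 0.0)
    field = fc.solve(system, method="cg", tol=1e-13, preconditioner="jacobi",
                     max_iter=20000)
    return mesh, system, field


class TestFloatingElectrode:
    def test_constraint_residual(self, floating_setup):
        _, system, field = floating_setup
        fl = system.floating[0]
        phi_m = field.metal_potentials[50]
        avg = fl.mass_row @ field.values / fl.area
        assert abs(phi_m - avg) < 1e-10 * np.abs(field.values).max()

    def test_matches_local_field_value(self, floating_setup):
        mesh, _, field = floating_setup
        patch_nodes = np.unique(mesh.facets[mesh.facet_markers == 50])
        centroid = mesh.nodes[patch_nodes].mean(axis=0)
        local = fc.evaluate(field, centroid[None])[0]
        assert field.metal_potentials[50] == pytest.approx(local, rel=0.01)

    def test_zero_net_current(self, floating_setup):
        _, system, field = floating_setup
        currents = fc.interface_currents(system, field)
        scale = max(abs(v) for v in currents.values())
        assert abs(currents[50]) < 1e-8 * scale

    def test_symmetric_pair_equal_potentials(self):
        # an exactly mirror-symmetric mesh: a half box plus its reflection
        half = mk.box_mesh([0.01, 0.01, 0.01], [5, 5, 5])
        n = half.num_nodes
        mirrored = half.nodes.copy()
        mirrored[:, 0] = 0.02 - mirrored[:, 0]
        nodes = np.vstack([half.nodes, mirrored])
        tets = np.vstack([half.tets, half.tets + n])
        # merge duplicate nodes on the mirror plane x = 0.01
        key = np.round(nodes / 1e-12).astype(np.int64)
        _, uniq_idx, inv = np.unique(key, axis=0, return_index=True,
                                     return_inverse=True)
        mesh = mk.TetMesh(nodes[uniq_idx], inv[tets],
                          np.ones(len(tets), dtype=np.int64))
        mesh.tets = mk._orient_positive(mesh.nodes, mesh.tets)
        bfaces = mesh.boundary_faces()
        cent = mesh.nodes[bfaces].mean(axis=1)
        top = np.abs(cent[:, 2] - 0.01) < 1e-9
        left = top & (np.abs(cent[:, 0] - 0.005) < 0.0021) \
            & (np.abs(cent[:, 1] - 0.005) < 0.003)
        right = top & (np.abs(cent[:, 0] - 0.015) < 0.0021) \
            & (np.abs(cent[:, 1] - 0.005) < 0.003)
        fmkr = np.zeros(len(bfaces), dtype=np.int64)
        fmkr[left] = 51
        fmkr[right] = 52
        mesh.facets = bfaces
        mesh.facet_markers = fmkr
        system = fc.assemble_stiffness(mesh, {1: 0.5})
        # symmetric source: dipole on the mirror plane pointing along z
        src = fc.SourceSpec.dipole((0.01, 0.005, 0.005), (0, 0, 1), 1e-4, 2e-3)
        fc.add_floating_electrode(system, fc.ElectrodeSpec(51, "recording",
                                                           FARADAIC), 0.0)
        fc.add_floating_electrode(system, fc.ElectrodeSpec(52, "recording",
                                                           FARADAIC), 0.0)
        fc.assemble_source_rhs(system, src)
        field = fc.solve(system, method="gmres", tol=1e-13,
                         preconditioner="ilu", max_iter=20000)
        a, b = field.metal_potentials[51], field.metal_potentials[52]
        scale = np.abs(field.values).max()
        assert abs(a - b) < 1e-8 * scale

    def test_wrong_role_rejected(self, box):
        system = fc.assemble_stiffness(box, {1: 0.5})
        with pytest.raises(ValueError, match="recording"):
            fc.add_floating_electrode(system, fc.ElectrodeSpec(
                mk.BOX_FACE_MARKERS["zmax"], "ground", FARADAIC), 0.0)

    def test_missing_marker_rejected(self, box):
        system = fc.assemble_stiffness(box, {1: 0.5})
        with pytest.raises(ValueError, match="marker"):
            fc.add_floating_electrode(system, fc.ElectrodeSpec(
                777, "recording", FARADAIC), 0.0)


class TestSources:
    def test_monopole_at_node(self, ball_tiny):
        system = fc.assemble_stiffness(ball_tiny, {1: 1.0})
        node = 7
        pos = ball_tiny.nodes[node]
        system.zero_mean = False  # suppress imbalance warning path
        fc.assemble_source_rhs(
            system, fc.SourceSpec(monopoles=[(pos, 2e-4)]))
        assert system.rhs[node] == pytest.approx(2e-4, rel=1e-9)
        others = np.abs(np.delete(system.rhs, node))
        assert others.max() < 1e-12 * 2e-4

    def test_dipole_rhs_sums_to_zero(self, ball_tiny):
        system = fc.assemble_stiffness(ball_tiny, {1: 1.0})
        fc.assemble_source_rhs(system, fc.SourceSpec.dipole(
            (0, 0, 0.01), (1, 1, 0), 1e-4, 1e-3))
        assert abs(system.rhs.sum()) < 1e-18

    def test_monopole_at_centroid_quarter_weights(self):
        nodes = np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        mesh = mk.TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([1]))
        system = fc.assemble_stiffness(mesh, {1: 1.0})
        system.zero_mean = False
        fc.assemble_source_rhs(system, fc.SourceSpec(
            monopoles=[(nodes.mean(axis=0), 1.0)]))
        assert np.allclose(system.rhs, 0.25, atol=1e-12)

    def test_point_outside_mesh_raises(self, ball_tiny):
        system = fc.assemble_stiffness(ball_tiny, {1: 1.0})
        with pytest.raises(ValueError, match="outside"):
            fc.assemble_source_rhs(system, fc.SourceSpec(
                monopoles=[((1.0, 1.0, 1.0), 1e-4), ((1.0, 1.0, 1.1), -1e-4)]))

    def test_dipole_moment_property(self):
        src = fc.SourceSpec.dipole((0, 0, 0.05), (1, 0, 0), 100e-6, 1e-3)
        assert np.allclose(src.moment, [1e-7, 0, 0])
        assert src.total_current == 0.0


class TestSolve:
    def test_cg_gmres_agree_on_spd(self, ball_small):
        system = fc.assemble_stiffness(ball_small, {1: 0.33})
        fc.assemble_source_rhs(system, fc.SourceSpec.dipole(
            (0, 0, 0.03), (1, 0, 0)))
        f1 = fc.solve(system, method="cg", tol=1e-11, preconditioner="jacobi")
        f2 = fc.solve(system, method="gmres", tol=1e-11,
                      preconditioner="ilu", max_iter=20000)
        scale = np.abs(f1.values).max()
        assert np.abs(f1.values - f2.values).max() < 1e-8 * scale

    def test_cg_rejected_for_complex_block(self, ball_tiny):
        system = fc.assemble_complex_block(ball_tiny, {1: 1.0 + 0.5j})
        with pytest.raises(ValueError, match="gmres"):
            fc.solve(system, method="cg")

    def test_zero_mean_reference(self, ball_small):
        system = fc.assemble_stiffness(ball_small, {1: 0.33})
        fc.assemble_source_rhs(system, fc.SourceSpec.dipole(
            (0, 0, 0.03), (0, 0, 1)))
        fld = fc.solve(system, method="cg", tol=1e-11,
                       preconditioner="jacobi")
        c = system.volume_weights()
        vol = c.sum()
        assert abs(c @ fld.values) < 1e-10 * np.sqrt(vol) * np.linalg.norm(
            fld.values)

    def test_nonconvergence_raises(self, ball_small):
        system = fc.assemble_stiffness(ball_small, {1: 0.33})
        fc.assemble_source_rhs(system, fc.SourceSpec.dipole(
            (0, 0, 0.03), (1, 0, 0)))
        with pytest.raises(fc.SolverError, match="iterations"):
            fc.solve(system, method="cg", tol=1e-13, max_iter=2,
                     preconditioner=None)


class TestEvaluate:
    def test_nodal_values_reproduced(self, ball_tiny):
        system = fc.assemble_stiffness(ball_tiny, {1: 1.0})
        vals = np.linalg.norm(ball_tiny.nodes, axis=1) ** 2
        field = fc.PotentialField(values=vals, mesh=ball_tiny)
        # strictly interior nodes to avoid boundary-edge ambiguity
        interior = np.setdiff1d(np.arange(ball_tiny.num_nodes),
                                np.unique(ball_tiny.facets))
        got = fc.evaluate(field, ball_tiny.nodes[interior])
        assert np.allclose(got, vals[interior], atol=1e-12)

    def test_linear_field_exact(self, box):
        coeff = np.array([1.5, -2.0, 0.5])
        field = fc.PotentialField(values=box.nodes @ coeff + 0.3, mesh=box)
        rng = np.random.default_rng(1)
        pts = rng.uniform([0.001, 0.001, 0.001], [0.019, 0.009, 0.009],
                          size=(40, 3))
        got = fc.evaluate(field, pts)
        assert np.allclose(got, pts @ coeff + 0.3, atol=1e-12)

    def test_outside_point_raises(self, ball_tiny):
        field = fc.PotentialField(values=np.zeros(ball_tiny.num_nodes),
                                  mesh=ball_tiny)
        with pytest.raises(ValueError, match="outside"):
            fc.evaluate(field, np.array([[1.0, 0.0, 0.0]]))


class TestP2Elements:
    def test_p2_stiffness_unit_tet_vs_quadrature_oracle(self):
        nodes = np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        mesh = mk.TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([1]))
        A = fc.assemble_stiffness(mesh, {1: 1.0}, order=2).operator.toarray()
        assert A.shape == (10, 10)
        # oracle: high-order numeric quadrature of grad(phi_i).grad(phi_j)
        # over the reference tet using a dense random-point Monte Carlo with
        # exact polynomial degree handled by a 3D Gauss grid
        from numpy.polynomial.legendre import leggauss

        xg, wg = leggauss(6)
        xg = 0.5 * (xg + 1)
        wg = 0.5 * wg
        pts, wts = [], []
        for i, xi in enumerate(xg):
            for j, yj in enumerate(xg):
                for k, zk in enumerate(xg):
                    # Duffy transform of the cube onto the tet
                    x = xi
                    y = yj * (1 - x)
                    z = zk * (1 - x - y)
                    w = wg[i] * wg[j] * wg[k] * (1 - x) * (1 - x - y)
                    pts.append((x, y, z))
                    wts.append(w)
        pts = np.asarray(pts)
        wts = np.asarray(wts)
        lam = np.column_stack([1 - pts.sum(axis=1), pts])
        G_lam = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
                         float)
        edges = fc._P2_EDGES
        oracle = np.zeros((10, 10))
        for lam_q, w in zip(lam, wts):
            gv = [(4 * lam_q[i] - 1) * G_lam[i] for i in range(4)]
            ge = [4 * (lam_q[a] * G_lam[b] + lam_q[b] * G_lam[a])
                  for a, b in edges]
            G = np.vstack([gv, ge])
            oracle += w * (G @ G.T)
        assert np.abs(A - oracle).max() < 1e-12

    def test_p2_reproduces_quadratic_interpolation(self, ball_tiny):
        # nodal + edge dofs of a quadratic function evaluate exactly
        edge_ids, edges, n_edges = fc._p2_edge_dofs(ball_tiny)

        def func(p):
            return 2.0 * p[..., 0] ** 2 - p[..., 1] * p[..., 2] + 0.1 * p[..., 0]

        mid = 0.5 * (ball_tiny.nodes[edges[:, 0]] + ball_tiny.nodes[edges[:, 1]])
        vals = np.concatenate([func(ball_tiny.nodes), func(mid)])
        field = fc.PotentialField(values=vals, mesh=ball_tiny, order=2)
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(30, 3))
        pts = pts / np.linalg.norm(pts, axis=1)[:, None] * 0.02
        assert np.allclose(fc.evaluate(field, pts), func(pts), atol=1e-12)

    def test_p2_solution_close_to_fine_p1(self, ball_small):
        src = fc.SourceSpec.dipole((0, 0, 0.03), (1, 0, 0))
        pts = mk.surface_sample_points(0.06, 100)
        s2 = fc.assemble_stiffness(ball_small, {1: 0.33}, order=2)
        fc.assemble_source_rhs(s2, src)
        f2 = fc.solve(s2, method="cg", tol=1e-11, preconditioner="jacobi",
                      max_iter=20000)
        fine = mk.structured_ball_mesh(0.09, 4)
        s1 = fc.assemble_stiffness(fine, {1: 0.33})
        fc.assemble_source_rhs(s1, src)
        f1 = fc.solve(s1, method="cg", tol=1e-11, preconditioner="jacobi")
        a = fc.evaluate(f2, pts)
        b = fc.evaluate(f1, pts)
        a -= a.mean()
        b -= b.mean()
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 0.10
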