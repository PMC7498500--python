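"""Lagrangian FEM assembly and solution on tetrahedral meshes.

Supports P1/P2 elements, scalar or tensor (an)isotropic admittivities,
homogeneous Neumann exterior boundaries, Robin electrode-interface boundary
conditions, floating recording electrodes via Lagrange multipliers, point
monopole/dipole sources, and Krylov solves with a zero-mean reference for
pure-Neumann problems.

Complex admittivities follow the coupled real-PDE (block) formulation: the
complex operator ``A = A_r + j A_j`` acts on ``u = u_r + j u_j`` and is
equivalent to the doubled real system

    [[A_r, -A_j], [A_j, A_r]] [u_r; u_j] = [b_r; b_i]

exposed by :meth:`FemSystem.to_block_operator` and used to verify the
assembly.  Solves exploit the isomorphism and run Krylov iterations on the
complex form, which halves the memory footprint; residuals are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from vcfem.dielectrics import Admittivity
from vcfem.interface_models import InterfaceModel, surface_admittance
from vcfem.meshkit import TetMesh, tet_volumes

__all__ = [
    "SourceSpec",
    "ElectrodeSpec",
    "FemSystem",
    "PotentialField",
    "SolverError",
    "assemble_stiffness",
    "assemble_complex_block",
    "add_robin_interface",
    "add_floating_electrode",
    "assemble_source_rhs",
    "solve",
    "evaluate",
    "interface_currents",
]


# ---------------------------------------------------------------------------
# Sources and electrodes
# ---------------------------------------------------------------------------

@dataclass
class SourceSpec:
    """Point monopole sources: list of ``(position, current)`` pairs.

    A dipole is represented as a +/- monopole pair; use :meth:`dipole`.
    """

    monopoles: list

    @classmethod
    def dipole(cls, position, orientation, current: float = 100e-6,
               separation: float = 1e-3) -> "SourceSpec":
        """Dipole as two opposite monopoles centered on ``position``.

        Defaults: 100 uA monopoles, 1 mm apart.
        """
        p = np.asarray(position, dtype=float)
        d = np.asarray(orientation, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("orientation must be a nonzero vector")
        d = d / nrm
        return cls(monopoles=[
            (p + 0.5 * separation * d, +current),
            (p - 0.5 * separation * d, -current),
        ])

    @property
    def total_current(self) -> float:
        return float(sum(i for _, i in self.monopoles))

    @property
    def moment(self) -> np.ndarray:
        """Dipole moment sum_k I_k x_k (A m)."""
        return np.sum([i * np.asarray(p, float) for p, i in self.monopoles], axis=0)


@dataclass
class ElectrodeSpec:
    """Surface electrode bound to a facet marker.

    ``role`` is ``stimulating`` (``phi_metal`` prescribed), ``ground``
    (``phi_metal = 0``) or ``recording`` (``phi_metal`` is an unknown solved
    via a Lagrange multiplier).
    """

    facet_marker: int
    role: str
    interface: InterfaceModel
    phi_metal: complex = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("stimulating", "recording", "ground"):
            raise ValueError(f"unknown electrode role {self.role!r}")
        if self.role == "ground":
            self.phi_metal = 0.0


# ---------------------------------------------------------------------------
# Element matrices
# ---------------------------------------------------------------------------

def _p1_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Per-cell constant gradients of the 4 barycentric basis functions.

    Returns ``(grads, vols)`` with grads of shape (M, 4, 3).
    """
    M = len(tets)
    A4 = np.ones((M, 4, 4))
    A4[:, :, 1:] = nodes[tets]
    C = np.linalg.inv(A4)          # lambda_j(x) = C[0,j] + C[1:,j] . x
    grads = np.transpose(C[:, 1:4, :], (0, 2, 1))  # (M, 4, 3)
    vols = np.abs(tet_volumes(nodes, tets))
    return grads, vols


# P2 edge local numbering on a tet (pairs of local vertices)
_P2_EDGES = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

# degree-2 quadrature on the reference tet (4 points, weights 1/4)
_QP_A = 0.5854101966249685
_QP_B = 0.1381966011250105
_P2_QPTS = np.array([
    [_QP_A, _QP_B, _QP_B, _QP_B],
    [_QP_B, _QP_A, _QP_B, _QP_B],
    [_QP_B, _QP_B, _QP_A, _QP_B],
    [_QP_B, _QP_B, _QP_B, _QP_A],
])


def _p2_edge_dofs(mesh: TetMesh):
    """Global edge dof numbering for P2: returns (edge_ids (M,6), edges, count)."""
    tets = mesh.tets
    edges = np.concatenate([tets[:, [a, b]] for a, b in _P2_EDGES])
    edges = np.sort(edges, axis=1)
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    edge_ids = inv.reshape(6, len(tets)).T
    return edge_ids, uniq, len(uniq)


def _p2_basis(lam: np.ndarray) -> np.ndarray:
    """P2 basis values from barycentric coordinates lam (..., 4) -> (..., 10)."""
    lam = np.asarray(lam, dtype=float)
    vert = lam * (2.0 * lam - 1.0)
    edge = np.stack([4.0 * lam[..., a] * lam[..., b] for a, b in _P2_EDGES], axis=-1)
    return np.concatenate([vert, edge], axis=-1)


def _cell_values(mesh: TetMesh, material_map: Mapping):
    """Per-cell complex scalar values and optional (M,3,3) tensors."""
    markers = np.unique(mesh.cell_markers)
    for m in markers:
        if int(m) not in material_map:
            raise KeyError(f"no material mapped for cell marker {int(m)}")
    scalars = np.zeros(mesh.num_cells, dtype=complex)
    tensors = None
    for m, val in material_map.items():
        sel = mesh.cell_markers == m
        if not sel.any():
            continue
        if isinstance(val, Admittivity):
            val = val.value
        val = np.asarray(val)
        if val.ndim == 2:
            if tensors is None:
                tensors = np.eye(3)[None] * scalars[:, None, None]
            tensors[sel] = val
        else:
            if tensors is not None:
                tensors[sel] = np.eye(3) * complex(val)
            else:
                scalars[sel] = complex(val)
    return scalars, tensors


def _assemble_volume(mesh: TetMesh, material_map: Mapping, order: int) -> sp.csr_matrix:
    """Complex stiffness matrix ``int y grad(u).grad(v) dx`` (P1 or P2)."""
    grads, vols = _p1_gradients(mesh.nodes, mesh.tets)
    if np.any(vols <= 0):
        raise ValueError("mesh contains zero-volume cells")
    scalars, tensors = _cell_values(mesh, material_map)

    if order == 1:
        if tensors is None:
            yg = scalars[:, None, None] * grads
        else:
            yg = np.einsum("mab,mjb->mja", tensors, grads)
        Ke = np.einsum("mia,mja->mij", grads, yg) * vols[:, None, None]
        conn = mesh.tets
        ndof = mesh.num_nodes
    elif order == 2:
        edge_ids, _, n_edges = _p2_edge_dofs(mesh)
        conn = np.concatenate([mesh.tets, mesh.num_nodes + edge_ids], axis=1)
        ndof = mesh.num_nodes + n_edges
        Ke = np.zeros((mesh.num_cells, 10, 10), dtype=complex)
        for lam in _P2_QPTS:
            gv = (4.0 * lam[None, :, None] - 1.0) * grads  # vertex functions
            ge = np.stack([
                4.0 * (lam[a] * grads[:, b, :] + lam[b] * grads[:, a, :])
                for a, b in _P2_EDGES
            ], axis=1)
            G = np.concatenate([gv, ge], axis=1)
            if tensors is None:
                yG = scalars[:, None, None] * G
            else:
                yG = np.einsum("mab,mjb->mja", tensors, G)
            Ke += 0.25 * np.einsum("mia,mja->mij", G, yG)
        Ke *= vols[:, None, None]
    else:
        raise ValueError("element order must be 1 or 2")

    n_loc = conn.shape[1]
    rows = np.repeat(conn, n_loc, axis=1).ravel()
    cols = np.tile(conn, (1, n_loc)).ravel()
    return sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()


def _volume_dof_weights(mesh: TetMesh, order: int, ndof: int) -> np.ndarray:
    """Weights c_i = int phi_i dx, for the zero-mean reference."""
    vols = np.abs(mesh.volumes())
    c = np.zeros(ndof)
    if order == 1:
        np.add.at(c, mesh.tets.ravel(), np.repeat(vols / 4.0, 4))
    else:
        edge_ids, _, _ = _p2_edge_dofs(mesh)
        # int of P2 vertex basis = -V/20; edge basis = V/5
        np.add.at(c, mesh.tets.ravel(), np.repeat(-vols / 20.0, 4))
        np.add.at(c, (mesh.num_nodes + edge_ids).ravel(), np.repeat(vols / 5.0, 6))
    return c


# ---------------------------------------------------------------------------
# System container
# ---------------------------------------------------------------------------

@dataclass
class _FloatingElectrode:
    spec: ElectrodeSpec
    dof: int               # index of the phi_metal unknown
    y_s: complex
    mass_row: np.ndarray   # m_i = int phi_i ds over the electrode
    area: float


@dataclass
class _BoundElectrode:
    spec: ElectrodeSpec
    y_s: complex
    mass_row: np.ndarray
    area: float


@dataclass
class FemSystem:
    """Assembled FEM operator, right-hand side and constraints.

    ``mode`` is ``"real"`` (purely resistive) or ``"complex_block"`` (complex
    admittivity in the coupled real-PDE representation).  The operator is held
    in its complex ``A_r + j A_j`` form; :meth:`to_block_operator` returns the
    equivalent doubled real block matrix.
    """

    mesh: TetMesh
    mode: str
    order: int
    n_nodes: int
    ndof: int              # field dofs (nodes for P1; nodes+edges for P2)
    operator: sp.csr_matrix
    rhs: np.ndarray
    zero_mean: bool = True
    floating: list = field(default_factory=list)
    bound_electrodes: list = field(default_factory=list)

    @property
    def has_robin(self) -> bool:
        return bool(self.bound_electrodes) or bool(self.floating)

    @property
    def total_dofs(self) -> int:
        return self.ndof + len(self.floating)

    def full_matrix(self) -> sp.csr_matrix:
        """Operator including floating-electrode borders (complex form)."""
        if not self.floating:
            return self.operator
        n = self.total_dofs
        dtype = complex if self.mode == "complex_block" else float
        rows, cols, data = [], [], []
        for fl in self.floating:
            m = (fl.y_s * fl.mass_row) if dtype is complex else \
                (fl.y_s.real * fl.mass_row)
            nz = np.flatnonzero(m)
            rows += [nz, np.full(len(nz), fl.dof), [fl.dof]]
            cols += [np.full(len(nz), fl.dof), nz, [fl.dof]]
            yS = fl.y_s * fl.area if dtype is complex else fl.y_s.real * fl.area
            data += [-m[nz], -m[nz], [yS]]
        border = sp.coo_matrix(
            (np.concatenate(data),
             (np.concatenate([np.asarray(r) for r in rows]),
              np.concatenate([np.asarray(c) for c in cols]))),
            shape=(n, n), dtype=dtype)
        A = sp.lil_matrix((n, n), dtype=self.operator.dtype)
        A[: self.ndof, : self.ndof] = self.operator
        return (A.tocsr() + border.tocsr()).tocsr()

    def full_rhs(self) -> np.ndarray:
        b = np.zeros(self.total_dofs, dtype=self.rhs.dtype)
        b[: self.ndof] = self.rhs
        return b

    def to_block_operator(self) -> tuple[sp.csr_matrix, np.ndarray]:
        """Doubled real block system [[A_r, -A_j], [A_j, A_r]], [b_r; b_i]."""
        A = self.full_matrix().astype(complex)
        b = self.full_rhs().astype(complex)
        Ar, Aj = A.real.tocsr(), A.imag.tocsr()
        block = sp.bmat([[Ar, -Aj], [Aj, Ar]], format="csr")
        return block, np.concatenate([b.real, b.imag])

    def volume_weights(self) -> np.ndarray:
        return _volume_dof_weights(self.mesh, self.order, self.ndof)


def assemble_stiffness(mesh: TetMesh, material_map: Mapping, order: int = 1) -> FemSystem:
    """Assemble the real stiffness system ``int sigma grad u . grad v dx``.

    ``material_map`` maps each cell marker to a real conductivity (scalar,
    3x3 tensor, or an :class:`Admittivity` with zero imaginary part).  The
    result is symmetric positive-semidefinite with the constants as nullspace
    under pure Neumann conditions.
    """
    A = _assemble_volume(mesh, material_map, order)
    if np.abs(A.imag).max() > 0:
        raise ValueError(
            "material map has a nonzero imaginary part; use assemble_complex_block"
        )
    A = sp.csr_matrix(A.real)
    ndof = A.shape[0]
    return FemSystem(mesh=mesh, mode="real", order=order, n_nodes=mesh.num_nodes,
                     ndof=ndof, operator=A.astype(float),
                     rhs=np.zeros(ndof, dtype=float))


def assemble_complex_block(mesh: TetMesh, material_map: Mapping, order: int = 1) -> FemSystem:
    """Assemble the complex-admittivity system in the coupled-block form.

    The operator is stored as ``A_r + j A_j``; the equivalent doubled real
    matrix with blocks ``[[A_r, -A_j], [A_j, A_r]]`` is available through
    :meth:`FemSystem.to_block_operator`.  With ``y_j = 0`` everywhere the
    block solve decouples into two copies of the real system.
    """
    A = _assemble_volume(mesh, material_map, order)
    ndof = A.shape[0]
    return FemSystem(mesh=mesh, mode="complex_block", order=order,
                     n_nodes=mesh.num_nodes, ndof=ndof, operator=A.astype(complex),
                     rhs=np.zeros(ndof, dtype=complex))


# ---------------------------------------------------------------------------
# Robin interfaces and floating electrodes
# ---------------------------------------------------------------------------

def _facet_mass(mesh: TetMesh, marker: int, ndof: int):
    """Facet mass matrix (coo parts), row integrals m_i and total area."""
    faces = mesh.facets_with_marker(marker)
    if len(faces) == 0:
        raise ValueError(f"no facets with marker {marker}")
    v = mesh.nodes[faces]
    areas = 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)
    # P1 triangle mass matrix: area/12 * (1 + delta_ij)
    Me = (np.ones((3, 3)) + np.eye(3)) / 12.0
    data = (areas[:, None, None] * Me).ravel()
    rows = np.repeat(faces, 3, axis=1).ravel()
    cols = np.tile(faces, (1, 3)).ravel()
    m = np.zeros(ndof)
    np.add.at(m, faces.ravel(), np.repeat(areas / 3.0, 3))
    return (data, rows, cols), m, float(areas.sum())


def _robin_parts(system: FemSystem, electrode: ElectrodeSpec, f: float):
    if system.order != 1:
        raise NotImplementedError("Robin interfaces are implemented for P1 elements")
    y_s = complex(surface_admittance(electrode.interface, f))
    if system.mode == "real" and abs(y_s.imag) > 0:
        raise ValueError("complex surface admittance requires complex_block mode")
    parts, m, area = _facet_mass(system.mesh, electrode.facet_marker, system.ndof)
    return y_s, parts, m, area


def add_robin_interface(system: FemSystem, electrode: ElectrodeSpec, f: float) -> None:
    """Add the Robin interface terms of one electrode at frequency ``f``.

    Stimulating/ground electrodes contribute ``y_k``-weighted facet mass
    terms to the operator and ``y_k phi_metal`` terms to the rhs.  Recording
    electrodes are delegated to :func:`add_floating_electrode`.
    """
    if electrode.role == "recording":
        add_floating_electrode(system, electrode, f)
        return
    y_s, (data, rows, cols), m, area = _robin_parts(system, electrode, f)
    dtype = system.operator.dtype
    y_cast = y_s if dtype == complex else y_s.real
    upd = sp.coo_matrix(((y_cast * data).astype(dtype), (rows, cols)),
                        shape=system.operator.shape)
    system.operator = (system.operator + upd.tocsr()).tocsr()
    system.rhs = system.rhs + np.asarray(y_cast * electrode.phi_metal * m,
                                         dtype=system.rhs.dtype)
    system.bound_electrodes.append(_BoundElectrode(electrode, y_s, m, area))
    system.zero_mean = False


def add_floating_electrode(system: FemSystem, electrode: ElectrodeSpec, f: float) -> None:
    """Add a floating (recording) electrode at frequency ``f``.

    Introduces one scalar unknown ``phi_metal`` coupled through the Robin
    terms, plus the constraint ``phi_metal = (1/S) int_S phi dS`` (scaled to
    keep the bordered operator symmetric).  The constraint equivalently
    enforces zero net interface current through the electrode.
    """
    if electrode.role != "recording":
        raise ValueError("floating electrodes must have role 'recording'")
    y_s, (data, rows, cols), m, area = _robin_parts(system, electrode, f)
    if area <= 0:
        raise ValueError(f"electrode marker {electrode.facet_marker} has zero area")
    dtype = system.operator.dtype
    y_cast = y_s if dtype == complex else y_s.real
    upd = sp.coo_matrix(((y_cast * data).astype(dtype), (rows, cols)),
                        shape=system.operator.shape)
    system.operator = (system.operator + upd.tocsr()).tocsr()
    dof = system.ndof + len(system.floating)
    system.floating.append(_FloatingElectrode(electrode, dof, y_s, m, area))
    system.zero_mean = False


# ---------------------------------------------------------------------------
# Sources
# ---------------------------------------------------------------------------

class _PointLocator:
    """Locate points in a tet mesh via a centroid KD-tree + barycentric test."""

    def __init__(self, mesh: TetMesh):
        self.mesh = mesh
        self.tree = cKDTree(mesh.centroids())
        M = mesh.num_cells
        A4 = np.ones((M, 4, 4))
        A4[:, :, 1:] = mesh.nodes[mesh.tets]
        self.C = np.linalg.inv(A4)  # lambda_j(x) = C[0,j] + C[1:,j] . x

    def locate(self, pts: np.ndarray, tol: float = 1e-8,
               nearest: bool = False):
        """Containing cell + barycentric coords per point.

        With ``nearest=True``, points slightly outside the mesh (within about
        half a cell of the surface) are assigned to the best candidate cell
        with clipped barycentric coordinates instead of raising.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        n = len(pts)
        cells = np.full(n, -1, dtype=np.int64)
        lams = np.zeros((n, 4))
        pending = np.arange(n)
        accept = tol if not nearest else 0.5
        for k in (8, 64, 512):
            if not len(pending):
                break
            kk = min(k, self.mesh.num_cells)
            _, cand = self.tree.query(pts[pending], k=kk)
            cand = cand.reshape(len(pending), kk)
            C = self.C[cand]                     # (p, kk, 4, 4)
            lam = C[:, :, 0, :] + np.einsum("pa,pkaj->pkj", pts[pending], C[:, :, 1:, :])
            worst = lam.min(axis=2)              # (p, kk)
            best = worst.argmax(axis=1)
            thr = -tol if k < 512 else -accept
            ok = worst[np.arange(len(pending)), best] >= thr
            sel = pending[ok]
            cells[sel] = cand[ok, best[ok]]
            lam_best = lam[np.arange(len(pending)), best][ok]
            lam_best = np.clip(lam_best, 0.0, None)
            lams[sel] = lam_best / lam_best.sum(axis=1, keepdims=True)
            pending = pending[~ok]
        if len(pending):
            raise ValueError(
                f"{len(pending)} point(s) outside the mesh, first: "
                f"{pts[pending[0]].tolist()}"
            )
        return cells, lams


def assemble_source_rhs(system: FemSystem, source: SourceSpec) -> None:
    """Add point-monopole contributions ``I * phi_i(x0)`` to the rhs.

    Basis-evaluation (barycentric) distribution: accuracy is independent of
    node placement.  For a closed dipole the rhs entries sum to zero exactly.
    """
    loc = _PointLocator(system.mesh)
    positions = np.asarray([p for p, _ in source.monopoles], dtype=float)
    currents = np.asarray([i for _, i in source.monopoles], dtype=float)
    if system.zero_mean and not system.has_robin and \
            abs(currents.sum()) > 1e-12 * (np.abs(currents).sum() + 1e-300):
        import warnings

        warnings.warn("source currents do not sum to zero; the pure-Neumann "
                      "problem is inconsistent", stacklevel=2)
    cells, lams = loc.locate(positions)
    b = np.zeros(system.ndof, dtype=system.rhs.dtype)
    if system.order == 1:
        for c, lam, cur in zip(cells, lams, currents):
            b[system.mesh.tets[c]] += cur * lam
    else:
        edge_ids, _, _ = _p2_edge_dofs(system.mesh)
        for c, lam, cur in zip(cells, lams, currents):
            conn = np.concatenate([system.mesh.tets[c],
                                   system.n_nodes + edge_ids[c]])
            b[conn] += cur * _p2_basis(lam)
    system.rhs = system.rhs + b


# ---------------------------------------------------------------------------
# Solution
# ---------------------------------------------------------------------------

@dataclass
class PotentialField:
    """Nodal potential solution (complex or real volts).

    ``values`` covers the field dofs; ``metal_potentials`` maps the facet
    marker of each floating electrode to its solved ``phi_metal``.
    """

    values: np.ndarray
    mesh: TetMesh
    order: int = 1
    metal_potentials: dict = field(default_factory=dict)
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("potential field contains non-finite values")


class SolverError(RuntimeError):
    pass


def _make_preconditioner(A: sp.csr_matrix, kind: str | None, singular: bool = False):
    if kind in (None, "none"):
        return None
    if kind == "jacobi":
        d = A.diagonal()
        d = np.where(np.abs(d) > 0, d, 1.0)
        inv = 1.0 / d
        return spla.LinearOperator(A.shape, matvec=lambda x: inv * x, dtype=A.dtype)
    if kind == "ilu":
        n = A.shape[0]
        B = A
        if singular:
            # pin one dof before factoring: a pure-Neumann operator is
            # singular and a near-singular incomplete factorization would
            # amplify nullspace noise and stall the Krylov iteration.  The
            # pinned factorization has a bounded inverse and, wrapped in the
            # constants-orthogonal projection, preconditions the projected
            # operator well.
            mask = np.ones(n)
            mask[0] = 0.0
            D = sp.diags(mask)
            B = (D @ A @ D + np.abs(A.diagonal()).mean()
                 * sp.coo_matrix(([1.0], ([0], [0])), shape=A.shape)).tocsr()
        # symmetric mode keeps the incomplete factorization (close to)
        # symmetric so it remains a valid CG preconditioner
        ilu = spla.spilu(sp.csc_matrix(B), drop_tol=1e-5, fill_factor=12.0,
                         diag_pivot_thresh=0.0, permc_spec="MMD_AT_PLUS_A",
                         options={"SymmetricMode": True})
        return spla.LinearOperator(A.shape, matvec=ilu.solve, dtype=A.dtype)
    raise ValueError(f"unknown preconditioner {kind!r}")


def solve(system: FemSystem, method: str = "cg", tol: float = 1e-8,
          max_iter: int = 5000, preconditioner: str | None = "jacobi") -> PotentialField:
    """Solve the assembled system with a Krylov method.

    ``cg`` is valid for real symmetric (positive semi-definite) systems only;
    ``complex_block`` systems must use ``gmres``.  Pure-Neumann systems are
    solved in the constants-orthogonal complement and the returned field is
    shifted to a volume-weighted zero mean (average-zero reference).
    """
    if method not in ("cg", "gmres"):
        raise ValueError(f"unknown method {method!r}")
    if system.mode == "complex_block" and method == "cg":
        raise ValueError(
            "the conjugate gradient method does not converge for the "
            "complex-block system; use method='gmres'"
        )
    if method == "cg" and preconditioner == "ilu":
        # the incomplete LU factors are not symmetric, which silently breaks
        # CG; pair ILU with GMRES or use the (symmetric) Jacobi scaling
        raise ValueError("the ILU preconditioner is not symmetric; use "
                         "method='gmres' or preconditioner='jacobi' with cg")
    A = system.full_matrix()
    b = system.full_rhs()

    pure_neumann = not system.has_robin
    M = _make_preconditioner(A, preconditioner, singular=pure_neumann)
    if pure_neumann:
        # constants span the nullspace: the rhs must be consistent
        incomp = abs(np.sum(b)) / (np.linalg.norm(b) + 1e-300)
        if incomp > 1e-8:
            import warnings

            warnings.warn(
                f"pure-Neumann rhs is inconsistent (relative imbalance "
                f"{incomp:.2e}); solve may stagnate", stacklevel=2
            )
        # iterate in the constants-orthogonal complement: wrap the operator
        # and preconditioner with the orthogonal projection P v = v - mean(v)
        # so Krylov methods see a nonsingular symmetric operator P A P
        n = A.shape[0]

        def _proj(v):
            return v - v.mean()

        b = _proj(b)
        A_op = spla.LinearOperator(A.shape, dtype=A.dtype,
                                   matvec=lambda v: _proj(A @ _proj(v)))
        if M is not None:
            M_inner = M
            M = spla.LinearOperator(A.shape, dtype=A.dtype,
                                    matvec=lambda v: _proj(M_inner @ _proj(v)))
    else:
        A_op = A

    it_count = [0]

    def callback(_):
        it_count[0] += 1

    if method == "cg":
        x, info_code = spla.cg(A_op, b, rtol=tol, maxiter=max_iter, M=M,
                               callback=callback)
    else:
        x, info_code = spla.gmres(A_op, b, rtol=tol, maxiter=max_iter, M=M,
                                  restart=200, callback=callback,
                                  callback_type="pr_norm")
    res = float(np.linalg.norm(b - A_op @ x) / (np.linalg.norm(b) + 1e-300))
    if info_code != 0 and res > 10 * tol:
        raise SolverError(
            f"{method} did not converge: info={info_code}, relative residual "
            f"{res:.3e} after {it_count[0]} iterations"
        )

    u = x[: system.ndof]
    if pure_neumann and system.zero_mean:
        c = system.volume_weights()
        u = u - (c @ u) / c.sum()
    metal = {}
    for fl in system.floating:
        val = x[fl.dof]
        metal[fl.spec.facet_marker] = (complex(val) if system.mode == "complex_block"
                                       else float(np.real(val)))
    if system.mode == "real":
        u = np.real(u)
    return PotentialField(values=u, mesh=system.mesh, order=system.order,
                          metal_potentials=metal,
                          info={"iterations": it_count[0], "residual": res,
                                "method": method})


def evaluate(field: PotentialField, points, nearest: bool = False) -> np.ndarray:
    """Evaluate the FEM solution at arbitrary points (barycentric interp).

    ``nearest=True`` tolerates points marginally outside the mesh (e.g., on
    a curved boundary approximated by chords) by clipping to the best cell.
    """
    loc = _PointLocator(field.mesh)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cells, lams = loc.locate(pts, nearest=nearest)
    mesh = field.mesh
    if field.order == 1:
        vals = np.einsum("pj,pj->p", field.values[mesh.tets[cells]], lams)
    else:
        edge_ids, _, _ = _p2_edge_dofs(mesh)
        conn = np.concatenate([mesh.tets[cells],
                               mesh.num_nodes + edge_ids[cells]], axis=1)
        vals = np.einsum("pj,pj->p", field.values[conn], _p2_basis(lams))
    return vals


def interface_currents(system: FemSystem, field: PotentialField) -> dict:
    """Net interface current ``int y (phi - phi_metal) ds`` per electrode.

    Keys are facet markers.  Kirchhoff: the values sum to zero (up to solver
    tolerance) when no volume sources inject current.
    """
    out = {}
    u = field.values
    for be in system.bound_electrodes:
        out[be.spec.facet_marker] = complex(
            be.y_s * (be.mass_row @ u - be.area * be.spec.phi_metal)
        )
    for fl in system.floating:
        phi_m = field.metal_potentials[fl.spec.facet_marker]
        out[fl.spec.facet_marker] = complex(
            fl.y_s * (fl.mass_row @ u - fl.area * phi_m)
        )
    return out
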