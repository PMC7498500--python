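"""Tetrahedral mesh data model, synthetic fixture generation and MSH I/O.

The mesh generators here build desk-scale fixtures (layered spheres for head
models, a slab-in-bath cylinder for micro-electrode arrays) from graded point
clouds tetrahedralized with scipy's Delaunay.  Subdomains are classified
geometrically and interface/exterior facets are tagged with integer markers.
All generation is deterministic for a fixed seed.

Units are SI (meters) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "TetMesh",
    "SphereLayerSpec",
    "generate_layered_sphere_mesh",
    "generate_slab_in_bath_mesh",
    "box_mesh",
    "structured_ball_mesh",
    "red_refine_uniform",
    "refine",
    "extract_submesh",
    "read_msh",
    "write_msh",
    "write_vtk",
    "surface_sample_points",
    "tet_volumes",
    "tet_inradii",
]

EXTERIOR_MARKER = 100


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra."""
    v = nodes[tets]
    a = v[:, 1] - v[:, 0]
    b = v[:, 2] - v[:, 0]
    c = v[:, 3] - v[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def _face_areas(nodes: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v = nodes[faces]
    return 0.5 * np.linalg.norm(
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
    )


def tet_inradii(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Inradius of each tet, defined as 3 V / (sum of face areas)."""
    vol = np.abs(tet_volumes(nodes, tets))
    total = np.zeros(len(tets))
    for combo in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
        total += _face_areas(nodes, tets[:, combo])
    return 3.0 * vol / total


def _orient_positive(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap two vertices of negatively oriented tets."""
    tets = tets.copy()
    neg = tet_volumes(nodes, tets) < 0
    tets[neg, 2], tets[neg, 3] = tets[neg, 3].copy(), tets[neg, 2].copy()
    return tets


_FACE_COMBOS = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))


def _all_faces(tets: np.ndarray) -> np.ndarray:
    """All 4M faces (sorted within face) of an (M,4) tet array."""
    faces = np.concatenate([tets[:, c] for c in _FACE_COMBOS])
    return np.sort(faces, axis=1)


# ---------------------------------------------------------------------------
# Mesh data model
# ---------------------------------------------------------------------------

@dataclass
class TetMesh:
    """Tetrahedral mesh with subdomain and facet markers.

    Attributes
    ----------
    nodes : (N, 3) float array
        Node coordinates in meters.
    tets : (M, 4) int array
        Four node indices per cell, positively oriented.
    cell_markers : (M,) int array
        Subdomain id per tet.
    facets : (K, 3) int array
        Marked triangular facets (exterior boundary and interface patches).
    facet_markers : (K,) int array
        Integer id per marked facet.
    marker_names : dict
        Map from marker id to a human-readable label.
    """

    nodes: np.ndarray
    tets: np.ndarray
    cell_markers: np.ndarray
    facets: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    facet_markers: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    marker_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.cell_markers = np.ascontiguousarray(self.cell_markers, dtype=np.int64)
        self.facets = np.ascontiguousarray(self.facets, dtype=np.int64).reshape(-1, 3)
        self.facet_markers = np.ascontiguousarray(self.facet_markers, dtype=np.int64)

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_cells(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets)

    def inradii(self) -> np.ndarray:
        return tet_inradii(self.nodes, self.tets)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def facet_areas(self) -> np.ndarray:
        return _face_areas(self.nodes, self.facets)

    def facets_with_marker(self, marker: int) -> np.ndarray:
        return self.facets[self.facet_markers == marker]

    def boundary_faces(self) -> np.ndarray:
        """Faces belonging to exactly one tet (the topological boundary)."""
        faces = _all_faces(self.tets)
        uniq, counts = np.unique(faces, axis=0, return_counts=True)
        return uniq[counts == 1]

    def validate(self, node_tol: float = 1e-12) -> None:
        """Check mesh invariants; raises ``ValueError`` on violation."""
        if self.tets.min(initial=0) < 0 or self.tets.max(initial=-1) >= self.num_nodes:
            raise ValueError("tet node index out of range")
        if len(self.cell_markers) != self.num_cells:
            raise ValueError("cell_markers must cover all tets")
        vols = self.volumes()
        if np.any(vols <= 0):
            raise ValueError(f"{int(np.sum(vols <= 0))} tets with non-positive volume")
        if len(self.facets) != len(self.facet_markers):
            raise ValueError("facet_markers length mismatch")
        if len(self.facets):
            all_faces = {tuple(f) for f in _all_faces(self.tets)}
            for f in np.sort(self.facets, axis=1):
                if tuple(f) not in all_faces:
                    raise ValueError(f"marked facet {tuple(f)} is not a face of any tet")
        # duplicate nodes within tolerance
        if self.num_nodes > 1:
            tree = cKDTree(self.nodes)
            pairs = tree.query_pairs(node_tol)
            if pairs:
                raise ValueError(f"duplicate nodes within {node_tol}: {sorted(pairs)[:5]}")

    def with_facets(self, facets: np.ndarray, markers: np.ndarray, names=None) -> "TetMesh":
        m = replace(self, facets=facets, facet_markers=markers)
        if names:
            m.marker_names = {**self.marker_names, **names}
        return m


# ---------------------------------------------------------------------------
# Quasi-uniform sphere sampling
# ---------------------------------------------------------------------------

def _fibonacci_unit_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = 2.0 * np.pi * i * (2.0 / (1.0 + np.sqrt(5.0)))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def surface_sample_points(radius: float, n: int) -> np.ndarray:
    """n deterministic quasi-uniform sample points on a sphere of ``radius``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    return radius * _fibonacci_unit_sphere(n)


def _sphere_lattice(radius: float, spacing: float) -> np.ndarray:
    """Fibonacci lattice on a sphere with approximate point spacing."""
    n = max(6, int(round(4.6 * np.pi * radius**2 / spacing**2)))
    return radius * _fibonacci_unit_sphere(n)


# ---------------------------------------------------------------------------
# Layered sphere fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereLayerSpec:
    """Specification of a concentric layered-sphere mesh.

    ``radii`` list the layer boundaries inner to outer; ``edge_length`` is the
    target edge length per layer (scalar broadcasts).  ``refine_region`` is an
    optional ``(center, radius, min_inradius)`` ball in which the mesh is
    graded down to roughly ``4 * min_inradius`` edge length.
    """

    radii: tuple
    layer_markers: tuple = ()
    edge_length: object = None
    refine_region: tuple | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if len(r) < 1 or np.any(np.diff(r) <= 0) or r[0] <= 0:
            raise ValueError("radii must be positive and strictly increasing")
        object.__setattr__(self, "radii", tuple(float(x) for x in r))
        markers = self.layer_markers or tuple(range(1, len(r) + 1))
        if len(markers) != len(r):
            raise ValueError("layer_markers must match radii")
        object.__setattr__(self, "layer_markers", tuple(int(m) for m in markers))
        h = self.edge_length
        if h is None:
            h = 0.1 * float(r[-1])
        h = np.broadcast_to(np.asarray(h, dtype=float), (len(r),)).copy()
        if np.any(h <= 0):
            raise ValueError("edge_length must be positive")
        object.__setattr__(self, "edge_length", tuple(float(x) for x in h))
        if self.refine_region is not None:
            center, rad, min_ir = self.refine_region
            if min_ir >= min(self.edge_length):
                raise ValueError("refine_region min_inradius must be < edge_length")
            object.__setattr__(
                self,
                "refine_region",
                (tuple(float(c) for c in center), float(rad), float(min_ir)),
            )


_GRADING_SLOPE = 0.7


def _sizing_target(pts: np.ndarray, h_coarse, refine_region) -> np.ndarray:
    """Graded sizing: fine inside the refine ball, linear growth outside."""
    h = np.broadcast_to(np.asarray(h_coarse, dtype=float), (len(pts),)).copy()
    if refine_region is None:
        return h
    center, rad, min_ir = refine_region
    h_fine = 4.0 * min_ir
    d = np.linalg.norm(pts - np.asarray(center), axis=1) - rad
    return np.minimum(h, np.maximum(h_fine, h_fine + _GRADING_SLOPE * np.maximum(d, 0.0)))


def _level_filter(level_h: float, h_fine: float, h_target: np.ndarray,
                  n_levels: int) -> np.ndarray:
    """Keep points whose graded target size maps onto this level's spacing."""
    lev = np.clip(np.round(np.log2(np.maximum(h_target, h_fine) / h_fine)),
                  0, n_levels - 1)
    this = int(round(np.log2(level_h / h_fine)))
    return lev == this


def _graded_sphere_points(radius: float, h_coarse: float, refine_region,
                          rng: np.random.Generator) -> np.ndarray:
    """Points on a sphere surface, graded toward the refine region."""

    def tangential_jitter(pts, scale):
        jitter = rng.normal(scale=scale, size=pts.shape)
        nrm = pts / radius
        jitter -= (jitter * nrm).sum(axis=1, keepdims=True) * nrm
        return pts + jitter

    if refine_region is None:
        return tangential_jitter(_sphere_lattice(radius, h_coarse), 0.08 * h_coarse)
    center, rad, min_ir = refine_region
    h_fine = min(4.0 * min_ir, h_coarse)
    n_levels = max(1, int(np.ceil(np.log2(h_coarse / h_fine))) + 1)
    out = []
    for lev in range(n_levels):
        h_l = min(h_fine * 2.0**lev, h_coarse)
        pts = _sphere_lattice(radius, h_l)
        h_tgt = _sizing_target(pts, h_coarse, refine_region)
        keep = _level_filter(h_l, h_fine, h_tgt, n_levels)
        if lev == n_levels - 1:
            keep |= h_tgt >= h_l
        pts = pts[keep]
        if len(pts):
            out.append(tangential_jitter(pts, 0.08 * h_l))
    return np.concatenate(out) if out else np.zeros((0, 3))


def _graded_volume_points(bbox_lo, bbox_hi, inside: Callable, h_coarse_of: Callable,
                          refine_region, rng: np.random.Generator,
                          h_coarse_max: float) -> np.ndarray:
    """Hierarchical jittered grids filtered by a graded sizing field."""
    if refine_region is None:
        h_fine = h_coarse_max
        n_levels = 1
    else:
        h_fine = min(4.0 * refine_region[2], h_coarse_max)
        n_levels = max(1, int(np.ceil(np.log2(h_coarse_max / h_fine))) + 1)
    out = []
    for lev in range(n_levels):
        h_l = min(h_fine * 2.0**lev, h_coarse_max)
        if lev < n_levels - 1 and refine_region is not None:
            # fine levels only live near the refine ball: restrict the grid
            center, rad, _ = refine_region
            reach = rad + (h_l * 2.0 - h_fine) / _GRADING_SLOPE + 2 * h_l
            lo = np.maximum(np.asarray(bbox_lo, float), np.asarray(center) - reach)
            hi = np.minimum(np.asarray(bbox_hi, float), np.asarray(center) + reach)
        else:
            lo, hi = np.asarray(bbox_lo, float), np.asarray(bbox_hi, float)
        if np.any(hi <= lo):
            continue
        axes = [np.arange(lo[k] + 0.5 * h_l, hi[k], h_l) for k in range(3)]
        if any(len(a) == 0 for a in axes):
            continue
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        grid = grid + rng.uniform(-0.25 * h_l, 0.25 * h_l, size=grid.shape)
        grid = grid[inside(grid)]
        if not len(grid):
            continue
        h_c = h_coarse_of(grid)
        h_tgt = _sizing_target(grid, h_c, refine_region)
        sel = _level_filter(h_l, h_fine, h_tgt, n_levels)
        if lev == n_levels - 1:
            # local coarse cap may exceed the finest spacing but undershoot
            # the top level; claim leftovers at the coarsest level
            sel |= h_tgt >= h_l
        out.append(grid[sel])
    return np.concatenate(out) if out else np.zeros((0, 3))


def _delaunay_mesh(points: np.ndarray, min_quality: float = 2e-3) -> np.ndarray:
    """Delaunay tetrahedralization; drops degenerate sliver tets."""
    tri = Delaunay(points)
    tets = _orient_positive(points, tri.simplices.astype(np.int64))
    vols = tet_volumes(points, tets)
    tets = tets[vols > 0]
    ir = tet_inradii(points, tets)
    edge = np.linalg.norm(points[tets[:, 1]] - points[tets[:, 0]], axis=1)
    return tets[ir > min_quality * edge]


def generate_layered_sphere_mesh(spec: SphereLayerSpec, seed: int = 0) -> TetMesh:
    """Generate a concentric layered-sphere tetrahedral mesh.

    Layers are tagged with ``spec.layer_markers`` (inner to outer), the
    outermost surface facets with the exterior marker and each internal layer
    interface with its own facet marker (``marker_names`` maps ids to
    ``"interface_<i>_<i+1>"`` labels).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    radii = np.asarray(spec.radii, dtype=float)
    h = np.asarray(spec.edge_length, dtype=float)
    R = radii[-1]
    region = spec.refine_region

    pts = []
    # interface + exterior surface lattices (spacing: min of adjacent layers)
    for k, r in enumerate(radii):
        h_surf = h[k] if k == len(radii) - 1 else min(h[k], h[k + 1])
        pts.append(_graded_sphere_points(r, h_surf, region, rng))

    # volume points per layer, with clearance from the interface spheres
    def coarse_of(x: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(x, axis=1)
        idx = np.searchsorted(radii, r)
        return h[np.clip(idx, 0, len(h) - 1)]

    def inside(x: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(x, axis=1)
        ok = r < R
        h_loc = _sizing_target(x, coarse_of(x), region)
        for rk in radii:
            ok &= np.abs(r - rk) > 0.55 * h_loc
        return ok

    vol = _graded_volume_points(
        [-R, -R, -R], [R, R, R], inside, coarse_of, region, rng, float(h.max())
    )
    if len(vol):
        pts.append(vol)
    points = np.concatenate(pts)

    tets = _delaunay_mesh(points)
    if len(tets) == 0:
        raise RuntimeError(
            "sphere mesh generation produced no cells; sizing too coarse for "
            f"radii {spec.radii} with edge_length {spec.edge_length}"
        )
    cent = points[tets].mean(axis=1)
    r_cent = np.linalg.norm(cent, axis=1)
    layer_idx = np.clip(np.searchsorted(radii, r_cent), 0, len(radii) - 1)
    cell_markers = np.asarray(spec.layer_markers)[layer_idx]
    mesh = TetMesh(points, tets, cell_markers)

    # facet marking by node radius
    node_r = np.linalg.norm(points, axis=1)
    bfaces = mesh.boundary_faces()
    facets, markers = [], []
    names = {m: f"layer{i+1}" for i, m in enumerate(spec.layer_markers)}
    tol = 0.02 * min(h.min(), radii[0])
    ext = np.all(np.abs(node_r[bfaces] - R) < 0.05 * R, axis=1)
    facets.append(bfaces[ext])
    markers.append(np.full(int(ext.sum()), EXTERIOR_MARKER))
    names[EXTERIOR_MARKER] = "exterior"

    # internal interfaces: faces shared by tets of different layers, with all
    # three nodes on the interface sphere
    faces = _all_faces(tets)
    owner_marker = np.concatenate([cell_markers] * 4)
    order = np.lexsort(faces.T)
    faces_s = faces[order]
    owner_s = owner_marker[order]
    same = np.all(faces_s[1:] == faces_s[:-1], axis=1)
    pair_idx = np.flatnonzero(same & (owner_s[1:] != owner_s[:-1]))
    shared = faces_s[pair_idx]
    for i, rk in enumerate(radii[:-1]):
        on_rk = np.all(np.abs(node_r[shared] - rk) < tol, axis=1)
        sel = shared[on_rk]
        if len(sel):
            mid = EXTERIOR_MARKER + 1 + i
            facets.append(sel)
            markers.append(np.full(len(sel), mid))
            names[mid] = f"interface_{i+1}_{i+2}"
    mesh.facets = np.concatenate(facets) if facets else np.zeros((0, 3), np.int64)
    mesh.facet_markers = np.concatenate(markers) if markers else np.zeros(0, np.int64)
    mesh.marker_names = names
    return mesh


# ---------------------------------------------------------------------------
# Structured fixtures: box and octahedron-based ball
# ---------------------------------------------------------------------------

_KUHN_TETS = (
    (0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
    (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7),
)

BOX_FACE_MARKERS = {"xmin": 1, "xmax": 2, "ymin": 3, "ymax": 4, "zmin": 5, "zmax": 6}


def box_mesh(lengths: Sequence[float], divisions: Sequence[int],
             origin: Sequence[float] = (0.0, 0.0, 0.0)) -> TetMesh:
    """Structured box mesh (6 Kuhn tets per cell) with per-face facet markers.

    Face markers follow :data:`BOX_FACE_MARKERS`; all cells get marker 1.
    """
    L = np.asarray(lengths, dtype=float)
    nd = np.asarray(divisions, dtype=int)
    if np.any(L <= 0) or np.any(nd < 1):
        raise ValueError("lengths must be positive and divisions >= 1")
    axes = [np.linspace(0, L[k], nd[k] + 1) + origin[k] for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    sx, sy = (nd[1] + 1) * (nd[2] + 1), nd[2] + 1

    def nid(i, j, k):
        return i * sx + j * sy + k

    tets = []
    for i in range(nd[0]):
        for j in range(nd[1]):
            for k in range(nd[2]):
                corners = [nid(i + (c >> 2 & 1), j + (c >> 1 & 1), k + (c & 1))
                           for c in range(8)]
                for t in _KUHN_TETS:
                    tets.append([corners[v] for v in t])
    tets = _orient_positive(nodes, np.asarray(tets, dtype=np.int64))
    mesh = TetMesh(nodes, tets, np.ones(len(tets), dtype=np.int64))
    bfaces = mesh.boundary_faces()
    cent = nodes[bfaces].mean(axis=1)
    eps = 1e-9 * float(L.max())
    facets, markers = [], []
    for name, axis, val in (("xmin", 0, origin[0]), ("xmax", 0, origin[0] + L[0]),
                            ("ymin", 1, origin[1]), ("ymax", 1, origin[1] + L[1]),
                            ("zmin", 2, origin[2]), ("zmax", 2, origin[2] + L[2])):
        sel = np.abs(cent[:, axis] - val) < eps
        facets.append(bfaces[sel])
        markers.append(np.full(int(sel.sum()), BOX_FACE_MARKERS[name]))
    mesh.facets = np.concatenate(facets)
    mesh.facet_markers = np.concatenate(markers)
    mesh.marker_names = {1: "box", **{v: k for k, v in BOX_FACE_MARKERS.items()}}
    return mesh


def structured_ball_mesh(radius: float, refinements: int = 2) -> TetMesh:
    """Ball mesh from uniform red refinement of an 8-tet octahedron.

    The refinement runs in octahedron coordinates and the final node cloud is
    mapped onto the ball with the smooth radial map ``x -> x |x|_1 / |x|_2``,
    which places boundary nodes exactly on the sphere.  Node positions are
    nested across refinement levels, so the mesh family is suitable for
    geometric convergence studies.  Points on the coordinate axes are fixed
    by the map.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    nodes = np.array([
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0],
        [0, 1, 0], [0, -1, 0],
        [0, 0, 1], [0, 0, -1],
    ], dtype=float) * radius
    tets = np.array([
        [0, 1, 3, 5], [0, 3, 2, 5], [0, 2, 4, 5], [0, 4, 1, 5],
        [0, 3, 1, 6], [0, 2, 3, 6], [0, 4, 2, 6], [0, 1, 4, 6],
    ], dtype=np.int64)
    tets = _orient_positive(nodes, tets)
    mesh = TetMesh(nodes, tets, np.ones(len(tets), dtype=np.int64))
    for _ in range(refinements):
        mesh = red_refine_uniform(mesh)
    x = mesh.nodes
    l1 = np.abs(x).sum(axis=1)
    l2 = np.linalg.norm(x, axis=1)
    mesh.nodes = x * np.where(l2 > 0, l1 / np.maximum(l2, 1e-300), 1.0)[:, None]
    mesh.tets = _orient_positive(mesh.nodes, mesh.tets)
    return _mark_exterior(mesh)


def _mark_exterior(mesh: TetMesh) -> TetMesh:
    b = mesh.boundary_faces()
    mesh.facets = b
    mesh.facet_markers = np.full(len(b), EXTERIOR_MARKER, dtype=np.int64)
    mesh.marker_names = {**mesh.marker_names, EXTERIOR_MARKER: "exterior"}
    return mesh


# ---------------------------------------------------------------------------
# Refinement
# ---------------------------------------------------------------------------

def red_refine_uniform(mesh: TetMesh) -> TetMesh:
    """Uniform red (1 -> 8) refinement.

    Each tet splits into 4 corner tets plus 4 tets from its inner octahedron
    (cut along its shortest diagonal).  Child cells inherit the parent's cell
    marker; marked facets split into 4 children with the same marker.  Volume
    is conserved exactly.
    """
    nodes = mesh.nodes
    tets = mesh.tets
    edges = np.concatenate([
        tets[:, [a, b]] for a, b in
        ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
    ])
    edges = np.sort(edges, axis=1)
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mids = 0.5 * (nodes[uniq[:, 0]] + nodes[uniq[:, 1]])
    mid_id = len(nodes) + np.arange(len(uniq))
    new_nodes = np.vstack([nodes, mids])
    m = mid_id[inv].reshape(6, len(tets)).T  # columns: m01 m02 m03 m12 m13 m23
    v0, v1, v2, v3 = tets.T
    m01, m02, m03, m12, m13, m23 = m.T
    corner = [
        np.column_stack([v0, m01, m02, m03]),
        np.column_stack([m01, v1, m12, m13]),
        np.column_stack([m02, m12, v2, m23]),
        np.column_stack([m03, m13, m23, v3]),
    ]
    # inner octahedron: cut along the shortest of the three diagonals
    d1 = np.linalg.norm(new_nodes[m01] - new_nodes[m23], axis=1)
    d2 = np.linalg.norm(new_nodes[m02] - new_nodes[m13], axis=1)
    d3 = np.linalg.norm(new_nodes[m03] - new_nodes[m12], axis=1)
    choice = np.argmin(np.column_stack([d1, d2, d3]), axis=1)
    octa = np.empty((len(tets), 4, 4), dtype=np.int64)
    for c, (a, b, p, q, r, s) in (
        (0, (m01, m23, m02, m13, m03, m12)),
        (1, (m02, m13, m01, m23, m03, m12)),
        (2, (m03, m12, m01, m23, m02, m13)),
    ):
        sel = choice == c
        if not sel.any():
            continue
        # diagonal (a,b); equator cycle p -> r -> q -> s
        octa[sel] = np.stack([
            np.column_stack([a, b, p, r]),
            np.column_stack([a, b, r, q]),
            np.column_stack([a, b, q, s]),
            np.column_stack([a, b, s, p]),
        ], axis=1)[sel]
    children = np.concatenate(corner + [octa[:, k, :] for k in range(4)])
    child_markers = np.tile(mesh.cell_markers, 8)
    children = _orient_positive(new_nodes, children)

    new_facets = np.zeros((0, 3), np.int64)
    new_fm = np.zeros(0, np.int64)
    if len(mesh.facets):
        f = mesh.facets
        emap = {(int(e0), int(e1)): int(mi) for (e0, e1), mi in zip(uniq, mid_id)}

        def mid_of(a, b):
            return np.asarray([emap[tuple(sorted((int(x), int(y))))]
                               for x, y in zip(a, b)], dtype=np.int64)

        a, b, c = f[:, 0], f[:, 1], f[:, 2]
        mab, mbc, mca = mid_of(a, b), mid_of(b, c), mid_of(c, a)
        new_facets = np.concatenate([
            np.column_stack([a, mab, mca]),
            np.column_stack([mab, b, mbc]),
            np.column_stack([mca, mbc, c]),
            np.column_stack([mab, mbc, mca]),
        ])
        new_fm = np.tile(mesh.facet_markers, 4)
    return TetMesh(new_nodes, children, child_markers, new_facets, new_fm,
                   dict(mesh.marker_names))


_TET_EDGES = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def refine(mesh: TetMesh, region: Callable[[np.ndarray], np.ndarray],
           min_inradius: float) -> TetMesh:
    """Refine cells in ``region`` until their inradius is <= ``min_inradius``.

    Conforming longest-edge bisection: every cell whose centroid satisfies the
    region predicate and whose inradius exceeds the threshold is bisected, and
    neighbors are bisected as needed to keep the mesh conforming.  Cell and
    facet markers are inherited by children.
    """
    if min_inradius <= 0:
        raise ValueError("min_inradius must be positive")
    nodes = [np.asarray(p, dtype=float) for p in mesh.nodes]
    tets = [tuple(int(v) for v in t) for t in mesh.tets]
    cmarks = [int(m) for m in mesh.cell_markers]
    fmarks = {tuple(sorted(int(v) for v in f)): int(m)
              for f, m in zip(mesh.facets, mesh.facet_markers)}

    for _ in range(64):
        pts = np.asarray(nodes, dtype=float)
        T = np.asarray(tets, dtype=np.int64)
        cent = pts[T].mean(axis=1)
        ir = tet_inradii(pts, T)
        needy = np.asarray(region(cent), dtype=bool) & (ir > min_inradius)
        if not needy.any():
            break
        _bisect_pass(nodes, tets, cmarks, fmarks, np.flatnonzero(needy))
    else:
        raise RuntimeError("refinement did not converge in 64 passes")

    pts = np.asarray(nodes, dtype=float)
    T = _orient_positive(pts, np.asarray(tets, dtype=np.int64))
    if fmarks:
        facets = np.asarray(sorted(fmarks), dtype=np.int64)
        fm = np.asarray([fmarks[tuple(f)] for f in map(tuple, facets)], dtype=np.int64)
    else:
        facets = np.zeros((0, 3), np.int64)
        fm = np.zeros(0, np.int64)
    out = TetMesh(pts, T, np.asarray(cmarks, dtype=np.int64), facets, fm,
                  dict(mesh.marker_names))
    faces = _all_faces(out.tets)
    _, counts = np.unique(faces, axis=0, return_counts=True)
    if counts.max(initial=0) > 2:
        raise AssertionError("refinement produced a non-conforming mesh")
    return out


def _bisect_pass(nodes: list, tets: list, cmarks: list, fmarks: dict,
                 seed_cells) -> None:
    """One marked-edge longest-edge bisection sweep (in-place)."""

    def edge_key(e):
        d = nodes[e[0]] - nodes[e[1]]
        return (float(np.dot(d, d)), -min(e), -max(e))

    def longest_edge(t):
        return max((tuple(sorted((t[a], t[b]))) for a, b in _TET_EDGES),
                   key=edge_key)

    marked: set = set()
    for ci in seed_cells:
        marked.add(longest_edge(tets[ci]))

    midpoint: dict = {}

    def get_mid(e):
        if e not in midpoint:
            nodes.append(0.5 * (nodes[e[0]] + nodes[e[1]]))
            midpoint[e] = len(nodes) - 1
            hit = [f for f in fmarks if e[0] in f and e[1] in f]
            for f in hit:
                mval = fmarks.pop(f)
                other = [v for v in f if v not in e][0]
                fmarks[tuple(sorted((e[0], midpoint[e], other)))] = mval
                fmarks[tuple(sorted((e[1], midpoint[e], other)))] = mval
        return midpoint[e]

    for _ in range(100000):
        todo = [ci for ci, t in enumerate(tets)
                if any(tuple(sorted((t[a], t[b]))) in marked for a, b in _TET_EDGES)]
        if not todo:
            return
        # closure: each affected tet must split along its own longest edge
        for ci in todo:
            marked.add(longest_edge(tets[ci]))
        for ci in sorted(todo, reverse=True):
            t = tets[ci]
            le = longest_edge(t)
            m = get_mid(le)
            rest = [v for v in t if v not in le]
            mark = cmarks[ci]
            del tets[ci], cmarks[ci]
            tets.append((le[0], m, rest[0], rest[1]))
            cmarks.append(mark)
            tets.append((m, le[1], rest[0], rest[1]))
            cmarks.append(mark)
    raise RuntimeError("bisection closure did not terminate")


# ---------------------------------------------------------------------------
# Submesh extraction
# ---------------------------------------------------------------------------

def extract_submesh(mesh: TetMesh, keep: Iterable[int]) -> tuple[TetMesh, np.ndarray]:
    """Restrict a mesh to cells whose marker is in ``keep``.

    Returns the submesh and a node index map ``old -> new`` (-1 for dropped
    nodes) for transferring nodal fields.  Fresh exterior facets created by
    the cut get a new marker id (labelled ``"cut"``).
    """
    keep = set(int(k) for k in keep)
    if not keep:
        raise ValueError("keep must be non-empty")
    present = set(int(m) for m in np.unique(mesh.cell_markers))
    missing = keep - present
    if missing:
        raise ValueError(f"markers {sorted(missing)} not present in mesh")
    sel = np.isin(mesh.cell_markers, list(keep))
    if not sel.any():
        raise ValueError("empty submesh")
    tets = mesh.tets[sel]
    used = np.unique(tets)
    node_map = np.full(mesh.num_nodes, -1, dtype=np.int64)
    node_map[used] = np.arange(len(used))
    sub = TetMesh(mesh.nodes[used], node_map[tets], mesh.cell_markers[sel])

    facets, markers = [], []
    if len(mesh.facets):
        sub_faces = {tuple(f) for f in _all_faces(sub.tets)}
        for f, m in zip(mesh.facets, mesh.facet_markers):
            nf = node_map[f]
            key = tuple(sorted(int(v) for v in nf))
            if nf.min() >= 0 and key in sub_faces:
                facets.append(key)
                markers.append(int(m))
    existing = set(facets)
    all_ids = [EXTERIOR_MARKER] + list(mesh.marker_names)
    if len(mesh.facet_markers):
        all_ids += [int(x) for x in np.unique(mesh.facet_markers)]
    cut_id = max(all_ids) + 1
    parent_faces = _all_faces(mesh.tets)
    uniq, counts = np.unique(parent_faces, axis=0, return_counts=True)
    interior_parent = {tuple(int(v) for v in f) for f, c in zip(uniq, counts) if c == 2}
    n_cut = 0
    for f in sub.boundary_faces():
        key = tuple(sorted(int(v) for v in f))
        if key in existing:
            continue
        old = tuple(sorted(int(used[v]) for v in f))
        if old in interior_parent:
            facets.append(key)
            markers.append(cut_id)
            n_cut += 1
    sub.facets = np.asarray(facets, dtype=np.int64).reshape(-1, 3)
    sub.facet_markers = np.asarray(markers, dtype=np.int64)
    sub.marker_names = dict(mesh.marker_names)
    if n_cut:
        sub.marker_names[cut_id] = "cut"
    return sub, node_map


# ---------------------------------------------------------------------------
# MSH 2.2 ASCII I/O
# ---------------------------------------------------------------------------

_MSH_TET = 4
_MSH_TRI = 2
_IGNORED_TYPES = {15, 1}  # points and lines
_VOLUME_TYPES = {5: "hexahedron", 6: "prism", 7: "pyramid"}


def write_msh(mesh: TetMesh, path) -> None:
    """Write a mesh in Gmsh MSH 2.2 ASCII format.

    Cell markers become physical volume tags, facet markers physical surface
    tags.  Node/element ids are 1-based.
    """
    facet_ids = set(int(m) for m in mesh.facet_markers)
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        if mesh.marker_names:
            fh.write("$PhysicalNames\n%d\n" % len(mesh.marker_names))
            for mid, name in sorted(mesh.marker_names.items()):
                dim = 2 if mid in facet_ids else 3
                fh.write(f'{dim} {mid} "{name}"\n')
            fh.write("$EndPhysicalNames\n")
        fh.write("$Nodes\n%d\n" % mesh.num_nodes)
        for i, p in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write("$EndNodes\n")
        fh.write("$Elements\n%d\n" % (mesh.num_cells + len(mesh.facets)))
        eid = 1
        for f, m in zip(mesh.facets, mesh.facet_markers):
            fh.write(f"{eid} {_MSH_TRI} 2 {m} {m} "
                     + " ".join(str(v + 1) for v in f) + "\n")
            eid += 1
        for t, m in zip(mesh.tets, mesh.cell_markers):
            fh.write(f"{eid} {_MSH_TET} 2 {m} {m} "
                     + " ".join(str(v + 1) for v in t) + "\n")
            eid += 1
        fh.write("$EndElements\n")


def read_msh(path) -> TetMesh:
    """Read a Gmsh MSH 2.2 ASCII file with physical tags.

    Only tetrahedral volume cells and triangular facets are supported; other
    volume element types raise an error naming the type.
    """
    nodes, node_ids = [], []
    tets, cmarks, facets, fmarks = [], [], [], []
    names: dict = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line == "$MeshFormat":
            ver = lines[i + 1].split()[0]
            if not ver.startswith("2"):
                raise ValueError(f"unsupported MSH version {ver}; expected 2.x ASCII")
            i += 3
        elif line == "$PhysicalNames":
            n = int(lines[i + 1])
            for k in range(n):
                parts = lines[i + 2 + k].split(maxsplit=2)
                names[int(parts[1])] = parts[2].strip().strip('"')
            i += n + 3
        elif line == "$Nodes":
            n = int(lines[i + 1])
            for k in range(n):
                parts = lines[i + 2 + k].split()
                node_ids.append(int(parts[0]))
                nodes.append([float(x) for x in parts[1:4]])
            i += n + 3
        elif line == "$Elements":
            n = int(lines[i + 1])
            for k in range(n):
                parts = [int(x) for x in lines[i + 2 + k].split()]
                etype, ntags = parts[1], parts[2]
                tags = parts[3:3 + ntags]
                conn = parts[3 + ntags:]
                phys = tags[0] if tags else 0
                if etype == _MSH_TET:
                    tets.append(conn)
                    cmarks.append(phys)
                elif etype == _MSH_TRI:
                    facets.append(conn)
                    fmarks.append(phys)
                elif etype in _IGNORED_TYPES:
                    continue
                elif etype in _VOLUME_TYPES:
                    raise ValueError(
                        f"unsupported element type {etype} "
                        f"({_VOLUME_TYPES[etype]}); only tetrahedra are supported"
                    )
                else:
                    raise ValueError(f"unsupported element type {etype}")
            i += n + 3
        else:
            i += 1
    if not tets:
        raise ValueError("no tetrahedra found in MSH file")
    id_map = {nid: k for k, nid in enumerate(node_ids)}
    nodes = np.asarray(nodes, dtype=float)
    tets = np.asarray([[id_map[v] for v in t] for t in tets], dtype=np.int64)
    tets = _orient_positive(nodes, tets)
    facets_arr = (np.asarray([[id_map[v] for v in f] for f in facets], dtype=np.int64)
                  if facets else np.zeros((0, 3), np.int64))
    return TetMesh(nodes, tets, np.asarray(cmarks, dtype=np.int64),
                   facets_arr, np.asarray(fmarks, dtype=np.int64), names)


def write_vtk(mesh: TetMesh, path, point_data: dict | None = None) -> None:
    """Write a legacy ASCII VTK unstructured grid for quick inspection."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nvcfem mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.num_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"CELLS {mesh.num_cells} {5 * mesh.num_cells}\n")
        for t in mesh.tets:
            fh.write("4 " + " ".join(map(str, t)) + "\n")
        fh.write(f"CELL_TYPES {mesh.num_cells}\n")
        fh.write("\n".join(["10"] * mesh.num_cells) + "\n")
        fh.write(f"CELL_DATA {mesh.num_cells}\nSCALARS marker int 1\n")
        fh.write("LOOKUP_TABLE default\n")
        fh.write("\n".join(map(str, mesh.cell_markers)) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.num_nodes}\n")
            for name, vals in point_data.items():
                vals = np.asarray(vals)
                comps = ((name + "_re", vals.real), (name + "_im", vals.imag)) \
                    if np.iscomplexobj(vals) else ((name, vals),)
                for cname, comp in comps:
                    fh.write(f"SCALARS {cname} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.17g}" for v in comp) + "\n")


# ---------------------------------------------------------------------------
# Slab-in-bath fixture
# ---------------------------------------------------------------------------

BATH_MARKER = 1
SLAB_MARKER = 2
GROUND_MARKER = 9
PATCH_MARKER_BASE = 10


def _rect_patch_points(center, dims, spacing, rng):
    """Jittered grid on a rectangle at z=0 with exact boundary points."""
    w, l = dims
    nx = max(2, int(np.ceil(w / spacing)) + 1)
    ny = max(2, int(np.ceil(l / spacing)) + 1)
    xs = np.linspace(-w / 2, w / 2, nx)
    ys = np.linspace(-l / 2, l / 2, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    P = np.column_stack([X.ravel(), Y.ravel()])
    interior = (np.abs(P[:, 0]) < w / 2 - 1e-15) & (np.abs(P[:, 1]) < l / 2 - 1e-15)
    jit = rng.uniform(-0.15, 0.15, size=P.shape) * np.array([w / (nx - 1), l / (ny - 1)])
    P[interior] += jit[interior]
    return np.column_stack([P[:, 0] + center[0], P[:, 1] + center[1],
                            np.zeros(len(P))])


def _disc_points(radius, spacing, z, rng, hole=None):
    """Sunflower lattice on a disc at height z, with exact rim points."""
    n = max(8, int(np.pi * radius**2 / spacing**2))
    i = np.arange(1, n + 1, dtype=float)
    r = radius * np.sqrt((i - 0.5) / n)
    th = i * 2.399963229728653  # golden angle
    P = np.column_stack([r * np.cos(th), r * np.sin(th)])
    P = P[np.linalg.norm(P, axis=1) < radius - 0.45 * spacing]
    P += rng.uniform(-0.15 * spacing, 0.15 * spacing, size=P.shape)
    n_rim = max(8, int(np.ceil(2 * np.pi * radius / spacing)))
    a = 2 * np.pi * np.arange(n_rim) / n_rim
    P = np.vstack([P, radius * np.column_stack([np.cos(a), np.sin(a)])])
    if hole is not None:
        hc, hdims = hole
        inside = (np.abs(P[:, 0] - hc[0]) < hdims[0] / 2 + 0.55 * spacing) & \
                 (np.abs(P[:, 1] - hc[1]) < hdims[1] / 2 + 0.55 * spacing)
        P = P[~inside]
    return np.column_stack([P[:, 0], P[:, 1], np.full(len(P), z)])


def generate_slab_in_bath_mesh(
    bath_diameter: float,
    bath_height: float,
    slab_dims: tuple[float, float, float],
    electrode_patches: Sequence[tuple] = (),
    ground_patch: tuple | None = None,
    edge_length: float | None = None,
    patch_edge_length: float | None = None,
    seed: int = 0,
) -> TetMesh:
    """Simplified MEA fixture: a tissue slab in a cylindrical bath.

    The bath is a cylinder of given diameter/height with its bottom at z=0;
    the slab is a box centered on the axis, resting on the bottom plane.
    ``electrode_patches`` are ``("rect", (width, length), (cx, cy))`` entries
    on the z=0 plane; each gets a unique facet marker starting at
    :data:`PATCH_MARKER_BASE`.  ``ground_patch`` is an optional
    ``(z_center, height, angle_center, angle_width)`` strip on the bath wall
    with marker :data:`GROUND_MARKER`.
    """
    R = bath_diameter / 2.0
    H = bath_height
    sx, sy, sz = slab_dims
    if sz >= H:
        raise ValueError("slab is as tall as the bath")
    if np.hypot(sx / 2, sy / 2) >= R:
        raise ValueError("slab corners extend outside the bath cylinder")
    rng = np.random.default_rng(seed)
    h = edge_length if edge_length is not None else bath_diameter / 10.0

    rects = []
    for shape, dims, center in electrode_patches:
        if shape != "rect":
            raise ValueError(f"unsupported patch shape {shape!r}")
        w, l = dims
        cx, cy = center
        if abs(cx) + w / 2 > sx / 2 or abs(cy) + l / 2 > sy / 2:
            raise ValueError("electrode patch extends outside the slab footprint")
        rects.append((cx - w / 2, cx + w / 2, cy - l / 2, cy + l / 2))
    for a in range(len(rects)):
        for b in range(a + 1, len(rects)):
            xa0, xa1, ya0, ya1 = rects[a]
            xb0, xb1, yb0, yb1 = rects[b]
            if xa0 < xb1 and xb0 < xa1 and ya0 < yb1 and yb0 < ya1:
                raise ValueError(f"electrode patches {a} and {b} overlap")

    pts = []
    patch_h = []
    for shape, dims, center in electrode_patches:
        hp = patch_edge_length or min(dims) / 3.0
        patch_h.append(hp)
        pts.append(_rect_patch_points(center, dims, hp, rng))

    h_slab = min(h, sz / 1.2)
    xs = np.linspace(-sx / 2, sx / 2, max(2, int(np.ceil(sx / h_slab)) + 1))
    ys = np.linspace(-sy / 2, sy / 2, max(2, int(np.ceil(sy / h_slab)) + 1))
    zs = np.linspace(0.0, sz, max(2, int(np.ceil(sz / h_slab)) + 1))
    Xs, Ys = np.meshgrid(xs, ys, indexing="ij")
    face_pts = [np.column_stack([Xs.ravel(), Ys.ravel(), np.full(Xs.size, sz)])]
    zmid = zs[1:-1]
    if len(zmid):
        for xv in (-sx / 2, sx / 2):
            Yf, Zf = np.meshgrid(ys, zmid, indexing="ij")
            face_pts.append(np.column_stack([np.full(Yf.size, xv), Yf.ravel(), Zf.ravel()]))
        for yv in (-sy / 2, sy / 2):
            Xf, Zf = np.meshgrid(xs[1:-1], zmid, indexing="ij")
            if Xf.size:
                face_pts.append(np.column_stack([Xf.ravel(), np.full(Xf.size, yv), Zf.ravel()]))
    pts.append(np.concatenate(face_pts))
    # slab bottom plane outside the electrode patches
    Xb, Yb = np.meshgrid(xs, ys, indexing="ij")
    bot = np.column_stack([Xb.ravel(), Yb.ravel(), np.zeros(Xb.size)])
    keep = np.ones(len(bot), dtype=bool)
    for (x0, x1, y0, y1), hp in zip(rects, patch_h):
        keep &= ~((bot[:, 0] > x0 - 0.7 * hp) & (bot[:, 0] < x1 + 0.7 * hp) &
                  (bot[:, 1] > y0 - 0.7 * hp) & (bot[:, 1] < y1 + 0.7 * hp))
    pts.append(bot[keep])

    pts.append(_disc_points(R, h, 0.0, rng, hole=((0.0, 0.0), (sx + h, sy + h))))
    pts.append(_disc_points(R, h, H, rng))
    n_th = max(8, int(np.ceil(2 * np.pi * R / h)))
    n_z = max(2, int(np.ceil(H / h)) + 1)
    th = 2 * np.pi * np.arange(n_th) / n_th
    zw = np.linspace(0.0, H, n_z)[1:-1]
    if len(zw):
        TH, ZW = np.meshgrid(th, zw, indexing="ij")
        pts.append(np.column_stack([R * np.cos(TH.ravel()), R * np.sin(TH.ravel()),
                                    ZW.ravel()]))

    def inside_bath(x):
        r = np.hypot(x[:, 0], x[:, 1])
        ok = (r < R - 0.5 * h) & (x[:, 2] > 0.4 * h) & (x[:, 2] < H - 0.4 * h)
        near_slab = (np.abs(x[:, 0]) < sx / 2 + 0.5 * h_slab) & \
                    (np.abs(x[:, 1]) < sy / 2 + 0.5 * h_slab) & \
                    (x[:, 2] < sz + 0.5 * h_slab)
        return ok & ~near_slab

    axes = [np.arange(-R + 0.5 * h, R, h), np.arange(-R + 0.5 * h, R, h),
            np.arange(0.5 * h, H, h)]
    if all(len(a) for a in axes):
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        grid += rng.uniform(-0.2 * h, 0.2 * h, size=grid.shape)
        grid = grid[inside_bath(grid)]
        if len(grid):
            pts.append(grid)
    # slab interior
    if sz > 2.2 * h_slab:
        axes = [np.arange(-sx / 2 + 0.6 * h_slab, sx / 2 - 0.55 * h_slab, h_slab),
                np.arange(-sy / 2 + 0.6 * h_slab, sy / 2 - 0.55 * h_slab, h_slab),
                np.arange(0.6 * h_slab, sz - 0.55 * h_slab, h_slab)]
        if all(len(a) for a in axes):
            g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
            g += rng.uniform(-0.2 * h_slab, 0.2 * h_slab, size=g.shape)
            pts.append(g)

    points = np.concatenate([p for p in pts if len(p)])
    r = np.hypot(points[:, 0], points[:, 1])
    over = r > R
    points[over, 0] *= R / r[over]
    points[over, 1] *= R / r[over]
    np.clip(points[:, 2], 0.0, H, out=points[:, 2])

    tets = _delaunay_mesh(points)
    cent = points[tets].mean(axis=1)
    in_slab = (np.abs(cent[:, 0]) < sx / 2) & (np.abs(cent[:, 1]) < sy / 2) & \
              (cent[:, 2] < sz)
    cell_markers = np.where(in_slab, SLAB_MARKER, BATH_MARKER)
    mesh = TetMesh(points, tets, cell_markers)

    bfaces = mesh.boundary_faces()
    fc = points[bfaces].mean(axis=1)
    fmark = np.full(len(bfaces), EXTERIOR_MARKER, dtype=np.int64)
    names = {BATH_MARKER: "bath", SLAB_MARKER: "slab", EXTERIOR_MARKER: "exterior"}
    vz = points[bfaces][:, :, 2]
    on_bottom = np.all(np.abs(vz) < 1e-9 * H, axis=1)
    for k, (x0, x1, y0, y1) in enumerate(rects):
        tolp = 1e-9 * R
        vx = points[bfaces][:, :, 0]
        vy = points[bfaces][:, :, 1]
        in_rect = np.all((vx > x0 - tolp) & (vx < x1 + tolp) &
                         (vy > y0 - tolp) & (vy < y1 + tolp), axis=1)
        sel = on_bottom & in_rect
        fmark[sel] = PATCH_MARKER_BASE + k
        names[PATCH_MARKER_BASE + k] = f"patch{k}"
    if ground_patch is not None:
        zc, gh, ac, aw = ground_patch
        fr = np.hypot(fc[:, 0], fc[:, 1])
        ang = np.arctan2(fc[:, 1], fc[:, 0])
        dang = np.angle(np.exp(1j * (ang - ac)))
        sel = (fr > 0.95 * R) & (np.abs(fc[:, 2] - zc) < gh / 2) & (np.abs(dang) < aw / 2)
        fmark[sel] = GROUND_MARKER
        names[GROUND_MARKER] = "ground"
    mesh.facets = bfaces
    mesh.facet_markers = fmark
    mesh.marker_names = names
    return mesh
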