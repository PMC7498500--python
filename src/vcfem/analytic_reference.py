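"""Analytical concentric-sphere dipole potentials and the RD metric.

Legendre series solution of the Poisson problem for a current dipole inside
the innermost of several concentric spherical shells with (complex)
admittivity per shell and an insulating exterior.  The dipole is decomposed
into radial and tangential components about its own radial axis; each
spherical-harmonic order couples the shells through a small linear system in
scaled radial coefficients (powers of radius ratios stay bounded, so the
solve is stable to arbitrary order).

Also provides the relative-difference (RD) validation metric

    RD = (1/N) sum_i |phi_i - psi_i| / max |psi|

and a depth/orientation sweep comparing FEM against the analytic series on
the innermost interface surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from vcfem import fem_core as fc
from vcfem.dielectrics import Admittivity
from vcfem.meshkit import TetMesh, surface_sample_points

__all__ = [
    "FourSphereModel",
    "dipole_potential",
    "relative_difference",
    "validate_study1",
    "RDRow",
]


@dataclass(frozen=True)
class FourSphereModel:
    """Concentric-shell model: radii inner to outer, admittivity per shell.

    ``n_terms`` truncates the Legendre series.  Admittivities may be real
    (conductivities) or complex (sigma + j w eps0 eps_r).
    """

    radii: tuple
    admittivities: tuple
    n_terms: int = 1000

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if np.any(np.diff(r) <= 0) or r[0] <= 0:
            raise ValueError("radii must be positive and strictly increasing")
        if len(self.admittivities) != len(r):
            raise ValueError("need one admittivity per shell")
        if any(abs(complex(y)) == 0 for y in self.admittivities):
            raise ValueError("admittivities must be nonzero")
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        object.__setattr__(self, "radii", tuple(float(x) for x in r))
        object.__setattr__(self, "admittivities",
                           tuple(complex(y) for y in self.admittivities))


def _shell_coefficients(model: FourSphereModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-order shell coefficients for a unit source coefficient.

    The order-``l`` potential in shell ``s`` (inner/outer radii rho_{s-1},
    rho_s; rho_0 = 0) is written in the scaled form

        A_s (r / rho_s)^l + B_s (rho_{s-1} / r)^(l+1)      [B_1 = 0]

    plus, in shell 1, the source term ``q (rho_1 / r)^(l+1)`` (valid for
    r > a), normalized to value 1 at the innermost interface so that all
    matrix and rhs entries stay O(1) for arbitrary order.  Solves the
    interface-continuity + exterior-Neumann system per order for q = 1;
    coefficients scale linearly with the actual q.  Returns ``A``, ``B`` of
    shape (n_terms + 1, n_shells); order index 0 is unused.
    """
    rho = np.asarray(model.radii, dtype=float)
    y = np.asarray(model.admittivities, dtype=complex)
    S = len(rho)
    L = model.n_terms
    ls = np.arange(1, L + 1, dtype=float)

    nunk = 2 * S - 1  # A_1, (A_s, B_s) for s >= 2
    M = np.zeros((L, nunk, nunk), dtype=complex)
    rhs = np.zeros((L, nunk), dtype=complex)

    def a_idx(s: int) -> int:  # 1-based shell index
        return 0 if s == 1 else 2 * s - 3

    def b_idx(s: int) -> int:
        return 2 * s - 2

    row = 0
    for k in range(1, S):  # interface at rho_k between shells k and k+1
        rk = rho[k - 1]
        ratio_in = (rho[k - 2] / rk) ** (ls + 1) if k >= 2 else None
        ratio_out = (rk / rho[k]) ** ls
        # continuity of phi
        M[:, row, a_idx(k)] = 1.0
        if k >= 2:
            M[:, row, b_idx(k)] = ratio_in
        M[:, row, a_idx(k + 1)] = -ratio_out
        M[:, row, b_idx(k + 1)] = -1.0
        if k == 1:
            rhs[:, row] = -1.0
        row += 1
        # continuity of y dphi/dr
        M[:, row, a_idx(k)] = y[k - 1] * ls / rk
        if k >= 2:
            M[:, row, b_idx(k)] = -y[k - 1] * (ls + 1) / rk * ratio_in
        M[:, row, a_idx(k + 1)] = -y[k] * ls / rk * ratio_out
        M[:, row, b_idx(k + 1)] = y[k] * (ls + 1) / rk
        if k == 1:
            rhs[:, row] = y[0] * (ls + 1) / rk
        row += 1
    # exterior Neumann at the outer radius
    R = rho[-1]
    M[:, row, a_idx(S)] = ls / R
    if S >= 2:
        M[:, row, b_idx(S)] = -(ls + 1) / R * (rho[S - 2] / R) ** (ls + 1)
    else:
        # single shell: the normalized source reaches the outer boundary
        rhs[:, row] = (ls + 1) / R
    sol = np.linalg.solve(M, rhs[..., None])[..., 0]

    A = np.zeros((L + 1, S), dtype=complex)
    B = np.zeros((L + 1, S), dtype=complex)
    A[1:, 0] = sol[:, 0]
    for s in range(2, S + 1):
        A[1:, s - 1] = sol[:, a_idx(s)]
        B[1:, s - 1] = sol[:, b_idx(s)]
    return A, B


def dipole_potential(model: FourSphereModel, dipole_position, dipole_moment,
                     points) -> np.ndarray:
    """Complex potential of a point current dipole at each evaluation point.

    ``dipole_position`` must lie strictly inside the innermost shell;
    ``points`` on or inside the outer radius.  Linear in ``dipole_moment``
    (A m); deterministic.
    """
    pos = np.asarray(dipole_position, dtype=float)
    mom = np.asarray(dipole_moment, dtype=complex)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rho = np.asarray(model.radii, dtype=float)
    y1 = model.admittivities[0]
    a = float(np.linalg.norm(pos))
    if a >= rho[0]:
        raise ValueError(
            f"dipole at radius {a:.4g} m is not inside the innermost shell "
            f"({rho[0]:.4g} m)"
        )
    r_pts = np.linalg.norm(pts, axis=1)
    if np.any(r_pts > rho[-1] * (1 + 1e-9)):
        raise ValueError("evaluation points must lie on or inside the outer radius")

    # local frame: e_z along the dipole radial axis
    if a > 0:
        ez = pos / a
    else:
        ez = np.array([0.0, 0.0, 1.0])
    ex = np.array([1.0, 0.0, 0.0])
    if abs(ez @ ex) > 0.9:
        ex = np.array([0.0, 1.0, 0.0])
    ex = ex - (ez @ ex) * ez
    ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)
    p_rad = complex(mom @ ez)
    p_tx = complex(mom @ ex)
    p_ty = complex(mom @ ey)

    r = np.maximum(r_pts, 1e-300)
    ct = np.clip((pts @ ez) / r, -1.0, 1.0)
    st = np.sqrt(np.maximum(0.0, 1.0 - ct * ct))
    rst = np.maximum(r * st, 1e-300)
    cpx = np.where(st > 1e-15, (pts @ ex) / rst, 0.0)
    cpy = np.where(st > 1e-15, (pts @ ey) / rst, 0.0)

    shell = np.clip(np.searchsorted(rho, r_pts * (1 - 1e-12)), 0, len(rho) - 1)
    A, B = _shell_coefficients(model)
    L = model.n_terms

    rho_out = rho[shell]
    rho_in = np.where(shell >= 1, rho[np.maximum(shell - 1, 0)], 0.0)
    u_ratio = r_pts / rho_out
    v_ratio = np.where(shell >= 1, rho_in / r, 0.0)
    in1 = shell == 0
    out_src = r_pts >= a

    # multiplicative radial factors, initialized at order l = 1; each stays
    # bounded so arbitrary series orders need no log-space handling
    rho1 = rho[0]
    u = u_ratio.copy()                       # (r/rho_s)^l
    v = v_ratio ** 2                         # (rho_{s-1}/r)^(l+1)
    w = 1.0 / rho1**2                        # a^(l-1) / rho_1^(l+1)
    s_out = 1.0 / r**2                       # a^(l-1) r^-(l+1); a^0 = 1
    s_in = (r / a**3) if a > 0 else np.zeros_like(r)  # r^l a^-(l+2)
    src_mask_out = in1 & out_src
    src_mask_in = in1 & ~out_src

    P_lm1 = np.ones_like(ct)                 # P_0
    P_l = ct.copy()                          # P_1
    P1_lm1 = np.zeros_like(ct)               # P_0^1
    P1_l = -st.copy()                        # P_1^1 (Condon-Shortley)

    fac_rad = p_rad / (4.0 * np.pi * y1)
    fac_tan_x = -p_tx / (4.0 * np.pi * y1)
    fac_tan_y = -p_ty / (4.0 * np.pi * y1)
    phi = np.zeros(len(pts), dtype=complex)
    for l in range(1, L + 1):
        lf = float(l)
        radial = w * (A[l, shell] * u + B[l, shell] * v)
        src = np.where(src_mask_out, s_out, 0.0)
        rad = fac_rad * lf * (radial + src)
        tan_common = radial + src
        if a > 0 and src_mask_in.any():
            s_in_m = np.where(src_mask_in, s_in, 0.0)
            rad = rad - fac_rad * (lf + 1.0) * s_in_m
            tan_common = tan_common + s_in_m
        phi += rad * P_l
        phi += (fac_tan_x * cpx + fac_tan_y * cpy) * tan_common * P1_l

        if l < L:
            u *= u_ratio
            v *= v_ratio
            w *= a / rho1
            s_out *= a / r
            if a > 0:
                s_in *= r / a
            P_next = ((2 * l + 1) * ct * P_l - l * P_lm1) / (l + 1)
            P_lm1, P_l = P_l, P_next
            if l == 1:
                P1_next = 3.0 * ct * P1_l
            else:
                P1_next = ((2 * l + 1) * ct * P1_l - (l + 1) * P1_lm1) / l
            P1_lm1, P1_l = P1_l, P1_next
    return phi


def axial_monopole_pair_potential(model: FourSphereModel, z_plus: float,
                                  z_minus: float, current: float,
                                  points) -> np.ndarray:
    """Potential of a +/- monopole pair on the +z axis inside shell 1.

    ``+current`` is injected at ``(0, 0, z_plus)`` and ``-current`` at
    ``(0, 0, z_minus)``; both radii must be below the innermost interface.
    Because the net current vanishes, the insulated-exterior problem is
    consistent and the axisymmetric (m = 0) Legendre series is exact.  The
    returned potential carries an arbitrary additive constant (gauge).

    Unlike the point-dipole solution this reference matches a finite-
    separation source exactly, which makes it the right oracle for mesh
    convergence studies with vertex-aligned monopoles.
    """
    rho = np.asarray(model.radii, dtype=float)
    y1 = model.admittivities[0]
    a1, a2 = float(z_plus), float(z_minus)
    if not (0 <= a1 < rho[0]) or not (0 <= a2 < rho[0]):
        raise ValueError("both monopoles must sit inside the innermost shell")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r_pts = np.linalg.norm(pts, axis=1)
    if np.any(r_pts > rho[-1] * (1 + 1e-9)):
        raise ValueError("evaluation points must lie on or inside the outer radius")
    r = np.maximum(r_pts, 1e-300)
    ct = np.clip(pts[:, 2] / r, -1.0, 1.0)

    shell = np.clip(np.searchsorted(rho, r_pts * (1 - 1e-12)), 0, len(rho) - 1)
    A, B = _shell_coefficients(model)
    L = model.n_terms
    rho1 = rho[0]

    rho_out = rho[shell]
    rho_in = np.where(shell >= 1, rho[np.maximum(shell - 1, 0)], 0.0)
    u_ratio = r_pts / rho_out
    v_ratio = np.where(shell >= 1, rho_in / r, 0.0)
    in1 = shell == 0
    fac = current / (4.0 * np.pi * y1)

    phi = np.zeros(len(pts), dtype=complex)
    # l = 0 source terms (no homogeneous correction needed: net flux cancels
    # outside both sources); gauge constant is free
    for a, sgn in ((a1, +1.0), (a2, -1.0)):
        out = in1 & (r_pts >= a)
        if a > 0:
            phi += sgn * fac * np.where(out, 1.0 / r, np.where(in1, 1.0 / a, 0.0))
        else:
            phi += sgn * fac * np.where(in1, 1.0 / r, 0.0)
    # outside shell 1 the l = 0 net term vanishes but the potential must stay
    # continuous: both sources contribute 1/r with opposite signs -> zero
    u = u_ratio.copy()                     # (r/rho_s)^l
    v = v_ratio ** 2                       # (rho_{s-1}/r)^(l+1)

    t1 = a1 / rho1
    t2 = a2 / rho1
    p1 = t1
    p2 = t2
    # per-source radial factors
    s1_out = np.where(r_pts >= a1, a1 / r**2, 0.0)   # a^l / r^(l+1)
    s2_out = np.where(r_pts >= a2, a2 / r**2, 0.0)
    s1_in = (np.where(r_pts < a1, r / a1**2, 0.0)) if a1 > 0 else np.zeros_like(r)
    s2_in = (np.where(r_pts < a2, r / a2**2, 0.0)) if a2 > 0 else np.zeros_like(r)

    P_lm1 = np.ones_like(ct)
    P_l = ct.copy()
    for l in range(1, L + 1):
        # _shell_coefficients solves for the normalized source (rho1/r)^(l+1);
        # the physical amplitude is fac (a1^l - a2^l) rho1^-(l+1)
        # = fac (p1 - p2) / rho1 with the running powers p1, p2
        radial = fac * (p1 - p2) / rho1 * (A[l, shell] * u + B[l, shell] * v)
        src = fac * np.where(in1, s1_out - s2_out + s1_in - s2_in, 0.0)
        phi += (radial + src) * P_l
        if l < L:
            u *= u_ratio
            v *= v_ratio
            p1 *= t1
            p2 *= t2
            s1_out *= a1 / r
            s2_out *= a2 / r
            if a1 > 0:
                s1_in *= r / a1
            if a2 > 0:
                s2_in *= r / a2
            P_next = ((2 * l + 1) * ct * P_l - l * P_lm1) / (l + 1)
            P_lm1, P_l = P_l, P_next
    return phi


def relative_difference(phi, psi) -> float:
    """RD = (1/N) sum |phi_i - psi_i| / max |psi| (complex moduli)."""
    phi = np.asarray(phi).ravel()
    psi = np.asarray(psi).ravel()
    if phi.shape != psi.shape:
        raise ValueError("phi and psi must have equal length")
    denom = np.abs(psi).max()
    if denom == 0:
        raise ValueError("reference solution is identically zero")
    return float(np.mean(np.abs(phi - psi)) / denom)


@dataclass
class RDRow:
    depth: float
    orientation: str
    rd: float
    iterations: int = 0


def _is_complex_map(material_map) -> bool:
    for v in material_map.values():
        val = v.value if isinstance(v, Admittivity) else v
        if np.abs(np.imag(np.asarray(val))).max() > 0:
            return True
    return False


def validate_study1(mesh: TetMesh, model: FourSphereModel, material_map,
                    depths: Sequence[float] = (1e-3, 2e-3, 3e-3, 4e-3, 5e-3),
                    orientations: Sequence[str] = ("radial", "tangential", "45deg"),
                    n_surface_points: int = 32400,
                    current: float = 100e-6, separation: float = 1e-3,
                    solver: str = "gmres", tol: float = 1e-8,
                    preconditioner: str = "ilu",
                    csv_path=None, plot_path=None) -> list[RDRow]:
    """Depth/orientation RD sweep of FEM against the analytic series.

    The dipole sits on the +z axis ``depth`` below the innermost interface,
    realized as +/- ``current`` monopoles ``separation`` apart (tangential
    axis: x).  Both solutions are evaluated at ``n_surface_points``
    quasi-uniform points on the innermost interface sphere and compared with
    the RD metric.  The operator is assembled once; only the rhs changes
    between dipoles.
    """
    r_eval = model.radii[0]
    pts = surface_sample_points(r_eval, n_surface_points)
    if _is_complex_map(material_map):
        system = fc.assemble_complex_block(mesh, material_map)
        method = "gmres"
    else:
        system = fc.assemble_stiffness(mesh, material_map)
        method = solver
    base_rhs = system.rhs.copy()

    rows: list[RDRow] = []
    for depth in depths:
        z0 = r_eval - depth
        for orientation in orientations:
            if orientation == "radial":
                direction = np.array([0.0, 0.0, 1.0])
            elif orientation == "tangential":
                direction = np.array([1.0, 0.0, 0.0])
            elif orientation in ("45deg", "45"):
                direction = np.array([1.0, 0.0, 1.0]) / np.sqrt(2.0)
            else:
                raise ValueError(f"unknown orientation {orientation!r}")
            src = fc.SourceSpec.dipole((0.0, 0.0, z0), direction,
                                       current=current, separation=separation)
            system.rhs = base_rhs.copy()
            fc.assemble_source_rhs(system, src)
            fld = fc.solve(system, method=method, tol=tol,
                           preconditioner=preconditioner, max_iter=20000)
            phi = fc.evaluate(fld, pts, nearest=True)
            psi = dipole_potential(model, (0.0, 0.0, z0),
                                   direction * current * separation, pts)
            # match gauges: compare in the zero-mean-over-points convention
            phi = phi - phi.mean()
            psi = psi - psi.mean()
            rows.append(RDRow(depth=float(depth), orientation=orientation,
                              rd=relative_difference(phi, psi),
                              iterations=fld.info.get("iterations", 0)))
    if csv_path is not None:
        with open(csv_path, "w") as fh:
            fh.write("depth_m,orientation,rd\n")
            for row in rows:
                fh.write(f"{row.depth:.6g},{row.orientation},{row.rd:.8g}\n")
    if plot_path is not None:
        _plot_rd(rows, plot_path)
    return rows


def _plot_rd(rows: list[RDRow], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for orientation in sorted({r.orientation for r in rows}):
        sel = sorted((r.depth, r.rd) for r in rows if r.orientation == orientation)
        ax.plot([d * 1e3 for d, _ in sel], [v for _, v in sel],
                marker="o", label=orientation)
    ax.set_xlabel("dipole depth below interface (mm)")
    ax.set_ylabel("relative difference")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
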