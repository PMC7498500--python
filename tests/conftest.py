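"""Shared fixtures: small deterministic meshes and material helpers."""

import numpy as np
import pytest

from vcfem import meshkit as mk
from vcfem.dielectrics import TISSUES, admittivity_of, cole_cole_eval

FOUR_SPHERE_RADII = (0.079, 0.080, 0.085, 0.090)
LAYER_TISSUES = ("grey", "csf", "skull", "scalp")


@pytest.fixture(scope="session")
def box():
    """Structured 20x10x10 mm box, 10x5x5 cells."""
    return mk.box_mesh([0.02, 0.01, 0.01], [10, 5, 5])


@pytest.fixture(scope="session")
def ball_small():
    """Octahedron-based ball, ~800 nodes."""
    return mk.structured_ball_mesh(0.09, 3)


@pytest.fixture(scope="session")
def ball_tiny():
    """Octahedron-based ball under 300 dofs (dense-oracle scale)."""
    return mk.structured_ball_mesh(0.05, 2)


@pytest.fixture(scope="session")
def sphere_one_layer():
    spec = mk.SphereLayerSpec(radii=(0.09,), edge_length=0.012)
    return mk.generate_layered_sphere_mesh(spec, seed=1)


@pytest.fixture(scope="session")
def sphere_four_layer():
    spec = mk.SphereLayerSpec(radii=FOUR_SPHERE_RADII,
                              edge_length=(0.008, 0.0035, 0.006, 0.006))
    return mk.generate_layered_sphere_mesh(spec, seed=2)


@pytest.fixture(scope="session")
def slab_mesh():
    """Small MEA-style slab-in-bath fixture with one patch and a ground."""
    return mk.generate_slab_in_bath_mesh(
        bath_diameter=19e-3, bath_height=5e-3, slab_dims=(4e-3, 4e-3, 0.6e-3),
        electrode_patches=[("rect", (1e-3, 1e-3), (0.0, 0.0))],
        ground_patch=(2.5e-3, 3e-3, 0.0, 1.2),
        edge_length=1.8e-3, patch_edge_length=0.4e-3, seed=5)


@pytest.fixture(scope="session")
def admittivities_10mhz():
    """Complex admittivity per four-sphere layer marker at 10 MHz."""
    out = {}
    for marker, tissue in enumerate(LAYER_TISSUES, start=1):
        sigma, eps_r = cole_cole_eval(TISSUES[tissue], 1e7)
        out[marker] = admittivity_of(sigma, eps_r, 1e7)
    return out


def dense_stiffness_oracle(nodes, tets, sigma_per_cell):
    """Independent dense P1 stiffness assembly for oracle comparisons.

    Computes basis gradients from the explicit face-normal formula
    (grad lambda_i = opposite-face normal / (3 V_i-height)) rather than the
    coefficient-matrix inverse used by the implementation.
    """
    n = len(nodes)
    A = np.zeros((n, n), dtype=complex)
    for t, sig in zip(tets, sigma_per_cell):
        v = nodes[t]
        e1, e2, e3 = v[1] - v[0], v[2] - v[0], v[3] - v[0]
        vol = abs(np.dot(e1, np.cross(e2, e3))) / 6.0
        grads = np.zeros((4, 3))
        for i in range(4):
            opp = [k for k in range(4) if k != i]
            p0, p1, p2 = v[opp[0]], v[opp[1]], v[opp[2]]
            nrm = np.cross(p1 - p0, p2 - p0)
            # orient the face normal away from vertex i, then gradient points
            # toward vertex i with magnitude 1/height
            if np.dot(nrm, v[i] - p0) > 0:
                nrm = -nrm
            grads[i] = -nrm / (6.0 * vol)
        for i in range(4):
            for j in range(4):
                A[t[i], t[j]] += sig * vol * np.dot(grads[i], grads[j])
    return A
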