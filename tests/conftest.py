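"""Shared fixtures. The expensive objects (meshed phantoms, FEM solves,
the surrogate calibration ladder) are session-scoped and reused across
test modules."""

import warnings

import numpy as np
import pytest

from tdcshead.cohort import calibrate_surrogate
from tdcshead.fem import scale_to_current, solve_potential
from tdcshead.mesh import Tissue
from tdcshead.phantom import (
    STANDARD_MONTAGES,
    LayerSpec,
    attach_electrodes,
    build_concentric_sphere,
    build_layered_sphere,
    build_slab,
)

warnings.filterwarnings("ignore", message="edge length .* exceeds the thinnest layer")


DEFAULT_LAYERS = LayerSpec(interior_coarsen_below=55.0)


@pytest.fixture(scope="session")
def default_phantom():
    """The standard five-tissue head phantom (78/71/65/63/60 mm, 5 mm edge)."""
    return build_layered_sphere(DEFAULT_LAYERS, seed=1)


@pytest.fixture(scope="session")
def wired_phantom(default_phantom):
    return attach_electrodes(default_phantom, STANDARD_MONTAGES["fp1fp2"])


@pytest.fixture(scope="session")
def phantom_solution(wired_phantom):
    return scale_to_current(solve_potential(wired_phantom), 2.0)


@pytest.fixture(scope="session")
def homogeneous_slab():
    """Single-tissue 40x40x10 mm slab with plate-electrode node sets."""
    return build_slab([10.0], [Tissue.SCALP], lx=40.0, ly=40.0, edge_length=2.5)


@pytest.fixture(scope="session")
def five_layer_slab():
    """Flat slab with the phantom's layer thicknesses (7/6/2/3/8 mm)."""
    return build_slab(
        [7.0, 6.0, 2.0, 3.0, 8.0],
        [Tissue.SCALP, Tissue.SKULL, Tissue.CSF, Tissue.GRAY_MATTER,
         Tissue.WHITE_MATTER],
        lx=40.0, ly=40.0, edge_length=1.0,
    )


THREE_LAYER_RADII = (80.0, 85.0, 92.0)          # brain, skull, scalp (ascending)
THREE_LAYER_SIGMA = (0.33, 0.0042, 0.33)


@pytest.fixture(scope="session")
def three_layer_sphere():
    """Classic three-shell validation head (4 mm edge) with polar Dirichlet
    cap electrodes of 15 mm geodesic radius."""
    mesh = build_concentric_sphere(
        radii=THREE_LAYER_RADII[::-1],
        tissues=(Tissue.SCALP, Tissue.SKULL, Tissue.GRAY_MATTER),
        edge_length=4.0,
        seed=0,
        interior_coarsen_below=70.0,
        interior_coarsen_factor=1.8,
    )
    r = np.linalg.norm(mesh.nodes, axis=1)
    outer = r > THREE_LAYER_RADII[-1] - 1e-6
    polar = np.arccos(np.clip(mesh.nodes[:, 2] / np.maximum(r, 1e-12), -1, 1))
    geo = THREE_LAYER_RADII[-1] * polar
    mesh.node_sets["anode"] = np.flatnonzero(outer & (geo < 15.0))
    mesh.node_sets["cathode"] = np.flatnonzero(
        outer & (THREE_LAYER_RADII[-1] * (np.pi - polar) < 15.0)
    )
    return mesh


@pytest.fixture(scope="session")
def three_layer_solution(three_layer_sphere):
    from tdcshead.fem import ConductivityTable

    cond = ConductivityTable({
        Tissue.SCALP: THREE_LAYER_SIGMA[2],
        Tissue.SKULL: THREE_LAYER_SIGMA[1],
        Tissue.GRAY_MATTER: THREE_LAYER_SIGMA[0],
    })
    return solve_potential(three_layer_sphere, cond), cond


@pytest.fixture(scope="session")
def surrogate():
    """FEM-calibrated thickness-to-field surrogate (6-point scalp ladder)."""
    return calibrate_surrogate(base_layers=DEFAULT_LAYERS, seed=0)
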