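"""Quasi-static tDCS field solver on labeled tetrahedral meshes.

The injected current obeys the conduction equation div(sigma grad phi) = 0
with fixed potentials on the two electrode contact surfaces; the field is
E = -grad phi, constant within each linear (P1) tetrahedral element.  The
solve uses unit Dirichlet potentials (+1 V anode, -1 V cathode) and the
solution is rescaled afterwards to the montage's target current -- the
problem is linear, so the rescaled solution solves the target-current
problem exactly.

Units: mesh coordinates in mm (converted to metres internally), conductivity
in S/m, potential in V, field in V/m, current in mA at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TetMesh, Tissue

#: Isotropic conductivities (S/m).  The skull value is the compact-bone
#: default of the simulator family this mirrors; the sponge is saline.
DEFAULT_CONDUCTIVITIES = {
    Tissue.SCALP: 0.465,
    Tissue.SKULL: 0.010,
    Tissue.CSF: 1.654,
    Tissue.GRAY_MATTER: 0.275,
    Tissue.WHITE_MATTER: 0.126,
    Tissue.ELECTRODE: 1.0,
}


class ConfigurationError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


class EmptyROIError(ValueError):
    pass


@dataclass(frozen=True)
class ConductivityTable:
    values: dict = None

    def __post_init__(self):
        vals = dict(DEFAULT_CONDUCTIVITIES)
        if self.values:
            vals.update({Tissue(k): float(v) for k, v in self.values.items()})
        if any(v <= 0 for v in vals.values()):
            raise ConfigurationError("conductivities must be positive")
        object.__setattr__(self, "values", vals)

    def for_mesh(self, mesh: TetMesh) -> np.ndarray:
        """Per-element sigma; raises if a mesh tissue has no entry."""
        present = mesh.tissues_present()
        missing = [t.name for t in present if t not in self.values]
        if missing:
            raise ConfigurationError(f"no conductivity for tissues: {missing}")
        lut = np.zeros(max(int(t) for t in Tissue) + 1)
        for t, v in self.values.items():
            lut[int(t)] = v
        return lut[mesh.labels]


@dataclass(frozen=True)
class ROISpec:
    """Spherical region of interest in mesh (mm) coordinates.

    The radius defaults to the 10 mm used for the primary field extraction;
    a 20 mm variant is used as a robustness check.  Membership is by element
    centroid; by default only gray-matter elements contribute.
    """

    center: tuple
    radius: float = 10.0
    tissue: Tissue | None = Tissue.GRAY_MATTER

    def __post_init__(self):
        if self.radius <= 0:
            raise ConfigurationError("ROI radius must be positive")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


@dataclass
class FieldSolution:
    """Node potentials and element fields for one montage solve."""

    mesh: TetMesh
    phi: np.ndarray            # (n_nodes,) V
    e_field: np.ndarray        # (n_elements, 3) V/m
    magnitude: np.ndarray      # (n_elements,) V/m
    injected_current_ma: float
    anode_set: str = "anode"
    cathode_set: str = "cathode"
    montage: str = ""

    def scaled(self, factor: float) -> "FieldSolution":
        return replace(
            self,
            phi=self.phi * factor,
            e_field=self.e_field * factor,
            magnitude=self.magnitude * abs(factor),
            injected_current_ma=self.injected_current_ma * factor,
        )


def _element_gradients(nodes_m: np.ndarray, elements: np.ndarray):
    """P1 shape-function gradients (per element, 4 x 3, units 1/m) + volumes."""
    p = nodes_m[elements]
    edges = p[:, 1:, :] - p[:, 0:1, :]
    det = np.linalg.det(edges)
    vol = np.abs(det) / 6.0
    inv = np.linalg.inv(edges)
    grads = np.empty((len(elements), 4, 3))
    grads[:, 1:, :] = inv.transpose(0, 2, 1)
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    return grads, vol


def assemble_stiffness(mesh: TetMesh, cond: ConductivityTable) -> sp.csr_matrix:
    """Conductivity-weighted stiffness matrix K (SI units: K @ phi = nodal A)."""
    sigma = cond.for_mesh(mesh)
    grads, vol = _element_gradients(mesh.nodes * 1e-3, mesh.elements)
    ke = sigma[:, None, None] * vol[:, None, None] * np.einsum(
        "eik,ejk->eij", grads, grads
    )
    elems = mesh.elements
    rows = np.repeat(elems, 4, axis=1).reshape(-1)
    cols = np.tile(elems, (1, 4)).reshape(-1)
    n = mesh.n_nodes
    return sp.coo_matrix((ke.reshape(-1), (rows, cols)), shape=(n, n)).tocsr()


def solve_potential(
    mesh: TetMesh,
    cond: ConductivityTable | None = None,
    anode_set: str = "anode",
    cathode_set: str = "cathode",
    rtol: float = 1e-10,
    direct_max_unknowns: int = 20000,
    montage: str = "",
) -> FieldSolution:
    """Solve for the potential with +1/-1 V on the two contact node sets.

    Small systems use a sparse direct factorisation; larger ones a
    Jacobi-preconditioned conjugate gradient (the operator is SPD).
    """
    cond = cond or ConductivityTable()
    for name in (anode_set, cathode_set):
        if name not in mesh.node_sets or len(mesh.node_sets[name]) == 0:
            raise ConfigurationError(f"mesh has no node set {name!r}")
    K = assemble_stiffness(mesh, cond)
    anode = np.asarray(mesh.node_sets[anode_set])
    cathode = np.asarray(mesh.node_sets[cathode_set])
    fixed = np.concatenate([anode, cathode])
    if len(np.unique(fixed)) != len(fixed):
        raise ConfigurationError("anode and cathode node sets overlap")
    vals = np.concatenate([np.ones(len(anode)), -np.ones(len(cathode))])
    free = np.setdiff1d(np.arange(mesh.n_nodes), fixed)

    phi = np.zeros(mesh.n_nodes)
    phi[fixed] = vals
    Kf = K[free]
    rhs = -Kf[:, fixed] @ vals
    Kff = Kf[:, free]
    if len(free) <= direct_max_unknowns:
        try:
            phi[free] = spla.spsolve(Kff.tocsc(), rhs)
        except Exception as exc:  # singular factorisation
            raise SolverError(f"direct solve failed: {exc}") from exc
    else:
        dinv = 1.0 / Kff.diagonal()
        precond = spla.LinearOperator(Kff.shape, lambda x: dinv * x)
        sol, info = spla.cg(Kff, rhs, rtol=rtol, maxiter=20000, M=precond)
        if info != 0:
            raise SolverError(
                f"CG did not converge (info={info}); electrode sets may be "
                "disconnected from the mesh"
            )
        phi[free] = sol
    if not np.all(np.isfinite(phi)):
        raise SolverError("non-finite potentials (singular system)")

    grads, _vol = _element_gradients(mesh.nodes * 1e-3, mesh.elements)
    e_field = -np.einsum("ei,eij->ej", phi[mesh.elements], grads)
    sol = FieldSolution(
        mesh=mesh,
        phi=phi,
        e_field=e_field,
        magnitude=np.linalg.norm(e_field, axis=1),
        injected_current_ma=0.0,
        anode_set=anode_set,
        cathode_set=cathode_set,
        montage=montage or str(mesh.metadata.get("montage", "")),
    )
    sol.injected_current_ma = injected_current(sol, anode_set, stiffness=K)
    return sol


def injected_current(
    sol: FieldSolution,
    electrode_set: str | None = None,
    cond: ConductivityTable | None = None,
    stiffness: sp.csr_matrix | None = None,
) -> float:
    """Current (mA) through a contact surface, positive out of the anode.

    Computed as the sum of discrete nodal residuals K phi over the contact
    nodes -- the FEM-consistent surface integral of sigma dphi/dn, exact for
    the discrete solution (so anode and cathode currents cancel to rounding).
    """
    electrode_set = electrode_set or sol.anode_set
    nodes = sol.mesh.node_sets.get(electrode_set)
    if nodes is None or len(nodes) == 0:
        raise ConfigurationError(f"empty or missing node set {electrode_set!r}")
    K = stiffness if stiffness is not None else assemble_stiffness(
        sol.mesh, cond or ConductivityTable()
    )
    residual = K @ sol.phi
    return float(residual[np.asarray(nodes)].sum() * 1e3)


def scale_to_current(sol: FieldSolution, target_ma: float) -> FieldSolution:
    """Rescale a solved potential to the target injected current (mA)."""
    if target_ma == 0:
        raise ConfigurationError("target current of 0 mA is degenerate")
    if sol.injected_current_ma == 0:
        raise SolverError("solution carries no current; cannot scale")
    return sol.scaled(target_ma / sol.injected_current_ma)


def roi_mean_magnitude(
    mesh: TetMesh,
    sol: FieldSolution,
    roi: ROISpec,
    volume_weighted: bool = True,
) -> float:
    """Mean |E| (V/m) over elements whose centroid lies in the ROI sphere.

    Volume-weighted by default; elements exactly on the radius are included.
    Raises :class:`EmptyROIError` rather than returning a silent 0.
    """
    cent = mesh.centroids()
    dist = np.linalg.norm(cent - np.asarray(roi.center), axis=1)
    sel = dist <= roi.radius
    if roi.tissue is not None:
        sel &= mesh.labels == int(roi.tissue)
    if not sel.any():
        raise EmptyROIError(
            f"no {'any-tissue' if roi.tissue is None else Tissue(roi.tissue).name} "
            f"element centroid within {roi.radius} mm of {roi.center}"
        )
    mag = sol.magnitude[sel]
    if volume_weighted:
        w = mesh.volumes()[sel]
        return float((mag * w).sum() / w.sum())
    return float(mag.mean())

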