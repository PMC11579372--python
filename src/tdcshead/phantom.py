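"""Layered-sphere head phantoms and sponge-electrode attachment.

The phantom is a concentric five-tissue sphere (scalp, skull, CSF, gray
matter, white matter).  It deliberately has no gyral folding: the mechanism
under study -- layer thickness attenuating the injected field -- survives the
simplification, and spherical geometry admits analytic cross-checks for both
the FEM solver and the thickness algorithm.

Meshing strategy: points are laid out on concentric Fibonacci-lattice shells
(one shell per tissue boundary, fill shells in between so the radial gap
never exceeds the target edge length), jointly triangulated with Delaunay,
and each tetrahedron labeled by the radial band containing its centroid.
Everything is deterministic for a fixed seed: the only randomness is one
rotation per shell, drawn from a seeded generator, which breaks the lattice
alignment between neighbouring shells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay

from .mesh import HEAD_TISSUES, TetMesh, Tissue


class LayerSpecError(ValueError):
    """Non-monotone radii or invalid meshing parameters."""


class MontageError(ValueError):
    """Invalid electrode configuration (roles, overlap, placement)."""


@dataclass(frozen=True)
class LayerSpec:
    """Outer radii (mm) of the five tissue shells, outermost first.

    ``radii[0]`` is the scalp (head) radius; white matter fills the core.
    Defaults give frontal-adult-like layer thicknesses: scalp 7 mm, skull
    6 mm, CSF 2 mm, gray matter 3 mm.
    """

    radii: tuple = (78.0, 71.0, 65.0, 63.0, 60.0)
    edge_length: float = 5.0
    interior_coarsen_below: float = 0.0   # radius under which spacing grows
    interior_coarsen_factor: float = 1.7

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        if len(r) != 5:
            raise LayerSpecError(f"expected 5 radii, got {len(r)}")
        if not np.all(np.diff(r) < 0):
            raise LayerSpecError(f"radii must be strictly decreasing: {tuple(r)}")
        if self.edge_length <= 0:
            raise LayerSpecError("edge length must be positive")
        thinnest = float(np.min(-np.diff(r)))
        if self.edge_length >= thinnest:
            warnings.warn(
                f"edge length {self.edge_length} mm exceeds the thinnest layer "
                f"({thinnest} mm); labels will be noisy",
                stacklevel=2,
            )

    def thicknesses(self) -> dict:
        r = self.radii
        return {
            Tissue.SCALP: r[0] - r[1],
            Tissue.SKULL: r[1] - r[2],
            Tissue.CSF: r[2] - r[3],
            Tissue.GRAY_MATTER: r[3] - r[4],
        }

    def with_scalp_thickness(self, scalp_mm: float) -> "LayerSpec":
        """Same inner anatomy, different scalp thickness (outer radius moves)."""
        if scalp_mm <= 0:
            raise LayerSpecError("scalp thickness must be positive")
        new_outer = self.radii[1] + scalp_mm
        return replace(self, radii=(new_outer,) + tuple(self.radii[1:]))


@dataclass(frozen=True)
class ElectrodeSpec:
    """One square sponge electrode projected onto the scalp."""

    direction: tuple          # unit vector from sphere centre to patch centre
    role: str                 # "anode" | "cathode"
    side_mm: float = 50.0     # 5 x 5 cm footprint
    thickness_mm: float = 5.0

    def __post_init__(self):
        if self.role not in ("anode", "cathode"):
            raise MontageError(f"electrode role must be anode/cathode, got {self.role!r}")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise MontageError("electrode direction must be nonzero")
        object.__setattr__(self, "direction", tuple(d / n))


@dataclass(frozen=True)
class Montage:
    """Anode/cathode pair with a target current."""

    name: str
    electrodes: tuple
    target_current_ma: float = 2.0

    def __post_init__(self):
        roles = sorted(e.role for e in self.electrodes)
        if roles != ["anode", "cathode"]:
            raise MontageError(
                f"montage {self.name!r} needs exactly one anode and one "
                f"cathode, got roles {roles}"
            )
        if self.target_current_ma <= 0:
            raise MontageError("target current must be positive")

    @property
    def anode(self) -> ElectrodeSpec:
        return next(e for e in self.electrodes if e.role == "anode")

    @property
    def cathode(self) -> ElectrodeSpec:
        return next(e for e in self.electrodes if e.role == "cathode")


def _unit(theta_deg, az_deg):
    t, a = np.deg2rad(theta_deg), np.deg2rad(az_deg)
    return (np.sin(t) * np.cos(a), np.sin(t) * np.sin(a), np.cos(t))


# Phantom analogues of the 10-10 positions used for stimulation.  Convention:
# +z vertex, +x nasion (forward), +y left ear.  Fp1/Fp2 sit low on the
# forehead either side of the midline; F3 is higher and further left.
ELECTRODE_DIRECTIONS = {
    "Fp1": _unit(72.0, 26.0),
    "Fp2": _unit(72.0, -26.0),
    "F3": _unit(54.0, 41.0),
}

STANDARD_MONTAGES = {
    "fp1fp2": Montage(
        "Fp1-Fp2",
        (
            ElectrodeSpec(ELECTRODE_DIRECTIONS["Fp1"], "anode"),
            ElectrodeSpec(ELECTRODE_DIRECTIONS["Fp2"], "cathode"),
        ),
    ),
    "f3fp2": Montage(
        "F3-Fp2",
        (
            ElectrodeSpec(ELECTRODE_DIRECTIONS["F3"], "anode"),
            ElectrodeSpec(ELECTRODE_DIRECTIONS["Fp2"], "cathode"),
        ),
    ),
}

# Gray-matter targets standing in for the bilateral dlPFC, specified directly
# in phantom coordinates (mid gray-matter shell of the default LayerSpec).
DLPFC_DIRECTIONS = {
    "left": _unit(45.0, 45.0),
    "right": _unit(45.0, -45.0),
}


def fibonacci_sphere(n: int, rotation: np.ndarray | None = None) -> np.ndarray:
    """n nearly-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / n)
    azim = np.pi * (1.0 + np.sqrt(5.0)) * i
    pts = np.column_stack(
        (np.sin(polar) * np.cos(azim), np.sin(polar) * np.sin(azim), np.cos(polar))
    )
    if rotation is not None:
        pts = pts @ rotation.T
    return pts


def _random_rotation(rng) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def build_concentric_sphere(
    radii,
    tissues,
    edge_length: float,
    seed: int = 0,
    interior_coarsen_below: float = 0.0,
    interior_coarsen_factor: float = 1.7,
) -> TetMesh:
    """Delaunay-mesh a ball partitioned into concentric labeled shells.

    Parameters
    ----------
    radii : decreasing outer radii (mm), one per shell
    tissues : matching :class:`Tissue` per shell; innermost fills the core
    """
    radii = [float(r) for r in radii]
    if not all(a > b for a, b in zip(radii, radii[1:])) or radii[-1] <= 0:
        raise LayerSpecError(f"radii must be strictly decreasing and positive: {radii}")
    if edge_length <= 0:
        raise LayerSpecError("edge length must be positive")
    if len(tissues) != len(radii):
        raise LayerSpecError("one tissue per shell required")

    rng = np.random.default_rng(seed)
    shells = set(radii)
    bounds = sorted(radii, reverse=True)
    for hi, lo in zip(bounds[:-1], bounds[1:]):
        k = int(np.floor((hi - lo) / edge_length))
        for j in range(1, k + 1):
            shells.add(hi - (hi - lo) * j / (k + 1))
    r = bounds[-1]
    while True:
        step = edge_length if r > interior_coarsen_below else edge_length * interior_coarsen_factor
        r -= step
        if r <= edge_length * 0.45:
            break
        shells.add(r)

    pts = [np.zeros((1, 3))]
    for rad in sorted(shells):
        spacing = edge_length if rad > interior_coarsen_below else edge_length * interior_coarsen_factor
        n = max(6, int(np.ceil(4.0 * np.pi * rad * rad / (0.866 * spacing**2))))
        pts.append(fibonacci_sphere(n, _random_rotation(rng)) * rad)
    nodes = np.vstack(pts)

    tri = Delaunay(nodes)
    elements = tri.simplices.astype(np.int64)
    cent = nodes[elements].mean(axis=1)
    crad = np.linalg.norm(cent, axis=1)
    # label by radial band; ties on a boundary radius go to the outer shell
    labels = np.full(len(elements), int(tissues[-1]), dtype=np.int16)
    for rad, tis in zip(radii, tissues):
        labels[crad <= rad] = int(tis)

    mesh = TetMesh(
        nodes,
        elements,
        labels,
        metadata={
            "kind": "concentric_sphere",
            "radii_mm": radii,
            "tissues": [Tissue(t).name for t in tissues],
            "edge_length_mm": edge_length,
            "seed": int(seed),
        },
    )
    mesh.orient_positive()
    vols = mesh.volumes()
    keep = vols > 1e-9 * edge_length**3
    if not keep.all():
        mesh = TetMesh(mesh.nodes, mesh.elements[keep], mesh.labels[keep],
                       metadata=mesh.metadata)
    return mesh


def build_layered_sphere(layers: LayerSpec, seed: int = 0) -> TetMesh:
    """Five-tissue head phantom per `layers`; deterministic for a fixed seed."""
    mesh = build_concentric_sphere(
        layers.radii,
        HEAD_TISSUES,
        layers.edge_length,
        seed=seed,
        interior_coarsen_below=layers.interior_coarsen_below,
        interior_coarsen_factor=layers.interior_coarsen_factor,
    )
    mesh.metadata["kind"] = "layered_sphere_phantom"
    mesh.metadata["layer_spec"] = {
        "radii": list(layers.radii),
        "edge_length": layers.edge_length,
    }
    return mesh


def build_slab(
    layer_thicknesses,
    tissues,
    lx: float = 40.0,
    ly: float = 40.0,
    edge_length: float = 5.0,
) -> TetMesh:
    """Structured flat-slab mesh: layers stacked along -z from z=0 downward.

    Each cube is cut into six tetrahedra (Kuhn split), which is conforming
    across neighbouring cubes.  Node sets ``top`` (z=0) and ``bottom`` are
    attached for plate-electrode boundary conditions.
    """
    layer_thicknesses = [float(t) for t in layer_thicknesses]
    if any(t <= 0 for t in layer_thicknesses):
        raise LayerSpecError("layer thicknesses must be positive")
    nx = max(1, int(round(lx / edge_length)))
    ny = max(1, int(round(ly / edge_length)))
    zs = [0.0]
    zlab = []
    for t, tis in zip(layer_thicknesses, tissues):
        nz = max(1, int(round(t / edge_length)))
        base = zs[-1]
        for k in range(1, nz + 1):
            zs.append(base - t * k / nz)
            zlab.append(int(tis))
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.asarray(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    nzp = len(zs)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * nzp + k

    # Kuhn split: six tets along the main diagonal of each cube
    perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    elements, labels = [], []
    for i in range(nx):
        for j in range(ny):
            for k in range(nzp - 1):
                corner = np.array([i, j, k])
                for p in perms:
                    steps = np.zeros((4, 3), dtype=int)
                    for v, axis in enumerate(p):
                        steps[v + 1] = steps[v]
                        steps[v + 1, axis] += 1
                    verts = corner + steps
                    elements.append([nid(*v) for v in verts])
                    labels.append(zlab[k])
    mesh = TetMesh(
        nodes,
        np.asarray(elements),
        np.asarray(labels),
        metadata={
            "kind": "slab",
            "layer_thicknesses_mm": layer_thicknesses,
            "tissues": [Tissue(t).name for t in tissues],
        },
    )
    mesh.orient_positive()
    mesh.node_sets["top"] = np.flatnonzero(np.isclose(nodes[:, 2], 0.0))
    mesh.node_sets["bottom"] = np.flatnonzero(np.isclose(nodes[:, 2], zs[-1]))
    return mesh


# -- electrodes ----------------------------------------------------------


def _tangent_basis(direction):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(helper, d)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(d, t1)
    return d, t1, t2


def _footprint_faces(mesh: TetMesh, spec: ElectrodeSpec):
    """Exterior scalp faces inside the geodesic square patch."""
    faces, parents = mesh.boundary_faces()
    scalp = mesh.labels[parents] == Tissue.SCALP
    faces, parents = faces[scalp], parents[scalp]
    fc = mesh.nodes[faces].mean(axis=1)
    radius = np.linalg.norm(fc, axis=1)
    d, t1, t2 = _tangent_basis(spec.direction)
    u_hat = fc / radius[:, None]
    cosang = np.clip(u_hat @ d, -1.0, 1.0)
    ang = np.arccos(cosang)
    # geodesic coordinates of the patch centre frame
    psi = np.arctan2(u_hat @ t2, u_hat @ t1)
    gu = radius * ang * np.cos(psi)
    gv = radius * ang * np.sin(psi)
    half = spec.side_mm / 2.0
    sel = (np.abs(gu) <= half) & (np.abs(gv) <= half) & (ang < np.pi / 2)
    if not sel.any():
        raise MontageError(
            f"{spec.role} footprint contains no scalp surface faces "
            f"(direction {spec.direction})"
        )
    return faces[sel], parents[sel]


def _face_areas(nodes, faces):
    p = nodes[faces]
    return 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )


def attach_electrodes(mesh: TetMesh, montage: Montage) -> TetMesh:
    """Extrude sponge electrodes outward from the scalp surface.

    Returns a new mesh: head elements are untouched; each footprint triangle
    becomes a radial prism of electrode-labeled tetrahedra (split around a
    prism centroid so neighbouring prisms conform).  Named node sets
    ``anode``/``cathode`` hold the outer contact surfaces, and
    ``metadata['electrodes']`` records footprint areas (mm^2).
    """
    out = mesh.copy()
    foot = {}
    for spec in (montage.anode, montage.cathode):
        foot[spec.role] = _footprint_faces(mesh, spec)
    a_faces = {tuple(f) for f in foot["anode"][0]}
    c_faces = {tuple(f) for f in foot["cathode"][0]}
    if a_faces & c_faces:
        raise MontageError(
            f"montage {montage.name!r}: anode and cathode footprints overlap "
            f"({len(a_faces & c_faces)} shared faces)"
        )

    nodes = [out.nodes]
    n_next = out.n_nodes
    new_elements, new_labels = [], []
    info = {}
    for spec in (montage.anode, montage.cathode):
        faces, _parents = foot[spec.role]
        used = np.unique(faces)
        # outer copies: radial offset by sponge thickness
        base = out.nodes[used]
        rhat = base / np.linalg.norm(base, axis=1)[:, None]
        top = base + rhat * spec.thickness_mm
        top_idx = {int(u): n_next + i for i, u in enumerate(used)}
        nodes.append(top)
        n_next += len(used)
        contact = np.array(sorted(top_idx.values()), dtype=np.int64)

        cent_start = n_next
        bverts = faces
        tverts = np.vectorize(top_idx.get)(faces)
        all_new = np.vstack(nodes)
        pcent = (all_new[bverts].sum(axis=1) + all_new[tverts].sum(axis=1)) / 6.0
        nodes.append(pcent)
        cent_idx = np.arange(cent_start, cent_start + len(faces))
        n_next += len(faces)

        tets = []
        for fi in range(len(faces)):
            b = bverts[fi]
            t = tverts[fi]
            c = cent_idx[fi]
            tets.append([b[0], b[1], b[2], c])       # bottom cap
            tets.append([t[0], t[1], t[2], c])       # top cap
            for e0, e1 in ((0, 1), (1, 2), (0, 2)):
                # quad side (b[e0], b[e1], t[e1], t[e0]); split along the
                # diagonal through the smallest global index so adjacent
                # prisms cut shared quads identically
                q = [b[e0], b[e1], int(t[e1]), int(t[e0])]
                lo = int(np.argmin(q))
                d0, d1 = q[lo], q[(lo + 2) % 4]
                o0, o1 = q[(lo + 1) % 4], q[(lo + 3) % 4]
                tets.append([d0, d1, o0, c])
                tets.append([d0, d1, o1, c])
        new_elements.extend(tets)
        new_labels.extend([int(Tissue.ELECTRODE)] * len(tets))
        out.node_sets[spec.role] = contact
        info[spec.role] = {
            "area_mm2": float(_face_areas(out.nodes, faces).sum()),
            "n_faces": int(len(faces)),
            "direction": list(spec.direction),
            "side_mm": spec.side_mm,
            "thickness_mm": spec.thickness_mm,
        }

    out.nodes = np.vstack(nodes)
    out.elements = np.vstack([out.elements, np.asarray(new_elements, dtype=np.int64)])
    out.labels = np.concatenate([out.labels, np.asarray(new_labels, dtype=np.int16)])
    out.orient_positive()
    out.metadata["montage"] = montage.name
    out.metadata["target_current_ma"] = montage.target_current_ma
    out.metadata["electrodes"] = info
    return out


# -- BMI -> scalp thickness ----------------------------------------------


@dataclass(frozen=True)
class BmiThicknessLink:
    """Monotone linear link from BMI (kg/m^2) to scalp thickness (mm).

    Defaults put a BMI-25 subject at 6.25 mm and a BMI-30 subject at 7 mm,
    matching the default phantom's 7 mm scalp at the psychosis-range BMI.
    """

    slope_mm_per_bmi: float = 0.15
    intercept_mm: float = 2.5
    noise_sd_mm: float = 0.0
    floor_mm: float = 2.0

    def __post_init__(self):
        if self.slope_mm_per_bmi < 0:
            raise ValueError("slope must be non-negative (thickness grows with BMI)")
        if self.floor_mm <= 0:
            raise ValueError("thickness floor must be positive")


def scalp_thickness_from_bmi(bmi, link: BmiThicknessLink = BmiThicknessLink(), seed=None):
    """Scalp thickness (mm) = intercept + slope*BMI + Gaussian noise, floored.

    `seed` may be an int or a ``numpy.random.Generator``; scalar in, scalar out.
    """
    bmi_arr = np.asarray(bmi, dtype=float)
    thick = link.intercept_mm + link.slope_mm_per_bmi * bmi_arr
    if link.noise_sd_mm > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        thick = thick + rng.normal(0.0, link.noise_sd_mm, size=bmi_arr.shape)
    thick = np.maximum(thick, link.floor_mm)
    return float(thick) if np.isscalar(bmi) else thick
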