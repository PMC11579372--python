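"""Normal-vector tissue-thickness measurement on labeled head meshes.

The thickness of each layer at a location is measured by walking inward:
take the outer-surface scalp triangles inside a surface ROI, find for each
triangle centre the minimum distance to the skull boundary surface, keep
only measurements whose direction agrees with the local inward normal
(within an angular tolerance -- the "perpendicularity" check), and average.
The skull foot-point triangles seed the skull-to-CSF measurement, and so on
down to gray matter; cortical thickness is measured from the gray-matter
surface to the white-matter boundary.  Scalp-to-cortex thickness is the sum
of the scalp, skull and CSF layers by definition.

Distances are from source triangle centroids to the nearest point anywhere
on the target surface (not centroid-to-centroid), computed with an exact
point-to-triangle projection over KD-tree candidate sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TetMesh, Tissue


class EmptyROIError(ValueError):
    pass


class MissingTissueError(ValueError):
    pass


class PerpendicularityError(RuntimeError):
    pass


class LayerError(RuntimeError):
    """A chained layer measurement failed; carries the layer name."""

    def __init__(self, layer: str, message: str):
        self.layer = layer
        super().__init__(f"{layer}: {message}")


# -- exact point-to-triangle projection ----------------------------------


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray):
    """Closest point on triangle i to point i (paired, vectorised).

    Parameters
    ----------
    points : (n, 3)
    triangles : (n, 3, 3) vertex coordinates

    Returns ``(foot_points, distances)``.  Standard region-based projection:
    project onto the triangle plane, then clamp to edges/vertices via the
    barycentric sign pattern.
    """
    p = np.asarray(points, dtype=float)
    a = triangles[:, 0]
    b = triangles[:, 1]
    c = triangles[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    foot = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        foot[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)                          # vertex A
    settle((d3 >= 0) & (d4 <= d3), b)                         # vertex B
    settle((d6 >= 0) & (d5 <= d6), c)                         # vertex C

    vc = d1 * d4 - d3 * d2
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    v = np.divide(d1, d1 - d3, out=np.zeros_like(d1), where=(d1 - d3) != 0)
    settle(m, a + v[:, None] * ab)                            # edge AB

    vb = d5 * d2 - d1 * d6
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w = np.divide(d2, d2 - d6, out=np.zeros_like(d2), where=(d2 - d6) != 0)
    settle(m, a + w[:, None] * ac)                            # edge AC

    va = d3 * d6 - d5 * d4
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    w = np.divide(d4 - d3, denom, out=np.zeros_like(denom), where=denom != 0)
    settle(m, b + w[:, None] * (c - b))                       # edge BC

    # interior
    denom = va + vb + vc
    v = np.divide(vb, denom, out=np.zeros_like(denom), where=denom != 0)
    w = np.divide(vc, denom, out=np.zeros_like(denom), where=denom != 0)
    settle(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)

    return foot, np.linalg.norm(p - foot, axis=1)


class TriangleSurface:
    """Triangle soup with nearest-point queries (KD-tree over centroids,
    exact projection on candidate triangles with a safe search radius)."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.tri = self.vertices[self.faces]
        self.centroids = self.tri.mean(axis=1)
        rel = self.tri - self.centroids[:, None, :]
        self._reach = float(np.linalg.norm(rel, axis=2).max()) if len(faces) else 0.0
        self._tree = cKDTree(self.centroids)

    def __len__(self):
        return len(self.faces)

    def nearest(self, points: np.ndarray):
        """Per query point: (foot point, distance, face index)."""
        points = np.atleast_2d(points)
        k = min(24, len(self.faces))
        _d, idx = self._tree.query(points, k=k)
        idx = np.atleast_2d(idx)
        best_d = np.full(len(points), np.inf)
        best_foot = np.zeros_like(points)
        best_face = np.zeros(len(points), dtype=np.int64)
        for col in range(idx.shape[1]):
            cand = idx[:, col]
            foot, dist = closest_point_on_triangles(points, self.tri[cand])
            better = dist < best_d
            best_d[better] = dist[better]
            best_foot[better] = foot[better]
            best_face[better] = cand[better]
        # a nearer triangle may exist outside the k candidates: re-check all
        # triangles whose centroid could beat the current best
        extra = self._tree.query_ball_point(points, best_d + self._reach)
        for i, cands in enumerate(extra):
            cands = np.setdiff1d(np.asarray(cands, dtype=np.int64), idx[i])
            if len(cands) == 0:
                continue
            foot, dist = closest_point_on_triangles(
                np.repeat(points[i : i + 1], len(cands), axis=0), self.tri[cands]
            )
            j = int(np.argmin(dist))
            if dist[j] < best_d[i]:
                best_d[i] = dist[j]
                best_foot[i] = foot[j]
                best_face[i] = cands[j]
        return best_foot, best_d, best_face


# -- surface patches ------------------------------------------------------


@dataclass
class SurfacePatch:
    """A set of boundary triangles of one tissue, with inward normals.

    ``parent_elements`` are the tetrahedra of `tissue` owning each face;
    inward normals point from each face toward its parent tet (i.e. into
    the tissue, in the direction of the measurement walk).
    """

    tissue: Tissue
    faces: np.ndarray            # (k, 3) node indices
    parent_elements: np.ndarray  # (k,)
    centroids: np.ndarray        # (k, 3) mm
    inward_normals: np.ndarray   # (k, 3) unit
    areas: np.ndarray            # (k,) mm^2

    def __len__(self):
        return len(self.faces)


def _make_patch(mesh: TetMesh, tissue: Tissue, faces, parents) -> SurfacePatch:
    p = mesh.nodes[faces]
    cent = p.mean(axis=1)
    nvec = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    areas = 0.5 * np.linalg.norm(nvec, axis=1)
    with np.errstate(invalid="ignore"):
        nhat = nvec / (2.0 * areas)[:, None]
    toward = mesh.nodes[mesh.elements[parents]].mean(axis=1) - cent
    flip = np.einsum("ij,ij->i", nhat, toward) < 0
    nhat[flip] *= -1.0
    return SurfacePatch(tissue, np.asarray(faces), np.asarray(parents), cent, nhat, areas)


def tissue_surface(mesh: TetMesh, tissue: Tissue) -> SurfacePatch:
    """Full boundary surface of one tissue (exterior + interfaces)."""
    faces, parents = mesh.tissue_boundary_faces(tissue)
    if len(faces) == 0:
        raise MissingTissueError(f"mesh has no {Tissue(tissue).name} elements")
    return _make_patch(mesh, tissue, faces, parents)


def outer_scalp_surface(mesh: TetMesh) -> SurfacePatch:
    """Exterior faces owned by scalp tetrahedra (the head surface)."""
    faces, parents = mesh.boundary_faces()
    sel = mesh.labels[parents] == Tissue.SCALP
    if not sel.any():
        raise MissingTissueError("mesh has no exterior scalp surface")
    return _make_patch(mesh, Tissue.SCALP, faces[sel], parents[sel])


def select_scalp_roi(mesh: TetMesh, center, radius: float = 10.0) -> SurfacePatch:
    """Outer-scalp surface triangles whose centroid lies within `radius` mm
    of `center` (Euclidean ball; at 10 mm on head-scale curvature the
    geodesic correction is negligible)."""
    if radius <= 0:
        raise ValueError("ROI radius must be positive")
    surf = outer_scalp_surface(mesh)
    center = np.asarray(center, dtype=float)
    dist = np.linalg.norm(surf.centroids - center, axis=1)
    sel = dist <= radius
    if not sel.any():
        raise EmptyROIError(
            f"no scalp surface element within {radius} mm of {tuple(center)} "
            f"(nearest at {dist.min():.1f} mm)"
        )
    return SurfacePatch(
        surf.tissue,
        surf.faces[sel],
        surf.parent_elements[sel],
        surf.centroids[sel],
        surf.inward_normals[sel],
        surf.areas[sel],
    )


@dataclass
class LayerMeasurement:
    """One layer's chained minimum-distance measurement."""

    mean_mm: float
    distances_mm: np.ndarray
    foot_patch: SurfacePatch       # unique foot-point faces on the target
    n_sources: int
    n_accepted: int


def layer_thickness(
    mesh: TetMesh,
    sources: SurfacePatch,
    target_tissue: Tissue,
    angle_tol_deg: float = 45.0,
    _target_surface: TriangleSurface | None = None,
    _target_patch: SurfacePatch | None = None,
) -> LayerMeasurement:
    """Mean minimum distance from source triangle centres to the boundary of
    `target_tissue`, keeping only directions within `angle_tol_deg` of each
    source's inward normal.

    Returns the measurement together with the unique foot-point faces, which
    seed the next layer of the chain.  Nearest-face ties are broken by the
    lowest face index (deterministic).
    """
    if len(sources) == 0:
        raise EmptyROIError("empty source patch")
    if _target_patch is None:
        _target_patch = tissue_surface(mesh, target_tissue)
    surf = _target_surface or TriangleSurface(mesh.nodes, _target_patch.faces)
    foot, dist, face_idx = surf.nearest(sources.centroids)

    direction = foot - sources.centroids
    norm = np.linalg.norm(direction, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", direction, sources.inward_normals) / norm
    # degenerate zero-distance hits count as aligned
    cosang = np.where(norm < 1e-12, 1.0, cosang)
    accepted = cosang >= np.cos(np.deg2rad(angle_tol_deg))
    if not accepted.any():
        raise PerpendicularityError(
            f"no {Tissue(target_tissue).name} foot point within "
            f"{angle_tol_deg} degrees of the inward normal for any source"
        )
    ufaces = np.unique(face_idx[accepted])
    foot_patch = SurfacePatch(
        _target_patch.tissue,
        _target_patch.faces[ufaces],
        _target_patch.parent_elements[ufaces],
        _target_patch.centroids[ufaces],
        _target_patch.inward_normals[ufaces],
        _target_patch.areas[ufaces],
    )
    d = dist[accepted]
    return LayerMeasurement(
        mean_mm=float(d.mean()),
        distances_mm=d,
        foot_patch=foot_patch,
        n_sources=len(sources),
        n_accepted=int(accepted.sum()),
    )


@dataclass
class ThicknessReport:
    """Per-location layer thicknesses (mm).

    ``scalp_to_cortex`` is scalp + skull + CSF by definition; cortical (gray
    matter) thickness is reported alongside but not included in the sum.
    """

    location: str
    scalp_mm: float
    skull_mm: float
    csf_mm: float
    cortex_mm: float
    element_counts: dict = field(default_factory=dict)

    @property
    def scalp_to_cortex_mm(self) -> float:
        return self.scalp_mm + self.skull_mm + self.csf_mm

    def to_dict(self) -> dict:
        return {
            "location": self.location,
            "scalp_mm": self.scalp_mm,
            "skull_mm": self.skull_mm,
            "csf_mm": self.csf_mm,
            "cortex_mm": self.cortex_mm,
            "scalp_to_cortex_mm": self.scalp_to_cortex_mm,
            "element_counts": dict(self.element_counts),
        }


_CHAIN = (
    ("scalp", Tissue.SKULL),
    ("skull", Tissue.CSF),
    ("csf", Tissue.GRAY_MATTER),
    ("cortex", Tissue.WHITE_MATTER),
)


def thickness_profile(
    mesh: TetMesh,
    center,
    radius: float = 10.0,
    angle_tol_deg: float = 45.0,
    location: str = "",
) -> ThicknessReport:
    """Chained scalp->skull->CSF->gray->white thickness measurement.

    Each layer's accepted foot-point faces become the next layer's sources.
    Failures are reported as :class:`LayerError` naming the layer.
    """
    try:
        sources = select_scalp_roi(mesh, center, radius)
    except (EmptyROIError, MissingTissueError) as exc:
        raise LayerError("scalp", str(exc)) from exc
    values = {}
    counts = {}
    layer_names = {Tissue.SKULL: "skull", Tissue.CSF: "CSF",
                   Tissue.GRAY_MATTER: "gray_matter", Tissue.WHITE_MATTER: "white_matter"}
    for name, target in _CHAIN:
        try:
            meas = layer_thickness(mesh, sources, target, angle_tol_deg)
        except MissingTissueError as exc:
            # a missing *target* tissue is named after that tissue
            raise LayerError(layer_names[target], str(exc)) from exc
        except (PerpendicularityError, EmptyROIError) as exc:
            raise LayerError(name, str(exc)) from exc
        values[name] = meas.mean_mm
        counts[name] = meas.n_accepted
        sources = meas.foot_patch
    return ThicknessReport(
        location=location or f"({center[0]:.0f},{center[1]:.0f},{center[2]:.0f})",
        scalp_mm=values["scalp"],
        skull_mm=values["skull"],
        csf_mm=values["csf"],
        cortex_mm=values["cortex"],
        element_counts=counts,
    )
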