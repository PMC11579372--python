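"""Labeled tetrahedral meshes.

A :class:`TetMesh` is the shared substrate for every downstream step: field
simulation needs element conductivities keyed by tissue, and the thickness
algorithm needs tissue interface surfaces.  Coordinates are millimetres
throughout; the FEM converts to SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


class Tissue(IntEnum):
    """Head tissue labels; integer values double as Gmsh physical tags."""

    SCALP = 1
    SKULL = 2
    CSF = 3
    GRAY_MATTER = 4
    WHITE_MATTER = 5
    ELECTRODE = 6


HEAD_TISSUES = (
    Tissue.SCALP,
    Tissue.SKULL,
    Tissue.CSF,
    Tissue.GRAY_MATTER,
    Tissue.WHITE_MATTER,
)

# local faces of a tetrahedron (vertex opposite each face omitted)
_TET_FACES = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


class MeshError(ValueError):
    pass


@dataclass
class TetMesh:
    """Tetrahedral mesh with per-element tissue labels.

    Parameters
    ----------
    nodes : (n, 3) float array, mm
    elements : (m, 4) int array of node indices
    labels : (m,) int array of :class:`Tissue` values
    node_sets : named node-index sets (e.g. electrode contact surfaces)
    metadata : free-form provenance (generator parameters, seed, ...)
    """

    nodes: np.ndarray
    elements: np.ndarray
    labels: np.ndarray
    node_sets: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int16)

    # -- derived geometry ------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_coords(self) -> np.ndarray:
        return self.nodes[self.elements]

    def centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)

    def signed_volumes(self) -> np.ndarray:
        p = self.element_coords()
        m = p[:, 1:, :] - p[:, 0:1, :]
        return np.linalg.det(m) / 6.0

    def volumes(self) -> np.ndarray:
        return np.abs(self.signed_volumes())

    def orient_positive(self) -> "TetMesh":
        """Swap two vertices of negatively oriented elements in place."""
        neg = self.signed_volumes() < 0
        if neg.any():
            self.elements[neg, 0], self.elements[neg, 1] = (
                self.elements[neg, 1].copy(),
                self.elements[neg, 0].copy(),
            )
        return self

    def tissues_present(self) -> set:
        return {Tissue(v) for v in np.unique(self.labels)}

    # -- faces -----------------------------------------------------------

    def _all_faces(self):
        """Every tet face as a sorted node triple, with parent element ids."""
        faces = self.elements[:, _TET_FACES].reshape(-1, 3)
        faces = np.sort(faces, axis=1)
        parents = np.repeat(np.arange(self.n_elements), 4)
        return faces, parents

    def _sorted_faces(self):
        """All faces lexicographically sorted so twins are adjacent."""
        faces, parents = self._all_faces()
        order = np.lexsort((faces[:, 2], faces[:, 1], faces[:, 0]))
        faces, parents = faces[order], parents[order]
        # run starts: a face equal to its predecessor is a twin
        new = np.ones(len(faces), dtype=bool)
        new[1:] = (faces[1:] != faces[:-1]).any(axis=1)
        starts = np.flatnonzero(new)
        counts = np.diff(np.append(starts, len(faces)))
        return faces, parents, starts, counts

    def boundary_faces(self):
        """Exterior faces (owned by exactly one tet).

        Returns ``(faces, parent_elements)`` with faces as sorted triples.
        """
        faces, parents, starts, counts = self._sorted_faces()
        ext = starts[counts == 1]
        return faces[ext], parents[ext]

    def tissue_boundary_faces(self, tissue: Tissue):
        """Boundary of one tissue: faces of its tets whose twin (if any)
        carries a different label.

        Returns ``(faces, parent_elements)``; parents are tets of `tissue`.
        """
        faces, parents, starts, counts = self._sorted_faces()
        out_faces, out_parents = [], []
        ext = starts[counts == 1]
        sel = self.labels[parents[ext]] == tissue
        out_faces.append(faces[ext][sel])
        out_parents.append(parents[ext][sel])
        sh = starts[counts == 2]
        a, b = parents[sh], parents[sh + 1]
        la, lb = self.labels[a], self.labels[b]
        mism = la != lb
        for pa, lab_a in ((a, la), (b, lb)):
            sel = mism & (lab_a == tissue)
            out_faces.append(faces[sh][sel])
            out_parents.append(pa[sel])
        faces = np.vstack(out_faces)
        parents = np.concatenate(out_parents)
        return faces, parents

    # -- validation ------------------------------------------------------

    def is_connected(self) -> bool:
        i = np.repeat(self.elements[:, 0], 3)
        j = self.elements[:, 1:].ravel()
        n = self.n_nodes
        adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
        ncomp, lab = connected_components(adj, directed=False)
        used = np.unique(self.elements)
        return len(np.unique(lab[used])) == 1

    def validate(self, require_head_tissues: bool = False) -> None:
        """Raise :class:`MeshError` on any violated invariant."""
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=-1) >= self.n_nodes:
            raise MeshError("element node index out of range")
        vols = self.signed_volumes()
        if (vols <= 0).any():
            raise MeshError(
                f"{(vols <= 0).sum()} elements with non-positive volume "
                "(call orient_positive() first)"
            )
        valid = {int(t) for t in Tissue}
        bad = set(np.unique(self.labels)) - valid
        if bad:
            raise MeshError(f"unknown tissue labels: {sorted(bad)}")
        if require_head_tissues:
            missing = set(HEAD_TISSUES) - self.tissues_present()
            if missing:
                raise MeshError(
                    "phantom missing tissues: "
                    + ", ".join(t.name for t in sorted(missing))
                )
        if not self.is_connected():
            raise MeshError("mesh is not connected")

    def copy(self) -> "TetMesh":
        return TetMesh(
            self.nodes.copy(),
            self.elements.copy(),
            self.labels.copy(),
            {k: np.asarray(v).copy() for k, v in self.node_sets.items()},
            dict(self.metadata),
        )
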