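"""Gmsh ASCII v2.2 mesh files with tissue labels as physical tags.

Only 4-node tetrahedra (element type 4) are read or written; the physical
tag carries the tissue label.  A JSON sidecar (``<mesh>.labels.json``)
stores the tag-to-tissue map and any named node sets, so a write/read
round-trip is lossless including electrode contact surfaces.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .mesh import TetMesh, Tissue

_TET_TYPE = 4


class MshParseError(ValueError):
    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


class UnknownTagError(ValueError):
    def __init__(self, tag):
        super().__init__(
            f"physical tag {tag} has no tissue mapping (sidecar or default)"
        )
        self.tag = tag


def default_sidecar_path(path) -> Path:
    return Path(str(path) + ".labels.json")


def write_msh(mesh: TetMesh, path, sidecar: bool = True) -> None:
    """Write Gmsh 2.2 ASCII (nodes 1-based) plus the JSON label sidecar."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write("$PhysicalNames\n")
        present = sorted({int(v) for v in np.unique(mesh.labels)})
        fh.write(f"{len(present)}\n")
        for tag in present:
            fh.write(f'3 {tag} "{Tissue(tag).name.lower()}"\n')
        fh.write("$EndPhysicalNames\n")
        fh.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {x:.10g} {y:.10g} {z:.10g}\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{mesh.n_elements}\n")
        for i, (elem, lab) in enumerate(zip(mesh.elements, mesh.labels), start=1):
            a, b, c, d = (int(v) + 1 for v in elem)
            fh.write(f"{i} {_TET_TYPE} 2 {int(lab)} {int(lab)} {a} {b} {c} {d}\n")
        fh.write("$EndElements\n")
    if sidecar:
        meta = {
            "tissue_tags": {t.name: int(t) for t in Tissue},
            "node_sets": {k: np.asarray(v).tolist() for k, v in mesh.node_sets.items()},
            "metadata": _jsonable(mesh.metadata),
        }
        default_sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_msh(path, sidecar: bool | str = True) -> TetMesh:
    """Read a Gmsh 2.2 ASCII tetrahedral mesh.

    Unknown physical tags raise :class:`UnknownTagError`; malformed
    sections raise :class:`MshParseError` with the offending line number.
    """
    path = Path(path)
    tag_map = {int(t): t for t in Tissue}
    node_sets = {}
    metadata = {}
    sc_path = None
    if sidecar is True:
        cand = default_sidecar_path(path)
        sc_path = cand if cand.exists() else None
    elif sidecar:
        sc_path = Path(sidecar)
    if sc_path is not None:
        meta = json.loads(Path(sc_path).read_text())
        tag_map = {int(v): Tissue(int(v)) for v in meta.get("tissue_tags", {}).values()}
        node_sets = {
            k: np.asarray(v, dtype=np.int64)
            for k, v in meta.get("node_sets", {}).items()
        }
        metadata = meta.get("metadata", {})

    lines = path.read_text().splitlines()
    nodes = None
    elements, labels = [], []
    i = 0
    try:
        while i < len(lines):
            line = lines[i].strip()
            if line == "$Nodes":
                count = int(lines[i + 1])
                raw = np.loadtxt(lines[i + 2 : i + 2 + count], ndmin=2)
                if raw.shape[0] != count or raw.shape[1] != 4:
                    raise MshParseError(path, i + 2, "malformed $Nodes block")
                order = np.argsort(raw[:, 0])
                nodes = raw[order, 1:4]
                if not np.array_equal(raw[order, 0], np.arange(1, count + 1)):
                    raise MshParseError(path, i + 2, "non-contiguous node ids")
                i += count + 2
                if lines[i].strip() != "$EndNodes":
                    raise MshParseError(path, i + 1, "missing $EndNodes")
            elif line == "$Elements":
                count = int(lines[i + 1])
                for j in range(count):
                    parts = lines[i + 2 + j].split()
                    etype = int(parts[1])
                    if etype != _TET_TYPE:
                        continue  # skip lower-dimensional entities
                    ntags = int(parts[2])
                    if ntags < 1:
                        raise MshParseError(path, i + 3 + j, "element without tags")
                    tag = int(parts[3])
                    if tag not in tag_map:
                        raise UnknownTagError(tag)
                    conn = [int(v) - 1 for v in parts[3 + ntags :]]
                    if len(conn) != 4:
                        raise MshParseError(
                            path, i + 3 + j, f"expected 4 nodes, got {len(conn)}"
                        )
                    elements.append(conn)
                    labels.append(int(tag_map[tag]))
                i += count + 2
                if lines[i].strip() != "$EndElements":
                    raise MshParseError(path, i + 1, "missing $EndElements")
            i += 1
    except (ValueError, IndexError) as exc:
        if isinstance(exc, (MshParseError, UnknownTagError)):
            raise
        raise MshParseError(path, i + 1, f"parse failure: {exc}") from exc
    if nodes is None or not elements:
        raise MshParseError(path, len(lines), "no nodes or no tetrahedra found")
    return TetMesh(nodes, np.asarray(elements), np.asarray(labels),
                   node_sets=node_sets, metadata=metadata)
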