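"""Triangle-mesh container with named face groups.

Every geometry operation in the package produces a :class:`TriMesh`:
float64 vertices in centimetres (right-handed frame, Z up) and int64
triangle faces indexing into them. Faces are partitioned into named,
contiguous, disjoint groups (``stem``, per-layer leaf groups, ``soil``)
so downstream radiative-transfer tooling can assign optical properties
per component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = ["TriMesh", "merge_meshes"]


@dataclass
class TriMesh:
    """Triangle mesh: ``vertices`` (n, 3) cm, ``faces`` (m, 3) 0-based,
    ``groups`` mapping name -> half-open face-index range [start, stop)."""

    vertices: np.ndarray
    faces: np.ndarray
    groups: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not self.groups and len(self.faces):
            self.groups = {"default": (0, len(self.faces))}
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if not np.all(np.isfinite(self.vertices)):
            raise DomainError("mesh contains non-finite vertex coordinates")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise DomainError("face index out of vertex range")
        spans = sorted(self.groups.values())
        covered = 0
        for start, stop in spans:
            if start != covered:
                raise DomainError("group ranges must be contiguous and disjoint")
            covered = stop
        if covered != len(self.faces):
            raise DomainError("group ranges must cover all faces")

    # -- basic queries --------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def bounds(self) -> np.ndarray:
        """(2, 3) array of [min; max] vertex coordinates."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    # -- transforms (all return new meshes; vertices are never aliased) --
    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "TriMesh":
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=np.float64).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=np.float64)
        return TriMesh(v.copy(), self.faces.copy(), dict(self.groups))

    def translated(self, offset) -> "TriMesh":
        return self.transformed(translation=np.asarray(offset, dtype=np.float64))

    # -- group extraction -----------------------------------------------
    def submesh(self, group: str) -> "TriMesh":
        """Extract one face group as a standalone mesh (vertices compacted)."""
        start, stop = self.groups[group]
        faces = self.faces[start:stop]
        used = np.unique(faces)
        remap = np.full(len(self.vertices), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriMesh(self.vertices[used].copy(), remap[faces],
                       {group: (0, stop - start)})


def merge_meshes(parts: list[tuple[str, TriMesh]]) -> TriMesh:
    """Concatenate meshes into one, assigning each part's faces to the named
    group. Consecutive parts sharing a name are coalesced into a single
    contiguous group; a name may not reappear after a different one.
    """
    verts: list[np.ndarray] = []
    faces: list[np.ndarray] = []
    groups: dict[str, tuple[int, int]] = {}
    v_off = 0
    f_off = 0
    last_name: str | None = None
    for name, mesh in parts:
        verts.append(mesh.vertices)
        faces.append(mesh.faces + v_off)
        nf = mesh.n_faces
        if name == last_name:
            start, _ = groups[name]
            groups[name] = (start, f_off + nf)
        else:
            if name in groups:
                raise DomainError(
                    f"group {name!r} reappears non-contiguously in merge"
                )
            groups[name] = (f_off, f_off + nf)
        last_name = name
        v_off += mesh.n_vertices
        f_off += nf
    if not verts:
        return TriMesh(np.empty((0, 3)), np.empty((0, 3), dtype=np.int64), {})
    return TriMesh(np.vstack(verts), np.vstack(faces), groups)
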