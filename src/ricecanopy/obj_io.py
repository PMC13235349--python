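"""Wavefront OBJ read/write with named face groups, and the JSON scene
manifest that binds mesh groups to optical-property files for an external
3D radiative-transfer engine.

OBJ conventions: units are centimetres, vertices printed with 6 decimal
places, faces 1-based, one ``g`` line per group. Output bytes are
deterministic for a given model, so scene files can be diffed and cached.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .assembly import HillModel, SceneModel
from .errors import FormatError, ValidationError
from .mesh import TriMesh
from .traits import PROSPECT_METADATA

__all__ = [
    "write_obj",
    "read_obj",
    "write_scene_manifest",
    "read_scene_manifest",
]

log = logging.getLogger(__name__)

_OBJ_HEADER = "# ricecanopy OBJ v1 (units: cm)\n"


def _as_mesh(model: TriMesh | HillModel | SceneModel) -> TriMesh:
    if isinstance(model, TriMesh):
        return model
    if isinstance(model, HillModel):
        return model.full
    if isinstance(model, SceneModel):
        return model.mesh
    raise FormatError(f"cannot write object of type {type(model).__name__}")


def write_obj(model: TriMesh | HillModel | SceneModel, path) -> None:
    """Write a mesh (or a hill/scene model's mesh) as Wavefront OBJ."""
    mesh = _as_mesh(model)
    lines = [_OBJ_HEADER]
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
    for name, (start, stop) in sorted(mesh.groups.items(), key=lambda kv: kv[1][0]):
        lines.append(f"g {name}\n")
        for f in mesh.faces[start:stop]:
            lines.append(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    Path(path).write_text("".join(lines))


def read_obj(path) -> TriMesh:
    """Parse an OBJ file into a :class:`TriMesh`.

    Handles ``v``, ``g`` and ``f`` records; quad faces are fan-triangulated;
    ``vn``/``vt``/``usemtl``/``mtllib`` records are ignored (debug-logged).
    Face indices are converted to 0-based; an index of 0 or out of range is
    a format error reporting the line number.
    """
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    groups: dict[str, tuple[int, int]] = {}
    current: str | None = None
    group_start = 0

    def close_group() -> None:
        nonlocal current, group_start
        if current is not None and len(faces) > group_start:
            if current in groups:
                raise FormatError(f"group {current!r} reopened (non-contiguous)")
            groups[current] = (group_start, len(faces))
        group_start = len(faces)

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tag, *rest = line.split()
        if tag == "v":
            verts.append([float(x) for x in rest[:3]])
        elif tag == "g":
            close_group()
            current = rest[0] if rest else "default"
        elif tag == "f":
            idx = []
            for token in rest:
                i = int(token.split("/")[0])
                if i == 0:
                    raise FormatError(f"line {lineno}: OBJ face index 0 is invalid")
                if i < 0:
                    i = len(verts) + i + 1
                if not 1 <= i <= len(verts):
                    raise FormatError(
                        f"line {lineno}: face index {i} out of range"
                    )
                idx.append(i - 1)
            if len(idx) < 3:
                raise FormatError(f"line {lineno}: face with fewer than 3 vertices")
            if current is None:
                current = "default"
            for k in range(1, len(idx) - 1):  # fan triangulation
                faces.append([idx[0], idx[k], idx[k + 1]])
        elif tag in ("vn", "vt", "usemtl", "mtllib", "o", "s"):
            log.debug("ignoring OBJ record %r at line %d", tag, lineno)
        else:
            log.debug("unknown OBJ record %r at line %d", tag, lineno)
    close_group()
    if not groups and faces:
        groups = {"default": (0, len(faces))}
    return TriMesh(
        np.array(verts, dtype=np.float64).reshape(-1, 3),
        np.array(faces, dtype=np.int64).reshape(-1, 3),
        groups,
    )


# -- scene manifest ----------------------------------------------------------

_MANIFEST_VERSION = 1


def _material_key(group: str) -> str:
    """Map a mesh group name to its material key: soil, stem, or L{layer}."""
    if group == "soil":
        return "soil"
    if group.endswith("_stem") or group == "stem":
        return "stem"
    layer = group.rsplit("_", 1)[-1] if "_" in group else group
    if layer.startswith("L") and layer[1:].isdigit():
        return layer
    raise ValidationError(f"cannot classify mesh group {group!r}")


def write_scene_manifest(
    scene: SceneModel,
    optics: dict[str, dict[str, str]],
    path,
    mesh_path: str | None = None,
    extra_metadata: dict | None = None,
) -> None:
    """Write the JSON manifest binding mesh groups to spectra files.

    ``optics`` maps material keys (``soil``, ``stem``, ``L1``...) to entries
    with a ``reflectance`` file and, for leaf layers and stem, a
    ``transmittance`` file. Every mesh group must be covered and every
    referenced file must exist; violations raise :class:`ValidationError`
    naming the offender.
    """
    materials: dict[str, dict[str, str]] = {}
    for group in scene.mesh.groups:
        key = _material_key(group)
        if key not in optics:
            raise ValidationError(f"no optical entry for group {group!r} (key {key!r})")
        entry = optics[key]
        if "reflectance" not in entry:
            raise ValidationError(f"entry {key!r} missing reflectance file")
        if key != "soil" and "transmittance" not in entry:
            raise ValidationError(f"entry {key!r} missing transmittance file")
        for kind, file in entry.items():
            if not Path(file).exists():
                raise ValidationError(f"{key}/{kind} file does not exist: {file}")
        materials[group] = dict(entry)

    metadata = {
        "units": "cm",
        "extent_cm": list(scene.spec.extent),
        "row_spacing_cm": scene.spec.row_spacing,
        "plant_spacing_cm": scene.spec.plant_spacing,
        "rows": scene.spec.rows,
        "hills_per_row": scene.spec.hills_per_row,
        "seed": scene.spec.seed,
        "leaf_spectra": dict(PROSPECT_METADATA),
    }
    if extra_metadata:
        metadata.update(extra_metadata)
    payload = {
        "format_version": _MANIFEST_VERSION,
        "mesh": mesh_path or "scene.obj",
        "materials": materials,
        "metadata": metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_scene_manifest(path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _MANIFEST_VERSION:
        raise FormatError("unrecognized manifest format version")
    return payload
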