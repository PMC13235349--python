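"""Plant, hill and field-scene assembly.

A single plant is a culm mesh with leaves attached at their position-ratio
heights, each rotated by its inclination and azimuth. A hill (the
transplanted clump) places ``plant_count`` plants on concentric rings —
one at the centre, then rings of capacity 6, 12, 18, ... at multiples of
the ring spacing — with seeded random perturbations of position, rotation
about the stem, and stem tilt, emulating the irregularity of a real clump.
A scene lays hills on a regular row/plant-spacing grid over a soil quad,
ready for export to a 3D radiative-transfer engine.

Within a hill, leaves of the same layer across all plants are merged into
one face group (L1 = flag-leaf layer) so that per-layer optical properties
can be assigned downstream; stems keep per-plant groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DomainError
from .mesh import TriMesh, merge_meshes
from .morphology import (
    DEFAULT_CURVATURE_K,
    DEFAULT_RESOLUTION,
    LeafSpec,
    StemSpec,
    build_leaf_mesh,
    build_stem_mesh,
)
from .records import StructureRecord
from .traits import RICE_LIA, LIAFunction

__all__ = [
    "PlantSpec",
    "HillSpec",
    "Placement",
    "SceneSpec",
    "HillModel",
    "SceneModel",
    "assemble_plant",
    "layout_hill_positions",
    "assemble_hill",
    "build_scene",
    "structure_to_plant_spec",
    "structure_to_hill_spec",
]

#: Maximum tilt perturbation (degrees) applied to a plant's stem by default.
DEFAULT_TILT_MAX = 8.0

#: Default number of leaves allowed on a plant (config bound, not biology).
MAX_LEAVES = 8


@dataclass(frozen=True)
class PlantSpec:
    """One tiller: a culm plus its ordered leaves (top layer first)."""

    stem: StemSpec
    leaves: tuple[LeafSpec, ...]
    plant_height: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "leaves", tuple(self.leaves))
        if not 2 <= len(self.leaves) <= MAX_LEAVES:
            raise DomainError(f"leaf count must be in [2, {MAX_LEAVES}]")
        if self.plant_height < self.stem.height:
            raise DomainError("plant_height must be >= stem height")


@dataclass(frozen=True)
class Placement:
    """Where and how one plant sits inside a hill."""

    offset: tuple[float, float]
    azimuth: float
    tilt_axis: tuple[float, float]
    tilt_angle: float


@dataclass(frozen=True)
class HillSpec:
    """A clump of ``plant_count`` plants with seeded placement perturbations.

    ``rotation_jitter`` bounds the random per-plant rotation about the stem
    (degrees; 360 = fully random orientation, 0 = none), ``position_jitter``
    the uniform per-coordinate offset (cm), ``tilt_max`` the stem tilt
    (degrees).
    """

    plant_count: int
    plant_template: PlantSpec | tuple[PlantSpec, ...]
    ring_spacing: float = 3.0
    position_jitter: float = 0.5
    rotation_jitter: float = 360.0
    tilt_max: float = DEFAULT_TILT_MAX
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plant_count < 1:
            raise DomainError("plant_count must be >= 1")
        if self.ring_spacing <= 0:
            raise DomainError("ring_spacing must be positive")
        if self.tilt_max < 0 or self.position_jitter < 0:
            raise DomainError("jitter magnitudes must be >= 0")
        if isinstance(self.plant_template, (list, tuple)):
            object.__setattr__(self, "plant_template", tuple(self.plant_template))
            if len(self.plant_template) != self.plant_count:
                raise DomainError("per-plant template list length != plant_count")

    def plant(self, index: int) -> PlantSpec:
        if isinstance(self.plant_template, tuple):
            return self.plant_template[index]
        return self.plant_template


@dataclass(frozen=True)
class SceneSpec:
    """Field layout: a rows x hills_per_row grid with row/plant spacings (cm),
    centred inside a soil extent of (width, depth) cm."""

    rows: int = 3
    hills_per_row: int = 6
    row_spacing: float = 30.0
    plant_spacing: float = 15.0
    extent: tuple[float, float] = (100.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.row_spacing <= 0 or self.plant_spacing <= 0:
            raise DomainError("spacings must be positive")
        if self.rows * self.hills_per_row < 1:
            raise DomainError("need at least one hill")


@dataclass
class HillModel:
    """Assembled hill: the full mesh plus the separately extracted stem
    structure and per-leaf-layer meshes."""

    full: TriMesh
    stem_only: TriMesh
    per_layer: dict[int, TriMesh] = field(default_factory=dict)


@dataclass
class SceneModel:
    """Assembled field scene: one merged mesh (groups ``soil``,
    ``hill{h}_plant{p}_stem``, ``hill{h}_L{layer}``) plus hill centres."""

    mesh: TriMesh
    spec: SceneSpec
    hill_centers: list[tuple[float, float]] = field(default_factory=list)


def assemble_plant(spec: PlantSpec, resolution: int = DEFAULT_RESOLUTION) -> TriMesh:
    """Mesh one plant: the culm plus each leaf translated onto the stem
    surface at height ``position_ratio * stem.height``, oriented by its
    inclination and azimuth. Groups: ``stem`` then ``L{layer_index}``."""
    parts: list[tuple[str, TriMesh]] = [("stem", build_stem_mesh(spec.stem))]
    for leaf in spec.leaves:
        mesh = build_leaf_mesh(leaf, resolution)
        h = leaf.position_ratio * spec.stem.height
        r = spec.stem.radius_at(h)
        az = math.radians(leaf.azimuth)
        # outward horizontal direction of the inclined blade: (sin az, -cos az)
        anchor = np.array([r * math.sin(az), -r * math.cos(az), h])
        parts.append((f"L{leaf.layer_index}", mesh.translated(anchor)))
    return merge_meshes(parts)


def _ring_layout(plant_count: int) -> list[tuple[int, int, int]]:
    """(ring index, slot index, slots in ring) for each plant, centre first,
    then rings of capacity 6*i filled in order."""
    out: list[tuple[int, int, int]] = [(0, 0, 1)]
    ring = 1
    while len(out) < plant_count:
        cap = 6 * ring
        take = min(cap, plant_count - len(out))
        for j in range(take):
            out.append((ring, j, take))
        ring += 1
    return out[:plant_count]


def layout_hill_positions(
    plant_count: int,
    ring_spacing: float,
    jitter: float,
    seed: int,
    *,
    rotation_jitter: float = 360.0,
    tilt_max: float = DEFAULT_TILT_MAX,
) -> list[Placement]:
    """Deterministic (per seed) concentric-ring placements for a hill.

    Ring *i* sits at radius ``i * ring_spacing`` with plants at equal angular
    spacing; each placement gets a uniform positional jitter in
    [-jitter, +jitter] per coordinate, a rotation about the stem uniform in
    [0, rotation_jitter) degrees, and a tilt of uniform magnitude in
    [0, tilt_max] about a uniformly oriented horizontal axis.
    """
    if plant_count < 1:
        raise DomainError("plant_count must be >= 1")
    rng = np.random.default_rng(seed)
    placements: list[Placement] = []
    for ring, slot, slots in _ring_layout(plant_count):
        radius = ring * ring_spacing
        theta = 2.0 * math.pi * slot / slots if slots else 0.0
        x = radius * math.cos(theta)
        y = radius * math.sin(theta)
        if jitter > 0:
            x += rng.uniform(-jitter, jitter)
            y += rng.uniform(-jitter, jitter)
        else:  # keep the draw sequence stable across jitter settings
            rng.uniform(-1, 1, size=2)
        azimuth = rng.uniform(0.0, 360.0)
        if rotation_jitter < 360.0:
            azimuth = azimuth % 360.0 * (rotation_jitter / 360.0)
        axis_angle = rng.uniform(0.0, 2.0 * math.pi)
        tilt = rng.uniform(0.0, tilt_max) if tilt_max > 0 else 0.0
        placements.append(
            Placement(
                offset=(x, y),
                azimuth=azimuth,
                tilt_axis=(math.cos(axis_angle), math.sin(axis_angle)),
                tilt_angle=tilt,
            )
        )
    return placements


def _axis_rotation(axis2d: tuple[float, float], deg: float) -> np.ndarray:
    """Rotation matrix about a horizontal unit axis (Rodrigues)."""
    ux, uy, uz = axis2d[0], axis2d[1], 0.0
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    k = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def assemble_hill(spec: HillSpec, resolution: int = DEFAULT_RESOLUTION) -> HillModel:
    """Assemble a hill from its placements.

    Each plant is rotated about the stem, tilted about its base, and
    translated to its placement. Output groups: per-plant stems first
    (``plant{p}_stem``), then each leaf layer merged across plants
    (``L{layer}``), so the face partition full = stems + sum of layers
    holds by construction.
    """
    placements = layout_hill_positions(
        spec.plant_count,
        spec.ring_spacing,
        spec.position_jitter,
        spec.seed,
        rotation_jitter=spec.rotation_jitter,
        tilt_max=spec.tilt_max,
    )
    stems: list[tuple[str, TriMesh]] = []
    layers: dict[int, list[tuple[str, TriMesh]]] = {}
    for p, place in enumerate(placements):
        plant = assemble_plant(spec.plant(p), resolution)
        rot = _axis_rotation(place.tilt_axis, place.tilt_angle) @ _rot_z(place.azimuth)
        moved = plant.transformed(rotation=rot,
                                  translation=(place.offset[0], place.offset[1], 0.0))
        stems.append((f"plant{p}_stem", moved.submesh("stem")))
        for name in plant.groups:
            if name.startswith("L"):
                layer = int(name[1:])
                layers.setdefault(layer, []).append((f"L{layer}", moved.submesh(name)))

    parts = list(stems)
    for layer in sorted(layers):
        parts.extend(layers[layer])
    full = merge_meshes(parts)
    stem_only = merge_meshes([("stem", m) for _, m in stems])
    per_layer = {
        layer: merge_meshes(layers[layer]) for layer in sorted(layers)
    }
    return HillModel(full=full, stem_only=stem_only, per_layer=per_layer)


def _soil_quad(extent: tuple[float, float]) -> TriMesh:
    w, d = extent[0] / 2.0, extent[1] / 2.0
    verts = np.array(
        [[-w, -d, 0.0], [w, -d, 0.0], [w, d, 0.0], [-w, d, 0.0]]
    )
    faces = np.array([[0, 1, 2], [0, 2, 3]], dtype=np.int64)
    return TriMesh(verts, faces, {"soil": (0, 2)})


def build_scene(
    scene: SceneSpec,
    hills: HillSpec | HillModel | list[HillSpec] | list[HillModel],
) -> SceneModel:
    """Place hills on the scene grid over a centred soil quad.

    ``hills`` may be one spec (replicated with per-hill reseeding
    ``scene.seed + hill_index``), or a list of specs/models of length
    rows * hills_per_row. Hill (row r, column c) is centred at
    ``(c * plant_spacing, r * row_spacing)`` shifted so the grid is centred
    in the extent.
    """
    n = scene.rows * scene.hills_per_row
    span_x = (scene.hills_per_row - 1) * scene.plant_spacing
    span_y = (scene.rows - 1) * scene.row_spacing
    if span_x > scene.extent[0] or span_y > scene.extent[1]:
        raise ConfigError("hill grid exceeds the scene extent")

    if isinstance(hills, (HillSpec, HillModel)):
        hills_list: list[HillSpec | HillModel] = [hills] * n
    else:
        hills_list = list(hills)
        if len(hills_list) != n:
            raise ConfigError(f"expected {n} hills, got {len(hills_list)}")

    parts: list[tuple[str, TriMesh]] = [("soil", _soil_quad(scene.extent))]
    centers: list[tuple[float, float]] = []
    for h, item in enumerate(hills_list):
        r, c = divmod(h, scene.hills_per_row)
        cx = c * scene.plant_spacing - span_x / 2.0
        cy = r * scene.row_spacing - span_y / 2.0
        centers.append((cx, cy))
        if isinstance(item, HillSpec):
            reseeded = HillSpec(
                plant_count=item.plant_count,
                plant_template=item.plant_template,
                ring_spacing=item.ring_spacing,
                position_jitter=item.position_jitter,
                rotation_jitter=item.rotation_jitter,
                tilt_max=item.tilt_max,
                seed=scene.seed + h,
            )
            model = assemble_hill(reseeded)
        else:
            model = item
        shifted = model.full.translated((cx, cy, 0.0))
        for name in shifted.groups:
            prefix = f"hill{h}_"
            parts.append((prefix + name, shifted.submesh(name)))
    mesh = merge_meshes(parts)
    return SceneModel(mesh=mesh, spec=scene, hill_centers=centers)


# -- bridging from estimated/measured structure records ---------------------

def structure_to_plant_spec(
    record: StructureRecord,
    lia: LIAFunction = RICE_LIA,
    curvature_k: float = DEFAULT_CURVATURE_K,
    phyllotaxy_offset: float = 180.0,
) -> PlantSpec:
    """Build a plant template from one hill's structural record.

    Leaves alternate azimuth by the phyllotaxy offset (rice is distichous,
    ~180 degrees apart); inclination comes from the record where present,
    otherwise from the LIA function at that leaf position.
    """
    leaves = []
    for leaf in record.per_leaf:
        incl = leaf.inclination if leaf.inclination is not None else lia(leaf.position)
        leaves.append(
            LeafSpec(
                length=leaf.length,
                max_width=leaf.width,
                inclination=float(np.clip(incl, 0.0, 89.999)),
                azimuth=(leaf.position - 1) * phyllotaxy_offset % 360.0,
                curvature_k=curvature_k,
                position_ratio=leaf.position_ratio,
                layer_index=leaf.position,
            )
        )
    stem = StemSpec(height=record.stem_height)
    return PlantSpec(
        stem=stem,
        leaves=tuple(leaves),
        plant_height=max(record.observation.plant_height, record.stem_height),
    )


def structure_to_hill_spec(
    record: StructureRecord,
    seed: int = 0,
    lia: LIAFunction = RICE_LIA,
    **hill_kwargs,
) -> HillSpec:
    """Build a hill spec whose plants all share the record's template."""
    template = structure_to_plant_spec(record, lia=lia)
    return HillSpec(
        plant_count=record.plant_count,
        plant_template=template,
        seed=seed,
        **hill_kwargs,
    )
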