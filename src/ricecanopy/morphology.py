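"""Parametric leaf and stem geometry.

A rice leaf is modelled as a strip of left/right edge-vertex pairs sampled
uniformly along the midrib. The transverse width follows an inverted
parabola (zero at base and tip, maximal at mid-length),

    w(z) = w_max * [1 - (2*(z/L - 0.5))**2],

and gravitational droop displaces each station by a quadratic sag

    y(z) = -k * z**2 / L,

where ``k`` (cm of displacement per cm^2 of run, per cm of length) controls
how strongly the blade bends away from its insertion axis. The blade is
generated with the midrib along +Z, rotated by the leaf inclination angle
(degrees from vertical, in the droop plane), then by the azimuth about the
stem axis; translation onto the stem is the assembler's job.

The culm (stem) is a tapered cylinder: rings of vertices generated in polar
coordinates at equally spaced heights, radius interpolated linearly from
base to top, adjacent rings stitched into a triangle mesh.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError
from .mesh import TriMesh

__all__ = [
    "LeafSpec",
    "StemSpec",
    "leaf_width_profile",
    "leaf_droop_profile",
    "build_leaf_mesh",
    "build_stem_mesh",
    "DEFAULT_CURVATURE_K",
    "DEFAULT_RESOLUTION",
]

#: Default droop curvature factor (per cm). Not a measured quantity; a mild,
#: visually plausible sag. Tunable everywhere it is consumed.
DEFAULT_CURVATURE_K = 0.05

#: Default number of midrib sampling stations per leaf.
DEFAULT_RESOLUTION = 20


@dataclass(frozen=True)
class LeafSpec:
    """Geometric description of one leaf blade.

    Parameters are in cm / degrees. ``inclination`` is measured from the
    vertical stem direction (0 = fully erect); ``azimuth`` orients the leaf
    about the stem axis; ``position_ratio`` in (0, 1] locates the insertion
    as a fraction of stem height; ``layer_index`` counts from the top
    (1 = flag leaf).
    """

    length: float
    max_width: float
    inclination: float = 0.0
    azimuth: float = 0.0
    curvature_k: float = DEFAULT_CURVATURE_K
    position_ratio: float = 1.0
    layer_index: int = 1

    def __post_init__(self) -> None:
        if self.length <= 0 or self.max_width <= 0:
            raise DomainError("leaf length and max_width must be positive")
        if not 0.0 <= self.inclination < 90.0:
            raise DomainError("inclination must lie in [0, 90) degrees")
        if self.curvature_k < 0:
            raise DomainError("curvature_k must be >= 0")
        if not 0.0 < self.position_ratio <= 1.0:
            raise DomainError("position_ratio must lie in (0, 1]")


@dataclass(frozen=True)
class StemSpec:
    """Tapered-cylinder culm: base/top radii (cm), segment/radial resolution.

    Radii default to a visually plausible culm; the paper trail for rice
    culm diameter is thin, so both are exposed as tunables.
    """

    height: float
    base_radius: float = 0.4
    top_radius: float = 0.25
    n_sections: int = 8
    n_radial: int = 12

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise DomainError("stem height must be positive")
        if not self.base_radius >= self.top_radius > 0:
            raise DomainError("require base_radius >= top_radius > 0")
        if self.n_sections < 1 or self.n_radial < 3:
            raise DomainError("need n_sections >= 1 and n_radial >= 3")

    def radius_at(self, height: float) -> float:
        """Linearly interpolated culm radius at a given height (cm)."""
        t = np.clip(height / self.height, 0.0, 1.0)
        return float(self.base_radius + (self.top_radius - self.base_radius) * t)


def leaf_width_profile(z, length: float, max_width: float):
    """Transverse blade width (cm) at distance ``z`` along the midrib.

    Accepts scalar or array ``z``; zero at both ends, ``max_width`` at
    mid-length.
    """
    if length <= 0:
        raise DomainError("length must be positive")
    z = np.asarray(z, dtype=np.float64)
    if np.any(z < 0) or np.any(z > length):
        raise DomainError("z must lie in [0, length]")
    w = max_width * (1.0 - (2.0 * (z / length - 0.5)) ** 2)
    return w if w.ndim else float(w)


def leaf_droop_profile(z, length: float, curvature_k: float):
    """Vertical sag displacement (cm, <= 0) at distance ``z`` along the midrib."""
    if length <= 0:
        raise DomainError("length must be positive")
    if curvature_k < 0:
        raise DomainError("curvature_k must be >= 0")
    z = np.asarray(z, dtype=np.float64)
    if np.any(z < 0) or np.any(z > length):
        raise DomainError("z must lie in [0, length]")
    y = -curvature_k * z**2 / length
    return y if y.ndim else float(y)


def _rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_leaf_mesh(spec: LeafSpec, resolution: int = DEFAULT_RESOLUTION) -> TriMesh:
    """Mesh one leaf blade as a triangle strip.

    ``resolution`` stations are sampled uniformly on [0, length]; each emits
    a left/right edge-vertex pair separated by the width profile and sagged
    by the droop profile, giving exactly ``2*resolution`` vertices and
    ``2*(resolution-1)`` faces in one group named ``leaf``. The blade is
    rotated by inclination (about X, within the droop plane) then azimuth
    (about Z); its insertion point stays at the origin.
    """
    if resolution < 2:
        raise ConfigError("resolution must be >= 2")
    z = np.linspace(0.0, spec.length, resolution)
    half_w = leaf_width_profile(z, spec.length, spec.max_width) / 2.0
    sag = leaf_droop_profile(z, spec.length, spec.curvature_k)

    verts = np.empty((2 * resolution, 3))
    verts[0::2, 0] = -half_w  # left edge
    verts[1::2, 0] = half_w   # right edge
    verts[0::2, 1] = verts[1::2, 1] = sag
    verts[0::2, 2] = verts[1::2, 2] = z

    rot = _rot_z(spec.azimuth) @ _rot_x(spec.inclination)
    verts = verts @ rot.T

    faces = np.empty((2 * (resolution - 1), 3), dtype=np.int64)
    for i in range(resolution - 1):
        a, b, c, d = 2 * i, 2 * i + 1, 2 * i + 2, 2 * i + 3
        faces[2 * i] = (a, b, d)      # consistent diagonal a-d
        faces[2 * i + 1] = (a, d, c)
    return TriMesh(verts, faces, {"leaf": (0, len(faces))})


def build_stem_mesh(spec: StemSpec) -> TriMesh:
    """Mesh the culm as a tapered open cylinder.

    ``n_sections + 1`` rings of ``n_radial`` vertices; ring *i* sits at
    height ``i * height / n_sections`` with linearly interpolated radius.
    Each section contributes ``2 * n_radial`` outward-wound triangles; one
    group named ``stem``.
    """
    s, a = spec.n_sections, spec.n_radial
    heights = np.linspace(0.0, spec.height, s + 1)
    radii = np.linspace(spec.base_radius, spec.top_radius, s + 1)
    theta = 2.0 * np.pi * np.arange(a) / a

    verts = np.empty(((s + 1) * a, 3))
    for i in range(s + 1):
        verts[i * a:(i + 1) * a, 0] = radii[i] * np.cos(theta)
        verts[i * a:(i + 1) * a, 1] = radii[i] * np.sin(theta)
        verts[i * a:(i + 1) * a, 2] = heights[i]

    faces = np.empty((2 * s * a, 3), dtype=np.int64)
    f = 0
    for i in range(s):
        lo, hi = i * a, (i + 1) * a
        for j in range(a):
            jn = (j + 1) % a
            faces[f] = (lo + j, lo + jn, hi + jn)
            faces[f + 1] = (lo + j, hi + jn, hi + j)
            f += 2
    return TriMesh(verts, faces, {"stem": (0, len(faces))})
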