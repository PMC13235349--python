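"""Core data records shared across the estimation, simulation and geometry
layers: the four rapid-mode canopy inputs and one hill's full vertical
structural parameter set."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from .errors import DomainError

__all__ = ["CanopyObservation", "LeafParams", "StructureRecord"]


@dataclass(frozen=True)
class CanopyObservation:
    """The four canopy-level inputs of the rapid mode.

    ``transplant_day``: days since transplanting; ``plant_height`` (PH, cm);
    ``agb``: above-ground biomass per hill (g); ``lai``: leaf area index.
    """

    transplant_day: float
    plant_height: float
    agb: float
    lai: float

    def __post_init__(self) -> None:
        vals = (self.transplant_day, self.plant_height, self.agb, self.lai)
        if not all(math.isfinite(v) for v in vals):
            raise DomainError("canopy observation values must be finite")
        if self.plant_height <= 0 or self.lai < 0 or self.agb < 0:
            raise DomainError("require plant_height > 0, lai >= 0, agb >= 0")


class LeafParams(NamedTuple):
    """Per-leaf vertical structural parameters at one leaf position
    (position counts top-down, 1 = flag leaf)."""

    position: int
    length: float
    width: float
    position_ratio: float
    inclination: float | None = None


@dataclass
class StructureRecord:
    """One hill's complete structural description: the canopy observation
    plus leaf count, plant (tiller) count, stem height and the per-leaf
    vertical parameters."""

    observation: CanopyObservation
    leaf_count: int
    plant_count: int
    stem_height: float
    per_leaf: list[LeafParams] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.per_leaf) != self.leaf_count:
            raise DomainError(
                f"per_leaf has {len(self.per_leaf)} entries, expected "
                f"leaf_count = {self.leaf_count}"
            )
        if self.plant_count < 1:
            raise DomainError("plant_count must be >= 1")
        if self.stem_height <= 0:
            raise DomainError("stem_height must be positive")
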