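"""Synthetic structural-parameter datasets.

Generates per-hill rice structural records whose marginal ranges match the
measured field statistics (jointing-booting stages, four nitrogen levels)
and whose cross-parameter correlation structure is qualitatively realistic:
transplanting day, plant height, stem height and above-ground biomass are
all strongly, monotonically coupled through a single latent "growth stage"
driver; LAI is only weakly coupled; tiller (plant) count is essentially
independent of growth stage, as observed in transplanted paddies where the
number of tillers per hill is set at transplanting.

Vertical leaf profiles follow the field regularities: leaf length peaks at
mid-canopy positions, leaf width increases toward the upper positions, the
position ratio decreases from the flag leaf downward, and the inclination
angle follows the fitted erectophile line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import ConfigError
from .records import CanopyObservation, LeafParams, StructureRecord
from .traits import RICE_LIA, LIAFunction

__all__ = [
    "ParamStat",
    "ParamRanges",
    "GeneratorConfig",
    "DEFAULT_RANGES",
    "generate_structural_dataset",
    "dataset_to_observations",
]


class ParamStat(NamedTuple):
    """Range and first two moments of one structural parameter."""

    min: float
    max: float
    mean: float
    sd: float


@dataclass(frozen=True)
class ParamRanges:
    """Measured field statistics of the structural parameters (Table-style
    min/max/mean/sd) used both to bound generated values and to clip
    rapid-mode predictions into physical range.

    Units: cm for heights/lengths, g for biomass; transplant_day in days
    after transplanting (range chosen to span tillering through booting).
    """

    plant_height: ParamStat = ParamStat(27.4, 113.0, 66.7587, 18.0828)
    lai: ParamStat = ParamStat(1.20, 8.03, 4.4871, 1.3196)
    agb: ParamStat = ParamStat(1.45, 81.18, 19.4322, 16.8237)
    leaf_count: ParamStat = ParamStat(2, 6, 3.81, 0.80)
    stem_height: ParamStat = ParamStat(11.6, 75.4, 42.31, 21.30)
    plant_count: ParamStat = ParamStat(7, 40, 22.63, 7.51)
    leaf_length: ParamStat = ParamStat(16.2, 57.4, 30.0805, 8.5020)
    leaf_width: ParamStat = ParamStat(0.70, 2.00, 1.1442, 0.2270)
    position_ratio: ParamStat = ParamStat(0.2984, 1.0, 0.8360, 0.1937)
    transplant_day: ParamStat = ParamStat(10.0, 90.0, 50.0, 20.0)

    def validate(self) -> None:
        for name, stat in self.__dict__.items():
            if not stat.min < stat.max:
                raise ConfigError(f"{name}: require min < max")
            if not stat.min <= stat.mean <= stat.max:
                raise ConfigError(f"{name}: mean outside [min, max]")


DEFAULT_RANGES = ParamRanges()


@dataclass(frozen=True)
class GeneratorConfig:
    """Generator settings: number of hills, seed, relative noise level, and
    the latent-driver loadings shaping each parameter's response to growth
    stage (exponents/slopes of the monotone coupling)."""

    n: int = 100
    seed: int = 0
    noise_sd: float = 0.05
    growth_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "stem_height_exp": 1.1,
            "agb_exp": 1.6,
            "lai_base": 0.35,
            "lai_slope": 0.30,
        }
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def _lerp(stat: ParamStat, t: float) -> float:
    return stat.min + (stat.max - stat.min) * t


def _noisy(value: float, stat: ParamStat, sd: float, rng: np.random.Generator) -> float:
    # multiplicative noise then truncation back into the measured range
    v = value * (1.0 + sd * rng.standard_normal()) if sd > 0 else value
    return float(np.clip(v, stat.min, stat.max))


def generate_structural_dataset(
    config: GeneratorConfig,
    ranges: ParamRanges = DEFAULT_RANGES,
    lia: LIAFunction = RICE_LIA,
) -> list[StructureRecord]:
    """Sample ``config.n`` hill records, deterministic per seed.

    Each hill draws a latent growth stage g ~ U(0, 1) that sets transplant
    day (linear), plant height (linear), stem height and AGB (monotone
    power laws) and leaf count (monotone step from 2 to 6 leaves); LAI is
    weakly coupled; tiller count is drawn independently. Per-leaf length,
    width and position ratio are smooth functions of (g, leaf position)
    plus multiplicative noise, truncated into the measured ranges.
    """
    ranges.validate()
    gc = config.growth_coefficients
    rng = np.random.default_rng(config.seed)
    sd = config.noise_sd
    records: list[StructureRecord] = []
    for _ in range(config.n):
        g = float(rng.uniform())
        transplant_day = _noisy(_lerp(ranges.transplant_day, g),
                                ranges.transplant_day, sd, rng)
        ph = _noisy(_lerp(ranges.plant_height, g), ranges.plant_height, sd, rng)
        stem_h = _noisy(_lerp(ranges.stem_height, g ** gc["stem_height_exp"]),
                        ranges.stem_height, sd, rng)
        agb = _noisy(_lerp(ranges.agb, g ** gc["agb_exp"]), ranges.agb, sd, rng)
        lai_raw = _lerp(ranges.lai, gc["lai_base"] + gc["lai_slope"] * g)
        lai = _noisy(lai_raw, ranges.lai, 3.0 * sd, rng)

        leaf_count = int(min(ranges.leaf_count.max,
                             ranges.leaf_count.min + int(g * 5)))
        plant_count = int(rng.integers(int(ranges.plant_count.min),
                                       int(ranges.plant_count.max) + 1))

        leaves: list[LeafParams] = []
        for p in range(1, leaf_count + 1):
            rel = (p - 1) / max(leaf_count - 1, 1)  # 0 = flag leaf, 1 = lowest
            len_shape = 1.0 - 0.35 * (2.0 * (rel - 0.5)) ** 2
            length = _noisy(
                _lerp(ranges.leaf_length, (0.12 + 0.75 * g) * len_shape),
                ranges.leaf_length, sd, rng)
            width = _noisy(
                _lerp(ranges.leaf_width, (0.15 + 0.70 * g) * (1.0 - 0.30 * rel)),
                ranges.leaf_width, sd, rng)
            ratio = _noisy(1.0 - rel * (0.55 + 0.12 * (1.0 - g)),
                           ranges.position_ratio, sd, rng)
            incl = lia(p)
            leaves.append(LeafParams(position=p, length=length, width=width,
                                     position_ratio=ratio, inclination=incl))
        records.append(
            StructureRecord(
                observation=CanopyObservation(
                    transplant_day=transplant_day,
                    plant_height=ph,
                    agb=agb,
                    lai=lai,
                ),
                leaf_count=leaf_count,
                plant_count=plant_count,
                stem_height=stem_h,
                per_leaf=leaves,
            )
        )
    return records


def dataset_to_observations(records: list[StructureRecord]) -> list[CanopyObservation]:
    """Project records onto the four rapid-mode canopy inputs (order kept)."""
    return [r.observation for r in records]
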