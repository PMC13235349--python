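import pytest

from ricecanopy import (
    GeneratorConfig,
    HillSpec,
    LeafSpec,
    PlantSpec,
    RICE_LIA,
    StemSpec,
    generate_structural_dataset,
)


@pytest.fixture(scope="session")
def plant_spec() -> PlantSpec:
    """Small three-leaf plant used across assembly tests."""
    stem = StemSpec(height=40.0)
    leaves = tuple(
        LeafSpec(
            length=30.0,
            max_width=1.2,
            inclination=RICE_LIA(p),
            azimuth=(p - 1) * 180.0,
            position_ratio=1.0 - 0.15 * (p - 1),
            layer_index=p,
        )
        for p in range(1, 4)
    )
    return PlantSpec(stem=stem, leaves=leaves, plant_height=60.0)


@pytest.fixture(scope="session")
def hill_spec(plant_spec) -> HillSpec:
    return HillSpec(plant_count=7, plant_template=plant_spec, seed=11)


@pytest.fixture(scope="session")
def noiseless_records():
    """Deterministic synthetic dataset used by recovery tests."""
    return generate_structural_dataset(GeneratorConfig(n=120, seed=5, noise_sd=0.0))
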