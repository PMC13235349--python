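"""Sensitivity pipeline: ensemble simulation, the gap-fraction reflectance
provider, random-forest importances and their aggregations, and the
vegetation indices."""

import numpy as np
import pytest

from ricecanopy import (
    ImportanceReport,
    SpectraTable,
    aggregate_importances,
    build_feature_table,
    compute_importances,
    compute_vegetation_indices,
    simulate_structure_ensemble,
    toy_reflectance,
)
from ricecanopy.errors import ConfigError, FormatError, NamingError
from ricecanopy.records import StructureRecord
from ricecanopy.sensitivity import (
    DEFAULT_WAVELENGTHS,
    synthetic_layer_spectra,
    synthetic_soil_spectrum,
)


class TestEnsemble:
    def test_requested_size_and_determinism(self):
        a = simulate_structure_ensemble(50, seed=1)
        b = simulate_structure_ensemble(50, seed=1)
        c = simulate_structure_ensemble(50, seed=2)
        assert len(a) == 50
        assert a == b
        assert a != c

    def test_invalid_size(self):
        with pytest.raises(ConfigError):
            simulate_structure_ensemble(0)


@pytest.fixture(scope="module")
def spectra():
    return (synthetic_layer_spectra(6), synthetic_soil_spectrum())


class TestToyReflectance:

    def test_zero_leaf_area_returns_soil(self, spectra):
        layers, soil = spectra
        records = simulate_structure_ensemble(1, seed=0)
        rec = records[0]
        rec = StructureRecord(
            observation=rec.observation, leaf_count=0, plant_count=rec.plant_count,
            stem_height=rec.stem_height, per_leaf=[],
        )
        assert np.array_equal(toy_reflectance(rec, layers, soil), soil.values)

    def test_dense_canopy_converges_to_leaf_mixture(self, spectra):
        layers, soil = spectra
        rec = simulate_structure_ensemble(1, seed=0)[0]
        dense = toy_reflectance(rec, layers, soil, ground_area_cm2=0.05)
        weights = {}
        from ricecanopy import leaf_area

        for leaf in rec.per_leaf:
            area = leaf_area(leaf.length, leaf.width) * rec.plant_count
            weights[leaf.position] = area * np.exp(-0.5 * (leaf.position - 1))
        wsum = sum(weights.values())
        mixture = sum(w / wsum * layers[k].values for k, w in weights.items())
        assert np.allclose(dense, np.clip(mixture, 0, 1), atol=1e-6)

    def test_more_plants_less_soil(self, spectra):
        """Doubling plant count strictly shrinks the soil gap fraction."""
        layers, soil = spectra
        rec = simulate_structure_ensemble(1, seed=3)[0]
        doubled = StructureRecord(
            observation=rec.observation, leaf_count=rec.leaf_count,
            plant_count=2 * rec.plant_count, stem_height=rec.stem_height,
            per_leaf=rec.per_leaf,
        )
        from ricecanopy import leaf_area

        area = sum(leaf_area(l.length, l.width) for l in rec.per_leaf)
        gap1 = np.exp(-0.5 * area * rec.plant_count / 1600.0)
        gap2 = np.exp(-0.5 * area * doubled.plant_count / 1600.0)
        assert gap2 < gap1

    def test_grid_mismatch_rejected(self, spectra):
        layers, _ = spectra
        rec = simulate_structure_ensemble(1, seed=0)[0]
        other_soil = synthetic_soil_spectrum(np.arange(400.0, 901.0, 10.0))
        with pytest.raises(FormatError):
            toy_reflectance(rec, layers, other_soil)

    def test_output_in_unit_interval(self, spectra):
        layers, soil = spectra
        for rec in simulate_structure_ensemble(20, seed=5):
            refl = toy_reflectance(rec, layers, soil)
            assert refl.min() >= 0.0 and refl.max() <= 1.0


@pytest.fixture(scope="module")
def dominance_setup():
    """Spectra constructed to depend only on plant count."""
    records = simulate_structure_ensemble(200, seed=8)
    features = build_feature_table(records, max_layers=6)
    wl = np.array([500.0, 600.0, 700.0, 800.0])
    counts = features["plant_count"].to_numpy()
    rows = np.clip(
        0.1 + 0.8 * (counts[:, None] - counts.min()) / np.ptp(counts)
        * np.ones((1, len(wl))),
        0, 1,
    )
    return features, SpectraTable(wl, rows)


class TestImportances:

    def test_importances_sum_to_one(self, dominance_setup):
        features, spectra = dominance_setup
        report = compute_importances(features, spectra, seed=0, n_estimators=100)
        assert sum(report.per_feature.values()) == pytest.approx(1.0, abs=1e-9)

    def test_plant_count_dominance_recovered(self, dominance_setup):
        features, spectra = dominance_setup
        report = compute_importances(features, spectra, seed=0, n_estimators=200)
        pc = report.per_feature["plant_count"]
        assert pc > 0.5
        assert pc == max(report.per_feature.values())

    def test_excluding_plant_count_renormalizes(self, dominance_setup):
        features, spectra = dominance_setup
        report = compute_importances(
            features, spectra, include_plant_count=False, seed=0, n_estimators=50
        )
        assert "plant_count" not in report.per_feature
        assert sum(report.per_feature.values()) == pytest.approx(1.0, abs=1e-9)

    def test_constant_feature_near_zero_importance(self, dominance_setup):
        features, spectra = dominance_setup
        features = features.copy()
        features["L6_length"] = 0.0  # constant column
        report = compute_importances(features, spectra, seed=1, n_estimators=50)
        assert report.per_feature["L6_length"] == pytest.approx(0.0, abs=1e-9)

    def test_row_count_mismatch_rejected(self, dominance_setup):
        features, spectra = dominance_setup
        with pytest.raises(ConfigError):
            compute_importances(features.iloc[:-1], spectra)

    def test_report_invariant_enforced(self):
        with pytest.raises(ConfigError):
            ImportanceReport(per_feature={"a": 0.4, "b": 0.4}, variant="with_plant_count")


class TestAggregation:
    def test_by_layer_enumeration(self):
        report = ImportanceReport(
            per_feature={"L1_length": 0.3, "L2_length": 0.7},
            variant="without_plant_count",
        )
        assert aggregate_importances(report, "by_layer") == pytest.approx(
            {"L1": 0.3, "L2": 0.7}
        )

    def test_by_parameter_type_pools_lengths(self):
        report = ImportanceReport(
            per_feature={"L1_length": 0.3, "L2_length": 0.5, "L1_width": 0.2},
            variant="without_plant_count",
        )
        grouped = aggregate_importances(report, "by_parameter_type")
        assert grouped["length"] == pytest.approx(0.8)
        assert grouped["width"] == pytest.approx(0.2)

    def test_group_sums_partition_total(self):
        report = ImportanceReport(
            per_feature={
                "plant_count": 0.4, "plant_height": 0.1,
                "L1_length": 0.2, "L2_width": 0.2, "L1_present": 0.1,
            },
            variant="with_plant_count",
        )
        for grouping in ("by_layer", "by_parameter_type"):
            grouped = aggregate_importances(report, grouping)
            assert sum(grouped.values()) == pytest.approx(1.0)

    def test_unparseable_name_rejected(self):
        report = ImportanceReport(
            per_feature={"bogus": 1.0}, variant="with_plant_count"
        )
        with pytest.raises(NamingError):
            aggregate_importances(report, "by_layer")


class TestVegetationIndices:
    def test_flat_spectrum_gives_zero_indices(self):
        wl = DEFAULT_WAVELENGTHS
        out = compute_vegetation_indices(np.full(len(wl), 0.3), wl)
        assert out["NDVI"] == pytest.approx(0.0)
        assert out["CIrededge"] == pytest.approx(0.0)

    def test_hand_arithmetic_ndvi(self):
        wl = np.array([670.0, 720.0, 800.0])
        spectrum = np.array([0.05, 0.25, 0.5])
        out = compute_vegetation_indices(spectrum, wl)
        assert out["NDVI"] == pytest.approx((0.5 - 0.05) / 0.55, abs=1e-4)
        assert out["NDVI"] == pytest.approx(0.8182, abs=1e-4)
        assert out["CIrededge"] == pytest.approx(0.5 / 0.25 - 1.0)

    def test_insufficient_grid_rejected(self):
        wl = np.arange(700.0, 801.0, 10.0)
        with pytest.raises(FormatError):
            compute_vegetation_indices(np.full(len(wl), 0.3), wl)


def test_provider_agnostic_pipeline():
    """File-shaped spectra (same grid/shape) drop into the same code path."""
    records = simulate_structure_ensemble(60, seed=4)
    features = build_feature_table(records)
    wl = np.linspace(400, 1000, 7)
    rng = np.random.default_rng(0)
    rows = rng.uniform(0.05, 0.6, size=(60, 7))
    report = compute_importances(
        features, SpectraTable(wl, rows), seed=0, n_estimators=20
    )
    assert sum(report.per_feature.values()) == pytest.approx(1.0, abs=1e-9)
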