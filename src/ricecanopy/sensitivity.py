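"""Structure-to-spectrum sensitivity analysis.

Simulates an ensemble of hill structures within the measured parameter
ranges, obtains a canopy reflectance spectrum for each from a pluggable
provider, and ranks the structural parameters by random-forest feature
importance — overall, aggregated by leaf layer, and aggregated by
parameter type, with and without the plant-count variable (plant count
dominates canopy reflectance through its direct effect on cover fraction,
so excluding it exposes the ranking among the vertical leaf parameters).

The built-in :func:`toy_reflectance` provider is a deliberately simple
gap-fraction mixing model (synthetic stand-in; a 3D radiative-transfer
engine such as LESS would be used on exported scenes in production): the
soil is seen through a Beer–Lambert gap ``exp(-0.5 * LAI_eff)`` and the
vegetated fraction is an area-weighted mixture of per-layer leaf spectra
with exponential extinction by depth. It exists so the pipeline is fully
testable offline; any provider returning one reflectance vector per
structure on a shared wavelength grid can be swapped in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .errors import ConfigError, FormatError, NamingError
from .records import StructureRecord
from .synthetic import (
    DEFAULT_RANGES,
    GeneratorConfig,
    ParamRanges,
    generate_structural_dataset,
)
from .traits import leaf_area

__all__ = [
    "DEFAULT_WAVELENGTHS",
    "Spectrum",
    "SpectraTable",
    "ImportanceReport",
    "simulate_structure_ensemble",
    "synthetic_leaf_spectrum",
    "synthetic_soil_spectrum",
    "synthetic_layer_spectra",
    "toy_reflectance",
    "build_feature_table",
    "compute_importances",
    "aggregate_importances",
    "compute_vegetation_indices",
]

#: Working spectral grid, 400–1000 nm at 10 nm (the canopy analysis range).
DEFAULT_WAVELENGTHS = np.arange(400.0, 1001.0, 10.0)

#: Canopy-level (non layer-parameter) feature names.
CANOPY_FEATURES = ("plant_count", "plant_height")

_LAYER_RE = re.compile(r"^L(\d+)_(length|width|inclination|position_ratio|present)$")


@dataclass
class Spectrum:
    """One spectrum on an explicit wavelength grid (nm, reflectance in [0,1])."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.wavelengths.shape != self.values.shape:
            raise FormatError("wavelength and value arrays differ in length")


@dataclass
class SpectraTable:
    """Ensemble reflectance: one row per structure on a shared grid."""

    wavelengths: np.ndarray
    rows: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=np.float64))
        if self.rows.shape[1] != len(self.wavelengths):
            raise FormatError("row length does not match wavelength grid")
        if self.rows.min() < 0 or self.rows.max() > 1:
            raise FormatError("reflectance values must lie in [0, 1]")


def simulate_structure_ensemble(
    n: int, ranges: ParamRanges = DEFAULT_RANGES, seed: int = 0,
    noise_sd: float = 0.05,
) -> list[StructureRecord]:
    """Sample ``n`` structures from the synthetic generator (deterministic
    per seed), the ensemble the importance analysis runs on."""
    if n < 1:
        raise ConfigError("ensemble size must be >= 1")
    return generate_structural_dataset(
        GeneratorConfig(n=n, seed=seed, noise_sd=noise_sd), ranges
    )


# -- synthetic component spectra (stand-ins for measured leaf/soil spectra) --

def synthetic_leaf_spectrum(
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS, greenness: float = 1.0
) -> Spectrum:
    """Synthetic green-leaf reflectance: low visible reflectance with a green
    bump, a red-edge sigmoid, and an NIR plateau. A labelled stand-in for
    measured per-layer leaf spectra, which are inputs in production use."""
    wl = np.asarray(wavelengths, dtype=np.float64)
    green_bump = 0.08 * greenness * np.exp(-(((wl - 550.0) / 40.0) ** 2))
    red_edge = 0.42 / (1.0 + np.exp(-(wl - 715.0) / 12.0))
    values = np.clip(0.04 + green_bump + red_edge, 0.0, 1.0)
    return Spectrum(wl, values)


def synthetic_soil_spectrum(wavelengths: np.ndarray = DEFAULT_WAVELENGTHS) -> Spectrum:
    """Synthetic dry-soil reflectance: slowly increasing with wavelength."""
    wl = np.asarray(wavelengths, dtype=np.float64)
    values = np.clip(0.08 + 0.25 * (wl - 400.0) / 600.0, 0.0, 1.0)
    return Spectrum(wl, values)


def synthetic_layer_spectra(
    n_layers: int, wavelengths: np.ndarray = DEFAULT_WAVELENGTHS
) -> dict[int, Spectrum]:
    """Per-layer synthetic leaf spectra; upper layers slightly greener
    (younger leaves), layer 1 = flag leaf."""
    return {
        layer: synthetic_leaf_spectrum(wavelengths, greenness=1.0 - 0.06 * (layer - 1))
        for layer in range(1, n_layers + 1)
    }


# -- toy reflectance provider ------------------------------------------------

def toy_reflectance(
    record: StructureRecord,
    layer_spectra: dict[int, Spectrum],
    soil: Spectrum,
    ground_area_cm2: float = 1600.0,
    extinction: float = 0.5,
) -> np.ndarray:
    """Gap-fraction mixing reflectance for one structure.

    Per-layer one-sided leaf area comes from the length x width allometry,
    scaled by plant count; the effective LAI over ``ground_area_cm2``
    (default the 40 x 40 cm single-hill plot) sets the soil gap
    ``exp(-0.5 * LAI_eff)``; the vegetated fraction mixes layer spectra
    with weights proportional to layer area times ``exp(-extinction *
    depth)`` (depth 0 = flag-leaf layer). Output is clipped to [0, 1].
    """
    for spec in layer_spectra.values():
        if not np.array_equal(spec.wavelengths, soil.wavelengths):
            raise FormatError("layer and soil spectra must share one wavelength grid")
    areas: dict[int, float] = {}
    for leaf in record.per_leaf:
        areas[leaf.position] = (
            areas.get(leaf.position, 0.0)
            + leaf_area(leaf.length, leaf.width) * record.plant_count
        )
    total = sum(areas.values())
    gap = float(np.exp(-0.5 * total / ground_area_cm2))
    if total == 0.0:
        return soil.values.copy()
    weights = {
        layer: area * np.exp(-extinction * (layer - 1))
        for layer, area in areas.items()
    }
    wsum = sum(weights.values())
    leaf_mix = sum(
        (w / wsum) * layer_spectra[layer].values for layer, w in weights.items()
    )
    return np.clip(gap * soil.values + (1.0 - gap) * leaf_mix, 0.0, 1.0)


# -- feature table and importances ------------------------------------------

def build_feature_table(
    records: list[StructureRecord], max_layers: int = 6
) -> pd.DataFrame:
    """Structure-parameter design matrix for the importance analysis.

    Columns: plant_count, plant_height, and per-layer
    ``L{layer}_{length,width,inclination,position_ratio}`` up to
    ``max_layers``; absent layers are encoded as 0 with an ``L{layer}_present``
    flag.
    """
    rows = []
    for r in records:
        row = {
            "plant_count": float(r.plant_count),
            "plant_height": r.observation.plant_height,
        }
        by_pos = {leaf.position: leaf for leaf in r.per_leaf}
        for layer in range(1, max_layers + 1):
            leaf = by_pos.get(layer)
            row[f"L{layer}_present"] = 1.0 if leaf else 0.0
            row[f"L{layer}_length"] = leaf.length if leaf else 0.0
            row[f"L{layer}_width"] = leaf.width if leaf else 0.0
            row[f"L{layer}_inclination"] = (
                leaf.inclination if leaf and leaf.inclination is not None else 0.0
            )
            row[f"L{layer}_position_ratio"] = leaf.position_ratio if leaf else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ImportanceReport:
    """Normalized feature importances (sum to 1) and their provenance."""

    per_feature: dict[str, float]
    variant: str  # with_plant_count | without_plant_count
    method: str = "impurity"

    def __post_init__(self) -> None:
        total = sum(self.per_feature.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("importances must sum to 1")

    def summary(self, top: int = 10) -> str:
        ranked = sorted(self.per_feature.items(), key=lambda kv: -kv[1])[:top]
        lines = [f"Feature importances ({self.variant}, {self.method})"]
        lines += [f"  {name:<22} {value:7.4f}" for name, value in ranked]
        return "\n".join(lines)


def compute_importances(
    features: pd.DataFrame,
    spectra: SpectraTable,
    include_plant_count: bool = True,
    seed: int = 0,
    n_estimators: int = 200,
    method: str = "impurity",
) -> ImportanceReport:
    """Random-forest importances of structural features for the spectra.

    One forest is fitted per wavelength band; per-band importances are
    averaged across the grid and normalized to sum to 1. With
    ``include_plant_count=False`` the plant-count column is dropped before
    fitting so the remaining importances renormalize among themselves.
    ``method`` selects impurity-based (default) or permutation importance.
    """
    if len(features) != len(spectra.rows):
        raise ConfigError("feature row count does not match spectra row count")
    if features.shape[1] < 2:
        raise ConfigError("need at least two features")
    cols = list(features.columns)
    if not include_plant_count and "plant_count" in cols:
        cols = [c for c in cols if c != "plant_count"]
    X = features[cols].to_numpy(dtype=np.float64)
    for j, c in enumerate(cols):
        if np.ptp(X[:, j]) == 0:
            # kept in the model (importance will be ~0), but worth surfacing
            import logging

            logging.getLogger(__name__).warning("constant feature column %r", c)
    acc = np.zeros(len(cols))
    rng = np.random.default_rng(seed)
    for band in range(spectra.rows.shape[1]):
        rf = RandomForestRegressor(
            n_estimators=n_estimators,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        y = spectra.rows[:, band]
        rf.fit(X, y)
        if method == "impurity":
            acc += rf.feature_importances_
        elif method == "permutation":
            pi = permutation_importance(
                rf, X, y, n_repeats=5,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            acc += np.maximum(pi.importances_mean, 0.0)
        else:
            raise ConfigError(f"unknown importance method {method!r}")
    total = acc.sum()
    if total == 0:
        raise ConfigError("all importances are zero (constant spectra?)")
    norm = acc / total
    return ImportanceReport(
        per_feature={c: float(v) for c, v in zip(cols, norm)},
        variant="with_plant_count" if include_plant_count else "without_plant_count",
        method=method,
    )


def aggregate_importances(
    report: ImportanceReport, grouping: str
) -> dict[str, float]:
    """Aggregate per-feature importances ``by_layer`` or ``by_parameter_type``.

    Layer-parameter names must follow ``L{layer}_{parameter}``; canopy-level
    names group under ``canopy`` (by layer) or themselves (by parameter
    type). Group sums partition the total importance.
    """
    if grouping not in ("by_layer", "by_parameter_type"):
        raise ConfigError(f"unknown grouping {grouping!r}")
    out: dict[str, float] = {}
    for name, value in report.per_feature.items():
        m = _LAYER_RE.match(name)
        if m:
            key = f"L{m.group(1)}" if grouping == "by_layer" else m.group(2)
        elif name in CANOPY_FEATURES:
            key = "canopy" if grouping == "by_layer" else name
        else:
            raise NamingError(f"feature name {name!r} does not follow the convention")
        out[key] = out.get(key, 0.0) + value
    return out


def compute_vegetation_indices(
    spectrum: np.ndarray, wavelengths: np.ndarray
) -> dict[str, float]:
    """NDVI (800/670 nm) and CIrededge (800/720 nm) from one spectrum."""
    wl = np.asarray(wavelengths, dtype=np.float64)
    if wl.min() > 670.0 or wl.max() < 800.0:
        raise FormatError("wavelength grid must cover 670-800 nm")
    spectrum = np.asarray(spectrum, dtype=np.float64)

    def band(nm: float) -> float:
        return float(spectrum[np.argmin(np.abs(wl - nm))])

    nir, red, red_edge = band(800.0), band(670.0), band(720.0)
    ndvi = (nir - red) / (nir + red) if (nir + red) != 0 else 0.0
    ci = nir / red_edge - 1.0 if red_edge != 0 else 0.0
    return {"NDVI": float(ndvi), "CIrededge": float(ci)}


def run_sensitivity(
    n: int = 1000,
    seed: int = 0,
    ranges: ParamRanges = DEFAULT_RANGES,
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
    n_estimators: int = 200,
    max_layers: int = 6,
) -> dict[str, ImportanceReport]:
    """End-to-end pipeline: ensemble -> toy spectra -> importances with and
    without plant count. Returns both reports keyed by variant."""
    records = simulate_structure_ensemble(n, ranges, seed)
    layer_spectra = synthetic_layer_spectra(max_layers, wavelengths)
    soil = synthetic_soil_spectrum(wavelengths)
    rows = np.vstack([
        toy_reflectance(r, layer_spectra, soil) for r in records
    ])
    spectra = SpectraTable(wavelengths, rows)
    features = build_feature_table(records, max_layers=max_layers)
    return {
        "with_plant_count": compute_importances(
            features, spectra, include_plant_count=True, seed=seed,
            n_estimators=n_estimators,
        ),
        "without_plant_count": compute_importances(
            features, spectra, include_plant_count=False, seed=seed,
            n_estimators=n_estimators,
        ),
    }
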