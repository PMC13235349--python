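"""Leaf allometry, pigment/water/dry-matter formulas, and the fitted
leaf-inclination-angle distribution function.

Rice leaf area follows the standard length x width allometry with a
species-specific correction coefficient of 0.7746. Chlorophyll a/b and
carotenoid contents come from the classical ethanol-extract absorbance
equations (A470/A649/A665); equivalent water thickness Cw and dry matter
content Cm are fresh/dry-weight differences per unit leaf area.

Rice is erectophile: upper leaves stand closer to vertical. The canopy's
leaf inclination angle (LIA, degrees from the vertical stem direction) is
modelled as a straight line in the leaf position index LP, with the default
field-fitted relation

    LIA = 85.64 - 4.12 * LP.

LP counts leaf positions top-down (1 = flag leaf), consistent with the
layer indexing used by the assembly and sensitivity machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "TraitRecord",
    "LIAFunction",
    "RICE_LIA",
    "leaf_area",
    "pigment_contents",
    "water_and_dry_matter",
    "leaf_inclination_angle",
    "fit_leaf_inclination_function",
    "LEAF_AREA_COEFFICIENT",
    "PROSPECT_METADATA",
]

#: Rice-specific leaf area correction coefficient (LA = a * b * coeff).
LEAF_AREA_COEFFICIENT = 0.7746

#: Leaf-spectrum provider settings recorded as scene metadata. Leaf optical
#: properties are inputs to this package (any PROSPECT-style provider); these
#: are the settings under which the default spectra are expected to be made.
PROSPECT_METADATA = {"model": "PROSPECT-5", "N": 1.5, "Cbrown": 0.0}


@dataclass
class TraitRecord:
    """One leaf sample's biochemical measurements and derived contents.

    Absorbances are unitless; FW/DW in g; LA in cm^2; Cw/Cm in g cm^-2.
    Pigment contents (Ca, Cb, Car) are in the raw units of the extraction
    formulas (mg/L of extract); the conversion to ug cm^-2 needs
    extract-volume constants that are not part of this model, so a units
    tag is carried instead.
    """

    A470: float = 0.0
    A649: float = 0.0
    A665: float = 0.0
    FW: float = 0.0
    DW: float = 0.0
    LA: float = float("nan")
    Ca: float = float("nan")
    Cb: float = float("nan")
    Car: float = float("nan")
    Cw: float = float("nan")
    Cm: float = float("nan")
    pigment_units: str = "formula (mg/L extract)"


def leaf_area(a: float, b: float) -> float:
    """Leaf area (cm^2) from maximum length ``a`` and maximum width ``b`` (cm)."""
    if a < 0 or b < 0:
        raise DomainError("leaf dimensions must be non-negative")
    return a * b * LEAF_AREA_COEFFICIENT


def pigment_contents(A470: float, A649: float, A665: float) -> tuple[float, float, float]:
    """Chlorophyll a, chlorophyll b and carotenoid contents from extract
    absorbances at 470/649/665 nm (classical ethanol-extract equations).

    Negative outputs are physically implausible but arithmetically possible
    for inconsistent absorbances; they are returned with a warning.
    """
    if min(A470, A649, A665) < 0:
        raise DomainError("absorbances must be non-negative")
    ca = 13.95 * A665 - 6.88 * A649
    cb = 24.96 * A649 - 7.32 * A665
    car = (1000.0 * A470 - 2.05 * ca - 114.8 * cb) / 245.0
    if min(ca, cb, car) < 0:
        warnings.warn(
            "pigment formula produced a negative content; check absorbances",
            stacklevel=2,
        )
    return ca, cb, car


def water_and_dry_matter(FW: float, DW: float, LA: float) -> tuple[float, float]:
    """Equivalent water thickness Cw and dry matter content Cm (g cm^-2)
    from fresh weight, dry weight (g) and leaf area (cm^2)."""
    if LA <= 0:
        raise DomainError("leaf area must be positive")
    if not FW >= DW >= 0:
        raise DomainError("require FW >= DW >= 0")
    return (FW - DW) / LA, DW / LA


@dataclass(frozen=True)
class LIAFunction:
    """Linear leaf-inclination-angle distribution: LIA(LP) = intercept + slope*LP.

    ``intercept`` in degrees, ``slope`` in degrees per leaf-position index.
    An erectophile canopy fit has negative slope.
    """

    intercept: float
    slope: float

    def __call__(self, lp: float) -> float:
        return leaf_inclination_angle(self, lp)


#: Default field-fitted erectophile relation: LIA = 85.64 - 4.12 * LP.
RICE_LIA = LIAFunction(intercept=85.64, slope=-4.12)


def leaf_inclination_angle(f: LIAFunction, lp: float) -> float:
    """Evaluate the LIA function at leaf position index ``lp`` (>= 0).

    The raw line can leave [0, 90] degrees for extreme LP; the result is
    clamped into that physical range with a warning, since downstream
    geometry requires a valid inclination.
    """
    if lp < 0:
        raise DomainError("leaf position index must be non-negative")
    angle = f.intercept + f.slope * lp
    if not 0.0 <= angle <= 90.0:
        clamped = float(np.clip(angle, 0.0, 90.0))
        warnings.warn(
            f"LIA({lp}) = {angle:.2f} deg clamped to {clamped:.2f}", stacklevel=2
        )
        return clamped
    return float(angle)


def fit_leaf_inclination_function(
    points: list[tuple[float, float]],
) -> tuple[LIAFunction, float, float]:
    """Ordinary-least-squares fit of the LIA line to (LP, mean angle) points.

    Returns the fitted function, R^2 and RMSE of the fit. Requires at least
    two distinct LP values.
    """
    lp = np.asarray([p[0] for p in points], dtype=np.float64)
    angle = np.asarray([p[1] for p in points], dtype=np.float64)
    if len(lp) < 2 or np.ptp(lp) == 0:
        raise DomainError("need >= 2 distinct leaf position values to fit")
    res = stats.linregress(lp, angle)
    fitted = LIAFunction(intercept=float(res.intercept), slope=float(res.slope))
    pred = res.intercept + res.slope * lp
    rss = float(np.sum((angle - pred) ** 2))
    tss = float(np.sum((angle - angle.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    rmse = float(np.sqrt(np.mean((angle - pred) ** 2)))
    return fitted, r2, rmse
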