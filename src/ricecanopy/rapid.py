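"""Rapid-mode structural parameter estimation.

Maps the four canopy inputs that UAV remote sensing can deliver —
transplanting day, plant height (PH), above-ground biomass (AGB) and LAI —
to the full vertical structure of a hill: leaf count (classification),
tiller/plant count and stem height (regression), and per-leaf length,
width and position ratio (regression with leaf position as an extra
feature, trained on leaf-exploded rows). Three interchangeable learners
are supported: an RBF support vector machine, a random forest, and
gradient-boosted trees (XGBoost); features are centred/scaled with
statistics from the training split only, and 5-fold cross-validation
scores are recorded at fit time.

The module exposes both a functional surface (``split_dataset`` /
``train_estimators`` / ``predict_structure`` / ``evaluate``) and a
model-object surface (:class:`RapidStructureModel` whose :meth:`fit`
returns a :class:`RapidStructureResults` with a ``summary()`` table),
in the style of statistical modelling packages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold, cross_val_score, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import LabelEncoder, StandardScaler
from sklearn.svm import SVC, SVR
from xgboost import XGBClassifier, XGBRegressor

from .errors import ConfigError, StateError, StratificationError
from .records import CanopyObservation, LeafParams, StructureRecord
from .synthetic import DEFAULT_RANGES, ParamRanges
from .traits import RICE_LIA, LIAFunction

__all__ = [
    "ALGORITHMS",
    "EstimatorBundle",
    "EvalReport",
    "RapidStructureModel",
    "RapidStructureResults",
    "split_dataset",
    "train_estimators",
    "predict_structure",
    "evaluate",
    "records_to_frame",
    "frame_to_records",
    "save_bundle",
    "load_bundle",
]

log = logging.getLogger(__name__)

ALGORITHMS = ("svm", "rf", "xgboost")

CANOPY_FEATURES = ["transplant_day", "plant_height", "agb", "lai"]
CANOPY_TARGETS = ["plant_count", "stem_height"]
VERTICAL_TARGETS = ["leaf_length", "leaf_width", "position_ratio"]

_BUNDLE_FORMAT_VERSION = 1


# -- table schemas -----------------------------------------------------------

def records_to_frame(records: Sequence[StructureRecord]) -> pd.DataFrame:
    """Long (leaf-exploded) table: one row per leaf, canopy columns repeated,
    keyed by ``hill_id``. This is the CSV schema the CLI reads and writes."""
    rows = []
    for h, rec in enumerate(records):
        for leaf in rec.per_leaf:
            rows.append(
                {
                    "hill_id": h,
                    "transplant_day": rec.observation.transplant_day,
                    "plant_height": rec.observation.plant_height,
                    "agb": rec.observation.agb,
                    "lai": rec.observation.lai,
                    "leaf_count": rec.leaf_count,
                    "plant_count": rec.plant_count,
                    "stem_height": rec.stem_height,
                    "leaf_position": leaf.position,
                    "leaf_length": leaf.length,
                    "leaf_width": leaf.width,
                    "position_ratio": leaf.position_ratio,
                    "inclination": leaf.inclination,
                }
            )
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[StructureRecord]:
    """Inverse of :func:`records_to_frame`."""
    records = []
    for _, grp in frame.groupby("hill_id", sort=True):
        first = grp.iloc[0]
        leaves = [
            LeafParams(
                position=int(r.leaf_position),
                length=float(r.leaf_length),
                width=float(r.leaf_width),
                position_ratio=float(r.position_ratio),
                inclination=None if pd.isna(r.inclination) else float(r.inclination),
            )
            for r in grp.sort_values("leaf_position").itertuples()
        ]
        records.append(
            StructureRecord(
                observation=CanopyObservation(
                    transplant_day=float(first.transplant_day),
                    plant_height=float(first.plant_height),
                    agb=float(first.agb),
                    lai=float(first.lai),
                ),
                leaf_count=int(first.leaf_count),
                plant_count=int(first.plant_count),
                stem_height=float(first.stem_height),
                per_leaf=leaves,
            )
        )
    return records


# -- splitting ---------------------------------------------------------------

def split_dataset(
    records: Sequence[StructureRecord],
    ratio: float = 0.7,
    stratify_on: str = "leaf_count",
    seed: int = 0,
    allow_fallback: bool = False,
) -> tuple[list[StructureRecord], list[StructureRecord]]:
    """Stratified train/test split at ``ratio`` (train fraction).

    Deterministic per seed; strata with a single record raise
    :class:`StratificationError` unless ``allow_fallback`` is set, in which
    case an unstratified split is used and a warning logged.
    """
    labels = np.array([getattr(r, stratify_on) for r in records])
    idx = np.arange(len(records))
    _, counts = np.unique(labels, return_counts=True)
    stratify = labels
    if counts.min() < 2:
        if not allow_fallback:
            raise StratificationError(
                f"stratum with a single record in {stratify_on!r}; "
                "pass allow_fallback=True for an unstratified split"
            )
        log.warning("stratification fallback: unstratified split used")
        stratify = None
    train_idx, test_idx = train_test_split(
        idx, train_size=ratio, stratify=stratify, random_state=seed
    )
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    return [records[i] for i in train_idx], [records[i] for i in test_idx]


# -- estimators --------------------------------------------------------------

def _make_regressor(algorithm: str, seed: int):
    if algorithm == "svm":
        model = SVR(kernel="rbf", C=10.0)
    elif algorithm == "rf":
        model = RandomForestRegressor(n_estimators=500, random_state=seed, n_jobs=1)
    elif algorithm == "xgboost":
        model = XGBRegressor(
            n_estimators=300, learning_rate=0.1, max_depth=4, reg_lambda=1.0,
            random_state=seed, n_jobs=1, verbosity=0,
        )
    else:
        raise ConfigError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    return Pipeline([("scale", StandardScaler()), ("model", model)])


def _make_classifier(algorithm: str, seed: int):
    if algorithm == "svm":
        model = SVC(kernel="rbf", C=10.0, random_state=seed)
    elif algorithm == "rf":
        model = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    elif algorithm == "xgboost":
        model = XGBClassifier(
            n_estimators=300, learning_rate=0.1, max_depth=4, reg_lambda=1.0,
            random_state=seed, n_jobs=1, verbosity=0,
        )
    else:
        raise ConfigError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    return Pipeline([("scale", StandardScaler()), ("model", model)])


def _canopy_matrix(records: Sequence[StructureRecord]) -> np.ndarray:
    return np.array(
        [
            [r.observation.transplant_day, r.observation.plant_height,
             r.observation.agb, r.observation.lai]
            for r in records
        ]
    )


def _vertical_matrix(records: Sequence[StructureRecord]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Leaf-exploded design matrix (canopy features + leaf position) and
    per-target vectors."""
    rows, y = [], {t: [] for t in VERTICAL_TARGETS}
    for r in records:
        base = [r.observation.transplant_day, r.observation.plant_height,
                r.observation.agb, r.observation.lai]
        for leaf in r.per_leaf:
            rows.append(base + [leaf.position])
            y["leaf_length"].append(leaf.length)
            y["leaf_width"].append(leaf.width)
            y["position_ratio"].append(leaf.position_ratio)
    return np.array(rows), {t: np.array(v) for t, v in y.items()}


@dataclass
class EstimatorBundle:
    """Trained rapid-mode models for one algorithm.

    Feature normalization lives inside each pipeline and is fitted on
    training data only. ``vertical_models`` take leaf position as a fifth
    feature; ``bounds`` clips predictions into physical range.
    """

    algorithm: str
    leaf_count_model: Pipeline
    label_encoder: LabelEncoder
    canopy_models: dict[str, Pipeline]
    vertical_models: dict[str, Pipeline]
    cv_scores: dict[str, float]
    cv_config: dict[str, int]
    bounds: ParamRanges = field(default_factory=lambda: DEFAULT_RANGES)
    fitted: bool = False


def train_estimators(
    train: Sequence[StructureRecord],
    algorithm: str = "rf",
    cv_folds: int = 5,
    seed: int = 0,
    bounds: ParamRanges = DEFAULT_RANGES,
) -> EstimatorBundle:
    """Fit the leaf-count classifier, canopy regressors and vertical
    (per-leaf) regressors on the training records, recording K-fold CV
    scores (accuracy for classification, R^2 for regression)."""
    if not train:
        raise ConfigError("training set is empty")
    if algorithm not in ALGORITHMS:
        raise ConfigError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    if len(train) < cv_folds:
        raise ConfigError("fewer training records than CV folds")

    X = _canopy_matrix(train)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_scores: dict[str, float] = {}

    le = LabelEncoder()
    y_count = le.fit_transform([r.leaf_count for r in train])
    clf = _make_classifier(algorithm, seed)
    if len(le.classes_) > 1:
        cv_scores["leaf_count"] = float(
            cross_val_score(clf, X, y_count, cv=cv, scoring="accuracy").mean()
        )
    clf.fit(X, y_count)

    canopy_models: dict[str, Pipeline] = {}
    for target in CANOPY_TARGETS:
        y = np.array([getattr(r, target) for r in train], dtype=np.float64)
        reg = _make_regressor(algorithm, seed)
        cv_scores[target] = float(cross_val_score(reg, X, y, cv=cv, scoring="r2").mean())
        reg.fit(X, y)
        canopy_models[target] = reg

    Xv, yv = _vertical_matrix(train)
    vertical_models: dict[str, Pipeline] = {}
    for target in VERTICAL_TARGETS:
        reg = _make_regressor(algorithm, seed)
        cv_scores[target] = float(
            cross_val_score(reg, Xv, yv[target], cv=cv, scoring="r2").mean()
        )
        reg.fit(Xv, yv[target])
        vertical_models[target] = reg

    return EstimatorBundle(
        algorithm=algorithm,
        leaf_count_model=clf,
        label_encoder=le,
        canopy_models=canopy_models,
        vertical_models=vertical_models,
        cv_scores=cv_scores,
        cv_config={"folds": cv_folds, "seed": seed},
        bounds=bounds,
        fitted=True,
    )


def _clip(value: float, lo: float, hi: float, what: str) -> float:
    if value < lo or value > hi:
        log.info("clipped %s from %.4f into [%.4f, %.4f]", what, value, lo, hi)
    return float(np.clip(value, lo, hi))


def predict_structure(
    bundle: EstimatorBundle,
    obs: CanopyObservation,
    lia: LIAFunction = RICE_LIA,
) -> StructureRecord:
    """Predict a full structural record from one canopy observation.

    Leaf count is classified first; each leaf position 1..count then gets
    length/width/position-ratio predictions, with the inclination angle
    attached from the LIA function. Predictions are clipped into the
    bundle's physical bounds (clip events logged); plant count is rounded
    to the nearest integer >= 1.
    """
    if not bundle.fitted:
        raise StateError("bundle is not trained")
    b = bundle.bounds
    x = np.array([[obs.transplant_day, obs.plant_height, obs.agb, obs.lai]])
    leaf_count = int(
        bundle.label_encoder.inverse_transform(bundle.leaf_count_model.predict(x))[0]
    )
    plant_count = max(1, round(float(bundle.canopy_models["plant_count"].predict(x)[0])))
    plant_count = int(_clip(plant_count, b.plant_count.min, b.plant_count.max,
                            "plant_count"))
    stem_height = _clip(float(bundle.canopy_models["stem_height"].predict(x)[0]),
                        b.stem_height.min, b.stem_height.max, "stem_height")
    leaves = []
    for p in range(1, leaf_count + 1):
        xv = np.array([[obs.transplant_day, obs.plant_height, obs.agb, obs.lai, p]])
        length = _clip(float(bundle.vertical_models["leaf_length"].predict(xv)[0]),
                       b.leaf_length.min, b.leaf_length.max, f"L{p} length")
        width = _clip(float(bundle.vertical_models["leaf_width"].predict(xv)[0]),
                      b.leaf_width.min, b.leaf_width.max, f"L{p} width")
        ratio = _clip(float(bundle.vertical_models["position_ratio"].predict(xv)[0]),
                      b.position_ratio.min, b.position_ratio.max, f"L{p} ratio")
        leaves.append(LeafParams(position=p, length=length, width=width,
                                 position_ratio=ratio, inclination=lia(p)))
    return StructureRecord(
        observation=obs,
        leaf_count=leaf_count,
        plant_count=plant_count,
        stem_height=stem_height,
        per_leaf=leaves,
    )


# -- evaluation --------------------------------------------------------------

@dataclass
class EvalReport:
    """Accuracy/precision/recall for the leaf-count classifier and
    R^2 / RMSE per regression target, on one evaluation set."""

    n: int
    accuracy: float
    precision: dict[int, float]
    recall: dict[int, float]
    macro_precision: float
    macro_recall: float
    confusion: np.ndarray
    classes: list[int]
    regression: dict[str, dict[str, float | None]]

    def summary(self) -> str:
        lines = [
            f"Leaf-count classification (n = {self.n})",
            f"  accuracy        {self.accuracy:8.4f}",
            f"  macro precision {self.macro_precision:8.4f}",
            f"  macro recall    {self.macro_recall:8.4f}",
            "Regression targets           R2        RMSE",
        ]
        for target, m in self.regression.items():
            r2 = "   n/a " if m["r2"] is None else f"{m['r2']:7.4f}"
            lines.append(f"  {target:<24} {r2}   {m['rmse']:9.4f}")
        return "\n".join(lines)


def _r2_rmse(y_true: np.ndarray, y_pred: np.ndarray,
             normalized_rmse: bool = False) -> dict[str, float | None]:
    rmse = float(np.sqrt(skm.mean_squared_error(y_true, y_pred)))
    if np.ptp(y_true) == 0:
        log.warning("zero-variance truth: R^2 undefined, reported as missing")
        r2: float | None = None
    else:
        r2 = float(skm.r2_score(y_true, y_pred))
    out: dict[str, float | None] = {"r2": r2, "rmse": rmse}
    if normalized_rmse:
        out["nrmse"] = rmse / float(np.mean(y_true))
    return out


def evaluate(
    bundle: EstimatorBundle,
    test: Sequence[StructureRecord],
    lia: LIAFunction = RICE_LIA,
    normalized_rmse: bool = False,
) -> EvalReport:
    """Score the bundle on an evaluation set.

    Classification metrics come from the multi-class confusion matrix
    (precision/recall one-vs-rest per class, macro-averaged); regression
    metrics are R^2 = 1 - RSS/TSS and RMSE. Vertical targets are scored on
    leaf-exploded rows using the true leaf positions.
    """
    if not test:
        raise ConfigError("evaluation set is empty")
    X = _canopy_matrix(test)
    y_true = np.array([r.leaf_count for r in test])
    y_pred = bundle.label_encoder.inverse_transform(bundle.leaf_count_model.predict(X))
    classes = sorted(set(y_true) | set(y_pred))
    confusion = skm.confusion_matrix(y_true, y_pred, labels=classes)
    precision, recall, _, _ = skm.precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )

    regression: dict[str, dict[str, float | None]] = {}
    for target in CANOPY_TARGETS:
        truth = np.array([getattr(r, target) for r in test], dtype=np.float64)
        pred = bundle.canopy_models[target].predict(X)
        regression[target] = _r2_rmse(truth, pred, normalized_rmse)
    Xv, yv = _vertical_matrix(test)
    for target in VERTICAL_TARGETS:
        pred = bundle.vertical_models[target].predict(Xv)
        regression[target] = _r2_rmse(yv[target], pred, normalized_rmse)

    return EvalReport(
        n=len(test),
        accuracy=float(skm.accuracy_score(y_true, y_pred)),
        precision={int(c): float(p) for c, p in zip(classes, precision)},
        recall={int(c): float(r) for c, r in zip(classes, recall)},
        macro_precision=float(np.mean(precision)),
        macro_recall=float(np.mean(recall)),
        confusion=confusion,
        classes=[int(c) for c in classes],
        regression=regression,
    )


# -- model-object surface ----------------------------------------------------

class RapidStructureModel:
    """Rapid-mode estimation model over a set of structural records.

    Follows the model/results pattern: construct from records (or a
    leaf-exploded DataFrame via :meth:`from_dataframe`), then :meth:`fit`
    splits, trains and evaluates, returning :class:`RapidStructureResults`.
    """

    def __init__(
        self,
        records: Sequence[StructureRecord],
        algorithm: str = "rf",
        cv_folds: int = 5,
        train_fraction: float = 0.7,
        bounds: ParamRanges = DEFAULT_RANGES,
    ) -> None:
        if algorithm not in ALGORITHMS:
            raise ConfigError(
                f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}"
            )
        self.records = list(records)
        self.algorithm = algorithm
        self.cv_folds = cv_folds
        self.train_fraction = train_fraction
        self.bounds = bounds

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "RapidStructureModel":
        return cls(frame_to_records(frame), **kwargs)

    def fit(self, seed: int = 0, allow_fallback: bool = False) -> "RapidStructureResults":
        train, test = split_dataset(
            self.records, ratio=self.train_fraction, seed=seed,
            allow_fallback=allow_fallback,
        )
        bundle = train_estimators(
            train, algorithm=self.algorithm, cv_folds=self.cv_folds,
            seed=seed, bounds=self.bounds,
        )
        return RapidStructureResults(self, bundle, train, test)


class RapidStructureResults:
    """Fitted rapid-mode results: the trained bundle plus train/test reports."""

    def __init__(self, model, bundle, train, test) -> None:
        self.model = model
        self.bundle = bundle
        self.train = train
        self.test = test
        self.train_report = evaluate(bundle, train)
        self.test_report = evaluate(bundle, test)

    def predict(self, obs: CanopyObservation, lia: LIAFunction = RICE_LIA) -> StructureRecord:
        return predict_structure(self.bundle, obs, lia)

    def summary(self) -> str:
        head = (
            f"Rapid-mode structure estimation ({self.bundle.algorithm}, "
            f"{len(self.train)} train / {len(self.test)} test hills, "
            f"{self.bundle.cv_config['folds']}-fold CV)"
        )
        cv = "\n".join(
            f"  CV {name:<24} {score:7.4f}"
            for name, score in self.bundle.cv_scores.items()
        )
        return "\n".join(
            [head, "Cross-validation scores", cv,
             "--- train ---", self.train_report.summary(),
             "--- test ---", self.test_report.summary()]
        )

    def save(self, path) -> None:
        save_bundle(self.bundle, path)


def save_bundle(bundle: EstimatorBundle, path) -> None:
    """Serialize a trained bundle to a single file with a version header."""
    joblib.dump({"format_version": _BUNDLE_FORMAT_VERSION, "bundle": bundle}, path)


def load_bundle(path) -> EstimatorBundle:
    payload = joblib.load(path)
    if payload.get("format_version") != _BUNDLE_FORMAT_VERSION:
        raise ConfigError("unrecognized bundle format version")
    return payload["bundle"]
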