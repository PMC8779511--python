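"""Metabolic rate (M, W/m²) from posture and activity-intensity features.

A sitting office occupant's metabolic rate varies so little (58–87 W/m²)
that its midpoint, 72.5 W/m², stands in for the whole range. A standing
occupant's rate spans 75–174 W/m², so the window's activity-intensity
features are classified into low / moderate / high levels and the class
probabilities (Pl, Pm, Ph) are blended into a continuous estimate:

    M = Pl * Ml + Pm * Mm + Ph * Mh

with level anchors Ml = 75, Mm = 125, Mh = 174 W/m² (the lower boundary,
middle value, and upper boundary of the standing range).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import __version__ as _pkg_version
from .activity import ActivityFeatures
from .core import PipelineConfig, Posture

__all__ = [
    "LEVELS",
    "ActivityProbabilities",
    "MetabolicResult",
    "ActivityClassifier",
    "fit_activity_classifier",
    "predict_probabilities",
    "estimate_m",
]

#: canonical class order; probability vectors are always emitted in it
LEVELS = ("low", "moderate", "high")

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class ActivityProbabilities:
    """Simplex-valid (Pl, Pm, Ph) in the fixed (low, moderate, high) order."""

    p_low: float
    p_moderate: float
    p_high: float

    def __post_init__(self) -> None:
        vals = (self.p_low, self.p_moderate, self.p_high)
        if any(not (0.0 <= p <= 1.0) for p in vals):
            raise ValueError(f"probabilities must lie in [0, 1], got {vals}")
        if abs(sum(vals) - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities must sum to 1, got {sum(vals)!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_low, self.p_moderate, self.p_high)

    @property
    def argmax_level(self) -> str:
        return LEVELS[int(np.argmax(self.as_tuple()))]


@dataclass(frozen=True)
class MetabolicResult:
    m: float
    posture: Posture
    probabilities: Optional[ActivityProbabilities] = None
    features: Optional[ActivityFeatures] = None


def estimate_m(
    posture: Posture,
    probabilities: Optional[ActivityProbabilities],
    config: Optional[PipelineConfig] = None,
    features: Optional[ActivityFeatures] = None,
) -> MetabolicResult:
    """Estimate M from posture and, for standing, level probabilities."""
    config = config or PipelineConfig()
    posture = Posture(posture)
    if posture is Posture.SIT:
        return MetabolicResult(m=config.m_sitting, posture=posture)
    if probabilities is None:
        raise ValueError("standing posture requires activity probabilities")
    ml, mm, mh = config.m_levels
    m = (
        probabilities.p_low * ml
        + probabilities.p_moderate * mm
        + probabilities.p_high * mh
    )
    return MetabolicResult(m=m, posture=posture, probabilities=probabilities, features=features)


class ActivityClassifier:
    """A trained 3-level activity-intensity classifier.

    Wraps an sklearn estimator and pins the probability column order to
    (low, moderate, high) regardless of the estimator's internal class
    ordering.
    """

    def __init__(self, estimator, model_kind: str, hyperparameters: dict, seed: int):
        self.estimator = estimator
        self.model_kind = model_kind
        self.hyperparameters = hyperparameters
        self.seed = seed
        self.version = _pkg_version

    def predict_probabilities(self, features: ActivityFeatures) -> ActivityProbabilities:
        return predict_probabilities(self, features)

    def predict_probabilities_batch(self, x: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(np.asarray(x, dtype=float))
        classes = list(self._classes())
        cols = [classes.index(level) for level in LEVELS]
        out = proba[:, cols]
        return out / out.sum(axis=1, keepdims=True)

    def _classes(self):
        est = self.estimator
        final = est[-1] if hasattr(est, "__getitem__") and hasattr(est, "steps") else est
        return final.classes_

    def save(self, path: str | Path) -> None:
        """Persist to a versioned file with embedded hyperparameters and seed."""
        joblib.dump(
            {
                "format": "thermocomfort-activity-classifier/1",
                "version": self.version,
                "model_kind": self.model_kind,
                "hyperparameters": self.hyperparameters,
                "seed": self.seed,
                "estimator": self.estimator,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ActivityClassifier":
        blob = joblib.load(path)
        if blob.get("format") != "thermocomfort-activity-classifier/1":
            raise ValueError(f"unrecognized classifier file format in {path}")
        obj = cls(
            estimator=blob["estimator"],
            model_kind=blob["model_kind"],
            hyperparameters=blob["hyperparameters"],
            seed=blob["seed"],
        )
        obj.version = blob["version"]
        return obj


_DEFAULT_HYPERPARAMETERS: Mapping[str, dict] = {
    "random_forest": {"max_depth": 2},
    "knn": {"metric": "manhattan", "weights": "distance", "n_neighbors": 13},
    "svm": {"C": 50, "kernel": "rbf", "gamma": "scale"},
}


def fit_activity_classifier(
    training: Sequence[tuple[ActivityFeatures, str]],
    model_kind: str = "random_forest",
    hyperparameters: Optional[dict] = None,
    seed: int = 0,
) -> ActivityClassifier:
    """Fit a low/moderate/high activity-level classifier.

    Windows labelled ``"ambiguous"`` (mixed-intensity, too hard to label)
    are dropped before fitting. Every remaining class must be represented.
    Feature z-scoring (training-set statistics) is applied for knn and svm
    but not for the tree-based random forest. Training is
    seed-deterministic and invariant to the order of the training sequence
    (examples are canonically sorted before fitting).
    """
    if model_kind not in _DEFAULT_HYPERPARAMETERS:
        raise ValueError(
            f"unknown model_kind {model_kind!r}; expected one of "
            f"{sorted(_DEFAULT_HYPERPARAMETERS)}"
        )
    kept = [(f, str(label)) for f, label in training if str(label) != "ambiguous"]
    for f, label in kept:
        if label not in LEVELS:
            raise ValueError(f"unknown activity level label {label!r}")
    present = {label for _, label in kept}
    for level in LEVELS:
        if level not in present:
            raise ValueError(f"training data has no examples of class {level!r}")

    # canonical order so permutations of the input cannot change the fit
    kept.sort(key=lambda fl: (fl[1], tuple(fl[0].as_array())))
    x = np.array([f.as_array() for f, _ in kept], dtype=float)
    y = np.array([label for _, label in kept])

    params = dict(_DEFAULT_HYPERPARAMETERS[model_kind])
    if hyperparameters:
        params.update(hyperparameters)

    if model_kind == "random_forest":
        est = RandomForestClassifier(random_state=seed, **params)
    elif model_kind == "knn":
        est = make_pipeline(StandardScaler(), KNeighborsClassifier(**params))
    else:  # svm
        est = make_pipeline(
            StandardScaler(), SVC(probability=True, random_state=seed, **params)
        )
    est.fit(x, y)
    return ActivityClassifier(est, model_kind, params, seed)


def predict_probabilities(
    classifier: ActivityClassifier, features: ActivityFeatures
) -> ActivityProbabilities:
    """Class probabilities for one feature window, in (low, moderate, high) order."""
    if not isinstance(classifier, ActivityClassifier):
        raise TypeError("classifier must be a fitted ActivityClassifier")
    row = classifier.predict_probabilities_batch(features.as_array()[None, :])[0]
    return ActivityProbabilities(
        p_low=float(row[0]), p_moderate=float(row[1]), p_high=float(row[2])
    )
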