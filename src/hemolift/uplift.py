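"""Two-model (T-learner) uplift estimation and response typing.

The uplift of patient *i* is u(x_i) = P(Y=1 | T=1, x_i) - P(Y=1 | T=0, x_i):
the incremental probability of a beneficial outcome under the treatment
regime.  The two-model approach fits one outcome-probability learner per
arm and differences their predictions.  Dichotomizing the two
probabilities at a threshold yields the four classical response types.

Supported learners: a logistic regression (standardized features, light L2
so quasi-separated resamples stay fittable) and a random forest
(probability = vote fraction).  A pooled single-model "baseline" predictor
of outcome risk — with no arm indicator — is also provided as the
traditional-prediction comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .treatment import PseudoPopulation

SUPPORTED_KINDS = ("logistic_regression", "random_forest")


@dataclass(frozen=True)
class LearnerSpec:
    """Which probability learner to use, with its hyperparameters."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SUPPORTED_KINDS:
            raise ValueError(
                f"unknown learner kind {self.kind!r}; supported: {SUPPORTED_KINDS}"
            )

    def with_seed(self, seed: int) -> "LearnerSpec":
        return LearnerSpec(self.kind, dict(self.hyperparameters), seed)


def make_learner(spec: LearnerSpec):
    """Instantiate an unfitted sklearn probability classifier."""
    hp = spec.hyperparameters
    if spec.kind == "logistic_regression":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "logit",
                    LogisticRegression(
                        C=hp.get("C", 100.0),
                        max_iter=hp.get("max_iter", 2000),
                    ),
                ),
            ]
        )
    return RandomForestClassifier(
        n_estimators=hp.get("n_trees", 500),
        max_features=hp.get("max_features", "sqrt"),
        max_depth=hp.get("max_depth", None),
        min_samples_leaf=hp.get("min_samples_leaf", 1),
        random_state=spec.seed,
        n_jobs=1,
    )


def _check_two_classes(y: np.ndarray, label: str) -> None:
    if np.min(y) == np.max(y):
        raise ValueError(f"{label} contains a single outcome class; cannot fit")


def _fit_proba(learner, X: pd.DataFrame, y: np.ndarray):
    learner.fit(X, y)
    return learner


def _predict_p1(learner, X: pd.DataFrame) -> np.ndarray:
    proba = learner.predict_proba(X)
    return proba[:, list(learner.classes_).index(1)]


@dataclass
class UpliftModel:
    """Pair of per-arm outcome models sharing one feature list."""

    model_treatment: object
    model_control: object
    learner_spec: LearnerSpec
    feature_names: list[str]


@dataclass
class UpliftScores:
    p_treat: np.ndarray
    p_control: np.ndarray

    @property
    def uplift(self) -> np.ndarray:
        return self.p_treat - self.p_control


def fit_two_model(
    features: pd.DataFrame,
    arms: np.ndarray,
    outcomes: np.ndarray,
    learner_spec: LearnerSpec,
) -> UpliftModel:
    """Fit the per-arm outcome models; deterministic given the learner seed.

    Each arm must contain both outcome classes (the error names the
    offending arm).  The two sub-models use derived seeds so the pair is
    reproducible but not artificially identical.
    """
    arms = np.asarray(arms, dtype=int)
    outcomes = np.asarray(outcomes, dtype=int)
    for arm_value, label in ((1, "treatment arm"), (0, "control arm")):
        mask = arms == arm_value
        if not mask.any():
            raise ValueError(f"{label} is empty; cannot fit")
        _check_two_classes(outcomes[mask], label)
    t_mask = arms == 1
    model_t = _fit_proba(
        make_learner(learner_spec.with_seed(learner_spec.seed * 2 + 1)),
        features[t_mask],
        outcomes[t_mask],
    )
    model_c = _fit_proba(
        make_learner(learner_spec.with_seed(learner_spec.seed * 2 + 2)),
        features[~t_mask],
        outcomes[~t_mask],
    )
    return UpliftModel(model_t, model_c, learner_spec, list(features.columns))


def fit_two_model_on_pseudo(
    pseudo: PseudoPopulation, learner_spec: LearnerSpec, feature_names: list[str]
) -> UpliftModel:
    return fit_two_model(
        pseudo.features(feature_names), pseudo.arm, pseudo.outcomes, learner_spec
    )


def predict_uplift(model: UpliftModel, features: pd.DataFrame) -> UpliftScores:
    """Per-patient (p_treat, p_control, uplift = p_treat - p_control)."""
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise KeyError(f"features missing from input: {missing}")
    X = features[model.feature_names]
    return UpliftScores(
        p_treat=_predict_p1(model.model_treatment, X),
        p_control=_predict_p1(model.model_control, X),
    )


class ResponseType(str, Enum):
    SURE_THING = "SureThing"        # benefits either way
    LOST_CAUSE = "LostCause"        # benefits neither way
    DO_NOT_DISTURB = "DoNotDisturb"  # harmed by treatment
    PERSUADABLE = "Persuadable"     # benefits only under treatment


def classify_response_type(
    scores: UpliftScores, threshold: float = 0.5
) -> np.ndarray:
    """Map (p_treat, p_control) to response types by strict thresholding
    ("above 0.5"), so a probability exactly at the threshold counts as not
    beneficial."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly in (0,1)")
    for p in (scores.p_treat, scores.p_control):
        p = np.asarray(p, dtype=float)
        if (p < 0).any() or (p > 1).any():
            raise ValueError("probabilities must lie in [0,1]")
    t = np.asarray(scores.p_treat) > threshold
    c = np.asarray(scores.p_control) > threshold
    out = np.where(
        t & c,
        ResponseType.SURE_THING.value,
        np.where(
            t & ~c,
            ResponseType.PERSUADABLE.value,
            np.where(~t & c, ResponseType.DO_NOT_DISTURB.value,
                     ResponseType.LOST_CAUSE.value),
        ),
    )
    return out


def per_patient_table(model: UpliftModel, cohort) -> pd.DataFrame:
    """Per-patient prediction export: ``patient_id, p_control, p_treat,
    uplift, response_type``."""
    scores = predict_uplift(model, cohort.features(model.feature_names))
    return pd.DataFrame(
        {
            "patient_id": cohort.df["patient_id"].to_numpy(),
            "p_control": scores.p_control,
            "p_treat": scores.p_treat,
            "uplift": scores.uplift,
            "response_type": classify_response_type(scores),
        }
    )


def fit_baseline_prediction(
    features: pd.DataFrame,
    outcomes: np.ndarray,
    learner_spec: LearnerSpec,
):
    """Traditional single prediction model of the beneficial outcome.

    Both arms are pooled and the arm indicator is *not* a feature: the
    model sorts patients purely by predicted outcome likelihood
    (descending), irrespective of treatment choice.
    """
    outcomes = np.asarray(outcomes, dtype=int)
    _check_two_classes(outcomes, "pooled outcome")
    learner = make_learner(learner_spec)
    return _fit_proba(learner, features, outcomes)


def predict_beneficial(learner, features: pd.DataFrame) -> np.ndarray:
    return _predict_p1(learner, features)
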