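"""The used-to-treat classifier: an RBF-kernel SVM with Platt calibration.

Organized as a model/results pair: :class:`UsedToTreatModel` holds the
design matrix and labels; :meth:`UsedToTreatModel.fit` selects the SVM
cost hyperparameter by ten-fold cross-validation with the 1-se rule,
fits the margin classifier, calibrates decision values to probabilities
with a logistic (Platt) map fitted on out-of-fold decision values, and
returns a :class:`UsedToTreatResults` carrying the fitted pieces, the
CV table, and prediction/evaluation methods.

Count-like features are log1p-transformed and all features are
standardized to zero mean / unit variance on the training data only;
the RBF kernel metric is otherwise dominated by heavy-tailed counts.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import COUNT_FEATURES, FEATURE_NAMES, NAIVE_FEATURES

DEFAULT_THRESHOLD = 0.99
DEFAULT_COST_GRID = tuple(2.0 ** k for k in range(-5, 16, 2))

FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "empirical-naive": ("n_drug", "n_ind") + NAIVE_FEATURES,
    "empirical": tuple(FEATURE_NAMES[:9]),
    "usage-kb": tuple(FEATURE_NAMES[9:15]),
    "attribute-kb": tuple(FEATURE_NAMES[15:25]),
}
ABLATION_ROWS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("empirical-naive", ("empirical-naive",)),
    ("empirical", ("empirical",)),
    ("usage-kb", ("usage-kb",)),
    ("attribute-kb", ("attribute-kb",)),
    ("empirical+usage-kb", ("empirical", "usage-kb")),
    ("empirical+attribute-kb", ("empirical", "attribute-kb")),
    ("all", ("empirical", "usage-kb", "attribute-kb")),
)


class TrainingError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and the derived metrics at the flag threshold."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def f1(self) -> float:
        p, s = self.ppv, self.sensitivity
        return 2 * p * s / (p + s) if p + s else 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "ppv": self.ppv,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


def one_se_cost(cv_table: pd.DataFrame) -> float:
    """1-se rule: the smallest cost whose mean CV error is within one
    standard error of the minimum mean CV error."""
    best = cv_table["mean_error"].idxmin()
    ceiling = cv_table.loc[best, "mean_error"] + cv_table.loc[best, "se_error"]
    eligible = cv_table[cv_table["mean_error"] <= ceiling]
    return float(eligible["cost"].min())


def fit_platt(decision_values: np.ndarray, labels: np.ndarray) -> LogisticRegression:
    """Unpenalized logistic map from decision values to probabilities."""
    decision_values = np.asarray(decision_values, dtype=float)
    if np.ptp(decision_values) == 0:
        raise CalibrationError("degenerate decision values: all equal")
    platt = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    platt.fit(decision_values.reshape(-1, 1), np.asarray(labels).astype(int))
    return platt


def _design_matrix(df: pd.DataFrame, feature_names) -> np.ndarray:
    X = df.loc[:, list(feature_names)].to_numpy(dtype=float).copy()
    for j, name in enumerate(feature_names):
        if name in COUNT_FEATURES:
            X[:, j] = np.log1p(np.maximum(X[:, j], 0.0))
    return X


class UsedToTreatModel:
    """SVM model of the used-to-treat relation over pair feature vectors."""

    def __init__(
        self,
        features: pd.DataFrame,
        labels: np.ndarray | pd.Series,
        feature_names: tuple[str, ...] = FEATURE_NAMES,
    ) -> None:
        self.feature_names = tuple(feature_names)
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise TrainingError(f"feature columns missing: {missing}")
        self.frame = features.reset_index(drop=True)
        self.X = _design_matrix(self.frame, self.feature_names)
        self.y = np.asarray(labels).astype(int)
        if len(self.y) != len(self.X):
            raise TrainingError("features and labels differ in length")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        feature_names: tuple[str, ...] = FEATURE_NAMES,
    ) -> "UsedToTreatModel":
        labels = (df[label_col] == "positive").astype(int).to_numpy()
        return cls(df, labels, feature_names)

    def fit(
        self,
        folds: int = 10,
        cost_grid: tuple[float, ...] = DEFAULT_COST_GRID,
        seed: int = 0,
    ) -> "UsedToTreatResults":
        """CV cost selection (1-se rule), final fit, Platt calibration."""
        classes, counts = np.unique(self.y, return_counts=True)
        if len(classes) < 2:
            raise TrainingError("training labels contain a single class")
        if counts.min() < folds:
            raise TrainingError(
                f"need at least {folds} examples of each class for {folds}-fold CV"
            )
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        rows = []
        for cost in cost_grid:
            pipe = Pipeline(
                [("scale", StandardScaler()), ("svm", SVC(kernel="rbf", C=cost))]
            )
            acc = cross_val_score(pipe, self.X, self.y, cv=cv, scoring="accuracy")
            err = 1.0 - acc
            rows.append(
                {
                    "cost": cost,
                    "mean_error": float(err.mean()),
                    "se_error": float(err.std(ddof=1) / np.sqrt(folds)),
                }
            )
        cv_table = pd.DataFrame(rows)
        cost = one_se_cost(cv_table)

        pipe = Pipeline(
            [("scale", StandardScaler()), ("svm", SVC(kernel="rbf", C=cost))]
        )
        # Platt map fitted on out-of-fold decision values, not in-sample
        oof = cross_val_predict(
            pipe, self.X, self.y, cv=cv, method="decision_function"
        )
        platt = fit_platt(oof, self.y)
        pipe.fit(self.X, self.y)
        gamma = pipe.named_steps["svm"]._gamma
        return UsedToTreatResults(
            model=self,
            pipeline=pipe,
            platt=platt,
            cost=cost,
            gamma=float(gamma),
            cv_table=cv_table,
            seed=seed,
            folds=folds,
        )


@dataclass
class UsedToTreatResults:
    """A fitted, calibrated used-to-treat classifier."""

    model: UsedToTreatModel
    pipeline: Pipeline
    platt: LogisticRegression
    cost: float
    gamma: float
    cv_table: pd.DataFrame
    seed: int
    folds: int
    metadata: dict = field(default_factory=dict)

    # -- prediction --------------------------------------------------------
    def decision_values(self, features: pd.DataFrame) -> np.ndarray:
        X = _design_matrix(features, self.model.feature_names)
        return self.pipeline.decision_function(X)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """Calibrated probability of the used-to-treat relation."""
        f = self.decision_values(features)
        return self.platt.predict_proba(f.reshape(-1, 1))[:, 1]

    def predict(
        self, features: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
    ) -> pd.DataFrame:
        """Per-pair probability and flag at the probability threshold."""
        prob = self.predict_proba(features)
        out = features.loc[:, ["drug", "indication"]].copy()
        out["probability"] = prob
        out["flag"] = prob >= threshold
        return out

    # -- evaluation --------------------------------------------------------
    def evaluate(
        self,
        features: pd.DataFrame,
        labels: np.ndarray | pd.Series,
        threshold: float = DEFAULT_THRESHOLD,
    ) -> EvaluationReport:
        y = np.asarray(labels).astype(int)
        if len(y) == 0:
            raise ValueError("empty evaluation set")
        flag = self.predict_proba(features) >= threshold
        return EvaluationReport(
            tp=int(np.sum(flag & (y == 1))),
            fp=int(np.sum(flag & (y == 0))),
            tn=int(np.sum(~flag & (y == 0))),
            fn=int(np.sum(~flag & (y == 1))),
        )

    @property
    def platt_slope(self) -> float:
        return float(self.platt.coef_[0, 0])

    @property
    def platt_intercept(self) -> float:
        return float(self.platt.intercept_[0])

    def summary(self) -> str:
        lines = [
            "Used-to-treat classifier (RBF-SVM, Platt-calibrated)",
            "=" * 52,
            f"training examples:   {len(self.model.y)} "
            f"({int(self.model.y.sum())} positive)",
            f"features:            {len(self.model.feature_names)}",
            f"CV folds:            {self.folds}",
            f"selected cost (1-se): {self.cost:g}",
            f"kernel gamma:        {self.gamma:.6g}",
            f"Platt slope:         {self.platt_slope:.4f}",
            f"Platt intercept:     {self.platt_intercept:.4f}",
            "",
            "cross-validation error by cost:",
            self.cv_table.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "version": 1,
            "feature_names": self.model.feature_names,
            "pipeline": self.pipeline,
            "platt": self.platt,
            "cost": self.cost,
            "gamma": self.gamma,
            "cv_table": self.cv_table,
            "seed": self.seed,
            "folds": self.folds,
            "n_train": len(self.model.y),
        }
        with Path(path).open("wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "UsedToTreatResults":
        with Path(path).open("rb") as fh:
            payload = pickle.load(fh)
        stub = UsedToTreatModel.__new__(UsedToTreatModel)
        stub.feature_names = tuple(payload["feature_names"])
        stub.frame = pd.DataFrame()
        stub.X = np.empty((0, len(stub.feature_names)))
        stub.y = np.empty(payload["n_train"], dtype=int)
        return cls(
            model=stub,
            pipeline=payload["pipeline"],
            platt=payload["platt"],
            cost=payload["cost"],
            gamma=payload["gamma"],
            cv_table=payload["cv_table"],
            seed=payload["seed"],
            folds=payload["folds"],
        )


def ablate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    groups: tuple[tuple[str, tuple[str, ...]], ...] = ABLATION_ROWS,
    folds: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Train and evaluate one classifier per feature-group combination.

    ``train``/``test`` are labeled feature frames (as produced by
    featurize + gold standard join). Returns one metrics row per group
    combination, the analog of a feature-ablation table. The default
    threshold is 0.5: ablation compares raw discrimination, not the
    high-confidence flagging cut.
    """
    rows = []
    for name, members in groups:
        unknown = [m for m in members if m not in FEATURE_GROUPS]
        if unknown:
            raise ValueError(f"unknown feature group(s): {unknown}")
        cols: tuple[str, ...] = ()
        for m in members:
            cols += tuple(c for c in FEATURE_GROUPS[m] if c not in cols)
        res = UsedToTreatModel.from_dataframe(train, feature_names=cols).fit(
            folds=folds, seed=seed
        )
        labels = (test["label"] == "positive").astype(int).to_numpy()
        report = res.evaluate(test, labels, threshold=threshold)
        rows.append({"feature_set": name, **report.as_dict()})
    return pd.DataFrame(rows)
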