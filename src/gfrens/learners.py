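"""Member models and ensemble averaging for GFR estimation.

Three member kinds share one prediction interface:

* ``regression`` — the fixed piecewise power-law equation; needs no training.
* ``ann`` — a single-hidden-layer (8 logistic units) neural network fitted
  with scikit-learn on z-standardised covariates and target, early stopping
  on an internal 20% validation split.
* ``svm`` — epsilon-insensitive RBF support vector regression, with kernel
  width and regularisation chosen by seeded 5-fold cross-validated grid
  search.

Covariates are age (years), a male indicator, and ln(serum creatinine); the
training target is measured GFR.  After fitting, the learned parameters are
extracted into a plain JSON-serialisable state and all predictions are
computed by a numpy forward pass from that state, so a model reloaded from
its serialised form reproduces predictions bit-exactly.

The ensemble estimator is the element-wise arithmetic mean of its members'
prediction vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .equations import DomainError, estimate_gfr_frame

__all__ = [
    "FEATURE_COLUMNS",
    "TrainingError",
    "MemberModel",
    "EnsembleModel",
    "build_features",
    "train_member",
    "predict",
    "ensemble_predict",
    "average_predictions",
    "DEFAULT_ANN_CONFIG",
    "DEFAULT_SVM_CONFIG",
]

FEATURE_COLUMNS = ("age", "male", "log_scr")

#: eGFR floor (ml/min/1.73 m²) so downstream ratios stay defined.
PREDICTION_FLOOR = 1.0

DEFAULT_ANN_CONFIG: dict[str, Any] = {
    "hidden_units": 8,
    "max_iter": 4000,
    "validation_fraction": 0.2,
    "tol": 1e-6,
    "floor": PREDICTION_FLOOR,
}

DEFAULT_SVM_CONFIG: dict[str, Any] = {
    "C_grid": [1.0, 10.0, 100.0],
    "gamma_grid": [0.03, 0.1, 0.3, 1.0],
    "epsilon": 0.1,
    "cv_folds": 5,
    "floor": PREDICTION_FLOOR,
}

MIN_DEVELOPMENT_SIZE = 50


class TrainingError(RuntimeError):
    """A member model failed to train."""


def build_features(cohort: pd.DataFrame) -> pd.DataFrame:
    """Feature frame (age, male indicator, ln creatinine), one row per
    record, order preserved."""
    if len(cohort) == 0:
        return pd.DataFrame(columns=list(FEATURE_COLUMNS))
    scr = np.asarray(cohort["scr"], dtype=float)
    if np.any(scr <= 0) or np.any(~np.isfinite(scr)):
        raise DomainError("serum creatinine must be positive and finite")
    from .equations import _male_indicator

    return pd.DataFrame(
        {
            "age": np.asarray(cohort["age"], dtype=float),
            "male": _male_indicator(cohort["sex"]).astype(float),
            "log_scr": np.log(scr),
        },
        index=cohort.index,
    )


@dataclass
class MemberModel:
    """One member of the ensemble: its kind, hyperparameters, and (for
    trained kinds) a JSON-serialisable fitted state."""

    kind: str  # regression | ann | svm
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    training_seed: Optional[int] = None
    state: Optional[dict[str, Any]] = None

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        return predict(self, cohort)

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "kind": self.kind,
            "hyperparameters": self.hyperparameters,
            "training_seed": self.training_seed,
            "state": self.state,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "MemberModel":
        return cls(
            kind=d["kind"],
            hyperparameters=dict(d.get("hyperparameters") or {}),
            training_seed=d.get("training_seed"),
            state=d.get("state"),
        )

    @classmethod
    def from_json(cls, source: str) -> "MemberModel":
        import os

        if os.path.exists(source):
            with open(source) as fh:
                return cls.from_dict(json.load(fh))
        return cls.from_dict(json.loads(source))


@dataclass
class EnsembleModel:
    """Ordered collection of members combined by arithmetic averaging."""

    members: list[MemberModel]

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        return ensemble_predict(self, cohort)


def regression_member() -> MemberModel:
    """The fixed piecewise-equation member (no fitted state)."""
    return MemberModel(kind="regression")


def _standardise_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant column (e.g. single-sex cohort)
    return (X - mean) / sd, mean, sd


def train_member(
    kind: str,
    development: pd.DataFrame,
    config: Optional[Mapping[str, Any]] = None,
    seed: int = 0,
) -> MemberModel:
    """Fit an ``ann`` or ``svm`` member on a development cohort with measured
    GFR.  Identical inputs and seed give bit-reproducible predictions."""
    if kind not in ("ann", "svm"):
        raise ValueError(f"trainable kinds are 'ann' and 'svm', got {kind!r}")
    if "mgfr" not in development.columns or development["mgfr"].isna().any():
        raise ValueError("every development record needs a measured GFR")
    cfg = dict(DEFAULT_ANN_CONFIG if kind == "ann" else DEFAULT_SVM_CONFIG)
    if config:
        cfg.update(config)
    min_n = int(cfg.pop("min_development_size", MIN_DEVELOPMENT_SIZE))
    if len(development) < min_n:
        raise ValueError(
            f"development cohort has {len(development)} records; need >= {min_n}"
        )

    X_raw = build_features(development).to_numpy(dtype=float)
    y_raw = np.asarray(development["mgfr"], dtype=float)
    Xs, x_mean, x_sd = _standardise_columns(X_raw)
    y_mean, y_sd = y_raw.mean(), y_raw.std()
    y_sd = y_sd if y_sd > 0 else 1.0
    ys = (y_raw - y_mean) / y_sd

    if kind == "ann":
        state = _fit_ann(Xs, ys, cfg, seed)
    else:
        state = _fit_svm(Xs, ys, cfg, seed)
    state.update(
        {
            "x_mean": x_mean.tolist(),
            "x_sd": x_sd.tolist(),
            "y_mean": float(y_mean),
            "y_sd": float(y_sd),
        }
    )
    return MemberModel(kind=kind, hyperparameters=cfg, training_seed=seed, state=state)


def _fit_ann(Xs, ys, cfg, seed):
    net = MLPRegressor(
        hidden_layer_sizes=(int(cfg["hidden_units"]),),
        activation="logistic",
        solver="adam",
        early_stopping=True,
        validation_fraction=float(cfg["validation_fraction"]),
        max_iter=int(cfg["max_iter"]),
        tol=float(cfg["tol"]),
        random_state=int(seed) % (2**31),
    )
    try:
        net.fit(Xs, ys)
    except Exception as exc:  # pragma: no cover - sklearn internal failure
        raise TrainingError(f"ann member failed to train: {exc}") from exc
    return {
        "w1": net.coefs_[0].tolist(),
        "b1": net.intercepts_[0].tolist(),
        "w2": net.coefs_[1].tolist(),
        "b2": net.intercepts_[1].tolist(),
    }


def _fit_svm(Xs, ys, cfg, seed):
    folds = KFold(
        n_splits=int(cfg["cv_folds"]), shuffle=True, random_state=int(seed) % (2**31)
    )
    best = None
    for C in cfg["C_grid"]:
        for gamma in cfg["gamma_grid"]:
            mse = 0.0
            for train_idx, test_idx in folds.split(Xs):
                m = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=cfg["epsilon"])
                m.fit(Xs[train_idx], ys[train_idx])
                resid = m.predict(Xs[test_idx]) - ys[test_idx]
                mse += float(resid @ resid)
            if best is None or mse < best[0]:
                best = (mse, C, gamma)
    _, C, gamma = best
    m = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=cfg["epsilon"])
    try:
        m.fit(Xs, ys)
    except Exception as exc:  # pragma: no cover
        raise TrainingError(f"svm member failed to train: {exc}") from exc
    return {
        "support_vectors": m.support_vectors_.tolist(),
        "dual_coef": m.dual_coef_.ravel().tolist(),
        "intercept": float(m.intercept_[0]),
        "gamma": float(gamma),
        "C": float(C),
    }


def _forward(model: MemberModel, X_raw: np.ndarray) -> np.ndarray:
    s = model.state
    Xs = (X_raw - np.asarray(s["x_mean"])) / np.asarray(s["x_sd"])
    if model.kind == "ann":
        h = 1.0 / (1.0 + np.exp(-(Xs @ np.asarray(s["w1"]) + np.asarray(s["b1"]))))
        ys = h @ np.asarray(s["w2"]) + np.asarray(s["b2"])
        ys = ys.ravel()
    else:
        sv = np.asarray(s["support_vectors"])
        d2 = ((Xs[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        ys = np.exp(-s["gamma"] * d2) @ np.asarray(s["dual_coef"]) + s["intercept"]
    return ys * s["y_sd"] + s["y_mean"]


def predict(model: MemberModel, cohort: pd.DataFrame) -> np.ndarray:
    """eGFR vector (ml/min/1.73 m²) for a cohort, floored at the configured
    minimum so ratios against measured GFR stay defined."""
    if len(cohort) == 0:
        return np.empty(0, dtype=float)
    floor = float(model.hyperparameters.get("floor", PREDICTION_FLOOR))
    if model.kind == "regression":
        out = estimate_gfr_frame(cohort)
    elif model.kind in ("ann", "svm"):
        if model.state is None:
            raise RuntimeError(f"{model.kind} member is not fitted")
        out = _forward(model, build_features(cohort).to_numpy(dtype=float))
    else:
        raise ValueError(f"unknown member kind {model.kind!r}")
    return np.maximum(out, floor)


def average_predictions(predictions: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise arithmetic mean of aligned prediction vectors."""
    if len(predictions) == 0:
        raise RuntimeError("cannot average an empty collection of predictions")
    stack = np.vstack([np.asarray(p, dtype=float) for p in predictions])
    return stack.mean(axis=0)


def ensemble_predict(ensemble: EnsembleModel, cohort: pd.DataFrame) -> np.ndarray:
    """Arithmetic mean of the member predictions for each patient."""
    if not ensemble.members:
        raise RuntimeError("ensemble has no members")
    return average_predictions([predict(m, cohort) for m in ensemble.members])
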