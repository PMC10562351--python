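"""Classifier families, parsimonious L1 selection, cross-validation and
Platt calibration.

Four families mirror the study design: gradient boosting and random
forest come from established libraries; the unpenalized logistic
baseline comes from scikit-learn; the neural network shares its
architecture and training loop with the federated module so local and
federated models are directly comparable. The L1-penalized logistic path
(for parsimonious feature selection) and the Platt calibrator are
implemented against closed-form gradients in-repo.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import TrainingError
from .evaluation import EvalReport, auroc, evaluate
from .features import MeanImputer
from . import federated as fd

__all__ = [
    "ModelSpec", "MLPBinaryClassifier", "AKIClassifier", "train", "kfold_cv",
    "PlattCalibrator", "platt_fit", "platt_apply", "L1LogisticSelector",
    "lasso_select", "FAMILIES",
]

FAMILIES = ("gradient_boosting", "neural_network", "random_forest",
            "logistic_regression")

DEFAULT_HYPERPARAMETERS: Dict[str, Dict] = {
    "gradient_boosting": {"n_estimators": 300, "max_depth": 4,
                          "learning_rate": 0.1},
    "random_forest": {"n_estimators": 500},
    "logistic_regression": {},
    "neural_network": {"hidden": (64, 32), "epochs": 40, "batch_size": 32,
                       "learning_rate": 1e-2, "l2": 5e-3, "n_ensemble": 5},
}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: Dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    def resolved(self) -> Dict:
        hp = dict(DEFAULT_HYPERPARAMETERS[self.family])
        hp.update(self.hyperparameters)
        return hp


def _check_xy(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if not np.all(np.isfinite(X)):
        raise TrainingError("X must be imputed and finite before training")
    if len(np.unique(y)) < 2:
        raise TrainingError("y must contain both classes")
    return X, y


class MLPBinaryClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style front end over the shared numpy MLP.

    Standardizes features internally (means/SDs of the fit data) since the
    raw clinical scales span four orders of magnitude.
    """

    def __init__(self, hidden: Tuple[int, ...] = (64, 32), epochs: int = 30,
                 batch_size: int = 32, learning_rate: float = 1e-2,
                 l2: float = 1e-2, seed: int = 0, standardize: bool = True,
                 val_fraction: float = 0.2, n_ensemble: int = 1):
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.l2 = l2
        self.seed = seed
        self.standardize = standardize
        self.val_fraction = val_fraction
        self.n_ensemble = n_ensemble

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPBinaryClassifier":
        """Trains epoch by epoch, keeping the weights with the best AUROC on
        an internal stratified validation split (set val_fraction=0 for
        plain fixed-epoch training). With n_ensemble > 1, independently
        seeded networks are fitted and their probabilities averaged."""
        X, y = _check_xy(X, y)
        if self.n_ensemble > 1:
            member_seeds = np.random.SeedSequence(self.seed).generate_state(
                self.n_ensemble)
            self.members_ = [
                MLPBinaryClassifier(
                    hidden=self.hidden, epochs=self.epochs,
                    batch_size=self.batch_size,
                    learning_rate=self.learning_rate, l2=self.l2,
                    seed=int(s % 2 ** 31), standardize=self.standardize,
                    val_fraction=self.val_fraction, n_ensemble=1,
                ).fit(X, y) for s in member_seeds]
            self.classes_ = np.array([0, 1])
            return self
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_
        yf = y.astype(float)
        spec = fd.MLPSpec(n_inputs=X.shape[1], hidden=tuple(self.hidden))
        seeds = np.random.SeedSequence(self.seed).generate_state(3)
        w = fd.init_weights(spec, int(seeds[0] % 2 ** 31))
        train_seed = int(seeds[1] % 2 ** 31)
        if self.val_fraction > 0:
            idx_tr, idx_val = fd._stratified_split(
                yf, self.val_fraction, int(seeds[2] % 2 ** 31))
            state = None
            best_w, best_score = w, -np.inf
            for ep in range(self.epochs):
                w, state = fd.local_train(
                    w, Xs[idx_tr], yf[idx_tr], 1, self.batch_size,
                    self.learning_rate,
                    int(np.random.SeedSequence([train_seed, ep]
                                               ).generate_state(1)[0] % 2 ** 31),
                    state=state, l2=self.l2)
                from .evaluation import auroc as _auroc

                score = _auroc(fd.forward(w, Xs[idx_val]), yf[idx_val])
                if score > best_score:
                    best_score, best_w = score, [a.copy() for a in w]
            self.weights_ = best_w
            self.best_val_auroc_ = float(best_score)
        else:
            self.weights_, _ = fd.local_train(
                w, Xs, yf, self.epochs, self.batch_size,
                self.learning_rate, train_seed, l2=self.l2)
        self.spec_ = spec
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if getattr(self, "members_", None):
            return np.mean([m.decision_function(X) for m in self.members_],
                           axis=0)
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return fd.forward(self.weights_, Xs)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = self.decision_function(X)
        return np.column_stack([1 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)


def _build_estimator(spec: ModelSpec):
    hp = spec.resolved()
    if spec.family == "gradient_boosting":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=spec.seed, n_jobs=1,
                             eval_metric="logloss", tree_method="hist", **hp)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.family == "logistic_regression":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(C=np.inf, max_iter=2000, **hp))
    return MLPBinaryClassifier(seed=spec.seed, **hp)


class AKIClassifier(BaseEstimator, ClassifierMixin):
    """One trained model: imputer + family estimator + optional calibrator.

    The imputer is fitted inside ``fit`` on the training rows only, so
    cross-validation refits it per fold automatically.
    """

    def __init__(self, family: str = "gradient_boosting",
                 hyperparameters: Optional[Dict] = None, seed: int = 0,
                 binary_mask: Optional[np.ndarray] = None,
                 registry_hash: str = "", threshold: float = 0.5):
        self.family = family
        self.hyperparameters = hyperparameters
        self.seed = seed
        self.binary_mask = binary_mask
        self.registry_hash = registry_hash
        self.threshold = threshold

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AKIClassifier":
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise TrainingError("y must contain both classes")
        self.spec_ = ModelSpec(self.family, self.hyperparameters or {},
                               self.seed)
        self.imputer_ = MeanImputer(binary_mask=self.binary_mask).fit(X)
        Xi = self.imputer_.transform(X)
        self.estimator_ = _build_estimator(self.spec_).fit(Xi, y)
        self.calibrator_: Optional[PlattCalibrator] = None
        self.classes_ = np.array([0, 1])
        return self

    def raw_scores(self, X: np.ndarray) -> np.ndarray:
        return self.estimator_.predict_proba(self.imputer_.transform(X))[:, 1]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = self.raw_scores(X)
        if self.calibrator_ is not None:
            p = self.calibrator_.transform(p)
        return np.column_stack([1 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    def calibrate(self, scores: np.ndarray, labels: np.ndarray) -> "AKIClassifier":
        """Attach a Platt calibrator fitted on held-out scores."""
        self.calibrator_ = PlattCalibrator().fit(scores, labels)
        return self


def train(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
          binary_mask: Optional[np.ndarray] = None,
          registry_hash: str = "") -> AKIClassifier:
    """Fit one family on an (imputable) feature matrix."""
    return AKIClassifier(
        family=spec.family, hyperparameters=spec.hyperparameters,
        seed=spec.seed, binary_mask=binary_mask,
        registry_hash=registry_hash).fit(X, y)


def kfold_cv(spec: ModelSpec, X: np.ndarray, y: np.ndarray, k: int = 5,
             seed: int = 0, binary_mask: Optional[np.ndarray] = None,
             threshold: float = 0.5
             ) -> Tuple[List[EvalReport], np.ndarray]:
    """Stratified k-fold cross-validation with per-fold imputer refitting.

    Returns per-fold EvalReports and the out-of-fold score vector (used to
    fit the Platt calibrator without training-set leakage).
    """
    y = np.asarray(y).astype(int)
    if k > y.size:
        raise ValueError("k may not exceed the number of samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(y.size, np.nan)
    reports = []
    for tr, te in skf.split(np.zeros_like(y), y):
        model = AKIClassifier(spec.family, spec.hyperparameters, spec.seed,
                              binary_mask=binary_mask).fit(X[tr], y[tr])
        scores = model.raw_scores(X[te])
        oof[te] = scores
        reports.append(evaluate(scores, y[te], threshold=threshold))
    return reports, oof


# ---------------------------------------------------------------------------
# Platt scaling (own Newton fit, smoothed targets)


@dataclass
class PlattCalibrator(BaseEstimator):
    """Sigmoid map p = 1 / (1 + exp(a*s + b)) fitted by maximum likelihood
    with the standard (N+1)/(N+2)-style target smoothing. Strict
    monotonicity (a < 0) is asserted after fitting, so calibrated and raw
    scores rank identically."""

    a_: float = field(default=np.nan, init=False)
    b_: float = field(default=np.nan, init=False)

    def fit(self, scores: Sequence[float], labels: Sequence[int]
            ) -> "PlattCalibrator":
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels).astype(int)
        if len(np.unique(y)) < 2:
            raise TrainingError("calibration needs both classes")
        if np.all(s == s[0]):
            raise TrainingError("degenerate scores: all equal")
        n_pos = int(y.sum())
        n_neg = y.size - n_pos
        t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0),
                     1.0 / (n_neg + 2.0))
        a, b = -1.0, 0.0
        for _ in range(100):
            z = a * s + b
            p = 1.0 / (1.0 + np.exp(z))
            d = p - t  # dNLL/dz is (t - p) * (-1) ... chain below
            # NLL = -sum t*log p + (1-t)*log(1-p); dp/dz = -p(1-p)
            g_z = (p - t) * -1.0  # dNLL/dz
            grad = np.array([np.sum(g_z * s), np.sum(g_z)])
            w = p * (1 - p)
            h11 = np.sum(w * s * s)
            h12 = np.sum(w * s)
            h22 = np.sum(w)
            H = np.array([[h11, h12], [h12, h22]]) + 1e-12 * np.eye(2)
            step = np.linalg.solve(H, grad)
            a, b = a - step[0], b - step[1]
            if np.abs(step).max() < 1e-10:
                break
        if a >= 0:
            raise TrainingError("Platt fit produced a non-monotone map")
        self.a_, self.b_ = float(a), float(b)
        return self

    def transform(self, scores: Sequence[float]) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return 1.0 / (1.0 + np.exp(self.a_ * s + self.b_))


def platt_fit(scores, labels) -> PlattCalibrator:
    return PlattCalibrator().fit(scores, labels)


def platt_apply(calibrator: PlattCalibrator, scores) -> np.ndarray:
    return calibrator.transform(scores)


# ---------------------------------------------------------------------------
# L1-penalized logistic path (FISTA with closed-form gradients)


def _logistic_grad(w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray
                   ) -> Tuple[np.ndarray, float]:
    p = 1.0 / (1.0 + np.exp(-(X @ w + b)))
    r = (p - y) / y.size
    return X.T @ r, float(r.sum())


def _fista_l1_logistic(X: np.ndarray, y: np.ndarray, lam: float,
                       w0: Optional[np.ndarray] = None, b0: float = 0.0,
                       max_iter: int = 400, tol: float = 1e-7
                       ) -> Tuple[np.ndarray, float]:
    """Minimize mean logistic NLL + lam * ||w||_1 (intercept unpenalized)."""
    n, d = X.shape
    L = (np.linalg.norm(X, 2) ** 2) / (4.0 * n) + 1e-12
    step = 1.0 / L
    w = np.zeros(d) if w0 is None else w0.copy()
    b = b0
    zw, zb, t = w.copy(), b, 1.0
    for _ in range(max_iter):
        gw, gb = _logistic_grad(zw, zb, X, y)
        w_new = zw - step * gw
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * lam, 0.0)
        b_new = zb - step * gb
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        zw = w_new + ((t - 1) / t_new) * (w_new - w)
        zb = b_new + ((t - 1) / t_new) * (b_new - b)
        delta = max(np.abs(w_new - w).max(initial=0.0), abs(b_new - b))
        w, b, t = w_new, b_new, t_new
        if delta < tol:
            break
    return w, b


class L1LogisticSelector(BaseEstimator):
    """Parsimonious feature selection by the L1-logistic path.

    Standardizes internally, runs a logarithmic penalty grid from the
    smallest lambda that zeroes every coefficient, scores each penalty by
    stratified cross-validated AUROC, and picks the largest penalty within
    one standard error of the best (the 1-SE rule). Features with nonzero
    refit coefficients are selected, in input order.
    """

    def __init__(self, n_lambdas: int = 30, lambda_min_ratio: float = 1e-3,
                 cv: int = 5, seed: int = 0, one_se: bool = True):
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.seed = seed
        self.one_se = one_se

    def fit(self, X: np.ndarray, y: np.ndarray) -> "L1LogisticSelector":
        X, y = _check_xy(X, y)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - mu) / sd
        yf = y.astype(float)
        lam_max = np.abs(Xs.T @ (yf - yf.mean())).max() / y.size
        lams = np.geomspace(lam_max, lam_max * self.lambda_min_ratio,
                            self.n_lambdas)
        skf = StratifiedKFold(n_splits=self.cv, shuffle=True,
                              random_state=self.seed)
        scores = np.zeros((self.n_lambdas, self.cv))
        for f, (tr, te) in enumerate(skf.split(Xs, y)):
            w, b = None, 0.0
            for i, lam in enumerate(lams):  # warm starts down the path
                w, b = _fista_l1_logistic(Xs[tr], yf[tr], lam, w, b)
                scores[i, f] = auroc(Xs[te] @ w + b, y[te]) if np.any(w) else 0.5
        mean = scores.mean(axis=1)
        se = scores.std(axis=1, ddof=1) / np.sqrt(self.cv)
        best = int(np.argmax(mean))
        if self.one_se:
            ok = np.flatnonzero(mean >= mean[best] - se[best])
            chosen = int(ok[0])  # largest penalty within 1 SE
        else:
            chosen = best
        w, b = None, 0.0
        for lam in lams[:chosen + 1]:
            w, b = _fista_l1_logistic(Xs, yf, lam, w, b)
        self.lambda_path_ = lams
        self.cv_mean_ = mean
        self.cv_se_ = se
        self.lambda_ = float(lams[chosen])
        self.coef_ = w / sd  # back on the raw scale
        self.intercept_ = float(b - (mu / sd) @ w)
        self.support_ = w != 0
        return self

    def get_support(self) -> np.ndarray:
        return self.support_


def lasso_select(X: np.ndarray, y: np.ndarray,
                 feature_names: Sequence[str], k: int = 5,
                 seed: int = 0) -> List[str]:
    """Names of the features the 1-SE L1-logistic path retains."""
    sel = L1LogisticSelector(cv=k, seed=seed).fit(X, y)
    if not sel.support_.any():
        raise TrainingError("L1 path selected no features at the 1-SE penalty")
    return [n for n, s in zip(feature_names, sel.support_) if s]


# ---------------------------------------------------------------------------
# artifact serialization (JSON; neural-network weights as nested lists)


def save_artifact(model: AKIClassifier, out_dir: str,
                  registry_json: Optional[Dict] = None) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "spec.json"), "w") as fh:
        json.dump({"family": model.family,
                   "hyperparameters": model.spec_.resolved(),
                   "seed": model.seed,
                   "registry_hash": model.registry_hash,
                   "threshold": model.threshold}, fh, indent=1, default=str)
    with open(os.path.join(out_dir, "imputer.json"), "w") as fh:
        json.dump({"means": model.imputer_.means_.tolist()}, fh)
    if model.calibrator_ is not None:
        with open(os.path.join(out_dir, "calibrator.json"), "w") as fh:
            json.dump({"a": model.calibrator_.a_, "b": model.calibrator_.b_}, fh)
    if model.family == "neural_network":
        est = model.estimator_
        members = getattr(est, "members_", None) or [est]
        with open(os.path.join(out_dir, "weights.json"), "w") as fh:
            json.dump({"members": [
                {"weights": [w.tolist() for w in m.weights_],
                 "mean": m.mean_.tolist(), "scale": m.scale_.tolist()}
                for m in members],
                "params": est.get_params()}, fh)
    if registry_json is not None:
        with open(os.path.join(out_dir, "registry.json"), "w") as fh:
            json.dump(registry_json, fh, indent=1)


def load_artifact(in_dir: str) -> AKIClassifier:
    """Reload a saved neural-network artifact (other families retrain from
    their recorded spec instead of deserializing)."""
    with open(os.path.join(in_dir, "spec.json")) as fh:
        spec = json.load(fh)
    if spec["family"] != "neural_network":
        raise ValueError("only neural-network artifacts are deserializable")
    model = AKIClassifier(family="neural_network", seed=spec["seed"],
                          registry_hash=spec.get("registry_hash", ""),
                          threshold=spec.get("threshold", 0.5))
    model.spec_ = ModelSpec("neural_network", {}, spec["seed"])
    with open(os.path.join(in_dir, "imputer.json")) as fh:
        means = np.asarray(json.load(fh)["means"])
    imp = MeanImputer()
    imp.means_ = means
    imp.n_features_in_ = means.size
    model.imputer_ = imp
    with open(os.path.join(in_dir, "weights.json")) as fh:
        blob = json.load(fh)
    params = {k: v for k, v in blob.get("params", {}).items()
              if k in MLPBinaryClassifier().get_params()}
    if isinstance(params.get("hidden"), list):
        params["hidden"] = tuple(params["hidden"])
    members = []
    for m in blob["members"]:
        est = MLPBinaryClassifier(**{**params, "n_ensemble": 1})
        est.weights_ = [np.asarray(w) for w in m["weights"]]
        est.mean_ = np.asarray(m["mean"])
        est.scale_ = np.asarray(m["scale"])
        est.classes_ = np.array([0, 1])
        members.append(est)
    if len(members) == 1:
        model.estimator_ = members[0]
    else:
        ens = MLPBinaryClassifier(**params)
        ens.members_ = members
        ens.classes_ = np.array([0, 1])
        model.estimator_ = ens
    model.calibrator_ = None
    cal_path = os.path.join(in_dir, "calibrator.json")
    if os.path.exists(cal_path):
        with open(cal_path) as fh:
            cal = json.load(fh)
        c = PlattCalibrator()
        c.a_, c.b_ = cal["a"], cal["b"]
        model.calibrator_ = c
    model.classes_ = np.array([0, 1])
    return model
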