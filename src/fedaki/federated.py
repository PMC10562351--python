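"""Neural classifier and the federated-averaging protocol.

The MLP (input -> 64 -> 32 -> 1, rectifier hidden units, sigmoid output,
binary cross-entropy loss) is implemented with closed-form gradients and
an Adam optimizer so federated runs are bit-reproducible and the
averaging equivalences can be tested exactly.

Protocol: K sites each split their derivation-era data 80/20 (stratified)
for local training and internal validation. Each round the server
broadcasts the global weights, every site trains E local epochs in
mini-batches of B, the server takes the sample-size-weighted element-wise
mean of the returned weights (FedAvg), and every site scores the new
aggregate on its own validation split. The best aggregate is the round
with the highest mean validation AUROC; each site also tracks its best
local model by its own validation score. Only weight arrays and scalar
scores ever cross the site boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import TrainingError
from .evaluation import EvalReport, auroc, evaluate

__all__ = [
    "MLPSpec", "FLConfig", "FLResult", "init_weights", "forward", "bce_loss",
    "bce_gradients", "AdamState", "local_train", "fedavg", "FLSite", "run_fl",
    "derive_round_seed",
]

WeightSet = List[np.ndarray]


@dataclass(frozen=True)
class MLPSpec:
    n_inputs: int
    hidden: Tuple[int, ...] = (64, 32)

    @property
    def layer_dims(self) -> List[Tuple[int, int]]:
        dims = [self.n_inputs, *self.hidden, 1]
        return list(zip(dims[:-1], dims[1:]))


@dataclass(frozen=True)
class FLConfig:
    """Protocol constants; defaults K=5 sites, 30 rounds, 2 local epochs,
    batch 32, Adam at learning rate 1e-2."""

    rounds: int = 30
    local_epochs: int = 2
    batch_size: int = 32
    learning_rate: float = 1e-2
    l2: float = 1e-2  # weight decay on weight matrices (biases free)
    val_fraction: float = 0.2
    sample_weighted: bool = True
    persist_optimizer: bool = False
    seed: int = 0


def init_weights(spec: MLPSpec, seed: int) -> WeightSet:
    """He-scaled random initialization, deterministic under seed."""
    rng = np.random.default_rng(seed)
    w: WeightSet = []
    for fan_in, fan_out in spec.layer_dims:
        w.append(rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
        w.append(np.zeros(fan_out))
    return w


def forward(w: WeightSet, X: np.ndarray,
            keep: bool = False):
    """Predicted probabilities; with keep=True also the layer activations."""
    acts = [X]
    a = X
    n_layers = len(w) // 2
    for i in range(n_layers):
        z = a @ w[2 * i] + w[2 * i + 1]
        a = np.maximum(z, 0.0) if i < n_layers - 1 else 1.0 / (1.0 + np.exp(-z))
        if keep:
            acts.append(a)
    p = a[:, 0]
    return (p, acts) if keep else p


def bce_loss(w: WeightSet, X: np.ndarray, y: np.ndarray,
             l2: float = 0.0, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy plus (l2/2) * sum of squared weight-matrix
    entries (biases unpenalized)."""
    p = np.clip(forward(w, X), eps, 1 - eps)
    loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    if l2:
        loss += 0.5 * l2 * sum(float((a * a).sum()) for a in w[0::2])
    return loss


def bce_gradients(w: WeightSet, X: np.ndarray, y: np.ndarray,
                  l2: float = 0.0) -> WeightSet:
    """Analytic gradients of mean binary cross-entropy wrt every array."""
    p, acts = forward(w, X, keep=True)
    n = X.shape[0]
    n_layers = len(w) // 2
    grads: WeightSet = [np.empty(0)] * len(w)
    # sigmoid + BCE: dL/dz_out = (p - y) / n
    delta = ((p - y) / n)[:, None]
    for i in range(n_layers - 1, -1, -1):
        a_prev = acts[i]
        grads[2 * i] = a_prev.T @ delta
        grads[2 * i + 1] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ w[2 * i].T) * (acts[i] > 0)
    if l2:
        for i in range(0, len(w), 2):
            grads[i] = grads[i] + l2 * w[i]
    return grads


@dataclass
class AdamState:
    m: WeightSet
    v: WeightSet
    t: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    @classmethod
    def zeros_like(cls, w: WeightSet) -> "AdamState":
        return cls(m=[np.zeros_like(a) for a in w],
                   v=[np.zeros_like(a) for a in w])

    def step(self, w: WeightSet, grads: WeightSet, lr: float) -> WeightSet:
        self.t += 1
        out: WeightSet = []
        for i, (a, g) in enumerate(zip(w, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1 ** self.t)
            vhat = self.v[i] / (1 - self.beta2 ** self.t)
            out.append(a - lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def local_train(w: WeightSet, X: np.ndarray, y: np.ndarray, epochs: int,
                batch_size: int, lr: float, seed: int,
                state: Optional[AdamState] = None, l2: float = 0.0
                ) -> Tuple[WeightSet, AdamState]:
    """E full passes in seeded shuffled mini-batches (last batch smaller),
    Adam updates at rate lr. epochs=0 returns the weights unchanged."""
    if X.shape[0] == 0:
        raise TrainingError("empty training data")
    rng = np.random.default_rng(seed)
    w = [a.copy() for a in w]
    if state is None:
        state = AdamState.zeros_like(w)
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            grads = bce_gradients(w, X[idx], y[idx], l2=l2)
            w = state.step(w, grads, lr)
    return w, state


def fedavg(weight_sets: Sequence[WeightSet],
           n_k: Sequence[int]) -> WeightSet:
    """Element-wise weighted mean with weights n_k / sum(n_k)."""
    if not weight_sets:
        raise ValueError("no weight sets to aggregate")
    shapes = [tuple(a.shape for a in ws) for ws in weight_sets]
    if len(set(shapes)) != 1:
        raise ValueError("weight sets have mismatched shapes")
    n_k = np.asarray(n_k, dtype=float)
    if np.any(n_k <= 0) or len(n_k) != len(weight_sets):
        raise ValueError("n_k must be positive and align with weight sets")
    lam = n_k / n_k.sum()
    return [sum(lam[k] * ws[i] for k, ws in enumerate(weight_sets))
            for i in range(len(weight_sets[0]))]


def derive_round_seed(seed: int, round_idx: int, site_idx: int) -> int:
    """Per-(round, site) seed for local mini-batch shuffling."""
    return int(np.random.SeedSequence(
        [int(seed), int(round_idx), int(site_idx)]).generate_state(1)[0]
        % (2 ** 31))


class FLSite:
    """One participating hospital: holds its data privately, exposes only
    weight sets and scalar scores.

    X/y are the site's derivation-era feature matrix (already imputed and
    standardized with site-local statistics fitted on the training split);
    temporal data are kept for final evaluation only.
    """

    def __init__(self, site_id: str, X: np.ndarray, y: np.ndarray,
                 X_temporal: Optional[np.ndarray] = None,
                 y_temporal: Optional[np.ndarray] = None,
                 val_fraction: float = 0.2, seed: int = 0):
        y = np.asarray(y, dtype=float)
        idx_tr, idx_val = _stratified_split(y, val_fraction, seed)
        if len(set(y[idx_tr])) < 2:
            raise TrainingError(
                f"site {site_id}: single-class training split")
        self.site_id = site_id
        self._X_train, self._y_train = X[idx_tr], y[idx_tr]
        self._X_val, self._y_val = X[idx_val], y[idx_val]
        self._X_temporal, self._y_temporal = X_temporal, y_temporal
        self._adam: Optional[AdamState] = None
        self.best_local_score_ = -np.inf
        self.best_local_weights_: Optional[WeightSet] = None
        self.best_local_round_ = -1

    @property
    def n_train(self) -> int:
        return self._X_train.shape[0]

    @property
    def has_temporal(self) -> bool:
        return self._X_temporal is not None and len(self._X_temporal) > 0

    def temporal_scores(self, weights: WeightSet) -> np.ndarray:
        """Scalar model scores on the site's temporal cohort (scores may
        leave the site; raw feature vectors never do)."""
        if not self.has_temporal:
            raise TrainingError(f"site {self.site_id}: no temporal data")
        return forward(weights, self._X_temporal)

    @property
    def temporal_labels(self) -> np.ndarray:
        if not self.has_temporal:
            raise TrainingError(f"site {self.site_id}: no temporal data")
        return np.asarray(self._y_temporal)

    def local_update(self, weights: WeightSet, config: FLConfig,
                     round_idx: int, site_idx: int) -> Tuple[WeightSet, int]:
        seed = derive_round_seed(config.seed, round_idx, site_idx)
        state = self._adam if config.persist_optimizer else None
        new_w, state = local_train(weights, self._X_train, self._y_train,
                                   config.local_epochs, config.batch_size,
                                   config.learning_rate, seed, state,
                                   l2=config.l2)
        if config.persist_optimizer:
            self._adam = state
        score = self.validate(new_w)
        if score > self.best_local_score_:
            self.best_local_score_ = score
            self.best_local_weights_ = [a.copy() for a in new_w]
            self.best_local_round_ = round_idx
        return new_w, self.n_train

    def validate(self, weights: WeightSet) -> float:
        return auroc(forward(weights, self._X_val), self._y_val)

    def evaluate_temporal(self, weights: WeightSet,
                          threshold: float = 0.5) -> EvalReport:
        return evaluate(self.temporal_scores(weights), self.temporal_labels,
                        threshold=threshold)


def _stratified_split(y: np.ndarray, val_fraction: float,
                      seed: int) -> Tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    val_idx: List[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        k = int(round(val_fraction * idx.size))
        val_idx.extend(idx[:k])
    val = np.zeros(y.size, dtype=bool)
    val[val_idx] = True
    return np.flatnonzero(~val), np.flatnonzero(val)


@dataclass
class FLResult:
    best_weights: WeightSet
    best_round: int
    round_mean_val: List[float]  # mean validation AUROC per round
    round_site_val: List[List[float]]
    best_local: Dict[str, Tuple[WeightSet, int]] = field(default_factory=dict)
    temporal_reports: Dict[str, EvalReport] = field(default_factory=dict)


def run_fl(sites: Sequence[FLSite], spec: MLPSpec,
           config: FLConfig = FLConfig()) -> FLResult:
    """Run the full federated-averaging study over the given sites."""
    global_w = init_weights(spec, config.seed)
    best_mean, best_round, best_w = -np.inf, -1, global_w
    round_mean_val: List[float] = []
    round_site_val: List[List[float]] = []
    for r in range(config.rounds):
        updates = [site.local_update(global_w, config, r, k)
                   for k, site in enumerate(sites)]
        global_w = fedavg([u[0] for u in updates], [u[1] for u in updates])
        scores = [site.validate(global_w) for site in sites]
        mean_score = float(np.mean(scores))
        round_mean_val.append(mean_score)
        round_site_val.append(scores)
        if mean_score > best_mean:
            best_mean, best_round = mean_score, r
            best_w = [a.copy() for a in global_w]
    result = FLResult(best_weights=best_w, best_round=best_round,
                      round_mean_val=round_mean_val,
                      round_site_val=round_site_val)
    for site in sites:
        result.best_local[site.site_id] = (site.best_local_weights_,
                                           site.best_local_round_)
        if site.has_temporal:
            result.temporal_reports[site.site_id] = \
                site.evaluate_temporal(best_w)
    return result
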