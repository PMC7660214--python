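"""Softmax-gated multi-graph ensemble.

Stage one trains one learning block per selected low-frequency population
graph.  Stage two fuses the blocks' 64-dimensional hidden representations
p_i with learnable importance weights alpha = softmax(w):

    H = sum_i alpha_i p_i          (weighted_sum mode, width 64)
    y_hat = sigmoid(H W + b)

trained with cross-entropy over labelled subjects.  A weighted_concat mode
instead concatenates the alpha-scaled blocks (width 64 m) before the
affine head.  Default training is end-to-end: block trunks, the scoring
vector w and the head are optimized jointly per fold; a two-stage mode
(pretrain blocks with their own softmax heads, then train gate + head on
frozen representations) is available for comparison.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _nn
from .spectral import categorize_frequency_regime, LOW_FREQUENCY

__all__ = [
    "softmax_gate",
    "ensemble_forward",
    "ensemble_loss",
    "GraphEnsembleClassifier",
    "GraphSelection",
    "EmptySelectionError",
    "select_low_frequency_graphs",
    "train_ensemble",
    "EnsembleResult",
    "average_probability_ensemble",
    "majority_vote_ensemble",
]

_EPS = 1e-12


def softmax_gate(w: np.ndarray) -> np.ndarray:
    """Normalized importance weights alpha_i = exp(w_i) / sum_j exp(w_j).

    Computed with max subtraction, so it is shift-invariant and stable for
    scores up to ~1e3 in magnitude.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size < 1:
        raise ValueError("scoring vector must be a non-empty 1-d array")
    return _nn.stable_softmax(w)


def ensemble_forward(
    block_reps: list[np.ndarray],
    w: np.ndarray,
    V: np.ndarray,
    b: float,
    mode: str = "weighted_sum",
) -> np.ndarray:
    """Fused per-subject probabilities from block representations."""
    if len(block_reps) != len(w):
        raise ValueError("one gate score per block representation required")
    reps = [np.asarray(r, dtype=float) for r in block_reps]
    n = reps[0].shape[0]
    if any(r.shape[0] != n for r in reps):
        raise ValueError("all block representations must share the subject count")
    alpha = softmax_gate(w)
    if mode == "weighted_sum":
        if any(r.shape[1] != reps[0].shape[1] for r in reps):
            raise ValueError("weighted_sum requires equal representation widths")
        H = sum(a * r for a, r in zip(alpha, reps))
    elif mode == "weighted_concat":
        H = np.hstack([a * r for a, r in zip(alpha, reps)])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _nn.sigmoid(H @ np.asarray(V, dtype=float) + b)


def ensemble_loss(y_hat: np.ndarray, y: np.ndarray, eps: float = _EPS) -> float:
    """Two-class cross-entropy summed over labelled subjects.

    Probabilities are clipped to [eps, 1 - eps] so exactly confident wrong
    predictions stay finite.
    """
    p = np.clip(np.asarray(y_hat, dtype=float), eps, 1.0 - eps)
    y = np.asarray(y, dtype=float)
    return float(-np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class GraphEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Softmax-gated ensemble over per-graph learning blocks.

    ``fit`` takes a list of m feature matrices (one per selected graph,
    each already low-pass filtered in its own graph's basis, rows aligned
    across matrices) and binary labels.  Fitted attributes include the
    scoring vector ``gate_scores_`` and the normalized gate ``alpha_``.

    Parameters mirror :class:`~popgse.blocks.BlockClassifier`; the scoring
    vector is initialized from a seeded normal at scale ``gate_init_scale``.
    """

    def __init__(
        self,
        mode: str = "weighted_sum",
        training: str = "end_to_end",
        hidden_sizes: tuple[int, int] = (512, 64),
        dropout: float = 0.3,
        learning_rate: float = 0.01,
        epochs: int = 200,
        gate_init_scale: float = 0.01,
        random_state: int = 0,
    ):
        self.mode = mode
        self.training = training
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.gate_init_scale = gate_init_scale
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _validate_inputs(self, Xs, y=None):
        if isinstance(Xs, np.ndarray) and Xs.ndim == 3:
            Xs = [Xs[i] for i in range(Xs.shape[0])]
        Xs = [np.asarray(X, dtype=float) for X in Xs]
        if len(Xs) < 1:
            raise ValueError("at least one block input is required")
        n = Xs[0].shape[0]
        if any(X.ndim != 2 or X.shape[0] != n for X in Xs):
            raise ValueError("all block inputs must be 2-d with equal row counts")
        if y is not None:
            y = np.asarray(y)
            if y.shape[0] != n:
                raise ValueError("labels must align with block input rows")
        return Xs, y

    def _head_width(self, m: int) -> int:
        return self.hidden_sizes[1] * (m if self.mode == "weighted_concat" else 1)

    def fit(self, Xs, y) -> "GraphEnsembleClassifier":
        if self.mode not in ("weighted_sum", "weighted_concat"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.training not in ("end_to_end", "two_stage"):
            raise ValueError(f"unknown training {self.training!r}")
        Xs, y = self._validate_inputs(Xs, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("training data must contain exactly two classes")
        if self.training == "end_to_end":
            self._fit_end_to_end(Xs, y_idx.astype(float))
        else:
            self._fit_two_stage(Xs, y_idx.astype(float))
        self.alpha_ = softmax_gate(self.gate_scores_)
        self.n_blocks_ = len(Xs)
        return self

    def _init_gate_head(self, rng, m):
        width = self._head_width(m)
        return (
            rng.normal(0.0, self.gate_init_scale, size=m),
            rng.normal(0.0, np.sqrt(1.0 / width), size=width),
            0.0,
        )

    def _fit_end_to_end(self, Xs, y):
        rng = np.random.default_rng(self.random_state)
        m, n = len(Xs), Xs[0].shape[0]
        blocks = [_nn.init_block(rng, X.shape[1], tuple(self.hidden_sizes)) for X in Xs]
        w, V, c = self._init_gate_head(rng, m)
        params: dict[str, np.ndarray] = {"w": w, "V": V, "c": np.array([c])}
        for i, bp in enumerate(blocks):
            for key, val in bp.items():
                params[f"blk{i}_{key}"] = val
        optimizer = _nn.Adam(params, lr=self.learning_rate)
        losses = np.empty(self.epochs)
        h2 = self.hidden_sizes[1]
        for epoch in range(self.epochs):
            reps, caches = [], []
            for i in range(m):
                bp = {k: params[f"blk{i}_{k}"] for k in ("W1", "b1", "W2", "b2")}
                rep, cache = _nn.block_forward(bp, Xs[i], self.dropout, rng, train=True)
                reps.append(rep)
                caches.append(cache)
            alpha = _nn.stable_softmax(params["w"])
            if self.mode == "weighted_sum":
                H = sum(a * r for a, r in zip(alpha, reps))
            else:
                H = np.hstack([a * r for a, r in zip(alpha, reps)])
            p = _nn.sigmoid(H @ params["V"] + params["c"][0])
            pc = np.clip(p, _EPS, 1.0 - _EPS)
            losses[epoch] = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
            # backward
            ds = (p - y) / n
            grads = {"V": H.T @ ds, "c": np.array([ds.sum()])}
            dH = np.outer(ds, params["V"])
            dalpha = np.empty(m)
            for i in range(m):
                dHi = dH if self.mode == "weighted_sum" else dH[:, i * h2 : (i + 1) * h2]
                dalpha[i] = float(np.sum(dHi * reps[i]))
                drep = alpha[i] * dHi
                bp = {k: params[f"blk{i}_{k}"] for k in ("W1", "b1", "W2", "b2")}
                bgrads = _nn.block_backward(bp, caches[i], drep)
                for key, val in bgrads.items():
                    grads[f"blk{i}_{key}"] = val
            grads["w"] = alpha * (dalpha - float(alpha @ dalpha))
            optimizer.step(grads)
        self.block_params_ = [
            {k: params[f"blk{i}_{k}"] for k in ("W1", "b1", "W2", "b2")} for i in range(m)
        ]
        self.gate_scores_ = params["w"]
        self.head_weights_ = params["V"]
        self.head_bias_ = float(params["c"][0])
        self.loss_curve_ = losses

    def _fit_two_stage(self, Xs, y):
        from .blocks import BlockClassifier

        rng = np.random.default_rng(self.random_state)
        m = len(Xs)
        self.stage1_blocks_ = []
        reps = []
        for i, X in enumerate(Xs):
            clf = BlockClassifier(
                hidden_sizes=self.hidden_sizes,
                dropout=self.dropout,
                learning_rate=self.learning_rate,
                epochs=self.epochs,
                random_state=self.random_state + i + 1,
            )
            clf.fit(X, y.astype(int))
            self.stage1_blocks_.append(clf)
            reps.append(clf.transform(X))
        self.block_params_ = [clf.params_ for clf in self.stage1_blocks_]
        w, V, c = self._init_gate_head(rng, m)
        params = {"w": w, "V": V, "c": np.array([c])}
        optimizer = _nn.Adam(params, lr=self.learning_rate)
        n = reps[0].shape[0]
        h2 = self.hidden_sizes[1]
        losses = np.empty(self.epochs)
        for epoch in range(self.epochs):
            alpha = _nn.stable_softmax(params["w"])
            if self.mode == "weighted_sum":
                H = sum(a * r for a, r in zip(alpha, reps))
            else:
                H = np.hstack([a * r for a, r in zip(alpha, reps)])
            p = _nn.sigmoid(H @ params["V"] + params["c"][0])
            pc = np.clip(p, _EPS, 1.0 - _EPS)
            losses[epoch] = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
            ds = (p - y) / n
            grads = {"V": H.T @ ds, "c": np.array([ds.sum()])}
            dH = np.outer(ds, params["V"])
            dalpha = np.empty(m)
            for i in range(m):
                dHi = dH if self.mode == "weighted_sum" else dH[:, i * h2 : (i + 1) * h2]
                dalpha[i] = float(np.sum(dHi * reps[i]))
            grads["w"] = alpha * (dalpha - float(alpha @ dalpha))
            optimizer.step(grads)
        self.gate_scores_ = params["w"]
        self.head_weights_ = params["V"]
        self.head_bias_ = float(params["c"][0])
        self.loss_curve_ = losses

    # -- inference ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "gate_scores_"):
            raise AttributeError("GraphEnsembleClassifier is not fitted")

    def block_representations(self, Xs) -> list[np.ndarray]:
        """Per-block 64-dim hidden representations, dropout disabled."""
        self._check_fitted()
        Xs, _ = self._validate_inputs(Xs)
        if len(Xs) != self.n_blocks_:
            raise ValueError(f"expected {self.n_blocks_} block inputs, got {len(Xs)}")
        reps = []
        for bp, X in zip(self.block_params_, Xs):
            rep, _ = _nn.block_forward(bp, X, 0.0, None, train=False)
            reps.append(rep)
        return reps

    def decision_probabilities(self, Xs) -> np.ndarray:
        """Fused probability of the positive class per subject."""
        reps = self.block_representations(Xs)
        return ensemble_forward(
            reps, self.gate_scores_, self.head_weights_, self.head_bias_, mode=self.mode
        )

    def predict_proba(self, Xs) -> np.ndarray:
        p = self.decision_probabilities(Xs)
        return np.column_stack([1.0 - p, p])

    def predict(self, Xs) -> np.ndarray:
        p = self.decision_probabilities(Xs)
        return self.classes_[(p >= 0.5).astype(int)]


# -- graph selection --------------------------------------------------------


class EmptySelectionError(RuntimeError):
    """No graph qualified as low-frequency; carries per-graph diagnostics."""

    def __init__(self, diagnostics: dict):
        self.diagnostics = diagnostics
        super().__init__(
            "no graph was categorized low_frequency; per-graph (regime, peak low-k "
            f"accuracy, peak accuracy): {diagnostics}"
        )


@dataclasses.dataclass
class GraphSelection:
    """Low-frequency graphs ranked by their peak low-cutoff accuracy."""

    selected: list
    regimes: dict
    peak_low_accuracy: dict

    @property
    def m(self) -> int:
        return len(self.selected)


def select_low_frequency_graphs(
    curves: dict,
    n: int,
    low_k_fraction: float = 0.2,
    margin: float = 0.01,
    top_m: int | None = None,
) -> GraphSelection:
    """Keep the graphs whose accuracy curves peak in the low spectrum.

    ``curves`` maps a graph key (config or name) to ``(k_grid, accuracies)``
    with the grid ending at n.  Selected graphs are ranked by their best
    accuracy at cutoffs k <= low_k_fraction * n, descending (ties broken by
    curve order); ``top_m`` optionally truncates the ranking.
    """
    regimes, peaks = {}, {}
    diagnostics = {}
    for key, (k_grid, accs) in curves.items():
        k_grid = np.asarray(k_grid)
        accs = np.asarray(accs, dtype=float)
        regime = categorize_frequency_regime(k_grid, accs, n, low_k_fraction, margin)
        low = k_grid <= low_k_fraction * n
        peak_low = float(accs[low].max()) if low.any() else float("-inf")
        regimes[key] = regime
        peaks[key] = peak_low
        name = key.name if hasattr(key, "name") else str(key)
        diagnostics[name] = (regime, peak_low, float(accs.max()))
    qualifying = [k for k in curves if regimes[k] == LOW_FREQUENCY]
    if not qualifying:
        raise EmptySelectionError(diagnostics)
    order = sorted(range(len(qualifying)), key=lambda i: -peaks[qualifying[i]])
    selected = [qualifying[i] for i in order]
    if top_m is not None:
        selected = selected[:top_m]
    return GraphSelection(selected=selected, regimes=regimes, peak_low_accuracy=peaks)


# -- cross-validated ensemble training --------------------------------------


@dataclasses.dataclass
class EnsembleResult:
    """Out-of-fold ensemble predictions and per-fold fitted state."""

    oof_probabilities: np.ndarray
    fold_assignments: np.ndarray
    fold_alphas: np.ndarray          # (n_folds, m)
    models: list

    @property
    def oof_predictions(self) -> np.ndarray:
        return (self.oof_probabilities >= 0.5).astype(int)


def train_ensemble(
    block_inputs: list[np.ndarray],
    y: np.ndarray,
    fold_assignments: np.ndarray,
    **params,
) -> EnsembleResult:
    """Fit one ensemble per fold and collect out-of-fold probabilities.

    Each fold's model is trained only on that fold's training subjects
    (block inputs were filtered upstream on the full-cohort graphs; no test
    label enters training).  Every subject receives exactly one out-of-fold
    probability.  The gate is re-learned per fold.
    """
    y = np.asarray(y)
    fold_assignments = np.asarray(fold_assignments)
    folds = np.unique(fold_assignments)
    n = y.shape[0]
    base_seed = int(params.pop("random_state", 0))
    oof = np.full(n, np.nan)
    alphas = []
    models = []
    for fi, fold in enumerate(folds):
        test = fold_assignments == fold
        train = ~test
        model = GraphEnsembleClassifier(random_state=base_seed + 1000 * fi, **params)
        model.fit([X[train] for X in block_inputs], y[train])
        oof[test] = model.decision_probabilities([X[test] for X in block_inputs])
        alphas.append(model.alpha_)
        models.append(model)
    assert not np.isnan(oof).any()
    return EnsembleResult(
        oof_probabilities=oof,
        fold_assignments=fold_assignments,
        fold_alphas=np.vstack(alphas),
        models=models,
    )


# -- reference fusion rules (comparison baselines only) ----------------------


def average_probability_ensemble(prob_list: list[np.ndarray]) -> np.ndarray:
    """Unweighted mean of per-model positive-class probabilities."""
    return np.mean(np.vstack(prob_list), axis=0)


def majority_vote_ensemble(pred_list: list[np.ndarray]) -> np.ndarray:
    """Per-subject majority over binary predictions (ties go positive)."""
    votes = np.vstack(pred_list)
    return (votes.mean(axis=0) >= 0.5).astype(int)
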