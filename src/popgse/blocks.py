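"""Per-graph learning blocks: frequency-filtered feed-forward classifiers.

One block belongs to one population graph.  Its input is the cohort feature
matrix low-pass filtered in that graph's Fourier basis (transductively: the
basis comes from the full-cohort graph, but no test label is ever used);
its body is a 512/64 rectifier network whose 64-unit activation is the
block representation consumed by the ensemble.  Sweeping the filter cutoff
k and cross-validating the block yields the accuracy-vs-k curve that
classifies a graph as low- or high-frequency.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_X_y, check_array

from . import _nn
from .cohort import FeatureMatrix
from .graphs import PopulationGraph
from .spectral import SpectralBasis, combinatorial_laplacian, eigendecompose, lowpass_filter

__all__ = [
    "BlockClassifier",
    "filter_features",
    "block_accuracy_curve",
    "save_block",
    "load_block",
]


def filter_features(basis: SpectralBasis, X: FeatureMatrix | np.ndarray, k: int) -> np.ndarray:
    """Low-pass filter a feature matrix, clamping k to the cohort size.

    The configured cutoff (e.g. 200) may exceed a small cohort's n; the
    effective cutoff is min(k, n).
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    return lowpass_filter(basis, values, min(int(k), basis.n))


class BlockClassifier(ClassifierMixin, BaseEstimator):
    """Two-hidden-layer rectifier network with a two-class softmax head.

    Defaults follow the reference training recipe: hidden sizes (512, 64),
    Adam at learning rate 0.01, 200 full-batch epochs, dropout 0.3 after
    each hidden layer, no early stopping.  ``transform`` exposes the
    64-dimensional post-rectifier hidden representation with dropout off.

    Parameters
    ----------
    hidden_sizes : tuple of two ints
    dropout : float in [0, 1)
    learning_rate : float
    epochs : int
    random_state : int
        Seeds both weight initialization and dropout masks; identical seeds
        give identical fitted parameters.
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, int] = (512, 64),
        dropout: float = 0.3,
        learning_rate: float = 0.01,
        epochs: int = 200,
        random_state: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.random_state = random_state

    def _validate_params_(self) -> None:
        if len(self.hidden_sizes) != 2 or min(self.hidden_sizes) < 1:
            raise ValueError("hidden_sizes must be two positive integers")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate and epochs must be positive")

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BlockClassifier":
        self._validate_params_()
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("training fold must contain exactly two classes")
        rng = np.random.default_rng(self.random_state)
        params = _nn.init_block(rng, X.shape[1], tuple(self.hidden_sizes))
        params.update(_nn.init_softmax_head(rng, self.hidden_sizes[1]))
        optimizer = _nn.Adam(params, lr=self.learning_rate)
        losses = np.empty(self.epochs)
        for epoch in range(self.epochs):
            hidden, cache = _nn.block_forward(params, X, self.dropout, rng, train=True)
            loss, dhidden, head_grads = _nn.softmax_head_loss(params, hidden, y_idx)
            grads = _nn.block_backward(params, cache, dhidden)
            grads.update(head_grads)
            optimizer.step(grads)
            losses[epoch] = loss
        self.params_ = params
        self.loss_curve_ = losses
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise AttributeError("BlockClassifier is not fitted")

    def transform(self, X: np.ndarray) -> np.ndarray:
        """64-dim hidden representation (post-rectifier, dropout disabled)."""
        self._check_fitted()
        X = check_array(X)
        hidden, _ = _nn.block_forward(self.params_, X, 0.0, None, train=False)
        return hidden

    hidden_representation = transform

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        hidden = self.transform(X)
        logits = hidden @ self.params_["W3"] + self.params_["b3"]
        return _nn.stable_softmax(logits, axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _as_basis(graph: PopulationGraph | SpectralBasis) -> SpectralBasis:
    if isinstance(graph, SpectralBasis):
        return graph
    return eigendecompose(combinatorial_laplacian(graph), source_config=graph.config)


def block_accuracy_curve(
    graph: PopulationGraph | SpectralBasis,
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    k_grid: np.ndarray,
    fold_assignments: np.ndarray,
    random_state: int = 0,
    **block_params,
) -> np.ndarray:
    """Mean cross-validated test accuracy of the block at each cutoff k.

    ``k_grid`` must be increasing and end at n so the curve covers the full
    spectrum; ``fold_assignments`` maps each subject to a CV fold.  One
    block is trained per (k, fold) pair on the filtered features of the
    training subjects and scored on the held-out subjects.
    """
    basis = _as_basis(graph)
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    k_grid = np.asarray(k_grid, dtype=int)
    if np.any(np.diff(k_grid) <= 0) or k_grid[-1] != basis.n:
        raise ValueError("k_grid must be strictly increasing and end at n")
    folds = np.unique(fold_assignments)
    accuracies = np.empty(len(k_grid))
    for ki, k in enumerate(k_grid):
        Xf = filter_features(basis, values, int(k))
        fold_acc = []
        for fi, fold in enumerate(folds):
            test = fold_assignments == fold
            train = ~test
            clf = BlockClassifier(random_state=random_state + fi, **block_params)
            clf.fit(Xf[train], y[train])
            fold_acc.append(float(np.mean(clf.predict(Xf[test]) == y[test])))
        accuracies[ki] = float(np.mean(fold_acc))
    return accuracies


def save_block(block: BlockClassifier, path: str | Path, graph_name: str | None = None) -> Path:
    """Checkpoint: npz of parameters plus a JSON manifest with a content hash."""
    block._check_fitted()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {k: v for k, v in block.params_.items()}
    arrays["classes"] = block.classes_
    np.savez(path.with_suffix(".npz"), **arrays)
    digest = hashlib.sha256(path.with_suffix(".npz").read_bytes()).hexdigest()
    manifest = {
        "spec": block.get_params(),
        "graph": graph_name,
        "n_features_in": int(block.n_features_in_),
        "sha256": digest,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
    return path.with_suffix(".npz")


def load_block(path: str | Path) -> BlockClassifier:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    stored = hashlib.sha256(path.with_suffix(".npz").read_bytes()).hexdigest()
    if stored != manifest["sha256"]:
        raise ValueError("checkpoint content hash mismatch")
    data = np.load(path.with_suffix(".npz"))
    spec = dict(manifest["spec"])
    spec["hidden_sizes"] = tuple(spec["hidden_sizes"])
    block = BlockClassifier(**spec)
    block.params_ = {k: data[k] for k in ("W1", "b1", "W2", "b2", "W3", "b3")}
    block.classes_ = data["classes"]
    block.n_features_in_ = manifest["n_features_in"]
    return block
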