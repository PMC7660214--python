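"""Graph-spectral analysis: Laplacian, graph Fourier transform, filtering.

The combinatorial Laplacian L = D - A of a population graph admits an
orthonormal eigendecomposition L = U diag(lambda) U^T with non-negative
eigenvalues.  Treating eigenvalues as frequencies, a node-signal x has
graph Fourier transform x_hat = U^T x; reconstructing from only the first
k modes (lowest frequencies) is ideal low-pass filtering.  A graph is
"low-frequency" for a prediction task when restricting to a small leading
fraction of the spectrum loses essentially no accuracy.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .graphs import PopulationGraph, GraphConfig

__all__ = [
    "SpectralBasis",
    "SpectralProfile",
    "combinatorial_laplacian",
    "eigendecompose",
    "gft",
    "igft",
    "lowpass_filter",
    "spectral_profile",
    "categorize_frequency_regime",
    "LowPassFilter",
]

LOW_FREQUENCY = "low_frequency"
HIGH_FREQUENCY = "high_frequency"


@dataclasses.dataclass
class SpectralBasis:
    """Orthonormal graph Fourier basis of one graph's Laplacian.

    ``eigenvectors`` holds modes as columns ordered by non-decreasing
    ``eigenvalues``.  Within numerically tied eigenvalues the order is the
    solver's (stable for a given input) and each eigenvector's sign is fixed
    so that its largest-magnitude entry is positive, making bases
    reproducible across runs.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    source_config: GraphConfig | None = None

    @property
    def n(self) -> int:
        return self.eigenvectors.shape[0]

    def validate(self) -> None:
        U, lam = self.eigenvectors, self.eigenvalues
        if np.abs(U.T @ U - np.eye(self.n)).max() > 1e-8:
            raise ValueError("eigenvectors are not orthonormal")
        if np.any(np.diff(lam) < -1e-10):
            raise ValueError("eigenvalues must be non-decreasing")
        if lam.min() < -1e-8:
            raise ValueError("Laplacian eigenvalues must be non-negative")


@dataclasses.dataclass
class SpectralProfile:
    """Per-mode coefficient magnitudes of one feature column.

    ``energy_fraction[k-1]`` is the share of squared coefficient mass in the
    first k modes; undefined (``defined`` False, NaN entries) for an exactly
    zero signal.
    """

    eigenvalues: np.ndarray
    coefficient_magnitudes: np.ndarray
    energy_fraction: np.ndarray
    defined: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eigenvalue_rank": np.arange(len(self.eigenvalues)),
                "eigenvalue": self.eigenvalues,
                "coefficient_magnitude": self.coefficient_magnitudes,
                "cumulative_energy": self.energy_fraction,
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def combinatorial_laplacian(graph: PopulationGraph | np.ndarray) -> np.ndarray:
    """L = D - A with D the diagonal matrix of weighted degrees."""
    A = graph.weights if isinstance(graph, PopulationGraph) else np.asarray(graph, dtype=float)
    degrees = A.sum(axis=1)
    return np.diag(degrees) - A


def normalized_laplacian(graph: PopulationGraph | np.ndarray) -> np.ndarray:
    """Symmetric normalized variant I - D^{-1/2} A D^{-1/2} (non-default)."""
    A = graph.weights if isinstance(graph, PopulationGraph) else np.asarray(graph, dtype=float)
    degrees = A.sum(axis=1)
    inv_sqrt = np.where(degrees > 0, 1.0 / np.sqrt(np.where(degrees > 0, degrees, 1.0)), 0.0)
    L = np.eye(A.shape[0]) - (inv_sqrt[:, None] * A) * inv_sqrt[None, :]
    # isolated nodes contribute zero rows rather than identity rows
    L[degrees == 0, :] = 0.0
    L[:, degrees == 0] = 0.0
    return L


def eigendecompose(
    L: np.ndarray, source_config: GraphConfig | None = None
) -> SpectralBasis:
    """Full symmetric eigendecomposition with deterministic sign convention."""
    L = np.asarray(L, dtype=float)
    if np.abs(L - L.T).max() > 1e-8:
        raise ValueError("Laplacian must be symmetric")
    eigenvalues, U = scipy.linalg.eigh((L + L.T) / 2.0)
    # sign fix: largest-magnitude entry of each column made positive
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    basis = SpectralBasis(eigenvectors=U, eigenvalues=eigenvalues, source_config=source_config)
    basis.validate()
    return basis


def _check_rows(basis: SpectralBasis, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[0] != basis.n:
        raise ValueError(f"signal has {X.shape[0]} rows, basis expects {basis.n}")
    return X


def gft(basis: SpectralBasis, X: np.ndarray) -> np.ndarray:
    """Graph Fourier transform U^T X (modes ordered by frequency)."""
    return basis.eigenvectors.T @ _check_rows(basis, X)


def igft(basis: SpectralBasis, Xhat: np.ndarray) -> np.ndarray:
    """Inverse transform U X_hat back to the node domain."""
    return basis.eigenvectors @ _check_rows(basis, Xhat)


def lowpass_filter(basis: SpectralBasis, X: np.ndarray, k: int) -> np.ndarray:
    """Reconstruct X from its first k frequency modes: U_k U_k^T X.

    The result lives in the node domain with the input's shape; the map is
    an orthogonal projection (idempotent, norm non-increasing).  k = n
    returns the input unchanged.
    """
    X = _check_rows(basis, X)
    n = basis.n
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    if k == n:
        return X.copy()
    Uk = basis.eigenvectors[:, :k]
    return Uk @ (Uk.T @ X)


def spectral_profile(basis: SpectralBasis, X: np.ndarray, feature_index: int) -> SpectralProfile:
    """Coefficient magnitudes and cumulative energy for one feature column."""
    X = _check_rows(basis, np.atleast_2d(np.asarray(X, dtype=float).T).T)
    if not 0 <= feature_index < X.shape[1]:
        raise IndexError(f"feature_index {feature_index} out of range")
    xhat = basis.eigenvectors.T @ X[:, feature_index]
    magnitudes = np.abs(xhat)
    total = float(np.sum(xhat**2))
    if total == 0.0:
        energy = np.full(basis.n, np.nan)
        defined = False
    else:
        energy = np.cumsum(xhat**2) / total
        defined = True
    return SpectralProfile(
        eigenvalues=basis.eigenvalues.copy(),
        coefficient_magnitudes=magnitudes,
        energy_fraction=energy,
        defined=defined,
    )


def categorize_frequency_regime(
    k_grid: np.ndarray,
    accuracies: np.ndarray,
    n: int,
    low_k_fraction: float = 0.2,
    margin: float = 0.01,
) -> str:
    """Classify an accuracy-vs-k curve as low- or high-frequency.

    Low-frequency: the best accuracy restricted to k <= low_k_fraction * n
    comes within ``margin`` of the best accuracy over the whole grid (which
    must include k = n).  The defaults mirror treating the first 20% of the
    spectrum as "low", with a one-point tolerance.
    """
    k_grid = np.asarray(k_grid)
    accuracies = np.asarray(accuracies, dtype=float)
    if k_grid.size == 0 or k_grid.size != accuracies.size:
        raise ValueError("k_grid and accuracies must be non-empty and aligned")
    if np.any(np.diff(k_grid) <= 0):
        raise ValueError("k_grid must be strictly increasing")
    if k_grid[-1] != n:
        raise ValueError("k_grid must end at n (the full spectrum)")
    low = k_grid <= low_k_fraction * n
    if not low.any():
        return HIGH_FREQUENCY
    if accuracies[low].max() >= accuracies.max() - margin:
        return LOW_FREQUENCY
    return HIGH_FREQUENCY


class LowPassFilter:
    """Transformer wrapping ideal low-pass filtering on a fixed graph.

    Operates transductively: the basis comes from the full-cohort graph and
    ``transform`` expects the full n-row feature matrix in node order.
    Composes with sklearn-style pipelines via fit/transform/get_params.
    """

    def __init__(self, basis: SpectralBasis | None = None, k: int = 200):
        self.basis = basis
        self.k = k

    def get_params(self, deep: bool = True) -> dict:
        return {"basis": self.basis, "k": self.k}

    def set_params(self, **params) -> "LowPassFilter":
        for key, value in params.items():
            if key not in ("basis", "k"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: np.ndarray, y=None) -> "LowPassFilter":
        if self.basis is None:
            raise ValueError("a SpectralBasis must be supplied before fitting")
        _check_rows(self.basis, X)
        self.k_effective_ = min(self.k, self.basis.n)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "k_effective_"):
            raise AttributeError("LowPassFilter is not fitted")
        return lowpass_filter(self.basis, X, self.k_effective_)

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
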