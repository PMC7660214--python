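"""Population-graph construction over a subject cohort.

Nodes are subjects; edge weights encode inter-subject similarity computed
from connectivity features, phenotype agreement, or both:

    W(i, j) = sim(x_i, x_j) * sum_h 1[M_h(v_i) = M_h(v_j)]

where ``sim`` is a Gaussian kernel of the correlation distance between the
two subjects' lower-triangle connectivity vectors and ``M_h`` ranges over
the selected categorical phenotypes (site, sex, binned age).  Dropping the
phenotype factor gives the connectivity-only graph; dropping the kernel
gives phenotype-only graphs whose weights are integer match counts.  Three
reference graphs — fully connected, identity (edgeless), and random binary
— serve as baselines.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cohort import Cohort, FeatureMatrix

__all__ = [
    "GraphConfig",
    "PopulationGraph",
    "PHENOTYPE_FEATURES",
    "rsfc_similarity",
    "pairwise_rsfc_similarity",
    "phenotype_match_count",
    "default_age_bins",
    "build_population_graph",
    "build_baseline_graph",
    "enumerate_graph_configs",
    "save_graph",
    "load_graph",
    "export_edge_list",
]

PHENOTYPE_FEATURES = ("site", "sex", "age")

# Fixed enumeration order for the seven non-empty phenotype subsets.
_PHENOTYPE_SUBSETS = (
    ("site",),
    ("sex",),
    ("age",),
    ("site", "sex"),
    ("site", "age"),
    ("sex", "age"),
    ("site", "sex", "age"),
)


class GraphConfigError(ValueError):
    """Raised for contradictory or empty graph definitions."""


@dataclasses.dataclass(frozen=True)
class GraphConfig:
    """Declarative recipe for one population graph.

    Exactly one of the three families must be active: connectivity and/or
    phenotype similarity (``use_rsfc`` / ``phenotype_features``), or a
    baseline (``baseline_kind`` in {fc, identity, random}).
    """

    use_rsfc: bool = False
    phenotype_features: tuple[str, ...] = ()
    baseline_kind: str = "none"
    age_bin_edges: tuple[float, ...] | None = None
    random_density: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_kind not in ("none", "fc", "identity", "random"):
            raise GraphConfigError(f"unknown baseline_kind {self.baseline_kind!r}")
        unknown = set(self.phenotype_features) - set(PHENOTYPE_FEATURES)
        if unknown:
            raise GraphConfigError(f"unknown phenotype features {sorted(unknown)}")
        if self.baseline_kind != "none":
            if self.use_rsfc or self.phenotype_features:
                raise GraphConfigError("baseline graphs take no similarity features")
        elif not self.use_rsfc and not self.phenotype_features:
            raise GraphConfigError("empty graph definition")
        if not 0.0 < self.random_density <= 1.0:
            raise GraphConfigError("random_density must lie in (0, 1]")

    @property
    def name(self) -> str:
        if self.baseline_kind != "none":
            return self.baseline_kind
        parts = ["sim"]
        if self.use_rsfc:
            parts.append("RSFC")
        parts.extend(self.phenotype_features)
        return "_".join(parts)


@dataclasses.dataclass
class PopulationGraph:
    """Symmetric non-negative subject-by-subject weight matrix."""

    weights: np.ndarray
    config: GraphConfig | None
    subject_ids: list[str]

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def name(self) -> str:
        return self.config.name if self.config is not None else "graph"

    def validate(self) -> None:
        W = self.weights
        if W.shape[0] != W.shape[1] or W.shape[0] != len(self.subject_ids):
            raise ValueError("weight matrix shape disagrees with subject count")
        if np.abs(W - W.T).max() > 1e-10:
            raise ValueError("weights must be symmetric")
        if np.diagonal(W).any():
            raise ValueError("diagonal must be exactly zero")
        if W.min() < 0:
            raise ValueError("weights must be non-negative")


def rsfc_similarity(xi: np.ndarray, xj: np.ndarray, sigma: float) -> float:
    """Gaussian kernel of the correlation distance between feature vectors.

    Returns ``exp(-rho^2 / (2 sigma^2))`` with ``rho = 1 - pearson(xi, xj)``.
    A constant (zero-variance) vector has no defined correlation; by
    convention its similarity to anything is 0.
    """
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape or xi.ndim != 1 or xi.size < 2:
        raise ValueError("inputs must be 1-d vectors of equal length >= 2")
    tol_i = 1e-12 * max(1.0, float(np.abs(xi).max()))
    tol_j = 1e-12 * max(1.0, float(np.abs(xj).max()))
    if xi.std() <= tol_i or xj.std() <= tol_j:
        return 0.0
    rho = 1.0 - float(np.corrcoef(xi, xj)[0, 1])
    return float(np.exp(-(rho**2) / (2.0 * sigma**2)))


def _correlation_distance_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise correlation distances plus a mask of constant rows."""
    X = np.asarray(X, dtype=float)
    tol = 1e-12 * np.maximum(1.0, np.abs(X).max(axis=1))
    constant = X.std(axis=1) <= tol
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    C = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
    np.clip(C, -1.0, 1.0, out=C)
    return 1.0 - C, constant


def pairwise_rsfc_similarity(X: np.ndarray, sigma: float | None = None) -> np.ndarray:
    """Dense similarity matrix for stacked feature vectors.

    When ``sigma`` is None it defaults to the mean off-diagonal correlation
    distance over the cohort, a scale-free choice that keeps the kernel
    responsive to the observed spread of distances.
    """
    rho, constant = _correlation_distance_matrix(X)
    n = rho.shape[0]
    if sigma is None:
        off = ~np.eye(n, dtype=bool)
        sigma = float(rho[off].mean())
        if sigma == 0.0:
            sigma = 1.0
    S = np.exp(-(rho**2) / (2.0 * sigma**2))
    S[constant, :] = 0.0
    S[:, constant] = 0.0
    return S


def default_age_bins(ages: np.ndarray, width: float = 5.0) -> tuple[float, ...]:
    """Consecutive fixed-width bin edges spanning the observed age range."""
    lo = width * np.floor(np.min(ages) / width)
    hi = np.max(ages)
    edges = np.arange(lo, hi + width, width)
    return tuple(float(e) for e in edges)


def _categorical_codes(
    phenotypes: pd.DataFrame, feature: str, age_bin_edges: tuple[float, ...] | None
) -> np.ndarray:
    col = phenotypes[feature]
    if feature == "age":
        edges = age_bin_edges or default_age_bins(col.to_numpy(dtype=float))
        codes = np.digitize(col.to_numpy(dtype=float), np.asarray(edges), right=False)
    else:
        codes = col.to_numpy()
    # missing values never match anything, including each other
    missing = pd.isna(col).to_numpy()
    codes = codes.astype(object)
    codes[missing] = None
    return codes


def phenotype_match_count(
    vi: dict,
    vj: dict,
    features: tuple[str, ...],
    age_bin_edges: tuple[float, ...] | None = None,
) -> int:
    """Number of selected phenotypes on which two subjects agree.

    Age is compared after binning by ``age_bin_edges``; a missing value
    matches nothing.
    """
    count = 0
    for feat in features:
        a, b = vi.get(feat), vj.get(feat)
        if a is None or b is None or pd.isna(a) or pd.isna(b):
            continue
        if feat == "age":
            edges = np.asarray(age_bin_edges if age_bin_edges else (0.0,))
            a, b = np.digitize([float(a), float(b)], edges, right=False)
        if a == b:
            count += 1
    return int(count)


def _phenotype_match_matrix(
    phenotypes: pd.DataFrame,
    features: tuple[str, ...],
    age_bin_edges: tuple[float, ...] | None,
) -> np.ndarray:
    n = len(phenotypes)
    M = np.zeros((n, n))
    for feat in features:
        codes = _categorical_codes(phenotypes, feat, age_bin_edges)
        eq = np.array(
            [[a is not None and b is not None and a == b for b in codes] for a in codes],
            dtype=float,
        )
        M += eq
    return M


def build_population_graph(
    features: FeatureMatrix | np.ndarray,
    cohort: Cohort,
    config: GraphConfig,
    sigma: float | None = None,
) -> PopulationGraph:
    """Assemble the weight matrix a config describes.

    Connectivity-plus-phenotype graphs factor exactly as the element-wise
    product of the corresponding connectivity-only and phenotype-only
    graphs; the diagonal is zeroed in every case.
    """
    config.validate()
    if cohort.n < 2:
        raise GraphConfigError("need at least two subjects")
    if config.baseline_kind != "none":
        return build_baseline_graph(
            config.baseline_kind,
            cohort.n,
            density=config.random_density,
            seed=config.seed,
            subject_ids=cohort.subject_ids,
            config=config,
        )
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    W = np.ones((cohort.n, cohort.n))
    if config.use_rsfc:
        W = W * pairwise_rsfc_similarity(X, sigma=sigma)
    if config.phenotype_features:
        W = W * _phenotype_match_matrix(
            cohort.phenotypes, config.phenotype_features, config.age_bin_edges
        )
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    graph = PopulationGraph(weights=W, config=config, subject_ids=list(cohort.subject_ids))
    graph.validate()
    return graph


def build_baseline_graph(
    kind: str,
    n: int,
    density: float = 0.1,
    seed: int = 0,
    subject_ids: list[str] | None = None,
    config: GraphConfig | None = None,
) -> PopulationGraph:
    """Reference graphs: fully connected, identity (edgeless), or random.

    The identity baseline is "adjacency = identity"; self-loops carry no
    Laplacian weight, so its stored off-diagonal weights are all zero and
    its Laplacian is the zero matrix.
    """
    if n < 2:
        raise GraphConfigError("need at least two subjects")
    if kind == "fc":
        W = np.ones((n, n))
    elif kind == "identity":
        W = np.zeros((n, n))
    elif kind == "random":
        if not 0.0 < density <= 1.0:
            raise GraphConfigError("density must lie in (0, 1]")
        rng = np.random.default_rng(seed)
        upper = rng.random((n, n)) < density
        W = np.triu(upper, k=1).astype(float)
        W = W + W.T
    else:
        raise GraphConfigError(f"unknown baseline kind {kind!r}")
    np.fill_diagonal(W, 0.0)
    if subject_ids is None:
        subject_ids = [f"sub-{i:04d}" for i in range(n)]
    if config is None:
        config = GraphConfig(baseline_kind=kind, random_density=density, seed=seed)
    graph = PopulationGraph(weights=W, config=config, subject_ids=list(subject_ids))
    graph.validate()
    return graph


def enumerate_graph_configs(
    include_baselines: bool = False,
    age_bin_edges: tuple[float, ...] | None = None,
    random_density: float = 0.1,
    seed: int = 0,
) -> list[GraphConfig]:
    """All graph configs in a fixed documented order.

    Order: the connectivity-only graph; the seven phenotype-only subsets
    (site, sex, age, site+sex, site+age, sex+age, site+sex+age); the seven
    connectivity+phenotype combinations in the same subset order; then,
    optionally, the fc / identity / random baselines.
    """
    configs = [GraphConfig(use_rsfc=True)]
    for subset in _PHENOTYPE_SUBSETS:
        configs.append(GraphConfig(phenotype_features=subset, age_bin_edges=age_bin_edges))
    for subset in _PHENOTYPE_SUBSETS:
        configs.append(
            GraphConfig(use_rsfc=True, phenotype_features=subset, age_bin_edges=age_bin_edges)
        )
    if include_baselines:
        for kind in ("fc", "identity", "random"):
            configs.append(
                GraphConfig(baseline_kind=kind, random_density=random_density, seed=seed)
            )
    return configs


# -- serialization ----------------------------------------------------------


def _config_to_dict(config: GraphConfig) -> dict:
    d = dataclasses.asdict(config)
    d["phenotype_features"] = list(config.phenotype_features)
    if config.age_bin_edges is not None:
        d["age_bin_edges"] = list(config.age_bin_edges)
    return d


def _config_from_dict(d: dict) -> GraphConfig:
    d = dict(d)
    d["phenotype_features"] = tuple(d.get("phenotype_features", ()))
    if d.get("age_bin_edges") is not None:
        d["age_bin_edges"] = tuple(d["age_bin_edges"])
    return GraphConfig(**d)


def save_graph(graph: PopulationGraph, path: str | Path, fmt: str = "csv") -> Path:
    """Write dense weights (CSV or HDF5) plus a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        pd.DataFrame(
            graph.weights, index=graph.subject_ids, columns=graph.subject_ids
        ).to_csv(path)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("weights", data=graph.weights)
            fh.create_dataset(
                "subject_ids", data=np.array(graph.subject_ids, dtype=h5py.string_dtype())
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    sidecar = {"config": _config_to_dict(graph.config) if graph.config else None}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_graph(path: str | Path) -> PopulationGraph:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    config = _config_from_dict(sidecar["config"]) if sidecar.get("config") else None
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            weights = np.asarray(fh["weights"])
            subject_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["subject_ids"]]
    else:
        frame = pd.read_csv(path, index_col=0)
        weights = frame.to_numpy(dtype=float)
        subject_ids = [str(s) for s in frame.index]
    graph = PopulationGraph(weights=weights, config=config, subject_ids=subject_ids)
    graph.validate()
    return graph


def export_edge_list(graph: PopulationGraph, path: str | Path) -> Path:
    """TSV of (subject_i, subject_j, weight) over nonzero upper-triangle pairs."""
    path = Path(path)
    iu, ju = np.triu_indices(graph.n, k=1)
    mask = graph.weights[iu, ju] != 0
    frame = pd.DataFrame(
        {
            "subject_i": [graph.subject_ids[i] for i in iu[mask]],
            "subject_j": [graph.subject_ids[j] for j in ju[mask]],
            "weight": graph.weights[iu[mask], ju[mask]],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
    return path
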