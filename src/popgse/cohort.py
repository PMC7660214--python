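"""Synthetic subject cohorts with connectivity and phenotype structure.

A cohort bundles, per subject, a resting-state functional connectivity
(RSFC) matrix — a symmetric region-by-region correlation matrix with unit
diagonal — together with categorical/continuous phenotypes (acquisition
site, sex, age) and a binary diagnosis label (1 = patient, 0 = control).

The generator plants a class-dependent mean shift on a designated subset of
lower-triangle connectivity features, adds per-site offset vectors and
i.i.d. Gaussian noise, and is a pure function of its parameter record: the
same :class:`SimulationParams` (including the seed) reproduce bit-identical
cohorts.  It emulates the statistical structure a population-graph analysis
assumes (similar connectivity profiles within a class, site batch effects,
sex imbalance) without simulating fMRI time series.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "FeatureMatrix",
    "SimulationParams",
    "generate_cohort",
    "smooth_cohort_params",
    "vectorize_rsfc",
    "feature_index_to_pair",
    "generate_barbell_fixture",
    "save_cohort",
    "load_cohort",
]

_SYMMETRY_TOL = 1e-10


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Generative settings for a synthetic cohort.

    Parameters
    ----------
    n_patients, n_controls
        Class sizes; both must be positive.
    r
        Number of brain regions; RSFC matrices are ``r x r`` and feature
        vectors have ``d = r(r-1)/2`` entries.
    effect_size
        Separation between class means on the signal features: patients get
        ``+effect_size/2``, controls ``-effect_size/2``.
    signal_fraction
        Fraction of the d lower-triangle features carrying the class shift
        (the first ``ceil(signal_fraction * d)`` features in traversal
        order; documented so tests can locate the planted signal).
    n_sites
        Number of acquisition sites, sampled uniformly per subject.
    site_effect
        Scale (s.d.) of each site's additive per-feature offset vector.
    sex_imbalance
        Probability that a subject is male (code 1); the cohorts this
        emulates are heavily male-skewed.
    age_range
        Uniform sampling range for age in years.
    noise_sd
        S.d. of i.i.d. Gaussian noise added to every feature.
    seed
        Seed for all randomness; identical params give identical cohorts.
    """

    n_patients: int = 150
    n_controls: int = 150
    r: int = 32
    effect_size: float = 0.6
    signal_fraction: float = 0.1
    n_sites: int = 5
    site_effect: float = 0.1
    sex_imbalance: float = 727 / 871
    age_range: tuple[float, float] = (6.0, 58.0)
    noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("class counts must be positive")
        if self.r < 2:
            raise ValueError("r must be at least 2")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in [0, 1]")
        if not 0.0 <= self.sex_imbalance <= 1.0:
            raise ValueError("sex_imbalance must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.age_range[0] < 0 or self.age_range[1] < self.age_range[0]:
            raise ValueError("age_range must be non-negative and ordered")


@dataclasses.dataclass
class Cohort:
    """Subjects with RSFC matrices, phenotypes and binary labels.

    ``rsfc`` is an ``(n, r, r)`` stack of symmetric matrices with unit
    diagonal and entries in [-1, 1]; ``phenotypes`` is a DataFrame indexed
    like ``subject_ids`` with columns site, sex, age; ``labels`` is an
    ``(n,)`` int array (1 = patient, 0 = control).
    """

    subject_ids: list[str]
    rsfc: np.ndarray
    phenotypes: pd.DataFrame
    labels: np.ndarray

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def r(self) -> int:
        return self.rsfc.shape[1]

    def validate(self) -> None:
        n = self.n
        if self.rsfc.shape[0] != n or len(self.labels) != n or len(self.phenotypes) != n:
            raise ValueError("per-subject fields disagree on subject count")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if self.rsfc.shape[1] != self.rsfc.shape[2]:
            raise ValueError("rsfc matrices must be square")
        asym = np.abs(self.rsfc - self.rsfc.transpose(0, 2, 1)).max()
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"rsfc matrices asymmetric beyond tolerance ({asym:.2e})")
        diag = np.diagonal(self.rsfc, axis1=1, axis2=2)
        if not np.allclose(diag, 1.0, atol=_SYMMETRY_TOL):
            raise ValueError("rsfc matrices must have unit diagonal")
        if not set(np.unique(self.labels)).issubset({0, 1}):
            raise ValueError("labels must be binary 0/1")


@dataclasses.dataclass
class FeatureMatrix:
    """Subjects-by-features view of the strict lower triangles.

    ``values`` has shape ``(n, d)`` with ``d = r(r-1)/2``; row i is subject
    i's strict lower triangle traversed row-major over index pairs
    ``(i, j)`` with ``i > j`` (``numpy.tril_indices(r, k=-1)`` order).
    """

    values: np.ndarray
    r: int

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def _tril_pairs(r: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(r, k=-1)


def feature_index_to_pair(index: int, r: int) -> tuple[int, int]:
    """Inverse of the lower-triangle traversal: feature index -> (row, col)."""
    rows, cols = _tril_pairs(r)
    d = len(rows)
    if not 0 <= index < d:
        raise IndexError(f"feature index {index} out of range for r={r} (d={d})")
    return int(rows[index]), int(cols[index])


def vectorize_rsfc(cohort: Cohort) -> FeatureMatrix:
    """Stack every subject's strict lower triangle into an (n, d) matrix."""
    asym = np.abs(cohort.rsfc - cohort.rsfc.transpose(0, 2, 1)).max()
    if asym > _SYMMETRY_TOL:
        raise ValueError(f"rsfc matrices asymmetric beyond tolerance ({asym:.2e})")
    rows, cols = _tril_pairs(cohort.r)
    return FeatureMatrix(values=cohort.rsfc[:, rows, cols].copy(), r=cohort.r)


def features_to_rsfc(features: FeatureMatrix) -> np.ndarray:
    """Rebuild symmetric unit-diagonal matrices from lower-triangle vectors."""
    r = features.r
    rows, cols = _tril_pairs(r)
    n = features.n
    mats = np.zeros((n, r, r))
    mats[:, rows, cols] = features.values
    mats = mats + mats.transpose(0, 2, 1)
    mats[:, np.arange(r), np.arange(r)] = 1.0
    return mats


def generate_cohort(params: SimulationParams) -> Cohort:
    """Draw a seeded synthetic cohort.

    Patients come first in subject order, then controls.  Feature values are
    class mean + site offset + noise, clipped to [-1, 1]; the diagonal is
    set to 1 and matrices are exactly symmetric by construction.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients + params.n_controls
    d = params.r * (params.r - 1) // 2

    labels = np.concatenate(
        [np.ones(params.n_patients, dtype=int), np.zeros(params.n_controls, dtype=int)]
    )
    n_signal = int(np.ceil(params.signal_fraction * d))
    means = np.zeros((n, d))
    means[:, :n_signal] = np.where(labels[:, None] == 1, 1.0, -1.0) * params.effect_size / 2.0

    sites = rng.integers(0, params.n_sites, size=n)
    site_offsets = rng.normal(0.0, params.site_effect, size=(params.n_sites, d))
    values = means + site_offsets[sites] + rng.normal(0.0, params.noise_sd, size=(n, d))
    np.clip(values, -1.0, 1.0, out=values)

    sexes = (rng.random(n) < params.sex_imbalance).astype(int)  # 1 = male
    ages = rng.uniform(params.age_range[0], params.age_range[1], size=n)

    subject_ids = [f"sub-{i:04d}" for i in range(n)]
    phenotypes = pd.DataFrame(
        {"site": sites, "sex": sexes, "age": ages}, index=pd.Index(subject_ids, name="subject_id")
    )
    rsfc = features_to_rsfc(FeatureMatrix(values=values, r=params.r))
    cohort = Cohort(subject_ids=subject_ids, rsfc=rsfc, phenotypes=phenotypes, labels=labels)
    cohort.validate()
    return cohort


def smooth_cohort_params(
    n_patients: int = 60, n_controls: int = 60, seed: int = 0
) -> SimulationParams:
    """Parameters for a cohort whose connectivity-bearing graphs are smooth.

    The planted class shift is strong relative to the noise (large effect
    over many features), sites are few, sexes near-balanced and the age
    range narrow, so that each phenotype-partitioned connectivity graph
    keeps its class-split eigenmodes inside the lowest fifth of the
    spectrum.  This is the regime the graph-selection analysis illustrates:
    connectivity-bearing graphs categorize as low-frequency while
    phenotype-only and baseline graphs do not.
    """
    return SimulationParams(
        n_patients=n_patients,
        n_controls=n_controls,
        r=12,
        effect_size=1.5,
        signal_fraction=0.4,
        noise_sd=0.15,
        site_effect=0.1,
        n_sites=3,
        sex_imbalance=0.6,
        age_range=(6.0, 28.0),
        seed=seed,
    )


def generate_barbell_fixture(n_per_cluster: int, bridge_edges: int):
    """Two complete clusters joined by unit-weight bridges, plus a signal.

    Returns an adjacency matrix over ``2 * n_per_cluster`` nodes (two
    cliques; ``bridge_edges`` distinct cross edges enumerated row-major over
    cluster-pair combinations) and the cluster-indicator signal (+1 on the
    first cluster, -1 on the second).  This is the standard toy case where a
    signal aligned with two components concentrates all spectral energy in
    the first modes.
    """
    if n_per_cluster < 2:
        raise ValueError("n_per_cluster must be at least 2")
    if bridge_edges < 0 or bridge_edges > n_per_cluster**2:
        raise ValueError("bridge_edges must lie in [0, n_per_cluster^2]")
    m = n_per_cluster
    n = 2 * m
    A = np.zeros((n, n))
    A[:m, :m] = 1.0
    A[m:, m:] = 1.0
    np.fill_diagonal(A, 0.0)
    for e in range(bridge_edges):
        i, j = divmod(e, m)
        A[i, m + j] = A[m + j, i] = 1.0
    signal = np.concatenate([np.ones(m), -np.ones(m)])
    return A, signal


# -- on-disk round trip -----------------------------------------------------
#
# Phenotypes travel as a CSV with header subject_id,site,sex,age,label.
# RSFC matrices travel either as one headerless CSV matrix per subject
# (<subject_id>.csv next to the phenotype table) or as a single HDF5 file
# with one dataset per subject keyed by subject_id.


def save_cohort(cohort: Cohort, directory: str | Path, rsfc_format: str = "hdf5") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table = cohort.phenotypes.copy()
    table["label"] = cohort.labels
    table.to_csv(directory / "phenotypes.csv", index_label="subject_id")
    if rsfc_format == "hdf5":
        with h5py.File(directory / "rsfc.h5", "w") as fh:
            for sid, mat in zip(cohort.subject_ids, cohort.rsfc):
                fh.create_dataset(sid, data=mat)
    elif rsfc_format == "csv":
        rsfc_dir = directory / "rsfc"
        rsfc_dir.mkdir(exist_ok=True)
        for sid, mat in zip(cohort.subject_ids, cohort.rsfc):
            np.savetxt(rsfc_dir / f"{sid}.csv", mat, delimiter=",")
    else:
        raise ValueError(f"unknown rsfc_format {rsfc_format!r}")
    return directory


def load_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)
    table = pd.read_csv(directory / "phenotypes.csv", index_col="subject_id")
    subject_ids = [str(s) for s in table.index]
    labels = table.pop("label").to_numpy(dtype=int)
    h5_path = directory / "rsfc.h5"
    if h5_path.exists():
        with h5py.File(h5_path, "r") as fh:
            rsfc = np.stack([np.asarray(fh[sid]) for sid in subject_ids])
    else:
        rsfc = np.stack(
            [np.loadtxt(directory / "rsfc" / f"{sid}.csv", delimiter=",") for sid in subject_ids]
        )
    cohort = Cohort(
        subject_ids=subject_ids, rsfc=rsfc, phenotypes=table, labels=labels
    )
    cohort.validate()
    return cohort
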