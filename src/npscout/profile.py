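"""Library-level analyses: chemical-space PCA and probability profiles.

PCA operates on the 16-column physicochemical matrix after z-scoring each
descriptor (the columns mix Da, Angstrom^2 and counts; unscaled PCA would be
dominated by molecular weight).  Component signs are fixed by making each
component's largest-magnitude loading positive, so projections are fully
deterministic.

Library profiles summarize a model's NP class probabilities over a molecule
collection: a fixed-bin histogram, the fraction predicted NP (p > 0.5), the
fractions pinned at exactly 0 or 1, and the near-threshold fraction
(p in [0.4, 0.6]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .classify import DECISION_THRESHOLD, NPClassifier
from .features import (
    FingerprintKind,
    MolLike,
    PHYSCHEM_FIELDS,
    PhyschemVector,
    featurize_matrix,
    physchem_vector,
)

DEFAULT_BINS = 20  # resolves the [0.4, 0.6] band exactly on bin edges


@dataclass
class PcaProjection:
    scores: np.ndarray  # (n, k)
    explained_variance_fraction: np.ndarray  # (k,), non-increasing
    loadings: np.ndarray  # (k, p)
    feature_names: list[str] = field(default_factory=list)
    dropped_columns: list[str] = field(default_factory=list)


def _to_matrix(vectors) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return np.asarray(vectors, dtype=float)
    rows = []
    for v in vectors:
        rows.append(v.to_array() if isinstance(v, PhyschemVector) else np.asarray(v, float))
    return np.vstack(rows)


def pca_project(
    vectors, k: int = 2, feature_names: Optional[Sequence[str]] = None
) -> PcaProjection:
    """Project z-scored descriptor vectors onto the top-k principal components.

    Constant descriptor columns carry no variance and are dropped with a
    warning before scaling.  Requires at least k + 1 rows.
    """
    X = _to_matrix(vectors)
    n, p = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} rows for k={k} components")
    names = list(feature_names) if feature_names is not None else (
        list(PHYSCHEM_FIELDS) if p == len(PHYSCHEM_FIELDS) else [f"x{i}" for i in range(p)]
    )
    std = X.std(axis=0, ddof=0)
    keep = std > 0
    dropped = [names[i] for i in range(p) if not keep[i]]
    if dropped:
        warnings.warn(f"dropping constant descriptor columns: {dropped}")
    X = X[:, keep]
    names = [names[i] for i in range(p) if keep[i]]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.copy()
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        lead = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, lead] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    return PcaProjection(
        scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
        feature_names=names,
        dropped_columns=dropped,
    )


@dataclass
class LibraryProfile:
    n: int
    histogram: np.ndarray  # counts per fixed-width probability bin
    bin_edges: np.ndarray
    fraction_predicted_np: Optional[float]
    fraction_p_exactly_1: Optional[float]
    fraction_p_exactly_0: Optional[float]
    fraction_near_threshold: Optional[float]  # p in [0.4, 0.6]

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "n": self.n,
            "histogram": self.histogram.tolist(),
            "bin_edges": self.bin_edges.tolist(),
            "fraction_predicted_np": self.fraction_predicted_np,
            "fraction_p_exactly_1": self.fraction_p_exactly_1,
            "fraction_p_exactly_0": self.fraction_p_exactly_0,
            "fraction_near_threshold": self.fraction_near_threshold,
        }


def probability_histogram(
    probabilities, n_bins: int = DEFAULT_BINS
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-width histogram over [0, 1]; exact 1.0 falls in the top bin."""
    p = np.asarray(probabilities, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    counts, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    return counts, edges


def summarize_probabilities(
    probabilities, n_bins: int = DEFAULT_BINS
) -> LibraryProfile:
    p = np.asarray(probabilities, dtype=float)
    counts, edges = probability_histogram(p, n_bins=n_bins)
    n = p.size
    if n == 0:
        return LibraryProfile(
            n=0,
            histogram=counts,
            bin_edges=edges,
            fraction_predicted_np=None,
            fraction_p_exactly_1=None,
            fraction_p_exactly_0=None,
            fraction_near_threshold=None,
        )
    return LibraryProfile(
        n=n,
        histogram=counts,
        bin_edges=edges,
        fraction_predicted_np=float(np.mean(p > DECISION_THRESHOLD)),
        fraction_p_exactly_1=float(np.mean(p == 1.0)),
        fraction_p_exactly_0=float(np.mean(p == 0.0)),
        fraction_near_threshold=float(np.mean((p >= 0.4) & (p <= 0.6))),
    )


def profile_library(
    model: NPClassifier, molecules: Sequence[MolLike], n_bins: int = DEFAULT_BINS
) -> tuple[LibraryProfile, np.ndarray]:
    """Score every molecule and summarize the probability distribution.

    Returns the profile plus the per-molecule probability vector (for the
    per-molecule CSV written by the CLI).
    """
    if len(molecules) == 0:
        return summarize_probabilities(np.array([]), n_bins=n_bins), np.array([])
    kind = (
        FingerprintKind.MACCS166
        if model.feature_set == "maccs"
        else FingerprintKind.MORGAN2_1024
    )
    X = featurize_matrix(molecules, kind)
    p = model.predict_np_probability(X)
    return summarize_probabilities(p, n_bins=n_bins), p
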