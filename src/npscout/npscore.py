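"""Fragment-based NP-likeness baseline score.

A trainable re-implementation of the classic fragment-frequency approach to
natural-product-likeness: every heavy atom contributes one *atom signature*
— a canonical string for its circular environment up to bond depth 3 — and
each signature is weighted by the smoothed log10 ratio of its relative
frequency in an NP corpus versus an SM corpus, clamped to [-3, 3].  A
molecule's score is the mean weight over its atom signatures (unseen
signatures contribute 0), so scores also lie in [-3, 3].  A molecule is
labeled NP iff its score strictly exceeds 0; the affine map (s + 3) / 6
normalizes scores to [0, 1] for ROC analysis.

For a signature *f* with occurrence counts c_NP(f), c_SM(f) and corpus
totals T_NP, T_SM, the weight is::

    w(f) = clamp( log10( ((c_NP(f)+a) / (T_NP+a)) /
                         ((c_SM(f)+a) / (T_SM+a)) ), -3, +3 )

with pseudo-count a (default 1).  Swapping the two corpora negates every
weight exactly.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator

from .datasets import NP, SM
from .features import MolLike, as_mol

SCORE_MIN = -3.0
SCORE_MAX = 3.0
DEFAULT_HEIGHT = 3
TABLE_SCHEMA_VERSION = 1


def _atom_signature(mol: Chem.Mol, atom_idx: int, height: int) -> str:
    """Canonical string for the environment of one atom up to ``height`` bonds.

    Uses the canonical SMILES of the environment subgraph rooted at the
    center atom, so identical chemical environments yield identical strings
    regardless of input atom numbering.
    """
    env = Chem.FindAtomEnvironmentOfRadiusN(
        mol, height, atom_idx, False, False  # useHs, enforceSize
    )
    if not env:
        # isolated atom or radius-0 environment: the atom itself
        atom = mol.GetAtomWithIdx(atom_idx)
        return Chem.MolFragmentToSmiles(mol, atomsToUse=[atom_idx], canonical=True)
    amap: dict[int, int] = {}
    submol = Chem.PathToSubmol(mol, env, atomMap=amap)
    return Chem.MolToSmiles(submol, rootedAtAtom=amap[atom_idx], canonical=True)


def enumerate_atom_signatures(
    mol: MolLike, height: int = DEFAULT_HEIGHT
) -> list[str]:
    """One signature per heavy atom, invariant to input atom order."""
    m = as_mol(mol)
    return [_atom_signature(m, i, height) for i in range(m.GetNumAtoms())]


@dataclass
class FragmentScoreTable:
    """Signature -> clamped log-ratio weight map with its training counts."""

    weights: dict[str, float]
    t_np: int
    t_sm: int
    alpha: float = 1.0
    height: int = DEFAULT_HEIGHT
    counts_np: dict[str, int] = field(default_factory=dict)
    counts_sm: dict[str, int] = field(default_factory=dict)

    def weight(self, signature: str) -> float:
        return self.weights.get(signature, 0.0)

    def to_json(self, path: str) -> None:
        payload = {
            "schema_version": TABLE_SCHEMA_VERSION,
            "height": self.height,
            "alpha": self.alpha,
            "t_np": self.t_np,
            "t_sm": self.t_sm,
            "weights": self.weights,
            "counts_np": self.counts_np,
            "counts_sm": self.counts_sm,
            "encoding": "canonical rooted environment SMILES",
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "FragmentScoreTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            weights=payload["weights"],
            t_np=payload["t_np"],
            t_sm=payload["t_sm"],
            alpha=payload["alpha"],
            height=payload["height"],
            counts_np=payload.get("counts_np", {}),
            counts_sm=payload.get("counts_sm", {}),
        )


def signature_weight(
    c_np: int, c_sm: int, t_np: int, t_sm: int, alpha: float = 1.0
) -> float:
    """Smoothed, clamped log10 frequency-ratio weight for one signature.

    Evaluated as a difference of logs so that swapping the corpora negates
    the weight exactly, bit for bit.
    """
    log_ratio = math.log10((c_np + alpha) / (t_np + alpha)) - math.log10(
        (c_sm + alpha) / (t_sm + alpha)
    )
    return float(np.clip(log_ratio, SCORE_MIN, SCORE_MAX))


def fit_fragment_scores(
    np_lib: Iterable[MolLike],
    sm_lib: Iterable[MolLike],
    alpha: float = 1.0,
    height: int = DEFAULT_HEIGHT,
) -> FragmentScoreTable:
    """Count atom signatures in both corpora and derive log-ratio weights."""
    counts_np: Counter = Counter()
    counts_sm: Counter = Counter()
    for mol in np_lib:
        counts_np.update(enumerate_atom_signatures(mol, height))
    for mol in sm_lib:
        counts_sm.update(enumerate_atom_signatures(mol, height))
    if not counts_np or not counts_sm:
        raise ValueError("both corpora must be non-empty")
    t_np = sum(counts_np.values())
    t_sm = sum(counts_sm.values())
    weights = {
        sig: signature_weight(counts_np[sig], counts_sm[sig], t_np, t_sm, alpha)
        for sig in set(counts_np) | set(counts_sm)
    }
    return FragmentScoreTable(
        weights=weights,
        t_np=t_np,
        t_sm=t_sm,
        alpha=alpha,
        height=height,
        counts_np=dict(counts_np),
        counts_sm=dict(counts_sm),
    )


def np_likeness_score(mol: MolLike, table: FragmentScoreTable) -> float:
    """Mean signature weight over the molecule's heavy atoms, in [-3, 3]."""
    sigs = enumerate_atom_signatures(mol, table.height)
    if not sigs:
        raise ValueError("molecule has no heavy atoms")
    return float(np.mean([table.weight(s) for s in sigs]))


def classify_by_score(score: float) -> int:
    """NP iff score > 0; a score of exactly 0 classifies as SM."""
    return NP if score > 0.0 else SM


def normalize_score(score: float) -> float:
    """Affine map of [-3, 3] onto [0, 1]."""
    if not (SCORE_MIN <= score <= SCORE_MAX):
        raise ValueError(f"score {score} outside [{SCORE_MIN}, {SCORE_MAX}]")
    return (score - SCORE_MIN) / (SCORE_MAX - SCORE_MIN)


class FragmentScorer(BaseEstimator):
    """sklearn-style estimator wrapping the fragment score table.

    ``fit(molecules, y)`` with NP=1/SM=0 labels counts signatures per class;
    ``decision_function`` returns raw scores in [-3, 3], ``predict_proba``
    the normalized [0, 1] scores, and ``predict`` the threshold-0 labels.
    """

    def __init__(self, alpha: float = 1.0, height: int = DEFAULT_HEIGHT):
        self.alpha = alpha
        self.height = height

    def fit(self, X: Sequence[MolLike], y) -> "FragmentScorer":
        y = np.asarray(y, dtype=int)
        np_lib = [m for m, lbl in zip(X, y) if lbl == NP]
        sm_lib = [m for m, lbl in zip(X, y) if lbl == SM]
        self.table_ = fit_fragment_scores(
            np_lib, sm_lib, alpha=self.alpha, height=self.height
        )
        self.classes_ = np.array([SM, NP])
        return self

    def decision_function(self, X: Sequence[MolLike]) -> np.ndarray:
        return np.array([np_likeness_score(m, self.table_) for m in X])

    def predict(self, X: Sequence[MolLike]) -> np.ndarray:
        return np.array([classify_by_score(s) for s in self.decision_function(X)])

    def predict_proba(self, X: Sequence[MolLike]) -> np.ndarray:
        p_np = np.array([normalize_score(s) for s in self.decision_function(X)])
        return np.column_stack([1.0 - p_np, p_np])
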