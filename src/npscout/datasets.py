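"""Training-set assembly: corpus pairing, splitting, fingerprint dedup/deconflict.

The NP corpus is paired with an equal-size random sample from the SM pool
(after removing any SM whose canonical SMILES appears among the NPs), the
merged library is split 4:1 into training and test molecules, and the
*training* fingerprints are then reduced: duplicate bit sets within a class
collapse to one row, and bit sets occurring in both classes are dropped from
both, so the feature representation carries no conflicting supervision.
Test data is never conflict-filtered.

Labels are integers throughout: ``NP = 1`` (positive class), ``SM = 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import BitFingerprint, FingerprintKind, fingerprint
from .standardize import ParentMolecule

NP = 1
SM = 0
LABEL_NAMES = {NP: "NP", SM: "SM"}
SCHEMA_VERSION = 1


@dataclass
class LabeledLibrary:
    molecules: list[ParentMolecule]
    labels: np.ndarray  # int array, NP=1 / SM=0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.molecules) != len(self.labels):
            raise ValueError("molecules and labels length mismatch")

    def __len__(self) -> int:
        return len(self.molecules)

    def subset(self, idx: Sequence[int]) -> "LabeledLibrary":
        idx = list(idx)
        return LabeledLibrary(
            molecules=[self.molecules[i] for i in idx], labels=self.labels[idx]
        )


def pair_corpora(
    np_lib: Sequence[ParentMolecule],
    sm_pool: Sequence[ParentMolecule],
    seed: int,
) -> LabeledLibrary:
    """Pair an NP corpus with an equal-size SM sample.

    SM-pool entries whose canonical SMILES occurs in the NP corpus are
    removed first; the remainder is sampled without replacement down to
    ``len(np_lib)``.  Deterministic given ``seed``.
    """
    np_forms = {m.canonical_smiles for m in np_lib}
    candidates = [m for m in sm_pool if m.canonical_smiles not in np_forms]
    if len(candidates) < len(np_lib):
        raise ValueError(
            f"SM pool too small after overlap removal: {len(candidates)} < {len(np_lib)}"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(candidates), size=len(np_lib), replace=False)
    sms = [candidates[i] for i in sorted(pick)]
    molecules = list(np_lib) + sms
    labels = np.array([NP] * len(np_lib) + [SM] * len(sms), dtype=int)
    return LabeledLibrary(molecules=molecules, labels=labels)


def split_train_test(
    lib: LabeledLibrary, ratio: tuple[int, int] = (4, 1), seed: int = 0
) -> tuple[LabeledLibrary, LabeledLibrary]:
    """Random disjoint, exhaustive train/test split at the given integer ratio.

    Sizes are within one molecule of the exact ratio; deterministic given
    ``seed``.
    """
    n = len(lib)
    if n == 0:
        raise ValueError("empty library")
    train_part, test_part = ratio
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * train_part / (train_part + test_part)))
    return lib.subset(perm[:n_train]), lib.subset(perm[n_train:])


@dataclass
class TrainingMatrix:
    """Deduplicated, conflict-free labeled fingerprint matrix."""

    fingerprints: list[BitFingerprint]
    labels: np.ndarray
    fingerprint_kind: FingerprintKind
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    def __len__(self) -> int:
        return len(self.fingerprints)

    @property
    def X(self) -> np.ndarray:
        return np.vstack([fp.to_array() for fp in self.fingerprints])

    @property
    def y(self) -> np.ndarray:
        return self.labels


def dedup_and_deconflict(
    train: LabeledLibrary,
    kind: FingerprintKind,
    fingerprints: Optional[Sequence[BitFingerprint]] = None,
) -> TrainingMatrix:
    """Collapse within-class duplicate fingerprints and drop cross-class ones.

    Structurally distinct molecules can share a bit set; each distinct bit
    set is kept once per class, and bit sets seen under both labels are
    removed from both classes.  Row order follows first occurrence in the
    input.  ``fingerprints`` may be supplied to reuse precomputed features.
    """
    kind = FingerprintKind(kind)
    if fingerprints is None:
        fingerprints = [fingerprint(m, kind) for m in train.molecules]
    first_seen: dict[frozenset, int] = {}
    label_sets: dict[frozenset, set] = {}
    order: list[frozenset] = []
    for i, fp in enumerate(fingerprints):
        key = fp.bits
        if key not in label_sets:
            label_sets[key] = set()
            first_seen[key] = i
            order.append(key)
        label_sets[key].add(int(train.labels[i]))
    kept = [key for key in order if len(label_sets[key]) == 1]
    n_conflict = sum(1 for key in order if len(label_sets[key]) > 1)
    fps = [BitFingerprint(kind=kind, bits=key) for key in kept]
    labels = np.array([next(iter(label_sets[key])) for key in kept], dtype=int)
    provenance = {
        "n_input": len(train),
        "n_distinct_fingerprints": len(order),
        "n_conflicting_fingerprints_removed": n_conflict,
        "n_output": len(kept),
        "fingerprint_kind": kind.value,
    }
    return TrainingMatrix(
        fingerprints=fps, labels=labels, fingerprint_kind=kind, provenance=provenance
    )


def save_training_matrix(matrix: TrainingMatrix, path: str) -> None:
    """Write a dataset container: JSON with hex fingerprints and provenance."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "fingerprint_kind": matrix.fingerprint_kind.value,
        "provenance": matrix.provenance,
        "rows": [
            {"fp": fp.to_hex(), "label": LABEL_NAMES[int(lbl)]}
            for fp, lbl in zip(matrix.fingerprints, matrix.labels)
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=None, separators=(",", ":"), sort_keys=True)


def load_training_matrix(path: str) -> TrainingMatrix:
    with open(path) as fh:
        payload = json.load(fh)
    kind = FingerprintKind(payload["fingerprint_kind"])
    fps = [BitFingerprint.from_hex(row["fp"], kind) for row in payload["rows"]]
    labels = np.array(
        [NP if row["label"] == "NP" else SM for row in payload["rows"]], dtype=int
    )
    return TrainingMatrix(
        fingerprints=fps,
        labels=labels,
        fingerprint_kind=kind,
        provenance=payload.get("provenance", {}),
    )
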