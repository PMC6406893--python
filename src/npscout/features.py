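"""Molecular descriptors: MACCS keys, Morgan fingerprints, physicochemical vectors.

Three feature sets are provided, mirroring the three model flavors:

* MACCS keys — the 166 public substructure keys.  RDKit's generator returns a
  167-bit vector whose bit 0 is unused; here key *k* (1-based) is stored at
  index *k - 1*, so vectors are dense 166-bit arrays.  This convention is
  recorded in model metadata so fingerprints are never mixed across
  conventions.
* Morgan fingerprints of radius 2, hashed to 1024 bits ("Morgan2").
* A 16-element physicochemical vector: the 15 classical 2D descriptors
  (weight, log P, TPSA, H-bond counts, heavy-atom/heteroatom counts,
  acid/base atom counts, formal charge, aromatic atoms, chiral centers,
  rings, rotatable-bond fraction) plus the Shannon entropy of the element
  distribution.

All featurizers are pure functions of the molecular graph: renumbering atoms
never changes any output.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, fields
from enum import Enum
from typing import Iterable, Sequence, Union

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.MACCSkeys import smartsPatts
from sklearn.base import BaseEstimator, TransformerMixin

from .standardize import ParentMolecule


class FingerprintKind(str, Enum):
    MACCS166 = "maccs"
    MORGAN2_1024 = "morgan2"

    @property
    def length(self) -> int:
        return 166 if self is FingerprintKind.MACCS166 else 1024


@dataclass(frozen=True)
class BitFingerprint:
    """A fixed-length binary fingerprint stored as its set-bit indices."""

    kind: FingerprintKind
    bits: frozenset

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.length):
            raise ValueError(f"bit index out of range for {self.kind}")

    @property
    def length(self) -> int:
        return self.kind.length

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.length, dtype=np.uint8)
        if self.bits:
            arr[sorted(self.bits)] = 1
        return arr

    def to_hex(self) -> str:
        return np.packbits(self.to_array()).tobytes().hex()

    @classmethod
    def from_hex(cls, hexstr: str, kind: FingerprintKind) -> "BitFingerprint":
        kind = FingerprintKind(kind)
        raw = np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8)
        arr = np.unpackbits(raw)[: kind.length]
        return cls(kind=kind, bits=frozenset(np.flatnonzero(arr).tolist()))


MolLike = Union[ParentMolecule, Chem.Mol, str]


def as_mol(mol: MolLike) -> Chem.Mol:
    if isinstance(mol, ParentMolecule):
        return mol.mol
    if isinstance(mol, str):
        out = Chem.MolFromSmiles(mol)
        if out is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        return out
    return mol


def maccs_fp(mol: MolLike) -> BitFingerprint:
    """166-bit public-SMARTS MACCS keys; key k lives at index k-1."""
    bv = MACCSkeys.GenMACCSKeys(as_mol(mol))
    bits = frozenset(b - 1 for b in bv.GetOnBits())
    return BitFingerprint(kind=FingerprintKind.MACCS166, bits=bits)


_MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


def morgan2_fp(mol: MolLike) -> BitFingerprint:
    """Circular-environment fingerprint, radius 2, hashed to 1024 bits."""
    bv = _MORGAN_GEN.GetFingerprint(as_mol(mol))
    return BitFingerprint(
        kind=FingerprintKind.MORGAN2_1024, bits=frozenset(bv.GetOnBits())
    )


def fingerprint(mol: MolLike, kind: FingerprintKind) -> BitFingerprint:
    kind = FingerprintKind(kind)
    return maccs_fp(mol) if kind is FingerprintKind.MACCS166 else morgan2_fp(mol)


def maccs_key_names() -> list[str]:
    """Feature names ``MACCS_<key>:<SMARTS>`` aligned with fingerprint indices."""
    names = []
    for key in range(1, 167):
        smarts, _ = smartsPatts.get(key, ("?", 0))
        names.append(f"MACCS_{key}:{smarts}")
    return names


def element_entropy(mol: MolLike) -> float:
    """Shannon entropy (bits) of the element distribution, implicit H included.

    Single-element atom sets (e.g. a pure-carbon cluster) have entropy 0.
    """
    m = as_mol(mol)
    counts: Counter = Counter()
    for atom in m.GetAtoms():
        counts[atom.GetSymbol()] += 1
        counts["H"] += atom.GetTotalNumHs()
    if counts.get("H") == 0:
        del counts["H"]
    total = sum(counts.values())
    return -sum((c / total) * math.log2(c / total) for c in counts.values() if c)


# SMARTS definitions for acidic / basic atom counts.  These are deliberately
# narrow, documented conventions: acids are the O-H of carboxylic, sulfonic
# and phosphonic/phosphoric groups (phenols excluded); bases are sp3 amines
# (amides, sulfonamides and aromatic N excluded) plus amidine/guanidine
# nitrogens.
ACID_SMARTS = [
    "[OX2H1][CX3]=[OX1]",
    "[OX2H1][SX4](=[OX1])=[OX1]",
    "[OX2H1][PX4]=[OX1]",
]
BASE_SMARTS = [
    "[NX3;H2,H1,H0;!$([NX3][CX3]=[OX1]);!$([NX3][SX4]=[OX1]);!$([NX3][CX3]=[NX2]);!a]",
    "[NX2]=[CX3][NX3]",
]
_ACID_PATTS = [Chem.MolFromSmarts(s) for s in ACID_SMARTS]
_BASE_PATTS = [Chem.MolFromSmarts(s) for s in BASE_SMARTS]


def _count_matched_atoms(mol: Chem.Mol, patts, position: int = 0) -> int:
    hits = set()
    for patt in patts:
        for match in mol.GetSubstructMatches(patt):
            hits.add(match[position])
    return len(hits)


PHYSCHEM_FIELDS = (
    "mw",
    "logp",
    "tpsa",
    "n_hba",
    "n_hbd",
    "n_heavy",
    "frac_rotatable",
    "n_N",
    "n_O",
    "n_acid",
    "n_base",
    "sum_formal_charge",
    "n_aromatic_atoms",
    "n_chiral",
    "n_rings",
    "element_entropy",
)


@dataclass(frozen=True)
class PhyschemVector:
    mw: float
    logp: float
    tpsa: float
    n_hba: int
    n_hbd: int
    n_heavy: int
    frac_rotatable: float
    n_N: int
    n_O: int
    n_acid: int
    n_base: int
    sum_formal_charge: int
    n_aromatic_atoms: int
    n_chiral: int
    n_rings: int
    element_entropy: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


def physchem_vector(mol: MolLike) -> PhyschemVector:
    """The 15 classical 2D descriptors plus element-distribution entropy.

    ``n_chiral`` counts all potential tetrahedral stereocenters (assigned or
    not), since stereo descriptors are stripped during standardization.
    ``frac_rotatable`` is rotatable bonds over total bonds (0 for a
    bond-free molecule).  log P and TPSA use Crippen and Ertl
    atomic-contribution schemes respectively.
    """
    m = as_mol(mol)
    n_bonds = m.GetNumBonds()
    chiral = Chem.FindMolChiralCenters(
        m, includeUnassigned=True, useLegacyImplementation=False
    )
    return PhyschemVector(
        mw=Descriptors.MolWt(m),
        logp=Crippen.MolLogP(m),
        tpsa=Descriptors.TPSA(m),
        n_hba=Lipinski.NumHAcceptors(m),
        n_hbd=Lipinski.NumHDonors(m),
        n_heavy=m.GetNumHeavyAtoms(),
        frac_rotatable=(Lipinski.NumRotatableBonds(m) / n_bonds) if n_bonds else 0.0,
        n_N=sum(1 for a in m.GetAtoms() if a.GetSymbol() == "N"),
        n_O=sum(1 for a in m.GetAtoms() if a.GetSymbol() == "O"),
        n_acid=_count_matched_atoms(m, _ACID_PATTS),
        n_base=_count_matched_atoms(m, _BASE_PATTS),
        sum_formal_charge=sum(a.GetFormalCharge() for a in m.GetAtoms()),
        n_aromatic_atoms=sum(1 for a in m.GetAtoms() if a.GetIsAromatic()),
        n_chiral=len(chiral),
        n_rings=Chem.rdMolDescriptors.CalcNumRings(m),
        element_entropy=element_entropy(m),
    )


class FingerprintFeaturizer(TransformerMixin, BaseEstimator):
    """sklearn transformer turning molecules into binary fingerprint matrices.

    Parameters
    ----------
    kind : {"maccs", "morgan2"}
        Fingerprint family; fixes the output width (166 or 1024).
    """

    def __init__(self, kind: str = "maccs"):
        self.kind = kind

    def fit(self, X: Sequence[MolLike], y=None) -> "FingerprintFeaturizer":
        self.kind_ = FingerprintKind(self.kind)
        self.n_features_out_ = self.kind_.length
        return self

    def transform(self, X: Sequence[MolLike]) -> np.ndarray:
        if not hasattr(self, "kind_"):
            self.fit(X)
        return np.vstack([fingerprint(m, self.kind_).to_array() for m in X])

    def get_feature_names_out(self, input_features=None):
        if FingerprintKind(self.kind) is FingerprintKind.MACCS166:
            return np.array(maccs_key_names())
        return np.array([f"morgan2_{i}" for i in range(1024)])


class PhyschemFeaturizer(TransformerMixin, BaseEstimator):
    """sklearn transformer producing the 16-column physicochemical matrix."""

    def fit(self, X: Sequence[MolLike], y=None) -> "PhyschemFeaturizer":
        self.n_features_out_ = len(PHYSCHEM_FIELDS)
        return self

    def transform(self, X: Sequence[MolLike]) -> np.ndarray:
        return np.vstack([physchem_vector(m).to_array() for m in X])

    def get_feature_names_out(self, input_features=None):
        return np.array(PHYSCHEM_FIELDS)


def featurize_matrix(mols: Iterable[MolLike], kind: FingerprintKind) -> np.ndarray:
    """Stack fingerprints for ``mols`` into an (n, length) uint8 matrix."""
    kind = FingerprintKind(kind)
    return np.vstack([fingerprint(m, kind).to_array() for m in mols])
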