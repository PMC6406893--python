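"""Molecule standardization pipeline.

Raw SMILES/SDF records are reduced to *parent molecules*: the largest
component of any salt, restricted to common organic elements, neutralized,
tautomer-canonicalized, stripped of stereochemistry, filtered to a 150-1500 Da
molecular-weight window, and deduplicated on the canonical SMILES of the
result.  Every removal is tallied in a :class:`StandardizationReport` so that
library curation is auditable.

The pipeline order is: parse -> strip minor components -> element filter ->
neutralize & merge tautomers -> strip stereo -> molecular-weight filter ->
deduplicate.  Each step is exposed as a standalone function; the composition
lives in :func:`standardize_library`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

# common organic elements retained during curation
ELEMENT_WHITELIST = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)

DEFAULT_MIN_MW = 150.0
DEFAULT_MAX_MW = 1500.0

_rdlog = RDLogger.logger()


@dataclass(frozen=True)
class RawRecord:
    """One unparsed library entry."""

    source_id: str
    smiles: str
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("RawRecord.smiles must be non-empty")


@dataclass(frozen=True)
class ParentMolecule:
    """A fully standardized molecule.

    ``canonical_smiles`` carries no stereo descriptors and is the identity
    used for deduplication.  ``mw`` is the average molecular weight in Da of
    the neutralized parent.
    """

    mol: Chem.Mol
    canonical_smiles: str
    mw: float
    source_id: str = ""
    name: Optional[str] = None

    def __hash__(self) -> int:  # identity is the canonical text form
        return hash(self.canonical_smiles)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParentMolecule):
            return NotImplemented
        return self.canonical_smiles == other.canonical_smiles


@dataclass
class StandardizationReport:
    n_input: int = 0
    n_parse_failed: int = 0
    n_salt_stripped: int = 0  # informational: records that had minor components
    n_element_rejected: int = 0
    n_mw_rejected: int = 0
    n_duplicates_removed: int = 0
    n_output: int = 0
    rows: list = field(default_factory=list)  # per-record audit entries

    def check(self) -> None:
        """Assert the conservation identity over record counts."""
        expected = (
            self.n_input
            - self.n_parse_failed
            - self.n_element_rejected
            - self.n_mw_rejected
            - self.n_duplicates_removed
        )
        if self.n_output != expected:
            raise AssertionError(
                f"report inconsistent: n_output={self.n_output}, expected {expected}"
            )


def parse_record(record: RawRecord) -> Optional[Chem.Mol]:
    """Parse a record's SMILES; return ``None`` on failure (never raises)."""
    _rdlog.setLevel(RDLogger.CRITICAL)
    try:
        return Chem.MolFromSmiles(record.smiles)
    finally:
        _rdlog.setLevel(RDLogger.ERROR)


def strip_minor_components(mol: Chem.Mol) -> Chem.Mol:
    """Keep only the largest component of a multi-fragment structure.

    The retained fragment is the one with the most heavy atoms; ties are
    broken by higher molecular weight, then by lexicographically smallest
    canonical SMILES, so the choice is deterministic.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 0:
        raise ValueError("empty molecular graph")
    if len(frags) == 1:
        return frags[0]
    return min(
        frags,
        key=lambda f: (-f.GetNumHeavyAtoms(), -Descriptors.MolWt(f), Chem.MolToSmiles(f)),
    )


def check_elements(mol: Chem.Mol, whitelist: frozenset = ELEMENT_WHITELIST) -> bool:
    """True iff every atom's element is in the organic whitelist."""
    return all(atom.GetSymbol() in whitelist for atom in mol.GetAtoms())


def check_mw(
    mol: Chem.Mol, min_mw: float = DEFAULT_MIN_MW, max_mw: float = DEFAULT_MAX_MW
) -> bool:
    """True iff average molecular weight lies in [min_mw, max_mw] (inclusive)."""
    return min_mw <= Descriptors.MolWt(mol) <= max_mw


_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMERIZER = rdMolStandardize.TautomerEnumerator()


def neutralize_and_merge_tautomer(mol: Chem.Mol) -> Chem.Mol:
    """Neutralize protonation states and map to the canonical tautomer.

    Charges that cannot be removed by (de)protonation (e.g. quaternary
    ammonium) are retained.  The composition with the tautomer canonicalizer
    is idempotent: re-applying it to its own output is a no-op.
    """
    neutral = _UNCHARGER.uncharge(mol)
    return _TAUTOMERIZER.Canonicalize(neutral)


def strip_stereo(mol: Chem.Mol) -> Chem.Mol:
    """Remove all tetrahedral and double-bond stereo descriptors."""
    out = Chem.Mol(mol)
    Chem.RemoveStereochemistry(out)
    return out


def standardize_mol(
    mol: Chem.Mol,
    min_mw: float = DEFAULT_MIN_MW,
    max_mw: float = DEFAULT_MAX_MW,
) -> tuple[Optional[ParentMolecule], str]:
    """Run the post-parse pipeline on one molecule.

    Returns ``(parent, status)`` where status is one of ``"ok"``,
    ``"element_rejected"``, ``"mw_rejected"``; parent is ``None`` on reject.
    """
    parent = strip_minor_components(mol)
    if not check_elements(parent):
        return None, "element_rejected"
    parent = neutralize_and_merge_tautomer(parent)
    parent = strip_stereo(parent)
    canonical = Chem.MolToSmiles(parent)
    # round-trip so downstream atom numbering matches the canonical form
    parent = Chem.MolFromSmiles(canonical)
    if parent is None:  # pragma: no cover - canonical SMILES always reparse
        return None, "element_rejected"
    mw = Descriptors.MolWt(parent)
    if not (min_mw <= mw <= max_mw):
        return None, "mw_rejected"
    return ParentMolecule(mol=parent, canonical_smiles=canonical, mw=mw), "ok"


def standardize_library(
    records: Iterable[RawRecord],
    min_mw: float = DEFAULT_MIN_MW,
    max_mw: float = DEFAULT_MAX_MW,
) -> tuple[list[ParentMolecule], StandardizationReport]:
    """Standardize a library of raw records with full accounting.

    Failures are tallied, never raised, so large-library runs always
    complete.  The output contains no duplicate canonical SMILES; the first
    occurrence wins.
    """
    report = StandardizationReport()
    seen: dict[str, str] = {}  # canonical smiles -> source_id of keeper
    parents: list[ParentMolecule] = []
    for record in records:
        report.n_input += 1
        mol = parse_record(record)
        if mol is None:
            report.n_parse_failed += 1
            report.rows.append((record.source_id, record.smiles, "", "parse_failed", ""))
            continue
        n_frags = len(Chem.GetMolFrags(mol))
        if n_frags > 1:
            report.n_salt_stripped += 1
        parent, status = standardize_mol(mol, min_mw=min_mw, max_mw=max_mw)
        if parent is None:
            if status == "element_rejected":
                report.n_element_rejected += 1
            else:
                report.n_mw_rejected += 1
            report.rows.append((record.source_id, record.smiles, "", "rejected", status))
            continue
        if parent.canonical_smiles in seen:
            report.n_duplicates_removed += 1
            report.rows.append(
                (
                    record.source_id,
                    record.smiles,
                    parent.canonical_smiles,
                    "duplicate",
                    f"kept:{seen[parent.canonical_smiles]}",
                )
            )
            continue
        seen[parent.canonical_smiles] = record.source_id
        parents.append(
            ParentMolecule(
                mol=parent.mol,
                canonical_smiles=parent.canonical_smiles,
                mw=parent.mw,
                source_id=record.source_id,
                name=record.name,
            )
        )
        report.rows.append(
            (record.source_id, record.smiles, parent.canonical_smiles, "ok", "")
        )
    report.n_output = len(parents)
    report.check()
    return parents, report


class MoleculeStandardizer:
    """Callable wrapper around :func:`standardize_library` holding the
    molecular-weight window as configuration."""

    def __init__(self, min_mw: float = DEFAULT_MIN_MW, max_mw: float = DEFAULT_MAX_MW):
        self.min_mw = min_mw
        self.max_mw = max_mw

    def __call__(
        self, records: Sequence[RawRecord]
    ) -> tuple[list[ParentMolecule], StandardizationReport]:
        return standardize_library(records, min_mw=self.min_mw, max_mw=self.max_mw)


def parent_from_smiles(smiles: str, source_id: str = "") -> ParentMolecule:
    """Standardize a single SMILES; raises ValueError on any rejection."""
    mols, report = standardize_library([RawRecord(source_id or smiles, smiles)])
    if not mols:
        raise ValueError(f"molecule rejected during standardization: {smiles!r}")
    return mols[0]
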