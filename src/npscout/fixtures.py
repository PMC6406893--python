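"""Synthetic toy corpora with planted class-discriminative chemistry.

Real NP/SM reference corpora are large licensed collections; the generator
here builds download-free stand-ins that reproduce the *statistical
contrasts* the classifier exploits, not realistic natural products:

* NP-like molecules are assembled from oxygen-rich, nitrogen-free aliphatic
  scaffolds (sugar-like pyranoses, lactones, fused/spiro carbocycles) with
  seeded random decoration, and carry at least two stereocenter-capable
  carbons — high oxygen count, high chirality, zero nitrogen, low
  element-distribution entropy.
* SM-like molecules are assembled from aromatic amine / amide / sulfonamide
  scaffolds and carry at least two nitrogen atoms — nitrogen-rich, flat,
  achiral.

At ``noise_rate`` > 0 a fraction of each class is replaced by motif-free
decoys (plain alkyl benzenes / cyclohexanes) so classifier tests assert
thresholds rather than perfection.  All emitted records are standardized
parents by construction: the generator runs its assemblies through the full
standardization pipeline and emits the surviving canonical SMILES, so
re-standardizing a fixture corpus is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger

from .datasets import NP, SM, LabeledLibrary
from .standardize import ParentMolecule, RawRecord, standardize_library

NP_SCAFFOLDS = [
    "OC1OC(CO)C(O)C(O)C1O",  # pyranose
    "CC1CCC(=O)O1",  # gamma-valerolactone
    "O=C1CCCCCO1",  # epsilon-caprolactone
    "CC1CCC2CCCCC2C1",  # methyldecalin
    "CC12CCC(CC1)C(C)(C)O2",  # bicyclic terpenoid ether
    "OC1CCC2(CCCCC2)O1",  # spiro hydroxy-tetrahydrofuran
]
NP_SUBSTITUENTS = [
    "O", "CO", "OC", "C", "CC", "OC(C)=O", "C(C)C", "CCO", "C(=O)O", "CCC",
]

SM_SCAFFOLDS = [
    "Nc1ccccc1",  # aniline
    "c1ccncc1",  # pyridine
    "c1cncnc1",  # pyrimidine
    "O=C(Nc1ccccc1)c1ccccc1",  # benzanilide
    "NS(=O)(=O)c1ccccc1",  # benzenesulfonamide
    "c1ccc2[nH]ccc2c1",  # indole
    "c1ccc(-c2ccccc2)cc1",  # biphenyl
]
SM_SUBSTITUENTS = [
    "F", "Cl", "C", "OC", "N(C)C", "C#N", "C(F)(F)F", "C(N)=O", "N1CCOCC1", "CN",
]
SM_N_SUBSTITUENTS = ["N(C)C", "C#N", "C(N)=O", "N1CCOCC1", "CN"]

DECOY_SCAFFOLDS = ["c1ccccc1", "C1CCCCC1", "C1CCOC1"]
DECOY_SUBSTITUENTS = ["C", "CC", "CCC", "CCCC", "OC", "OCC", "CCCCC"]


@dataclass
class FixtureSpec:
    n_np: int
    n_sm: int
    seed: int = 0
    noise_rate: float = 0.05
    planted_np_motifs: list = field(default_factory=lambda: list(NP_SCAFFOLDS))
    planted_sm_motifs: list = field(default_factory=lambda: list(SM_SCAFFOLDS))


def _attach(core: Chem.Mol, sub_smiles: str, position: int):
    """Bond a substituent fragment onto a scaffold atom; None if invalid."""
    sub = Chem.MolFromSmiles(sub_smiles)
    combo = Chem.RWMol(Chem.CombineMols(core, sub))
    combo.AddBond(position, core.GetNumAtoms(), Chem.BondType.SINGLE)
    mol = combo.GetMol()
    RDLogger.DisableLog("rdApp.error")
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    finally:
        RDLogger.EnableLog("rdApp.error")
    return mol


def _open_positions(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetTotalNumHs() >= 1 and a.GetSymbol() in ("C", "N")
    ]


def _assemble(
    rng: np.random.Generator,
    scaffolds: list[str],
    substituents: list[str],
    forced_substituents: int = 0,
    forced_pool: list[str] | None = None,
    n_extra: tuple[int, int] = (1, 5),
) -> Chem.Mol | None:
    scaffold = scaffolds[int(rng.integers(len(scaffolds)))]
    mol = Chem.MolFromSmiles(scaffold)
    n_sub = int(rng.integers(n_extra[0], n_extra[1] + 1))
    picks = [ (forced_pool or substituents)[int(rng.integers(len(forced_pool or substituents)))]
              for _ in range(forced_substituents) ]
    picks += [ substituents[int(rng.integers(len(substituents)))]
               for _ in range(max(0, n_sub - forced_substituents)) ]
    for sub in picks:
        positions = _open_positions(mol)
        if not positions:
            return None
        pos = int(positions[int(rng.integers(len(positions)))])
        grown = _attach(mol, sub, pos)
        if grown is None:
            continue
        mol = grown
    return mol


def _n_nitrogen(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "N")


def _n_chiral_capable(mol: Chem.Mol) -> int:
    return len(
        Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
    )


def _generate_class(
    rng: np.random.Generator,
    n: int,
    kind: str,
    seen: set,
    max_batches: int = 200,
) -> list[ParentMolecule]:
    """Generate ``n`` distinct standardized parents satisfying ``kind`` rules."""
    out: list[ParentMolecule] = []
    batch_no = 0
    while len(out) < n and batch_no < max_batches:
        batch_no += 1
        candidates = []
        for _ in range(2 * (n - len(out)) + 8):
            if kind == "np":
                mol = _assemble(rng, NP_SCAFFOLDS, NP_SUBSTITUENTS, n_extra=(1, 5))
            elif kind == "sm":
                mol = _assemble(
                    rng,
                    SM_SCAFFOLDS,
                    SM_SUBSTITUENTS,
                    forced_substituents=1,
                    forced_pool=SM_N_SUBSTITUENTS,
                    n_extra=(2, 5),
                )
            else:  # decoy
                mol = _assemble(rng, DECOY_SCAFFOLDS, DECOY_SUBSTITUENTS, n_extra=(3, 6))
            if mol is not None:
                candidates.append(Chem.MolToSmiles(mol))
        records = [RawRecord(f"{kind}-{batch_no}-{i}", smi) for i, smi in enumerate(candidates)]
        parents, _report = standardize_library(records)
        for parent in parents:
            if parent.canonical_smiles in seen:
                continue
            m = parent.mol
            if kind == "np" and (_n_nitrogen(m) > 0 or _n_chiral_capable(m) < 2):
                continue
            if kind == "sm" and _n_nitrogen(m) < 2:
                continue
            seen.add(parent.canonical_smiles)
            out.append(parent)
            if len(out) == n:
                break
    if len(out) < n:
        raise RuntimeError(f"fixture grammar exhausted: got {len(out)}/{n} {kind}")
    return out


def make_corpus(spec: FixtureSpec) -> tuple[list[RawRecord], list[RawRecord]]:
    """Generate (np_records, sm_records), standardization-stable by construction."""
    lib = make_labeled_library(spec)
    np_records = [
        RawRecord(f"np-{i}", m.canonical_smiles)
        for i, m in enumerate(lib.molecules)
        if lib.labels[i] == NP
    ]
    sm_records = [
        RawRecord(f"sm-{i}", m.canonical_smiles)
        for i, m in enumerate(lib.molecules)
        if lib.labels[i] == SM
    ]
    return np_records, sm_records


def make_labeled_library(spec: FixtureSpec) -> LabeledLibrary:
    """Generate the corpus directly as standardized parents with labels."""
    if spec.n_np <= 0 or spec.n_sm <= 0:
        raise ValueError("n_np and n_sm must be positive")
    rng = np.random.default_rng(spec.seed)
    seen: set = set()
    n_np_decoy = int(round(spec.noise_rate * spec.n_np))
    n_sm_decoy = int(round(spec.noise_rate * spec.n_sm))
    np_mols = _generate_class(rng, spec.n_np - n_np_decoy, "np", seen)
    sm_mols = _generate_class(rng, spec.n_sm - n_sm_decoy, "sm", seen)
    np_decoys = _generate_class(rng, n_np_decoy, "decoy", seen) if n_np_decoy else []
    sm_decoys = _generate_class(rng, n_sm_decoy, "decoy", seen) if n_sm_decoy else []
    molecules = np_mols + np_decoys + sm_mols + sm_decoys
    labels = np.array(
        [NP] * (len(np_mols) + len(np_decoys)) + [SM] * (len(sm_mols) + len(sm_decoys)),
        dtype=int,
    )
    return LabeledLibrary(molecules=molecules, labels=labels)


# ---------------------------------------------------------------------------
# edge cases


def make_edge_cases() -> list[tuple[RawRecord, str]]:
    """Labeled records exercising each standardization filter.

    Returns ``(record, expected)`` pairs where expected is one of
    ``ok | salt_ok | parse_failed | element_rejected | mw_rejected |
    duplicate``.
    """
    long_chain = "C" * 120  # ~1685 Da alkane
    return [
        (RawRecord("salt", "COc1ccc2cc(C(C)C(=O)[O-])ccc2c1.[Na+]"), "salt_ok"),
        (RawRecord("organometallic", "CC[Fe]CC(=O)c1ccccc1"), "element_rejected"),
        (RawRecord("too_light", "CCO"), "mw_rejected"),
        (RawRecord("too_heavy", long_chain), "mw_rejected"),
        (RawRecord("keto", "O=C(CC(=O)c1ccccc1)c1ccccc1"), "ok"),
        (RawRecord("enol", "OC(=CC(=O)c1ccccc1)c1ccccc1"), "duplicate"),
        (RawRecord("stereo_R", "C[C@H](O)c1ccc(CCCCCC)cc1"), "ok"),
        (RawRecord("stereo_S", "C[C@@H](O)c1ccc(CCCCCC)cc1"), "duplicate"),
        (RawRecord("malformed", "C1CC"), "parse_failed"),
    ]


# ---------------------------------------------------------------------------
# planted attribution set


@dataclass
class PlantedMolecule:
    mol: Chem.Mol
    planted_atoms: list[int]  # indices of the NP-motif atoms
    motif_smiles: str


def make_planted_attribution_set(seed: int, n: int = 20) -> list[PlantedMolecule]:
    """SM-like scaffolds with one embedded NP motif and its atom indices.

    Each molecule grafts a sugar-like polyol ring (an NP-class motif) onto an
    aromatic nitrogen-bearing frame, emulating natural-product derivatives
    whose attribution maps mix NP-like and SM-like regions.  Atom indices of
    the grafted motif are recorded; the returned Mol objects must be used
    as-is (re-canonicalization would renumber atoms).
    """
    rng = np.random.default_rng(seed)
    motif = "OC1OC(CO)C(O)C(O)C1O"
    out: list[PlantedMolecule] = []
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        frame = _assemble(
            rng,
            SM_SCAFFOLDS,
            SM_SUBSTITUENTS,
            forced_substituents=1,
            forced_pool=SM_N_SUBSTITUENTS,
            n_extra=(2, 4),
        )
        if frame is None or _n_nitrogen(frame) < 2:
            continue
        positions = [
            a.GetIdx()
            for a in frame.GetAtoms()
            if a.GetTotalNumHs() >= 1 and a.GetSymbol() == "C"
        ]
        if not positions:
            continue
        pos = int(positions[int(rng.integers(len(positions)))])
        n_frame = frame.GetNumAtoms()
        planted = _attach(frame, motif, pos)
        if planted is None:
            continue
        motif_atoms = list(range(n_frame, planted.GetNumAtoms()))
        out.append(
            PlantedMolecule(mol=planted, planted_atoms=motif_atoms, motif_smiles=motif)
        )
    if len(out) < n:
        raise RuntimeError("could not build planted attribution set")
    return out
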