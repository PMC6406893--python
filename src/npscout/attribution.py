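"""Per-atom attribution of the NP class probability ("similarity maps").

For a Morgan2-1024 random-forest model, each heavy atom's weight is the drop
in predicted NP probability when every fingerprint environment *centered* on
that atom is removed from the bit vector::

    weight_i = P(NP | full fingerprint) - P(NP | fingerprint without atom i)

Bits that are also supported by environments centered on other atoms are
retained, so masking never invents bits and weights stay fine-grained.
Positive weights (atom pushes the call toward NP) render green; negative
weights (toward SM) render orange, with shading scaled by the molecule's
maximum absolute weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Draw import rdMolDraw2D

from .features import BitFingerprint, FingerprintKind, MolLike, as_mol

GREEN = (0.0, 0.8, 0.0)
ORANGE = (1.0, 0.55, 0.0)

_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


@dataclass
class AtomWeightVector:
    """Signed per-heavy-atom contributions to the NP class probability."""

    molecule_id: str
    weights: np.ndarray
    base_probability: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("atom weights must be finite")


def morgan2_bit_info(mol: MolLike) -> tuple[frozenset, dict]:
    """Morgan2-1024 on-bits plus bit -> ((atom, radius), ...) provenance."""
    m = as_mol(mol)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    bv = _GEN.GetFingerprint(m, additionalOutput=ao)
    return frozenset(bv.GetOnBits()), dict(ao.GetBitInfoMap())


def fingerprint_without_atom(
    mol: MolLike, atom_index: int, mode: str = "centered"
) -> BitFingerprint:
    """Morgan2 fingerprint with one atom's environments masked out.

    ``mode="centered"`` (default, the established similarity-map convention)
    removes only the bits whose every environment is centered on the atom;
    ``mode="containing"`` also removes bits from environments that merely
    contain the atom.
    """
    m = as_mol(mol)
    if not (0 <= atom_index < m.GetNumAtoms()):
        raise IndexError(f"atom index {atom_index} out of range")
    bits, info = morgan2_bit_info(m)
    if mode == "centered":
        kept = {
            b
            for b in bits
            if any(center != atom_index for center, _radius in info.get(b, ()))
        }
    elif mode == "containing":
        kept = set()
        for b in bits:
            for center, radius in info.get(b, ()):
                env = Chem.FindAtomEnvironmentOfRadiusN(m, radius, center, False, False)
                atoms = {center}
                for bond_idx in env:
                    bond = m.GetBondWithIdx(bond_idx)
                    atoms.add(bond.GetBeginAtomIdx())
                    atoms.add(bond.GetEndAtomIdx())
                if atom_index not in atoms:
                    kept.add(b)
                    break
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return BitFingerprint(kind=FingerprintKind.MORGAN2_1024, bits=frozenset(kept))


def atom_probability_weights(
    model, mol: MolLike, molecule_id: str = "", mode: str = "centered"
) -> AtomWeightVector:
    """Per-atom NP-probability drops under atom masking.

    ``model`` must expose ``predict_np_probability`` over 1024-bit Morgan2
    vectors (its ``feature_set`` must be ``"morgan2"`` when declared).
    """
    feature_set = getattr(model, "feature_set", "morgan2")
    if feature_set != "morgan2":
        raise ValueError(
            f"similarity maps require a morgan2 model, got feature_set={feature_set!r}"
        )
    m = as_mol(mol)
    bits, _ = morgan2_bit_info(m)
    full = BitFingerprint(kind=FingerprintKind.MORGAN2_1024, bits=bits)
    n = m.GetNumAtoms()
    rows = np.vstack(
        [full.to_array()]
        + [fingerprint_without_atom(m, i, mode=mode).to_array() for i in range(n)]
    )
    probs = np.asarray(model.predict_np_probability(rows), dtype=float)
    base = float(probs[0])
    weights = base - probs[1:]
    return AtomWeightVector(
        molecule_id=molecule_id, weights=weights, base_probability=base
    )


def atom_color_table(
    weights: np.ndarray, max_abs: Optional[float] = None
) -> list[Optional[tuple]]:
    """Map signed weights to RGBA highlight colors.

    Positive -> green, negative -> orange, alpha proportional to
    |weight| / max|weight| (per-molecule scaling by default; pass ``max_abs``
    for an absolute scale).  Zero weights map to ``None`` (unshaded).
    """
    weights = np.asarray(weights, dtype=float)
    scale = max_abs if max_abs is not None else float(np.max(np.abs(weights), initial=0.0))
    table: list[Optional[tuple]] = []
    for w in weights:
        if scale == 0.0 or w == 0.0:
            table.append(None)
            continue
        alpha = min(1.0, abs(w) / scale)
        rgb = GREEN if w > 0 else ORANGE
        table.append((rgb[0], rgb[1], rgb[2], alpha))
    return table


def render_similarity_map(
    mol: MolLike,
    weights: np.ndarray,
    fmt: str = "svg",
    size: tuple[int, int] = (400, 400),
    max_abs: Optional[float] = None,
) -> bytes:
    """Render a 2D depiction with atoms shaded by attribution weight.

    Returns SVG (text) or PNG bytes.  All-zero weight vectors render an
    unshaded depiction.
    """
    m = Chem.Mol(as_mol(mol))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != m.GetNumAtoms():
        raise ValueError("weights length does not match heavy-atom count")
    colors = atom_color_table(weights, max_abs=max_abs)
    highlight_atoms = [i for i, c in enumerate(colors) if c is not None]
    highlight_colors = {i: colors[i] for i in highlight_atoms}
    if fmt == "svg":
        drawer = rdMolDraw2D.MolDraw2DSVG(*size)
    elif fmt == "png":
        drawer = rdMolDraw2D.MolDraw2DCairo(*size)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer,
        m,
        highlightAtoms=highlight_atoms,
        highlightAtomColors=highlight_colors,
    )
    drawer.FinishDrawing()
    out = drawer.GetDrawingText()
    return out.encode() if isinstance(out, str) else out
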