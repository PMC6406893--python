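"""Readers and writers for molecule libraries and run artifacts.

SMILES files hold one record per line — SMILES, then an optional
whitespace-separated name.  SDF (V2000) input is parsed with RDKit's
supplier and converted to SMILES records.  Standardization reports are
written as CSV audit trails.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Union

from rdkit import Chem

from .standardize import ParentMolecule, RawRecord, StandardizationReport


def read_smiles_file(path: Union[str, Path]) -> list[RawRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else None
            records.append(RawRecord(source_id=f"line{lineno}", smiles=smiles, name=name))
    return records


def read_sdf(path: Union[str, Path]) -> list[RawRecord]:
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            # preserve the failure so standardization tallies it
            records.append(RawRecord(source_id=f"sdf{i}", smiles="*invalid*"))
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else None
        records.append(
            RawRecord(source_id=f"sdf{i}", smiles=Chem.MolToSmiles(mol), name=name or None)
        )
    return records


def read_library(path: Union[str, Path]) -> list[RawRecord]:
    """Dispatch on extension: .sdf via RDKit supplier, anything else as SMILES."""
    if str(path).lower().endswith(".sdf"):
        return read_sdf(path)
    return read_smiles_file(path)


def write_smiles_file(molecules: Iterable[ParentMolecule], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for m in molecules:
            label = m.name or m.source_id
            fh.write(f"{m.canonical_smiles}\t{label}\n" if label else f"{m.canonical_smiles}\n")


def write_report_csv(report: StandardizationReport, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "input_smiles", "parent_smiles", "status", "reject_reason"])
        writer.writerows(report.rows)
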