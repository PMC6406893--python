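"""Standardization pipeline: parsing, salt stripping, filters, dedup, audit."""

import numpy as np
import pytest
from rdkit import Chem

from npscout.standardize import (
    RawRecord,
    check_elements,
    check_mw,
    neutralize_and_merge_tautomer,
    parse_record,
    standardize_library,
    strip_minor_components,
    strip_stereo,
)


def canon(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


class TestParse:
    def test_valid_aromatic(self):
        mol = parse_record(RawRecord("a", "c1ccccc1O"))
        assert mol is not None and mol.GetNumHeavyAtoms() == 7

    @pytest.mark.parametrize("bad", ["C1CC", "not_a_smiles", "C(C"])
    def test_malformed_returns_none(self, bad):
        assert parse_record(RawRecord("b", bad)) is None

    def test_batch_counts_failures(self, clean_library):
        records = [
            RawRecord(f"ok{i}", m.canonical_smiles)
            for i, m in enumerate(clean_library.molecules[:100])
        ] + [RawRecord(f"bad{i}", "C1CC") for i in range(5)]
        _, report = standardize_library(records)
        assert report.n_parse_failed == 5
        assert report.n_output == 100


class TestSaltStripping:
    def test_sodium_acetate_keeps_acetate(self):
        mol = Chem.MolFromSmiles("CC(=O)[O-].[Na+]")
        parent = strip_minor_components(mol)
        assert Chem.MolToSmiles(parent) == Chem.MolToSmiles(Chem.MolFromSmiles("CC(=O)[O-]"))

    def test_single_fragment_unchanged(self):
        mol = Chem.MolFromSmiles("c1ccccc1")
        assert Chem.MolToSmiles(strip_minor_components(mol)) == "c1ccccc1"

    def test_largest_heavy_atom_fragment_wins(self):
        # 8 vs 3 heavy atoms
        mol = Chem.MolFromSmiles("CCCCCCCC.CCC")
        assert Chem.MolToSmiles(strip_minor_components(mol)) == "CCCCCCCC"

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            strip_minor_components(Chem.MolFromSmiles(""))


class TestElementFilter:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("CC[Fe]CC", False),  # transition metal
            ("OCC1OC(O)C(O)C(O)C1O", True),  # glucose: C,H,O
            ("C[Se]CCC(N)C(=O)O", True),  # selenomethionine: Se allowed
            ("CC[Si](CC)CC", True),  # silicon allowed
        ],
    )
    def test_whitelist(self, smiles, expected):
        assert check_elements(Chem.MolFromSmiles(smiles)) is expected


class TestMwFilter:
    def test_ethanol_below_window(self):
        assert check_mw(Chem.MolFromSmiles("CCO")) is False

    def test_glucose_inside_window(self):
        assert check_mw(Chem.MolFromSmiles("OCC1OC(O)C(O)C(O)C1O")) is True

    def test_boundaries_inclusive(self):
        from rdkit.Chem import Descriptors

        mol = Chem.MolFromSmiles("OCC1OC(O)C(O)C(O)C1O")
        mw = Descriptors.MolWt(mol)
        assert check_mw(mol, min_mw=mw, max_mw=mw) is True


class TestNeutralizeAndTautomer:
    def test_protonated_amine_neutralized(self):
        out = neutralize_and_merge_tautomer(Chem.MolFromSmiles("CC[NH3+]"))
        assert Chem.MolToSmiles(out) == "CCN"

    def test_keto_enol_merge(self):
        keto = neutralize_and_merge_tautomer(
            Chem.MolFromSmiles("O=C(CC(=O)c1ccccc1)c1ccccc1")
        )
        enol = neutralize_and_merge_tautomer(
            Chem.MolFromSmiles("OC(=CC(=O)c1ccccc1)c1ccccc1")
        )
        assert Chem.MolToSmiles(keto) == Chem.MolToSmiles(enol)

    def test_idempotent(self):
        once = neutralize_and_merge_tautomer(Chem.MolFromSmiles("CC(O)=CC(C)=O"))
        twice = neutralize_and_merge_tautomer(once)
        assert Chem.MolToSmiles(once) == Chem.MolToSmiles(twice)

    def test_quaternary_nitrogen_keeps_charge(self):
        out = neutralize_and_merge_tautomer(Chem.MolFromSmiles("C[N+](C)(C)C"))
        assert any(a.GetFormalCharge() == 1 for a in out.GetAtoms())


class TestStereoStripping:
    @pytest.mark.parametrize(
        "a,b",
        [
            ("C[C@H](N)C(=O)O", "C[C@@H](N)C(=O)O"),
            ("C/C=C/C", "C/C=C\\C"),
        ],
    )
    def test_stereo_pairs_collapse(self, a, b):
        sa = Chem.MolToSmiles(strip_stereo(Chem.MolFromSmiles(a)))
        sb = Chem.MolToSmiles(strip_stereo(Chem.MolFromSmiles(b)))
        assert sa == sb

    def test_achiral_unchanged(self):
        assert Chem.MolToSmiles(strip_stereo(Chem.MolFromSmiles("CCO"))) == "CCO"


class TestLibraryPipeline:
    def test_stereoisomer_pairs_deduplicate(self, clean_library):
        base = [m.canonical_smiles for m in clean_library.molecules[:46]]
        records = [RawRecord(f"r{i}", s) for i, s in enumerate(base)]
        records.append(RawRecord("iso1a", "C[C@H](O)c1ccc(CCCCCC)cc1"))
        records.append(RawRecord("iso1b", "C[C@@H](O)c1ccc(CCCCCC)cc1"))
        records.append(RawRecord("iso2a", "CC(=O)O[C@H]1CC[C@H](CCCC)CC1"))
        records.append(RawRecord("iso2b", "CC(=O)O[C@@H]1CC[C@H](CCCC)CC1"))
        mols, report = standardize_library(records)
        assert len(records) == 50
        assert len(mols) == 48
        assert report.n_duplicates_removed == 2

    def test_planted_rejects_counted(self, clean_library):
        records = [
            RawRecord(f"r{i}", m.canonical_smiles)
            for i, m in enumerate(clean_library.molecules[:10])
        ]
        records.append(RawRecord("fe", "CC[Fe]CC(=O)c1ccccc1"))
        records.append(RawRecord("light", "OCC(O)CO"))  # glycerol, MW 92
        _, report = standardize_library(records)
        assert report.n_element_rejected == 1
        assert report.n_mw_rejected == 1

    def test_empty_input(self):
        mols, report = standardize_library([])
        assert mols == [] and report.n_input == 0 and report.n_output == 0

    def test_idempotence(self, small_library):
        records = [
            RawRecord(f"r{i}", m.canonical_smiles)
            for i, m in enumerate(small_library.molecules[:100])
        ]
        mols, report = standardize_library(records)
        assert report.n_output == report.n_input == 100
        assert [m.canonical_smiles for m in mols] == [r.smiles for r in records]

    def test_permutation_invariance(self, clean_library):
        records = [
            RawRecord(f"r{i}", m.canonical_smiles)
            for i, m in enumerate(clean_library.molecules[:40])
        ]
        shuffled = list(records)
        np.random.default_rng(0).shuffle(shuffled)
        out1, _ = standardize_library(records)
        out2, _ = standardize_library(shuffled)
        assert {m.canonical_smiles for m in out1} == {m.canonical_smiles for m in out2}

    def test_report_conservation(self, clean_library):
        records = [RawRecord("dup1", clean_library.molecules[0].canonical_smiles)] * 3
        records += [RawRecord("bad", "C1CC"), RawRecord("light", "CCO")]
        _, report = standardize_library(records)
        report.check()  # raises on violation
        assert (
            report.n_output
            == report.n_input
            - report.n_parse_failed
            - report.n_element_rejected
            - report.n_mw_rejected
            - report.n_duplicates_removed
        )

    def test_no_stereo_in_output(self, small_library):
        for m in small_library.molecules[:50]:
            assert "@" not in m.canonical_smiles
            assert "/" not in m.canonical_smiles
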