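"""SMILES construction: vocabulary, fragment surgery, assembly, bookkeeping.

Reference structures are taken from, or assembled out of, Chemical Component
Dictionary entries — a route entirely independent of the package's
string-surgery implementation — and compared by InChIKey.
"""

import re
from collections import Counter

import pytest
from rdkit import Chem
from rdkit.Chem.Descriptors import ExactMolWt
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

from phospep import (
    Linkage,
    ModChain,
    SmilesBuildError,
    ValidationFailedError,
    apply_mod_chain,
    assemble,
    chain_fragment,
    formula_and_mass,
    parse,
    residue_smiles,
    to_smiles,
    verify_roundtrip,
    vocabulary,
)
from phospep.structure import allowed_sites

#: vocabulary key -> CCD component id of the identical free amino acid
CCD_COMPONENTS = {
    "G": "GLY", "A": "ALA", "V": "VAL", "L": "LEU", "I": "ILE", "P": "PRO",
    "F": "PHE", "W": "TRP", "M": "MET", "S": "SER", "T": "THR", "C": "CYS",
    "Y": "TYR", "N": "ASN", "Q": "GLN", "D": "ASP", "E": "GLU", "K": "LYS",
    "R": "ARG", "H": "HIS", "U": "SEC", "O": "PYL",
    "Hyp3(S)": "HY3", "Hyp4(R)": "HYP", "Hyl5(R)": "LYZ",
    # D-enantiomers with CCD counterparts
    "a": "DAL", "s": "DSN", "t": "DTH", "p": "DPR", "w": "DTR",
}

E, A = Linkage.ESTER, Linkage.AMIDE


def mol_key(mol) -> str:
    return Chem.MolToInchiKey(mol)


# ---------------------------------------------------------------------------
# vocabulary integrity


@pytest.mark.parametrize("key, ccd", sorted(CCD_COMPONENTS.items()))
def test_vocabulary_matches_ccd_reference(key, ccd, ccd_mol):
    """Each arranged SMILES denotes the same structure as the CCD component."""
    assert verify_roundtrip(residue_smiles(key).smiles) == mol_key(ccd_mol(ccd))


def test_arrangement_convention():
    """Amine first, carboxyl last; recognition patterns unique per residue."""
    for key, entry in sorted(vocabulary().items()):
        assert entry.smiles.startswith("N")
        assert entry.smiles.endswith("C(=O)O")
        patterns = [a.pattern for a in entry.attachments.values()]
        assert len(patterns) == len(set(patterns))
        for p in patterns:
            assert entry.smiles.count(p) == 1


def test_attachment_sites_agree_with_computed_site_table():
    """The SMILES-side attachment points cover exactly the allowed sites."""
    for key, entry in sorted(vocabulary().items()):
        assert set(entry.attachments) == set(allowed_sites(key))


def test_d_enantiomer_differs_only_in_stereo():
    l, d = residue_smiles("T"), residue_smiles("t")
    ml, md = Chem.MolFromSmiles(l.smiles), Chem.MolFromSmiles(d.smiles)
    assert CalcMolFormula(ml) == CalcMolFormula(md)
    assert mol_key(ml) != mol_key(md)
    assert mol_key(ml).split("-")[0] == mol_key(md).split("-")[0]  # same skeleton


def test_rearrangement_preserves_identity():
    """Identifier round-trip: atom order does not change the structure."""
    assert verify_roundtrip("NCC(=O)O") == verify_roundtrip("OC(=O)CN")


def test_unparsable_smiles_is_a_hard_failure():
    with pytest.raises(SmilesBuildError):
        verify_roundtrip("C(((")


# ---------------------------------------------------------------------------
# phosphate-chain grafting


class TestApplyModChain:
    def test_single_phosphate_after_threonine_hydroxyl(self):
        out = apply_mod_chain(residue_smiles("T"), 3, ModChain(1))
        assert out == "N[C@@H]([C@H](OP(=O)(O)O)C)C(=O)O"

    def test_diphosphate_extends_the_first_unit(self):
        out = apply_mod_chain(residue_smiles("T"), 3, ModChain(2, (E,)))
        assert "P(=O)(O)OP(=O)(O)O" in out

    def test_branch_amide_rewrites_the_inner_unit(self):
        out = apply_mod_chain(residue_smiles("T"), 3, ModChain(2, (E,), frozenset({0})))
        assert "P(=O)(N)OP(=O)(O)O" in out

    def test_amide_linkage_bridges_with_nitrogen(self):
        out = apply_mod_chain(residue_smiles("S"), 3, ModChain(2, (A,)))
        assert "P(=O)(O)NP(=O)(O)O" in out

    def test_terminal_amide_swaps_one_oxygen_for_nitrogen(self):
        plain = apply_mod_chain(residue_smiles("S"), 3, ModChain(1))
        amide = apply_mod_chain(residue_smiles("S"), 3, ModChain(1, terminal_amide=True))
        assert plain.count("P") == amide.count("P") == 1
        assert plain.count("O") == amide.count("O") + 1
        assert amide.count("N") == plain.count("N") + 1

    def test_site_without_attachment_point(self):
        with pytest.raises(SmilesBuildError):
            apply_mod_chain(residue_smiles("A"), 3, ModChain(1))

    @pytest.mark.parametrize(
        "key, text, ccd",
        [("T", "T[3*]", "TPO"), ("S", "S[3*]", "SEP"), ("Y", "Y[7*]", "PTR")],
    )
    def test_phosphoresidues_match_ccd_references(self, key, text, ccd, ccd_mol):
        assert verify_roundtrip(to_smiles(text).smiles) == mol_key(ccd_mol(ccd))


def test_chain_fragment_shapes():
    assert chain_fragment(ModChain(1)) == "P(=O)(O)O"
    assert chain_fragment(ModChain(2, (E,))) == "P(=O)(O)OP(=O)(O)O"
    assert chain_fragment(ModChain(2, (A,))) == "P(=O)(O)NP(=O)(O)O"
    assert chain_fragment(ModChain(2, (E,), frozenset({0}))) == "P(=O)(N)OP(=O)(O)O"
    assert chain_fragment(ModChain(2, (E,), terminal_amide=True)) == "P(=O)(O)OP(=O)(O)N"
    assert chain_fragment(ModChain(1, terminal_amide=True)) == "P(=O)(O)N"


# ---------------------------------------------------------------------------
# peptide assembly


class TestAssemble:
    def test_two_glycines(self, ccd_peptide):
        out = assemble(["NCC(=O)O", "NCC(=O)O"])
        assert out == "NCC(=O)NCC(=O)O"
        assert verify_roundtrip(out) == mol_key(ccd_peptide(["GLY", "GLY"]))

    def test_single_residue_unchanged(self):
        assert assemble(["N[C@@H](C)C(=O)O"]) == "N[C@@H](C)C(=O)O"

    def test_c_terminal_amide(self):
        assert assemble(["NCC(=O)O"], [True]) == "NCC(=O)N"

    def test_internal_string_must_end_in_carboxyl(self):
        with pytest.raises(SmilesBuildError):
            assemble(["NCC(=O)N", "NCC(=O)O"])


class TestToSmiles:
    def test_alanine(self):
        assert to_smiles("A").smiles == "N[C@@H](C)C(=O)O"

    def test_one_phosphorus_per_star(self):
        assert to_smiles("AS[3*]G").smiles.count("P") == 1

    def test_worked_tripeptide_against_ccd_assembly(self, ccd_peptide):
        """The amidated-diphosphate tripeptide equals a graph-built reference."""
        from rdkit.Chem import BondType, RWMol

        result = to_smiles("HT[3*[~]*]A")
        mol = Chem.MolFromSmiles(result.smiles)
        assert sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "P") == 2
        p_bonded_n = sum(
            1 for a in mol.GetAtoms()
            if a.GetSymbol() == "N"
            and any(nb.GetSymbol() == "P" for nb in a.GetNeighbors())
        )
        assert p_bonded_n == 1

        # reference: His-Thr-Ala from CCD residues, then build the amidated
        # diphosphate atom-by-atom on the threonine side-chain oxygen
        ref = RWMol(Chem.AddHs(ccd_peptide(["HIS", "THR", "ALA"])))
        og1 = next(
            a for a in ref.GetAtoms()
            if a.HasProp("ccd_name") and a.GetProp("ccd_name") == "OG1"
        )
        h = next(nb for nb in og1.GetNeighbors() if nb.GetSymbol() == "H")
        og1_idx = og1.GetIdx()
        h_idx = h.GetIdx()
        ref.RemoveAtom(h_idx)
        if h_idx < og1_idx:
            og1_idx -= 1

        def add(sym):
            return ref.AddAtom(Chem.Atom(sym))

        p1, o1d, n1 = add("P"), add("O"), add("N")
        bridge = add("O")
        p2, o2d, o2a, o2b = add("P"), add("O"), add("O"), add("O")
        ref.AddBond(og1_idx, p1, BondType.SINGLE)
        ref.AddBond(p1, o1d, BondType.DOUBLE)
        ref.AddBond(p1, n1, BondType.SINGLE)
        ref.AddBond(p1, bridge, BondType.SINGLE)
        ref.AddBond(bridge, p2, BondType.SINGLE)
        ref.AddBond(p2, o2d, BondType.DOUBLE)
        ref.AddBond(p2, o2a, BondType.SINGLE)
        ref.AddBond(p2, o2b, BondType.SINGLE)
        ref_mol = ref.GetMol()
        Chem.SanitizeMol(ref_mol)
        assert verify_roundtrip(result.smiles) == mol_key(ref_mol)

    def test_provenance_log_has_one_fragment_per_residue(self):
        result = to_smiles("AS[3*]G")
        assert [k for k, _ in result.fragments] == ["A", "S", "G"]
        assert result.smiles == assemble([s for _, s in result.fragments])

    def test_strict_mode_refuses_violations(self):
        with pytest.raises(ValidationFailedError):
            to_smiles("AT[4*]G")

    def test_deterministic(self):
        assert to_smiles("HT[3*[~]*]A").smiles == to_smiles("HT[3*[~]*]A").smiles


# ---------------------------------------------------------------------------
# sweeps over the generated corpus


def test_corpus_smiles_parse_with_legal_valences(corpus):
    """Every generated peptide SMILES is accepted by the chemistry backend."""
    for s in corpus:
        result = to_smiles(s)
        assert Chem.MolFromSmiles(result.smiles) is not None, s


def test_phosphate_count_equals_star_count(corpus):
    for s in corpus:
        assert to_smiles(s).smiles.count("P") == s.count("*"), s


def test_output_is_kekule(corpus):
    """No aromatic (lowercase) atom tokens outside bracket atoms."""
    for s in corpus[:200]:
        out = to_smiles(s).smiles
        bare = re.sub(r"\[[^]]*\]", "", out)  # bracket atoms may hold @, Se, H
        assert not re.search(r"[cnosp]", bare), out


def test_formula_accounting_agrees_with_chemistry_backend(corpus):
    """Composition summation equals the formula of the built molecule."""
    for s in corpus[:200]:
        fm = formula_and_mass(s)
        mol = Chem.MolFromSmiles(to_smiles(s).smiles)
        assert fm.formula == CalcMolFormula(mol), s
        assert fm.monoisotopic == pytest.approx(ExactMolWt(mol), abs=1e-4)


# ---------------------------------------------------------------------------
# formula and mass bookkeeping


def test_glycine_formula():
    assert formula_and_mass("G").formula == "C2H5NO2"


def test_condensation_loses_one_water():
    assert formula_and_mass("GG").formula == "C4H8N2O3"


def test_phosphate_delta_is_hpo3():
    d = formula_and_mass("S[3*]").monoisotopic - formula_and_mass("S").monoisotopic
    assert d == pytest.approx(79.96633, abs=1e-5)
    comp_p = dict(formula_and_mass("S[3*]").composition)
    comp = dict(formula_and_mass("S").composition)
    assert {k: comp_p[k] - comp.get(k, 0) for k in comp_p if comp_p[k] != comp.get(k, 0)} == {
        "H": 1, "O": 3, "P": 1,
    }


def test_amide_swaps_o_for_n():
    amide = dict(formula_and_mass("S[3*~]").composition)
    plain = dict(formula_and_mass("S[3*]").composition)
    assert amide["N"] == plain["N"] + 1
    assert amide["O"] == plain["O"] - 1
    assert amide["H"] == plain["H"] + 1


@pytest.mark.parametrize("k", range(1, 11))
def test_glycine_homopolymer_closed_form(k):
    """(Gly)k has formula C_{2k} H_{3k+2} N_k O_{k+1}."""
    fm = formula_and_mass("G" * k)
    expected = Counter({"C": 2 * k, "H": 3 * k + 2, "N": k, "O": k + 1})
    assert Counter(dict(fm.composition)) == expected
    mol = Chem.MolFromSmiles(to_smiles("G" * k).smiles)
    assert CalcMolFormula(mol) == fm.formula
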