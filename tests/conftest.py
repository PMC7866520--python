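"""Shared fixtures: the fixture corpus and CCD-based reference builders.

Reference structures come from the Chemical Component Dictionary bundled
with biotite: an independent source of amino-acid connectivity and 3D
stereochemistry against which vocabulary SMILES strings and assembled
peptides are compared via InChIKey.
"""

from __future__ import annotations

import pytest

from phospep import generate_fixtures

#: fixed corpus seed used across property tests
CORPUS_SEED = 20260930


@pytest.fixture(scope="session")
def corpus() -> list[str]:
    """1000 random valid representations (deterministic)."""
    return generate_fixtures(CORPUS_SEED, 1000)


# ---------------------------------------------------------------------------
# CCD reference construction (independent of the package's string surgery)


def _ccd_raw(code: str):
    """Explicit-H RWMol of a CCD component with 3D-derived stereo tags."""
    import biotite.structure.info as info
    from rdkit import Chem
    from rdkit.Chem import Atom, BondType, Conformer, RWMol

    comp = info.residue(code)
    m = RWMol()
    for el, chg in zip(comp.element, comp.charge):
        a = Atom(el.capitalize())
        a.SetFormalCharge(int(chg))
        a.SetNoImplicit(True)
        m.AddAtom(a)
    bt = {1: BondType.SINGLE, 2: BondType.DOUBLE, 3: BondType.TRIPLE,
          5: BondType.SINGLE, 6: BondType.DOUBLE}
    for i, j, o in comp.bonds.as_array():
        m.AddBond(int(i), int(j), bt.get(int(o), BondType.SINGLE))
    conf = Conformer(m.GetNumAtoms())
    for i, xyz in enumerate(comp.coord):
        conf.SetAtomPosition(i, [float(x) for x in xyz])
    m.AddConformer(conf)
    mol = m.GetMol()
    Chem.SanitizeMol(mol)
    Chem.AssignStereochemistryFrom3D(mol)
    rw = RWMol(mol)
    for idx, name in enumerate(comp.atom_name):
        rw.GetAtomWithIdx(idx).SetProp("ccd_name", str(name))
    return rw


def _neutralize(rw) -> None:
    """Remove one proton from each positively charged N (CCD cation forms)."""
    from rdkit.Chem import RWMol

    while True:
        target = None
        for atom in rw.GetAtoms():
            if atom.GetFormalCharge() == 1 and atom.GetSymbol() == "N":
                hs = [nb for nb in atom.GetNeighbors() if nb.GetSymbol() == "H"]
                if hs:
                    target = (atom.GetIdx(), hs[0].GetIdx())
                    break
        if target is None:
            return
        atom_idx, h_idx = target
        rw.RemoveAtom(h_idx)
        rw.GetAtomWithIdx(atom_idx if atom_idx < h_idx else atom_idx - 1).SetFormalCharge(0)


def _finish(rw):
    from rdkit import Chem

    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


@pytest.fixture(scope="session")
def ccd_mol():
    """Neutral free-amino-acid molecule for a CCD component code."""

    def build(code: str):
        rw = _ccd_raw(code)
        _neutralize(rw)
        return _finish(rw)

    return build


@pytest.fixture(scope="session")
def ccd_peptide():
    """Condense CCD residues into a peptide by explicit graph surgery.

    For each junction the C-terminal hydroxyl (OXT + its H) of residue i is
    removed, one amine hydrogen of residue i+1 is removed, and a C-N single
    bond is formed.  Entirely independent of the package's string assembly.
    """

    def build(codes: list[str]):
        from rdkit import Chem
        from rdkit.Chem import BondType, RWMol

        combined = None
        for code in codes:
            part = _ccd_raw(code).GetMol()
            combined = part if combined is None else Chem.CombineMols(combined, part)
        rw = RWMol(combined)

        def named(tag: str) -> list[int]:
            return [a.GetIdx() for a in rw.GetAtoms()
                    if a.HasProp("ccd_name") and a.GetProp("ccd_name") == tag]

        for junction in range(len(codes) - 1):
            c_idx = named("C")[junction]          # carbonyl C of residue `junction`
            oxt = next(nb for nb in rw.GetAtomWithIdx(c_idx).GetNeighbors()
                       if nb.HasProp("ccd_name") and nb.GetProp("ccd_name") == "OXT")
            n_idx = named("N")[junction + 1]      # amine N of the next residue
            n_atom = rw.GetAtomWithIdx(n_idx)
            n_h = [nb.GetIdx() for nb in n_atom.GetNeighbors() if nb.GetSymbol() == "H"]
            doomed = sorted(
                [oxt.GetIdx(), n_h[-1]]
                + [nb.GetIdx() for nb in oxt.GetNeighbors() if nb.GetSymbol() == "H"],
                reverse=True,
            )
            c_keep, n_keep = c_idx, n_idx
            for d in doomed:
                rw.RemoveAtom(d)
                if d < c_keep:
                    c_keep -= 1
                if d < n_keep:
                    n_keep -= 1
            rw.AddBond(c_keep, n_keep, BondType.SINGLE)
        _neutralize(rw)
        return _finish(rw)

    return build
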