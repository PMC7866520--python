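"""Translation of the phosphopeptide notation into SMILES.

The construction treats each residue's arranged SMILES string as a scaffold
with attachment points located by recognition patterns (unique substrings of
the scaffold).  Building a peptide proceeds residue by residue from the
N-terminus:

1. look the residue up in the vocabulary;
2. graft the phosphate chain of every modification block into the scaffold
   at its site's recognition pattern (after / before / instead of it);
3. concatenate the residue strings: each non-C-terminal ``C(=O)O`` loses its
   final hydroxyl ``O`` and bonds to the next residue's leading amine N —
   the monomer-concatenation scheme used for polymer SMILES assembly;
4. a C-terminal ``~`` rewrites the final ``C(=O)O`` into ``C(=O)N``.

A single phosphate unit is ``P(=O)(O)O``.  Chains grow by appending further
units after the previous one (``P(=O)(O)OP(=O)(O)O`` for a phosphodiester
link; a bridging ``N`` instead of the bridging ``O`` for an amide link); a
branch amide ``[~]`` turns the unit's non-bridging hydroxyl into ``(N)`` and
a trailing ``~`` amidates the final hydroxyl.  Every rewrite is a pure
string operation on the fixed vocabulary strings, made safe by the
load-time guarantee that each recognition pattern occurs exactly once.

Outputs are Kekule, neutral SMILES; phosphorus stereocentres are left
undefined.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache

from .notation import Linkage, ModChain, PeptideRepr, parse
from .structure import build_graph
from .validation import Violation, validate
from .vocabulary import (
    Attachment,
    InsertMode,
    ResidueSmilesEntry,
    get_entry,
)

#: SMILES representation of one phosphate group
PHOSPHATE = "P(=O)(O)O"

_CARBOXYL_TAIL = "C(=O)O"


class SmilesBuildError(ValueError):
    """Construction cannot proceed (corrupt pattern, bad assembly input)."""


class ValidationFailedError(ValueError):
    """Strict conversion refused because the peptide has violations."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        msgs = "; ".join(
            f"residue {v.residue_index}: {v.rule_id}" for v in violations
        )
        super().__init__(f"peptide failed validation: {msgs}")


def residue_smiles(key: str) -> ResidueSmilesEntry:
    """Vocabulary entry (arranged SMILES + attachment points) for ``key``."""
    return get_entry(key)


# ---------------------------------------------------------------------------
# phosphate-chain fragments


def chain_fragment(chain: ModChain) -> str:
    """SMILES fragment of a whole phosphate chain, bridges included.

    The bridging atom written at the end of each non-terminal unit is the
    first atom of the ester/amide link to the next unit; the final unit ends
    in the free hydroxyl (or ``N`` when terminally amidated).
    """
    parts = []
    for i in range(chain.units):
        non_bridging = "N" if i in chain.branch_amide else "O"
        if i < chain.units - 1:
            tail = "N" if chain.linkages[i] is Linkage.AMIDE else "O"
        else:
            tail = "N" if chain.terminal_amide else "O"
        parts.append(f"P(=O)({non_bridging}){tail}")
    return "".join(parts)


def _graft(smiles: str, attachment: Attachment, fragment: str) -> str:
    """Insert ``fragment`` into ``smiles`` at the attachment's pattern."""
    n = smiles.count(attachment.pattern)
    if n != 1:
        raise SmilesBuildError(
            f"recognition pattern {attachment.pattern!r} occurs {n} times "
            f"(vocabulary corrupt or conflicting modifications)"
        )
    insert = attachment.insert.replace("{P}", fragment)
    if attachment.mode is InsertMode.AFTER:
        replacement = attachment.pattern + insert
    elif attachment.mode is InsertMode.BEFORE:
        replacement = insert + attachment.pattern
    else:  # INSTEAD_OF
        replacement = insert
    return smiles.replace(attachment.pattern, replacement)


def apply_mod_chain(entry: ResidueSmilesEntry, site: int, chain: ModChain) -> str:
    """Residue SMILES with the phosphate chain grafted at ``site``."""
    if site not in entry.attachments:
        raise SmilesBuildError(
            f"residue {entry.key!r} has no attachment point at site {site}"
        )
    return _graft(entry.smiles, entry.attachments[site], chain_fragment(chain))


def _modified_residue_smiles(entry: ResidueSmilesEntry,
                             mods: tuple[tuple[int, ModChain], ...]) -> str:
    # apply in descending site order: side-chain grafts first, so the
    # terminal C(=O)O pattern of a site-1 block still matches afterwards
    smiles = entry.smiles
    for site, chain in sorted(mods, key=lambda m: -m[0]):
        if site not in entry.attachments:
            raise SmilesBuildError(
                f"residue {entry.key!r} has no attachment point at site {site}"
            )
        smiles = _graft(smiles, entry.attachments[site], chain_fragment(chain))
    return smiles


# ---------------------------------------------------------------------------
# peptide assembly


def assemble(residue_strings: list[str], c_amide_flags: list[bool] | None = None) -> str:
    """Concatenate arranged residue strings into one peptide SMILES.

    Every non-C-terminal string must end in ``C(=O)O``; its final ``O`` is
    dropped so the carbonyl bonds to the next residue's leading amine N.
    """
    if not residue_strings:
        raise SmilesBuildError("nothing to assemble")
    if c_amide_flags is None:
        c_amide_flags = [False] * len(residue_strings)
    if any(c_amide_flags[:-1]):
        raise SmilesBuildError("alpha-carboxyl amide on a non-C-terminal residue")
    parts = []
    for s in residue_strings[:-1]:
        if not s.endswith(_CARBOXYL_TAIL):
            raise SmilesBuildError(
                f"internal residue string does not end in {_CARBOXYL_TAIL!r}: {s!r}"
            )
        parts.append(s[:-1])  # drop the hydroxyl O of C(=O)O
    last = residue_strings[-1]
    if c_amide_flags[-1]:
        if not last.endswith(_CARBOXYL_TAIL):
            raise SmilesBuildError(
                "cannot amidate a C-terminus that does not end in C(=O)O"
            )
        last = last[: -len(_CARBOXYL_TAIL)] + "C(=O)N"
    parts.append(last)
    return "".join(parts)


@dataclass(frozen=True)
class SmilesResult:
    """Peptide SMILES plus the per-residue strings that were concatenated."""

    smiles: str
    fragments: tuple[tuple[str, str], ...]   # (residue key, grafted string)


def to_smiles(p: PeptideRepr | str, strict: bool = True) -> SmilesResult:
    """Full pipeline: vocabulary lookup, chain grafting, peptide assembly.

    With ``strict=True`` (default) the peptide must validate clean; the
    violations are attached to the raised :class:`ValidationFailedError`.
    """
    if isinstance(p, str):
        p = parse(p)
    if strict:
        violations = validate(p)
        if violations:
            raise ValidationFailedError(violations)
    fragments = []
    for residue in p.residues:
        entry = get_entry(residue.key)
        fragments.append((residue.key, _modified_residue_smiles(entry, residue.mods)))
    smiles = assemble(
        [s for _, s in fragments],
        [r.c_amide for r in p.residues],
    )
    return SmilesResult(smiles=smiles, fragments=tuple(fragments))


# ---------------------------------------------------------------------------
# molecular formula and mass bookkeeping

# monoisotopic and average atomic masses (CODATA/IUPAC standard values)
_MASSES = {
    "H": (1.00782503, 1.008),
    "C": (12.0, 12.011),
    "N": (14.00307401, 14.007),
    "O": (15.99491462, 15.999),
    "P": (30.97376200, 30.974),
    "S": (31.97207117, 32.06),
    "Se": (79.91652176, 78.971),
}

_H2O = Counter({"H": 2, "O": 1})
_HPO3 = Counter({"H": 1, "P": 1, "O": 3})


@dataclass(frozen=True)
class FormulaMass:
    formula: str
    monoisotopic: float
    average: float
    composition: tuple[tuple[str, int], ...]


@lru_cache(maxsize=None)
def _residue_composition(key: str) -> Counter:
    g = build_graph(key)
    comp: Counter = Counter()
    for atom in g.atoms:
        comp[atom.element] += 1
        comp["H"] += atom.hydrogens
    return comp


def _hill_formula(comp: Counter) -> str:
    order = ["C", "H"] + sorted(e for e in comp if e not in ("C", "H"))
    return "".join(
        f"{el}{comp[el]}" if comp[el] > 1 else el for el in order if comp[el]
    )


def formula_and_mass(p: PeptideRepr | str) -> FormulaMass:
    """Molecular formula and masses by residue-composition summation.

    Sum of the free amino acid formulas, minus one water per peptide bond,
    plus one HPO3 per phosphate unit, with one O -> N(+H) exchange per amide
    (``~``) of any kind.
    """
    if isinstance(p, str):
        p = parse(p)
    comp: Counter = Counter()
    for residue in p.residues:
        comp += _residue_composition(residue.key)
        for _, chain in residue.mods:
            comp += Counter({k: v * chain.units for k, v in _HPO3.items()})
            amides = chain.amide_count
            if amides:
                comp["O"] -= amides
                comp["N"] += amides
                comp["H"] += amides
        if residue.c_amide:
            comp["O"] -= 1
            comp["N"] += 1
            comp["H"] += 1
    n_bonds = len(p.residues) - 1
    comp -= Counter({k: v * n_bonds for k, v in _H2O.items()})
    if any(v < 0 for v in comp.values()):
        raise SmilesBuildError("negative element count in composition")
    mono = sum(_MASSES[el][0] * n for el, n in comp.items())
    avg = sum(_MASSES[el][1] * n for el, n in comp.items())
    return FormulaMass(
        formula=_hill_formula(comp),
        monoisotopic=mono,
        average=avg,
        composition=tuple(sorted(comp.items())),
    )


# ---------------------------------------------------------------------------
# identifier round-trip verification


def verify_roundtrip(smiles: str) -> str:
    """Canonical InChIKey of ``smiles``; hard failure on unparsable input.

    Used to prove that rearranged vocabulary strings and assembled peptides
    denote the same normalized structure as independently built references.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesBuildError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToInchiKey(mol)
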