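"""Built-in residue vocabulary.

The vocabulary ships as a structured data file (``data/residues.json``) with
one record per L-form residue: notation key, arranged SMILES string,
one-letter parent symbol for sequence stripping, and per-site attachment
points (recognition pattern + insertion rule).  D-enantiomers are derived at
load time by flipping every tetrahedral stereo descriptor in the SMILES and
in the recognition patterns; their keys are the lowercase one-letter symbols
and the ``D-``-prefixed multi-letter names.

Arranged SMILES strings follow the convention: alpha-amine group first, then
alpha-carbon, side chain, and the alpha-carboxyl group ``C(=O)O`` last, in
Kekule notation with neutral (non-zwitterionic) protonation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Mapping


class VocabularyError(ValueError):
    """Raised when the shipped vocabulary data violates its own contract."""


class UnknownResidueError(KeyError):
    """Lookup of a residue key that is not in the built-in vocabulary."""

    def __init__(self, key: str):
        super().__init__(key)
        self.key = key

    def __str__(self) -> str:  # KeyError repr-quotes its arg; keep it readable
        return f"unknown residue {self.key!r} (not in the built-in vocabulary)"


class InsertMode(str, Enum):
    """Position of an inserted fragment relative to its recognition pattern."""

    BEFORE = "before"
    AFTER = "after"
    INSTEAD_OF = "instead_of"


@dataclass(frozen=True)
class Attachment:
    """One attachment point of a residue scaffold.

    ``pattern`` is the recognition pattern: a substring of the residue's
    arranged SMILES that occurs exactly once and marks the attachment point.
    ``insert`` is the text that is placed after / before / instead of the
    pattern; the placeholder ``{P}`` is substituted with the phosphate-chain
    fragment.
    """

    pattern: str
    mode: InsertMode
    insert: str


@dataclass(frozen=True)
class ResidueSmilesEntry:
    """Vocabulary record: arranged SMILES plus per-site attachment points."""

    key: str
    name: str
    parent: str          # one-letter symbol for plain-sequence stripping
    smiles: str
    attachments: Mapping[int, Attachment]
    is_d: bool = False


def _flip_stereo(s: str) -> str:
    """Mirror every tetrahedral stereo descriptor (``@`` <-> ``@@``)."""
    return s.replace("@@", "\x00").replace("@", "@@").replace("\x00", "@")


def _derive_d_entry(entry: ResidueSmilesEntry, d_key: str) -> ResidueSmilesEntry:
    attachments = {
        site: Attachment(_flip_stereo(a.pattern), a.mode, _flip_stereo(a.insert))
        for site, a in entry.attachments.items()
    }
    return ResidueSmilesEntry(
        key=d_key,
        name=f"D-{entry.name}" if entry.key != "G" else entry.name,
        parent=entry.parent.lower() if entry.key != "G" else entry.parent,
        smiles=_flip_stereo(entry.smiles),
        attachments=attachments,
        is_d=True,
    )


def _check_entry(entry: ResidueSmilesEntry) -> None:
    s = entry.smiles
    if not s.startswith("N"):
        raise VocabularyError(f"{entry.key}: SMILES must start with the alpha-amine N")
    if not s.endswith("C(=O)O"):
        raise VocabularyError(f"{entry.key}: SMILES must end with the alpha-carboxyl C(=O)O")
    seen: dict[str, int] = {}
    for site, att in entry.attachments.items():
        n = s.count(att.pattern)
        if n != 1:
            raise VocabularyError(
                f"{entry.key}: recognition pattern {att.pattern!r} for site {site} "
                f"occurs {n} times (must be exactly once)"
            )
        if att.pattern in seen:
            raise VocabularyError(
                f"{entry.key}: sites {seen[att.pattern]} and {site} share the "
                f"recognition pattern {att.pattern!r}"
            )
        seen[att.pattern] = site


def _load() -> dict[str, ResidueSmilesEntry]:
    raw = json.loads(
        resources.files("phospep").joinpath("data/residues.json").read_text("utf-8")
    )
    table: dict[str, ResidueSmilesEntry] = {}
    for rec in raw["residues"]:
        attachments = {
            int(site): Attachment(a["pattern"], InsertMode(a["mode"]), a["insert"])
            for site, a in rec["attachments"].items()
        }
        entry = ResidueSmilesEntry(
            key=rec["key"],
            name=rec["name"],
            parent=rec["parent"],
            smiles=rec["smiles"],
            attachments=attachments,
        )
        _check_entry(entry)
        table[entry.key] = entry
        for alias in rec.get("aliases", ()):
            table[alias] = entry  # stereo-unspecified spelling of the natural isomer
        d_key = rec.get("d_key")
        if d_key:
            d_entry = _derive_d_entry(entry, d_key)
            _check_entry(d_entry)
            table[d_key] = d_entry
    return table


_TABLE: dict[str, ResidueSmilesEntry] | None = None


def vocabulary() -> dict[str, ResidueSmilesEntry]:
    """The full key -> entry table (L-forms, D-forms, multi-letter names)."""
    global _TABLE
    if _TABLE is None:
        _TABLE = _load()
    return _TABLE


def get_entry(key: str) -> ResidueSmilesEntry:
    try:
        return vocabulary()[key]
    except KeyError:
        raise UnknownResidueError(key) from None
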