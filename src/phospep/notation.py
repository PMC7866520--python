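"""Parser and canonical serializer for the phosphopeptide notation.

The notation encodes each residue as a one-letter symbol (uppercase
L-proteinogenic including selenocysteine and pyrrolysine, lowercase
D-enantiomer) or a multi-letter name between ``<`` and ``>``.  A bare ``~``
directly after the symbol marks an amidated alpha-carboxyl group.  Each
modification block ``[<site><chain>]`` attaches a phosphate chain to the
numbered atom ``site`` of the residue:

* ``*``           one phosphate unit;
* ``**``          two units joined by a phosphodiester bond;
* ``*~*``         two units joined by an amide (bridging N) bond;
* ``*[~]*``       branch amidation of the unit preceding ``[~]``;
* ``**~``         amidation of the terminal phosphate unit.

Grammar (informally)::

    peptide  := residue+
    residue  := symbol '~'? block*
    symbol   := LETTER | '<' name '>'
    block    := '[' INT chain ']'
    chain    := '*' ( '[~]' | '~'? '*' )* '~'?

The serializer emits the canonical form: modification blocks in ascending
site order.  ``parse`` and ``serialize`` are mutually inverse on canonical
strings and on parsed structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Iterable, TextIO


#: One-letter alphabet: the 20 standard amino acids plus selenocysteine (U)
#: and pyrrolysine (O); lowercase letters denote D-enantiomers.
ONE_LETTER = frozenset("ACDEFGHIKLMNPQRSTVWYUO")


class ParseError(ValueError):
    """Syntax error in a notation string, with the offending position."""

    def __init__(self, message: str, position: int, text: str = ""):
        self.position = position
        self.text = text
        super().__init__(f"{message} (at position {position})")


class Linkage(str, Enum):
    """Bond type between two consecutive phosphate units in a chain."""

    ESTER = "ester"   # bridging O (phosphodiester)
    AMIDE = "amide"   # bridging N


@dataclass(frozen=True)
class ModChain:
    """A phosphate chain attached at one modification site.

    ``units`` phosphate groups; ``linkages[i]`` joins unit ``i`` to unit
    ``i+1``; ``branch_amide`` holds 0-based unit indices whose non-bridging
    hydroxyl is amidated (``[~]``); ``terminal_amide`` amidates the free
    hydroxyl of the last unit (trailing ``~``).
    """

    units: int
    linkages: tuple[Linkage, ...] = ()
    branch_amide: frozenset[int] = frozenset()
    terminal_amide: bool = False

    def __post_init__(self):
        if self.units < 1:
            raise ValueError("a phosphate chain needs at least one unit")
        if len(self.linkages) != self.units - 1:
            raise ValueError("need exactly units-1 linkages")
        if any(not 0 <= i < self.units for i in self.branch_amide):
            raise ValueError("branch amide index out of range")

    @property
    def amide_count(self) -> int:
        """Total number of O -> N amide substitutions encoded by the chain."""
        return (
            len(self.branch_amide)
            + sum(1 for l in self.linkages if l is Linkage.AMIDE)
            + (1 if self.terminal_amide else 0)
        )


@dataclass(frozen=True)
class ResidueCode:
    """One residue token: symbol or multi-letter name, plus modifications."""

    symbol: str | None = None
    multi_letter: str | None = None
    c_amide: bool = False
    mods: tuple[tuple[int, ModChain], ...] = ()

    def __post_init__(self):
        if (self.symbol is None) == (self.multi_letter is None):
            raise ValueError("exactly one of symbol/multi_letter must be set")
        sites = [s for s, _ in self.mods]
        if len(sites) != len(set(sites)):
            raise ValueError("duplicate modification site in one residue")
        if any(s < 1 for s in sites):
            raise ValueError("modification sites are positive integers")
        # canonical form: ascending site order
        object.__setattr__(self, "mods", tuple(sorted(self.mods, key=lambda m: m[0])))

    @property
    def key(self) -> str:
        """Vocabulary lookup key (the one-letter or multi-letter symbol)."""
        return self.symbol if self.symbol is not None else self.multi_letter  # type: ignore[return-value]


@dataclass(frozen=True)
class PeptideRepr:
    """Parsed peptide: ordered residues, index 0 = N-terminus."""

    residues: tuple[ResidueCode, ...]

    def __post_init__(self):
        if not self.residues:
            raise ValueError("a peptide has at least one residue")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[ResidueCode]:
        return iter(self.residues)


# ---------------------------------------------------------------------------
# parsing


def parse(text: str) -> PeptideRepr:
    """Parse a notation string into a :class:`PeptideRepr`.

    Raises :class:`ParseError` with the offending position on malformed
    input (unbalanced brackets, unknown one-letter symbol, modification
    chain not starting with ``*``, stray ``~`` ...).
    """
    if not text:
        raise ParseError("empty input", 0, text)
    for i, ch in enumerate(text):
        if ch.isspace():
            raise ParseError("whitespace is not allowed in a representation", i, text)
    residues = []
    pos = 0
    while pos < len(text):
        residue, pos = _parse_residue(text, pos)
        residues.append(residue)
    return PeptideRepr(tuple(residues))


def _parse_residue(text: str, pos: int) -> tuple[ResidueCode, int]:
    ch = text[pos]
    symbol: str | None = None
    multi: str | None = None
    if ch == "<":
        end = text.find(">", pos + 1)
        if end < 0:
            raise ParseError("unbalanced '<'", pos, text)
        name = text[pos + 1 : end]
        if not name:
            raise ParseError("empty '<>' residue name", pos, text)
        if "<" in name:
            raise ParseError("nested '<' in residue name", pos, text)
        multi = name
        pos = end + 1
    elif ch == ">":
        raise ParseError("unbalanced '>'", pos, text)
    elif ch.isalpha():
        if ch.upper() not in ONE_LETTER:
            raise ParseError(f"unknown one-letter symbol {ch!r}", pos, text)
        symbol = ch
        pos += 1
    elif ch == "[":
        raise ParseError("modification block with no preceding residue", pos, text)
    elif ch == "~":
        raise ParseError("'~' with no preceding residue", pos, text)
    else:
        raise ParseError(f"unexpected character {ch!r}", pos, text)

    c_amide = False
    if pos < len(text) and text[pos] == "~":
        c_amide = True
        pos += 1

    mods: list[tuple[int, ModChain]] = []
    while pos < len(text) and text[pos] == "[":
        site, chain, pos = _parse_mod_block(text, pos)
        if any(site == s for s, _ in mods):
            raise ParseError(f"duplicate modification site {site}", pos, text)
        mods.append((site, chain))
    if pos < len(text) and text[pos] == "~":
        raise ParseError(
            "'~' for the alpha-carboxyl amide must directly follow the residue symbol",
            pos, text,
        )
    if pos < len(text) and text[pos] == "]":
        raise ParseError("unbalanced ']'", pos, text)
    return ResidueCode(symbol=symbol, multi_letter=multi, c_amide=c_amide,
                       mods=tuple(mods)), pos


def _parse_mod_block(text: str, pos: int) -> tuple[int, ModChain, int]:
    start = pos
    pos += 1  # consume '['
    digits = ""
    while pos < len(text) and text[pos].isdigit():
        digits += text[pos]
        pos += 1
    if not digits:
        raise ParseError("modification block must start with a site number", start, text)
    site = int(digits)
    if site < 1:
        raise ParseError("modification site must be a positive integer", start, text)

    if pos >= len(text):
        raise ParseError("unbalanced '['", start, text)
    if text[pos] != "*":
        raise ParseError("modification chain must start with '*'", pos, text)
    units = 1
    pos += 1
    linkages: list[Linkage] = []
    branch: set[int] = set()
    terminal = False
    while True:
        if pos >= len(text):
            raise ParseError("unbalanced '['", start, text)
        ch = text[pos]
        if ch == "]":
            pos += 1
            break
        if terminal:
            raise ParseError("terminal '~' must close the modification block", pos, text)
        if ch == "*":
            linkages.append(Linkage.ESTER)
            units += 1
            pos += 1
        elif ch == "[":
            if text[pos : pos + 3] != "[~]":
                raise ParseError("expected '[~]' branch amide", pos, text)
            if units - 1 in branch:
                raise ParseError("a phosphate unit carries at most one branch amide",
                                 pos, text)
            branch.add(units - 1)
            pos += 3
        elif ch == "~":
            pos += 1
            if pos >= len(text):
                raise ParseError("unbalanced '['", start, text)
            if text[pos] == "*":
                linkages.append(Linkage.AMIDE)
                units += 1
                pos += 1
            elif text[pos] == "]":
                terminal = True
            else:
                raise ParseError("'~' must precede '*' or close the block", pos - 1, text)
        else:
            raise ParseError(f"unexpected character {ch!r} in modification chain",
                             pos, text)
    chain = ModChain(units=units, linkages=tuple(linkages),
                     branch_amide=frozenset(branch), terminal_amide=terminal)
    return site, chain, pos


# ---------------------------------------------------------------------------
# serialization


def serialize(p: PeptideRepr) -> str:
    """Canonical notation string for ``p`` (mod blocks in ascending site order)."""
    out: list[str] = []
    for r in p.residues:
        out.append(r.symbol if r.symbol is not None else f"<{r.multi_letter}>")
        if r.c_amide:
            out.append("~")
        for site, chain in r.mods:  # already canonically sorted
            out.append(f"[{site}{_chain_text(chain)}]")
    return "".join(out)


def _chain_text(chain: ModChain) -> str:
    s = ""
    for i in range(chain.units):
        s += "*"
        if i in chain.branch_amide:
            s += "[~]"
        if i < chain.units - 1 and chain.linkages[i] is Linkage.AMIDE:
            s += "~"
    if chain.terminal_amide:
        s += "~"
    return s


# ---------------------------------------------------------------------------
# file input: one representation per line, or FASTA-like records


def read_records(handle: TextIO | Iterable[str]) -> list[tuple[str, str]]:
    """Read ``(identifier, representation)`` pairs from a text source.

    Plain format: one representation per line, ``#`` comment lines and blank
    lines skipped; identifiers are 1-based line numbers.  If the first
    non-blank line starts with ``>``, the source is read as FASTA-like
    records (``>id`` header followed by the representation).
    """
    lines = list(handle)
    stripped = [(i + 1, ln.strip()) for i, ln in enumerate(lines)]
    content = [(i, ln) for i, ln in stripped if ln and not ln.startswith("#")]
    if not content:
        return []
    if content[0][1].startswith(">"):
        from Bio.SeqIO.FastaIO import SimpleFastaParser

        return [
            (title.split()[0] if title.split() else title, seq)
            for title, seq in SimpleFastaParser(iter(lines))
        ]
    return [(f"line{i}", ln) for i, ln in content]
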