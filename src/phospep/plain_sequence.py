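"""Stripping a modified representation to a plain one-letter sequence.

Phosphopeptide databases should be searchable with unmodified sequences
(e.g. as BLAST queries), so every representation built from proteinogenic
residues or their post-translational derivatives must reduce to a standard
one-letter string: modification blocks and amide markers are dropped,
hydroxyproline isomers become P, hydroxylysine becomes K, and D-residues are
written with the uppercase symbol of their L-counterpart (``keep_case=True``
preserves the lowercase D convention instead).
"""

from __future__ import annotations

from .notation import PeptideRepr
from .vocabulary import UnknownResidueError, vocabulary


class ConversionError(ValueError):
    """A residue has no proteinogenic parent (e.g. an unnatural amino acid)."""


def to_plain(p: PeptideRepr, keep_case: bool = False) -> str:
    """One character per residue, scanned N- to C-terminus."""
    table = vocabulary()
    out = []
    for idx, residue in enumerate(p.residues):
        entry = table.get(residue.key)
        if entry is None:
            raise ConversionError(
                f"residue {residue.key!r} at position {idx} has no proteinogenic "
                "parent; conversion to an unmodified sequence is not applicable"
            )
        out.append(entry.parent if keep_case else entry.parent.upper())
    return "".join(out)
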