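"""Semantic validation of parsed phosphopeptide representations.

A representation can be syntactically well-formed yet chemically impossible:
a phosphate on a threonine methyl carbon, both imidazole nitrogens of one
histidine phosphorylated, or a group that is simultaneously phosphorylated
and engaged in a peptide bond.  ``validate`` returns the full list of such
violations (it never raises); an empty list means the peptide is legal.
"""

from __future__ import annotations

from dataclasses import dataclass

from .notation import PeptideRepr
from .structure import IMIDAZOLE_N, allowed_sites
from .vocabulary import UnknownResidueError

# rule identifiers (closed set)
SITE_NOT_MODIFIABLE = "SITE_NOT_MODIFIABLE"
DOUBLE_IMIDAZOLE = "DOUBLE_IMIDAZOLE"
INTERNAL_CARBOXYL_PHOSPHO = "INTERNAL_CARBOXYL_PHOSPHO"
INTERNAL_AMINE_PHOSPHO = "INTERNAL_AMINE_PHOSPHO"
UNKNOWN_RESIDUE = "UNKNOWN_RESIDUE"
UNSUPPORTED_COMBINATION = "UNSUPPORTED_COMBINATION"
INTERNAL_C_AMIDE = "INTERNAL_C_AMIDE"

RULE_IDS = frozenset({
    SITE_NOT_MODIFIABLE, DOUBLE_IMIDAZOLE, INTERNAL_CARBOXYL_PHOSPHO,
    INTERNAL_AMINE_PHOSPHO, UNKNOWN_RESIDUE, UNSUPPORTED_COMBINATION,
    INTERNAL_C_AMIDE,
})


@dataclass(frozen=True)
class Violation:
    residue_index: int           # 0-based position in the peptide
    site: int | None
    rule_id: str
    message: str

    def __post_init__(self):
        if self.rule_id not in RULE_IDS:
            raise ValueError(f"unknown rule id {self.rule_id!r}")


def validate(p: PeptideRepr) -> list[Violation]:
    """Check every modification of ``p`` against the site-legality rules.

    Site 1 (alpha-carboxyl) may only be modified on the C-terminal residue
    and site 2 (alpha-amine) only on the N-terminal one — an internal group
    cannot be phosphorylated and form a peptide bond at the same time.  A
    single-residue peptide is a free amino acid: both termini are available.
    """
    violations: list[Violation] = []
    last = len(p.residues) - 1
    for idx, residue in enumerate(p.residues):
        key = residue.key
        try:
            sites = allowed_sites(key)
        except UnknownResidueError:
            violations.append(Violation(
                idx, None, UNKNOWN_RESIDUE,
                f"residue {key!r} is not in the built-in vocabulary",
            ))
            continue

        if residue.c_amide and idx != last:
            violations.append(Violation(
                idx, None, INTERNAL_C_AMIDE,
                "alpha-carboxyl amidation on a non-C-terminal residue",
            ))
        if residue.c_amide and any(site == 1 for site, _ in residue.mods):
            violations.append(Violation(
                idx, 1, UNSUPPORTED_COMBINATION,
                "alpha-carboxyl cannot be both amidated and phosphorylated",
            ))

        imidazole_sites = []
        for site, chain in residue.mods:
            if site not in sites:
                violations.append(Violation(
                    idx, site, SITE_NOT_MODIFIABLE,
                    f"atom {site} of residue {key!r} carries no modifiable group",
                ))
                continue
            if site == 1 and idx != last:
                violations.append(Violation(
                    idx, site, INTERNAL_CARBOXYL_PHOSPHO,
                    "carboxyl group simultaneously phosphorylated and in a peptide bond",
                ))
            if site == 2 and idx != 0:
                violations.append(Violation(
                    idx, site, INTERNAL_AMINE_PHOSPHO,
                    "amine group simultaneously phosphorylated and in a peptide bond",
                ))
            if sites[site] == IMIDAZOLE_N:
                imidazole_sites.append(site)
            if chain.terminal_amide and (chain.units - 1) in chain.branch_amide:
                violations.append(Violation(
                    idx, site, UNSUPPORTED_COMBINATION,
                    "terminal phosphate with both branch and terminal amidation",
                ))
        if len(imidazole_sites) >= 2:
            violations.append(Violation(
                idx, None, DOUBLE_IMIDAZOLE,
                "both imidazole ring nitrogens phosphorylated; only one is basic",
            ))
    return violations


def violations_table(records):
    """Tabulate ``(input_text, [Violation, ...])`` pairs as a DataFrame.

    Columns: input, residue_index, site, rule_id, message — the TSV/JSON
    report layout used by the command-line interface.
    """
    import pandas as pd

    rows = [
        {
            "input": text,
            "residue_index": v.residue_index,
            "site": v.site,
            "rule_id": v.rule_id,
            "message": v.message,
        }
        for text, violations in records
        for v in violations
    ]
    df = pd.DataFrame(
        rows, columns=["input", "residue_index", "site", "rule_id", "message"]
    )
    df["site"] = df["site"].astype("Int64")  # keep sites integral despite NaNs
    return df
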