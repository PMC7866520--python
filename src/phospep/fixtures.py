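"""Seeded random generator of valid phosphopeptide representations.

Used for property testing and demonstration data.  Every emitted string is
canonical (it round-trips through parse/serialize) and validates clean:
side-chain sites are drawn only from each residue's computed allowed-site
table, at most one imidazole nitrogen of a histidine is used, terminal
modifications are restricted to the peptide termini, and chain shapes are
drawn from the repertoire of mono-, di- and triphosphates with and without
amidation.
"""

from __future__ import annotations

import random

from .notation import Linkage, ModChain, PeptideRepr, ResidueCode, serialize
from .structure import IMIDAZOLE_N, allowed_sites
from .vocabulary import vocabulary

#: phosphate-chain shapes the generator draws from
CHAIN_SHAPES: dict[str, ModChain] = {
    "*": ModChain(1),
    "**": ModChain(2, (Linkage.ESTER,)),
    "***": ModChain(3, (Linkage.ESTER, Linkage.ESTER)),
    "*~": ModChain(1, terminal_amide=True),
    "**~": ModChain(2, (Linkage.ESTER,), terminal_amide=True),
    "*~*": ModChain(2, (Linkage.AMIDE,)),
    "*[~]*": ModChain(2, (Linkage.ESTER,), branch_amide=frozenset({0})),
}


def generate_fixtures(
    seed: int,
    n: int,
    max_len: int = 8,
    mod_rate: float = 0.3,
) -> list[str]:
    """``n`` random canonical representations, deterministic for a seed.

    ``mod_rate`` is the per-residue probability of a side-chain phosphate
    (terminal site-1/site-2/amide decorations occur at a third of that
    rate); ``mod_rate=0`` yields plain sequences.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = random.Random(seed)
    keys = sorted(vocabulary())
    one_letter_l = [k for k in keys if len(k) == 1 and k.isupper()]
    one_letter_d = [k for k in keys if len(k) == 1 and k.islower()]
    multi = [k for k in keys if len(k) > 1]
    shapes = sorted(CHAIN_SHAPES)

    out = []
    for _ in range(n):
        length = rng.randint(1, max_len)
        residues = []
        for i in range(length):
            r = rng.random()
            if r < 0.08:
                key = rng.choice(multi)
            elif r < 0.18:
                key = rng.choice(one_letter_d)
            else:
                key = rng.choice(one_letter_l)
            sites = allowed_sites(key)
            side = [s for s in sorted(sites) if s > 2]
            imid = [s for s in side if sites[s] == IMIDAZOLE_N]
            if len(imid) > 1:  # histidine: at most one ring N
                keep = rng.choice(imid)
                side = [s for s in side if sites[s] != IMIDAZOLE_N or s == keep]

            mods: list[tuple[int, ModChain]] = []
            if side and rng.random() < mod_rate:
                k = 2 if len(side) > 1 and rng.random() < 0.2 else 1
                for s in rng.sample(side, k):
                    mods.append((s, CHAIN_SHAPES[rng.choice(shapes)]))
            c_amide = False
            if i == 0 and rng.random() < mod_rate / 3:
                mods.append((2, CHAIN_SHAPES[rng.choice(shapes)]))
            if i == length - 1 and rng.random() < mod_rate / 3:
                if rng.random() < 0.5:
                    mods.append((1, CHAIN_SHAPES[rng.choice(shapes)]))
                else:
                    c_amide = True
            residues.append(ResidueCode(
                symbol=key if len(key) == 1 else None,
                multi_letter=key if len(key) > 1 else None,
                c_amide=c_amide,
                mods=tuple(mods),
            ))
        out.append(serialize(PeptideRepr(tuple(residues))))
    return out
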