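"""Molecular graphs of the vocabulary residues and continuous atom numbering.

Every residue in the vocabulary is backed by a molecular graph (heavy atoms,
bonds, hydrogen counts) built from its SMILES string.  The continuous
numbering assigns one unbroken series of locants to a whole amino acid,
instead of the separate chain/ring numbering used in systematic nomenclature,
so that a single integer identifies any modification site.  The rules, in
priority order:

1. the carbon of the (alpha-)carboxyl group is locant 1;
2. with several carboxyl groups, the one nearest the amine group wins;
3. heteroatoms (N, O, S, ...) are numbered only when non-terminal, i.e.
   bonded to at least two heavy atoms (-NH-, -N=, -O-, -S- are numbered;
   -NH2, -OH, -SH are not);
4. ring atoms take the smallest attainable locant sum, and the ring atom
   carrying the substituent that contains carboxyl 1 comes first;
5. ring atoms are numbered before substituent atoms (except the chain that
   carries carboxyl 1);
6. side chains are numbered following the position of their attachment;
7. remaining ties are broken by Cahn-Ingold-Prelog-style priority (highest
   atomic number spheres first).

The allowed-site table (which locants of each residue may carry a phosphate
group) is *computed* from these graphs and labels, not hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx

from .vocabulary import UnknownResidueError, get_entry

# functional-group labels
ALPHA_CARBOXYL = "ALPHA_CARBOXYL"
ALPHA_AMINE = "ALPHA_AMINE"
SIDE_HYDROXYL = "SIDE_HYDROXYL"
SIDE_CARBOXYL = "SIDE_CARBOXYL"
SIDE_AMINE = "SIDE_AMINE"
GUANIDINE = "GUANIDINE"
IMIDAZOLE_N = "IMIDAZOLE_N"
INDOLE_N = "INDOLE_N"
THIOL = "THIOL"

#: groups a phosphate chain may be attached to, and whether the site locant
#: is the labelled atom itself (ring N) or fixed by convention
_SIDE_CHAIN_GROUPS = (
    SIDE_HYDROXYL, SIDE_CARBOXYL, SIDE_AMINE, GUANIDINE,
    IMIDAZOLE_N, INDOLE_N, THIOL,
)

_ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "Se": 34}


class NumberingError(ValueError):
    """The graph cannot be numbered (e.g. no carboxyl group present)."""


@dataclass(frozen=True)
class GraphAtom:
    element: str
    hydrogens: int
    in_ring: bool = False


@dataclass
class MolecularGraph:
    """Heavy-atom graph of one amino acid with functional-group labels.

    ``groups`` maps a label to the indices of the heavy atoms bearing that
    group (the attachment atoms): the carbon for terminal -OH/-SH/-NH2
    groups, the carboxyl or guanidine carbon, the ring nitrogen itself for
    imidazole/indole nitrogens.
    """

    atoms: tuple[GraphAtom, ...]
    bonds: tuple[tuple[int, int, int], ...]
    groups: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def adjacency(self) -> dict[int, tuple[tuple[int, int], ...]]:
        adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(self.atoms))}
        for i, j, order in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        return {k: tuple(v) for k, v in adj.items()}

    def heavy_degree(self, i: int, adj=None) -> int:
        adj = adj or self.adjacency()
        return len(adj[i])


@dataclass(frozen=True)
class AtomNumbering:
    """Locants for the numbered atoms; terminal heteroatoms stay unnumbered."""

    numbers: dict[int, int]          # atom index -> locant (1..k)
    unnumbered: frozenset[int]

    def locant(self, atom: int) -> int:
        return self.numbers[atom]


# ---------------------------------------------------------------------------
# graph construction


def graph_from_smiles(smiles: str) -> MolecularGraph:
    """Heavy-atom graph from a SMILES string (labels not yet assigned)."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    atoms = tuple(
        GraphAtom(a.GetSymbol(), a.GetTotalNumHs(), a.IsInRing())
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    )
    return MolecularGraph(atoms=atoms, bonds=bonds)


@lru_cache(maxsize=None)
def build_graph(residue_key: str) -> MolecularGraph:
    """Labelled molecular graph of a vocabulary residue.

    Raises :class:`~phospep.vocabulary.UnknownResidueError` for keys outside
    the built-in vocabulary.
    """
    entry = get_entry(residue_key)
    g = graph_from_smiles(entry.smiles)
    g.groups = label_groups(g)
    return g


# ---------------------------------------------------------------------------
# functional-group labelling


def _carboxyl_carbons(g: MolecularGraph, adj) -> list[int]:
    out = []
    for i, atom in enumerate(g.atoms):
        if atom.element != "C":
            continue
        terminal_o = [
            (j, order) for j, order in adj[i]
            if g.atoms[j].element == "O" and len(adj[j]) == 1
        ]
        if len(terminal_o) == 2 and sorted(o for _, o in terminal_o) == [1, 2]:
            out.append(i)
    return out


def _bfs_distance(adj, start: int, targets: set[int]) -> int:
    if start in targets:
        return 0
    seen = {start}
    frontier = [start]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for a in frontier:
            for nb, _ in adj[a]:
                if nb in seen:
                    continue
                if nb in targets:
                    return d
                seen.add(nb)
                nxt.append(nb)
        frontier = nxt
    return len(adj) + 1


def _alpha_carboxyl(g: MolecularGraph, adj, carboxyls: list[int]) -> int:
    nitrogens = {i for i, a in enumerate(g.atoms) if a.element == "N"}
    if not nitrogens or len(carboxyls) == 1:
        return carboxyls[0]
    return min(carboxyls, key=lambda c: (_bfs_distance(adj, c, nitrogens), c))


def label_groups(g: MolecularGraph) -> dict[str, tuple[int, ...]]:
    """Detect and label the functional groups of an amino-acid graph."""
    adj = g.adjacency()
    carboxyls = _carboxyl_carbons(g, adj)
    if not carboxyls:
        raise NumberingError("no carboxyl group in graph")
    alpha_cx = _alpha_carboxyl(g, adj, carboxyls)
    alpha_c = next(
        (j for j, _ in adj[alpha_cx] if g.atoms[j].element == "C"), None
    )
    if alpha_c is None:
        raise NumberingError("carboxyl carbon has no carbon neighbour")
    alpha_n = next(
        (j for j, _ in adj[alpha_c] if g.atoms[j].element == "N"), None
    )
    if alpha_n is None:
        raise NumberingError("no alpha-amine nitrogen found")

    groups: dict[str, list[int]] = {ALPHA_CARBOXYL: [alpha_cx], ALPHA_AMINE: [alpha_n]}

    def add(label: str, atom: int) -> None:
        groups.setdefault(label, []).append(atom)

    guanidine_c = {
        i for i, a in enumerate(g.atoms)
        if a.element == "C"
        and sum(1 for j, _ in adj[i] if g.atoms[j].element == "N") == 3
    }
    for c in guanidine_c:
        add(GUANIDINE, c)

    ring_systems = _ring_systems(g)

    for i, atom in enumerate(g.atoms):
        terminal = len(adj[i]) == 1
        heavy_nb = adj[i][0][0] if terminal else None
        if atom.element == "O" and terminal and atom.hydrogens == 1:
            if heavy_nb not in carboxyls:  # carboxyl OH is part of the carboxyl
                add(SIDE_HYDROXYL, heavy_nb)
        elif atom.element == "S" and terminal and atom.hydrogens == 1:
            add(THIOL, heavy_nb)
        elif atom.element == "N" and terminal and atom.hydrogens == 2 and i != alpha_n:
            nb = heavy_nb
            if (
                g.atoms[nb].element == "C"
                and nb not in carboxyls
                and nb not in guanidine_c
                and not any(
                    order == 2 and g.atoms[j].element == "O" for j, order in adj[nb]
                )
            ):
                add(SIDE_AMINE, nb)
        elif atom.element == "N" and atom.in_ring and i != alpha_n:
            system = next(rs for rs in ring_systems if i in rs)
            n_count = sum(1 for a in system if g.atoms[a].element == "N")
            if len(system) == 5 and n_count == 2:
                add(IMIDAZOLE_N, i)
            elif len(system) >= 8 and n_count == 1 and atom.hydrogens >= 1:
                add(INDOLE_N, i)

    for c in carboxyls:
        if c != alpha_cx:
            add(SIDE_CARBOXYL, c)

    return {label: tuple(sorted(atoms)) for label, atoms in groups.items()}


def _ring_systems(g: MolecularGraph) -> list[frozenset[int]]:
    """Fused ring systems: connected components of the ring-atom subgraph."""
    G = nx.Graph()
    G.add_nodes_from(range(len(g.atoms)))
    G.add_edges_from((i, j) for i, j, _ in g.bonds)
    ring_atoms: set[int] = set()
    for cycle in nx.cycle_basis(G):
        ring_atoms.update(cycle)
    if not ring_atoms:
        return []
    return [frozenset(c) for c in nx.connected_components(G.subgraph(ring_atoms))]


# ---------------------------------------------------------------------------
# Cahn-Ingold-Prelog-style branch comparison (rule 7)


def branch_priority_key(g: MolecularGraph, adj, parent: int, atom: int):
    """Comparable key for the branch rooted at ``atom`` entered from ``parent``.

    Morgan-like sphere expansion: each sphere is the descending-sorted list
    of atomic numbers one bond further from the root, with double/triple
    bonds contributing duplicated entries and hydrogens included.  Stereo
    descriptors are ignored; ties between branches that survive this
    comparison are between automorphic branches for every vocabulary residue.
    """
    spheres = [(_ATOMIC_NUMBER[g.atoms[atom].element],)]
    frontier = [(atom, parent)]
    for _ in range(len(g.atoms)):
        zs: list[int] = []
        nxt = set()
        for at, par in frontier:
            for nb, order in adj[at]:
                if nb == par:
                    continue
                zs.extend([_ATOMIC_NUMBER[g.atoms[nb].element]] * order)
                nxt.add((nb, at))
            zs.extend([1] * g.atoms[at].hydrogens)
        if not zs:
            break
        spheres.append(tuple(sorted(zs, reverse=True)))
        frontier = sorted(nxt)
    return tuple(spheres)


# ---------------------------------------------------------------------------
# the numbering algorithm


def numberable_atoms(g: MolecularGraph) -> set[int]:
    """Rule 3: all carbons, plus heteroatoms bonded to >= 2 heavy atoms."""
    adj = g.adjacency()
    return {
        i for i, a in enumerate(g.atoms)
        if a.element == "C" or len(adj[i]) >= 2
    }


def number_atoms(g: MolecularGraph) -> AtomNumbering:
    """Assign continuous locants to ``g`` following rules 1-7."""
    adj = g.adjacency()
    numberable = numberable_atoms(g)
    carboxyls = _carboxyl_carbons(g, adj)
    if not carboxyls:
        raise NumberingError("graph has no carboxyl group (rule 1 undefined)")
    c1 = _alpha_carboxyl(g, adj, carboxyls)

    ring_systems = _ring_systems(g)
    system_of = {a: rs for rs in ring_systems for a in rs}

    order: list[int] = [c1]
    numbered: set[int] = {c1}

    def cip_sorted(parent: int, cands: list[int]) -> list[int]:
        return sorted(
            cands,
            key=lambda x: branch_priority_key(g, adj, parent, x),
            reverse=True,
        )

    def pending(a: int) -> list[int]:
        return [nb for nb, _ in adj[a] if nb in numberable and nb not in numbered]

    def take(x: int) -> None:
        order.append(x)
        numbered.add(x)
        visit(x)

    def complete_ring(rs: frozenset[int]) -> None:
        # rule 4/5: consecutive locants through the whole (fused) ring
        # system; continue from the most recently numbered ring atom, CIP
        # priority breaking ties among equally recent candidates.
        while True:
            cands = [
                x for x in rs
                if x in numberable and x not in numbered
                and any(nb in numbered for nb, _ in adj[x])
            ]
            if not cands:
                break

            def anchor(x: int) -> int:
                return max(order.index(nb) for nb, _ in adj[x] if nb in numbered)

            best_anchor = max(anchor(x) for x in cands)
            tied = [x for x in cands if anchor(x) == best_anchor]
            nxt = tied[0] if len(tied) == 1 else cip_sorted(order[best_anchor], tied)[0]
            order.append(nxt)
            numbered.add(nxt)

    def visit(a: int) -> None:
        rs = system_of.get(a)
        if rs is not None and any(
            x in numberable and x not in numbered for x in rs
        ):
            complete_ring(rs)
            # rule 6: substituents of ring atoms in ring-locant order
            for r in [x for x in order if x in rs]:
                for nb in cip_sorted(r, pending(r)):
                    if nb not in numbered:
                        take(nb)
        else:
            # rule 6/7: depth-first into each branch, highest priority first
            for nb in cip_sorted(a, pending(a)):
                if nb not in numbered:
                    take(nb)

    visit(c1)

    if set(order) != numberable:
        raise NumberingError("numberable atoms not fully reachable")
    numbers = {atom: i + 1 for i, atom in enumerate(order)}
    unnumbered = frozenset(range(len(g.atoms))) - numberable
    return AtomNumbering(numbers=numbers, unnumbered=unnumbered)


# ---------------------------------------------------------------------------
# the allowed-site table (computed, not hard-coded)


@lru_cache(maxsize=None)
def allowed_sites(residue_key: str) -> dict[int, str]:
    """Map site locant -> functional-group label for one vocabulary residue.

    Site 1 (alpha-carboxyl) and site 2 (alpha-amine; the ring-nitrogen
    position for proline-type residues) exist for every residue; side-chain
    sites are derived from the numbered attachment atoms of the labelled
    groups.
    """
    g = build_graph(residue_key)
    numbering = number_atoms(g)
    sites = {1: ALPHA_CARBOXYL, 2: ALPHA_AMINE}
    for label in _SIDE_CHAIN_GROUPS:
        for atom in g.groups.get(label, ()):
            sites[numbering.locant(atom)] = label
    return sites
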