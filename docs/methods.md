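# Methods

## Scope

`phospep` implements a residue-based ("biological") code for phosphorylated
amino acids and peptides: a grammar and parser, a continuous atom-numbering
scheme that names modification sites, a semantic validator, conversion to
plain one-letter sequences, and translation into SMILES by
recognition-pattern fragment insertion. Phosphonopeptides (C–P bonds) are
out of scope: the notation covers phosphate groups attached through O, N or
S functional groups only, and the validator rejects placements on
unfunctionalized carbons.

## The notation

Each residue is one uppercase letter (L-form; the 20 standard amino acids
plus U = selenocysteine and O = pyrrolysine), one lowercase letter
(D-enantiomer), or a multi-letter name in angle brackets (`<Hyp3(S)>`).
A bare `~` directly after the symbol amidates the α-carboxyl group.
Modification blocks `[<site><chain>]` attach phosphate chains: `*` per unit,
units joined by phosphodiester bonds by default, `~` between two `*` for an
amide (bridging-N) link, `[~]` for branch amidation of the preceding unit,
and a trailing `~` for terminal amidation. Blocks are re-emitted in
ascending site order; `parse` and `serialize` are mutually inverse on
canonical strings and on parsed structures.

Grammar notes where the notation itself is silent:

* `~` for the α-carboxyl amide must precede any modification block (the
  printed form is `S~[3*]`).
* `[n~]` (an amide with zero phosphate units) is a parse error.
* A branch amide together with a trailing amide on the same terminal unit
  parses, but the validator flags it as an unsupported combination.
* Multi-letter names are opaque, case-sensitive vocabulary keys. The
  built-in vocabulary holds `Hyp3(S)`, `Hyp4(R)`, `Hyl5(R)`, their
  D-enantiomers (`D-Hyp3(R)`, `D-Hyp4(S)`, `D-Hyl5(S)` — the stereo
  descriptor of the hydroxylated carbon flips with the mirror image), and
  the stereo-unspecified aliases `Hyp3`/`Hyp4`/`Hyl5`, which resolve to the
  naturally occurring isomers ((2S,3S)-3-hydroxyproline,
  (2S,4R)-4-hydroxyproline, (2S,5R)-5-hydroxylysine). Unknown names parse
  and are reported as `UNKNOWN_RESIDUE` downstream.
* Glycine is achiral; `g` is accepted and denotes the same structure as `G`.

## Continuous atom numbering

Systematic nomenclature numbers chains and heterocycles separately, so a
single integer cannot name an arbitrary position in an amino acid. The
continuous scheme assigns one unbroken series of locants per residue:

1. the carboxyl carbon is locant 1;
2. with several carboxyl groups, the one nearest the amine wins;
3. heteroatoms are numbered only when non-terminal (bonded to ≥ 2 heavy
   atoms): `-NH-`, `-N=`, `-O-`, `-S-` are numbered, `-NH2`, `-OH`, `-SH`
   are not;
4. ring atoms take the smallest attainable locant sum, and the ring atom
   carrying the substituent that contains carboxyl 1 comes first;
5. a ring, once entered, is numbered completely before its substituents
   (fused systems count as one ring);
6. side chains are numbered following the position of their attachment;
7. remaining ties are broken by Cahn–Ingold–Prelog-style priority.

Implementation: a greedy traversal from the carboxyl carbon. Inside a ring
system the next locant goes to an unnumbered ring atom adjacent to the most
recently numbered one, CIP priority breaking ties; outside rings the
traversal is depth-first, entering the highest-priority branch first. The
CIP comparison is a Morgan-like sphere expansion over atomic numbers with
bond-order duplication and explicit hydrogens — full CIP with stereo is not
needed, because every tie that survives the sphere comparison in this
vocabulary is between automorphic branches. Two readings of the rules are
fixed here and used consistently: "smallest sum of digits" is the sum of
ring-atom locants, and when two side chains at different attachment atoms
are both pending, the most recently attached one is completed first
(depth-first); no vocabulary residue distinguishes the alternatives.

The allowed-site table is *computed* from the numbered graphs: site 1
(α-carboxyl) and site 2 (α-amine, which for proline-type residues denotes
the ring-nitrogen attachment position) exist for every residue, and each
labelled side-chain group contributes the locant of its attachment heavy
atom — the carbon bearing a terminal O/N/S group (Ser C3, Tyr C7, Asp C4,
Lys C6, Cys C3), the guanidine carbon (Arg C7), or the ring nitrogen itself
when the nitrogen is non-terminal (His N5/N7, Trp N6). The histidine ring is
built in the Nδ-H tautomer; both ring nitrogens are exposed as sites, and
the two give distinct phosphorylation products. Selenocysteine's selenol is
not among the modifiable groups, so U exposes sites 1 and 2 only.

Tests back this with an exhaustive oracle: every numbering consistent with
rules 1–3 (connected growth orders from the correct carboxyl) is enumerated
— at most 640 for any vocabulary graph — and ranked by an independent
transcription of rules 4–7; the traversal's choice must be minimal. A
permutation-invariance test checks that shuffling atom input order yields an
isomorphic numbered graph.

## Validation

`validate` returns violations, never raises. Rules: every modification site
must be in the residue's allowed-site table; site 1 only on the C-terminal
residue and site 2 only on the N-terminal residue (an internal carboxyl or
amine cannot be phosphorylated and form a peptide bond simultaneously; a
single-residue peptide is a free amino acid with both termini available);
at most one imidazole nitrogen of a histidine may be phosphorylated (only
one ring nitrogen is basic); a bare `~` only on the C-terminal residue.
Two phosphates on one residue through different groups (e.g. hydroxylysine
O5 and N6) are legal. `S~[1*]`-type combinations (amidated *and*
phosphorylated α-carboxyl) and branch-plus-terminal amide on one unit are
reported as `UNSUPPORTED_COMBINATION`.

## Plain-sequence conversion

One output character per residue, scanning N→C: modification blocks and
amide markers are dropped, hydroxyproline isomers map to P, hydroxylysine to
K, and D-residues are uppercased to their L-symbol so the result is usable
as a database or alignment query (`keep_case=True` preserves lowercase).
Residues without a proteinogenic parent raise a `ConversionError`.

## SMILES construction

Vocabulary SMILES strings are arranged α-amine, α-carbon, side chain,
α-carboxyl (`N...C(=O)O`), Kekulé throughout, neutral protonation. Each
attachment point is a recognition pattern — a substring occurring exactly
once in the residue's string, verified at vocabulary load — plus an
insertion mode (after / before / instead-of). A phosphate unit is
`P(=O)(O)O`; chains are composed textually (`P(=O)(O)OP(=O)(O)O` for a
diphosphate, bridging `N` for an amide link, `P(=O)(N)` for a branch amide,
trailing `N` for terminal amidation — every amide is a single O→N
exchange). Hydroxyl sites insert after the hydroxyl oxygen; the α-amine
grafts a parenthesized branch on the leading N; site 1 appends to the
terminal `C(=O)O` (mixed anhydride); side carboxyls are written `C(O)=O` so
their pattern is unique and yields an acyl phosphate; the two histidine
ring nitrogens use distinct patterns producing distinct tautomer-specific
products. Multiple blocks on one residue are applied in descending site
order so earlier grafts cannot shadow later patterns. Assembly drops the
final `O` of each non-C-terminal `C(=O)O` and concatenates the next
residue's string, the classic monomer-concatenation scheme for polymer
SMILES; a C-terminal `~` rewrites `C(=O)O` to `C(=O)N`. Phosphorus
stereocentres are left undefined.

Correctness is established by identifier round-trips: every vocabulary
string, and reference phospho- and peptide structures, are compared by
InChIKey against molecules built independently from Chemical Component
Dictionary records (graph surgery on CCD residues with 3D-derived
stereochemistry), so the string-surgery route and the reference route share
no code.

## Formula and mass bookkeeping

Composition by summation: free-residue formulas (counted from the graphs)
minus one H2O per peptide bond, plus HPO3 per phosphate unit, with one
O→N+H exchange per amide of any kind. Monoisotopic and average masses come
from a standard isotope table (H, C, N, O, P, S, Se). The monoisotopic
phosphate delta is 79.96633 Da. Tests cross-check the summation against the
formula and exact mass of the actually assembled molecules.

## Synthetic-data generator

`generate_fixtures(seed, n, max_len=8, mod_rate=0.3)` emits canonical,
validation-clean representations: residue symbols drawn with 74% uppercase,
10% lowercase (D), 8% multi-letter weights; per-residue side-chain
modification probability `mod_rate` with sites drawn only from the computed
allowed-site table (one imidazole nitrogen at most); chain shapes uniform
over {`*`, `**`, `***`, `*~`, `**~`, `*~*`, `*[~]*`}; N-terminal site-2 and
C-terminal site-1/amide decorations at `mod_rate/3`. The defaults emulate
short food-derived phosphopeptides with realistic modification density.
What the generator does **not** emulate: real site-occupancy statistics
(Ser/Thr/Tyr dominance), homologous sequence context, or observational
noise — passing sweeps demonstrate notational and chemical soundness of the
pipeline, not biological realism of the sequences.

## Problem sizes and numerical choices

Property sweeps run on 1000 generated peptides (parse/serialize round-trip,
validation cleanliness, SMILES valence checks) with formula cross-checks on
a 200-peptide subset; the exhaustive numbering oracle covers every
vocabulary graph. The full suite completes in well under a minute on one
CPU. There is no floating-point fitting anywhere; mass comparisons use
1e-4–1e-5 Da absolute tolerances against the chemistry backend.

## Known limitations

* The vocabulary is the built-in table; arbitrary `<...>` residues parse
  but cannot be numbered, validated chemically, or converted.
* The numbering algorithm presumes an amino acid (≥ 1 carboxyl, ≥ 1 N) and
  graphs of vocabulary scale; it is not a general nomenclature engine.
* Aromatic-input SMILES are not accepted in the vocabulary file (Kekulé
  only), and generated SMILES leave phosphorus configuration undefined.
* Fragment-ion (b/y) masses, charge states and 3D structure are out of
  scope; only whole-molecule formulas and masses are computed.
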