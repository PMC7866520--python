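# phospep

Parser, validator and SMILES translator for a compact residue-based notation
of phosphorylated amino acids and peptides.

Phosphorylation is among the most important post-translational modifications
of peptides and proteins, yet sequence databases lack a uniform,
machine-readable way to say *which* atom of *which* residue carries *what
kind* of phosphate group. This package implements such a code for
phosphopeptide annotation: one-letter residue symbols (lowercase for
D-enantiomers, `<...>` names for non-proteinogenic residues) carry
modification blocks like `[3*]` (a phosphate on atom 3), `[3**~]` (an
amidated diphosphate), or `[3*[~]*]` (a diphosphate whose inner unit is
amidated). The library answers four questions about any such string:

* **Is it well-formed?** — a grammar with precise, position-annotated
  errors (`phospep.parse` / `phospep.serialize`).
* **Is it chemically meaningful?** — sites are checked against a
  *computed* allowed-site table. Each residue's molecular graph is numbered
  with one continuous series of locants (carboxyl C = 1; terminal
  heteroatoms unnumbered; rings before substituents, smallest locant sums,
  CIP tie-breaks), which reproduces the published table: Ser/Thr/Cys 3,
  Asp 4, Glu/4-Hyp/5-Hyl-OH 5, Lys/5-Hyl-N/Trp-N 6, Tyr/Arg/His-N 7
  (`phospep.allowed_sites`, `phospep.validate`).
* **What is its plain sequence?** — stripping to a one-letter query string
  for database search or alignment, hydroxyproline → P, hydroxylysine → K
  (`phospep.to_plain`).
* **What molecule is it?** — translation to Kekulé SMILES by grafting
  phosphate-chain fragments at recognition patterns (unique substrings of
  each residue's arranged SMILES scaffold) and concatenating residues into
  peptide bonds, plus molecular formulas and monoisotopic/average masses by
  composition summation (`phospep.to_smiles`, `phospep.formula_and_mass`,
  `phospep.verify_roundtrip`).

See `docs/methods.md` for the numbering rules, the fragment-surgery
algorithm and the design decisions.

## Worked example

```sh
$ printf 'AS[3*]<Hyp3(S)>[6*]Ga\nHT[3*[~]*]A\nS~[3*]\n' > demo.txt
$ phospep to-smiles demo.txt
id      input   smiles  formula monoisotopic_mass       inchikey        error
line1   AS[3*]<Hyp3(S)>[6*]Ga   N[C@@H](C)C(=O)N[C@@H](COP(=O)(O)O)C(=O)N1[C@@H]([C@@H](OP(=O)(O)O)CC1)C(=O)NCC(=O)N[C@H](C)C(=O)O       C16H29N5O14P2   577.11862       VVVPZDZPXBHWOS-SSSAOXCUSA-N
line2   HT[3*[~]*]A     N[C@@H](CC1=CN=CN1)C(=O)N[C@@H]([C@H](OP(=O)(N)OP(=O)(O)O)C)C(=O)N[C@@H](C)C(=O)O       C13H24N6O10P2   486.10291       BTDAEJSMDLZCQS-LNDPCREXSA-N
line3   S~[3*]  N[C@@H](COP(=O)(O)O)C(=O)N      C3H9N2O5P       184.02491       GQJPKKHUNPAXDB-REOHCLBHSA-N
```

Line 1 is the pentapeptide Ala–phosphoSer–phospho-3-hydroxyPro–Gly–D-Ala:
two single phosphates (`P(=O)(O)O`) sit on the serine oxygen and the
hydroxyproline ring oxygen, and the formula/mass columns show the summed
composition (577.11862 Da monoisotopic). Line 2 carries an amidated
diphosphate on threonine — note the `P(=O)(N)OP(=O)(O)O` fragment, one
oxygen of the inner phosphate exchanged for nitrogen. Line 3 is
phosphoserine amide: the bare `~` turned the terminal `C(=O)O` into
`C(=O)N`. The InChIKey column is the round-trip identifier used throughout
the tests to prove structures equal their independently built references.

```sh
$ phospep to-plain demo.txt          # plain query sequences: ASPGA, HTA, S
$ phospep validate demo.txt          # empty report: all three are legal
$ printf 'AT[4*]G\nAH[5*][7*]G\n' | phospep validate --strict -
input        residue_index  site  rule_id              message
AT[4*]G      1              4     SITE_NOT_MODIFIABLE  atom 4 of residue 'T' carries no modifiable group
AH[5*][7*]G  1                    DOUBLE_IMIDAZOLE     both imidazole ring nitrogens phosphorylated; only one is basic
```

Threonine has no functional group on atom 4, and only one imidazole
nitrogen of a histidine is basic enough to phosphorylate — both strings are
rejected (`--strict` exits non-zero). Other commands: `phospep parse`,
`phospep mass`, and `phospep fixtures --seed 1 -n 100` for deterministic
random valid representations.

From Python:

```pycon
>>> import phospep
>>> phospep.allowed_sites("Hyl5(R)")
{1: 'ALPHA_CARBOXYL', 2: 'ALPHA_AMINE', 5: 'SIDE_HYDROXYL', 6: 'SIDE_AMINE'}
>>> phospep.to_smiles("S[3*]").smiles
'N[C@@H](COP(=O)(O)O)C(=O)O'
>>> round(phospep.formula_and_mass("S[3*]").monoisotopic, 5)
185.00892
```

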