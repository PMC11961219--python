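# Methods

## Scope and design

`pepfeat` converts peptide sequences, with optional post-translational
modifications (PTMs), into five machine-learning-ready numeric encodings.
The package is deliberately free of third-party dependencies: every parser
(FASTA, CSV, the NCBI substitution-matrix format) and every numeric routine
is standard-library Python, so the library drops into any environment and
its outputs are reproducible bit-for-bit. Outputs are plain lists of lists
(`EncodingMatrix`) that convert directly to numpy arrays or tensors.

## Vocabulary and PTM model

The symbol dictionary has 28 entries: the 20 canonical amino acids in
alphabetical one-letter order, then 8 modified-residue variants, also
alphabetical: `K[ac] K[me] K[me2] R[me] R[me2] S[p] T[p] Y[p]`. A modified
residue is a *distinct symbol*, not an annotation: one-hot and label
encodings separate `S` from `S[p]` exactly as they separate `S` from `T`.
With generative begin/end tokens enabled, `<beg>` and `<end>` are appended
at indices 28 and 29; the label-padding index is one past the end of the
active vocabulary (28, or 30 with specials), so padding can never collide
with a real symbol. This ordering is frozen and ships with the package —
stability across runs and platforms is part of the contract, since label
indices feed downstream embedding layers.

The chosen PTM set covers the three classes most relevant to peptide
function — phosphorylation (S/T/Y), acetylation (K) and mono/di-methylation
(K/R) — as residue-level variants. Terminus-level modifications
(N-terminal acetylation, C-terminal amidation) were considered and excluded:
they are sequence-level flags, not residue symbols, and cannot participate
in a bijective symbol↔index map of fixed size. The set lives in one
configuration table (`vocabulary.PTM_TAGS` / `PTM_VARIANTS`), so swapping
members requires no code change elsewhere.

## Descriptor catalogs

**Per-residue (18 scales, `data/aa_scales.json`).** Kyte–Doolittle
hydropathy, Eisenberg consensus hydrophobicity, Hopp–Woods hydrophilicity,
average and monoisotopic residue masses (ExPASy), van der Waals volume,
Grantham polarity, free-amino-acid pI, side-chain pKa, side-chain charge at
pH 7, H-bond donor/acceptor counts, aromatic and aliphatic indicators,
Vihinen flexibility, Zimmerman bulkiness, Charton polarizability, and
theoretical maximum solvent accessibility (Tien 2013). Each entry records
units and citation and is exported as JSON (`pepfeat describe`). PTM
variants inherit the base residue's value unless the scale declares an
override; overrides are limited to what the modification physically
changes — mass deltas (phospho +79.966 Da, acetyl +42.011, methyl +14.016
monoisotopic), charge (phosphate ≈ −1.76 e at pH 7 from its second
ionization at pKa 6.5; acetyl-lysine 0) and hydrogen-bonding counts.
Hydrophobicity and structure-derived scales have no published PTM entries
and deliberately inherit.

**Whole-peptide (48 descriptors).** Twenty composition fractions (by base
amino acid, so they always sum to 1), length, average and monoisotopic
molecular weight, net charge at pH 7, charge density (charge/MW),
isoelectric point, instability index, aromaticity, aliphatic index (Ikai),
Boman index, GRAVY, Eisenberg mean hydrophobicity, hydrophobic moment at
100°, seven residue-class fractions (hydrophobic, polar, positive,
negative, tiny, small, large — membership sets documented in
`global_descriptors.py`), H-bond donor/acceptor totals, PTM count and
fraction, cysteine count, proline fraction, and N-/C-terminal hydropathy
indicators. The catalog is a registry queried by name; subsets select in
the order requested.

## Numerical choices

- **Charge model.** Henderson–Hasselbalch over the free N- and C-terminus,
  the D/E/C/Y (acidic) and H/K/R (basic) side chains, phosphate groups (two
  acidic ionizations, pKa 1.2 and 6.5) and acetyl-lysine (amine removed).
  Default pKa table: Lehninger (N-term 9.69, C-term 2.34, D 3.65, E 4.25,
  C 8.18, Y 10.07, H 6.00, K 10.53, R 12.48); a Sillero table ships in the
  same JSON file and is selectable by name, because pI values are
  pKa-set-dependent and published calculators disagree at the 0.1–0.5 pH
  level.
- **Isoelectric point.** The charge is a strictly decreasing function of pH
  and, with both termini free, positive at pH 0 and negative at pH 14, so a
  unique root exists in [0, 14]. Bisection to an interval of 1e-4 pH
  returns the midpoint. A consequence worth documenting: the "full
  protonation/deprotonation" limits at the pH boundaries hold only up to
  per-group residuals of `10^-pKa` and `10^(pKa−14)`. These are negligible
  for most groups but reach 0.029 elementary charges *per arginine* at
  pH 14 (pKa 12.48), so the pH-14 charge of an R-containing peptide sits
  measurably above −(1 + #DECY). The unit tests assert the exact residual
  form rather than pretending the asymptote is reached at the boundary.
- **Instability index.** `(10/L) Σ DIWV(x_i, x_{i+1})` over the bundled
  Guruprasad table; defined for L ≥ 2 (the standalone function raises for
  shorter input; inside the 48-vector a single residue reports 0.0 so the
  vector stays total). PTM residues use their base letter — the published
  weights have no PTM entries.
- **Hydrophobic moment.** Magnitude of the vector sum of Eisenberg
  hydrophobicities at successive multiples of the twist angle (default
  100°, the α-helix), divided by residue count. A single residue gives
  |h|; 18 uniform residues sweep exactly five turns and cancel to 0.
- **Masses.** Sum of residue masses plus one water; `average` is the
  default mass type (fixed for reproducibility), `monoisotopic` on request.
- **BLOSUM62.** The NCBI matrix ships verbatim in the standard text format
  and is parsed at first use; encoding columns follow the alphabetical
  amino-acid ordering used everywhere else in the package. All 8 PTM types
  collapse into the single optional 21st binary column — a per-PTM-type
  expansion is out of scope.
- **Degenerate inputs.** Empty sequences are rejected at parse time;
  padding shorter than the sequence, labels outside the vocabulary, one-hot
  rows without exactly one 1, pH outside [0, 14] and PTM probabilities
  outside [0, 1] all raise typed errors from one `PepfeatError` hierarchy.

## Synthetic data

All test inputs come from the seeded generator: residues uniform over the
20 canonical amino acids, each eligible residue independently modified with
a configurable probability (tag uniform among those legal for the base),
draws in a fixed order so a seed fully determines the output. The
throughput workload is the generator's default condition — random
unmodified 20-mers — with 10,000 sequences used in the test suite and
acceptance script; the benchmark subcommand scales to arbitrary n for
machine-dependent measurements, which are reported but never asserted.
Uniform-composition random peptides emulate none of the biases of real
peptide collections (amino-acid usage, positional motifs, length
distributions, co-occurrence of PTMs with motifs), so passing tests
demonstrate correctness of the encodings and descriptor arithmetic, not
predictive value of any representation on biological data.

## Known limitations

- The 18-scale and 48-descriptor catalogs are documented, citation-backed
  choices; other packages ship different membership, and both catalogs are
  JSON/registry-driven precisely so they can be re-pointed.
- Non-natural amino acids, cyclic peptides, terminus-level PTMs and
  structure-derived descriptors are out of scope.
- Descriptor values for PTM-bearing residues outside mass/charge/H-bond
  overrides inherit the unmodified residue and are therefore approximate.
- pI and net charge assume independent ionizations (no electrostatic
  coupling between groups), the standard approximation for sequence-based
  calculators.
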