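# pepfeat

Dependency-free peptide featurization for machine learning.

Machine-learning pipelines for peptides — activity prediction, toxicity
screening, de-novo generative design — all start by turning an amino-acid
sequence into numbers. `pepfeat` does exactly that, with no third-party
dependency, for sequences that may carry post-translational modifications
(PTMs) such as phosphorylation, acetylation and methylation. It is aimed at
practitioners who want to compare representation strategies without gluing
together several heavyweight packages.

## The five encodings

For a peptide of `L` residues over a 28-symbol dictionary (20 canonical
amino acids + 8 PTM-modified residue variants):

| encoder | captures | dimension |
|---|---|---|
| `peptide_descriptors` | 48 whole-peptide physicochemical descriptors | 48×1 |
| `aa_descriptors` | 18 per-residue property scales | L×18 |
| `blosum62` | evolutionary similarity (BLOSUM62 rows) + binary PTM flag | L×21 |
| `one_hot` | symbol identity per position | L×28 |
| `label` | vocabulary index per position | L×1 |

All per-position encoders optionally wrap sequences in `<beg>`/`<end>`
tokens (dictionary 28→30, rows L→L+2) for generative sequence models, and
support right-padding for batching.

The core numeric descriptors, in standard notation:

- **Net charge** at pH is the Henderson–Hasselbalch sum over ionizable
  groups: `Q(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH))`,
  over the free termini, D/E/C/Y and H/K/R side chains and charged PTMs
  (Lehninger pKa set by default). The **isoelectric point** is the root
  of this monotone function, found by bisection on pH ∈ [0, 14].
- **Instability index** (Guruprasad): `II = (10/L) Σ_i DIWV(x_i, x_i+1)`
  over the published dipeptide weight values.
- **Hydrophobic moment** (Eisenberg, default 100° helical twist):
  `μH = |Σ_j h_j e^(ijδ)| / L` with Eisenberg consensus hydrophobicities.
- Plus molecular weight (average or monoisotopic, PTM mass deltas
  included), GRAVY, aliphatic index, Boman index, composition fractions,
  and more — 48 in total (`pepfeat describe`).

## PTM notation

A modified residue carries a bracketed tag: `AS[p]K` is Ala–phosphoSer–Lys.
Tags: `[p]` phospho (S/T/Y), `[ac]` acetyl (K), `[me]`/`[me2]` mono/di-methyl
(K/R). Illegal combinations (e.g. `G[p]`) and non-canonical letters are
rejected with positioned error messages.

## Worked example

```python
from pepfeat import (parse_peptide, isoelectric_point, molecular_weight,
                     instability_index, net_charge, blosum62_encode)

seq = parse_peptide("GLFDIVKS[p]VVGALGSL")
print("pI  ", round(isoelectric_point(seq), 3))
print("MW  ", round(molecular_weight(seq), 2))
print("II  ", round(instability_index(seq), 2))
print("Q7  ", round(net_charge(seq, 7.0), 3))
m = blosum62_encode(seq)
print("blosum shape", m.shape, "ptm flag", m.rows[7][20])
```

prints

```
pI   3.016
MW   1654.86
II   -0.63
Q7   -1.762
blosum shape (16, 21) ptm flag 1.0
```

The phosphate pulls the isoelectric point down to 3.0 and contributes
−1.76 charges at pH 7; the instability index below 40 classifies the
peptide as stable; row 8 of the BLOSUM62 encoding flags the phosphoserine
in its 21st column while columns 1–20 stay those of serine.

The same runs from the shell, streaming record-by-record so
million-sequence FASTA files process at bounded memory:

```sh
pepfeat encode --method peptide_descriptors \
    --subset isoelectric_point,molecular_weight,instability_index \
    --input peptides.fasta -o descriptors.csv
pepfeat generate -n 1000 --length 20 --ptm-probability 0.1 --seed 7 -o random.fasta
pepfeat vocab --add-specials
pepfeat benchmark -n 100000 --length 20   # wall time + peak memory, informational
```

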