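"""BLOSUM62 evolutionary encoding.

Each residue becomes the vector of its BLOSUM62 substitution scores against
the 20 standard amino acids (columns in alphabetical one-letter order), so
similar amino acids get similar vectors. An optional 21st binary column
flags whether the residue carries any post-translational modification —
all 8 PTM types collapse to the one flag.

The matrix ships with the package as the NCBI BLOSUM62 file in the standard
substitution-matrix text format and is parsed at first use.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Tuple

from .errors import InvalidSymbolError
from .matrix import EncodingMatrix
from .vocabulary import STANDARD_AMINO_ACIDS, PeptideSequence

_scores: Dict[Tuple[str, str], int] = {}


def _parse_ncbi_matrix(text: str) -> Dict[Tuple[str, str], int]:
    scores: Dict[Tuple[str, str], int] = {}
    header: List[str] = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if not header:
            header = fields
            continue
        row_aa, values = fields[0], fields[1:]
        for col_aa, v in zip(header, values):
            scores[(row_aa, col_aa)] = int(v)
    return scores


def _matrix() -> Dict[Tuple[str, str], int]:
    if not _scores:
        text = resources.files("pepfeat.data").joinpath("blosum62.txt").read_text()
        _scores.update(_parse_ncbi_matrix(text))
    return _scores


def blosum62_score(a: str, b: str) -> int:
    """The BLOSUM62 substitution score for an ordered amino-acid pair."""
    for x in (a, b):
        if x not in STANDARD_AMINO_ACIDS:
            raise InvalidSymbolError(f"'{x}' is not a canonical amino acid")
    return _matrix()[(a, b)]


def blosum62_row(aa: str) -> List[int]:
    """The 20-vector of BLOSUM62 scores of ``aa`` against A..Y (alphabetical)."""
    if aa not in STANDARD_AMINO_ACIDS:
        raise InvalidSymbolError(f"'{aa}' is not a canonical amino acid")
    m = _matrix()
    return [m[(aa, b)] for b in STANDARD_AMINO_ACIDS]


def blosum62_encode(seq: PeptideSequence, ptm_dimension: bool = True) -> EncodingMatrix:
    """Encode a peptide as an L x 21 matrix (L x 20 with ``ptm_dimension=False``).

    Columns 1-20 are the BLOSUM62 row of each residue's base amino acid;
    column 21, when enabled, is 1 for residues carrying any PTM and 0
    otherwise.
    """
    cols = [f"blosum62_{a}" for a in STANDARD_AMINO_ACIDS]
    if ptm_dimension:
        cols.append("has_ptm")
    rows, labels = [], []
    for t in seq.tokens:
        row = [float(v) for v in blosum62_row(t.base)]
        if ptm_dimension:
            row.append(1.0 if t.is_modified else 0.0)
        rows.append(row)
        labels.append(t.symbol)
    return EncodingMatrix(rows, labels, cols)
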