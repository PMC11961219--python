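"""One-hot and label (integer) encodings over the shared vocabulary.

Both encoders speak the same 28-symbol dictionary (30 with the generative
``<beg>``/``<end>`` specials), so for every sequence ``s`` and position ``i``
the label ``label_encode(s)[i]`` equals the column index of the single 1 in
row ``i`` of ``one_hot_encode(s)``.

Padding (for fixed-size batches) is applied on the right: one-hot padding
rows are all-zero, label padding uses a dedicated index one past the end of
the vocabulary (28 without specials, 30 with), so it never collides with a
real symbol.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

from .errors import InvalidLabelError, LengthError, MalformedMatrixError
from .matrix import EncodingMatrix
from .vocabulary import (
    BEGIN_TOKEN,
    END_TOKEN,
    PeptideSequence,
    Vocabulary,
    build_vocabulary,
    parse_peptide,
)

_PAD_LABEL = "<pad>"


def _effective_symbols(seq: PeptideSequence, add_specials: bool) -> List[str]:
    symbols = [t.symbol for t in seq.tokens]
    if add_specials:
        symbols = [BEGIN_TOKEN, *symbols, END_TOKEN]
    return symbols


def _check_padding(n_rows: int, pad_to: Optional[int]) -> int:
    if pad_to is None:
        return n_rows
    if pad_to < n_rows:
        raise LengthError(
            f"pad_to={pad_to} is shorter than the encoded length {n_rows}"
        )
    return pad_to


def one_hot_encode(
    seq: PeptideSequence,
    add_specials: bool = False,
    pad_to: Optional[int] = None,
) -> EncodingMatrix:
    """Encode a peptide as an L x 28 binary matrix (L+2 x 30 with specials).

    Each non-padding row contains exactly one 1, at the vocabulary index of
    that residue's symbol; a PTM-modified residue lights its own dedicated
    column, not its base's. Padding rows are all-zero.
    """
    vocab = build_vocabulary(include_specials=add_specials)
    symbols = _effective_symbols(seq, add_specials)
    total = _check_padding(len(symbols), pad_to)
    d = len(vocab)
    rows, labels = [], []
    for s in symbols:
        row = [0.0] * d
        row[vocab.index(s)] = 1.0
        rows.append(row)
        labels.append(s)
    for _ in range(total - len(symbols)):
        rows.append([0.0] * d)
        labels.append(_PAD_LABEL)
    return EncodingMatrix(rows, labels, list(vocab.symbols))


def one_hot_decode(matrix: EncodingMatrix) -> PeptideSequence:
    """Invert :func:`one_hot_encode`, stripping specials and padding rows.

    Raises :class:`MalformedMatrixError` if any non-zero row does not contain
    exactly one 1.
    """
    symbols = []
    for i, row in enumerate(matrix.rows):
        ones = [j for j, v in enumerate(row) if v == 1.0]
        nonzero = sum(1 for v in row if v != 0.0)
        if nonzero == 0:
            continue  # padding row
        if len(ones) != 1 or nonzero != 1:
            raise MalformedMatrixError(
                f"row {i} does not contain exactly one 1 (found {nonzero} non-zeros)"
            )
        sym = matrix.col_labels[ones[0]]
        if sym in (BEGIN_TOKEN, END_TOKEN):
            continue
        symbols.append(sym)
    return parse_peptide("".join(symbols))


def label_encode(
    seq: PeptideSequence,
    add_specials: bool = False,
    pad_to: Optional[int] = None,
) -> List[int]:
    """Encode a peptide as the list of vocabulary indices of its residues."""
    vocab = build_vocabulary(include_specials=add_specials)
    symbols = _effective_symbols(seq, add_specials)
    total = _check_padding(len(symbols), pad_to)
    labels = [vocab.index(s) for s in symbols]
    labels.extend([vocab.pad_index] * (total - len(symbols)))
    return labels


def label_decode(
    labels: Sequence[int], add_specials: Optional[bool] = None
) -> PeptideSequence:
    """Invert :func:`label_encode`, stripping specials and padding indices.

    ``add_specials`` selects the vocabulary; when ``None`` it is inferred
    from the index range (indices >= 28 imply the special-token vocabulary).
    """
    if add_specials is None:
        add_specials = any(x >= 28 for x in labels)
    vocab = build_vocabulary(include_specials=add_specials)
    symbols = []
    for i, x in enumerate(labels):
        if not isinstance(x, int) or isinstance(x, bool):
            raise InvalidLabelError(f"label at position {i} is not an integer: {x!r}")
        if x == vocab.pad_index:
            continue
        if not 0 <= x < len(vocab):
            raise InvalidLabelError(
                f"label {x} at position {i} is outside the vocabulary "
                f"(valid: 0..{len(vocab) - 1}, padding: {vocab.pad_index})"
            )
        sym = vocab.symbol(x)
        if sym in (BEGIN_TOKEN, END_TOKEN):
            continue
        symbols.append(sym)
    return parse_peptide("".join(symbols))
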