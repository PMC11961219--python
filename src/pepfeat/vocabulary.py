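"""Symbol universe and peptide notation.

A peptide is written as a string of one-letter amino-acid codes in which a
modified residue carries a bracketed tag suffix::

    residue  :=  LETTER [ '[' tag ']' ]
    peptide  :=  residue+

``AS[p]K`` is a 3-residue peptide whose second residue is phosphoserine.
Supported tags and the bases they are legal on:

====== ===================== ============
tag    modification          legal bases
====== ===================== ============
p      phosphorylation       S, T, Y
ac     acetylation           K
me     mono-methylation      K, R
me2    di-methylation        K, R
====== ===================== ============

The core vocabulary has 28 symbols: the 20 canonical amino acids in
alphabetical order followed by the 8 modified-residue symbols, also
alphabetical (``K[ac] K[me] K[me2] R[me] R[me2] S[p] T[p] Y[p]``). With
generative special tokens enabled, ``<beg>`` and ``<end>`` are appended at
indices 28 and 29. The ordering is frozen: it is part of the package's
public contract, so encodings are reproducible across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence, Tuple

from .errors import EmptyInputError, IllegalModificationError, InvalidSymbolError

STANDARD_AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: tag -> (human name, bases the tag is legal on). This table is the single
#: point of configuration for the supported PTM set.
PTM_TAGS: Mapping[str, Tuple[str, frozenset]] = {
    "p": ("phosphorylation", frozenset("STY")),
    "ac": ("acetylation", frozenset("K")),
    "me": ("mono-methylation", frozenset("KR")),
    "me2": ("di-methylation", frozenset("KR")),
}

#: The 8 modified-residue symbols in frozen vocabulary order.
PTM_VARIANTS: Tuple[str, ...] = (
    "K[ac]", "K[me]", "K[me2]", "R[me]", "R[me2]", "S[p]", "T[p]", "Y[p]",
)

BEGIN_TOKEN: str = "<beg>"
END_TOKEN: str = "<end>"


@dataclass(frozen=True)
class ResidueToken:
    """One sequence element: a canonical amino acid plus an optional PTM tag."""

    base: str
    ptm: Optional[str] = None

    def __post_init__(self) -> None:
        if self.base not in STANDARD_AMINO_ACIDS:
            raise InvalidSymbolError(
                f"'{self.base}' is not one of the 20 canonical amino acids"
            )
        if self.ptm is not None:
            if self.ptm not in PTM_TAGS:
                raise InvalidSymbolError(f"unknown PTM tag '{self.ptm}'")
            name, legal = PTM_TAGS[self.ptm]
            if self.base not in legal:
                raise IllegalModificationError(
                    f"{name} ('{self.ptm}') is not legal on residue '{self.base}' "
                    f"(legal bases: {''.join(sorted(legal))})"
                )

    @property
    def symbol(self) -> str:
        """The vocabulary symbol, e.g. ``'A'`` or ``'S[p]'``."""
        return self.base if self.ptm is None else f"{self.base}[{self.ptm}]"

    @property
    def is_modified(self) -> bool:
        return self.ptm is not None


@dataclass(frozen=True)
class PeptideSequence:
    """An ordered, immutable list of residue tokens with optional provenance."""

    tokens: Tuple[ResidueToken, ...]
    source_id: Optional[str] = None
    metadata: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if not self.tokens:
            raise EmptyInputError("a peptide must contain at least one residue")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[ResidueToken]:
        return iter(self.tokens)

    def __str__(self) -> str:
        return render_peptide(self)

    @classmethod
    def from_text(cls, text: str, source_id: Optional[str] = None) -> "PeptideSequence":
        return parse_peptide(text, source_id=source_id)

    def __add__(self, other: "PeptideSequence") -> "PeptideSequence":
        return PeptideSequence(self.tokens + other.tokens)


def parse_peptide(text: str, source_id: Optional[str] = None) -> PeptideSequence:
    """Parse the bracket notation into a :class:`PeptideSequence`.

    Lowercase letters are accepted and canonicalised to uppercase; tags are
    case-insensitive. Position numbers in error messages are 1-based residue
    positions.

    Raises
    ------
    EmptyInputError
        on an empty (or whitespace-only) string.
    InvalidSymbolError
        on a letter outside the 20 canonical codes or an unknown tag.
    IllegalModificationError
        when a tag is applied to a base it is not legal for.
    """
    text = text.strip()
    if not text:
        raise EmptyInputError("empty peptide string")
    tokens = []
    i = 0
    pos = 0
    n = len(text)
    while i < n:
        ch = text[i].upper()
        pos += 1
        if ch not in STANDARD_AMINO_ACIDS:
            raise InvalidSymbolError(
                f"invalid symbol '{text[i]}' at residue position {pos}"
            )
        i += 1
        ptm = None
        if i < n and text[i] == "[":
            close = text.find("]", i + 1)
            if close < 0:
                raise InvalidSymbolError(
                    f"unterminated PTM tag at residue position {pos}"
                )
            tag = text[i + 1 : close].lower()
            if tag not in PTM_TAGS:
                raise InvalidSymbolError(
                    f"unknown PTM tag '[{tag}]' at residue position {pos}"
                )
            ptm = tag
            i = close + 1
        try:
            tokens.append(ResidueToken(ch, ptm))
        except IllegalModificationError as exc:
            raise IllegalModificationError(f"{exc} (residue position {pos})") from None
    return PeptideSequence(tuple(tokens), source_id=source_id)


def render_peptide(seq: PeptideSequence) -> str:
    """Render a sequence back to bracket notation; inverse of :func:`parse_peptide`."""
    return "".join(t.symbol for t in seq.tokens)


@dataclass(frozen=True)
class Vocabulary:
    """Ordered symbol set with a bijective symbol<->index map."""

    symbols: Tuple[str, ...]
    include_specials: bool
    index_of: Mapping[str, int] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "index_of", {s: i for i, s in enumerate(self.symbols)}
        )

    def __len__(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        try:
            return self.index_of[symbol]
        except KeyError:
            raise InvalidSymbolError(f"'{symbol}' is not in the vocabulary") from None

    def symbol(self, index: int) -> str:
        if not 0 <= index < len(self.symbols):
            raise InvalidSymbolError(f"index {index} is outside the vocabulary")
        return self.symbols[index]

    def token_index(self, token: ResidueToken) -> int:
        return self.index(token.symbol)

    @property
    def pad_index(self) -> int:
        """Reserved padding index for label encoding: one past the last symbol."""
        return len(self.symbols)

    def to_json(self, indent: int = 1) -> str:
        """Dump the vocabulary as JSON (symbol, index, base, ptm, description)."""
        entries = []
        for i, s in enumerate(self.symbols):
            if s in (BEGIN_TOKEN, END_TOKEN):
                base = ptm = None
                desc = "sequence-begin token" if s == BEGIN_TOKEN else "sequence-end token"
            elif "[" in s:
                base, tag = s[0], s[2:-1]
                ptm = tag
                desc = f"{PTM_TAGS[tag][0]} of {base}"
            else:
                base, ptm = s, None
                desc = f"canonical amino acid {s}"
            entries.append(
                {"symbol": s, "index": i, "base": base, "ptm": ptm, "description": desc}
            )
        return json.dumps(entries, indent=indent)


def build_vocabulary(include_specials: bool = False) -> Vocabulary:
    """Build the frozen vocabulary: 28 core symbols, 30 with begin/end specials."""
    symbols: Sequence[str] = tuple(STANDARD_AMINO_ACIDS) + PTM_VARIANTS
    if include_specials:
        symbols = symbols + (BEGIN_TOKEN, END_TOKEN)
    return Vocabulary(tuple(symbols), include_specials=include_specials)
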