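"""File ingestion/emission and the seeded random-peptide generator.

FASTA and CSV are read with the standard library only; sequence lines may
use the bracket PTM notation. The random generator draws residues uniformly
from the 20 canonical amino acids and, independently per eligible residue,
applies a PTM with a configurable probability — it supplies every test
input and the throughput workload (by default: unmodified 20-mers).
"""

from __future__ import annotations

import csv
import random
from typing import IO, Iterator, List, Optional, Union

from .errors import EmptyInputError, FileFormatError, PepfeatError, RangeError
from .vocabulary import (
    PTM_TAGS,
    STANDARD_AMINO_ACIDS,
    PeptideSequence,
    parse_peptide,
    render_peptide,
)

PathOrHandle = Union[str, IO[str]]


def _open_maybe(path_or_fh: PathOrHandle, mode: str = "r"):
    if hasattr(path_or_fh, "read") or hasattr(path_or_fh, "write"):
        return path_or_fh, False
    return open(path_or_fh, mode, newline="" if "w" in mode else None), True


def read_fasta(path: PathOrHandle) -> List[PeptideSequence]:
    """Read all records of a FASTA file; the full header becomes ``source_id``.

    Raises :class:`FileFormatError` with a line number for sequence data
    before the first header, and re-raises symbol errors citing the record.
    An empty file yields an empty list.
    """
    fh, close = _open_maybe(path)
    records: List[PeptideSequence] = []
    header: Optional[str] = None
    chunks: List[str] = []

    def flush() -> None:
        if header is None:
            return
        text = "".join(chunks)
        try:
            records.append(parse_peptide(text, source_id=header))
        except EmptyInputError:
            raise FileFormatError(f"record '{header}' has no sequence") from None
        except PepfeatError as exc:
            raise type(exc)(f"record '{header}': {exc}") from None

    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise FileFormatError(
                        f"line {lineno}: sequence data before first FASTA header"
                    )
                chunks.append(line)
        flush()
    finally:
        if close:
            fh.close()
    return records


def write_fasta(path: PathOrHandle, sequences: List[PeptideSequence]) -> None:
    fh, close = _open_maybe(path, "w")
    try:
        for i, seq in enumerate(sequences):
            fh.write(f">{seq.source_id or f'peptide_{i + 1}'}\n")
            fh.write(render_peptide(seq) + "\n")
    finally:
        if close:
            fh.close()


def read_sequence_csv(path: PathOrHandle, column: str) -> List[PeptideSequence]:
    """Read peptides from a named CSV column, keeping other columns as metadata.

    Row order is preserved; quoted fields are handled by the csv module.
    Raises :class:`FileFormatError` if the column is missing.
    """
    fh, close = _open_maybe(path)
    try:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or column not in reader.fieldnames:
            raise FileFormatError(
                f"CSV is missing the sequence column '{column}' "
                f"(found: {', '.join(reader.fieldnames or [])})"
            )
        out = []
        for i, row in enumerate(reader, start=1):
            meta = {k: v for k, v in row.items() if k != column}
            try:
                seq = parse_peptide(row[column])
            except PepfeatError as exc:
                raise type(exc)(f"CSV row {i}: {exc}") from None
            out.append(
                PeptideSequence(seq.tokens, source_id=f"row_{i}", metadata=meta)
            )
        return out
    finally:
        if close:
            fh.close()


def iter_random_peptides(
    n: int,
    length: int = 20,
    ptm_probability: float = 0.0,
    seed: int = 0,
) -> Iterator[PeptideSequence]:
    """Stream ``n`` seeded random peptides without materialising the list.

    Residues are uniform over the 20 canonical amino acids. Each residue
    whose base supports a PTM is modified with probability
    ``ptm_probability``, the tag drawn uniformly among its legal tags.
    Draws follow a fixed order (base, then modification), so a seed fully
    determines the output.
    """
    if n < 1 or length < 1:
        raise RangeError("n and length must both be >= 1")
    if not 0.0 <= ptm_probability <= 1.0:
        raise RangeError(f"ptm_probability must be in [0, 1], got {ptm_probability}")
    rng = random.Random(seed)
    legal_tags = {
        base: sorted(tag for tag, (_, bases) in PTM_TAGS.items() if base in bases)
        for base in STANDARD_AMINO_ACIDS
    }
    for i in range(n):
        parts = []
        for _ in range(length):
            base = rng.choice(STANDARD_AMINO_ACIDS)
            parts.append(base)
            tags = legal_tags[base]
            if tags and ptm_probability > 0.0 and rng.random() < ptm_probability:
                parts.append(f"[{rng.choice(tags)}]")
        yield parse_peptide("".join(parts), source_id=f"random_{i + 1}")


def generate_random_peptides(
    n: int,
    length: int = 20,
    ptm_probability: float = 0.0,
    seed: int = 0,
) -> List[PeptideSequence]:
    """List-returning wrapper around :func:`iter_random_peptides`."""
    return list(iter_random_peptides(n, length, ptm_probability, seed))
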