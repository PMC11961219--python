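"""Numeric output container shared by the per-residue encoders.

Kept as a thin list-of-rows wrapper so the package stays dependency-free;
``rows`` converts directly to a numpy array or torch tensor downstream.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import IO, List, Sequence, Tuple


@dataclass
class EncodingMatrix:
    """An L x D matrix with residue row labels and column metadata."""

    rows: List[List[float]]
    row_labels: List[str]
    col_labels: List[str]

    def __post_init__(self) -> None:
        d = len(self.col_labels)
        if any(len(r) != d for r in self.rows):
            raise ValueError("all rows must match the number of column labels")
        if len(self.row_labels) != len(self.rows):
            raise ValueError("one row label per row required")

    @property
    def shape(self) -> Tuple[int, int]:
        return len(self.rows), len(self.col_labels)

    def column(self, name: str) -> List[float]:
        j = self.col_labels.index(name)
        return [r[j] for r in self.rows]

    def write_csv(self, fh: IO[str], id_prefix: Sequence[str] = ()) -> None:
        """Write long-format CSV rows: [*id_prefix, position, residue, values...]."""
        w = csv.writer(fh)
        for i, (label, row) in enumerate(zip(self.row_labels, self.rows), start=1):
            w.writerow([*id_prefix, i, label, *row])

    def to_json(self) -> str:
        return json.dumps(
            {"row_labels": self.row_labels, "col_labels": self.col_labels,
             "rows": self.rows}
        )
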