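"""Per-residue physicochemical encoding (L x 18 by default).

Every residue is mapped to 18 literature property values — hydropathy and
hydrophobicity scales, masses, volume, polarity, ionization, hydrogen-bond
counts, aromatic/aliphatic indicators, flexibility, bulkiness,
polarizability and solvent accessibility. The catalog ships as a JSON data
file (name, units, 20 values, PTM overrides, citation) so it can be
inspected, exported, or replaced wholesale. PTM-modified residues inherit
the base amino acid's value unless the scale declares an override (mass and
charge-bearing scales do).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence

from .errors import CatalogError
from .matrix import EncodingMatrix
from .vocabulary import PeptideSequence, ResidueToken


@dataclass(frozen=True)
class PropertyScale:
    """A named per-residue property with units, citation and PTM overrides."""

    name: str
    units: str
    citation: str
    values: Mapping[str, float]
    ptm_overrides: Mapping[str, float] = field(default_factory=dict)

    def value(self, token: ResidueToken) -> float:
        if token.is_modified and token.symbol in self.ptm_overrides:
            return self.ptm_overrides[token.symbol]
        return self.values[token.base]


class DescriptorCatalog:
    """Ordered collection of :class:`PropertyScale` objects."""

    def __init__(self, scales: Sequence[PropertyScale]):
        self.scales = list(scales)
        self._by_name = {s.name: s for s in self.scales}
        if len(self._by_name) != len(self.scales):
            raise CatalogError("duplicate scale names in catalog")

    def __len__(self) -> int:
        return len(self.scales)

    def names(self) -> List[str]:
        return [s.name for s in self.scales]

    def get(self, name: str) -> PropertyScale:
        try:
            return self._by_name[name]
        except KeyError:
            raise CatalogError(
                f"unknown property '{name}'; valid names: {', '.join(self.names())}"
            ) from None

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(
            [
                {
                    "name": s.name,
                    "units": s.units,
                    "citation": s.citation,
                    "values": dict(s.values),
                    "ptm_overrides": dict(s.ptm_overrides),
                }
                for s in self.scales
            ],
            indent=indent,
        )


_catalog: Optional[DescriptorCatalog] = None


def default_catalog() -> DescriptorCatalog:
    """The shipped 18-scale catalog, loaded once from the JSON data file."""
    global _catalog
    if _catalog is None:
        raw = json.loads(
            resources.files("pepfeat.data").joinpath("aa_scales.json").read_text()
        )
        _catalog = DescriptorCatalog(
            [
                PropertyScale(
                    name=s["name"],
                    units=s["units"],
                    citation=s["citation"],
                    values=s["values"],
                    ptm_overrides=s.get("ptm_overrides", {}),
                )
                for s in raw["scales"]
            ]
        )
    return _catalog


def get_scale(name: str) -> PropertyScale:
    return default_catalog().get(name)


def list_aa_properties() -> List[str]:
    """The 18 property names in their stable catalog order."""
    return default_catalog().names()


def aa_descriptor_encode(
    seq: PeptideSequence, properties: Optional[Sequence[str]] = None
) -> EncodingMatrix:
    """Encode a peptide as an L x 18 matrix (L x k for a k-name subset).

    Entry (i, j) is property j's value for residue i; row i depends only on
    token i. Unknown property names raise :class:`CatalogError` listing the
    valid names.
    """
    catalog = default_catalog()
    scales = [catalog.get(n) for n in (properties or catalog.names())]
    rows = [[s.value(t) for s in scales] for t in seq.tokens]
    return EncodingMatrix(rows, [t.symbol for t in seq.tokens], [s.name for s in scales])
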