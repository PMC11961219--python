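"""Whole-peptide descriptors: one 48-dimensional numeric vector per sequence.

The catalog covers amino-acid composition (20 fractions), size and mass,
the charge model (net charge, charge density, isoelectric point),
stability (Guruprasad instability index), hydrophobicity (GRAVY, Eisenberg
mean, Boman index, 100-degree hydrophobic moment), residue-class fractions,
hydrogen-bonding totals, PTM counts and terminal hydropathy indicators.

Charge model
------------
Net charge at a given pH is the Henderson–Hasselbalch sum over the free
N-terminus, free C-terminus, the ionizable side chains (D, E, C, Y acidic;
H, K, R basic) and PTM-introduced groups (a phosphate contributes two
acidic ionizations; acetylation of lysine removes its amine). The default
pKa set is the Lehninger table; alternative sets ship in the same JSON file
and are selectable by name. The isoelectric point is the root of this
monotone-decreasing function on pH in [0, 14], found by bisection.

PTMs contribute their mass and charge deltas; the dipeptide instability
weights and hydrophobicity scales have no published PTM entries, so those
descriptors use the base residue.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .aa_descriptors import get_scale
from .errors import CatalogError, LengthError, RangeError
from .vocabulary import STANDARD_AMINO_ACIDS, PeptideSequence

WATER_AVERAGE = 18.01528
WATER_MONOISOTOPIC = 18.010565

#: Negated Radzicka–Wolfenden transfer free energies (kcal/mol) used for the
#: Boman protein-binding index; proline was not measured and is set to 0.
BOMAN_SCALE: Dict[str, float] = {
    "L": -4.92, "I": -4.92, "V": -4.04, "F": -2.98, "M": -2.35, "W": -2.33,
    "A": -1.81, "C": -1.28, "G": -0.94, "P": 0.0, "Y": 0.14, "T": 2.57,
    "S": 3.40, "H": 4.66, "Q": 5.54, "K": 5.55, "N": 6.64, "E": 6.81,
    "D": 8.72, "R": 14.92,
}

# Residue-class sets used by the fraction descriptors (by base amino acid).
AROMATIC = frozenset("FWY")
POSITIVE = frozenset("HKR")
NEGATIVE = frozenset("DE")
POLAR = frozenset("DEHKNQRSTY")
TINY = frozenset("ACGST")
SMALL = frozenset("ACDGNPSTV")
LARGE = frozenset("EFHIKLMQRWY")
HYDROPHOBIC = frozenset("ACFILMV")  # Kyte–Doolittle hydropathy > 0


# ----------------------------------------------------------------- pKa model

_pka_raw: Optional[dict] = None


def _pka_tables() -> dict:
    global _pka_raw
    if _pka_raw is None:
        _pka_raw = json.loads(
            resources.files("pepfeat.data").joinpath("pka_tables.json").read_text()
        )
    return _pka_raw


def list_pka_tables() -> List[str]:
    return sorted(_pka_tables()["tables"])


def _ionizable_groups(
    seq: PeptideSequence, table_name: str
) -> List[Tuple[float, int]]:
    """All (pKa, sign) ionizations of a peptide under a named pKa table."""
    tables = _pka_tables()["tables"]
    try:
        t = tables[table_name]
    except KeyError:
        raise CatalogError(
            f"unknown pKa table '{table_name}'; available: {', '.join(sorted(tables))}"
        ) from None
    groups: List[Tuple[float, int]] = [
        (t["n_terminus"], +1),
        (t["c_terminus"], -1),
    ]
    removed = t.get("ptm_removes_sidechain", {})
    for tok in seq.tokens:
        if not (tok.is_modified and removed.get(tok.symbol)):
            if tok.base in t["acidic_sidechains"]:
                groups.append((t["acidic_sidechains"][tok.base], -1))
            elif tok.base in t["basic_sidechains"]:
                groups.append((t["basic_sidechains"][tok.base], +1))
        if tok.is_modified:
            for pka in t.get("ptm_acidic_groups", {}).get(tok.ptm, []):
                groups.append((pka, -1))
    return groups


def net_charge(
    seq: PeptideSequence, ph: float = 7.0, pka_table: str = "lehninger"
) -> float:
    """Net charge in elementary units at the given pH (default 7.0).

    Henderson–Hasselbalch over every ionizable group: a base contributes
    ``+1/(1+10^(pH-pKa))``, an acid ``-1/(1+10^(pKa-pH))``. Strictly
    decreasing in pH. Raises :class:`RangeError` for pH outside [0, 14].
    """
    if not 0.0 <= ph <= 14.0:
        raise RangeError(f"pH must be in [0, 14], got {ph}")
    total = 0.0
    for pka, sign in _ionizable_groups(seq, pka_table):
        if sign > 0:
            total += 1.0 / (1.0 + 10.0 ** (ph - pka))
        else:
            total -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    return total


def isoelectric_point(
    seq: PeptideSequence, pka_table: str = "lehninger", tol: float = 1e-4
) -> float:
    """The pH at which net charge is zero, by bisection on [0, 14] to ``tol``.

    With both termini free the charge runs from positive at pH 0 to negative
    at pH 14 and is strictly decreasing, so the root exists and is unique.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka_table) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# -------------------------------------------------------------------- masses


def molecular_weight(seq: PeptideSequence, mass_type: str = "average") -> float:
    """Peptide mass in daltons: residue masses plus one water, PTM deltas included."""
    if mass_type == "average":
        scale, water = get_scale("residue_mass_average"), WATER_AVERAGE
    elif mass_type == "monoisotopic":
        scale, water = get_scale("residue_mass_monoisotopic"), WATER_MONOISOTOPIC
    else:
        raise CatalogError(
            f"mass_type must be 'average' or 'monoisotopic', got '{mass_type}'"
        )
    return sum(scale.value(t) for t in seq.tokens) + water


# ----------------------------------------------------------------- stability

_diwv: Optional[Dict[str, Dict[str, float]]] = None


def diwv_table() -> Dict[str, Dict[str, float]]:
    """The 20x20 dipeptide instability weight values, loaded from package data."""
    global _diwv
    if _diwv is None:
        raw = json.loads(
            resources.files("pepfeat.data").joinpath("diwv.json").read_text()
        )
        _diwv = raw["values"]
    return _diwv


def instability_index(seq: PeptideSequence) -> float:
    """Guruprasad instability index: (10/L) * sum of DIWV over adjacent pairs.

    Values above 40 predict an unstable peptide. PTM-modified residues use
    their base letter (the published weights have no PTM entries). Requires
    length >= 2.
    """
    if len(seq) < 2:
        raise LengthError("instability index requires at least 2 residues")
    w = diwv_table()
    bases = [t.base for t in seq.tokens]
    total = sum(w[a][b] for a, b in zip(bases, bases[1:]))
    return 10.0 / len(seq) * total


# ------------------------------------------------------------ hydrophobicity


def gravy(seq: PeptideSequence) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value."""
    s = get_scale("kyte_doolittle_hydropathy")
    return sum(s.value(t) for t in seq.tokens) / len(seq)


def mean_hydrophobicity(seq: PeptideSequence) -> float:
    """Mean Eisenberg consensus hydrophobicity."""
    s = get_scale("eisenberg_hydrophobicity")
    return sum(s.value(t) for t in seq.tokens) / len(seq)


def boman_index(seq: PeptideSequence) -> float:
    """Mean protein-binding potential; higher values favour protein binding."""
    return sum(BOMAN_SCALE[t.base] for t in seq.tokens) / len(seq)


def hydrophobic_moment(seq: PeptideSequence, angle: float = 100.0) -> float:
    """Eisenberg hydrophobic moment at a helical twist (default 100 degrees).

    The magnitude of the vector sum of Eisenberg hydrophobicities placed at
    successive multiples of ``angle``, divided by the number of residues;
    an amphipathicity measure.
    """
    s = get_scale("eisenberg_hydrophobicity")
    delta = math.radians(angle)
    sin_sum = cos_sum = 0.0
    for i, t in enumerate(seq.tokens):
        h = s.value(t)
        sin_sum += h * math.sin(i * delta)
        cos_sum += h * math.cos(i * delta)
    return math.hypot(sin_sum, cos_sum) / len(seq)


# ----------------------------------------------------------- catalog plumbing


def _fraction(seq: PeptideSequence, members: frozenset) -> float:
    return sum(1 for t in seq.tokens if t.base in members) / len(seq)


def _scale_total(seq: PeptideSequence, scale_name: str) -> float:
    s = get_scale(scale_name)
    return sum(s.value(t) for t in seq.tokens)


def aliphatic_index(seq: PeptideSequence) -> float:
    """Ikai aliphatic index: 100*(X_A + 2.9*X_V + 3.9*(X_I + X_L))."""
    f = {a: _fraction(seq, frozenset(a)) for a in "AVIL"}
    return 100.0 * (f["A"] + 2.9 * f["V"] + 3.9 * (f["I"] + f["L"]))


def _safe_instability(seq: PeptideSequence) -> float:
    # In the 48-vector a single residue has no dipeptide, reported as 0.0;
    # the standalone operation still raises for length < 2.
    return instability_index(seq) if len(seq) >= 2 else 0.0


_DescriptorFn = Callable[[PeptideSequence], float]


def _build_registry() -> List[Tuple[str, str, _DescriptorFn]]:
    reg: List[Tuple[str, str, _DescriptorFn]] = []
    for a in STANDARD_AMINO_ACIDS:
        reg.append(
            (f"fraction_{a}", "composition",
             lambda s, _a=a: _fraction(s, frozenset(_a)))
        )
    reg.extend(
        [
            ("length", "composition", lambda s: float(len(s))),
            ("molecular_weight", "sum-scale",
             lambda s: molecular_weight(s, "average")),
            ("molecular_weight_monoisotopic", "sum-scale",
             lambda s: molecular_weight(s, "monoisotopic")),
            ("net_charge_ph7", "charge-model", lambda s: net_charge(s, 7.0)),
            ("charge_density", "charge-model",
             lambda s: net_charge(s, 7.0) / molecular_weight(s, "average")),
            ("isoelectric_point", "charge-model", isoelectric_point),
            ("instability_index", "dipeptide-model", _safe_instability),
            ("aromaticity", "composition", lambda s: _fraction(s, AROMATIC)),
            ("aliphatic_index", "composition", aliphatic_index),
            ("boman_index", "mean-scale", boman_index),
            ("gravy", "mean-scale", gravy),
            ("eisenberg_mean_hydrophobicity", "mean-scale", mean_hydrophobicity),
            ("hydrophobic_moment_100", "moment-model", hydrophobic_moment),
            ("hydrophobic_fraction", "composition",
             lambda s: _fraction(s, HYDROPHOBIC)),
            ("polar_fraction", "composition", lambda s: _fraction(s, POLAR)),
            ("positive_fraction", "composition", lambda s: _fraction(s, POSITIVE)),
            ("negative_fraction", "composition", lambda s: _fraction(s, NEGATIVE)),
            ("tiny_fraction", "composition", lambda s: _fraction(s, TINY)),
            ("small_fraction", "composition", lambda s: _fraction(s, SMALL)),
            ("large_fraction", "composition", lambda s: _fraction(s, LARGE)),
            ("h_bond_donor_total", "sum-scale",
             lambda s: _scale_total(s, "h_bond_donors")),
            ("h_bond_acceptor_total", "sum-scale",
             lambda s: _scale_total(s, "h_bond_acceptors")),
            ("ptm_count", "composition",
             lambda s: float(sum(1 for t in s.tokens if t.is_modified))),
            ("ptm_fraction", "composition",
             lambda s: sum(1 for t in s.tokens if t.is_modified) / len(s)),
            ("cysteine_count", "composition",
             lambda s: float(sum(1 for t in s.tokens if t.base == "C"))),
            ("proline_fraction", "composition",
             lambda s: _fraction(s, frozenset("P"))),
            ("n_terminal_hydropathy", "composition",
             lambda s: get_scale("kyte_doolittle_hydropathy").values[s.tokens[0].base]),
            ("c_terminal_hydropathy", "composition",
             lambda s: get_scale("kyte_doolittle_hydropathy").values[s.tokens[-1].base]),
        ]
    )
    return reg


_REGISTRY = _build_registry()
_BY_NAME = {name: fn for name, _, fn in _REGISTRY}


def list_global_descriptors() -> List[str]:
    """The 48 descriptor names in their stable catalog order."""
    return [name for name, _, _ in _REGISTRY]


def describe_global_catalog(indent: int = 1) -> str:
    """JSON description of the global catalog (name + computation kind)."""
    return json.dumps(
        [{"name": n, "kind": k} for n, k, _ in _REGISTRY], indent=indent
    )


def global_descriptor_vector(
    seq: PeptideSequence, names: Optional[Sequence[str]] = None
) -> List[float]:
    """Compute the 48-vector (or the requested subset, in the given order)."""
    if names is None:
        names = list_global_descriptors()
    out = []
    for n in names:
        try:
            fn = _BY_NAME[n]
        except KeyError:
            raise CatalogError(
                f"unknown descriptor '{n}'; valid names: "
                f"{', '.join(list_global_descriptors())}"
            ) from None
        out.append(fn(seq))
    return out
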