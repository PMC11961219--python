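"""Whole-peptide descriptors: charge model, pI, stability, hydrophobicity.

Oracles: biopython for molecular weight and the instability index, a numpy
grid scan for the isoelectric point, and an inline trigonometric
re-implementation for the hydrophobic moment.
"""

import math
import random

import numpy as np
import pytest
from Bio.SeqUtils import molecular_weight as bp_molecular_weight
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from pepfeat import (
    CatalogError,
    LengthError,
    PeptideSequence,
    RangeError,
    global_descriptor_vector,
    hydrophobic_moment,
    instability_index,
    isoelectric_point,
    list_global_descriptors,
    molecular_weight,
    net_charge,
    parse_peptide,
    render_peptide,
)
from pepfeat.global_descriptors import diwv_table

# Lehninger pKa constants, re-listed here independently of the package data.
PKA_ACID = {"cterm": 2.34, "D": 3.65, "E": 4.25, "C": 8.18, "Y": 10.07}
PKA_BASE = {"nterm": 9.69, "H": 6.00, "K": 10.53, "R": 12.48}

# Eisenberg consensus hydrophobicity, re-typed for the moment oracle.
EISENBERG = {"A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
             "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
             "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
             "Y": 0.26, "V": 1.08}


def grid_scan_pi(seq, fine_step=1e-4):
    """Independent pI oracle: coarse numpy grid, then a fine local grid."""
    def charges(ph_grid):
        total = np.zeros_like(ph_grid)
        groups = [(PKA_BASE["nterm"], +1), (PKA_ACID["cterm"], -1)]
        for t in seq.tokens:
            if t.base in PKA_ACID:
                groups.append((PKA_ACID[t.base], -1))
            elif t.base in PKA_BASE:
                groups.append((PKA_BASE[t.base], +1))
        for pka, sign in groups:
            if sign > 0:
                total += 1.0 / (1.0 + 10.0 ** (ph_grid - pka))
            else:
                total -= 1.0 / (1.0 + 10.0 ** (pka - ph_grid))
        return total

    coarse = np.arange(0.0, 14.0 + 1e-9, 0.001)
    best = coarse[np.argmin(np.abs(charges(coarse)))]
    fine = np.arange(max(0.0, best - 0.002), min(14.0, best + 0.002), fine_step)
    return fine[np.argmin(np.abs(charges(fine)))]


class TestMolecularWeight:
    def test_single_glycine(self):
        assert molecular_weight(parse_peptide("G")) == pytest.approx(75.07, abs=0.01)

    def test_additivity_under_concatenation(self):
        s1, s2 = parse_peptide("ACDK"), parse_peptide("WWGH")
        water = 18.01528
        assert molecular_weight(s1 + s2) == pytest.approx(
            molecular_weight(s1) + molecular_weight(s2) - water, abs=1e-6
        )

    def test_phosphate_mass_delta(self):
        delta = (molecular_weight(parse_peptide("S[p]"), "monoisotopic")
                 - molecular_weight(parse_peptide("S"), "monoisotopic"))
        assert delta == pytest.approx(79.966, abs=1e-3)

    def test_matches_biopython_on_random_peptides(self, random_unmodified):
        for seq in random_unmodified[:100]:
            text = render_peptide(seq)
            assert molecular_weight(seq) == pytest.approx(
                bp_molecular_weight(text, "protein"), rel=1e-4
            )
            assert molecular_weight(seq, "monoisotopic") == pytest.approx(
                bp_molecular_weight(text, "protein", monoisotopic=True), rel=1e-4
            )

    def test_unknown_mass_type(self):
        with pytest.raises(CatalogError):
            molecular_weight(parse_peptide("G"), "isotopic")


class TestNetCharge:
    def test_ph_outside_range_rejected(self):
        for ph in (-0.1, 14.2):
            with pytest.raises(RangeError):
                net_charge(parse_peptide("ACDK"), ph)

    def test_strictly_decreasing_in_ph(self, random_unmodified):
        for seq in random_unmodified[:30]:
            values = [net_charge(seq, ph) for ph in np.linspace(0, 14, 30)]
            assert all(a > b for a, b in zip(values, values[1:]))

    @staticmethod
    def _oracle_charge(seq, ph):
        """Independent Henderson–Hasselbalch sum from the re-typed constants."""
        groups = [(PKA_BASE["nterm"], +1), (PKA_ACID["cterm"], -1)]
        for t in seq.tokens:
            if t.base in PKA_ACID:
                groups.append((PKA_ACID[t.base], -1))
            elif t.base in PKA_BASE:
                groups.append((PKA_BASE[t.base], +1))
        return sum(
            sign / (1.0 + 10.0 ** (sign * (ph - pka))) for pka, sign in groups
        )

    def test_full_protonation_limit(self, random_unmodified):
        # At pH 0 the charge approaches +(1 + #HKR); the deviation is the sum
        # of the acid- and base-group residuals, each bounded by 10^-pKa.
        for seq in random_unmodified[:50]:
            bases = [t.base for t in seq.tokens]
            limit = 1 + sum(bases.count(a) for a in "HKR")
            bound = 10.0 ** -PKA_ACID["cterm"] + 10.0 ** -PKA_BASE["nterm"]
            bound += sum(10.0 ** -PKA_ACID[a] for a in bases if a in PKA_ACID)
            bound += sum(10.0 ** -PKA_BASE[a] for a in bases if a in PKA_BASE)
            q = net_charge(seq, 0.0)
            assert q == pytest.approx(self._oracle_charge(seq, 0.0), abs=1e-12)
            assert abs(q - limit) <= bound + 1e-12

    def test_full_deprotonation_limit(self, random_unmodified):
        # At pH 14 the charge approaches -(1 + #DECY); the residual is
        # dominated by arginine, 10^-(14-12.48) ~ 0.029 per R.
        for seq in random_unmodified[:50]:
            bases = [t.base for t in seq.tokens]
            limit = -(1 + sum(bases.count(a) for a in "DECY"))
            bound = 10.0 ** (PKA_BASE["nterm"] - 14.0)
            bound += 10.0 ** -(14.0 - PKA_ACID["cterm"])
            bound += sum(10.0 ** (PKA_BASE[a] - 14.0)
                         for a in bases if a in PKA_BASE)
            bound += sum(10.0 ** (PKA_ACID[a] - 14.0)
                         for a in bases if a in PKA_ACID)
            q = net_charge(seq, 14.0)
            assert q == pytest.approx(self._oracle_charge(seq, 14.0), abs=1e-12)
            assert abs(q - limit) <= bound + 1e-12

    def test_acetyl_lysine_loses_positive_charge(self):
        assert net_charge(parse_peptide("K[ac]"), 7.0) == pytest.approx(
            net_charge(parse_peptide("A"), 7.0), abs=1e-6
        )
        assert net_charge(parse_peptide("K"), 7.0) > net_charge(
            parse_peptide("K[ac]"), 7.0) + 0.9

    def test_phosphorylation_adds_negative_charge(self):
        assert net_charge(parse_peptide("AS[p]K"), 7.0) < net_charge(
            parse_peptide("ASK"), 7.0) - 1.5


class TestIsoelectricPoint:
    def test_charge_at_pi_is_zero(self, random_modified):
        for seq in random_modified[:100]:
            assert abs(net_charge(seq, isoelectric_point(seq))) < 1e-3

    def test_acidic_below_7_basic_above(self):
        assert isoelectric_point(parse_peptide("DDDD")) < 7.0
        assert isoelectric_point(parse_peptide("KKKK")) > 7.0

    def test_agrees_with_grid_scan_oracle(self, random_unmodified):
        for seq in random_unmodified[:100]:
            assert isoelectric_point(seq) == pytest.approx(
                grid_scan_pi(seq), abs=0.01
            )

    def test_unknown_pka_table_rejected(self):
        with pytest.raises(CatalogError):
            isoelectric_point(parse_peptide("ACDK"), pka_table="imaginary")

    def test_alternative_pka_table_shifts_but_stays_ordered(self):
        assert isoelectric_point(parse_peptide("DDDD"), "sillero") < 7.0
        assert isoelectric_point(parse_peptide("KKKK"), "sillero") > 7.0


class TestInstabilityIndex:
    def test_dipeptide_closed_form(self):
        w = diwv_table()
        assert instability_index(parse_peptide("GG")) == pytest.approx(
            5.0 * w["G"]["G"]
        )

    def test_homopolymer_closed_form(self):
        w = diwv_table()
        for n in (2, 5, 17):
            seq = parse_peptide("W" * n)
            assert instability_index(seq) == pytest.approx(
                10.0 * (n - 1) / n * w["W"]["W"]
            )

    def test_length_one_rejected(self):
        with pytest.raises(LengthError):
            instability_index(parse_peptide("G"))

    def test_matches_pair_loop_and_biopython(self, random_unmodified):
        w = diwv_table()
        for seq in random_unmodified:
            if len(seq) < 2:
                continue
            text = render_peptide(seq)
            naive = 10.0 / len(seq) * sum(
                w[a][b] for a, b in zip(text, text[1:])
            )
            assert instability_index(seq) == pytest.approx(naive, abs=1e-9)
            assert instability_index(seq) == pytest.approx(
                ProteinAnalysis(text).instability_index(), abs=0.01
            )

    def test_ptm_residues_use_base_letter(self):
        assert instability_index(parse_peptide("AS[p]K")) == instability_index(
            parse_peptide("ASK")
        )


class TestHydrophobicMoment:
    def test_single_residue_is_absolute_hydrophobicity(self):
        for aa in "AWRD":
            assert hydrophobic_moment(parse_peptide(aa)) == pytest.approx(
                abs(EISENBERG[aa])
            )

    def test_matches_trigonometric_oracle(self, random_unmodified):
        for seq in random_unmodified:
            for angle in (100.0, 160.0):
                delta = math.radians(angle)
                h = [EISENBERG[t.base] for t in seq.tokens]
                s = sum(v * math.sin(i * delta) for i, v in enumerate(h))
                c = sum(v * math.cos(i * delta) for i, v in enumerate(h))
                expected = math.sqrt(s * s + c * c) / len(seq)
                assert hydrophobic_moment(seq, angle) == pytest.approx(expected)

    def test_uniform_sequence_cancels_over_full_turn_cycle(self):
        # 18 residues at 100 degrees sweep exactly 5 turns, so equal-magnitude
        # vectors cancel and the moment vanishes.
        assert hydrophobic_moment(parse_peptide("A" * 18)) == pytest.approx(
            0.0, abs=1e-9
        )


class TestDescriptorVector:
    def test_48_unique_names_all_computable(self):
        names = list_global_descriptors()
        assert len(names) == 48
        assert len(set(names)) == 48
        vec = global_descriptor_vector(parse_peptide("ACDK"))
        assert len(vec) == 48
        assert all(math.isfinite(v) for v in vec)

    def test_composition_fractions_sum_to_one(self, random_modified):
        names = list_global_descriptors()
        idx = [i for i, n in enumerate(names) if n.startswith("fraction_")]
        assert len(idx) == 20
        for seq in random_modified[:50]:
            vec = global_descriptor_vector(seq)
            assert sum(vec[i] for i in idx) == pytest.approx(1.0, abs=1e-9)

    def test_subset_matches_individual_operations(self):
        seq = parse_peptide("GLFDIVKKVVGALGSL")
        trio = global_descriptor_vector(
            seq, ["isoelectric_point", "molecular_weight", "instability_index"]
        )
        assert trio == [
            isoelectric_point(seq),
            molecular_weight(seq),
            instability_index(seq),
        ]

    def test_unknown_name_rejected(self):
        with pytest.raises(CatalogError, match="isoelectric_point"):
            global_descriptor_vector(parse_peptide("ACDK"), ["pH"])

    def test_charge_density_times_mw_equals_charge(self, random_modified):
        names = list_global_descriptors()
        for seq in random_modified[:30]:
            vec = dict(zip(names, global_descriptor_vector(seq)))
            assert vec["charge_density"] * vec["molecular_weight"] == pytest.approx(
                vec["net_charge_ph7"], abs=1e-9
            )

    def test_composition_invariant_order_sensitive_split(self):
        seq = parse_peptide("ACDEFGHIKLMNP")
        rng = random.Random(11)
        perm = list(range(len(seq)))
        rng.shuffle(perm)
        shuffled = PeptideSequence(tuple(seq.tokens[i] for i in perm))
        names = list_global_descriptors()
        a = dict(zip(names, global_descriptor_vector(seq)))
        b = dict(zip(names, global_descriptor_vector(shuffled)))
        for n in names:
            if n.startswith("fraction_") or n in (
                "length", "molecular_weight", "aromaticity", "gravy",
                "net_charge_ph7", "isoelectric_point",
            ):
                assert a[n] == pytest.approx(b[n], abs=1e-9)
        assert a["instability_index"] != pytest.approx(b["instability_index"])
        assert a["hydrophobic_moment_100"] != pytest.approx(b["hydrophobic_moment_100"])

    def test_finite_over_full_alphabet_and_lengths(self):
        # every symbol of the 28-symbol alphabet, plus length extremes
        all_symbols = "ACDEFGHIKLMNPQRSTVWYK[ac]K[me]K[me2]R[me]R[me2]S[p]T[p]Y[p]"
        for text in ("G", all_symbols, "M" * 500):
            vec = global_descriptor_vector(parse_peptide(text))
            assert all(math.isfinite(v) for v in vec)

    def test_single_residue_reports_zero_instability_in_vector(self):
        names = list_global_descriptors()
        vec = dict(zip(names, global_descriptor_vector(parse_peptide("G"))))
        assert vec["instability_index"] == 0.0
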