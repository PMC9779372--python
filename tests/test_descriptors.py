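"""Descriptor suite against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from acpdesign import (
    CANONICAL_AA,
    HelixGeometry,
    Peptide,
    describe,
    face_segregation,
    helical_wheel,
    hydrophobic_moment,
    mean_hydrophobicity,
    molecular_weight,
    net_charge,
    solubility_estimate,
)
from acpdesign.peptide import HYDROPHOBIC_AA

sequences = st.text(alphabet=CANONICAL_AA, min_size=1, max_size=30)


def _pep(seq):
    return Peptide("t", seq)


# ---------------------------------------------------------------- oracles

def oracle_moment(seq, scale, delta_deg=100.0):
    """Independent complex-accumulation hydrophobic moment."""
    acc = 0j
    for n, r in enumerate(seq):
        acc += scale.hydrophobicity[r] * np.exp(1j * math.radians(delta_deg) * n)
    return abs(acc) / len(seq)


def oracle_hh_charge(seq, scale, ph):
    """Henderson-Hasselbalch titration written independently."""
    q = 0.0
    q += 1 / (1 + 10 ** (ph - scale.pka_nterm))
    q -= 1 / (1 + 10 ** (scale.pka_cterm - ph))
    for r in seq:
        if r in "KRH":
            q += 1 / (1 + 10 ** (ph - scale.pka_side_chain[r]))
        elif r in "DECY":
            q -= 1 / (1 + 10 ** (scale.pka_side_chain[r] - ph))
    return q


def oracle_face_segregation(seq, delta_deg=100.0):
    """Exhaustive 360-step half-plane arc scan."""
    angles = [(n * delta_deg) % 360 for n, r in enumerate(seq) if r in HYDROPHOBIC_AA]
    if not angles:
        return 0.0
    best = 0
    for start in range(360):
        inside = sum(1 for a in angles if (a - start) % 360 < 180)
        best = max(best, inside)
    return best / len(angles)


# ------------------------------------------------------ molecular weight

class TestMolecularWeight:
    def test_free_glycine(self):
        assert molecular_weight(_pep("G")) == pytest.approx(75.07, abs=0.01)

    def test_diglycine(self):
        # one peptide bond: 2 x 75.07 - 18.02
        assert molecular_weight(_pep("GG")) == pytest.approx(132.12, abs=0.01)

    def test_all_twenty_against_summation_oracle(self, scale):
        seq = CANONICAL_AA
        expected = sum(scale.residue_mass[r] for r in seq) - 19 * scale.water_mass
        assert molecular_weight(_pep(seq), scale) == pytest.approx(expected, abs=1e-9)
        assert expected > 0

    @given(sequences)
    def test_strictly_positive(self, seq):
        assert molecular_weight(_pep(seq)) > 0


# ------------------------------------------------------------ net charge

class TestNetCharge:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAA", 0), ("KRKR", 4), ("DDEE", -4), ("KDH", 0),
            ("GIGKFLHSAKKF", 3),  # 3 K, termini cancel, H neutral
        ],
    )
    def test_integer_mode_hand_counts(self, seq, expected):
        assert net_charge(_pep(seq), mode="integer") == expected

    def test_hh_single_lysine_closed_form(self, scale):
        got = net_charge(_pep("K"), ph=7.0, scale=scale)
        assert got == pytest.approx(oracle_hh_charge("K", scale, 7.0), abs=1e-12)

    @given(seq=sequences)
    def test_hh_matches_oracle(self, scale, seq):
        got = net_charge(_pep(seq), ph=7.0, scale=scale)
        assert got == pytest.approx(oracle_hh_charge(seq, scale, 7.0), abs=1e-10)

    @given(sequences)
    def test_hh_strictly_decreasing_in_ph(self, seq):
        phs = np.linspace(2.0, 12.0, 11)
        charges = [net_charge(_pep(seq), ph=p) for p in phs]
        assert all(a > b for a, b in zip(charges, charges[1:]))

    @given(sequences.filter(lambda s: any(r not in "KR" for r in s)))
    def test_k_substitution_raises_integer_charge_by_one_or_more(self, seq):
        # replacing a neutral residue adds exactly +1; an acidic one adds +2
        pos = next(i for i, r in enumerate(seq) if r not in "KR")
        before = net_charge(_pep(seq), mode="integer")
        sub = seq[:pos] + "K" + seq[pos + 1:]
        delta = net_charge(_pep(sub), mode="integer") - before
        assert delta == (2 if seq[pos] in "DE" else 1)

    def test_invalid_ph_rejected(self):
        for ph in (0.0, -1.0, 14.0):
            with pytest.raises(ValueError):
                net_charge(_pep("K"), ph=ph)


# ---------------------------------------------------------- hydrophobicity

class TestHydrophobicity:
    def test_homopolymer_mean_equals_residue_value(self, scale):
        assert mean_hydrophobicity(_pep("LLLL"), scale) == pytest.approx(
            scale.hydrophobicity["L"]
        )

    def test_two_residue_mean(self, scale):
        expected = (scale.hydrophobicity["L"] + scale.hydrophobicity["K"]) / 2
        assert mean_hydrophobicity(_pep("LK"), scale) == pytest.approx(expected)

    @given(seq=sequences)
    def test_matches_brute_force_mean(self, scale, seq):
        expected = sum(scale.hydrophobicity[r] for r in seq) / len(seq)
        assert mean_hydrophobicity(_pep(seq), scale) == pytest.approx(
            expected, abs=1e-12
        )


# ------------------------------------------------------ hydrophobic moment

class TestHydrophobicMoment:
    @pytest.mark.parametrize("r", list(CANONICAL_AA))
    def test_single_residue_is_abs_h(self, r, scale):
        assert hydrophobic_moment(_pep(r), scale=scale) == pytest.approx(
            abs(scale.hydrophobicity[r]), abs=1e-12
        )

    @pytest.mark.parametrize("r", list(CANONICAL_AA))
    def test_homopolymer_18mer_vanishes(self, r):
        # 18 unit vectors at 100 deg steps cover all multiples of 20 deg
        assert hydrophobic_moment(_pep(r * 18)) <= 1e-9

    @given(seq=sequences)
    def test_matches_vector_sum_oracle(self, scale, seq):
        got = hydrophobic_moment(_pep(seq), scale=scale)
        assert got == pytest.approx(oracle_moment(seq, scale), abs=1e-10)

    @given(seq=sequences)
    def test_bounded_by_largest_scale_magnitude(self, scale, seq):
        mu = hydrophobic_moment(_pep(seq), scale=scale)
        assert 0 <= mu <= max(abs(v) for v in scale.hydrophobicity.values()) + 1e-12


# ----------------------------------------------------------- helical wheel

class TestHelicalWheel:
    def test_angles_follow_delta(self):
        rows = helical_wheel(_pep("AK"))
        assert [(r[0], r[2]) for r in rows] == [(0, 0.0), (1, 100.0)]
        assert rows[0][3] == "hydrophobic" and rows[1][3] == "basic"

    def test_full_turns_wrap_to_zero(self):
        rows = helical_wheel(_pep("A" * 19))
        assert rows[18][2] == pytest.approx(0.0)  # 1800 mod 360

    @given(sequences)
    def test_one_entry_per_residue_in_order(self, seq):
        rows = helical_wheel(_pep(seq))
        assert [r[1] for r in rows] == list(seq)
        assert all(0 <= r[2] < 360 for r in rows)


# -------------------------------------------------------- face segregation

class TestFaceSegregation:
    def test_no_hydrophobics_returns_zero(self):
        assert face_segregation(_pep("K" * 9)) == 0.0

    def test_perfectly_segregated_face(self):
        # hydrophobic residues at wheel positions 0 and 100 degrees only
        assert face_segregation(_pep("LLKKKKKKK")) == 1.0

    def test_short_peptides_rejected(self):
        with pytest.raises(ValueError):
            face_segregation(_pep("LK"))

    @given(st.text(alphabet=CANONICAL_AA, min_size=3, max_size=25))
    def test_matches_arc_scan_oracle(self, seq):
        assert face_segregation(_pep(seq)) == pytest.approx(
            oracle_face_segregation(seq)
        )


# --------------------------------------------------------------- solubility

@pytest.mark.parametrize(
    "seq,expected",
    [
        ("KKKKKKKKKK", "good"),
        ("LLLLLLLLLL", "poor"),
        ("KLLLLLLLLLLLLLLL", "poor"),  # hydrophilic fraction 1/16 < 0.25
        ("SSSSTTTTNNNN", "poor"),      # hydrophilic but zero net charge
    ],
)
def test_solubility_heuristic(seq, expected):
    assert solubility_estimate(_pep(seq)) == expected


# ------------------------------------------------------------------ describe

class TestDescribe:
    def test_single_glycine_profile(self, scale):
        d = describe(_pep("G"))
        assert d.length == 1
        assert d.molecular_weight == pytest.approx(75.07, abs=0.01)
        assert d.hydrophobic_moment == pytest.approx(
            abs(scale.hydrophobicity["G"])
        )

    def test_pure_function(self, rng):
        seq = "".join(CANONICAL_AA[i] for i in rng.integers(0, 20, 19))
        assert describe(_pep(seq)) == describe(_pep(seq))

    @given(seq=st.text(alphabet=CANONICAL_AA, min_size=19, max_size=19))
    def test_components_agree_with_operations(self, scale, seq):
        p = _pep(seq)
        d = describe(p)
        assert d.molecular_weight == molecular_weight(p)
        assert d.net_charge == net_charge(p)
        assert d.net_charge_integer == net_charge(p, mode="integer")
        assert d.mean_hydrophobicity == mean_hydrophobicity(p)
        assert d.hydrophobic_moment == hydrophobic_moment(p)
        assert d.face_segregation == face_segregation(p)
        assert d.solubility == solubility_estimate(p)
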