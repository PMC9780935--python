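"""Formula algebra, masses, ion m/z, ppm errors and isotope patterns."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyt_mass

from limoscreen.chemcore import (
    ISOTOPES,
    FormulaError,
    IsotopePattern,
    M_H_NEG,
    M_H_POS,
    MolecularFormula,
    ion_mz,
    isotope_pattern,
    isotope_probabilities,
    monoisotopic_mass,
    parse_formula,
    pattern_score,
    ppm_error,
)

formulas = st.dictionaries(
    st.sampled_from(["C", "H", "N", "O", "S"]),
    st.integers(min_value=1, max_value=30),
    min_size=1,
).map(MolecularFormula)


class TestParse:
    @pytest.mark.parametrize("text,expected", [
        ("C10H16", {"C": 10, "H": 16}),
        ("H", {"H": 1}),
        ("C16H23O10", {"C": 16, "H": 23, "O": 10}),
        ("SO3", {"S": 1, "O": 3}),
        ("C2H5NO2S", {"C": 2, "H": 5, "N": 1, "O": 2, "S": 1}),
    ])
    def test_examples(self, text, expected):
        assert parse_formula(text).as_dict() == expected

    @pytest.mark.parametrize("bad", ["", "  ", "Xx10", "C10H16Q", "C-2", "(CH3)2", "C0"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    def test_equality_is_count_equality(self):
        assert parse_formula("CH4") == parse_formula("HCH3")
        assert parse_formula("CH4") != parse_formula("CH3")


class TestMass:
    def test_worked_values(self):
        assert monoisotopic_mass(parse_formula("C10H16O3")) == pytest.approx(
            184.1099, abs=1e-4)
        assert monoisotopic_mass(parse_formula("H2O")) == pytest.approx(
            18.01056, abs=1e-5)
        assert monoisotopic_mass(parse_formula("C10H16")) == pytest.approx(
            136.12520, abs=1e-5)

    @pytest.mark.parametrize("f", ["C10H16", "C16H24O10", "C12H21NO5S", "H2O"])
    def test_agrees_with_pyteomics(self, f):
        # independent mass oracle
        assert monoisotopic_mass(parse_formula(f)) == pytest.approx(
            pyt_mass.calculate_mass(formula=f), abs=2e-6)

    @given(f1=formulas, f2=formulas)
    @settings(max_examples=50, deadline=None)
    def test_additivity(self, f1, f2):
        assert monoisotopic_mass(f1 + f2) == pytest.approx(
            monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9)


class TestIonMz:
    @pytest.mark.parametrize("f,expected", [
        ("C16H22O8", 341.12420),
        ("C10H14O5S", 245.04892),
    ])
    def test_deprotonated(self, f, expected):
        assert ion_mz(parse_formula(f), M_H_NEG) == pytest.approx(expected, abs=1e-5)

    def test_protonated_water(self):
        assert ion_mz(parse_formula("H2O"), M_H_POS) == pytest.approx(
            19.01784, abs=1e-5)

    def test_deprotonation_needs_hydrogen(self):
        with pytest.raises(FormulaError):
            ion_mz(parse_formula("SO3"), M_H_NEG)

    @given(f=formulas)
    @settings(max_examples=50, deadline=None)
    def test_adduct_pair_symmetry(self, f):
        if f["H"] < 1:
            return
        assert ion_mz(f, M_H_NEG) + ion_mz(f, M_H_POS) == pytest.approx(
            2 * monoisotopic_mass(f), abs=1e-9)


class TestPpm:
    def test_printed_sign_convention(self):
        # observed above theoretical reports a negative error
        assert round(ppm_error(341.12420, 341.1243), 1) == -0.3
        assert round(ppm_error(222.11357, 222.1134), 1) == 0.8

    def test_identity_and_errors(self):
        assert ppm_error(345.0, 345.0) == 0.0
        with pytest.raises(ValueError):
            ppm_error(0.0, 345.0)

    @given(t=st.floats(100, 1000), o=st.floats(100, 1000))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_up_to_scale(self, t, o):
        assert ppm_error(t, o) == pytest.approx(
            -ppm_error(o, t) * o / t, rel=1e-9)


def brute_force_offsets(f: MolecularFormula, max_offset: int) -> np.ndarray:
    """Independent isotopologue enumeration: multinomial compositions per
    element, combined across elements; no convolution code shared with the
    implementation."""
    def element_dist(el, n):
        iso = ISOTOPES[el]
        base = iso[0][0]
        out = {}
        for combo in itertools.product(range(n + 1), repeat=len(iso)):
            if sum(combo) != n:
                continue
            coeff = math.factorial(n)
            p = 1.0
            off = 0
            for k, (m, ab) in zip(combo, iso):
                coeff //= math.factorial(k)
                p *= ab ** k
                off += k * int(round(m - base))
            out[off] = out.get(off, 0.0) + coeff * p
        return out

    total = {0: 1.0}
    for el, n in f.counts:
        dist = element_dist(el, n)
        new = {}
        for o1, p1 in total.items():
            for o2, p2 in dist.items():
                new[o1 + o2] = new.get(o1 + o2, 0.0) + p1 * p2
        total = new
    arr = np.zeros(max_offset + 1)
    for o, p in total.items():
        if o <= max_offset:
            arr[o] = p
    return arr


class TestIsotopePattern:
    def test_single_carbon(self):
        pat = isotope_pattern(parse_formula("C"), max_offset=1, prune=0)
        assert pat.abundance_at(1) == pytest.approx(0.0108, abs=2e-4)

    def test_deuterium_negligible(self):
        pat = isotope_pattern(parse_formula("H2"), max_offset=1, prune=0)
        assert pat.abundance_at(1) < 1e-3

    def test_large_glucuronide_m1(self):
        # frozen from the in-repo brute-force enumeration oracle
        pat = isotope_pattern(parse_formula("C16H24O10"), max_offset=2)
        assert pat.abundance_at(1) == pytest.approx(0.1796, abs=1e-3)

    @pytest.mark.parametrize("f", ["C10H16", "C6H8O6", "C2H5NO2S", "CHNOS"])
    def test_matches_brute_force_oracle(self, f):
        mf = parse_formula(f)
        oracle = brute_force_offsets(mf, 3)
        pat = isotope_pattern(mf, max_offset=3, prune=0)
        base = oracle.max()
        for off, _, ab in pat.peaks:
            assert ab == pytest.approx(oracle[off] / base, abs=1e-9)

    @given(f=formulas)
    @settings(max_examples=20, deadline=None)
    def test_probability_conservation(self, f):
        if f.n_atoms() > 30:
            return
        probs = isotope_probabilities(f, 40)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_base_peak_mz_is_monoisotopic(self):
        f = parse_formula("C16H24O10")
        pat = isotope_pattern(f, max_offset=2)
        assert pat.peaks[0][1] == pytest.approx(monoisotopic_mass(f), abs=1e-6)

    def test_prune_drops_small_peaks(self):
        f = parse_formula("C10H16")
        full = isotope_pattern(f, max_offset=3, prune=0)
        pruned = isotope_pattern(f, max_offset=3, prune=0.01)
        assert len(pruned.peaks) < len(full.peaks)
        assert all(a >= 0.01 for _, _, a in pruned.peaks)


class TestPatternScore:
    def test_identity(self):
        pat = isotope_pattern(parse_formula("C16H24O10"), max_offset=2)
        assert pattern_score(pat, pat) == 1.0

    def test_hand_evaluated_half(self):
        obs = IsotopePattern(((0, 136.125, 1.0),))
        theo = IsotopePattern(((0, 136.125, 1.0), (1, 137.128, 1.0)))
        assert pattern_score(obs, theo) == pytest.approx(0.5)

    def test_symmetry(self):
        a = isotope_pattern(parse_formula("C16H24O10"), max_offset=2)
        b = isotope_pattern(parse_formula("C10H14O5S"), max_offset=2)
        assert pattern_score(a, b) == pytest.approx(pattern_score(b, a))


def test_all_printed_rows_within_window(fixture_df):
    """Every observed feature mass is within the 10 ppm screening window."""
    from limoscreen.chemcore import anion_mz
    for _, row in fixture_df.iterrows():
        theo = anion_mz(parse_formula(row["anion_formula"]))
        assert abs(ppm_error(theo, row["mz"])) <= 10.0
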