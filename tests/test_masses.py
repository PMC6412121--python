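"""Mass bookkeeping against an independent residue-mass oracle, ion m/z,
heavy-label shifts, and the MS2 ladder identities."""

import pytest

from silnas.digestion import Fragment
from silnas.masses import (
    DEFAULT_MZ_WINDOW,
    chain_composition,
    composition,
    make_species,
    monoisotopic_mass,
    ms2_ladders,
    mz_negative,
    observable_charges,
)
from silnas.rna import LABEL_SCHEMES, ModificationSite

# Independent oracle: literature monoisotopic residue masses (nucleoside
# 3'-monophosphate minus water) and terminal-group increments, summed per
# letter — a different decomposition from the implementation's
# nucleoside-plus-linkage bookkeeping.
RESIDUE = {"A": 329.052520, "C": 305.041290, "G": 345.047434, "U": 306.025302}
WATER = 18.010565
HPO3 = 79.966331
PROTON = 1.00727646
C13_MINUS_C12 = 1.0033548


def oracle_mass(seq, three_prime="linear-phosphate", five_prime="hydroxyl"):
    """5'-OH / 3'-p chain = sum(residues) + water; end-group variants add or
    remove one HPO3 / water."""
    mass = sum(RESIDUE[b] for b in seq) + WATER
    if three_prime == "hydroxyl":
        mass -= HPO3
    elif three_prime == "cyclic-phosphate":
        mass -= WATER
    if five_prime == "monophosphate":
        mass += HPO3
    elif five_prime == "triphosphate":
        mass += 3 * HPO3
    return mass


def frag(seq, start=1, **kw):
    return Fragment("m", start, start + len(seq) - 1, seq, **kw)


class TestMonoisotopicMass:
    def test_empty_composition_is_zero(self):
        assert monoisotopic_mass({}) == 0.0

    @pytest.mark.parametrize("seq", ["CACUCCG", "AAGAU", "UUG", "G", "ACGU"])
    @pytest.mark.parametrize(
        "ends",
        [
            ("hydroxyl", "linear-phosphate"),
            ("hydroxyl", "hydroxyl"),
            ("monophosphate", "linear-phosphate"),
            ("hydroxyl", "cyclic-phosphate"),
            ("triphosphate", "hydroxyl"),
        ],
    )
    def test_agrees_with_residue_oracle_to_1e4(self, seq, ends):
        five, three = ends
        got = monoisotopic_mass(chain_composition(seq, five, three))
        assert got == pytest.approx(oracle_mass(seq, three, five), abs=1e-4)

    def test_mass_additivity_at_phosphodiester_split(self):
        whole = monoisotopic_mass(chain_composition("CACUCCG", "hydroxyl", "hydroxyl"))
        left = monoisotopic_mass(chain_composition("CAC", "hydroxyl", "linear-phosphate"))
        right = monoisotopic_mass(chain_composition("UCCG", "hydroxyl", "hydroxyl"))
        assert left + right == pytest.approx(whole + monoisotopic_mass({"H": 2, "O": 1}), abs=1e-9)


class TestHeavyChannel:
    def test_t1_scheme_labels_ten_carbons_per_g(self):
        c_light = composition(frag("CACUCCG"))
        c_heavy = composition(frag("CACUCCG"), channel="heavy", scheme=LABEL_SCHEMES["T1-scheme"])
        assert c_heavy["C13"] == 10
        assert c_light["C"] - c_heavy["C"] == 10
        # only the carbon pools differ
        assert {k: v for k, v in c_light.items() if k not in "C"} == {
            k: v for k, v in c_heavy.items() if k not in ("C", "C13")
        }

    @pytest.mark.parametrize(
        "seq, scheme, n13",
        [("CACUCCG", "T1-scheme", 10), ("AAGAU", "A-scheme", 9), ("UUGG", "A-scheme", 18)],
    )
    def test_heavy_shift_is_label_count_times_isotope_delta(self, seq, scheme, n13):
        light = make_species(frag(seq))
        heavy = make_species(frag(seq), channel="heavy", scheme=LABEL_SCHEMES[scheme])
        assert heavy.monoisotopic_mass - light.monoisotopic_mass == pytest.approx(
            n13 * C13_MINUS_C12, abs=1e-4
        )

    def test_heavy_shift_independent_of_modifications(self):
        site = ModificationSite("m", 2, "2'-O-methyl")
        light = make_species(frag("CACUCCG"), (site,))
        heavy = make_species(frag("CACUCCG"), (site,), "heavy", LABEL_SCHEMES["T1-scheme"])
        assert heavy.monoisotopic_mass - light.monoisotopic_mass == pytest.approx(
            10 * C13_MINUS_C12, abs=1e-6
        )


class TestModificationDeltas:
    def test_methyl_adds_ch2_anywhere(self):
        base = make_species(frag("CACUCCG")).monoisotopic_mass
        for pos in (1, 4, 7):
            site = ModificationSite("m", pos, "2'-O-methyl")
            assert make_species(frag("CACUCCG"), (site,)).monoisotopic_mass - base == (
                pytest.approx(14.01565, abs=1e-4)
            )

    def test_pseudouridine_is_mass_silent(self):
        site = ModificationSite("m", 3, "pseudouridine")
        assert make_species(frag("UAU"), (site,)).composition == make_species(frag("UAU")).composition

    def test_site_outside_fragment_rejected(self):
        with pytest.raises(ValueError, match="outside fragment"):
            composition(frag("ACG", start=10), (ModificationSite("m", 2, "2'-O-methyl"),))


class TestIons:
    def test_mz_definition_and_charge_validation(self):
        assert mz_negative(1000.0, 1) == pytest.approx(1000.0 - PROTON)
        assert mz_negative(1000.0, 2) == pytest.approx((1000.0 - 2 * PROTON) / 2)
        with pytest.raises(ValueError):
            mz_negative(1000.0, 0)

    def test_window_filter(self):
        assert observable_charges(300.0, DEFAULT_MZ_WINDOW) == []
        # the 7-mer benchmark fragment must be visible doubly charged
        mass = monoisotopic_mass(chain_composition("CACUCCG", "hydroxyl", "linear-phosphate"))
        assert 2 in observable_charges(mass, DEFAULT_MZ_WINDOW)

    def test_isobaric_permutations_collide_at_every_charge(self):
        a = make_species(frag("CACUCCG"))
        b = make_species(frag("ACCCCUG"))
        assert a.composition == b.composition
        for z in (1, 2, 3):
            assert mz_negative(a.monoisotopic_mass, z) == mz_negative(b.monoisotopic_mass, z)


class TestMs2Ladders:
    def test_two_mer_has_four_series_per_charge(self):
        ions = ms2_ladders(make_species(frag("AG")), max_charge=2)
        assert len(ions) == 8
        assert {i.series for i in ions} == {"c", "y", "w", "a-B"}

    def test_series_closure_c_plus_y_equals_precursor_plus_water(self):
        sp = make_species(frag("CACUCCG"))
        ions = {(i.series, i.index): i.mz for i in ms2_ladders(sp, max_charge=1)}
        water = monoisotopic_mass({"H": 2, "O": 1})
        n = 7
        for i in range(1, n):
            total = (ions[("c", i)] + PROTON) + (ions[("y", n - i)] + PROTON)
            assert total == pytest.approx(sp.monoisotopic_mass + water, abs=1e-6)

    def test_methyl_shifts_only_ions_containing_the_residue(self):
        plain = make_species(frag("CACUCCG"))
        site = ModificationSite("m", 4, "2'-O-methyl")  # residue 4 of 7
        meth = make_species(frag("CACUCCG"), (site,))
        p = {(i.series, i.index, i.charge): i.mz for i in ms2_ladders(plain, 1)}
        m = {(i.series, i.index, i.charge): i.mz for i in ms2_ladders(meth, 1)}
        ch2 = 14.015650
        for key in p:
            series, index, _ = key
            contains = index >= 4 if series in ("c", "a-B") else index >= 4  # suffix length
            if series in ("y", "w"):
                contains = index > 7 - 4
            if contains:
                assert m[key] - p[key] == pytest.approx(ch2, abs=1e-4), key
            else:
                assert m[key] == pytest.approx(p[key], abs=1e-9), key

    def test_single_residue_fragment_rejected(self):
        with pytest.raises(ValueError):
            ms2_ladders(make_species(frag("G")), max_charge=1)
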