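"""Search-space construction, MS1 matching, MS2 scoring and ambiguity
resolution, including the base-composition isobar collision."""

import numpy as np
import pandas as pd
import pytest

from silnas.digestion import Fragment
from silnas.identify import (
    build_search_space,
    enumerate_variants,
    find_features,
    match_ms1,
    read_peaklist,
    resolve,
    score_ms2,
)
from silnas.masses import make_species, ms2_ladders, mz_negative
from silnas.rna import ModificationSite, RnaMolecule

WIDE = (200.0, 4000.0)


@pytest.fixture(scope="module")
def gag_space():
    return build_search_space([RnaMolecule("m", "GAG")], ["RNaseT1"], max_missed=0,
                              window=WIDE, include_heavy=False, variable_methyl=False)


class TestSearchSpace:
    def test_gag_zero_missed_fragments(self, gag_space):
        frags = {
            (i.species.fragment.start, i.species.fragment.end)
            for i in gag_space.ions
        }
        assert frags == {(1, 1), (2, 3)}

    def test_missed_cleavage_adds_full_length(self):
        space = build_search_space([RnaMolecule("m", "GAG")], ["RNaseT1"], max_missed=1,
                                   window=WIDE, include_heavy=False, variable_methyl=False)
        frags = {(i.species.fragment.start, i.species.fragment.end) for i in space.ions}
        assert (1, 3) in frags

    def test_variable_methyl_policy_adds_single_placements(self):
        f = Fragment("m", 2, 3, "AG")
        variants = enumerate_variants(f, known_sites=(), variable_methyl=True)
        assert () in variants
        singles = [v for v in variants if len(v) == 1]
        assert {v[0].position for v in singles} == {2, 3}

    def test_fixed_sites_exempt_from_variable_cap(self):
        known = (
            ModificationSite("m", 2, "2'-O-methyl"),
            ModificationSite("m", 3, "2'-O-methyl"),
        )
        f = Fragment("m", 2, 4, "GGC")
        variants = enumerate_variants(f, known_sites=known, variable_methyl=True)
        assert known in variants  # the doubly methylated species is reachable

    def test_deterministic_and_window_filtered(self):
        kw = dict(enzymes=["RNaseT1"], max_missed=1, window=(480, 1980))
        a = build_search_space([RnaMolecule("m", "GAGCUGAC")], **kw)
        b = build_search_space([RnaMolecule("m", "GAGCUGAC")], **kw)
        assert [(i.mz, i.charge) for i in a.ions] == [(i.mz, i.charge) for i in b.ions]
        assert all(480 <= i.mz <= 1980 for i in a.ions)


class TestMatchMs1:
    def test_round_trip_and_tolerance(self, gag_space):
        target = gag_space.ions[0]
        peaks = pd.DataFrame(
            {"mz": [target.mz * (1 + 2e-6), target.mz * (1 + 12e-6)],
             "rt": [10.0, 11.0], "intensity": [100.0, 100.0]}
        )
        ids = match_ms1(peaks, gag_space, tol_ppm=5)
        matched_peaks = {i.peak_index for i in ids}
        assert 0 in matched_peaks and 1 not in matched_peaks
        assert all(abs(i.ppm_error) <= 5 for i in ids)

    def test_shrinking_tolerance_never_adds_matches(self, gag_space):
        rng = np.random.default_rng(7)
        mzs = [i.mz * (1 + rng.normal(0, 3e-6)) for i in gag_space.ions[:6]]
        peaks = pd.DataFrame({"mz": mzs, "rt": 10.0, "intensity": 1.0})
        wide = {(i.peak_index, i.ion.species.key) for i in match_ms1(peaks, gag_space, 5)}
        narrow = {(i.peak_index, i.ion.species.key) for i in match_ms1(peaks, gag_space, 2)}
        assert narrow <= wide

    def test_isobar_pair_flagged_as_one_ambiguity_group(self, u1):
        space = build_search_space([u1], ["RNaseT1"], max_missed=0,
                                   include_heavy=False, variable_methyl=False)
        iso = make_species(Fragment("U1", 69, 75, "CACUCCG"))
        peaks = pd.DataFrame(
            {"mz": [mz_negative(iso.monoisotopic_mass, 2)], "rt": [10.0], "intensity": [1.0]}
        )
        ids = match_ms1(peaks, space, tol_ppm=5)
        seqs = {i.ion.species.fragment.sequence for i in ids}
        assert seqs == {"CACUCCG", "ACCCCUG"}
        assert all(i.ambiguous for i in ids)
        assert len({i.isobaric_group for i in ids}) == 1

    def test_non_positive_tolerance_rejected(self, gag_space):
        with pytest.raises(ValueError):
            match_ms1(pd.DataFrame({"mz": [500.0], "rt": [1.0], "intensity": [1.0]}),
                      gag_space, tol_ppm=0)


class TestScoreMs2:
    def _spectrum(self, species, **kw):
        ions = ms2_ladders(species, max_charge=2, **kw)
        return pd.DataFrame({"mz": [i.mz for i in ions], "intensity": 100.0})

    def test_self_match_is_maximal_and_isobar_scores_lower(self):
        from silnas.masses import IonSpecies

        a = make_species(Fragment("U1", 69, 75, "CACUCCG"))
        b = make_species(Fragment("U1", 85, 91, "ACCCCUG"))
        spec_a = self._spectrum(a)
        ion_a = IonSpecies(a, 2, mz_negative(a.monoisotopic_mass, 2))
        ion_b = IonSpecies(b, 2, mz_negative(b.monoisotopic_mass, 2))
        count_self, frac_self = score_ms2(spec_a, ion_a)
        count_other, frac_other = score_ms2(spec_a, ion_b)
        assert count_self == len(ms2_ladders(a, max_charge=2))
        assert count_other < count_self
        assert frac_self == pytest.approx(1.0)

    def test_empty_spectrum_scores_zero(self):
        from silnas.masses import IonSpecies

        a = make_species(Fragment("m", 1, 3, "ACG"))
        ion = IonSpecies(a, 1, mz_negative(a.monoisotopic_mass, 1))
        assert score_ms2(pd.DataFrame({"mz": [], "intensity": []}), ion) == (0, 0.0)

    def test_random_noise_scores_near_zero(self, rng):
        from silnas.masses import IonSpecies

        a = make_species(Fragment("m", 1, 5, "ACGUC"))
        ion = IonSpecies(a, 1, mz_negative(a.monoisotopic_mass, 1))
        noise = pd.DataFrame(
            {"mz": rng.uniform(200, 2000, size=50), "intensity": 1.0}
        )
        count, frac = score_ms2(noise, ion)
        assert count <= 2 and frac <= 0.05


class TestResolve:
    def _ambiguous_ids(self):
        u1 = RnaMolecule(
            "U1",
            "AUACUUACCUGG" + "CACUCCG" + "G" + "ACCCCUG" + "AAUUCC",
        )
        space = build_search_space([u1], ["RNaseT1"], max_missed=0,
                                   include_heavy=False, variable_methyl=False)
        iso = make_species(Fragment("U1", 13, 19, "CACUCCG"))
        peaks = pd.DataFrame(
            {"mz": [mz_negative(iso.monoisotopic_mass, 2)], "rt": [10.0], "intensity": [1.0]}
        )
        return iso, match_ms1(peaks, space, tol_ppm=5)

    def test_discriminating_ms2_selects_single_winner(self):
        iso, ids = self._ambiguous_ids()
        ions = ms2_ladders(iso, max_charge=2)
        spectra = [dict(
            precursor_mz=mz_negative(iso.monoisotopic_mass, 2), rt=10.0,
            peaks=pd.DataFrame({"mz": [i.mz for i in ions], "intensity": 100.0}),
        )]
        final = resolve(ids, spectra)
        assert len(final) == 1
        assert final[0].ion.species.fragment.sequence == "CACUCCG"
        assert not final[0].ambiguous

    def test_without_ms2_group_is_retained_flagged(self):
        _, ids = self._ambiguous_ids()
        final = resolve(ids, spectra=None)
        assert len(final) == 2
        assert all(i.ambiguous for i in final)


class TestPeaklistIO:
    def test_tsv_round_trip(self, tmp_path):
        table = pd.DataFrame({"mz": [500.1, 600.2], "rt": [1.0, 2.0], "intensity": [10.0, 20.0]})
        path = tmp_path / "peaks.tsv"
        table.to_csv(path, sep="\t", index=False)
        assert read_peaklist(path).equals(table)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"mz": [1.0]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_peaklist(path)


class TestFindFeatures:
    def test_gaussian_peak_becomes_one_feature(self):
        rt = np.arange(9.5, 10.5, 0.02)
        inten = 1000 * np.exp(-0.5 * ((rt - 10.0) / 0.05) ** 2)
        peaks = pd.DataFrame({"mz": 800.0, "rt": rt, "intensity": inten})
        feats = find_features(peaks, 5.0)
        assert len(feats) == 1
        assert feats.loc[0, "rt"] == pytest.approx(10.0, abs=0.02)
        assert feats.loc[0, "intensity"] == pytest.approx(1000.0, rel=0.01)
        assert feats.loc[0, "area"] == pytest.approx(1000 * 0.05 * np.sqrt(2 * np.pi), rel=0.02)

    def test_rt_resolved_species_split_into_two_features(self):
        rt = np.arange(9.0, 12.0, 0.02)
        inten = 1000 * np.exp(-0.5 * ((rt - 10.0) / 0.05) ** 2) + 500 * np.exp(
            -0.5 * ((rt - 11.0) / 0.05) ** 2
        )
        peaks = pd.DataFrame({"mz": 800.0, "rt": rt, "intensity": inten})
        feats = find_features(peaks, 5.0)
        assert len(feats) == 2
        assert sorted(feats["intensity"].round(-1)) == [500.0, 1000.0]
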