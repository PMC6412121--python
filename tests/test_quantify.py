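"""The two estimators, XIC machinery, and replicate aggregation."""

import numpy as np
import pandas as pd
import pytest

from silnas.quantify import (
    CorrectionFactor,
    PairedMeasurement,
    aggregate_and_compare,
    correction_factor,
    extract_xic,
    integrate_peak,
    peak_area_estimate,
    pick_peaks,
    silnas_estimate,
    warn_on_collisions,
)


def make_k(k=1.0):
    return CorrectionFactor(k=k, n_pairs=10, ratios=(k,) * 10)


class TestCorrectionFactor:
    def test_identity_and_constant_ratio(self):
        assert correction_factor([(1000.0, 1000.0)] * 10).k == pytest.approx(1.0)
        assert correction_factor([(1100.0, 1000.0)] * 10).k == pytest.approx(1.1)

    def test_recovers_mixing_from_lognormal_pairs(self, rng):
        truth = 0.9
        pairs = [
            (truth * 1e6 * np.exp(rng.normal(0, 0.05)), 1e6 * np.exp(rng.normal(0, 0.05)))
            for _ in range(10)
        ]
        k = correction_factor(pairs)
        # CI ~ k * cv * sqrt(2/10)
        assert k.k == pytest.approx(truth, abs=3 * truth * 0.05 * np.sqrt(0.2))

    def test_median_policy_and_minimum_pairs(self):
        pairs = [(1.0, 1.0)] * 9 + [(100.0, 1.0)]
        assert correction_factor(pairs, policy="median").k == pytest.approx(1.0)
        with pytest.raises(ValueError, match="at least 5"):
            correction_factor(pairs[:3])
        with pytest.raises(ValueError, match="positive"):
            correction_factor([(1.0, 0.0)] * 10)

    def test_warns_below_ten_pairs(self):
        with pytest.warns(UserWarning, match="correction pairs"):
            correction_factor([(1.0, 1.0)] * 7)


class TestSilnasEstimate:
    @pytest.mark.parametrize(
        "light, heavy, k, expected",
        [(1000.0, 1000.0, 1.0, 0.0), (0.0, 1000.0, 1.0, 1.0), (250.0, 1000.0, 1.0, 0.75)],
    )
    def test_definition(self, light, heavy, k, expected):
        m = PairedMeasurement(("U1", 70, "m"), "rep1", light_unmod=light, heavy=heavy)
        est = silnas_estimate(m, make_k(k))
        assert est.f_mod == pytest.approx(expected)
        assert not est.clamped

    def test_negative_raw_estimate_clamped_and_flagged(self):
        m = PairedMeasurement(("s",), "rep1", light_unmod=1200.0, heavy=1000.0)
        est = silnas_estimate(m, make_k(1.0))
        assert est.f_mod == 0.0 and est.clamped

    def test_consistency_diagnostic(self):
        m = PairedMeasurement(("s",), "r", light_unmod=250.0, heavy=1000.0, light_mod=750.0)
        est = silnas_estimate(m, make_k(1.0))
        assert est.diagnostic == pytest.approx(1.0)

    def test_zero_heavy_rejected(self):
        with pytest.raises(ValueError, match="heavy"):
            PairedMeasurement(("s",), "r", light_unmod=1.0, heavy=0.0)

    def test_scale_invariance(self):
        m1 = PairedMeasurement(("s",), "r", light_unmod=300.0, heavy=1000.0)
        m2 = PairedMeasurement(("s",), "r", light_unmod=300.0 * 7, heavy=1000.0 * 7)
        assert silnas_estimate(m1, make_k()).f_mod == pytest.approx(
            silnas_estimate(m2, make_k()).f_mod
        )


class TestXic:
    def test_unrelated_mz_gives_empty_trace(self):
        peaks = pd.DataFrame({"mz": [700.0], "rt": [1.0], "intensity": [10.0]})
        assert extract_xic(peaks, 900.0, 5.0).empty

    def test_gaussian_round_trip(self):
        rt = np.arange(0, 2, 0.02)
        inten = 500 * np.exp(-0.5 * ((rt - 1.0) / 0.1) ** 2)
        peaks = pd.DataFrame({"mz": 900.0, "rt": rt, "intensity": inten})
        trace = extract_xic(peaks, 900.0, 5.0)
        assert np.allclose(trace["intensity"], inten)

    def test_collision_warning_for_species_within_tolerance(self):
        with pytest.warns(UserWarning, match="merge"):
            pairs = warn_on_collisions({"a": 900.0, "b": 900.0 * (1 + 3e-6)}, 5.0)
        assert pairs == [("a", "b")]


class TestIntegratePeak:
    def test_rectangular_pulse_area_exact(self):
        chrom = pd.DataFrame({"rt": [0.0, 1.0, 2.0], "intensity": [5.0, 5.0, 5.0]})
        assert integrate_peak(chrom, boundaries=(0.0, 2.0)).area == pytest.approx(10.0)

    def test_gaussian_area_closed_form(self):
        rt = np.arange(-1, 1, 0.005)
        A, sigma = 1000.0, 0.05
        chrom = pd.DataFrame({"rt": rt, "intensity": A * np.exp(-0.5 * (rt / sigma) ** 2)})
        peak = integrate_peak(chrom)
        assert peak.area == pytest.approx(A * sigma * np.sqrt(2 * np.pi), rel=0.01)

    def test_zero_trace_flags_no_peak(self):
        chrom = pd.DataFrame({"rt": [0.0, 1.0], "intensity": [0.0, 0.0]})
        peak = integrate_peak(chrom)
        assert peak.area == 0.0 and peak.flag == "no peak"

    def test_boundaries_outside_trace_rejected(self):
        chrom = pd.DataFrame({"rt": [0.0, 1.0], "intensity": [1.0, 1.0]})
        with pytest.raises(ValueError, match="boundaries"):
            integrate_peak(chrom, boundaries=(5.0, 6.0))

    def test_pick_peaks_separates_resolved_peaks(self):
        rt = np.arange(0, 3, 0.02)
        inten = 100 * np.exp(-0.5 * ((rt - 1.0) / 0.05) ** 2) + 300 * np.exp(
            -0.5 * ((rt - 2.0) / 0.05) ** 2
        )
        peaks = pick_peaks(pd.DataFrame({"rt": rt, "intensity": inten}))
        assert len(peaks) == 2
        assert peaks[0].apex_intensity == pytest.approx(100, rel=0.02)
        assert peaks[1].apex_intensity == pytest.approx(300, rel=0.02)


class TestPeakAreaEstimate:
    @pytest.mark.parametrize(
        "mod, unmod, expected",
        [([0.0], [100.0], 0.0), ([100.0], [0.0], 1.0), ([300.0], [100.0], 0.75),
         ([200.0, 100.0], [100.0], 0.75)],  # composite isomer summation
    )
    def test_definition_and_composites(self, mod, unmod, expected):
        est = peak_area_estimate(mod, unmod, site=("U2", 11, "m"), replicate="r")
        assert est.f_mod == pytest.approx(expected)

    def test_both_zero_flagged_undefined(self):
        est = peak_area_estimate([0.0], [0.0])
        assert np.isnan(est.f_mod)

    def test_scale_invariance(self):
        a = peak_area_estimate([300.0], [100.0]).f_mod
        b = peak_area_estimate([300.0 * 9], [100.0 * 9]).f_mod
        assert a == pytest.approx(b)


class TestAggregateAndCompare:
    def _table(self, values_by_condition, site=("U1", 70, "m"), method="silnas"):
        rows = []
        for cond, values in values_by_condition.items():
            for i, v in enumerate(values):
                rows.append(dict(site=site, method=method, condition=cond,
                                 replicate=f"rep{i}", f_mod=v))
        return pd.DataFrame(rows)

    def test_mean_and_sem_by_definition(self):
        reports = aggregate_and_compare(
            self._table({"control": [0.79, 0.75, 0.82], "kd": [0.2, 0.25, 0.22]})
        )
        row = reports[0].per_condition.set_index("condition").loc["control"]
        values = np.array([0.79, 0.75, 0.82])
        assert row["mean"] == pytest.approx(values.mean())
        assert row["sem"] == pytest.approx(values.std(ddof=1) / np.sqrt(3))
        assert row["n"] == 3

    def test_identical_replicates_have_zero_sem_and_null_p(self):
        reports = aggregate_and_compare(
            self._table({"a": [0.5, 0.5, 0.5], "b": [0.5, 0.5, 0.5]}), reference="a"
        )
        assert reports[0].per_condition["sem"].iloc[0] == 0.0
        assert reports[0].comparisons["p_value"].iloc[0] == pytest.approx(1.0)

    def test_large_effect_is_significant(self):
        reports = aggregate_and_compare(
            self._table({"control": [0.79, 0.78, 0.80], "kd": [0.24, 0.23, 0.25]})
        )
        assert bool(reports[0].comparisons["significant"].iloc[0])

    def test_single_replicate_reports_undefined_sem(self):
        reports = aggregate_and_compare(self._table({"a": [0.5], "b": [0.4]}))
        assert np.isnan(reports[0].per_condition["sem"].iloc[0])
        assert np.isnan(reports[0].comparisons["p_value"].iloc[0])

    def test_three_conditions_use_tukey_adjustment(self):
        table = self._table(
            {"control": [0.79, 0.78, 0.80], "kd1": [0.24, 0.23, 0.25], "kd2": [0.78, 0.80, 0.79]}
        )
        reports = aggregate_and_compare(table, reference="control")
        comp = reports[0].comparisons.set_index("condition")
        assert bool(comp.loc["kd1", "significant"])
        assert not bool(comp.loc["kd2", "significant"])
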