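"""Single-marker quantification: relative correction factors, relative
retention times, peak location, SMD and validation statistics."""

import numpy as np
import pandas as pd
import pytest

from qamsherb import reference_data as ref
from qamsherb.qams import (
    compute_rcf,
    compute_rrt,
    durability_summary,
    locate_peaks_by_rrt,
    qams_quantify,
    round_half_away,
    rsd_percent,
    smd,
    validation_stats,
)


class TestComputeRcf:
    def test_identity_when_standard_equals_analyte(self):
        entry = compute_rcf([(100.0, 1.0, 100.0, 1.0), (50.0, 0.5, 50.0, 0.5)])
        assert entry.mean_f == pytest.approx(1.0)
        assert entry.rsd == pytest.approx(0.0)

    def test_published_per_level_values_reproduce_summary_rows(self):
        levels = ref.rcf_levels()
        entry = compute_rcf(
            # feed areas/concs that realize exactly the published f values
            [(f, 1.0, 1.0, 1.0) for f in levels["magnoflorine"]]
        )
        assert round_half_away(entry.mean_f, 4) == 2.4537
        assert round_half_away(entry.rsd, 2) == 0.48

    def test_slope_ratio_oracle_from_published_lines(self):
        # areas from the published calibration lines at stock concs:
        # direct arithmetic gives f = (126165 * 1.55) / (177380.95 * 1.0)
        a_s = 39003.0 * 1.0 + 87162.0
        a_i = 15369.0 * 1.55 + 153559.0
        entry = compute_rcf([(a_s, 1.0, a_i, 1.55)] * 2)
        expected = (a_s * 1.55) / (a_i * 1.0)
        assert entry.mean_f == pytest.approx(expected)
        assert entry.mean_f == pytest.approx(1.1024, abs=1e-4)

    def test_zero_area_error_names_injection(self):
        with pytest.raises(ValueError, match="injection 1"):
            compute_rcf([(1.0, 1.0, 1.0, 1.0), (0.0, 1.0, 1.0, 1.0)])

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="2 levels"):
            compute_rcf([(1.0, 1.0, 1.0, 1.0)])


class TestComputeRrt:
    def test_identity(self):
        assert compute_rrt(25.0, 25.0) == 1.0

    def test_simple_ratio(self):
        assert compute_rrt(10.0, 25.0) == pytest.approx(0.4)

    def test_published_conditions_reproduce_summary(self):
        rrt = ref.rrt_conditions()["magnoflorine"]
        assert rrt.mean() == pytest.approx(0.4784, abs=5e-5)
        assert rsd_percent(rrt) == pytest.approx(2.8, abs=5e-2)

    def test_zero_reference_time_rejected(self):
        with pytest.raises(ValueError):
            compute_rrt(10.0, 0.0)


class TestLocatePeaksByRrt:
    def peaks(self, rts):
        return pd.DataFrame({"rt_min": rts, "area": 1000.0, "height": 100.0})

    def test_all_analytes_matched_to_truth(self):
        is_rt = 27.0
        table = self.peaks([0.478 * is_rt, 0.849 * is_rt, 0.967 * is_rt, is_rt])
        found = locate_peaks_by_rrt(
            table, is_rt, {"a": 0.478, "b": 0.849, "c": 0.967}, tolerance=0.03
        )
        assert found["a"]["rt_min"] == pytest.approx(0.478 * is_rt)
        assert found["b"]["rt_min"] == pytest.approx(0.849 * is_rt)
        assert found["c"]["rt_min"] == pytest.approx(0.967 * is_rt)

    def test_peak_outside_tolerance_reported_absent(self):
        table = self.peaks([0.60 * 27.0])
        found = locate_peaks_by_rrt(table, 27.0, {"a": 0.478}, tolerance=0.03)
        assert found["a"] is None

    def test_two_analytes_claiming_one_peak_is_an_error(self):
        table = self.peaks([0.50 * 27.0])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            locate_peaks_by_rrt(table, 27.0, {"a": 0.49, "b": 0.51}, tolerance=0.03)

    def test_rrt_more_stable_than_rt_across_conditions(self):
        # retention times shift together across instrument/column
        # changes; ratios to the internal standard mostly cancel
        rng = np.random.default_rng(0)
        rts, rrts = [], []
        for _ in range(6):
            stretch = 1 + rng.normal(0, 0.03)  # condition-wide rt shift
            jitter = rng.normal(0, 0.002, 2)
            t_i, t_s = 12.9 * stretch * (1 + jitter[0]), 27.0 * stretch * (1 + jitter[1])
            rts.append(t_i)
            rrts.append(compute_rrt(t_i, t_s))
        assert np.std(rrts, ddof=1) / np.mean(rrts) < 0.2 * np.std(rts, ddof=1) / np.mean(rts)


class TestQamsQuantify:
    def test_unit_factor_identity(self):
        assert qams_quantify(1.0, 500.0, 500.0, 30.0) == 30.0

    def test_noiseless_pipeline_identity(self):
        # proportional responses: f from standards, applied to a sample,
        # returns the true mass fraction to machine precision
        k_s, k_i = 39003.0, 15369.0
        f = compute_rcf(
            [(k_s * 1.0 * l, 1.0 * l, k_i * 1.55 * l, 1.55 * l) for l in (0.2, 0.5, 1.0)]
        ).mean_f
        w_true_i, w_true_s = 63.0, 30.5
        a_i = k_i * (w_true_i / 40.0)  # 0.5 g / 20 mL extraction
        a_s = k_s * (w_true_s / 40.0)
        assert qams_quantify(f, a_i, a_s, w_true_s) == pytest.approx(w_true_i, rel=1e-12)

    def test_missing_internal_standard_area_rejected(self):
        with pytest.raises(ValueError, match="internal-standard"):
            qams_quantify(1.0, 100.0, 0.0, 30.0)


class TestSmd:
    def test_equal_methods_give_zero(self):
        assert smd(30.0, 30.0) == 0.0

    def test_published_sample_value(self):
        # magnoflorine in batch S1: (72.054 - 72.997) / 72.054 * 100
        assert smd(72.054, 72.997) == pytest.approx(-1.309, abs=5e-4)

    def test_all_published_cells_below_2pct(self):
        quant = ref.quantification_table()
        values = [
            smd(quant.loc[s, f"{a}_esm"], quant.loc[s, f"{a}_qams"])
            for a in ("magnoflorine", "jatrorrhizine", "palmatine")
            for s in quant.index
        ]
        assert len(values) == 30
        assert max(abs(v) for v in values) < 2.0

    def test_formula_is_asymmetric(self):
        assert smd(100.0, 90.0) != -smd(90.0, 100.0)
        assert smd(100.0, 90.0) == pytest.approx(10.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            smd(0.0, 1.0)


class TestDurability:
    def test_column_instrument_block_summary(self):
        table = durability_summary(
            ref.durability_column_instrument()[["magnoflorine", "jatrorrhizine", "palmatine"]]
        )
        assert table.loc["magnoflorine", "mean_f"] == 2.4713
        assert table.loc["magnoflorine", "rsd_percent"] == pytest.approx(1.4, abs=0.05)
        assert table.loc["jatrorrhizine", "rsd_percent"] == pytest.approx(0.86, abs=0.005)

    def test_temperature_block_summary(self):
        table = durability_summary(ref.durability_temperature())
        assert table.loc["magnoflorine", "mean_f"] == 2.4411
        assert table.loc["palmatine", "rsd_percent"] == pytest.approx(0.27, abs=0.005)

    def test_constant_values_zero_rsd(self):
        table = durability_summary(pd.DataFrame({"x": [1.5, 1.5, 1.5]}))
        assert table.loc["x", "rsd_percent"] == 0.0

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError, match="2 conditions"):
            durability_summary(pd.DataFrame({"x": [1.0]}))


class TestValidationStats:
    def test_identical_replicates_zero_rsd(self):
        assert validation_stats([5.0, 5.0, 5.0], "precision") == 0.0

    def test_perfect_recovery_is_100pct(self):
        found = np.array([10.0, 12.0, 14.0])
        spiked = np.array([5.0, 7.0, 9.0])
        assert validation_stats(found, "recovery", base=5.0, spiked=spiked) == pytest.approx(100.0)

    def test_repeatability_rsd_tracks_area_cv(self):
        rng = np.random.default_rng(3)
        rsds = [
            validation_stats(30.0 * (1 + rng.normal(0, 0.018, 6)), "repeatability")
            for _ in range(500)
        ]
        assert np.mean(rsds) == pytest.approx(1.8, rel=0.1)

    def test_mismatched_spike_design_rejected(self):
        with pytest.raises(ValueError, match="spike design"):
            validation_stats([1.0, 2.0, 3.0], "recovery", base=0.0, spiked=[1.0, 2.0])


class TestRounding:
    @pytest.mark.parametrize(
        "x,d,expected",
        [(2.45365, 4, 2.4537), (0.125, 2, 0.13), (-0.125, 2, -0.13), (1.0035, 3, 1.004)],
    )
    def test_half_away_from_zero(self, x, d, expected):
        assert round_half_away(x, d) == expected

    def test_rsd_uses_sample_sd(self):
        values = [1.0, 2.0, 3.0]
        manual = 100.0 * (1.0 / 2.0)  # sample SD of 1,2,3 is exactly 1
        assert rsd_percent(values) == pytest.approx(manual)
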