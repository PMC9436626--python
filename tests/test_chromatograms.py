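"""Peak detection, integration and noise estimation against closed-form
and simulated-truth oracles."""

import numpy as np
import pytest

from qamsherb.chromatograms import (
    Chromatogram,
    detect_peaks,
    estimate_noise,
    integrate_peak,
    read_chromatogram,
    write_chromatogram,
)
from qamsherb.simulate import PeakSpec, RunDesign, generate_chromatogram

SQRT2PI = np.sqrt(2 * np.pi)


def gaussian_trace(height=1000.0, rt=10.0, sigma=0.1, duration=20.0, rate=100.0, noise=0.0, seed=0):
    t = np.linspace(0, duration, int(duration * rate) + 1)
    y = height * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, t.size)
    return Chromatogram(t, y)


class TestIO:
    def test_round_trip_lossless(self, tmp_path):
        chrom, _ = generate_chromatogram(
            [PeakSpec("x", 10.0, 0.1, 0.5, 1000.0)], RunDesign(noise_sd=2.0, seed=7)
        )
        path = tmp_path / "trace.csv"
        write_chromatogram(chrom, path)
        back = read_chromatogram(path)
        np.testing.assert_allclose(back.time, chrom.time, rtol=1e-9)
        np.testing.assert_allclose(back.intensity, chrom.intensity, rtol=1e-9)
        assert back.metadata["injection_id"] == "inj"

    def test_crlf_and_lf_parse_identically(self, tmp_path):
        lf = tmp_path / "lf.csv"
        write_chromatogram(gaussian_trace(rate=10.0), lf)
        crlf = tmp_path / "crlf.csv"
        crlf.write_bytes(lf.read_bytes().replace(b"\n", b"\r\n"))
        a, b = read_chromatogram(lf), read_chromatogram(crlf)
        np.testing.assert_array_equal(a.time, b.time)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_shuffled_times_error_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        rows = "\n".join(f"{t},0.0" for t in [0.0, 1.0, 0.5] + list(range(2, 12)))
        path.write_text("time_min,intensity\n" + rows + "\n")
        with pytest.raises(ValueError, match="row 2"):
            read_chromatogram(path)


class TestEstimateNoise:
    def test_flat_baseline_zero(self):
        assert estimate_noise(gaussian_trace(height=0.0), (0.0, 5.0)) == 0.0

    def test_white_noise_recovered_within_5pct(self):
        chrom = gaussian_trace(height=0.0, duration=50.0, rate=100.0, noise=3.0, seed=1)
        assert estimate_noise(chrom, (0.0, 50.0)) == pytest.approx(3.0, rel=0.05)

    def test_linear_drift_does_not_inflate_estimate(self):
        t = np.linspace(0, 20, 2001)
        rng = np.random.default_rng(2)
        chrom = Chromatogram(t, 50.0 * t + rng.normal(0, 3.0, t.size))
        assert estimate_noise(chrom, (0.0, 20.0)) == pytest.approx(3.0, rel=0.1)

    def test_window_outside_run_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            estimate_noise(gaussian_trace(), (15.0, 25.0))

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="20 points"):
            estimate_noise(gaussian_trace(rate=1.0), (0.0, 2.0))


class TestDetectPeaks:
    def test_pure_noise_rarely_yields_peaks(self):
        # false-positive control at min_snr=3 with a width requirement
        n_with_peaks = 0
        for seed in range(40):
            chrom = gaussian_trace(height=0.0, duration=20.0, rate=60.0, noise=3.0, seed=seed)
            table = detect_peaks(chrom, noise_sd=3.0, min_snr=3.0, min_width=0.05)
            n_with_peaks += len(table) > 0
        assert n_with_peaks <= 2  # >= 95% of seeds clean

    def test_dominant_peak_detected_once(self):
        chrom = gaussian_trace(height=60.0, noise=3.0, rate=60.0, seed=5)
        table = detect_peaks(chrom, noise_sd=3.0, min_snr=3.0, min_width=0.05)
        assert len(table) == 1
        assert table["rt_min"].iloc[0] == pytest.approx(10.0, abs=0.02)
        assert table["snr"].iloc[0] == pytest.approx(20.0, rel=0.25)

    def test_two_gaussians_6sigma_apart_resolved_in_order(self):
        t = np.linspace(0, 20, 2001)
        y = 1000 * np.exp(-0.5 * ((t - 10.0) / 0.1) ** 2)
        y += 800 * np.exp(-0.5 * ((t - 10.6) / 0.1) ** 2)
        table = detect_peaks(Chromatogram(t, y), noise_sd=1.0, min_snr=3.0)
        assert len(table) == 2
        assert table["rt_min"].iloc[0] == pytest.approx(10.0, abs=0.02)
        assert table["rt_min"].iloc[1] == pytest.approx(10.6, abs=0.02)
        # perpendicular drop: bounds meet at the valley, never overlap
        assert table["right_min"].iloc[0] <= table["left_min"].iloc[1] + 1e-9

    def test_empty_chromatogram_gives_empty_table(self):
        chrom = gaussian_trace(height=0.0)
        assert detect_peaks(chrom, noise_sd=0.0).empty

    def test_table_sorted_and_bounds_bracket_apex(self):
        chrom, _ = generate_chromatogram(
            [PeakSpec(f"x{i}", 4.0 + 3.0 * i, 0.08, 0.5, 20000.0) for i in range(4)],
            RunDesign(duration=20.0, sampling_rate=60.0, noise_sd=2.0, seed=3),
        )
        table = detect_peaks(chrom, noise_sd=2.0, min_snr=5.0, min_width=0.05)
        assert (table["rt_min"].diff().dropna() > 0).all()
        assert ((table["left_min"] < table["rt_min"]) & (table["rt_min"] < table["right_min"])).all()


class TestIntegratePeak:
    def test_noiseless_gaussian_closed_form(self):
        h, s = 1000.0, 0.1
        chrom = gaussian_trace(height=h, sigma=s)
        area = integrate_peak(chrom, (10.0 - 5 * s, 10.0 + 5 * s), baseline="none")
        assert area == pytest.approx(h * s * SQRT2PI, rel=0.005)

    def test_all_zero_trace_integrates_to_zero(self):
        assert integrate_peak(gaussian_trace(height=0.0), (2.0, 8.0)) == 0.0

    def test_adjacent_bounds_are_additive_without_baseline(self):
        chrom = gaussian_trace()
        whole = integrate_peak(chrom, (8.0, 12.0), baseline="none")
        parts = integrate_peak(chrom, (8.0, 10.0), baseline="none") + integrate_peak(
            chrom, (10.0, 12.0), baseline="none"
        )
        assert parts == pytest.approx(whole, rel=1e-12)

    def test_zero_width_bounds_rejected(self):
        with pytest.raises(ValueError, match="width"):
            integrate_peak(gaussian_trace(), (5.0, 5.0))

    def test_sloped_baseline_subtracted(self):
        t = np.linspace(0, 20, 2001)
        y = 5.0 * t + 1000 * np.exp(-0.5 * ((t - 10.0) / 0.1) ** 2)
        area = integrate_peak(Chromatogram(t, y), (9.0, 11.0))
        assert area == pytest.approx(1000 * 0.1 * SQRT2PI, rel=0.005)


class TestParameterRecovery:
    def test_detection_recovers_true_areas_within_1pct_at_high_snr(self):
        # peaks at S/N >= 50: detect + integrate vs simulated truth
        specs = [
            PeakSpec("a", 6.0, 0.08, 0.5, 30000.0),
            PeakSpec("b", 12.0, 0.08, 0.2, 25000.0),
            PeakSpec("c", 17.0, 0.08, 1.0, 40000.0),
        ]
        for seed in range(5):
            design = RunDesign(duration=22.0, sampling_rate=60.0, noise_sd=20.0, seed=seed)
            chrom, truth = generate_chromatogram(specs, design)
            table = detect_peaks(chrom, noise_sd=20.0, min_snr=10.0, min_width=0.05)
            assert len(table) == 3
            assert (table["snr"] >= 50).all()
            for _, row in truth.iterrows():
                j = (table["rt_min"] - row["rt"]).abs().idxmin()
                assert table.loc[j, "area"] == pytest.approx(row["area"], rel=0.01)
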