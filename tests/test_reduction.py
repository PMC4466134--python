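import io

import numpy as np
import pytest

from einscan import (
    NoiseModel,
    RawScan,
    SummedIntensitySeries,
    bin_by_temperature,
    detect_slope_changes,
    generate_scan,
    normalize_to_reference,
    read_scan,
    subtract_empty_cell,
    summed_intensity,
    write_scan,
)


class TestScanIO:
    def test_toy_grid_round_trip(self, toy_raw_scan):
        buf = io.StringIO()
        write_scan(toy_raw_scan, buf)
        back = read_scan(io.StringIO(buf.getvalue()))
        assert back.shape == (3, 3)
        np.testing.assert_allclose(back.q_values, toy_raw_scan.q_values)
        np.testing.assert_allclose(back.intensities, toy_raw_scan.intensities)
        np.testing.assert_allclose(back.errors, toy_raw_scan.errors)
        assert back.metadata["instrument"] == "IN16"

    def test_generator_output_round_trips(self, default_truth, in16, tmp_path):
        scan = generate_scan(default_truth, in16, noise=NoiseModel(5000.0, 7))
        path = tmp_path / "scan.csv"
        write_scan(scan, path)
        back = read_scan(path)
        np.testing.assert_allclose(back.intensities, scan.intensities)
        np.testing.assert_allclose(back.temperatures, scan.temperatures)
        # embedded truth survives the text round trip
        assert back.metadata["truth"]["k_methyl"] == default_truth.k_methyl
        assert back.metadata["truth"]["pdt_onset"] == default_truth.pdt_onset

    def test_negative_intensity_rejected(self):
        text = "Q,T,I,dI\n0.5,20,-1,1\n0.5,30,1,1\n"
        with pytest.raises(ValueError):
            read_scan(io.StringIO(text))

    def test_ragged_grid_rejected(self):
        text = "Q,T,I,dI\n0.5,20,1,0.1\n1.0,20,1,0.1\n0.5,30,1,0.1\n"
        with pytest.raises(ValueError, match="ragged"):
            read_scan(io.StringIO(text))


class TestEmptyCellSubtraction:
    def test_zero_empty_cell_is_identity(self, toy_raw_scan):
        empty = RawScan(
            toy_raw_scan.q_values,
            toy_raw_scan.temperatures,
            np.zeros_like(toy_raw_scan.intensities),
            np.zeros_like(toy_raw_scan.errors),
        )
        out = subtract_empty_cell(toy_raw_scan, empty)
        np.testing.assert_allclose(out.intensities, toy_raw_scan.intensities)

    def test_transmission_scaling(self, toy_raw_scan):
        empty = RawScan(
            toy_raw_scan.q_values,
            toy_raw_scan.temperatures,
            np.full_like(toy_raw_scan.intensities, 10.0),
            np.zeros_like(toy_raw_scan.errors),
        )
        out = subtract_empty_cell(toy_raw_scan, empty, transmission=0.95)
        assert out.intensities[0, 0] == pytest.approx(100.0 - 9.5)

    def test_full_cancellation_clips_to_zero(self, toy_raw_scan):
        out = subtract_empty_cell(toy_raw_scan, toy_raw_scan, transmission=1.0)
        assert np.all(out.intensities == 0.0)

    def test_grid_mismatch_rejected(self, toy_raw_scan):
        empty = RawScan(
            toy_raw_scan.q_values * 2,
            toy_raw_scan.temperatures,
            toy_raw_scan.intensities,
            toy_raw_scan.errors,
        )
        with pytest.raises(ValueError, match="grid"):
            subtract_empty_cell(toy_raw_scan, empty)


class TestNormalisation:
    def test_reference_row_is_unity(self, toy_raw_scan):
        scan = normalize_to_reference(toy_raw_scan, 20.0)
        np.testing.assert_allclose(scan.intensities[0], 1.0)

    def test_column_division(self, toy_raw_scan):
        scan = normalize_to_reference(toy_raw_scan, 20.0)
        assert scan.intensities[2, 0] == pytest.approx(80.0 / 100.0)
        assert scan.intensities[2, 2] == pytest.approx(40.0 / 80.0)

    def test_idempotent_on_values(self, toy_raw_scan):
        once = normalize_to_reference(toy_raw_scan, 20.0)
        twice = normalize_to_reference(once, 20.0)
        np.testing.assert_allclose(twice.intensities, once.intensities)

    def test_missing_reference_row_rejected(self, toy_raw_scan):
        with pytest.raises(ValueError, match="no scan row"):
            normalize_to_reference(toy_raw_scan, 200.0)

    def test_relative_errors_add_in_quadrature(self, toy_raw_scan):
        scan = normalize_to_reference(toy_raw_scan, 20.0)
        raw = toy_raw_scan
        rel = np.sqrt(
            (raw.errors[2, 0] / raw.intensities[2, 0]) ** 2
            + (raw.errors[0, 0] / raw.intensities[0, 0]) ** 2
        )
        assert scan.errors[2, 0] == pytest.approx(scan.intensities[2, 0] * rel)


class TestTemperatureBinning:
    def test_scan_on_grid_unchanged(self, noise_free_in16_scan):
        binned = bin_by_temperature(noise_free_in16_scan, 5.0)
        np.testing.assert_allclose(binned.temperatures,
                                   noise_free_in16_scan.temperatures)
        np.testing.assert_allclose(binned.intensities,
                                   noise_free_in16_scan.intensities)

    def test_two_rows_merge_to_centre(self):
        q = np.array([1.0])
        t = np.array([298.0, 302.0])
        i = np.array([[2.0], [4.0]])
        e = np.array([[1.0], [1.0]])
        scan = normalize_to_reference(
            RawScan(np.array([1.0]), np.array([20.0, 298.0, 302.0]),
                    np.array([[1.0], [2.0], [4.0]]),
                    np.array([[0.0], [0.0], [0.0]])), 20.0)
        binned = bin_by_temperature(scan, 5.0)
        assert binned.temperatures[-1] == pytest.approx(300.0)
        # plain mean when errors are absent
        assert binned.intensities[-1, 0] == pytest.approx(3.0)

    def test_wider_bins_halve_rows(self, noise_free_in16_scan):
        n5 = bin_by_temperature(noise_free_in16_scan, 5.0).temperatures.size
        n10 = bin_by_temperature(noise_free_in16_scan, 10.0).temperatures.size
        assert n10 == n5 // 2

    def test_inverse_variance_weighting_exact(self):
        raw = RawScan(np.array([1.0]), np.array([20.0, 21.0, 23.0]),
                      np.array([[10.0], [8.0], [14.0]]),
                      np.array([[1.0], [1.0], [2.0]]))
        scan = normalize_to_reference(raw, 20.0)
        binned = bin_by_temperature(scan, 5.0)
        w = 1.0 / scan.errors[:, 0] ** 2
        expect = np.sum(w * scan.intensities[:, 0]) / np.sum(w)
        assert binned.intensities[0, 0] == pytest.approx(expect)


class TestSummedIntensity:
    def test_constant_scan_gives_unit_series(self, toy_raw_scan):
        scan = normalize_to_reference(
            RawScan(toy_raw_scan.q_values, toy_raw_scan.temperatures,
                    np.full((3, 3), 5.0), np.zeros((3, 3))), 20.0)
        series = summed_intensity(scan, (0.0, 2.0))
        np.testing.assert_allclose(series.values, 1.0)

    def test_single_column_window(self, noise_free_in16_scan):
        scan = noise_free_in16_scan
        q0 = scan.q_values[3]
        series = summed_intensity(scan, (q0 - 1e-6, q0 + 1e-6))
        np.testing.assert_allclose(series.values, scan.intensities[:, 3])

    def test_empty_window_rejected(self, noise_free_in16_scan):
        with pytest.raises(ValueError, match="window"):
            summed_intensity(noise_free_in16_scan, (10.0, 12.0))

    def test_commutes_with_q_restriction(self, noise_free_in16_scan):
        scan = noise_free_in16_scan
        window = (0.5, 1.5)
        direct = summed_intensity(scan, window)
        sel = (scan.q_values > window[0]) & (scan.q_values < window[1])
        from einscan import ElasticScan

        restricted = ElasticScan(
            scan.q_values[sel], scan.temperatures,
            scan.intensities[:, sel], scan.errors[:, sel],
            reference_temperature=scan.reference_temperature,
        )
        indirect = summed_intensity(restricted, (0.0, 100.0))
        np.testing.assert_allclose(direct.values, indirect.values)

    def test_monotone_non_increasing_for_generated_scan(self, noise_free_in16_scan):
        series = summed_intensity(noise_free_in16_scan, (0.2, 2.0))
        assert np.all(np.diff(series.values) <= 1e-12)


class TestSlopeChangeDetection:
    @staticmethod
    def _series(t, log_values, err=0.0):
        return SummedIntensitySeries(
            temperatures=t, values=np.exp(log_values),
            errors=np.full(t.size, err), q_window=(0.2, 2.0),
        )

    def test_exact_line_has_no_breaks(self):
        t = np.arange(100.0, 305.1, 5.0)
        report = detect_slope_changes(self._series(t, -0.001 * (t - 100)))
        assert report.breakpoints == []
        assert len(report.segment_slopes) == 1

    def test_noise_free_single_break_recovered_exactly(self):
        t = np.arange(100.0, 305.1, 5.0)
        y = -0.001 * (t - 100) - 0.004 * np.maximum(0.0, t - 240.0)
        report = detect_slope_changes(self._series(t, y))
        assert len(report.breakpoints) == 1
        assert abs(report.breakpoints[0] - 240.0) <= 5.0
        assert report.segment_slopes[1] < report.segment_slopes[0]

    def test_too_few_points_rejected(self):
        t = np.arange(100.0, 130.0, 5.0)
        with pytest.raises(ValueError, match="at least 8"):
            detect_slope_changes(self._series(t, -0.001 * (t - 100)))

    def test_generated_default_scenario_finds_pdt(self, in16, default_truth):
        raw = generate_scan(default_truth, in16, noise=NoiseModel(5000.0, 3))
        scan = normalize_to_reference(raw, 20.0)
        report = detect_slope_changes(summed_intensity(scan, (0.2, 2.0)))
        assert any(abs(b - 240.0) <= 5.0 for b in report.breakpoints)
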