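"""Chromatogram quantifier: IO round-trips, window areas, allele ratios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lofscreen import (
    TraceData,
    mutant_ratio,
    normalized_intensities,
    read_trace,
    titration_calibration,
    window_areas,
    write_trace_abif,
)
from lofscreen.trace_quant import write_trace_text

from conftest import make_titration_trace


class TestTraceIO:
    def test_text_round_trip_preserves_everything(self, tmp_path):
        trace = make_titration_trace(0.3, noise_sd=20.0, rng=np.random.default_rng(0))
        path = tmp_path / "trace.txt"
        write_trace_text(trace, path)
        back = read_trace(path)
        assert np.allclose(back.channels, trace.channels, rtol=1e-9)
        assert np.array_equal(back.peak_positions, trace.peak_positions)
        assert back.called_bases == trace.called_bases

    def test_synthetic_abif_round_trip(self, tmp_path):
        trace = make_titration_trace(0.4)
        path = tmp_path / "trace.ab1"
        write_trace_abif(trace, path)
        back = read_trace(path)
        assert back.called_bases == trace.called_bases
        assert np.array_equal(back.peak_positions, trace.peak_positions)
        # ABIF stores rounded 16-bit intensities
        assert np.abs(back.channels - np.rint(trace.channels)).max() == 0
        est = mutant_ratio(back, 64, "A", "G")
        assert est.mutant_fraction == pytest.approx(0.4, abs=1e-3)

    def test_non_monotone_peak_index_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TraceData(channels=np.zeros((4, 50)), peak_positions=[10, 10], called_bases="AC")

    def test_malformed_text_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("1\t2\t3\t4\n")
        with pytest.raises(ValueError, match="TRACE"):
            read_trace(path)


class TestWindowAreas:
    def test_flat_zero_channels_have_zero_area(self):
        trace = TraceData(np.zeros((4, 30)), [15], "A")
        assert np.all(window_areas(trace, 15, 4) == 0.0)

    def test_single_gaussian_mass_against_numeric_oracle(self):
        # unit-height Gaussian, sigma = 2, in a +/-6 window on channel A
        x = np.arange(41)
        channels = np.zeros((4, 41))
        channels[0] = np.exp(-((x - 20.0) ** 2) / 8.0)
        trace = TraceData(channels, [20], "A")
        areas = window_areas(trace, 20, 6)
        full_mass = np.sqrt(2 * np.pi) * 2.0
        assert areas[0] == pytest.approx(full_mass, abs=0.2)
        assert np.all(areas[1:] == 0.0)

    def test_linearity_preserves_height_ratio(self):
        x = np.arange(41)
        shape = np.exp(-((x - 20.0) ** 2) / 8.0)
        channels = np.zeros((4, 41))
        channels[0] = 7.0 * shape
        channels[2] = 3.0 * shape
        trace = TraceData(channels, [20], "A")
        areas = window_areas(trace, 20, 4)
        assert areas[0] / areas[2] == pytest.approx(7.0 / 3.0, rel=1e-9)

    def test_out_of_range_window_rejected(self):
        trace = TraceData(np.ones((4, 30)), [2], "A")
        with pytest.raises(ValueError, match="scan range"):
            window_areas(trace, 2, 4)


class TestNormalizedIntensities:
    def test_pure_trace_gives_one_hot_rows(self):
        trace = make_titration_trace(0.0)
        rows = normalized_intensities(trace, trace.peak_positions)
        assert np.allclose(rows.sum(axis=1), 1.0, atol=1e-9)
        base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
        # neighbouring peaks bleed ~1e-9 of their mass into the window
        for row, base in zip(rows, trace.called_bases):
            assert row[base_index[base]] == pytest.approx(1.0, abs=1e-8)

    def test_fifty_fifty_mixture_row(self):
        trace = make_titration_trace(0.5)
        row = normalized_intensities(trace, [64])[0]
        assert row[0] == pytest.approx(0.5, abs=1e-8)  # A (wild type)
        assert row[2] == pytest.approx(0.5, abs=1e-8)  # G (mutant)

    def test_zero_total_area_yields_nan_row(self):
        trace = TraceData(np.zeros((4, 30)), [15], "A")
        row = normalized_intensities(trace, [15])[0]
        assert np.all(np.isnan(row))

    @settings(derandomize=True, max_examples=50)
    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 10_000))
    def test_rows_sum_to_one_and_scale_invariant(self, scale, seed):
        rng = np.random.default_rng(seed)
        trace = make_titration_trace(0.3, noise_sd=30.0, rng=rng)
        rows = normalized_intensities(trace, trace.peak_positions)
        assert np.allclose(rows.sum(axis=1), 1.0, atol=1e-9)
        scaled = TraceData(trace.channels * scale, trace.peak_positions, trace.called_bases)
        assert np.allclose(
            normalized_intensities(scaled, scaled.peak_positions), rows, atol=1e-9
        )


class TestMutantRatio:
    def test_mutant_only_trace(self):
        trace = make_titration_trace(1.0)
        assert mutant_ratio(trace, 64, "A", "G").mutant_fraction == pytest.approx(1.0)

    def test_constructed_mixture_recovered_exactly(self):
        est = mutant_ratio(make_titration_trace(0.3), 64, "A", "G")
        assert est.mutant_fraction == pytest.approx(0.3, abs=1e-9)
        assert sum(est.per_base_fraction) == pytest.approx(1.0, abs=1e-9)

    def test_same_base_pair_rejected(self):
        with pytest.raises(ValueError):
            mutant_ratio(make_titration_trace(0.3), 64, "A", "A")

    def test_error_decreases_with_signal_to_noise(self):
        mean_err = []
        for noise in (10.0, 60.0, 150.0):
            errs = []
            for seed in range(30):
                rng = np.random.default_rng(seed)
                est = mutant_ratio(
                    make_titration_trace(0.4, noise_sd=noise, rng=rng), 64, "A", "G"
                )
                errs.append(abs(est.mutant_fraction - 0.4))
            mean_err.append(np.mean(errs))
        assert mean_err[0] < mean_err[1] < mean_err[2]


class TestTitrationCalibration:
    def test_perfect_estimates(self):
        cal = titration_calibration([(0.25, 0.25), (0.5, 0.5), (0.75, 0.75)])
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.monotonic and not cal.underestimates

    def test_uniform_shrinkage_flags_underestimation(self):
        cal = titration_calibration([(f, 0.9 * f) for f in (0.2, 0.4, 0.6, 0.8)])
        assert cal.slope == pytest.approx(0.9)
        assert cal.underestimates

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            titration_calibration([(0.5, 0.4), (0.5, 0.6), (0.5, 0.5)])
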