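"""Monte-Carlo engine: chi-square correctness, sampling expectations, power."""

import numpy as np
import pytest
from scipy import stats

from lofscreen import (
    CountTable,
    EditOutcome,
    ScreenDesign,
    barcode_ratio,
    chi_square_proportions,
    estimate_power,
    gene_recovery_curve,
    power_grid,
    sample_counts,
)
from lofscreen.screen_simulator import _pearson_2x2


class TestChiSquare:
    def test_identical_proportions_give_zero_statistic(self):
        stat, p = chi_square_proportions(CountTable(100, 100, 80_000, 80_000))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_is_untestable(self):
        stat, p = chi_square_proportions(CountTable(0, 0, 80_000, 80_000))
        assert np.isnan(stat) and np.isnan(p)

    def test_symmetric_under_row_and_column_swap(self):
        t = CountTable(120, 85, 79_500, 80_400)
        base = chi_square_proportions(t)
        rows = chi_square_proportions(CountTable(79_500, 80_400, 120, 85))
        cols = chi_square_proportions(CountTable(85, 120, 80_400, 79_500))
        assert base == pytest.approx(rows)
        assert base == pytest.approx(cols)

    @pytest.mark.parametrize("correction", [False, True])
    def test_matches_scipy_contingency(self, correction):
        rng = np.random.default_rng(11)
        tables = rng.integers(1, 200_000, size=(300, 4))
        for ts, te, cs, ce in tables:
            stat, p = chi_square_proportions(
                CountTable(int(ts), int(te), int(cs), int(ce)), correction=correction
            )
            ref = stats.chi2_contingency(
                [[ts, te], [cs, ce]], correction=correction
            )
            assert stat == pytest.approx(ref.statistic, rel=1e-10, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CountTable(-1, 10, 10, 10)


class TestSampleCounts:
    def test_expectations_match_read_model(self, yeast_design):
        rng = np.random.default_rng(5)
        outcome = EditOutcome(mu=0.2, s_mut=0.05)
        draws = [sample_counts(yeast_design, outcome, rng) for _ in range(4_000)]
        ts = np.array([t.target_start for t in draws], dtype=float)
        te = np.array([t.target_end for t in draws], dtype=float)
        cs = np.array([t.control_start for t in draws], dtype=float)
        # E[target_start] = d; E[control_start] = c*d; E[target_end] = d / ratio
        assert ts.mean() == pytest.approx(100.0, abs=4 * 10 / np.sqrt(len(ts)))
        assert cs.mean() == pytest.approx(80_000.0, abs=4 * 300 / np.sqrt(len(cs)))
        expected_end = 100.0 / barcode_ratio(0.2, 0.05, 26)
        assert expected_end == pytest.approx(85.27, abs=0.01)
        assert te.mean() == pytest.approx(expected_end, abs=4 * 10 / np.sqrt(len(te)))


class TestEstimatePower:
    def test_reproducible_under_fixed_seed(self, yeast_design):
        outcome = EditOutcome(mu=0.3, s_mut=0.05)
        p1 = estimate_power(yeast_design, outcome, 2_000, rng=np.random.default_rng(3))
        p2 = estimate_power(yeast_design, outcome, 2_000, rng=np.random.default_rng(3))
        assert p1 == p2

    def test_seeds_agree_within_sampling_error(self, yeast_design):
        outcome = EditOutcome(mu=0.4, s_mut=0.05)
        ps = [
            estimate_power(yeast_design, outcome, 4_000, rng=np.random.default_rng(s))
            for s in (1, 2)
        ]
        se = np.sqrt(ps[0] * (1 - ps[0]) / 4_000)
        assert abs(ps[0] - ps[1]) < 6 * se + 1e-9

    def test_neutral_gene_detected_at_alpha_rate(self, yeast_design):
        p = estimate_power(
            yeast_design, EditOutcome(mu=0.5, s_mut=0.0), 10_000,
            rng=np.random.default_rng(9),
        )
        ci = 2.576 * np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(p - 0.05) < ci

    def test_lethal_fully_edited_always_detected(self, yeast_design):
        p = estimate_power(
            yeast_design, EditOutcome(mu=1.0, s_mut=1.0), 1_000,
            rng=np.random.default_rng(2),
        )
        assert p == 1.0

    def test_untestable_tables_count_as_non_detection(self):
        # a tiny pool sequenced at depth 1 yields frequent zero-margin tables
        design = ScreenDesign(n_targets=1, n_controls=1, guides_per_target=1,
                              depth=1, generations=26)
        p = estimate_power(
            design, EditOutcome(mu=1.0, s_mut=1.0), 500,
            rng=np.random.default_rng(0),
        )
        assert 0.0 <= p <= 1.0  # NaN p-values must not propagate

    def test_vectorized_pvalues_match_scalar_path(self):
        rng = np.random.default_rng(21)
        arr = rng.integers(1, 5_000, size=(50, 4))
        _, pv = _pearson_2x2(*[arr[:, i].astype(float) for i in range(4)])
        for row, p_vec in zip(arr, pv):
            _, p_scalar = chi_square_proportions(CountTable(*map(int, row)))
            assert p_vec == pytest.approx(p_scalar, abs=1e-12)


class TestPowerGrid:
    def test_shape_alpha_row_and_determinism(self, yeast_design):
        mu = [0.0, 0.3, 0.9]
        s = [0.0, 0.05]
        g1 = power_grid(yeast_design, mu, s, iterations=1_500, seed=7)
        g2 = power_grid(yeast_design, mu, s, iterations=1_500, seed=7)
        assert g1.power.shape == (2, 3)
        assert np.array_equal(g1.power, g2.power)
        # s = 0 row stays near the nominal significance level
        assert np.all(np.abs(g1.power[0] - 0.05) < 0.03)
        df = g1.to_dataframe()
        assert set(df.columns) == {"mu", "s", "power"} and len(df) == 6


class TestGeneRecovery:
    def test_neutral_catalogue_recovers_nothing(self, yeast_design):
        curve = gene_recovery_curve(
            yeast_design, np.zeros(12), [0.5, 1.0], thresholds=(0.5,),
            iterations=300, seed=1,
        )
        assert np.all(curve.detected_fraction < 0.1)

    def test_lethal_catalogue_fully_recovered_at_full_editing(self, yeast_design):
        curve = gene_recovery_curve(
            yeast_design, np.ones(12), [1.0], thresholds=(0.95,),
            iterations=300, seed=1,
        )
        assert curve.detected_fraction[0, 0] == pytest.approx(1.0)

    def test_fraction_non_increasing_in_threshold(self, yeast_design):
        rng = np.random.default_rng(4)
        effects = rng.uniform(0.0, 0.3, size=15)
        curve = gene_recovery_curve(
            yeast_design, effects, [0.2, 0.6], thresholds=(0.5, 0.8, 0.95),
            iterations=300, seed=2,
        )
        assert np.all(np.diff(curve.detected_fraction, axis=0) <= 1e-12)

    def test_diploid_equals_haploid_at_squared_mu(self, yeast_design):
        """Ploidy acts only through the effective edit fraction mu**2."""
        diploid = ScreenDesign(
            n_targets=4800, n_controls=800, guides_per_target=8,
            depth=100, generations=26, ploidy=2,
        )
        effects = np.array([0.05, 0.1])
        c_dip = gene_recovery_curve(diploid, effects, [0.6], thresholds=(0.5,),
                                    iterations=400, seed=3)
        c_hap = gene_recovery_curve(yeast_design, effects, [0.36], thresholds=(0.5,),
                                    iterations=400, seed=3)
        assert np.array_equal(c_dip.gene_power, c_hap.gene_power)

    def test_guide_aggregation_any_of_g_beats_single_guide(self, yeast_design):
        effects = np.array([0.05])
        single = gene_recovery_curve(yeast_design, effects, [0.3], thresholds=(0.5,),
                                     iterations=800, seed=5)
        any_guide = gene_recovery_curve(yeast_design, effects, [0.3], thresholds=(0.5,),
                                        iterations=800, seed=5, min_guides=1)
        assert any_guide.gene_power[0, 0] >= single.gene_power[0, 0]
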