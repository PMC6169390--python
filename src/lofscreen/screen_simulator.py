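"""Monte-Carlo detection-power engine for pooled LOF screens.

Each simulated screen draws four independent binomial read counts — one target
guide and the pooled controls, each at the start and the end of the
competition — and asks whether a Pearson chi-square test of equal proportions
on the resulting 2x2 table is significant.  Detection power at a (mu, s_mut)
point is the fraction of significant iterations; sweeping the point over a
grid yields a power surface, and evaluating each gene of a fitness-effect
catalogue gives genome-wide recovery curves.

The chi-square statistic is computed vectorially from expected counts
(1 degree of freedom, no continuity correction by default) so that a
10,000-iteration power estimate is a handful of array operations.  Tables
with a zero row or column margin are untestable and count as non-detections:
a screen cannot call a gene from zero reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .screen_model import (
    EditOutcome,
    ScreenDesign,
    effective_edit_fraction,
    read_probability,
)

__all__ = [
    "CountTable",
    "PowerGrid",
    "RecoveryCurve",
    "sample_counts",
    "chi_square_proportions",
    "estimate_power",
    "power_grid",
    "gene_recovery_curve",
]


@dataclass(frozen=True)
class CountTable:
    """Read counts for one target guide vs the pooled controls at start/end."""

    target_start: int
    target_end: int
    control_start: int
    control_end: int

    def __post_init__(self) -> None:
        for name in ("target_start", "target_end", "control_start", "control_end"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        """2x2 array: rows = (target, control), columns = (start, end)."""
        return np.array(
            [[self.target_start, self.target_end], [self.control_start, self.control_end]],
            dtype=float,
        )

    @property
    def testable(self) -> bool:
        """True unless a row or column margin is zero."""
        a = self.as_array()
        return bool(a.sum(axis=0).min() > 0 and a.sum(axis=1).min() > 0)


@dataclass
class PowerGrid:
    """Detection power over a (mu, s_mut) grid."""

    mu_values: np.ndarray
    s_values: np.ndarray
    power: np.ndarray  # shape (len(s_values), len(mu_values))
    iterations: int
    alpha: float

    def __post_init__(self) -> None:
        self.mu_values = np.asarray(self.mu_values, dtype=float)
        self.s_values = np.asarray(self.s_values, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (len(self.s_values), len(self.mu_values)):
            raise ValueError("power matrix shape must be (len(s_values), len(mu_values))")

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long-format table with columns mu, s, power."""
        mu, s = np.meshgrid(self.mu_values, self.s_values)
        return pd.DataFrame(
            {"mu": mu.ravel(), "s": s.ravel(), "power": self.power.ravel()}
        )


@dataclass
class RecoveryCurve:
    """Fraction of genes detected vs mutagenesis rate, per success-rate threshold."""

    mu_values: np.ndarray
    thresholds: np.ndarray
    detected_fraction: np.ndarray  # shape (len(thresholds), len(mu_values))
    gene_power: np.ndarray = field(default=None, repr=False)  # (n_genes, n_mu)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, thr in enumerate(self.thresholds):
            for j, mu in enumerate(self.mu_values):
                rows.append({"threshold": thr, "mu": mu, "detected_fraction": self.detected_fraction[i, j]})
        return pd.DataFrame(rows)


def sample_counts(design: ScreenDesign, outcome: EditOutcome, rng: np.random.Generator) -> CountTable:
    """Draw one simulated 2x2 read-count table.

    Four independent binomial draws with sample size k_p * d and the success
    probabilities from :func:`lofscreen.screen_model.read_probability`.
    """
    n = design.total_reads
    return CountTable(
        target_start=int(rng.binomial(n, read_probability(design, timepoint="start"))),
        target_end=int(rng.binomial(n, read_probability(design, outcome, "end"))),
        control_start=int(rng.binomial(n, read_probability(design, category="control"))),
        control_end=int(rng.binomial(n, read_probability(design, category="control"))),
    )


def _pearson_2x2(ts, te, cs, ce, correction: bool = False):
    """Vectorized Pearson chi-square for 2x2 tables (1 df).

    Rows (target, control) x columns (start, end).  Expected counts are
    row_sum * col_sum / N.  Returns (statistic, p_value); untestable tables
    (a zero margin) give NaN for both.
    """
    ts = np.asarray(ts, dtype=float)
    te = np.asarray(te, dtype=float)
    cs = np.asarray(cs, dtype=float)
    ce = np.asarray(ce, dtype=float)
    n = ts + te + cs + ce
    row_t = ts + te
    row_c = cs + ce
    col_s = ts + cs
    col_e = te + ce
    testable = (row_t > 0) & (row_c > 0) & (col_s > 0) & (col_e > 0)
    safe_n = np.where(n > 0, n, 1.0)
    stat = np.zeros_like(n)
    for obs, r, c in ((ts, row_t, col_s), (te, row_t, col_e), (cs, row_c, col_s), (ce, row_c, col_e)):
        expected = r * c / safe_n
        safe_e = np.where(expected > 0, expected, 1.0)
        dev = np.abs(obs - expected)
        if correction:
            dev = np.maximum(dev - 0.5, 0.0)
        stat = stat + np.where(expected > 0, dev * dev / safe_e, 0.0)
    stat = np.where(testable, stat, np.nan)
    pval = np.where(testable, stats.chi2.sf(np.where(testable, stat, 0.0), df=1), np.nan)
    return stat, pval


def chi_square_proportions(table: CountTable, correction: bool = False):
    """Pearson chi-square test of equal proportions on one 2x2 count table.

    Tests whether the target guide's share of reads differs between the two
    timepoints, relative to the pooled controls.  Returns
    ``(statistic, p_value)``; both are NaN for an untestable (zero-margin)
    table, which callers treat as a non-detection.
    """
    stat, pval = _pearson_2x2(
        table.target_start, table.target_end, table.control_start, table.control_end,
        correction=correction,
    )
    return float(stat), float(pval)


def _sample_count_arrays(design, outcome, iterations, rng):
    n = design.total_reads
    p_start = read_probability(design, timepoint="start")
    p_end = read_probability(design, outcome, "end")
    p_ctrl = read_probability(design, category="control")
    ts = rng.binomial(n, p_start, size=iterations)
    te = rng.binomial(n, p_end, size=iterations)
    cs = rng.binomial(n, p_ctrl, size=iterations)
    ce = rng.binomial(n, p_ctrl, size=iterations)
    return ts, te, cs, ce


def estimate_power(
    design: ScreenDesign,
    outcome: EditOutcome,
    iterations: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    correction: bool = False,
) -> float:
    """Detection power: fraction of simulated screens significant at ``alpha``.

    Each iteration draws an independent 2x2 count table and applies the
    chi-square test; untestable tables count as non-detections.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    ts, te, cs, ce = _sample_count_arrays(design, outcome, iterations, rng)
    _, pval = _pearson_2x2(ts, te, cs, ce, correction=correction)
    detected = np.nan_to_num(pval, nan=1.0) < alpha
    return float(detected.mean())


def power_grid(
    design: ScreenDesign,
    mu_values,
    s_values,
    iterations: int = 1_000,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    correction: bool = False,
) -> PowerGrid:
    """Detection power over the Cartesian grid ``s_values x mu_values``.

    Each cell runs :func:`estimate_power` on its own child random stream
    derived from ``seed``, so results are reproducible and independent of
    evaluation order.
    """
    mu_values = np.asarray(mu_values, dtype=float)
    s_values = np.asarray(s_values, dtype=float)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(s_values) * len(mu_values))
    power = np.empty((len(s_values), len(mu_values)))
    k = 0
    for i, s in enumerate(s_values):
        for j, mu in enumerate(mu_values):
            rng = np.random.default_rng(children[k])
            power[i, j] = estimate_power(
                design, EditOutcome(mu=float(mu), s_mut=float(s)),
                iterations=iterations, alpha=alpha, rng=rng, correction=correction,
            )
            k += 1
    return PowerGrid(mu_values=mu_values, s_values=s_values, power=power,
                     iterations=iterations, alpha=alpha)


def _gene_power_aggregated(design, outcome, iterations, alpha, rng, min_guides, correction):
    """Success rate when a gene is called if >= min_guides of its g guides are significant."""
    g = design.guides_per_target
    n = design.total_reads
    p_start = read_probability(design, timepoint="start")
    p_end = read_probability(design, outcome, "end")
    p_ctrl = read_probability(design, category="control")
    cs = rng.binomial(n, p_ctrl, size=iterations)
    ce = rng.binomial(n, p_ctrl, size=iterations)
    ts = rng.binomial(n, p_start, size=(g, iterations))
    te = rng.binomial(n, p_end, size=(g, iterations))
    _, pval = _pearson_2x2(ts, te, cs[None, :], ce[None, :], correction=correction)
    detected = np.nan_to_num(pval, nan=1.0) < alpha
    return float((detected.sum(axis=0) >= min_guides).mean())


def gene_recovery_curve(
    design: ScreenDesign,
    effects,
    mu_values,
    thresholds=(0.5, 0.8, 0.95),
    iterations: int = 1_000,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    min_guides: int | None = None,
    correction: bool = False,
) -> RecoveryCurve:
    """Fraction of genes recovered vs mutagenesis rate.

    For every gene (one selection coefficient from ``effects``) and every
    mutagenesis rate in ``mu_values``, the per-gene detection success rate is
    estimated by Monte Carlo (with the ploidy-adjusted effective edit
    fraction applied through the read model).  A gene counts as recovered at
    a threshold when its success rate meets or exceeds it.

    By default each gene is evaluated as a single representative guide;
    ``min_guides=m`` switches to an m-of-g guide aggregation rule.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.size == 0:
        raise ValueError("effects must be non-empty")
    if np.any(effects < 0) or np.any(effects > 1):
        raise ValueError("selection coefficients must lie in [0, 1]")
    mu_values = np.asarray(mu_values, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0) or np.any(thresholds > 1):
        raise ValueError("thresholds must lie in (0, 1]")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(effects.size * mu_values.size)
    gene_power = np.empty((effects.size, mu_values.size))
    k = 0
    for i, s in enumerate(effects):
        for j, mu in enumerate(mu_values):
            rng = np.random.default_rng(children[k])
            outcome = EditOutcome(mu=float(mu), s_mut=float(s))
            if min_guides is None:
                gene_power[i, j] = estimate_power(
                    design, outcome, iterations=iterations, alpha=alpha,
                    rng=rng, correction=correction,
                )
            else:
                gene_power[i, j] = _gene_power_aggregated(
                    design, outcome, iterations, alpha, rng, min_guides, correction,
                )
            k += 1
    detected = np.array([(gene_power >= thr).mean(axis=0) for thr in thresholds])
    return RecoveryCurve(
        mu_values=mu_values, thresholds=thresholds,
        detected_fraction=detected, gene_power=gene_power,
    )
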