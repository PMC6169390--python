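"""Closed-form competition model for pooled CRISPR-LOF barcode screens.

In a pooled loss-of-function (LOF) screen the guide RNA doubles as a strain
barcode (Bar-seq style).  Cells carrying a guide against a gene are a mixture:
a fraction ``mu`` (the mutagenesis rate achieved after editing and recovery)
actually carries the LOF and grows with relative fitness ``1 - s_mut`` per
generation, while the remaining ``1 - mu`` are effectively wild type.  Control
guides target nothing and grow like wild type.  This module provides the
closed-form abundance dynamics of that mixture and the binomial read-sampling
probabilities used by the Monte-Carlo simulator.

Central quantity: the control-to-mutant barcode abundance ratio after ``t``
generations,

    n_WT(t) / n_BC(t) = 1 / (mu * ((1 - s_mut)**t - 1) + 1)

assuming equal starting abundance.  The ratio is 1 for neutral or unedited
populations and grows without bound as the edited subpopulation dies off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScreenDesign",
    "EditOutcome",
    "relative_fitness",
    "barcode_ratio",
    "read_probability",
    "effective_edit_fraction",
]


@dataclass(frozen=True)
class ScreenDesign:
    """Layout and sequencing parameters of a pooled LOF screen.

    Parameters
    ----------
    n_targets
        Number of LOF target loci (genes) in the pool.
    n_controls
        Number of control guides, treated as one pooled category.
    guides_per_target
        Guides per target locus.
    depth
        Expected average sequencing reads per guide.
    generations
        Length of the pooled growth competition, in generations.
    ploidy
        1 (haploid) or 2 (diploid; both alleles must be edited for a LOF).
    """

    n_targets: int
    n_controls: int
    guides_per_target: int
    depth: int
    generations: int = 26
    ploidy: int = 1

    def __post_init__(self) -> None:
        for name in ("n_targets", "n_controls", "guides_per_target", "depth"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value <= 0:
                raise ValueError(f"{name} must be a strictly positive integer, got {value!r}")
        if not isinstance(self.generations, (int, np.integer)) or self.generations < 0:
            raise ValueError(f"generations must be a non-negative integer, got {self.generations!r}")
        if self.ploidy not in (1, 2):
            raise ValueError(f"ploidy must be 1 or 2, got {self.ploidy!r}")

    @property
    def total_guides(self) -> int:
        """Total guide count k_p = guides_per_target * n_targets + n_controls."""
        return self.guides_per_target * self.n_targets + self.n_controls

    @property
    def total_reads(self) -> int:
        """Expected total read budget k_p * depth (the binomial sample size)."""
        return self.total_guides * self.depth


@dataclass(frozen=True)
class EditOutcome:
    """A (mu, s_mut) pair: per-cell mutagenesis rate and LOF selection coefficient."""

    mu: float
    s_mut: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu!r}")
        if not 0.0 <= self.s_mut <= 1.0:
            raise ValueError(f"s_mut must lie in [0, 1], got {self.s_mut!r}")


def relative_fitness(s_mut, generations):
    """Cumulative mutant/wild-type fitness ratio ``(1 - s_mut)**generations``.

    Growth rates are assumed constant over time, so the per-generation fitness
    ratio ``1 - s_mut`` compounds geometrically.  Accepts scalars or arrays.
    """
    s = np.asarray(s_mut, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("s_mut must lie in [0, 1]")
    g = np.asarray(generations)
    if np.any(g < 0):
        raise ValueError("generations must be non-negative")
    out = np.power(1.0 - s, g)
    return out.item() if np.isscalar(s_mut) and np.isscalar(generations) else out


def barcode_ratio(mu, s_mut, generations, initial_ratio=1.0):
    """Control-to-mutant barcode abundance ratio n_WT(t)/n_BC(t).

    ``initial_ratio * 1 / (mu * ((1 - s_mut)**t - 1) + 1)`` where t is
    ``generations``.  Equals ``initial_ratio`` when mu = 0, s_mut = 0 or
    t = 0; diverges (returns ``inf``) in the degenerate all-edited-all-dead
    limit mu = 1, s_mut = 1 with t > 0, where the barcode vanishes entirely.

    Accepts scalars or broadcastable arrays.
    """
    m = np.asarray(mu, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("mu must lie in [0, 1]")
    w = relative_fitness(s_mut, generations)
    # algebraically mu*(w - 1) + 1; written as a convex combination so the
    # mu -> 1, w -> 0 corner does not cancel catastrophically
    denom = m * np.asarray(w) + (1.0 - m)
    with np.errstate(divide="ignore"):
        out = np.where(denom > 0.0, initial_ratio / np.where(denom > 0.0, denom, 1.0), np.inf)
    scalars = all(np.isscalar(v) for v in (mu, s_mut, generations))
    return float(out) if scalars else out


def effective_edit_fraction(mu, ploidy):
    """Fraction of cells with a full LOF given per-allele edit rate ``mu``.

    Haploids need one edit (returns mu).  Diploids need both alleles edited;
    under independent per-allele editing the fraction is mu**2.
    """
    m = np.asarray(mu, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("mu must lie in [0, 1]")
    if ploidy == 1:
        return mu
    if ploidy == 2:
        out = m * m
        return float(out) if np.isscalar(mu) else out
    raise ValueError(f"ploidy must be 1 or 2, got {ploidy!r}")


def read_probability(
    design: ScreenDesign,
    outcome: EditOutcome | None = None,
    timepoint: str = "start",
    category: str = "target",
):
    """Binomial success probability for one barcode's read count.

    Every read count is modelled as B(k_p * d, p) with

    - p = 1/k_p for a single target guide at the start,
    - p = c/k_p for the pooled controls at either timepoint,
    - p = (1/k_p) * n_BC(t)/n_WT(t) for a target guide after ``t``
      generations of competition (the reciprocal of :func:`barcode_ratio`,
      with ``mu`` replaced by the ploidy-adjusted effective edit fraction).

    Probabilities are marginal per barcode; the pool is not renormalized
    after selection.
    """
    if timepoint not in ("start", "end"):
        raise ValueError(f"timepoint must be 'start' or 'end', got {timepoint!r}")
    if category not in ("target", "control"):
        raise ValueError(f"category must be 'target' or 'control', got {category!r}")
    kp = design.total_guides
    if category == "control":
        return design.n_controls / kp
    if timepoint == "start":
        return 1.0 / kp
    if outcome is None:
        raise ValueError("an EditOutcome is required for a target at the end timepoint")
    mu_eff = effective_edit_fraction(outcome.mu, design.ploidy)
    ratio = barcode_ratio(mu_eff, outcome.s_mut, design.generations)
    if np.isinf(ratio):
        return 0.0
    return (1.0 / kp) / ratio
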