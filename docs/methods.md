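# Methods

## Competition model

A pooled LOF screen is modelled as a haploid selection experiment with
incomplete editing. Each target guide's population is a mixture: a fraction
μ (the mutagenesis rate after recovery, i.e. at the start of the
competition) carries the LOF and has relative fitness 1 − s per generation;
the remaining 1 − μ are phenotypically wild type. Growth rates are constant
in time, so the cumulative mutant/wild-type fitness ratio after t
generations is (1 − s)^t, and with equal starting abundance the
control-to-target barcode ratio is

    n_WT(t) / n_BC(t) = 1 / (μ·((1 − s)^t − 1) + 1).

The implementation evaluates the denominator as the convex combination
μ·(1 − s)^t + (1 − μ), which is algebraically identical but avoids
catastrophic cancellation at the μ → 1, (1 − s)^t → 0 corner; the fully
edited lethal corner (μ = 1, s = 1, t > 0) is reported as an infinite ratio
and maps to a zero read probability downstream. A configurable initial
abundance ratio is exposed but defaults to 1 (equal starting proportions).

**Assumptions.** Constant per-generation fitness; no de-novo editing during
the competition; no bottlenecks or drift in cell numbers (selection is
deterministic; all stochasticity enters through read sampling); each
barcode's read count is a marginal binomial — probabilities are *not*
renormalized across the pool after selection, so one depleted barcode does
not inflate the others. At the pool sizes modelled here (one barcode in
~39,200) the renormalization term is O(1/k_p) and negligible.

## Read sampling and detection

With k_p = g·(targets) + c guides sequenced at d expected reads per guide,
counts are independent binomial draws with n = k_p·d trials: success
probability 1/k_p for a target guide at the start, (1/k_p)·n_BC(t)/n_WT(t)
at the end, and c/k_p for the pooled controls at both timepoints. Detection
uses the Pearson chi-square test of equal proportions (1 degree of freedom,
upper tail) on the 2×2 table (target, pooled control) × (start, end);
default α = 0.05.

No continuity correction is applied by default: at the expected counts of
this design (≈100 reads per target guide) the Yates correction makes the
test conservative (measured type-I rate ≈ 0.042 at α = 0.05 versus 0.050
without), which would systematically depress power. The correction is
available as a flag. Tables with a zero row or column margin are untestable
and counted as non-detections — a screen cannot call a gene from zero reads.

The chi-square is computed vectorially from expected counts so that a
10,000-iteration power estimate costs a handful of array operations; the
test suite verifies it against an independent contingency-table
implementation to 1e-8 on 1,000 random tables.

### A note on the headline operating points

Under this model the design with 4,800 targets, 800 pooled controls, 8
guides/target, d = 100 and 26 generations yields detection power ≈ 0.19 for
(μ = 0.2, s = 0.05) and ≈ 0.95 for (μ = 0.6, s = 0.05) — reproducibly
across chi-square variants (Pearson, Yates-corrected, G-test) and consistent
with a normal-approximation check: the expected barcode depletion is 14.7
reads against a sampling standard deviation of √(100 + 85.3) ≈ 13.6, i.e.
z ≈ 1.08 at μ = 0.2 and z ≈ 3.5 at μ = 0.6. Operating-point figures of 25%
and >99% quoted for this design elsewhere would require roughly 25–35% less
count variance than four independent binomial draws produce; the package
reports what the stated model implies.

## Diploid screens

A diploid LOF requires both alleles edited. The package models per-allele
editing as independent with the same rate μ and heterozygotes as
phenotypically wild type, giving an effective LOF fraction μ², which is fed
into the barcode ratio in place of μ. This is the simplest model consistent
with a recessive LOF; dominant or dosage-sensitive effects, and correlated
editing of the two alleles (e.g. via gene conversion), are not modelled and
would raise diploid power toward the haploid curve.

## Power grids and gene-recovery curves

Power surfaces evaluate the Monte-Carlo power on a (μ, s) grid; recovery
curves evaluate, for every gene in a fitness-effect catalogue, the per-gene
detection success rate as a function of μ, and report the fraction of genes
whose success rate meets each threshold (defaults 0.5, 0.8, 0.95 — the
thresholds are a display choice, configurable). Each grid cell / gene×μ
point runs on its own child stream spawned from the root seed
(`numpy.random.SeedSequence`), so results are bit-reproducible and
independent of evaluation order.

By default a gene is evaluated as a single representative guide at its
(μ, s); an m-of-g guide aggregation mode (gene called when ≥ m of its g
guides are individually significant, controls shared across guides) is
provided but off by default, since guides against the same gene generally
differ in efficiency and cutting them all at one μ would overstate
aggregation gains.

**Problem sizes.** The analysis drivers run desk-scale settings chosen to
characterize the surfaces without waste: 21×21 grids at 1,000
iterations/cell, 200-gene catalogues at 300 iterations/point, and 10,000
iterations for single operating points and calibration checks (Monte-Carlo
s.e. ≤ 0.005). Full-resolution sweeps (100×100 × 10,000) are a
configuration change, not a code path.

## Synthetic fitness-effect catalogue

Genome-wide deletion fitness effects in rich media are emulated by a
four-part mixture: a point mass of neutral genes at s = 0 (default weight
0.30), a right-skewed bulk on (0, 0.25] — a Beta(1.2, 3) scaled by 0.25 —
carrying the remaining mass (default 0.65), a uniform tail on (0.25, 1]
(default 0.05), and an optional lethal point mass at s = 1 (default 0,
since essential genes are excluded from LOF target lists). The defaults
place ~95% of genes at s ≤ 0.25, matching the qualitative shape of
deletion-collection Bar-seq measurements; the generator makes no attempt to
reproduce any specific empirical histogram, so recovery-curve *shapes* are
illustrative while their orderings (haploid vs diploid, d = 100 vs 200) are
model properties.

## Chromatogram quantification

The estimator takes a four-channel trace plus called peak positions (from an
ABIF file's processed channels and base-call index, or the plain-text
dialect). At a queried position it integrates each channel by the
trapezoidal rule over a window of half-width 4 scan units (default;
"small window" is the operative design constraint — wide enough to average
point noise, narrow enough to exclude neighbouring peaks at the ~12-scan
spacing of capillary traces), after subtracting the per-channel within-window
minimum as a baseline (robust to DC offset without curve fitting, floored at
zero). Normalizing the four areas by their sum gives the per-base
composition (the heat-map quantity); restricting to the wild-type and mutant
bases gives the mutant fraction.

Because wild-type and mutant peaks at a position share centre and shape,
windowed areas are exactly proportional to the mixture before noise — the
estimator inverts noiseless synthetic traces to machine precision. With
baseline noise at 5% of peak height the single-trace error has s.d. ≈ 0.03
and a small positive bias at f = 0 / negative near f = 1 (the baseline floor
clips symmetric noise), which is why titration calibration reports a slope
slightly below 1 — an *underestimation* tendency flagged by
`titration_calibration`. Adjacent-peak tail bleed contributes O(1e-9) at
16-scan spacing and is not deconvolved; the estimator is semi-quantitative
by design.

Synthetic traces use Gaussian peaks. Real capillary peak shapes vary
(asymmetry, width drift along the read), but the estimator uses only
windowed areas, which are shape-robust; what the synthetic tests do *not*
exercise is miscalled peak positions, dye blobs, or mobility-shift overlap
between adjacent bases.

## Known limitations

- Forward model only: no estimation of μ or s from observed screen data.
- No guide-synthesis error model (a fraction of cells carrying unusable
  guides would act as extra controls and dilute power).
- No multiple-testing control across genes; each guide is tested marginally
  at P < 0.05, so genome-wide false-discovery behaviour is outside scope.
- No read-level sequencing error or PCR-amplification noise; depth d enters
  only through the binomial sample size.
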