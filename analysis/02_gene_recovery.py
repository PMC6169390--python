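"""Genome-wide gene-recovery curves: haploid vs diploid, d = 100 vs 200.

Samples a synthetic catalogue of deletion fitness effects (most between 0 and
0.25, a neutral point mass, a small strong-effect tail), then asks what
fraction of genes would be recovered by the screen as a function of
mutagenesis rate, for three per-gene success-rate thresholds.  Three screen
variants are compared: haploid at 100 reads/guide, diploid at 100, and
diploid at 200 (doubled sequencing depth).

Writes results/recovery_*.csv (+ plots + manifests) and prints a summary.
Run from the repository root:  python analysis/02_gene_recovery.py
"""

from pathlib import Path

from lofscreen import RunConfig
from lofscreen.reporting import run_recovery_curves

OUT = Path(__file__).resolve().parent.parent / "results"

N_GENES = 200
MU_POINTS = 21
ITERATIONS = 300


def main(seed: int = 0) -> None:
    variants = {
        "recovery_haploid_d100": RunConfig(ploidy=1, depth=100, iterations=ITERATIONS, seed=seed),
        "recovery_diploid_d100": RunConfig(ploidy=2, depth=100, iterations=ITERATIONS, seed=seed),
        "recovery_diploid_d200": RunConfig(ploidy=2, depth=200, iterations=ITERATIONS, seed=seed),
    }
    curves = {}
    for label, config in variants.items():
        curves[label] = run_recovery_curves(
            config, OUT, n_genes=N_GENES, mu_points=MU_POINTS, label=label,
        )

    # summarize at a mid-range mutagenesis rate and the loosest threshold
    j = MU_POINTS // 2  # mu = 0.5
    print(f"gene-recovery curves written to {OUT} "
          f"({N_GENES} genes, {ITERATIONS} iterations/point)")
    print("fraction of genes recovered at mu = 0.5, success-rate threshold 0.5:")
    for label, curve in curves.items():
        print(f"  {label}: {curve.detected_fraction[0, j]:.3f}")
    hap = curves["recovery_haploid_d100"].detected_fraction[0]
    dip = curves["recovery_diploid_d100"].detected_fraction[0]
    dip200 = curves["recovery_diploid_d200"].detected_fraction[0]
    print("finding: diploid screens recover fewer genes at matched mu "
          f"(mean gap {float((hap - dip).mean()):.3f}); doubling depth to 200 "
          f"recovers part of it (mean gain {float((dip200 - dip).mean()):.3f}).")


if __name__ == "__main__":
    main()
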