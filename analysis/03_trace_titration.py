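"""Titration calibration of the chromatogram allele-frequency estimator.

Generates synthetic Sanger traces in which one position carries a known
mutant/wild-type mixture, quantifies the mutant fraction by windowed peak
areas, and calibrates estimated against true fractions — noiseless (exact
recovery) and at 5% baseline noise (the tolerance study).

Writes results/titration.csv and prints the calibration summary.
Run from the repository root:  python analysis/03_trace_titration.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lofscreen import TraceSpec, generate_trace, mutant_ratio, titration_calibration

OUT = Path(__file__).resolve().parent.parent / "results"

FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)
NOISE_SD = 50.0  # 5% of the 1000-unit peak height
REPLICATES = 20


def one_trace(f: float, noise_sd: float = 0.0, rng=None):
    spec = TraceSpec(
        positions=np.arange(16, 16 * 8, 16),
        base_calls="ATCACGT",
        mutant_fraction=[0, 0, 0, f, 0, 0, 0],
        mutant_bases="AAAGAAA",
        noise_sd=noise_sd,
    )
    trace = generate_trace(spec, rng)
    return mutant_ratio(trace, 64, wt_base="A", mutant_base="G").mutant_fraction


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in FRACTIONS:
        rows.append({"true_fraction": f, "noise_sd": 0.0, "replicate": 0,
                     "estimated_fraction": one_trace(f)})
    rng = np.random.default_rng(seed)
    for f in FRACTIONS:
        for r in range(REPLICATES):
            rows.append({"true_fraction": f, "noise_sd": NOISE_SD, "replicate": r,
                         "estimated_fraction": one_trace(f, NOISE_SD, rng)})
    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "titration.csv", index=False)

    clean = frame[frame.noise_sd == 0]
    noisy = frame[frame.noise_sd > 0]
    max_clean_err = (clean.estimated_fraction - clean.true_fraction).abs().max()
    means = noisy.groupby("true_fraction").estimated_fraction.mean()
    cal = titration_calibration(list(zip(noisy.true_fraction, noisy.estimated_fraction)))

    print(f"titration table written to {OUT}/titration.csv")
    print(f"noiseless recovery: max |error| = {max_clean_err:.2e}")
    print("noisy (5% of peak height) per-fraction mean estimates:")
    for f, m in means.items():
        print(f"  true {f:.2f} -> mean estimate {m:.3f}")
    print(f"calibration: slope = {cal.slope:.3f}, intercept = {cal.intercept:.3f}, "
          f"max deviation = {cal.max_deviation:.3f}, monotonic means = "
          f"{bool(means.sort_index().diff().dropna().ge(0).all())}")
    if cal.underestimates:
        print("finding: the estimator slightly underestimates high mutant fractions "
              "(slope < 1), matching the qualitative behaviour expected of "
              "windowed-area quantification of mixed traces.")


if __name__ == "__main__":
    main()
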