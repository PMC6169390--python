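import numpy as np
import pytest

from lofscreen import ScreenDesign, TraceSpec, generate_trace


@pytest.fixture
def yeast_design() -> ScreenDesign:
    """The genome-wide yeast screen layout used throughout the analyses."""
    return ScreenDesign(
        n_targets=4800, n_controls=800, guides_per_target=8,
        depth=100, generations=26, ploidy=1,
    )


@pytest.fixture
def small_design() -> ScreenDesign:
    """A scaled-down pool for tests that iterate over whole count tables."""
    return ScreenDesign(
        n_targets=50, n_controls=20, guides_per_target=2,
        depth=100, generations=26, ploidy=1,
    )


def make_titration_trace(fraction: float, noise_sd: float = 0.0, rng=None):
    """Seven well-separated peaks; the middle one carries an A->G mixture."""
    spec = TraceSpec(
        positions=np.arange(16, 16 * 8, 16),
        base_calls="ATCACGT",
        mutant_fraction=[0, 0, 0, fraction, 0, 0, 0],
        mutant_bases="AAAGAAA",
        noise_sd=noise_sd,
    )
    return generate_trace(spec, rng)
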