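"""Synthetic inputs: fitness-effect catalogues, screen count tables, traces.

Everything the pipeline consumes can be generated here without external
downloads:

* :class:`FitnessEffectDistribution` — a four-component mixture emulating the
  genome-wide distribution of deletion fitness effects measured in yeast
  Bar-seq competition assays: a point mass of neutral genes at s = 0, a
  right-skewed bulk of mild effects on (0, 0.25] (where most non-essential
  deletion phenotypes fall), a small uniform tail of strong effects on
  (0.25, 1], and an optional lethal point mass at s = 1.
* :func:`generate_trace` — synthetic four-channel Sanger chromatograms with
  Gaussian peaks and a controllable mutant/wild-type mixture per position,
  for exercising the trace quantifier end to end.
* :func:`generate_screen_counts` — a full per-guide count table (targets +
  controls, start and end) drawn from the screen read model.
* :func:`write_trace_abif` — a minimal synthetic ABIF (.ab1) writer so the
  binary reading path can be tested without instrument files.

All generators are deterministic under a fixed :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen_model import EditOutcome, ScreenDesign, read_probability
from .trace_quant import BASES, _BASE_INDEX, TraceData

__all__ = [
    "FitnessEffectDistribution",
    "TraceSpec",
    "sample_effects",
    "generate_trace",
    "generate_screen_counts",
    "write_trace_abif",
]


@dataclass(frozen=True)
class FitnessEffectDistribution:
    """Mixture model of selection coefficients across a gene catalogue.

    Component weights: ``neutral_fraction`` at exactly 0, ``tail_fraction``
    uniform on (0.25, 1], ``lethal_fraction`` at exactly 1, and the remainder
    in the bulk — a Beta(``bulk_a``, ``bulk_b``) scaled onto (0, 0.25].
    Defaults put most of the mass at small effects, as observed for
    non-essential gene deletions in rich media.
    """

    neutral_fraction: float = 0.30
    tail_fraction: float = 0.05
    lethal_fraction: float = 0.0
    bulk_a: float = 1.2
    bulk_b: float = 3.0
    bulk_scale: float = 0.25

    def __post_init__(self) -> None:
        for name in ("neutral_fraction", "tail_fraction", "lethal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.neutral_fraction + self.tail_fraction + self.lethal_fraction > 1.0 + 1e-12:
            raise ValueError("component fractions must sum to at most 1")
        if self.bulk_a <= 0 or self.bulk_b <= 0 or not 0 < self.bulk_scale <= 1:
            raise ValueError("invalid bulk shape parameters")

    @property
    def bulk_fraction(self) -> float:
        return 1.0 - self.neutral_fraction - self.tail_fraction - self.lethal_fraction

    def mean(self) -> float:
        """Closed-form mixture mean."""
        bulk_mean = self.bulk_scale * self.bulk_a / (self.bulk_a + self.bulk_b)
        tail_mean = (0.25 + 1.0) / 2.0
        return (
            self.bulk_fraction * bulk_mean
            + self.tail_fraction * tail_mean
            + self.lethal_fraction * 1.0
        )


def sample_effects(
    dist: FitnessEffectDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` selection coefficients from the mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    u = rng.random(n)
    out = np.empty(n)
    p_neutral = dist.neutral_fraction
    p_tail = p_neutral + dist.tail_fraction
    p_lethal = p_tail + dist.lethal_fraction
    neutral = u < p_neutral
    tail = (u >= p_neutral) & (u < p_tail)
    lethal = (u >= p_tail) & (u < p_lethal)
    bulk = u >= p_lethal
    out[neutral] = 0.0
    out[lethal] = 1.0
    out[tail] = 0.25 + 0.75 * rng.random(int(tail.sum()))
    out[bulk] = dist.bulk_scale * rng.beta(dist.bulk_a, dist.bulk_b, size=int(bulk.sum()))
    return out


# ---------------------------------------------------------------------------
# chromatogram traces

@dataclass
class TraceSpec:
    """Blueprint for a synthetic chromatogram.

    One Gaussian peak per entry of ``positions``; at each position a fraction
    ``mutant_fraction[i]`` of the peak height goes to ``mutant_bases[i]`` and
    the rest to ``base_calls[i]``.  ``peak_width`` is the Gaussian sigma in
    scan units; ``noise_sd`` adds zero-mean Gaussian baseline noise (clipped
    at zero, as a detector would).
    """

    positions: np.ndarray
    base_calls: str
    mutant_fraction: np.ndarray = None
    mutant_bases: str | None = None
    peak_width: float = 2.0
    noise_sd: float = 0.0
    peak_height: float = 1000.0
    pad: int = 12

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if len(self.base_calls) != len(self.positions):
            raise ValueError("one called base per position is required")
        if self.mutant_fraction is None:
            self.mutant_fraction = np.zeros(len(self.positions))
        self.mutant_fraction = np.asarray(self.mutant_fraction, dtype=float)
        if len(self.mutant_fraction) != len(self.positions):
            raise ValueError("one mutant fraction per position is required")
        if np.any((self.mutant_fraction < 0) | (self.mutant_fraction > 1)):
            raise ValueError("mutant fractions must lie in [0, 1]")
        if self.mutant_bases is not None and len(self.mutant_bases) != len(self.positions):
            raise ValueError("one mutant base per position is required")
        for b in self.base_calls + (self.mutant_bases or ""):
            if b not in _BASE_INDEX:
                raise ValueError(f"unknown base {b!r}")


def generate_trace(spec: TraceSpec, rng: np.random.Generator | None = None) -> TraceData:
    """Render a :class:`TraceSpec` into four-channel intensities.

    Peaks closer together than 3 sigma are rejected: their windows would
    overlap too much for the areas to be attributable to single base calls.
    Before noise, the per-position channel amplitudes are exactly
    ``(1 - f) * peak_height`` (wild type) and ``f * peak_height`` (mutant),
    so windowed area proportions match the specified mixture.
    """
    if np.any(np.diff(spec.positions) < 3.0 * spec.peak_width):
        raise ValueError("peak positions closer than 3 sigma are not supported")
    n_scans = int(spec.positions[-1]) + spec.pad + 1 if len(spec.positions) else spec.pad
    if spec.positions[0] - spec.pad < 0:
        raise ValueError("first peak too close to the scan start for the configured pad")
    channels = np.zeros((4, n_scans))
    x = np.arange(n_scans)
    for i, pos in enumerate(spec.positions):
        shape = np.exp(-((x - pos) ** 2) / (2.0 * spec.peak_width**2))
        f = spec.mutant_fraction[i]
        wt = spec.base_calls[i]
        channels[_BASE_INDEX[wt]] += (1.0 - f) * spec.peak_height * shape
        if f > 0:
            if spec.mutant_bases is None:
                raise ValueError("mutant_bases must be given where mutant_fraction > 0")
            mut = spec.mutant_bases[i]
            if mut == wt:
                raise ValueError("mutant base must differ from the called base")
            channels[_BASE_INDEX[mut]] += f * spec.peak_height * shape
    if spec.noise_sd > 0:
        if rng is None:
            raise ValueError("an rng is required when noise_sd > 0")
        channels = np.maximum(channels + rng.normal(0.0, spec.noise_sd, channels.shape), 0.0)
    return TraceData(
        channels=channels,
        peak_positions=spec.positions.copy(),
        called_bases=spec.base_calls,
    )


# ---------------------------------------------------------------------------
# full screen count tables

def generate_screen_counts(
    design: ScreenDesign,
    effects,
    mu: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-guide start/end read counts for a whole pool.

    One row per guide (``guides_per_target`` rows per target gene followed by
    the controls), each drawn independently from the binomial read model: all
    guides at probability 1/k_p at the start; target guides at the
    ratio-shifted probability at the end; controls unchanged.

    Returns a DataFrame with columns gene, guide, category, s, reads_start,
    reads_end.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.size != design.n_targets:
        raise ValueError("one selection coefficient per target locus is required")
    n = design.total_reads
    p0 = read_probability(design, timepoint="start")
    p_end = np.array([
        read_probability(design, EditOutcome(mu=float(mu), s_mut=float(s)), "end")
        for s in effects
    ])
    g = design.guides_per_target
    gene_idx = np.repeat(np.arange(design.n_targets), g)
    target_start = rng.binomial(n, p0, size=design.n_targets * g)
    target_end = rng.binomial(n, np.repeat(p_end, g))
    ctrl_start = rng.binomial(n, p0, size=design.n_controls)
    ctrl_end = rng.binomial(n, p0, size=design.n_controls)
    frames = [
        pd.DataFrame({
            "gene": [f"gene{i:05d}" for i in gene_idx],
            "guide": [f"gene{i:05d}_g{j % g}" for j, i in enumerate(gene_idx)],
            "category": "target",
            "s": effects[gene_idx],
            "reads_start": target_start,
            "reads_end": target_end,
        }),
        pd.DataFrame({
            "gene": "control",
            "guide": [f"ctrl_{j:04d}" for j in range(design.n_controls)],
            "category": "control",
            "s": 0.0,
            "reads_start": ctrl_start,
            "reads_end": ctrl_end,
        }),
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# synthetic ABIF writer

def _abif_entry(name: bytes, number: int, etype: int, esize: int, num: int, data: bytes):
    size = len(data)
    return (name, number, etype, esize, num, size, data)


def write_trace_abif(trace: TraceData, path) -> None:
    """Write a minimal synthetic ABIF (.ab1) file for a :class:`TraceData`.

    Synthetic: emits only the directory entries the quantifier needs —
    processed channels DATA9-12 (16-bit, GATC filter-wheel order), FWO_1,
    base calls PBAS2 with placeholder qualities PCON2, and the peak index
    PLOC2.  Real instrument files carry many more tags; this writer exists so
    the binary parsing path can be exercised on generated data.
    """
    fwo = "GATC"
    channels = np.clip(np.rint(trace.channels), 0, 32767).astype(">i2")
    entries = []
    for k, base in enumerate(fwo):
        data = channels[_BASE_INDEX[base]].tobytes()
        entries.append(_abif_entry(b"DATA", 9 + k, 4, 2, trace.n_scans, data))
    entries.append(_abif_entry(b"FWO_", 1, 2, 1, 4, fwo.encode()))
    peaks = np.asarray(trace.peak_positions, dtype=">i2")
    entries.append(_abif_entry(b"PLOC", 2, 4, 2, len(peaks), peaks.tobytes()))
    entries.append(_abif_entry(
        b"PBAS", 2, 2, 1, len(trace.called_bases), trace.called_bases.encode()
    ))
    entries.append(_abif_entry(
        b"PCON", 2, 2, 1, len(trace.called_bases), bytes([40] * len(trace.called_bases))
    ))

    header_fmt = ">H4sI2H3I"
    header_size = 4 + struct.calcsize(header_fmt)  # magic + header struct
    blobs = []
    offsets = []
    offset = header_size
    for *_, size, data in entries:
        if size > 4:
            offsets.append(offset)
            blobs.append(data)
            offset += size
        else:
            offsets.append(None)
    dir_offset = offset

    with open(path, "wb") as fh:
        fh.write(b"ABIF")
        fh.write(struct.pack(
            header_fmt, 101, b"tdir", 1, 1023, 28, len(entries),
            28 * len(entries), dir_offset,
        ))
        for blob in blobs:
            fh.write(blob)
        for (name, number, etype, esize, num, size, data), off in zip(entries, offsets):
            if off is None:
                inline = data.ljust(4, b"\x00")
                fh.write(struct.pack(">4sI2HI", name, number, etype, esize, num))
                fh.write(struct.pack(">I", size))
                fh.write(inline)
                fh.write(struct.pack(">I", 0))
            else:
                fh.write(struct.pack(">4sI2H4I", name, number, etype, esize, num, size, off, 0))
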