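"""Semi-quantitative allele-frequency estimation from Sanger chromatograms.

When a mixed cell population is Sanger-sequenced directly, the chromatogram
at an edited position shows superimposed peaks for the wild-type and mutant
bases whose relative intensity reflects the allele mixture.  The estimator
here integrates each dye channel over a small window around the called peak
position, normalizes by the total area in the window, and reports the mutant
base's share — a cheap, semi-quantitative readout of mutagenesis rate that a
titration of known mixtures can calibrate.

Input traces come either from ABIF (.ab1) capillary-sequencer files (parsed
with Biopython) or from a plain-text dialect (see :func:`read_trace`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "BASES",
    "TraceData",
    "AlleleRatioEstimate",
    "CalibrationSummary",
    "read_trace",
    "window_areas",
    "normalized_intensities",
    "mutant_ratio",
    "titration_calibration",
]


@dataclass
class TraceData:
    """Four-channel chromatogram with called peak positions.

    ``channels`` is a (4, n_scans) array in fixed base order A, C, G, T
    (regardless of the instrument's filter-wheel order); ``peak_positions``
    are the scan indices of the called bases, strictly increasing.
    """

    channels: np.ndarray
    peak_positions: np.ndarray
    called_bases: str

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.peak_positions = np.asarray(self.peak_positions, dtype=int)
        if self.channels.ndim != 2 or self.channels.shape[0] != 4:
            raise ValueError("channels must be a (4, n_scans) array")
        if len(self.peak_positions) != len(self.called_bases):
            raise ValueError("one called base per peak position is required")
        if np.any(np.diff(self.peak_positions) <= 0):
            raise ValueError("peak positions must be strictly increasing")
        if len(self.peak_positions) and (
            self.peak_positions[0] < 0 or self.peak_positions[-1] >= self.n_scans
        ):
            raise ValueError("peak positions fall outside the scan range")

    @property
    def n_scans(self) -> int:
        return self.channels.shape[1]


@dataclass(frozen=True)
class AlleleRatioEstimate:
    """Normalized channel fractions at one position plus the mutant share."""

    position: int
    per_base_fraction: tuple
    mutant_fraction: float


@dataclass(frozen=True)
class CalibrationSummary:
    """Least-squares calibration of estimated vs true mixture fractions."""

    slope: float
    intercept: float
    r_value: float
    max_deviation: float
    monotonic: bool
    underestimates: bool


# ---------------------------------------------------------------------------
# reading

_TEXT_MAGIC = "#TRACE"


def _read_trace_text(lines) -> TraceData:
    rows, peaks, bases = [], [], []
    section = "channels"
    header_seen = False
    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        if line.startswith(_TEXT_MAGIC):
            header_seen = True
            continue
        if line.startswith("#CHANNELS"):
            section = "channels"
            continue
        if line.startswith("#PEAKS"):
            section = "peaks"
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if section == "channels":
            if len(fields) != 4:
                raise ValueError("channel rows must have four tab-separated intensities")
            rows.append([float(v) for v in fields])
        else:
            if len(fields) != 2:
                raise ValueError("peak rows must be '<scan index>\\t<base>'")
            peaks.append(int(fields[0]))
            if fields[1] not in _BASE_INDEX:
                raise ValueError(f"unknown base {fields[1]!r}")
            bases.append(fields[1])
    if not header_seen:
        raise ValueError("not a text trace: missing #TRACE header")
    if not rows:
        raise ValueError("text trace has no intensity rows")
    return TraceData(
        channels=np.array(rows, dtype=float).T,
        peak_positions=np.array(peaks, dtype=int),
        called_bases="".join(bases),
    )


def _read_trace_abif(path) -> TraceData:
    from Bio import SeqIO

    record = SeqIO.read(str(path), "abi")
    raw = record.annotations["abif_raw"]
    fwo = raw.get("FWO_1", b"GATC")
    if isinstance(fwo, bytes):
        fwo = fwo.decode()
    channels = np.zeros((4, len(raw["DATA9"])), dtype=float)
    for k, base in enumerate(fwo):
        channels[_BASE_INDEX[base]] = np.asarray(raw[f"DATA{9 + k}"], dtype=float)
    peaks = raw.get("PLOC2", raw.get("PLOC1"))
    if peaks is None:
        raise ValueError("ABIF file has no base-call position index (PLOC)")
    called = raw.get("PBAS2", raw.get("PBAS1", b""))
    if isinstance(called, bytes):
        called = called.decode()
    return TraceData(
        channels=channels,
        peak_positions=np.asarray(peaks, dtype=int),
        called_bases=called,
    )


def read_trace(source) -> TraceData:
    """Read a chromatogram from an ABIF (.ab1) file or the plain-text dialect.

    The text dialect is::

        #TRACE	1
        #CHANNELS	A	C	G	T
        <one row of four tab-separated intensities per scan>
        #PEAKS
        <scan index>	<called base>

    ABIF files are detected by their 4-byte magic; the four processed-data
    channels (DATA9-12) are mapped to A/C/G/T order via the instrument's
    filter-wheel order tag, and peak positions come from the base-call index.
    """
    if hasattr(source, "read"):
        return _read_trace_text(source)
    path = Path(source)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic == b"ABIF":
        return _read_trace_abif(path)
    with open(path) as fh:
        return _read_trace_text(fh)


def write_trace_text(trace: TraceData, destination) -> None:
    """Write a :class:`TraceData` in the plain-text trace dialect."""
    buf = io.StringIO()
    buf.write(f"{_TEXT_MAGIC}\t1\n")
    buf.write("#CHANNELS\tA\tC\tG\tT\n")
    for row in trace.channels.T:
        buf.write("\t".join(format(v, ".10g") for v in row) + "\n")
    buf.write("#PEAKS\n")
    for pos, base in zip(trace.peak_positions, trace.called_bases):
        buf.write(f"{int(pos)}\t{base}\n")
    text = buf.getvalue()
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


# ---------------------------------------------------------------------------
# quantification

def window_areas(trace: TraceData, position: int, half_width: int = 4) -> np.ndarray:
    """Per-channel area under the curve in a window around a peak position.

    Integrates each channel over ``[position - half_width, position +
    half_width]`` by the trapezoidal rule, after subtracting the channel's
    within-window minimum (a simple per-window baseline, floored at zero).
    """
    lo, hi = position - half_width, position + half_width
    if lo < 0 or hi >= trace.n_scans:
        raise ValueError(
            f"window [{lo}, {hi}] falls outside the scan range [0, {trace.n_scans - 1}]"
        )
    window = trace.channels[:, lo : hi + 1]
    baseline = window.min(axis=1, keepdims=True)
    corrected = np.maximum(window - baseline, 0.0)
    return np.trapezoid(corrected, axis=1)


def normalized_intensities(trace: TraceData, positions, half_width: int = 4) -> np.ndarray:
    """Per-base intensity fractions at each position (rows sum to 1).

    Each row holds the four windowed channel areas divided by their total —
    the quantity plotted as a per-position base-composition heat map.  A
    position with zero total area yields a row of NaN.
    """
    positions = np.atleast_1d(np.asarray(positions, dtype=int))
    out = np.empty((len(positions), 4))
    for i, pos in enumerate(positions):
        areas = window_areas(trace, int(pos), half_width)
        total = areas.sum()
        out[i] = areas / total if total > 0 else np.nan
    return out


def mutant_ratio(
    trace: TraceData,
    position: int,
    wt_base: str,
    mutant_base: str,
    half_width: int = 4,
) -> AlleleRatioEstimate:
    """Mutant-allele fraction at a position from the wt/mutant channel areas.

    The mutant fraction is the mutant base's windowed area divided by the
    summed areas of the wild-type and mutant bases only, so co-migrating
    signal from the other two channels does not dilute the ratio.
    """
    if wt_base == mutant_base:
        raise ValueError("wild-type and mutant bases must differ")
    for b in (wt_base, mutant_base):
        if b not in _BASE_INDEX:
            raise ValueError(f"unknown base {b!r}")
    fractions = normalized_intensities(trace, [position], half_width)[0]
    areas = window_areas(trace, position, half_width)
    pair = areas[_BASE_INDEX[wt_base]] + areas[_BASE_INDEX[mutant_base]]
    if pair <= 0:
        raise ValueError("both specified bases have zero area in the window")
    return AlleleRatioEstimate(
        position=int(position),
        per_base_fraction=tuple(fractions),
        mutant_fraction=float(areas[_BASE_INDEX[mutant_base]] / pair),
    )


def titration_calibration(pairs) -> CalibrationSummary:
    """Calibrate estimated against true mixture fractions.

    ``pairs`` is a sequence of ``(true_fraction, estimated_fraction)``
    tuples, at least three, spanning distinct true fractions.  Fits an
    ordinary least-squares line (estimated ~ true) and flags systematic
    underestimation (slope < 1 or negative intercept) and loss of
    monotonicity.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("at least three (true, estimated) pairs are required")
    true, est = arr[:, 0], arr[:, 1]
    if np.allclose(true, true[0]):
        raise ValueError("true fractions are degenerate (all identical)")
    order = np.argsort(true)
    fit = stats.linregress(true, est)
    return CalibrationSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_value=float(fit.rvalue),
        max_deviation=float(np.max(np.abs(est - true))),
        monotonic=bool(np.all(np.diff(est[order]) >= 0)),
        underestimates=bool(fit.slope < 1.0 or fit.intercept < 0.0),
    )
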