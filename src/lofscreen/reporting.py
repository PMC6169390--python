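"""Seeded orchestration of the simulator with tabular and graphical outputs.

Two canned analyses mirror the figures a screen designer wants:

* :func:`run_power_surface` — the detection-power heat map over a
  (mu, s_mut) grid at a configurable resolution (desk-scale 20x20 x 1,000
  iterations by default; the full 100x100 x 10,000 sweep is just a larger
  configuration).
* :func:`run_recovery_curves` — genome-wide gene-recovery curves: the
  fraction of a gene catalogue detected as a function of mutagenesis rate,
  for several per-gene success-rate thresholds, optionally for a diploid
  pool and/or doubled sequencing depth.

Every run writes CSV tables (with ``#`` header comments recording the full
parameterization), a matplotlib figure, and a JSON manifest with a SHA-256
checksum per output file, so identical seeds are verifiably identical runs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import __version__
from .config import RunConfig
from .screen_simulator import PowerGrid, RecoveryCurve, gene_recovery_curve, power_grid
from .synthetic_data import FitnessEffectDistribution, sample_effects

__all__ = ["RunManifest", "run_power_surface", "run_recovery_curves"]

logger = logging.getLogger("lofscreen")


@dataclass
class RunManifest:
    """Provenance record for one reporting run."""

    config: dict
    seed: int
    version: str = __version__
    created: str = field(default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds"))
    outputs: dict = field(default_factory=dict)

    def register(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[Path(path).name] = digest

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def _comment_header(config: RunConfig, extra: dict) -> str:
    items = {**config.to_dict(), **extra}
    lines = [f"# {k} = {v}" for k, v in items.items()]
    return "\n".join(lines) + "\n"


def _write_csv(path: Path, header: str, frame) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False)


def run_power_surface(
    config: RunConfig,
    out_dir,
    mu_points: int = 20,
    s_points: int = 20,
    plot: bool = True,
) -> PowerGrid:
    """Compute and save the detection-power surface for a screen design."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mu_values = np.linspace(0.0, 1.0, mu_points)
    s_values = np.linspace(0.0, 1.0, s_points)
    logger.info("power surface: %dx%d grid, %d iterations", s_points, mu_points, config.iterations)
    grid = power_grid(
        config.design(), mu_values, s_values,
        iterations=config.iterations, alpha=config.alpha, seed=config.seed,
    )
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    extra = {"mu_points": mu_points, "s_points": s_points}
    csv_path = out_dir / "power_grid.csv"
    _write_csv(csv_path, _comment_header(config, extra), grid.to_dataframe())
    manifest.register(csv_path)
    if plot:
        fig, ax = plt.subplots(figsize=(6, 5))
        mesh = ax.pcolormesh(grid.mu_values, grid.s_values, grid.power,
                             vmin=0, vmax=1, shading="nearest", cmap="viridis")
        fig.colorbar(mesh, ax=ax, label=f"detection rate (P < {config.alpha})")
        ax.set_xlabel("mutagenesis rate $\\mu$")
        ax.set_ylabel("selection coefficient $s$")
        ax.set_title(f"LOF detection power, {config.generations} generations, d={config.depth}")
        png_path = out_dir / "power_grid.png"
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
        manifest.register(png_path)
    manifest.write(out_dir / "power_grid_manifest.json")
    return grid


def run_recovery_curves(
    config: RunConfig,
    out_dir,
    effects=None,
    n_genes: int = 200,
    mu_points: int = 21,
    thresholds=(0.5, 0.8, 0.95),
    plot: bool = True,
    label: str = "recovery",
) -> RecoveryCurve:
    """Compute and save gene-recovery curves for a gene-effect catalogue.

    ``effects`` may be an explicit array of selection coefficients; when
    omitted, ``n_genes`` effects are drawn from the default
    :class:`FitnessEffectDistribution` using the run seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    effects_ss, curve_ss = ss.spawn(2)
    if effects is None:
        effects = sample_effects(
            FitnessEffectDistribution(), n_genes, np.random.default_rng(effects_ss)
        )
    effects = np.asarray(effects, dtype=float)
    mu_values = np.linspace(0.0, 1.0, mu_points)
    logger.info("recovery curves: %d genes, %d mu points, %d iterations",
                effects.size, mu_points, config.iterations)
    curve = gene_recovery_curve(
        config.design(), effects, mu_values, thresholds=thresholds,
        iterations=config.iterations, alpha=config.alpha, seed=curve_ss,
    )
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    extra = {"n_genes": effects.size, "mu_points": mu_points,
             "thresholds": list(thresholds)}
    csv_path = out_dir / f"{label}.csv"
    _write_csv(csv_path, _comment_header(config, extra), curve.to_dataframe())
    manifest.register(csv_path)
    if plot:
        fig, ax = plt.subplots(figsize=(6, 4.5))
        for i, thr in enumerate(curve.thresholds):
            ax.plot(curve.mu_values, curve.detected_fraction[i],
                    label=f"success rate ≥ {thr:g}")
        ax.set_xlabel("mutagenesis rate $\\mu$")
        ax.set_ylabel(f"fraction of genes detected (P < {config.alpha})")
        ax.set_ylim(0, 1.02)
        ax.legend(frameon=False)
        ploidy_txt = "diploid" if config.ploidy == 2 else "haploid"
        ax.set_title(f"Gene recovery, {ploidy_txt}, d={config.depth}")
        png_path = out_dir / f"{label}.png"
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
        manifest.register(png_path)
    manifest.write(out_dir / f"{label}_manifest.json")
    return curve
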