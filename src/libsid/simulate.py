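"""Synthetic LIBS dataset generator.

Emulates the structure of a coffee-variety LIBS campaign so every
downstream stage is testable without the (undeposited) real spectra:

* geometry — ``n_varieties x samples_per_variety x shots_per_sample`` rows
  on the 246.53-880.26 nm grid;
* emission lines — Lorentzian (Stark-broadened; Gaussian by config)
  profiles at known line wavelengths, with per-variety line intensities set
  by a species concentration matrix times per-line relative strengths;
* continuum — a low sloped baseline;
* shot-to-shot variation — a unit-mean lognormal multiplicative gain
  (lognormal keeps intensities positive) plus additive Gaussian detector
  noise, which may drive background samples negative exactly as in real
  raw spectra;
* outliers — a deterministic count of shots per sample whose *line
  emission* is multiplied by an aberrant factor, i.e. an anomalous
  line-to-continuum ratio.  A whole-spectrum gain would be cancelled by the
  later total-area normalization; scaling only the emission keeps the
  planted outliers visible to the carbon-line RSD filter that runs on
  normalized spectra.

A clean shot for variety :math:`v` is

.. math::

   I(\\lambda) = g \\Big( f \\sum_j c_{v, s(j)} \\, r_j \\,
   L_j(\\lambda) + b(\\lambda) \\Big) + \\varepsilon(\\lambda)

with gain :math:`g`, outlier factor :math:`f` (1 for normal shots),
concentrations :math:`c`, relative strengths :math:`r`, unit-height
profiles :math:`L_j`, baseline :math:`b`, and noise :math:`\\varepsilon`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import EmissionLine, GridSpec, ShotMeta, SpectrumSet, builtin_line_table

__all__ = ["SimConfig", "line_profile", "simulate_shot", "simulate_dataset", "species_order"]


def species_order(lines: Sequence[EmissionLine]) -> list[str]:
    """Distinct species labels in order of first appearance in ``lines``."""
    seen: list[str] = []
    for line in lines:
        if line.species not in seen:
            seen.append(line.species)
    return seen


@dataclass
class SimConfig:
    """Generator configuration; defaults reproduce the study geometry.

    ``concentration_matrix`` is ``n_varieties x n_species`` (species ordered
    as in :func:`species_order`); ``None`` means all ones (no between-variety
    differences).  The paper-like preset in :mod:`libsid.presets` supplies a
    matrix with three orthogonal variety contrasts.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    n_varieties: int = 4
    samples_per_variety: int = 24
    shots_per_sample: int = 16
    lines: list[EmissionLine] = field(default_factory=builtin_line_table)
    concentration_matrix: np.ndarray | None = None
    line_width_nm: float = 0.15
    line_shape: str = "lorentzian"
    baseline_level: float = 0.02
    baseline_slope: float = 0.0
    shot_gain_cv: float = 0.10
    noise_sd: float = 0.0
    outlier_fraction: float = 0.10
    outlier_gain_factor: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if not (1 <= self.n_varieties <= 4):
            raise ValueError("n_varieties must be in 1..4 (category coding)")
        if self.samples_per_variety < 1 or self.shots_per_sample < 1:
            raise ValueError("samples_per_variety and shots_per_sample must be >= 1")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.line_width_nm <= 0:
            raise ValueError("line_width_nm must be > 0")
        if self.line_shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown line_shape {self.line_shape!r}")
        if self.baseline_level < 0 or self.noise_sd < 0 or self.shot_gain_cv < 0:
            raise ValueError("baseline_level, noise_sd, shot_gain_cv must be >= 0")
        if self.outlier_gain_factor <= 0:
            raise ValueError("outlier_gain_factor must be > 0")
        C = self.concentrations()
        n_species = len(species_order(self.lines))
        if C.shape != (self.n_varieties, n_species):
            raise ValueError(
                f"concentration_matrix shape {C.shape} != "
                f"({self.n_varieties}, {n_species})"
            )
        if np.any(C <= 0):
            raise ValueError("concentration_matrix must be strictly positive")

    def concentrations(self) -> np.ndarray:
        n_species = len(species_order(self.lines))
        if self.concentration_matrix is None:
            return np.ones((self.n_varieties, n_species))
        return np.asarray(self.concentration_matrix, dtype=float)

    @property
    def n_shots(self) -> int:
        return self.n_varieties * self.samples_per_variety * self.shots_per_sample

    def outliers_per_sample(self) -> int:
        # deterministic count so downstream assertions are exact
        return int(np.floor(self.outlier_fraction * self.shots_per_sample + 0.5))


def line_profile(
    center_nm: float,
    fwhm_nm: float,
    grid: np.ndarray,
    shape: str = "lorentzian",
) -> np.ndarray:
    """Unit-peak-height line profile evaluated on ``grid``.

    Lorentzian ``1 / (1 + ((x - c) / (fwhm/2))^2)`` by default; Gaussian
    with the same FWHM when ``shape == "gaussian"``.  The analytic maximum
    (1.0) lies at ``center_nm``, so on the grid the maximum sits at the
    nearest grid point.
    """
    grid = np.asarray(grid, dtype=float)
    if fwhm_nm <= 0:
        raise ValueError("fwhm_nm must be > 0")
    if not (grid[0] <= center_nm <= grid[-1]):
        raise ValueError(
            f"line center {center_nm} nm outside grid span "
            f"[{grid[0]}, {grid[-1]}] nm"
        )
    d = grid - center_nm
    if shape == "lorentzian":
        gamma = fwhm_nm / 2.0
        return 1.0 / (1.0 + (d / gamma) ** 2)
    if shape == "gaussian":
        return np.exp(-4.0 * np.log(2.0) * (d / fwhm_nm) ** 2)
    raise ValueError(f"unknown line shape {shape!r}")


def _emission_matrix(config: SimConfig, grid: np.ndarray) -> np.ndarray:
    """Per-variety clean emission spectra (n_varieties x n_points)."""
    order = species_order(config.lines)
    sp_index = {s: i for i, s in enumerate(order)}
    C = config.concentrations()
    E = np.zeros((config.n_varieties, grid.size))
    for line in config.lines:
        prof = line_profile(line.wavelength_nm, config.line_width_nm, grid, config.line_shape)
        weights = C[:, sp_index[line.species]] * line.relative_strength
        E += weights[:, None] * prof[None, :]
    return E


def _baseline(config: SimConfig, grid: np.ndarray) -> np.ndarray:
    return config.baseline_level + config.baseline_slope * (grid - grid[0])


def _gains(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Unit-mean lognormal gains with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def simulate_shot(
    variety: int,
    config: SimConfig,
    rng: np.random.Generator,
    is_outlier: bool = False,
) -> np.ndarray:
    """One simulated spectrum for ``variety`` (1-based)."""
    config.validate()
    if not 1 <= variety <= config.n_varieties:
        raise ValueError(f"variety {variety} not in 1..{config.n_varieties}")
    grid = config.grid.make()
    emission = _emission_matrix(config, grid)[variety - 1]
    baseline = _baseline(config, grid)
    gain = _gains(rng, 1, config.shot_gain_cv)[0]
    factor = config.outlier_gain_factor if is_outlier else 1.0
    spectrum = gain * (factor * emission + baseline)
    if config.noise_sd > 0:
        spectrum = spectrum + rng.normal(0.0, config.noise_sd, grid.size)
    return spectrum


def simulate_dataset(config: SimConfig) -> SpectrumSet:
    """Full synthetic campaign, reproducible from ``config.seed``.

    Rows are ordered variety -> sample -> site.  Each sample receives
    exactly ``round(outlier_fraction * shots_per_sample)`` outlier shots at
    randomly chosen sites; the ground truth is recorded in the metadata.
    """
    config.validate()
    grid = config.grid.make()
    E = _emission_matrix(config, grid)
    B = _baseline(config, grid)
    rng = np.random.default_rng(config.seed)
    n_out = config.outliers_per_sample()
    S, T = config.samples_per_variety, config.shots_per_sample

    blocks: list[np.ndarray] = []
    meta: list[ShotMeta] = []
    for v in range(1, config.n_varieties + 1):
        n_rows = S * T
        gains = _gains(rng, n_rows, config.shot_gain_cv)
        flags = np.zeros(n_rows, dtype=bool)
        for s in range(S):
            sites = rng.choice(T, size=n_out, replace=False) if n_out else []
            for t in sites:
                flags[s * T + t] = True
        factors = np.where(flags, config.outlier_gain_factor, 1.0)
        block = (gains * factors)[:, None] * E[v - 1][None, :] + gains[:, None] * B[None, :]
        if config.noise_sd > 0:
            block += rng.normal(0.0, config.noise_sd, block.shape)
        blocks.append(block)
        for s in range(S):
            for t in range(T):
                meta.append(
                    ShotMeta(
                        variety=v,
                        sample_id=f"V{v}S{s + 1:02d}",
                        site_id=f"T{t + 1:02d}",
                        is_outlier_truth=bool(flags[s * T + t]),
                    )
                )
    return SpectrumSet(grid=grid, intensities=np.vstack(blocks), meta=meta)
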