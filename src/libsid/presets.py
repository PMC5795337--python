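"""Study-condition presets for the synthetic LIBS generator and pipeline.

The *paper-like* preset fixes the synthetic dataset to the structure of
the motivating coffee-variety study: 4 varieties x 24 samples x 16 site
spectra on the 246.53-880.26 nm grid (20,937 points), all twenty built-in
emission lines planted, 10% shot-gain CV, 10% planted outliers with a 3x
line-emission factor, and a concentration matrix giving each of the twelve
species a between-variety contrast.

The contrasts use three orthogonal patterns over the four varieties
(species contrast vs. the rest; two finer origin contrasts), so the
between-class signal is exactly three-dimensional and lands in the first
three principal components.  Contrast amplitudes are larger for the weak
trace-element lines (Fe, Al, Na, N) than for the strong matrix lines
(Ca, K, Mg): trace composition varies more between cultivars than the
organic matrix, and this keeps every line's loading peak well above the
selection threshold.  Line relative strengths span roughly 1-12 to mimic
the large intensity spread between strong ionic resonance lines and weak
neutral lines in real coffee spectra.

The *mini* preset is a scaled-down variant (4,096-point grid, 3 samples x
8 shots per variety, reduced tuning grids) for fast end-to-end and CLI
checks; it is not intended to reproduce study numbers.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import models as M
from .core import GridSpec, builtin_line_table
from .outliers import OutlierConfig
from .pipeline import PipelineConfig
from .preprocess import WTConfig
from .select import SelectionConfig
from .simulate import SimConfig, species_order

__all__ = [
    "paper_like_sim_config",
    "paper_like_pipeline_config",
    "mini_sim_config",
    "mini_pipeline_config",
]

# per-line relative emission strengths (arbitrary units, peak height scale)
_LINE_STRENGTH: dict[float, float] = {
    247.87: 5.0,   # C I
    279.56: 8.0,   # Mg II
    280.28: 6.0,   # Mg II
    285.22: 4.0,   # Mg I
    315.93: 5.0,   # Ca II
    317.97: 5.5,   # Ca II
    358.57: 2.4,   # Al II
    388.32: 5.0,   # CN
    393.39: 12.0,  # Ca II
    396.85: 9.0,   # Ca II
    422.68: 3.0,   # Al II
    588.99: 4.0,   # Na I
    656.38: 6.0,   # H
    746.92: 3.2,   # N I
    766.54: 10.0,  # K I
    769.98: 6.0,   # K I
    777.33: 5.0,   # O I
    821.69: 2.0,   # N I
    844.75: 1.5,   # Fe I
    868.10: 1.25,  # Fe I
}

# which of the three variety-contrast patterns each species follows,
# and the peak-to-peak relative amplitude of its concentration contrast
_SPECIES_PATTERN: dict[str, int] = {
    "C I": 0, "Mg I": 0, "Mg II": 0, "Ca II": 0, "K I": 0, "CN": 0, "H": 0, "O I": 0,
    "Al II": 1, "Na I": 1,
    "N I": 2, "Fe I": 2,
}
_SPECIES_CONTRAST: dict[str, float] = {
    "C I": 0.24, "Mg I": 0.25, "Mg II": 0.25, "Ca II": 0.20,
    "K I": 0.20, "CN": 0.28, "H": 0.20, "O I": 0.26,
    "Al II": 0.50, "Na I": 0.45,
    "N I": 0.50, "Fe I": 0.80,
}

# orthogonal contrasts over the four variety categories
_PATTERNS = np.array(
    [
        [0.5, 0.5, -0.5, -0.5],   # species contrast (Arabica vs Robusta)
        [0.5, -0.5, 0.5, -0.5],   # origin contrast A
        [0.5, -0.5, -0.5, 0.5],   # origin contrast B
    ]
)


def _paper_lines():
    return [
        replace(line, relative_strength=_LINE_STRENGTH[line.wavelength_nm])
        for line in builtin_line_table()
    ]


def _paper_concentrations(lines) -> np.ndarray:
    order = species_order(lines)
    C = np.ones((4, len(order)))
    for j, sp in enumerate(order):
        pattern = _PATTERNS[_SPECIES_PATTERN[sp]]
        C[:, j] = 1.0 + _SPECIES_CONTRAST[sp] * pattern
    return C


def paper_like_sim_config(seed: int = 0) -> SimConfig:
    """Full-scale synthetic campaign emulating the study conditions."""
    lines = _paper_lines()
    return SimConfig(
        grid=GridSpec(),
        n_varieties=4,
        samples_per_variety=24,
        shots_per_sample=16,
        lines=lines,
        concentration_matrix=_paper_concentrations(lines),
        line_width_nm=0.15,
        line_shape="lorentzian",
        baseline_level=0.02,
        baseline_slope=-1.5e-5,
        shot_gain_cv=0.10,
        noise_sd=0.05,
        outlier_fraction=0.10,
        outlier_gain_factor=3.0,
        seed=seed,
    )


def paper_like_pipeline_config(seed: int = 0) -> PipelineConfig:
    """Pipeline preset: db5/10 denoising, per-sample 75% RSD filter, 2:1
    split, 3-PC selection, and all three classifiers.

    The SVM preset grid uses integer powers of two over [2^-8, 2^8] (step
    1.0 in log2) — on the clean synthetic classes a finer grid only adds
    runtime; the :class:`~libsid.models.SVMConfig` default keeps the finer
    0.2 step for real-data use.
    """
    return PipelineConfig(
        sim=paper_like_sim_config(seed),
        wt=WTConfig(),
        outlier=OutlierConfig(),
        split=M.SplitConfig(),
        selection=SelectionConfig(),
        models={
            "plsda": M.PLSDAConfig(),
            "rbfnn": M.RBFNNConfig(),
            "svm": M.SVMConfig(grid_step_log2=1.0),
        },
        feature_mode="selected",
        seed=seed,
    )


def mini_sim_config(seed: int = 0) -> SimConfig:
    """Small, fast variant: coarse grid, 3 samples x 8 shots per variety."""
    lines = _paper_lines()
    return SimConfig(
        grid=GridSpec(246.53, 880.26, 4096),
        n_varieties=4,
        samples_per_variety=3,
        shots_per_sample=8,
        lines=lines,
        concentration_matrix=_paper_concentrations(lines),
        line_width_nm=0.5,  # grid step is ~0.15 nm here; keep lines resolved
        baseline_level=0.02,
        baseline_slope=-1.5e-5,
        shot_gain_cv=0.10,
        noise_sd=0.05,
        outlier_fraction=0.125,
        outlier_gain_factor=3.0,
        seed=seed,
    )


def mini_pipeline_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(
        sim=mini_sim_config(seed),
        wt=WTConfig(),
        outlier=OutlierConfig(),
        split=M.SplitConfig(),
        selection=SelectionConfig(dedupe_window_nm=0.6),
        models={
            "plsda": M.PLSDAConfig(max_lv=8),
            "rbfnn": M.RBFNNConfig(spread_grid=(0.1, 0.3, 1.0, 3.0, 10.0), cv_folds=3),
            "svm": M.SVMConfig(grid_step_log2=4.0, cv_folds=3),
        },
        feature_mode="selected",
        seed=seed,
    )
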