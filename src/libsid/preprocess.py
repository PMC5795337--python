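"""Spectral preprocessing: baseline correction, wavelet denoising, area normalization.

The stage order matches standard LIBS practice for this pipeline: clip the
noise-induced negative values, denoise with a discrete wavelet transform
(Daubechies-5, level 10 by default), then normalize each spectrum to unit
total area to suppress matrix effects and shot-energy variation.

Wavelet thresholding follows the Donoho universal rule: detail
coefficients at every level are soft-thresholded at
``threshold_scale * sigma_level * sqrt(2 ln N)`` where ``sigma_level`` is
the median-absolute-deviation noise estimate of that level's coefficients
and ``N`` the spectrum length; approximation coefficients are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .core import SpectrumSet

__all__ = [
    "WTConfig",
    "baseline_correct",
    "wt_denoise",
    "area_normalize",
    "preprocess_set",
]


@dataclass(frozen=True)
class WTConfig:
    """Wavelet denoising configuration (db5, level 10 by default)."""

    basis: str = "db5"
    level: int = 10
    threshold_rule: str = "soft"
    threshold_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("decomposition level must be >= 1")
        if self.threshold_rule not in ("soft", "hard"):
            raise ValueError(f"threshold_rule must be 'soft' or 'hard', got {self.threshold_rule!r}")
        if self.threshold_scale < 0:
            raise ValueError("threshold_scale must be >= 0")
        try:
            wavelet = pywt.Wavelet(self.basis)
        except ValueError as exc:
            raise ValueError(f"unknown wavelet basis {self.basis!r}") from exc
        if not wavelet.orthogonal:
            raise ValueError(f"wavelet basis {self.basis!r} is not orthogonal")


def baseline_correct(spectrum: np.ndarray, method: str = "clip") -> np.ndarray:
    """Eliminate negative values.

    ``"clip"`` (default) sets negatives to zero, preserving peak heights;
    ``"min_subtract"`` shifts the whole spectrum by its minimum instead.
    Nonnegative input is returned unchanged (same values, new array).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if method == "clip":
        return np.maximum(spectrum, 0.0)
    if method == "min_subtract":
        lo = spectrum.min(axis=-1, keepdims=True)
        return spectrum - np.minimum(lo, 0.0)
    raise ValueError(f"unknown baseline method {method!r}")


def _denoise_block(X: np.ndarray, config: WTConfig) -> np.ndarray:
    """Denoise each row of a 2-D block; vectorized over rows."""
    n = X.shape[-1]
    if n < 2**config.level:
        raise ValueError(
            f"spectrum length {n} < 2^{config.level}; lower the decomposition level"
        )
    coeffs = pywt.wavedec(X, config.basis, level=config.level, mode="symmetric", axis=-1)
    out = [coeffs[0]]  # approximation untouched
    factor = np.sqrt(2.0 * np.log(n))
    for detail in coeffs[1:]:
        sigma = np.median(np.abs(detail), axis=-1, keepdims=True) / 0.6745
        thr = config.threshold_scale * sigma * factor
        if config.threshold_rule == "soft":
            detail = np.sign(detail) * np.maximum(np.abs(detail) - thr, 0.0)
        else:
            detail = np.where(np.abs(detail) >= thr, detail, 0.0)
        out.append(detail)
    rec = pywt.waverec(out, config.basis, mode="symmetric", axis=-1)
    return rec[..., :n]


def wt_denoise(spectrum: np.ndarray, config: WTConfig | None = None) -> np.ndarray:
    """Wavelet-threshold denoise one spectrum (length preserved)."""
    config = config or WTConfig()
    spectrum = np.asarray(spectrum, dtype=float)
    return _denoise_block(spectrum[None, :], config)[0]


def area_normalize(spectrum: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Scale the spectrum so its trapezoidal area over ``grid`` equals 1."""
    spectrum = np.asarray(spectrum, dtype=float)
    area = np.trapezoid(spectrum, np.asarray(grid, dtype=float))
    if not area > 0:
        raise ValueError(f"total area {area} is not positive; cannot normalize")
    return spectrum / area


def preprocess_set(
    sset: SpectrumSet,
    wt_config: WTConfig | None = None,
    baseline_method: str = "clip",
) -> SpectrumSet:
    """Apply baseline -> denoise -> normalize to every row; metadata unchanged.

    Rows are processed independently, so processing commutes with row
    permutation.  The operation is not idempotent: thresholds re-estimated
    on a denoised spectrum keep shrinking detail coefficients.
    """
    config = wt_config or WTConfig()
    X = baseline_correct(sset.intensities, method=baseline_method)
    X = _denoise_block(X, config)
    areas = np.trapezoid(X, sset.grid, axis=-1)
    bad = np.flatnonzero(~(areas > 0))
    if bad.size:
        raise ValueError(
            f"row {bad[0]}: total area {areas[bad[0]]} is not positive after denoising"
        )
    X = X / areas[:, None]
    return sset.with_intensities(X)
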