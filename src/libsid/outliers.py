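"""Resampling outlier filter on the carbon-line intensity.

Aberrant shots are detected per sample from the shot-to-shot stability of
the C I 247.86 nm emission: among all (or 100,000 randomly drawn) subsets
holding ``keep_fraction`` of a sample's shots, the subset with the minimum
relative standard deviation (RSD) of the carbon-line intensity is kept and
the complement discarded.  With 16 shots per sample and a 75% keep rule
there are only C(16,12) = 1820 candidate subsets, so exhaustive
enumeration is exact and cheaper than the randomized search; ``mode="auto"``
(default) picks enumeration whenever feasible and falls back to the seeded
random search otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .core import SpectrumSet

__all__ = [
    "OutlierConfig",
    "reference_line_intensity",
    "rsd",
    "exhaustive_min_rsd_subset",
    "select_min_rsd_subset",
    "remove_outliers",
]

_EXHAUSTIVE_GUARD = 10**6  # hard cap on enumerable subsets
_AUTO_LIMIT = 10**5  # auto mode prefers enumeration up to this many subsets


@dataclass(frozen=True)
class OutlierConfig:
    reference_line_nm: float = 247.86
    window_nm: float = 0.2
    keep_fraction: float = 0.75
    n_iterations: int = 100_000
    group_by: str = "sample"
    mode: str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.group_by not in ("sample", "variety"):
            raise ValueError("group_by must be 'sample' or 'variety'")
        if self.mode not in ("random", "exhaustive", "auto"):
            raise ValueError("mode must be 'random', 'exhaustive' or 'auto'")
        if self.window_nm <= 0:
            raise ValueError("window_nm must be > 0")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def reference_line_intensity(
    spectrum: np.ndarray,
    grid: np.ndarray,
    line_nm: float = 247.86,
    window_nm: float = 0.2,
) -> float:
    """Maximum intensity within ``line_nm +- window_nm`` (robust to grid offsets)."""
    grid = np.asarray(grid, dtype=float)
    mask = np.abs(grid - line_nm) <= window_nm
    if not mask.any():
        raise ValueError(
            f"window {line_nm} +- {window_nm} nm contains no grid points"
        )
    return float(np.asarray(spectrum, dtype=float)[..., mask].max())


def rsd(values: np.ndarray) -> float:
    """Relative standard deviation in percent: 100 * sd(n-1) / mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("RSD needs at least two values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def _subset_rsds(values: np.ndarray, subsets: np.ndarray) -> np.ndarray:
    """RSD of ``values[subset]`` for every row of ``subsets`` (vectorized)."""
    V = values[subsets]
    means = V.mean(axis=1)
    sds = V.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * sds / means
    out[~np.isfinite(out)] = np.inf
    return out


def exhaustive_min_rsd_subset(values: np.ndarray, keep_fraction: float) -> np.ndarray:
    """Exact minimum-RSD subset of size ``round(keep_fraction * n)``.

    Ties resolve to the lexicographically smallest index set (enumeration
    order).  Guarded against combinatorial blow-up.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    k = _round_half_up(keep_fraction * n)
    if k < 2:
        raise ValueError(f"subset size {k} too small for an RSD (need >= 2)")
    n_subsets = comb(n, k)
    if n_subsets > _EXHAUSTIVE_GUARD:
        raise ValueError(
            f"C({n},{k}) = {n_subsets} subsets exceeds the enumeration guard "
            f"({_EXHAUSTIVE_GUARD}); use mode='random'"
        )
    subsets = np.array(list(itertools.combinations(range(n), k)), dtype=int)
    rsds = _subset_rsds(values, subsets)
    return subsets[int(np.argmin(rsds))]  # argmin -> first -> lex smallest


def select_min_rsd_subset(
    values: np.ndarray,
    config: OutlierConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Best subset among ``n_iterations`` uniformly drawn size-k subsets."""
    values = np.asarray(values, dtype=float)
    n = values.size
    k = _round_half_up(config.keep_fraction * n)
    if k < 2:
        raise ValueError(f"subset size {k} too small for an RSD (need >= 2)")
    if k == n:
        return np.arange(n)
    best_rsd = np.inf
    best: np.ndarray | None = None
    remaining = config.n_iterations
    chunk = 20_000
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        # first k slots of a uniform random permutation = uniform k-subset
        draws = np.argsort(rng.random((m, n)), axis=1)[:, :k]
        rsds = _subset_rsds(values, draws)
        i = int(np.argmin(rsds))
        if rsds[i] < best_rsd:
            best_rsd = float(rsds[i])
            best = np.sort(draws[i])
    assert best is not None
    return best


def _group_keys(sset: SpectrumSet, group_by: str) -> list[tuple]:
    if group_by == "sample":
        return [(m.variety, m.sample_id) for m in sset.meta]
    return [(m.variety,) for m in sset.meta]


def remove_outliers(
    sset: SpectrumSet,
    config: OutlierConfig | None = None,
    return_report: bool = False,
) -> SpectrumSet | tuple[SpectrumSet, pd.DataFrame]:
    """Keep, per group, the minimum-RSD ``keep_fraction`` subset of shots.

    Groups are samples by default (``group_by="variety"`` pools a whole
    variety).  Retained counts are exactly ``round(keep_fraction * n)`` per
    group.  With ``return_report=True`` also returns a per-group table of
    sizes, before/after RSD, search mode, and removed row indices.
    """
    config = config or OutlierConfig()
    keys = _group_keys(sset, config.group_by)
    groups: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)

    mask = np.abs(sset.grid - config.reference_line_nm) <= config.window_nm
    if not mask.any():
        raise ValueError(
            f"reference window {config.reference_line_nm} +- {config.window_nm} nm "
            "contains no grid points"
        )
    line_intensity = sset.intensities[:, mask].max(axis=1)

    min_group = int(np.ceil(1.0 / (1.0 - config.keep_fraction))) if config.keep_fraction < 1 else 1
    rng = np.random.default_rng(config.seed)
    kept_rows: list[int] = []
    records = []
    for key, rows in groups.items():
        n = len(rows)
        if n < min_group:
            raise ValueError(
                f"group {key} has {n} shots; need >= {min_group} for "
                f"keep_fraction {config.keep_fraction}"
            )
        values = line_intensity[rows]
        k = _round_half_up(config.keep_fraction * n)
        if k == n:
            local = np.arange(n)
            mode = "identity"
        else:
            mode = config.mode
            if mode == "auto":
                mode = "exhaustive" if comb(n, k) <= _AUTO_LIMIT else "random"
            if mode == "exhaustive":
                local = exhaustive_min_rsd_subset(values, config.keep_fraction)
            else:
                local = select_min_rsd_subset(values, config, rng)
        keep = [rows[i] for i in local]
        kept_rows.extend(keep)
        removed = sorted(set(rows) - set(keep))
        records.append(
            {
                "group": "/".join(str(p) for p in key),
                "n_shots": n,
                "n_kept": len(keep),
                "rsd_before": rsd(values) if n >= 2 else np.nan,
                "rsd_after": rsd(values[local]) if k >= 2 else np.nan,
                "mode": mode,
                "removed_rows": removed,
            }
        )
    kept_rows.sort()
    filtered = sset.subset(kept_rows)
    if return_report:
        return filtered, pd.DataFrame(records)
    return filtered
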