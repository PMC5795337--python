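"""PCA-loading variable selection and emission-line assignment.

Principal component analysis of the calibration spectra concentrates the
between-variety signal in the first few components; wavelengths where the
absolute loadings of those components peak are the informative variables.
Candidates are local maxima of ``|loading|`` exceeding a prominence
threshold expressed in units of that loading vector's standard deviation,
de-duplicated so that a weaker candidate within ``dedupe_window_nm`` of a
stronger one (side lobes flanking a strong line) is dropped, and finally
assigned to the nearest known emission line within ``match_tolerance_nm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.decomposition import PCA

from .core import EmissionLine, SpectrumSet, builtin_line_table

__all__ = [
    "PCAModel",
    "SelectionConfig",
    "SelectedVariable",
    "SelectionResult",
    "pca_fit",
    "pick_loading_peaks",
    "assign_lines",
    "select_variables",
]


@dataclass
class PCAModel:
    """Mean spectrum, orthonormal loading rows, explained-variance ratios."""

    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (n_components, n_points)
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def scores(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_spectrum) @ self.loadings.T


@dataclass(frozen=True)
class SelectionConfig:
    n_pcs: int = 3
    peak_prominence: float = 4.0  # multiples of the loading vector's sd
    dedupe_window_nm: float = 0.3
    match_tolerance_nm: float = 0.5
    max_variables: int | None = None

    def __post_init__(self) -> None:
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if self.peak_prominence <= 0 or self.dedupe_window_nm <= 0 or self.match_tolerance_nm <= 0:
            raise ValueError("prominence, dedupe window and match tolerance must be > 0")
        if self.max_variables is not None and self.max_variables < 1:
            raise ValueError("max_variables must be >= 1 when given")


@dataclass
class SelectedVariable:
    index: int
    wavelength_nm: float
    pc: int  # 1-based source component
    loading: float
    species: str = "unassigned"
    ambiguous: bool = False


@dataclass
class SelectionResult:
    variables: list[SelectedVariable]
    pca: PCAModel | None = None

    def wavelengths(self) -> np.ndarray:
        return np.array([v.wavelength_nm for v in self.variables])

    def indices(self) -> np.ndarray:
        return np.array([v.index for v in self.variables], dtype=int)

    def species_set(self) -> set[str]:
        return {v.species for v in self.variables if v.species != "unassigned"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "index": v.index,
                    "wavelength_nm": v.wavelength_nm,
                    "pc": v.pc,
                    "loading": v.loading,
                    "species": v.species,
                    "ambiguous": v.ambiguous,
                }
                for v in self.variables
            ]
        )

    def matched_lines(
        self, lines: Sequence[EmissionLine], tolerance_nm: float = 0.5
    ) -> set[float]:
        """Line wavelengths from ``lines`` matched by some selected variable."""
        hit = set()
        for line in lines:
            for v in self.variables:
                if abs(v.wavelength_nm - line.wavelength_nm) <= tolerance_nm:
                    hit.add(line.wavelength_nm)
                    break
        return hit


def pca_fit(X: np.ndarray, n_components: int, random_state: int = 0) -> PCAModel:
    """Mean-centered PCA via SVD (randomized solver for wide data, seeded).

    Raises on degenerate (constant) data.  Loadings rows are orthonormal;
    at full rank the explained-variance ratios sum to 1 and scores times
    loadings reconstruct the centered data.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if n_components > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError(
            f"n_components {n_components} exceeds min(n_shots - 1, n_points) "
            f"= {min(X.shape[0] - 1, X.shape[1])}"
        )
    if np.allclose(X, X[0], rtol=0.0, atol=0.0):
        raise ValueError("degenerate data: all spectra identical")
    pca = PCA(n_components=n_components, svd_solver="auto", random_state=random_state)
    pca.fit(X)
    return PCAModel(
        mean_spectrum=pca.mean_,
        loadings=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def pick_loading_peaks(
    model: PCAModel,
    grid: np.ndarray,
    config: SelectionConfig | None = None,
) -> list[SelectedVariable]:
    """High-|loading| local maxima of the first ``n_pcs`` components.

    Candidates within ``dedupe_window_nm`` of a stronger candidate (any
    component) are dropped; the survivors are returned sorted by wavelength.
    """
    config = config or SelectionConfig()
    if model.n_components < config.n_pcs:
        raise ValueError(
            f"model has {model.n_components} components, need {config.n_pcs}"
        )
    grid = np.asarray(grid, dtype=float)
    candidates: list[SelectedVariable] = []
    for pc in range(config.n_pcs):
        loading = model.loadings[pc]
        sd = float(loading.std())
        if sd == 0:
            continue
        magnitude = np.abs(loading)
        peaks, _ = find_peaks(magnitude, height=config.peak_prominence * sd)
        for idx in peaks:
            candidates.append(
                SelectedVariable(
                    index=int(idx),
                    wavelength_nm=float(grid[idx]),
                    pc=pc + 1,
                    loading=float(loading[idx]),
                )
            )
    # strongest first; ties broken by earlier component then lower index
    candidates.sort(key=lambda c: (-abs(c.loading), c.pc, c.index))
    kept: list[SelectedVariable] = []
    for cand in candidates:
        if all(abs(cand.wavelength_nm - k.wavelength_nm) > config.dedupe_window_nm for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c.wavelength_nm)
    return kept


def assign_lines(
    candidates: Sequence[SelectedVariable],
    line_table: Sequence[EmissionLine] | None = None,
    tolerance_nm: float = 0.5,
) -> SelectionResult:
    """Assign each candidate the species of the nearest line within tolerance.

    A candidate exactly equidistant from two lines takes the lower-index
    (shorter-wavelength) line and is flagged ambiguous.
    """
    lines = list(line_table) if line_table is not None else builtin_line_table()
    if not lines:
        raise ValueError("line table is empty")
    wavelengths = np.array([l.wavelength_nm for l in lines])
    assigned: list[SelectedVariable] = []
    for cand in candidates:
        dists = np.abs(wavelengths - cand.wavelength_nm)
        j = int(np.argmin(dists))  # first minimum -> lower-index tie-break
        ambiguous = bool(np.sum(dists == dists[j]) > 1)
        species = lines[j].species if dists[j] <= tolerance_nm else "unassigned"
        assigned.append(
            SelectedVariable(
                index=cand.index,
                wavelength_nm=cand.wavelength_nm,
                pc=cand.pc,
                loading=cand.loading,
                species=species,
                ambiguous=ambiguous and species != "unassigned",
            )
        )
    return SelectionResult(variables=assigned)


def select_variables(
    calibration_set: SpectrumSet,
    config: SelectionConfig | None = None,
    line_table: Sequence[EmissionLine] | None = None,
) -> SelectionResult:
    """PCA -> loading-peak picking -> line assignment on a calibration set."""
    config = config or SelectionConfig()
    model = pca_fit(calibration_set.intensities, config.n_pcs)
    candidates = pick_loading_peaks(model, calibration_set.grid, config)
    if config.max_variables is not None and len(candidates) > config.max_variables:
        candidates = sorted(candidates, key=lambda c: -abs(c.loading))[: config.max_variables]
        candidates.sort(key=lambda c: c.wavelength_nm)
    result = assign_lines(candidates, line_table, config.match_tolerance_nm)
    result.pca = model
    return result
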