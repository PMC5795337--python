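"""Shared data containers and I/O for LIBS spectral datasets.

A laser-induced breakdown spectroscopy (LIBS) campaign yields, per sampled
site on a pellet, one accumulated emission spectrum on a common wavelength
grid.  The whole pipeline — simulation, preprocessing, outlier filtering,
variable selection, classification — consumes and returns a single
container, :class:`SpectrumSet`: a wavelength grid (nm, ascending), an
``n_shots x n_points`` intensity matrix in arbitrary units, and one
:class:`ShotMeta` record per row (variety category 1-4, sample id, site id,
and, for simulated data, the ground-truth outlier flag).

The built-in emission-line table lists the twenty atomic/molecular lines
(C I, Mg I/II, Al II, CN, H, Ca II, Fe I, K I, Na I, N I, O I) that the
variable-selection stage is expected to find in coffee-bean spectra.

On-disk format is deliberately plain text: a CSV whose first row is the
wavelength grid and whose remaining rows are shots, plus a ``.meta.json``
sidecar carrying the per-shot metadata.  The round trip is bit-exact for
finite float64 values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "ShotMeta",
    "SpectrumSet",
    "EmissionLine",
    "SpectrumIOError",
    "builtin_line_table",
    "read_line_table",
    "load_spectrum_set",
    "save_spectrum_set",
]


class SpectrumIOError(ValueError):
    """A spectrum file pair is missing, empty, or internally inconsistent."""


@dataclass(frozen=True)
class GridSpec:
    """Uniform wavelength grid specification.

    Defaults describe the analyzed range 246.53-880.26 nm sampled at
    20,937 points.  The grid is stored as data everywhere downstream, so a
    non-uniform instrument grid loads transparently from file.
    """

    start_nm: float = 246.53
    end_nm: float = 880.26
    n_points: int = 20937

    def __post_init__(self) -> None:
        if not self.start_nm < self.end_nm:
            raise ValueError(
                f"start_nm ({self.start_nm}) must be < end_nm ({self.end_nm})"
            )
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")

    def make(self) -> np.ndarray:
        """Return the strictly increasing wavelength vector (nm)."""
        return np.linspace(self.start_nm, self.end_nm, self.n_points)


@dataclass(frozen=True)
class ShotMeta:
    """Per-shot metadata.

    ``variety`` uses the category coding 1-4 (Typica, Catimor, Fushan,
    Xinglong in the motivating study).  ``is_outlier_truth`` is only set by
    the simulator and records whether the shot was planted as aberrant.
    """

    variety: int
    sample_id: str
    site_id: str
    is_outlier_truth: bool | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.variety, (int, np.integer)) and 1 <= self.variety <= 4):
            raise ValueError(f"variety must be an integer in 1..4, got {self.variety!r}")


@dataclass
class SpectrumSet:
    """Wavelength grid + intensity matrix + per-shot metadata."""

    grid: np.ndarray
    intensities: np.ndarray
    meta: list[ShotMeta]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim == 1:
            self.intensities = self.intensities[None, :]
        self.meta = list(self.meta)
        self.validate()

    def validate(self) -> None:
        """Re-check invariants (call before writing if arrays were mutated)."""
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("grid must be a 1-D vector with >= 2 points")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        if self.intensities.shape[1] != self.grid.size:
            raise ValueError(
                f"intensity columns ({self.intensities.shape[1]}) do not match "
                f"grid length ({self.grid.size})"
            )
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError(
                f"metadata length ({len(self.meta)}) does not match "
                f"number of shots ({self.intensities.shape[0]})"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    # -- convenience views -------------------------------------------------

    @property
    def n_shots(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid.size

    @property
    def varieties(self) -> np.ndarray:
        """Integer class labels, one per shot."""
        return np.array([m.variety for m in self.meta], dtype=int)

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(m) for m in self.meta])

    def subset(self, indices: Sequence[int] | np.ndarray) -> "SpectrumSet":
        """Row subset preserving order of ``indices``; grid is shared."""
        idx = np.asarray(indices, dtype=int)
        return SpectrumSet(
            grid=self.grid,
            intensities=self.intensities[idx],
            meta=[self.meta[i] for i in idx],
        )

    def with_intensities(self, intensities: np.ndarray) -> "SpectrumSet":
        """Same grid and metadata with a replaced intensity matrix."""
        return SpectrumSet(grid=self.grid, intensities=intensities, meta=list(self.meta))


@dataclass(frozen=True)
class EmissionLine:
    """A known spectral line: wavelength (nm), species label, simulator weight."""

    wavelength_nm: float
    species: str
    relative_strength: float = 1.0

    def __post_init__(self) -> None:
        if not (200.0 <= self.wavelength_nm <= 900.0):
            raise ValueError(
                f"wavelength {self.wavelength_nm} nm outside plausible LIBS "
                "range 200-900 nm"
            )
        if not self.relative_strength > 0:
            raise ValueError("relative_strength must be positive")


# The twenty lines routinely selected from coffee-bean LIBS spectra, with
# their element assignments.  Wavelengths ascending; C I 247.87 is the
# carbon line whose 247.86 nm intensity drives the RSD outlier filter.
_LINE_TABLE: tuple[tuple[float, str], ...] = (
    (247.87, "C I"),
    (279.56, "Mg II"),
    (280.28, "Mg II"),
    (285.22, "Mg I"),
    (315.93, "Ca II"),
    (317.97, "Ca II"),
    (358.57, "Al II"),
    (388.32, "CN"),
    (393.39, "Ca II"),
    (396.85, "Ca II"),
    (422.68, "Al II"),
    (588.99, "Na I"),
    (656.38, "H"),
    (746.92, "N I"),
    (766.54, "K I"),
    (769.98, "K I"),
    (777.33, "O I"),
    (821.69, "N I"),
    (844.75, "Fe I"),
    (868.10, "Fe I"),
)


def builtin_line_table() -> list[EmissionLine]:
    """The built-in 20-line table (fresh list; entries are immutable)."""
    return [EmissionLine(w, s) for w, s in _LINE_TABLE]


def read_line_table(path: str | Path) -> list[EmissionLine]:
    """Read a user line table from CSV (wavelength_nm, species[, relative_strength])."""
    df = pd.read_csv(path)
    required = {"wavelength_nm", "species"}
    if not required.issubset(df.columns):
        raise SpectrumIOError(
            f"line table {path} must have columns {sorted(required)}"
        )
    strengths = df.get("relative_strength", pd.Series(1.0, index=df.index))
    lines = [
        EmissionLine(float(w), str(s), float(r))
        for w, s, r in zip(df["wavelength_nm"], df["species"], strengths)
    ]
    return sorted(lines, key=lambda l: l.wavelength_nm)


# -- persistence -----------------------------------------------------------


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def save_spectrum_set(sset: SpectrumSet, path: str | Path) -> None:
    """Write ``path`` (CSV: wavelengths row, then one row per shot) plus sidecar.

    Values are written with 17 significant digits so that
    :func:`load_spectrum_set` inverts this bit-exactly for finite float64.
    """
    sset.validate()
    path = Path(path)
    block = np.vstack([sset.grid, sset.intensities])
    np.savetxt(path, block, fmt="%.17g", delimiter=",")
    records = []
    for m in sset.meta:
        records.append(
            {
                "variety": int(m.variety),
                "sample_id": m.sample_id,
                "site_id": m.site_id,
                "is_outlier_truth": m.is_outlier_truth,
            }
        )
    _meta_path(path).write_text(json.dumps(records, indent=1))


def load_spectrum_set(path: str | Path) -> SpectrumSet:
    """Inverse of :func:`save_spectrum_set`.

    Raises :class:`SpectrumIOError` on empty files or when the metadata
    sidecar disagrees with the matrix dimensions.
    """
    path = Path(path)
    try:
        block = np.loadtxt(path, delimiter=",", ndmin=2)
    except (OSError, ValueError) as exc:
        raise SpectrumIOError(f"cannot read spectra CSV {path}: {exc}") from exc
    if block.size == 0:
        raise SpectrumIOError(f"spectra CSV {path} is empty")
    if block.shape[0] < 2:
        raise SpectrumIOError(
            f"spectra CSV {path} has only the wavelength row and no shots"
        )
    grid, intensities = block[0], block[1:]
    meta_file = _meta_path(path)
    if not meta_file.exists():
        raise SpectrumIOError(f"metadata sidecar {meta_file} not found")
    records = json.loads(meta_file.read_text())
    if len(records) != intensities.shape[0]:
        raise SpectrumIOError(
            f"metadata length ({len(records)}) does not match number of "
            f"spectra rows ({intensities.shape[0]}) in {path}"
        )
    meta = [
        ShotMeta(
            variety=int(r["variety"]),
            sample_id=str(r["sample_id"]),
            site_id=str(r["site_id"]),
            is_outlier_truth=r.get("is_outlier_truth"),
        )
        for r in records
    ]
    try:
        return SpectrumSet(grid=grid, intensities=intensities, meta=meta)
    except ValueError as exc:
        raise SpectrumIOError(f"invalid spectrum set in {path}: {exc}") from exc
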