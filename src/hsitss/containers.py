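"""Core in-memory containers for the hyperspectral TSS pipeline.

A hyperspectral capture is a 3-D block (rows x cols x bands) with a
wavelength grid; per-sample work happens on a samples x bands table of
mean region-of-interest spectra paired with reference TSS values
(total soluble solids, in degrees Brix).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Hypercube:
    """3-D spectral image: ``values[row, col, band]`` with band wavelengths ``grid`` (nm).

    Values are either raw digital counts or unitless reflectance; the
    container does not distinguish — calibration state is up to the caller.
    """

    values: np.ndarray
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("hypercube values must be rows x cols x bands")
        if self.values.shape[2] != self.grid.shape[0]:
            raise ValueError(
                f"band axis length {self.values.shape[2]} != grid length {self.grid.shape[0]}"
            )
        if self.grid.ndim != 1 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.grid.shape[0]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the grid band nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.grid - wavelength_nm)))


@dataclass
class MaskImage:
    """Boolean foreground mask with provenance of how it was built."""

    flags: np.ndarray
    threshold: float
    band_pair_nm: tuple[float, float]

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_foreground(self) -> int:
        return int(self.flags.sum())


@dataclass
class SpectraTable:
    """Samples x bands matrix of mean ROI spectra plus reference TSS (°Brix)."""

    X: np.ndarray
    y: np.ndarray
    grid: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be samples x bands")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X rows and y length differ")
        if self.X.shape[1] != self.grid.shape[0]:
            raise ValueError("X columns and grid length differ")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(self.X.shape[0])]
        if len(self.sample_ids) != self.X.shape[0]:
            raise ValueError("sample_ids length and X rows differ")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("spectra table must not contain missing values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def subset(self, indices: np.ndarray) -> "SpectraTable":
        idx = np.asarray(indices, dtype=int)
        return SpectraTable(
            X=self.X[idx],
            y=self.y[idx],
            grid=self.grid,
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class SplitAssignment:
    """Disjoint calibration / prediction index sets covering all samples."""

    calibration: np.ndarray
    prediction: np.ndarray

    def __post_init__(self) -> None:
        self.calibration = np.asarray(self.calibration, dtype=int)
        self.prediction = np.asarray(self.prediction, dtype=int)
        if self.calibration.size == 0:
            raise ValueError("calibration set must be nonempty")
        overlap = np.intersect1d(self.calibration, self.prediction)
        if overlap.size:
            raise ValueError("calibration and prediction sets overlap")


@dataclass
class ChemicalMap:
    """Per-pixel predicted TSS image (°Brix).

    Background pixels are NaN (never 0 °Brix — zero is a valid concentration).
    Saturated pixels are flagged and excluded from summary statistics.
    """

    values: np.ndarray
    mask: np.ndarray
    saturated: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.saturated = np.asarray(self.saturated, dtype=bool)
        if not (self.values.shape == self.mask.shape == self.saturated.shape):
            raise ValueError("map, mask and saturation flags must share one shape")

    def valid_pixels(self) -> np.ndarray:
        """Foreground, non-saturated prediction values."""
        return self.values[self.mask & ~self.saturated]

    def statistics(self) -> dict[str, float]:
        vals = self.valid_pixels()
        if vals.size == 0:
            return {"mean": float("nan"), "min": float("nan"), "max": float("nan"), "n": 0}
        return {
            "mean": float(vals.mean()),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n": int(vals.size),
        }
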