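"""Pixel-wise TSS prediction maps: unfold -> predict -> fold.

A calibrated hypercube is unfolded into a pixels x bands matrix, a fitted
calibration model (PLSR, LS-SVM, or the bundled published 23-wavelength
multilinear model) predicts TSS for every foreground pixel, and the vector
is folded back into an image. Saturated pixels are flagged and excluded
from map statistics; background pixels carry NaN. Maps are rendered on a
linear blue-to-red pseudo-colour ramp (low to high TSS).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from .containers import ChemicalMap, Hypercube, MaskImage
from .errors import WavelengthMismatchError
from .preprocess import median_filter_image
from .synthetic import FULL_SCALE

# blue (low) -> cyan -> green -> yellow -> red (high); endpoints are pure
TSS_COLORMAP = LinearSegmentedColormap.from_list(
    "tss", [(0, 0, 1), (0, 1, 1), (0, 1, 0), (1, 1, 0), (1, 0, 0)]
)


def unfold(cube: Hypercube) -> tuple[np.ndarray, tuple[int, int]]:
    """Row-major pixels x bands matrix plus the spatial shape for refolding."""
    rows, cols, bands = cube.shape
    return cube.values.reshape(rows * cols, bands), (rows, cols)


def fold(matrix: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`unfold` for a per-pixel vector or matrix."""
    matrix = np.asarray(matrix)
    rows, cols = shape
    if matrix.ndim == 1:
        return matrix.reshape(rows, cols)
    return matrix.reshape(rows, cols, matrix.shape[1])


@dataclass
class PublishedTSSModel:
    """The published 23-wavelength multilinear TSS model (°Brix).

    Prediction is ``intercept + sum_i c_i * lambda_i`` where lambda_i is the
    reflectance at the i-th listed wavelength, in the printed order.
    """

    intercept: float
    coefficients: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.coefficients.shape[0] != 23 or self.wavelengths.shape[0] != 23:
            raise ValueError("the published model has exactly 23 coefficient/wavelength pairs")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != 23:
            raise ValueError("expected 23 reflectance values per sample")
        return self.intercept + X @ self.coefficients


def load_published_model() -> PublishedTSSModel:
    """Load the bundled published-model coefficients (``data/eq12.json``)."""
    text = resources.files("hsitss.data").joinpath("eq12.json").read_text()
    spec = json.loads(text)
    return PublishedTSSModel(
        intercept=spec["intercept"],
        coefficients=spec["coefficients"],
        wavelengths=spec["wavelengths_nm"],
    )


def evaluate_published_model(spectrum: np.ndarray) -> float:
    """Evaluate the published model on one 23-value reflectance vector."""
    spectrum = np.asarray(spectrum, dtype=float).ravel()
    if spectrum.shape[0] != 23:
        raise ValueError("expected exactly 23 reflectance values")
    model = load_published_model()
    return float(model.predict(spectrum[None, :])[0])


def _resolve_bands(grid: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """Nearest-band indices, rejecting mismatches beyond half a grid step."""
    grid = np.asarray(grid, dtype=float)
    half_step = 0.5 * np.max(np.diff(grid)) if grid.size > 1 else np.inf
    idx = np.empty(wavelengths.shape[0], dtype=int)
    for i, nm in enumerate(np.asarray(wavelengths, dtype=float)):
        j = int(np.argmin(np.abs(grid - nm)))
        if np.abs(grid[j] - nm) > half_step:
            raise WavelengthMismatchError(
                f"model wavelength {nm} nm is {abs(grid[j] - nm):.2f} nm from the "
                f"nearest grid band ({grid[j]:.2f} nm), beyond half a grid step"
            )
        idx[i] = j
    return idx


def find_saturated(raw: Hypercube, wavelengths: np.ndarray | None = None,
                   full_scale: float = FULL_SCALE) -> np.ndarray:
    """Pixels whose raw count sits at sensor full-scale in any model wavelength."""
    if wavelengths is None:
        bands = np.arange(raw.n_bands)
    else:
        bands = _resolve_bands(raw.grid, np.asarray(wavelengths, dtype=float))
    return np.any(raw.values[:, :, bands] >= full_scale, axis=2)


def predict_map(
    cube: Hypercube,
    mask: MaskImage,
    model,
    denoise: bool = False,
    saturated: np.ndarray | None = None,
    denoise_window: int = 5,
) -> ChemicalMap:
    """Predict TSS for every foreground pixel of a calibrated cube.

    ``model`` is anything with ``predict(pixels x bands)`` and a
    ``wavelengths`` attribute (None means: use the full cube grid).
    With ``denoise=True`` each needed band image is median filtered
    (``denoise_window`` square) before prediction.
    """
    if mask.flags.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    wavelengths = getattr(model, "wavelengths", None)
    if wavelengths is None:
        bands = np.arange(cube.n_bands)
    else:
        bands = _resolve_bands(cube.grid, np.asarray(wavelengths, dtype=float))

    planes = cube.values[:, :, bands]
    if denoise:
        planes = np.stack(
            [median_filter_image(planes[:, :, k], denoise_window)
             for k in range(planes.shape[2])],
            axis=2,
        )

    rows, cols = mask.flags.shape
    values = np.full((rows, cols), np.nan)
    fg = mask.flags
    if fg.any():
        preds = np.asarray(model.predict(planes[fg])).ravel()
        values[fg] = preds
    if saturated is None:
        saturated = np.zeros((rows, cols), dtype=bool)
    return ChemicalMap(values=values, mask=fg.copy(), saturated=np.asarray(saturated, bool))


def render_pseudocolour(
    cmap_image: ChemicalMap, lo: float, hi: float,
    background_rgb: tuple[float, float, float] = (0.5, 0.5, 0.5),
) -> tuple[np.ndarray, dict]:
    """Linear pseudo-colour rendering: ``lo`` -> blue, ``hi`` -> red.

    Returns (rows x cols x 3 uint8 RGB, colour-bar metadata).
    """
    if not lo < hi:
        raise ValueError("lo must be below hi")
    norm = np.clip((cmap_image.values - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.empty(cmap_image.values.shape + (3,), dtype=float)
    rgb[:] = background_rgb
    fg = cmap_image.mask & np.isfinite(cmap_image.values)
    rgb[fg] = TSS_COLORMAP(norm[fg])[:, :3]
    meta = {
        "colormap": "tss (blue=low, red=high)",
        "lo_brix": float(lo),
        "hi_brix": float(hi),
        "background_rgb": list(background_rgb),
    }
    return (rgb * 255).round().astype(np.uint8), meta


def save_map_png(rgb: np.ndarray, path: str | Path) -> Path:
    from PIL import Image

    path = Path(path)
    Image.fromarray(rgb, mode="RGB").save(path)
    return path
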