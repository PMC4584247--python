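"""Reflectance calibration, band cropping, background masking and ROI spectra.

Raw digital counts are calibrated against white (~99 % reflectance) and dark
(~0 %) reference frames::

    I = (I_raw - I_dark) / (I_white - I_dark)

Background removal follows the two-band subtract-and-threshold scheme: the
difference between a high-contrast near-infrared band (default 893 nm) and a
visible band (default 569 nm) is large on fruit and near zero on background,
so thresholding the difference image (default 0.4) yields the fruit mask.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from .containers import Hypercube, MaskImage
from .errors import DegenerateReferenceError, EmptyROIError, EmptySelectionError

DEFAULT_MASK_BANDS_NM = (893.0, 569.0)
DEFAULT_MASK_THRESHOLD = 0.4
DEFAULT_CROP_NM = (420.0, 1000.0)


def calibrate_reflectance(
    raw: Hypercube, white: Hypercube, dark: Hypercube
) -> Hypercube:
    """Element-wise ``(raw - dark) / (white - dark)``; no clipping is applied.

    Calibrated values may exceed [0, 1] (specular highlights, saturated
    pixels); downstream stages flag rather than alter them.
    """
    if not (raw.shape == white.shape == dark.shape):
        raise ValueError("raw, white and dark cubes must share one shape")
    if not (
        np.array_equal(raw.grid, white.grid) and np.array_equal(raw.grid, dark.grid)
    ):
        raise ValueError("raw, white and dark cubes must share one wavelength grid")
    denom = white.values - dark.values
    if np.any(denom == 0):
        raise DegenerateReferenceError(
            "white and dark references coincide at some pixel/band"
        )
    return Hypercube((raw.values - dark.values) / denom, raw.grid)


def crop_bands(cube: Hypercube, lo_nm: float, hi_nm: float) -> Hypercube:
    """Keep exactly the bands with ``lo_nm <= lambda <= hi_nm`` (closed interval)."""
    if lo_nm > hi_nm:
        raise ValueError("lo_nm must not exceed hi_nm")
    keep = (cube.grid >= lo_nm) & (cube.grid <= hi_nm)
    if not keep.any():
        raise EmptySelectionError(f"no bands inside [{lo_nm}, {hi_nm}] nm")
    return Hypercube(cube.values[:, :, keep], cube.grid[keep])


def build_mask(
    cube: Hypercube,
    band_a_nm: float = DEFAULT_MASK_BANDS_NM[0],
    band_b_nm: float = DEFAULT_MASK_BANDS_NM[1],
    threshold: float = DEFAULT_MASK_THRESHOLD,
) -> MaskImage:
    """Foreground where ``image(band_a) - image(band_b) >= threshold``.

    Bands are resolved to the nearest grid band; wavelengths outside the
    grid's span are rejected.
    """
    lo, hi = cube.grid[0], cube.grid[-1]
    for nm in (band_a_nm, band_b_nm):
        if not lo <= nm <= hi:
            raise ValueError(f"band {nm} nm outside grid range [{lo}, {hi}] nm")
    ia = cube.band_index(band_a_nm)
    ib = cube.band_index(band_b_nm)
    diff = cube.values[:, :, ia] - cube.values[:, :, ib]
    return MaskImage(
        flags=diff >= threshold,
        threshold=threshold,
        band_pair_nm=(band_a_nm, band_b_nm),
    )


def extract_mean_spectrum(cube: Hypercube, mask: MaskImage) -> np.ndarray:
    """Arithmetic mean spectrum over the mask's foreground pixels, per band."""
    if mask.flags.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    if mask.n_foreground == 0:
        raise EmptyROIError("mask contains no foreground pixels")
    return cube.values[mask.flags].mean(axis=0)


def median_filter_image(img: np.ndarray, window: int = 5) -> np.ndarray:
    """Square median filter with reflection padding at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    return ndimage.median_filter(img, size=window, mode="reflect")
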