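"""Seeded synthetic hyperspectral captures of dark berries for end-to-end testing.

The generator emulates a 512-band visible/near-infrared (380-1030 nm)
push-broom capture of dark-skinned fruit on a neutral background:

* low reflectance (< 10 %) across the visible 420-650 nm window, as for
  anthocyanin/chlorophyll-rich mature fruit;
* a broad reflectance peak near 850 nm;
* an absorption valley around 960-980 nm (O-H combination band of water and
  carbohydrates) whose depth grows linearly with total soluble solids (TSS),
  so a linear calibration model is recoverable;
* multiplicative sensor noise, a per-pixel "bumpy surface" scatter factor,
  and a small fraction of saturated (full-scale) pixels.

Raw counts are synthesized as ``dark + (white - dark) * R * scatter * noise``
so that white/dark reflectance calibration inverts the model exactly in the
noise-free case.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import Hypercube, SpectraTable

FULL_SCALE = 1.0  # sensor full-scale in white-normalized digital counts

# TSS summary statistics of the emulated fruit population (°Brix)
TSS_MEAN = 6.75
TSS_SD = 1.55
TSS_LO = 3.21
TSS_HI = 10.99


@dataclass
class SpectralModelParams:
    """Parametric fruit reflectance model plus sensor imperfections.

    The noise-free fruit reflectance at wavelength lambda for a fruit with
    soluble-solids content ``tss`` is a sum of Gaussian shape components::

        R(lambda; tss) = sum_i (amp_i + sens_i * tss) * exp(-(lambda - c_i)^2 / (2 w_i^2))

    ``baseline_components`` holds (center nm, width nm, amplitude) triples;
    ``tss_sensitivity`` the per-component coupling (reflectance per °Brix).
    The default valley component (970 nm) has a negative amplitude and a
    negative coupling: higher TSS digs a deeper absorption valley.
    """

    baseline_components: list[tuple[float, float, float]] = field(
        default_factory=lambda: [
            (715.0, 500.0, 0.05),   # broad low floor across the visible
            (850.0, 80.0, 0.45),    # near-infrared reflectance peak
            (1010.0, 100.0, 0.15),  # long-wavelength shoulder
            (970.0, 18.0, -0.05),   # water/carbohydrate absorption valley
        ]
    )
    tss_sensitivity: list[float] = field(
        default_factory=lambda: [0.0, 0.0, 0.0, -0.010]
    )
    noise_sd: float = 0.01
    scatter_sd: float = 0.03
    saturation_rate: float = 0.005
    background_reflectance: float = 0.25

    def __post_init__(self) -> None:
        if len(self.tss_sensitivity) != len(self.baseline_components):
            raise ValueError("one sensitivity per baseline component required")
        if self.noise_sd < 0 or self.scatter_sd < 0:
            raise ValueError("noise/scatter spreads must be nonnegative")
        if not 0.0 <= self.saturation_rate < 1.0:
            raise ValueError("saturation_rate must lie in [0, 1)")

    def fruit_reflectance(self, grid: np.ndarray, tss: float) -> np.ndarray:
        """Noise-free fruit reflectance spectrum for one TSS value."""
        grid = np.asarray(grid, dtype=float)
        r = np.zeros_like(grid)
        for (center, width, amp), sens in zip(
            self.baseline_components, self.tss_sensitivity
        ):
            r += (amp + sens * tss) * np.exp(-((grid - center) ** 2) / (2.0 * width**2))
        return r


@dataclass
class CaptureGeometry:
    """Image size and circular fruit-blob placement (row, col, radius in pixels)."""

    shape: tuple[int, int]
    centers: list[tuple[float, float]]
    radius: float

    def footprints(self) -> list[np.ndarray]:
        """Boolean footprint image per blob; raises on overlap or out-of-bounds."""
        rows, cols = self.shape
        rr, cc = np.mgrid[0:rows, 0:cols]
        masks = []
        occupied = np.zeros(self.shape, dtype=bool)
        for r0, c0 in self.centers:
            if (
                r0 - self.radius < 0
                or c0 - self.radius < 0
                or r0 + self.radius >= rows
                or c0 + self.radius >= cols
            ):
                raise ValueError("blob does not fit inside the image")
            m = (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius**2
            if not m.any():
                raise ValueError("blob footprint is empty")
            if (m & occupied).any():
                raise ValueError("blobs overlap")
            occupied |= m
            masks.append(m)
        return masks


def grid_layout(n_blobs: int, radius: float, margin: int = 4) -> CaptureGeometry:
    """Pack ``n_blobs`` circular blobs on a near-square lattice."""
    if n_blobs <= 0:
        raise ValueError("n_blobs must be positive")
    per_row = int(np.ceil(np.sqrt(n_blobs)))
    n_rows = int(np.ceil(n_blobs / per_row))
    pitch = int(2 * radius + 2 * margin + 1)
    shape = (n_rows * pitch + 2 * margin, per_row * pitch + 2 * margin)
    centers = []
    for k in range(n_blobs):
        i, j = divmod(k, per_row)
        centers.append(
            (margin + pitch * i + pitch / 2.0, margin + pitch * j + pitch / 2.0)
        )
    return CaptureGeometry(shape=shape, centers=centers, radius=radius)


@dataclass
class SyntheticCapture:
    """Raw/white/dark frames plus the generating ground truth."""

    raw: Hypercube
    white: Hypercube
    dark: Hypercube
    truth_tss: np.ndarray
    footprints: list[np.ndarray]
    grid: np.ndarray
    saturated: np.ndarray  # rows x cols flags: raw forced to sensor full-scale


def make_wavelength_grid(n_bands: int, lo_nm: float, hi_nm: float) -> np.ndarray:
    """Evenly spaced band-center grid from ``lo_nm`` to ``hi_nm`` inclusive."""
    if n_bands < 2:
        raise ValueError("need at least 2 bands")
    if not lo_nm < hi_nm:
        raise ValueError("lo_nm must be below hi_nm")
    return np.linspace(lo_nm, hi_nm, n_bands)


def draw_tss_values(
    n: int,
    seed: int,
    mean: float = TSS_MEAN,
    sd: float = TSS_SD,
    lo: float = TSS_LO,
    hi: float = TSS_HI,
) -> np.ndarray:
    """Draw TSS values (°Brix) from a normal truncated to [lo, hi]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not lo < hi:
        raise ValueError("lo must be below hi")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _illumination(grid: np.ndarray) -> np.ndarray:
    """Smooth source/detector gain profile (white minus dark), in counts."""
    return 0.5 + 0.4 * np.exp(-((grid - 750.0) ** 2) / (2.0 * 300.0**2))


def render_capture(
    tss: np.ndarray,
    grid: np.ndarray,
    geometry: CaptureGeometry,
    params: SpectralModelParams | None = None,
    seed: int = 0,
) -> SyntheticCapture:
    """Render raw, white and dark frames for fruit blobs with the given TSS values.

    Raw counts are ``dark + (white - dark) * R * scatter * noise`` clipped to
    the sensor range, with a ``saturation_rate`` fraction of fruit pixels
    forced to full scale. The scatter factor is constant across bands for a
    pixel (surface geometry); noise is independent per pixel and band.
    """
    params = params or SpectralModelParams()
    tss = np.asarray(tss, dtype=float)
    grid = np.asarray(grid, dtype=float)
    footprints = geometry.footprints()
    if tss.shape[0] != len(footprints):
        raise ValueError("one TSS value per blob required")

    rng = np.random.default_rng(seed)
    rows, cols = geometry.shape
    n_bands = grid.shape[0]

    dark = np.full((rows, cols, n_bands), 0.04)
    white = dark + _illumination(grid)[None, None, :]

    reflectance = np.full(
        (rows, cols, n_bands), params.background_reflectance, dtype=float
    )
    for m, t in zip(footprints, tss):
        reflectance[m] = params.fruit_reflectance(grid, t)

    scatter = 1.0 + params.scatter_sd * rng.standard_normal((rows, cols))
    scatter = np.clip(scatter, 0.05, None)
    noise = 1.0 + params.noise_sd * rng.standard_normal((rows, cols, n_bands))

    raw = dark + (white - dark) * reflectance * scatter[:, :, None] * noise
    raw = np.clip(raw, 0.0, FULL_SCALE)

    saturated = np.zeros((rows, cols), dtype=bool)
    if params.saturation_rate > 0:
        fruit = np.zeros((rows, cols), dtype=bool)
        for m in footprints:
            fruit |= m
        fruit_idx = np.flatnonzero(fruit.ravel())
        n_sat = int(round(params.saturation_rate * fruit_idx.size))
        if n_sat > 0:
            chosen = rng.choice(fruit_idx, size=n_sat, replace=False)
            sat = np.zeros(rows * cols, dtype=bool)
            sat[chosen] = True
            saturated = sat.reshape(rows, cols)
            raw[saturated] = FULL_SCALE

    return SyntheticCapture(
        raw=Hypercube(raw, grid),
        white=Hypercube(white, grid),
        dark=Hypercube(dark, grid),
        truth_tss=tss,
        footprints=footprints,
        grid=grid,
        saturated=saturated,
    )


def make_spectra_table(
    n_samples: int,
    seed: int,
    grid: np.ndarray | None = None,
    params: SpectralModelParams | None = None,
    spectrum_noise_sd: float = 0.002,
) -> SpectraTable:
    """Sample-level shortcut: mean ROI spectra without rendering full images.

    Emulates the per-sample averaged fruit spectrum directly — the fruit
    reflectance model evaluated at each sample's TSS plus a small residual
    (what pixel averaging over a footprint leaves of the pixel noise).
    """
    params = params or SpectralModelParams()
    if grid is None:
        grid = make_wavelength_grid(512, 380.0, 1030.0)
    rng = np.random.default_rng(seed)
    tss = draw_tss_values(n_samples, seed=int(rng.integers(2**31)))
    scatter = 1.0 + params.scatter_sd * rng.standard_normal(n_samples)
    X = np.empty((n_samples, grid.shape[0]))
    for i, t in enumerate(tss):
        X[i] = params.fruit_reflectance(grid, t) * scatter[i]
    X += spectrum_noise_sd * rng.standard_normal(X.shape)
    return SpectraTable(X=X, y=tss, grid=np.asarray(grid, dtype=float))
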