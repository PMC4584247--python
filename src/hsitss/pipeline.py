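"""End-to-end study orchestration: generate -> preprocess -> partition ->
wavelength selection -> calibration models -> TSS maps.

One :class:`PipelineConfig` (YAML-serializable) drives the whole run; every
stage seed derives deterministically from the master seed, so a run is fully
reproducible from the config alone. Artifacts land in a run directory:
spectra table, split indices, selection probabilities, selected wavelengths
per cut-off, fitted models (JSON), a metrics table with one row per model
(family, band count, LVs, R/RMSE on calibration, leave-one-out CV and
prediction sets, gamma, sigma2), pseudo-colour maps, and a manifest.
"""
from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemical_imaging import find_saturated, predict_map, render_pseudocolour, save_map_png
from .containers import SpectraTable
from .models import (
    MetricsReport,
    compute_metrics,
    fit_lssvm,
    fit_plsr,
    grid_search_lssvm,
    loo_cv,
    select_n_lv,
)
from .partition import spxy_split
from .preprocess import (
    DEFAULT_CROP_NM,
    DEFAULT_MASK_BANDS_NM,
    DEFAULT_MASK_THRESHOLD,
    build_mask,
    calibrate_reflectance,
    crop_bands,
    extract_mean_spectrum,
)
from .random_frog import FrogParams, run_random_frog, select_by_cutoff
from .synthetic import (
    SpectralModelParams,
    draw_tss_values,
    grid_layout,
    make_wavelength_grid,
    render_capture,
)


@dataclass
class PipelineConfig:
    """All knobs of one study run; see field names for the stage each drives."""

    n_samples: int = 310
    n_bands: int = 512
    grid_lo_nm: float = 380.0
    grid_hi_nm: float = 1030.0
    blobs_per_capture: int = 6
    blob_radius: float = 9.0
    crop_nm: tuple[float, float] = DEFAULT_CROP_NM
    mask_bands_nm: tuple[float, float] = DEFAULT_MASK_BANDS_NM
    mask_threshold: float = DEFAULT_MASK_THRESHOLD
    n_calibration: int = 235
    frog: FrogParams = field(default_factory=FrogParams)
    sp_cutoffs: tuple[float, ...] = (0.7, 0.85)
    lv_max: int = 25
    model_families: tuple[str, ...] = ("plsr", "lssvm-linear", "lssvm-rbf")
    gamma_grid_points: int = 13
    sigma2_grid_points: int = 17
    denoise_maps: bool = True
    map_range_brix: tuple[float, float] = (3.0, 11.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        frog = FrogParams(**raw.pop("frog", {}))
        cfg = cls(frog=frog, **{k: v for k, v in raw.items()})
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def stage_seed(self, stage: int) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        return int(np.random.SeedSequence([self.seed, stage]).generate_state(1)[0] % (2**31))


def simulate_spectra(config: PipelineConfig) -> tuple[SpectraTable, list]:
    """Render captures blob-by-blob, calibrate, mask, crop and average spectra.

    Returns the cropped spectra table and the list of per-capture artifacts
    (capture, calibrated cube, mask) for downstream mapping.
    """
    grid = make_wavelength_grid(config.n_bands, config.grid_lo_nm, config.grid_hi_nm)
    tss = draw_tss_values(config.n_samples, seed=config.stage_seed(1))
    params = SpectralModelParams()
    geometry = grid_layout(config.blobs_per_capture, config.blob_radius)

    spectra, truth = [], []
    captures = []
    rng = np.random.default_rng(config.stage_seed(2))
    for start in range(0, config.n_samples, config.blobs_per_capture):
        chunk = tss[start : start + config.blobs_per_capture]
        geo = geometry if chunk.size == config.blobs_per_capture else grid_layout(
            chunk.size, config.blob_radius
        )
        cap = render_capture(chunk, grid, geo, params, seed=int(rng.integers(2**31)))
        calibrated = calibrate_reflectance(cap.raw, cap.white, cap.dark)
        mask = build_mask(
            calibrated, *config.mask_bands_nm, threshold=config.mask_threshold
        )
        cropped = crop_bands(calibrated, *config.crop_nm)
        for m, t in zip(cap.footprints, chunk):
            roi = mask.flags & m
            if not roi.any():  # fully saturated blob: fall back to the footprint
                roi = m
            spectra.append(cropped.values[roi].mean(axis=0))
            truth.append(t)
        captures.append((cap, cropped, mask))
    table = SpectraTable(X=np.array(spectra), y=np.array(truth), grid=cropped.grid)
    return table, captures


def fit_and_score(
    table: SpectraTable,
    split,
    family: str,
    wavelengths: np.ndarray | None,
    config: PipelineConfig,
) -> tuple[object, MetricsReport]:
    """Fit one model family on the calibration set; score on all three sets."""
    if wavelengths is None:
        cols = np.arange(table.grid.shape[0])
        used_wl = table.grid
    else:
        cols = np.array([int(np.argmin(np.abs(table.grid - w))) for w in wavelengths])
        used_wl = table.grid[cols]
    Xc, yc = table.X[split.calibration][:, cols], table.y[split.calibration]
    Xp, yp = table.X[split.prediction][:, cols], table.y[split.prediction]

    extras: dict = {"n_wavelengths": int(cols.size), "family": family}
    if family == "plsr":
        n_lv, _ = select_n_lv(Xc, yc, config.lv_max)
        model = fit_plsr(Xc, yc, n_lv, wavelengths=used_wl)
        factory = lambda Xt, yt: fit_plsr(Xt, yt, min(n_lv, Xt.shape[0] - 1))
        extras["n_lv"] = n_lv
    elif family in ("lssvm-linear", "lssvm-rbf"):
        kernel = family.split("-")[1]
        gamma_grid = np.logspace(0, 9, config.gamma_grid_points)
        sigma2_grid = np.logspace(-2, 6, config.sigma2_grid_points)
        gamma, sigma2, _ = grid_search_lssvm(Xc, yc, kernel, gamma_grid, sigma2_grid)
        model = fit_lssvm(Xc, yc, kernel, gamma, sigma2, wavelengths=used_wl)
        factory = lambda Xt, yt: fit_lssvm(Xt, yt, kernel, gamma, sigma2)
        extras["gamma"] = gamma
        extras["sigma2"] = sigma2
    else:
        raise ValueError(f"unknown model family {family!r}")

    r_c, rmse_c = compute_metrics(yc, model.predict(Xc))
    r_cv, rmse_cv, _ = loo_cv(Xc, yc, factory)
    r_p, rmse_p = compute_metrics(yp, model.predict(Xp))
    report = MetricsReport(r_c, rmse_c, r_cv, rmse_cv, r_p, rmse_p, extras=extras)
    return model, report


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full study; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        table, captures = simulate_spectra(config)
        pd.DataFrame(
            np.column_stack([table.y, table.X]),
            columns=["tss_brix"] + [f"{w:.2f}nm" for w in table.grid],
            index=table.sample_ids,
        ).to_csv(outdir / "spectra.csv", index_label="sample_id")

        stage = "partition"
        split = spxy_split(table, config.n_calibration)
        pd.DataFrame({"index": split.calibration}).to_csv(
            outdir / "calibration_indices.csv", index=False
        )
        pd.DataFrame({"index": split.prediction}).to_csv(
            outdir / "prediction_indices.csv", index=False
        )

        stage = "random_frog"
        frog_params = FrogParams(**{**asdict(config.frog), "seed": config.stage_seed(3)})
        frog = run_random_frog(table, frog_params)
        pd.DataFrame({"wavelength_nm": table.grid, "sp": frog.sp}).to_csv(
            outdir / "sp.csv", index=False
        )
        selections: dict[float, np.ndarray] = {}
        for cutoff in config.sp_cutoffs:
            wl = select_by_cutoff(frog, table.grid, cutoff)
            selections[cutoff] = wl
            pd.DataFrame({"wavelength_nm": wl}).to_csv(
                outdir / f"selected_wavelengths_sp{cutoff:g}.csv", index=False
            )

        stage = "models"
        rows = []
        fitted: dict[str, object] = {}
        wavesets: list[tuple[str, np.ndarray | None]] = [("full", None)]
        for cutoff, wl in selections.items():
            if wl.size >= 2:
                wavesets.append((f"sp{cutoff:g}", wl))
        for set_name, wl in wavesets:
            for family in config.model_families:
                model, report = fit_and_score(table, split, family, wl, config)
                row = {"wavelength_set": set_name, **report.to_dict()}
                rows.append(row)
                key = f"{set_name}_{family}"
                fitted[key] = model
                (outdir / f"model_{key}.json").write_text(
                    json.dumps(model.to_dict(), indent=1)
                )
        metrics = pd.DataFrame(rows)
        col_order = [
            "wavelength_set", "family", "n_wavelengths", "n_lv",
            "R_C", "RMSE_C", "R_CV", "RMSE_CV", "R_P", "RMSE_P",
            "gamma", "sigma2",
        ]
        metrics = metrics.reindex(columns=[c for c in col_order if c in metrics])
        metrics.to_csv(outdir / "metrics.csv", index=False)

        stage = "maps"
        map_model_key = next(
            (k for k in fitted if k.startswith("sp") and "plsr" in k), "full_plsr"
        )
        map_model = fitted.get(map_model_key)
        if map_model is not None and captures:
            cap, cropped, mask = captures[0]
            saturated = find_saturated(cap.raw)
            cmap_img = predict_map(
                cropped, mask, map_model,
                denoise=config.denoise_maps, saturated=saturated,
            )
            rgb, meta = render_pseudocolour(cmap_img, *config.map_range_brix)
            save_map_png(rgb, outdir / "tss_map.png")
            stats = cmap_img.statistics()
            (outdir / "tss_map_stats.json").write_text(
                json.dumps({"model": map_model_key, **meta, **stats}, indent=1)
            )

        manifest = {
            "package": "hsitss",
            "version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "seed": config.seed,
            "stage_seeds": {s: config.stage_seed(i) for i, s in
                            enumerate(["_", "tss", "captures", "frog"]) if i},
            "config": config.to_dict(),
            "artifacts": sorted(p.name for p in outdir.iterdir()),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir
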