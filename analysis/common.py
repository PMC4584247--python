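"""Shared configuration and I/O helpers for the numbered analysis scripts.

The analysis runs the full study at a reduced but still informative scale
(60 fruit samples, Random Frog at T=400) so the whole sequence finishes in
a few minutes on one CPU; the package itself is scale-free.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from hsitss import FrogParams, PipelineConfig, SpectraTable

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"

CONFIG = PipelineConfig(
    n_samples=60,
    n_calibration=45,  # the study's 3:1 calibration:prediction ratio
    frog=FrogParams(T=400, Q=50, theta=0.3, omega=3.0, eta=0.1, n_lv_max=5),
    sp_cutoffs=(0.7, 0.85),
    lv_max=12,
    seed=2026,
)


def save_table(table: SpectraTable, path: Path) -> None:
    pd.DataFrame(
        np.column_stack([table.y, table.X]),
        columns=["tss_brix"] + [f"{w:.2f}nm" for w in table.grid],
        index=table.sample_ids,
    ).to_csv(path, index_label="sample_id")


def load_table(path: Path) -> SpectraTable:
    df = pd.read_csv(path, index_col=0)
    grid = np.array([float(c.rstrip("nm")) for c in df.columns[1:]])
    return SpectraTable(
        X=df.iloc[:, 1:].to_numpy(),
        y=df.iloc[:, 0].to_numpy(),
        grid=grid,
        sample_ids=[str(i) for i in df.index],
    )
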