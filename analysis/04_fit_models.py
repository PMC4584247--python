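"""Fit PLSR and LS-SVM calibration models on full and selected wavelengths.

Builds the model-comparison table (one row per wavelength set x model family
with R/RMSE on calibration, leave-one-out CV and prediction sets) and
quantifies, via relative percent change, what the wavelength reduction costs.
Writes results/analysis/metrics.csv and model JSON files.
"""
import json

import pandas as pd
from common import CONFIG, RESULTS, load_table

from hsitss import relative_change
from hsitss.containers import SplitAssignment
from hsitss.pipeline import fit_and_score


def main() -> None:
    table = load_table(RESULTS / "spectra.csv")
    split = SplitAssignment(
        calibration=pd.read_csv(RESULTS / "calibration_indices.csv")["index"].to_numpy(),
        prediction=pd.read_csv(RESULTS / "prediction_indices.csv")["index"].to_numpy(),
    )
    wavesets = [("full", None)]
    for cutoff in CONFIG.sp_cutoffs:
        wl = pd.read_csv(
            RESULTS / f"selected_wavelengths_sp{cutoff:g}.csv"
        )["wavelength_nm"].to_numpy()
        if wl.size >= 2:
            wavesets.append((f"sp{cutoff:g}", wl))

    rows = []
    for set_name, wl in wavesets:
        for family in CONFIG.model_families:
            model, report = fit_and_score(table, split, family, wl, CONFIG)
            rows.append({"wavelength_set": set_name, **report.to_dict()})
            (RESULTS / f"model_{set_name}_{family}.json").write_text(
                json.dumps(model.to_dict(), indent=1))
            print(f"{set_name:>6} {family:<13} "
                  f"R_P={report.r_p:.3f} RMSE_P={report.rmse_p:.3f} °Brix")
    metrics = pd.DataFrame(rows)
    metrics.to_csv(RESULTS / "metrics.csv", index=False)

    full = metrics[(metrics.wavelength_set == "full") & (metrics.family == "plsr")]
    sel = metrics[(metrics.wavelength_set != "full") & (metrics.family == "plsr")]
    if not full.empty and not sel.empty:
        ref, new = full.iloc[0], sel.iloc[0]
        print(f"\nreduced PLSR ({sel.iloc[0].wavelength_set}) vs full-band PLSR: "
              f"R_P change {relative_change(ref.R_P, new.R_P):+.3g}%, "
              f"RMSE_P change {relative_change(ref.RMSE_P, new.RMSE_P):+.3g}%, "
              f"variables {relative_change(ref.n_wavelengths, new.n_wavelengths):+.3g}%")


if __name__ == "__main__":
    main()
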