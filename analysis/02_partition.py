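"""Split samples into calibration and prediction sets with SPXY.

SPXY (Kennard-Stone on joint, max-normalized spectral + TSS distances) picks
a calibration set that spans both spaces; the study's 3:1 ratio is kept.
Writes the two index lists under results/analysis/.
"""
import pandas as pd
from common import CONFIG, RESULTS, load_table

from hsitss import spxy_split


def main() -> None:
    table = load_table(RESULTS / "spectra.csv")
    split = spxy_split(table, CONFIG.n_calibration)
    pd.DataFrame({"index": split.calibration}).to_csv(
        RESULTS / "calibration_indices.csv", index=False)
    pd.DataFrame({"index": split.prediction}).to_csv(
        RESULTS / "prediction_indices.csv", index=False)
    y_cal, y_pred = table.y[split.calibration], table.y[split.prediction]
    print(f"SPXY split: {split.calibration.size} calibration / "
          f"{split.prediction.size} prediction samples")
    print(f"calibration TSS range {y_cal.min():.2f}-{y_cal.max():.2f} °Brix "
          f"contains prediction range {y_pred.min():.2f}-{y_pred.max():.2f}: "
          f"{y_cal.min() <= y_pred.min() and y_cal.max() >= y_pred.max()}")


if __name__ == "__main__":
    main()
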