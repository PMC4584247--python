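"""Rank wavelengths by Random Frog selection probability and apply SP cut-offs.

Runs the pseudo-MCMC subset search over the calibrated spectra and writes
per-band selection probabilities (sp.csv) plus the important-wavelength lists
at the 0.7 and 0.85 cut-offs.
"""
from dataclasses import replace

import pandas as pd
from common import CONFIG, RESULTS, load_table

from hsitss import run_random_frog, select_by_cutoff


def main() -> None:
    table = load_table(RESULTS / "spectra.csv")
    params = replace(CONFIG.frog, seed=CONFIG.stage_seed(3))
    result = run_random_frog(table, params)
    pd.DataFrame({"wavelength_nm": table.grid, "sp": result.sp}).to_csv(
        RESULTS / "sp.csv", index=False)
    print(f"Random Frog: T={params.T}, Q={params.Q}; "
          f"max SP {result.sp.max():.2f}, mean subset size {result.trace.mean():.1f}")
    for cutoff in CONFIG.sp_cutoffs:
        wl = select_by_cutoff(result, table.grid, cutoff)
        pd.DataFrame({"wavelength_nm": wl}).to_csv(
            RESULTS / f"selected_wavelengths_sp{cutoff:g}.csv", index=False)
        head = ", ".join(f"{w:.0f}" for w in wl[:10])
        print(f"SP >= {cutoff}: {wl.size} wavelengths selected "
              f"({head}{'...' if wl.size > 10 else ''} nm)")


if __name__ == "__main__":
    main()
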