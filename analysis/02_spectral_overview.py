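"""Class mean spectra, difference spectra and smoothed 2nd derivatives.

For the plasma and saliva cohorts: where do the classes differ?  The
largest |healthy - IBD| excursions should sit inside the WAMAC water
bands, in both the raw means and the Savitzky-Golay 2nd-derivative view.
Writes results/spectral_differences.csv; mean-spectra figures go to
scratch/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from aquaphot.aquaphotomics import band_assignments
from aquaphot.preprocess import PreprocessSpec, apply_pipeline
from aquaphot.spectra_io import FIRST_OVERTONE, class_mean_spectra, subset_range
from aquaphot.synthetic import generate_cohort, preset

SEED = 17
ROOT = Path(__file__).resolve().parents[1]
DERIV = PreprocessSpec([("smooth", {"window_points": 13}),
                        ("savgol_derivative", {"deriv": 2})])


def top_bands(wavelengths: np.ndarray, diff: np.ndarray, k: int = 5) -> list[str]:
    idx = np.argsort(np.abs(diff))[-k:][::-1]
    tags = band_assignments(wavelengths[idx])
    return [f"{wavelengths[i]:.1f}nm:{t or 'outside'}" for i, t in zip(idx, tags)]


def main() -> None:
    rows = []
    for name in ("plasma_ibd", "saliva_ibd"):
        win = subset_range(generate_cohort(preset(name, seed=SEED)), FIRST_OVERTONE)
        raw = class_mean_spectra(win, by="label2")
        diff_raw = raw.differences.loc["IBD-healthy"].to_numpy()
        deriv = class_mean_spectra(apply_pipeline(win, DERIV), by="label2")
        diff_d2 = deriv.differences.loc["IBD-healthy"].to_numpy()
        rows.append({
            "preset": name,
            "max_abs_diff_raw": float(np.abs(diff_raw).max()),
            "top5_raw": "; ".join(top_bands(win.wavelengths, diff_raw)),
            "top5_deriv2": "; ".join(top_bands(win.wavelengths, diff_d2)),
        })
        print(f"{name}: top raw-difference wavelengths -> {rows[-1]['top5_raw']}")

        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
            for cls in raw.means.index:
                axes[0].plot(win.wavelengths, raw.means.loc[cls], label=cls)
                axes[1].plot(win.wavelengths, deriv.means.loc[cls], label=cls)
            axes[0].set_ylabel("absorbance")
            axes[1].set_ylabel("2nd derivative")
            axes[1].set_xlabel("wavelength (nm)")
            axes[0].legend()
            axes[0].set_title(f"{name}: class mean spectra")
            fig.savefig(ROOT / "scratch" / f"{name}_means.png", dpi=110)
            plt.close(fig)
        except Exception as exc:  # plotting is best-effort
            print(f"(skipping figure: {exc})")
    (ROOT / "results").mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(ROOT / "results" / "spectral_differences.csv", index=False)
    print("wrote results/spectral_differences.csv")


if __name__ == "__main__":
    main()
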