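"""Water matrix coordinates (WAMACs) and aquagram computation.

Aquaphotomics reads the water absorbance spectrum of a biofluid as a
holistic biomarker: a perturbation such as disease reshuffles the
population of water molecular species (free water, solvation shells,
1-4 hydrogen-bonded clusters), which shifts absorbance inside twelve
characteristic sub-bands (C1..C12) of the 1300-1600 nm first overtone.
The aquagram displays, per sample class, the z-scored absorbance averaged
over each band: A'(lambda) = (A(lambda) - mu(lambda)) / sigma(lambda),
with mu and sigma taken over all spectra after scatter correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra_io import SpectraSet
from . import preprocess


@dataclass(frozen=True)
class WamacBand:
    """One water absorbance band: id C1..C12, nm range, structural assignment."""

    id: str
    low: float
    high: float
    assignment: str

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.id}: require low < high")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def width(self) -> float:
        return self.high - self.low


_WAMAC_BANDS = (
    WamacBand("C1", 1336.0, 1348.0, "2nu3: H2O asymmetric stretching vibration"),
    WamacBand("C2", 1360.0, 1366.0, "OH-.(H2O)1,2,4: water solvation shell"),
    WamacBand("C3", 1370.0, 1376.0,
              "nu1 + nu3: H2O symmetric and asymmetric stretching vibration"),
    WamacBand("C4", 1380.0, 1388.0,
              "OH-.(H2O)1,4: water solvation shell; O2-.(H2O)4 hydrated "
              "superoxide clusters; 2nu1: H2O symmetric stretching"),
    WamacBand("C5", 1398.0, 1418.0,
              "water confined in a local field of ions (trapped water); "
              "S0: free water; water with free OH-"),
    WamacBand("C6", 1421.0, 1430.0, "water hydration band, H-OH bend and O-H...O"),
    WamacBand("C7", 1432.0, 1444.0, "S1: water molecules with 1 hydrogen bond"),
    WamacBand("C8", 1448.0, 1454.0, "OH-.(H2O)4,5: water solvation shell"),
    WamacBand("C9", 1458.0, 1468.0,
              "S2: water molecules with 2 hydrogen bonds; 2nu2 + nu3: "
              "H2O bending and asymmetric stretching"),
    WamacBand("C10", 1472.0, 1482.0, "S3: water molecules with 3 hydrogen bonds"),
    WamacBand("C11", 1482.0, 1495.0, "S4: water molecules with 4 hydrogen bonds"),
    WamacBand("C12", 1506.0, 1516.0,
              "nu1: H2O symmetric stretching; nu2: H2O bending; strongly bonded water"),
)

BAND_IDS = tuple(b.id for b in _WAMAC_BANDS)


def wamac_table() -> list[WamacBand]:
    """The 12 water matrix coordinates with their nm ranges and assignments."""
    return list(_WAMAC_BANDS)


def band_assignments(wavelengths: np.ndarray) -> np.ndarray:
    """Band id per wavelength ("" where no band covers it).

    Membership is closed on both ends; the single shared boundary between
    consecutive printed ranges (1482 nm, ending C10 and starting C11) is
    resolved to the lower band so every wavelength has at most one band.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    out = np.full(wavelengths.shape, "", dtype=object)
    for band in _WAMAC_BANDS:
        mask = (wavelengths >= band.low) & (wavelengths <= band.high) & (out == "")
        out[mask] = band.id
    return out


def extract_wamac(s: SpectraSet) -> SpectraSet:
    """Restrict a spectra set to the wavelengths inside the 12 WAMAC bands.

    The result keeps the original grid points that fall in a band (gapped
    grid); :func:`band_assignments` recovers the band tag per column.
    """
    tags = band_assignments(s.wavelengths)
    mask = tags != ""
    if not mask.any():
        raise ValueError("grid does not overlap any WAMAC band")
    return SpectraSet(s.wavelengths[mask], s.absorbance[:, mask], s.meta, allow_gaps=True)


@dataclass
class AquagramResult:
    """Aquagram values per class and band, plus the per-wavelength z-matrix."""

    band_ids: list[str]
    classes: list[str]
    values: pd.DataFrame          # index class, columns band id
    aprime: np.ndarray            # (n_spectra, n_wamac_wavelengths)
    wavelengths: np.ndarray       # the WAMAC wavelengths, ascending
    wavelength_bands: np.ndarray  # band id per column of aprime

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: class, band_id, value."""
        long = self.values.reset_index(names="class").melt(
            id_vars="class", var_name="band_id", value_name="value"
        )
        order = {b: i for i, b in enumerate(self.band_ids)}
        long["_o"] = long["band_id"].map(order)
        return long.sort_values(["class", "_o"]).drop(columns="_o").reset_index(drop=True)


def aquagram(s: SpectraSet, class_field: str = "label2", scatter: str = "msc") -> AquagramResult:
    """Compute aquagram values per class over the 12 WAMAC bands.

    Spectra are scatter-corrected (MSC against the dataset mean, or SNV),
    restricted to the WAMAC wavelengths, and z-scored per wavelength over
    *all* spectra (sample sd).  Each class/band cell is the mean z-score over
    that class's spectra and the band's wavelengths.
    """
    if s.n_spectra < 2:
        raise ValueError("aquagram needs at least 2 spectra")
    if scatter == "msc":
        corrected = preprocess.msc(s.absorbance, reference="mean")
    elif scatter == "snv":
        corrected = preprocess.snv(s.absorbance)
    elif scatter == "none":  # spectra already scatter-corrected upstream
        corrected = s.absorbance
    else:
        raise ValueError(
            f"unknown scatter correction {scatter!r} (use 'msc', 'snv' or 'none')")

    tags = band_assignments(s.wavelengths)
    mask = tags != ""
    if not mask.any():
        raise ValueError("grid does not overlap any WAMAC band")
    wl = s.wavelengths[mask]
    bands_per_wl = tags[mask]
    a = corrected[:, mask]
    mu = a.mean(axis=0)
    sigma = a.std(axis=0, ddof=1)
    if np.any(sigma <= 0):
        bad = wl[np.flatnonzero(sigma <= 0)[0]]
        raise ValueError(f"zero standard deviation at {bad} nm; aquagram undefined")
    aprime = (a - mu) / sigma

    labels = s.labels(class_field)
    classes = sorted(set(labels))
    present = [b for b in BAND_IDS if b in set(bands_per_wl)]
    values = pd.DataFrame(index=classes, columns=present, dtype=float)
    for c in classes:
        rows = aprime[labels == c]
        for b in present:
            values.loc[c, b] = rows[:, bands_per_wl == b].mean()
    return AquagramResult(present, classes, values, aprime, wl, bands_per_wl)


def plot_aquagram(result: AquagramResult, path) -> None:
    """Radar chart: 12 spokes C1..C12, one trace per class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(result.band_ids)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    for c in result.classes:
        vals = result.values.loc[c].to_numpy(dtype=float)
        ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]], label=c)
    ax.set_xticks(angles)
    ax.set_xticklabels(result.band_ids)
    ax.set_title("Aquagram (z-scored band absorbance)")
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1))
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
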