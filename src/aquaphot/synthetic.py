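"""Seeded synthetic cohorts of water-dominated NIR biofluid spectra.

Blood plasma and saliva are ~91% and ~99% water, so their 1300-1600 nm
absorbance is dominated by the first overtone of the water OH stretch,
peaking near 1450 nm.  The generator models a spectrum as one broad
Gaussian at 1450 nm plus one narrower Gaussian per WAMAC band (centered at
the band midpoint), and encodes disease as class-dependent fractional
shifts of the band amplitudes — the water spectral pattern a diagnosis
would read.  On top of the class signal it layers:

* subject-level jitter on the class effect (subjects of one class are not
  identical) plus a small class-independent per-subject band perturbation,
  giving the subject > replicate variance structure that makes
  replicate-leakage tests meaningful;
* multiplicative and additive scatter per replicate — exactly the
  artifacts SNV/MSC are designed to remove;
* iid Gaussian instrument noise.

Everything is deterministic given ``CohortSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .aquaphotomics import BAND_IDS, wamac_table
from .spectra_io import SpectraSet

#: broad OH first-overtone component: center, sigma (nm), amplitude (AU)
WATER_PEAK_CENTER = 1450.0
WATER_PEAK_SIGMA = 45.0
WATER_PEAK_AMPLITUDE = 1.0

#: amplitude of each WAMAC band component, absorbance units
BAND_AMPLITUDE = 0.06

#: default class effect magnitude: fractional shift of a band amplitude
DEFAULT_EFFECT = 0.05


@dataclass(frozen=True)
class BandComponent:
    """One Gaussian absorbance component of the synthetic water spectrum."""

    center: float
    width: float
    base_amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.base_amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        z = (np.asarray(wavelengths, dtype=float) - self.center) / self.width
        return self.base_amplitude * np.exp(-0.5 * z * z)


def band_components() -> list[BandComponent]:
    """One component per WAMAC band: center = band midpoint, sigma = half width."""
    return [BandComponent(b.center, b.width / 2.0, BAND_AMPLITUDE) for b in wamac_table()]


def water_base_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Baseline water absorbance: broad 1450 nm peak + 12 WAMAC components.

    The global maximum lies at the grid point nearest 1450 nm (the broad
    component dominates everything else).
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size == 0:
        raise ValueError("empty wavelength vector")
    if wavelengths.min() < 1200 or wavelengths.max() > 1700:
        raise ValueError("generator is parameterized for 1200-1700 nm")
    broad = BandComponent(WATER_PEAK_CENTER, WATER_PEAK_SIGMA, WATER_PEAK_AMPLITUDE)
    out = broad.profile(wavelengths)
    for comp in band_components():
        out = out + comp.profile(wavelengths)
    return out


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``effects`` maps class name -> {band id -> fractional amplitude shift}.
    Class keys follow label3 (healthy/CD/UC); an ``IBD`` entry acts as the
    shared disease direction used for CD/UC subjects that have no explicit
    override.  ``noise_sd`` is instrument noise in absorbance units
    (per-point sd) with spectral correlation length
    ``noise_correlation_nm`` — slow-scan spectrophotometer noise is
    smooth in wavelength, not independent per point (0 gives iid noise);
    ``scatter_slope_sd``/``scatter_offset_sd`` control per-replicate
    multiplicative/additive scatter; ``subject_jitter`` scales the class
    effect per subject (sd as a fraction of the effect) and
    ``subject_band_sd`` adds a class-independent per-subject band
    perturbation (subject identity signal).
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"healthy": 3, "CD": 2, "UC": 8})
    replicates: int = 3
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 2.5e-4
    noise_correlation_nm: float = 5.0
    scatter_slope_sd: float = 0.02
    scatter_offset_sd: float = 0.005
    subject_jitter: float = 0.1
    subject_band_sd: float = 0.002
    grid_low: float = 1280.0
    grid_high: float = 1630.0
    grid_step: float = 0.5
    specimen: str = "plasma"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for cls, n in self.n_per_class.items():
            if n < 0:
                raise ValueError(f"negative subject count for class {cls!r}")
        known = set(BAND_IDS)
        for cls, bands in self.effects.items():
            bad = set(bands) - known
            if bad:
                raise ValueError(f"unknown band id(s) in effects[{cls!r}]: {sorted(bad)}")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.grid_high - self.grid_low) / self.grid_step)) + 1
        return self.grid_low + self.grid_step * np.arange(n)

    def class_effect(self, label3: str) -> dict[str, float]:
        """Resolve the band-effect map for a subject's class (IBD fallback)."""
        if label3 in self.effects:
            return self.effects[label3]
        if label3 in ("CD", "UC") and "IBD" in self.effects:
            return self.effects["IBD"]
        return {}

    def to_yaml(self) -> str:
        d = {k: getattr(self, k) for k in (
            "n_per_class", "replicates", "effects", "noise_sd", "scatter_slope_sd",
            "scatter_offset_sd", "subject_jitter", "subject_band_sd",
            "grid_low", "grid_high", "grid_step", "specimen", "seed")}
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortSpec":
        return cls(**(yaml.safe_load(text) or {}))


def _plasma_effects(e: float) -> dict[str, dict[str, float]]:
    # healthy plasma: active bands C1-C4 and C8; in IBD those drop while the
    # strongly hydrogen-bonded species C11 (4 bonds) and C12 rise.  CD shifts
    # further toward bound water: C1-C8 down, C9-C12 up.
    ibd = {**{b: -e for b in ("C1", "C2", "C3", "C4", "C8")}, "C11": e, "C12": e}
    cd = {**{f"C{i}": -e for i in range(1, 9)}, **{f"C{i}": e for i in range(9, 13)}}
    return {"healthy": {}, "IBD": ibd, "UC": dict(ibd), "CD": cd}


def _saliva_effects(e: float) -> dict[str, dict[str, float]]:
    # saliva mirrors plasma: in IBD the 2-4-bonded and strongly bonded water
    # share (C9-C12) decreases while C1-C8 increase; CD shows a raised C6
    # hydration band with C9-C11 reduced.
    ibd = {**{f"C{i}": e for i in range(1, 9)}, **{f"C{i}": -e for i in range(9, 13)}}
    cd = {"C6": e, "C9": -e, "C10": -e, "C11": -e}
    return {"healthy": {}, "IBD": ibd, "UC": dict(ibd), "CD": cd}


PRESETS = ("plasma_ibd", "saliva_ibd", "null")


def preset(name: str, seed: int = 0, effect: float = DEFAULT_EFFECT) -> CohortSpec:
    """Named cohort recipes: plasma_ibd, saliva_ibd, or null (no class signal).

    All three use the study's cohort structure — 13 subjects (3 healthy,
    2 CD, 8 UC) with 3 replicate spectra each, n = 39 — and differ only in
    the class effect maps.  ``null`` zeroes every effect and is the type-I
    error control.
    """
    if name == "plasma_ibd":
        return CohortSpec(effects=_plasma_effects(effect), specimen="plasma", seed=seed)
    if name == "saliva_ibd":
        return CohortSpec(effects=_saliva_effects(effect), specimen="saliva", seed=seed)
    if name == "null":
        return CohortSpec(effects={}, specimen="plasma", seed=seed)
    raise ValueError(f"unknown preset {name!r} (choose from {PRESETS})")


def generate_cohort(spec: CohortSpec) -> SpectraSet:
    """Draw one cohort of replicate spectra according to ``spec``.

    Per subject: band effect = class effect * (1 + jitter) + subject band
    noise.  Per replicate: spectrum = slope * (base with scaled band
    amplitudes) + offset + iid noise, slope ~ 1 + N(0, scatter_slope_sd),
    offset ~ N(0, scatter_offset_sd).  Bit-identical given the same seed.
    """
    rng = np.random.default_rng(spec.seed)
    wl = spec.wavelengths
    broad = BandComponent(WATER_PEAK_CENTER, WATER_PEAK_SIGMA, WATER_PEAK_AMPLITUDE)
    broad_profile = broad.profile(wl)
    comps = band_components()
    profiles = np.stack([c.profile(wl) for c in comps])  # (12, n_wl)

    # smoothing kernel for spectrally correlated instrument noise
    kernel = None
    if spec.noise_sd > 0 and spec.noise_correlation_nm > 0 and wl.size > 1:
        step = wl[1] - wl[0]
        sigma_pts = spec.noise_correlation_nm / step
        half = int(np.ceil(4 * sigma_pts))
        if wl.size > 2 * half:  # grids too short to smooth fall back to iid
            t = np.arange(-half, half + 1)
            kernel = np.exp(-0.5 * (t / sigma_pts) ** 2)
            kernel /= np.sqrt(np.sum(kernel**2))  # unit-variance-preserving

    rows, meta_rows = [], []
    subject_no = 0
    for cls in sorted(spec.n_per_class):
        if cls not in ("healthy", "CD", "UC"):
            raise ValueError(f"unknown class name {cls!r} (expected healthy/CD/UC)")
        class_eff = spec.class_effect(cls)
        eff_vec = np.array([class_eff.get(b, 0.0) for b in BAND_IDS])
        for _ in range(spec.n_per_class[cls]):
            subject_no += 1
            sid = f"{cls}{subject_no:02d}"
            jitter = rng.normal(0.0, spec.subject_jitter)
            subj_noise = rng.normal(0.0, spec.subject_band_sd, size=len(BAND_IDS)) \
                if spec.subject_band_sd > 0 else np.zeros(len(BAND_IDS))
            subj_eff = eff_vec * (1.0 + jitter) + subj_noise
            base = broad_profile + (1.0 + subj_eff) @ profiles
            for rep in range(1, spec.replicates + 1):
                slope = 1.0 + rng.normal(0.0, spec.scatter_slope_sd)
                offset = rng.normal(0.0, spec.scatter_offset_sd)
                if spec.noise_sd > 0:
                    white = rng.normal(0.0, spec.noise_sd, size=wl.size)
                    if kernel is not None:
                        pad = len(kernel) // 2
                        padded = np.r_[white[pad:0:-1], white, white[-2:-pad - 2:-1]]
                        noise = np.convolve(padded, kernel, mode="valid")
                    else:
                        noise = white
                else:
                    noise = 0.0
                rows.append(slope * base + offset + noise)
                meta_rows.append({
                    "id": f"{sid}:{rep}", "subject_id": sid, "replicate": rep,
                    "specimen": spec.specimen, "label3": cls,
                })
    if not rows:
        raise ValueError("cohort spec yields zero spectra")
    return SpectraSet(wl, np.vstack(rows), pd.DataFrame(meta_rows))


def null_like(spec: CohortSpec, seed: int | None = None) -> CohortSpec:
    """Same cohort structure with all class effects removed."""
    return replace(spec, effects={}, seed=spec.seed if seed is None else seed)
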