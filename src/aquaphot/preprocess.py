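"""Chemometric pretreatment operators for NIR spectra.

Every operator named in the analysis is implemented as a composable
transform over a spectra matrix (rows = spectra): standard normal variate
(SNV), multiplicative scatter correction (MSC), Savitzky-Golay smoothing
and derivatives, normalization variants, polynomial detrending, two-point
linear baseline correction and the absorbance/transmittance conversions.

Two calling surfaces exist:

* plain functions on arrays (``snv``, ``msc``, ``savgol`` ...), each
  preserving the wavelength grid;
* :class:`PreprocessSpec`, an ordered list of named steps that can be
  fitted on a calibration set (:func:`fit_pipeline`) and then applied to
  held-out spectra without touching their statistics — MSC's reference
  spectrum is the only stateful quantity, and it is always estimated from
  the training spectra alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import yaml
from scipy.signal import savgol_filter

STEP_NAMES = (
    "snv", "msc", "normalize", "smooth", "savgol_derivative",
    "detrend", "baseline_linear", "to_transmittance", "to_absorbance",
)


def _as2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum (x - mean) / sd, sample sd.

    Removes multiplicative and additive scatter; output rows have mean 0
    and sd 1.  A constant spectrum has zero variance and is rejected.
    """
    a, squeeze = _as2d(x)
    if a.shape[1] < 2:
        raise ValueError("snv needs at least 2 wavelengths")
    sd = a.std(axis=1, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero variance: constant spectrum has no SNV transform")
    out = (a - a.mean(axis=1, keepdims=True)) / sd[:, None]
    return out[0] if squeeze else out


def msc(x: np.ndarray, reference: np.ndarray | str = "mean") -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum is regressed on the reference, ``x ~ a + b * ref``, and
    corrected as ``(x - a) / b``.  The reference defaults to the mean
    spectrum of ``x`` itself; pass an explicit vector (e.g. a calibration
    mean) to correct held-out spectra without leakage.
    """
    a, squeeze = _as2d(x)
    if a.shape[1] < 2:
        raise ValueError("msc needs at least 2 wavelengths")
    ref = a.mean(axis=0) if isinstance(reference, str) and reference == "mean" \
        else np.asarray(reference, dtype=float)
    if ref.shape != (a.shape[1],):
        raise ValueError("reference length does not match the wavelength grid")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise ValueError("reference spectrum has zero variance")
    slopes = (a - a.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(slopes) < 1e-12):
        raise ValueError("degenerate slope in MSC fit (|b| < 1e-12)")
    intercepts = a.mean(axis=1) - slopes * ref.mean()
    out = (a - intercepts[:, None]) / slopes[:, None]
    return out[0] if squeeze else out


def savgol(x: np.ndarray, window_points: int = 13, poly_order: int = 2,
           deriv: int = 0, step: float = 1.0) -> np.ndarray:
    """Savitzky-Golay filter: windowed polynomial least squares.

    At each point the ``deriv``-th derivative of the local polynomial fit is
    evaluated at the window center, scaled by ``step**(-deriv)`` so that
    derivative units are per nm.  An even ``window_points`` is widened by one
    (symmetric windows need an odd length).  Edges use polynomial
    extrapolation from the first/last full window.
    """
    a, squeeze = _as2d(x)
    if window_points % 2 == 0:
        window_points += 1
    if window_points > a.shape[1]:
        raise ValueError(
            f"window of {window_points} points exceeds spectrum length {a.shape[1]}"
        )
    if poly_order >= window_points:
        raise ValueError("poly_order must be smaller than the window")
    if deriv > poly_order:
        raise ValueError("derivative order cannot exceed poly_order")
    if step <= 0:
        raise ValueError("step must be positive (nm)")
    out = savgol_filter(a, window_points, poly_order, deriv=deriv,
                        delta=step, axis=1, mode="interp")
    return out[0] if squeeze else out


def normalize(x: np.ndarray, method: str = "unit_vector", step: float = 1.0) -> np.ndarray:
    """Per-spectrum normalization: unit_vector (L2), min_max, or area."""
    a, squeeze = _as2d(x)
    if method == "unit_vector":
        norms = np.linalg.norm(a, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero spectrum has no unit-vector normalization")
        out = a / norms[:, None]
    elif method == "min_max":
        lo, hi = a.min(axis=1, keepdims=True), a.max(axis=1, keepdims=True)
        if np.any(hi == lo):
            raise ValueError("constant spectrum has no min-max normalization")
        out = (a - lo) / (hi - lo)
    elif method == "area":
        area = a.sum(axis=1) * step
        if np.any(area == 0):
            raise ValueError("zero-area spectrum has no area normalization")
        out = a / area[:, None]
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return out[0] if squeeze else out


def detrend(x: np.ndarray, order: int = 1, wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Subtract the least-squares polynomial of the given order per spectrum."""
    a, squeeze = _as2d(x)
    if order < 0 or order >= a.shape[1]:
        raise ValueError("order must be in [0, n_points)")
    t = np.arange(a.shape[1], dtype=float) if wavelengths is None \
        else np.asarray(wavelengths, dtype=float)
    # shared Vandermonde least squares for all rows
    v = np.vander(t - t.mean(), order + 1)
    coef, *_ = np.linalg.lstsq(v, a.T, rcond=None)
    out = a - (v @ coef).T
    return out[0] if squeeze else out


def baseline_linear(x: np.ndarray) -> np.ndarray:
    """Subtract the straight line through the first and last points."""
    a, squeeze = _as2d(x)
    if a.shape[1] < 2:
        raise ValueError("baseline correction needs at least 2 points")
    n = a.shape[1]
    frac = np.arange(n) / (n - 1)
    line = a[:, [0]] + (a[:, [-1]] - a[:, [0]]) * frac
    out = a - line
    return out[0] if squeeze else out


def to_transmittance(x: np.ndarray) -> np.ndarray:
    """Absorbance to transmittance, T = 10^(-A)."""
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite absorbance")
    return np.power(10.0, -a)


def to_absorbance(x: np.ndarray) -> np.ndarray:
    """Transmittance to absorbance, A = -log10(T); requires T > 0."""
    t = np.asarray(x, dtype=float)
    if np.any(t <= 0):
        raise ValueError("transmittance must be positive")
    return -np.log10(t)


# ---------------------------------------------------------------------------
# Pipelines


@dataclass
class PreprocessSpec:
    """Ordered, parameterized pretreatment recipe.

    ``steps`` is a list of ``(name, params)`` pairs drawn from the closed
    operator set; e.g. ``[("snv", {}), ("msc", {})]`` is the SNV-MSC recipe.
    """

    steps: list[tuple[str, dict[str, Any]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        norm = []
        for entry in self.steps:
            if isinstance(entry, str):
                name, params = entry, {}
            elif isinstance(entry, dict):
                name = entry["name"]
                params = {k: v for k, v in entry.items() if k != "name"}
            else:
                name, params = entry
            if name not in STEP_NAMES:
                raise ValueError(f"unknown pretreatment step {name!r}")
            norm.append((name, dict(params)))
        self.steps = norm

    @property
    def tag(self) -> str:
        """Short human-readable label, e.g. ``snv-msc`` (``raw`` if empty)."""
        return "-".join(n for n, _ in self.steps) or "raw"

    def to_yaml(self) -> str:
        return yaml.safe_dump({"steps": [{"name": n, **p} for n, p in self.steps]},
                              sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PreprocessSpec":
        data = yaml.safe_load(text) or {}
        return cls(steps=data.get("steps", []))


class FittedPipeline:
    """A pretreatment recipe with its train-set statistics frozen.

    Stateless steps apply identically everywhere; MSC stores the reference
    spectrum (the calibration mean after the preceding steps) so test
    spectra never contribute to any fitted statistic.
    """

    def __init__(self, spec: PreprocessSpec, fitted_params: list[dict[str, Any]]):
        self.spec = spec
        self._fitted = fitted_params

    def transform_matrix(self, x: np.ndarray, step: float) -> np.ndarray:
        a = np.asarray(x, dtype=float)
        for (name, params), fitted in zip(self.spec.steps, self._fitted):
            a = _apply_step(a, name, params, fitted, step)
        return a

    def transform(self, s):
        return s.with_absorbance(self.transform_matrix(s.absorbance, s.step or 1.0))


def _apply_step(a: np.ndarray, name: str, params: dict, fitted: dict, step: float) -> np.ndarray:
    if name == "snv":
        return snv(a)
    if name == "msc":
        return msc(a, reference=fitted.get("reference", "mean"))
    if name == "normalize":
        return normalize(a, method=params.get("method", "unit_vector"), step=step)
    if name == "smooth":
        return savgol(a, params.get("window_points", 13), params.get("poly_order", 2),
                      deriv=0, step=step)
    if name == "savgol_derivative":
        return savgol(a, params.get("window_points", 13), params.get("poly_order", 2),
                      deriv=params.get("deriv", 1), step=step)
    if name == "detrend":
        return detrend(a, order=params.get("order", 1))
    if name == "baseline_linear":
        return baseline_linear(a)
    if name == "to_transmittance":
        return to_transmittance(a)
    if name == "to_absorbance":
        return to_absorbance(a)
    raise ValueError(f"unknown step {name!r}")  # pragma: no cover


def fit_pipeline(train, spec: PreprocessSpec) -> FittedPipeline:
    """Fit dataset-level statistics on the calibration set only.

    ``train`` is a SpectraSet (or matrix); steps run in order on the
    training spectra, and each MSC step freezes the training mean spectrum
    at that point in the chain as its reference.
    """
    a = train.absorbance if hasattr(train, "absorbance") else np.asarray(train, dtype=float)
    step = train.step if hasattr(train, "step") else 1.0
    step = step or 1.0
    fitted: list[dict[str, Any]] = []
    for name, params in spec.steps:
        f: dict[str, Any] = {}
        if name == "msc":
            f["reference"] = a.mean(axis=0)
        fitted.append(f)
        a = _apply_step(a, name, params, f, step)
    return FittedPipeline(spec, fitted)


def apply_pipeline(s, spec: PreprocessSpec):
    """Fit on the given set and transform it (convenience for whole-set use)."""
    return fit_pipeline(s, spec).transform(s)
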