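"""Spectra containers and table I/O.

A :class:`SpectraSet` holds a uniform wavelength grid (nm), an absorbance
matrix with one row per replicate spectrum, and a per-spectrum metadata
table carrying subject identity, replicate index, specimen type and the
diagnostic label at two granularities (three-class healthy/CD/UC and the
derived two-class healthy/IBD).  Every downstream stage — pretreatment,
PCA, classification, aquagram — consumes and emits this object.

Spectra travel as wide CSV (first column ``id``, remaining columns numeric
wavelengths in nm); metadata as a CSV keyed by the same ``id``.  A spectrum
id is ``subject_id:replicate`` — replicates are distinct rows and are never
silently averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_LABEL3 = ("healthy", "CD", "UC")
VALID_SPECIMEN = ("plasma", "saliva")

#: tolerance on wavelength-grid uniformity, nm
_GRID_TOL = 1e-9

META_COLUMNS = ["id", "subject_id", "replicate", "specimen", "label3"]


def label2_from_label3(label3: Iterable[str]) -> list[str]:
    """Collapse the three-class label to healthy/IBD (CD or UC -> IBD)."""
    out = []
    for v in label3:
        if v == "healthy":
            out.append("healthy")
        elif v in ("CD", "UC"):
            out.append("IBD")
        else:
            raise ValueError(f"unknown label3 value: {v!r}")
    return out


@dataclass(frozen=True)
class WavelengthRange:
    """Closed wavelength interval [low, high] in nm."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"require low < high, got [{self.low}, {self.high}]")


#: the analysis window used throughout: first overtone of the water OH stretch
FIRST_OVERTONE = WavelengthRange(1300.0, 1600.0)


@dataclass
class SpectraSet:
    """Wavelength grid + absorbance matrix + per-spectrum metadata.

    Parameters
    ----------
    wavelengths
        Strictly increasing, uniformly spaced grid in nm.
    absorbance
        ``(n_spectra, n_wavelengths)`` matrix of unitless absorbance A.
    meta
        One row per spectrum with columns ``id, subject_id, replicate,
        specimen, label3``; ``label2`` is derived on construction.
    allow_gaps
        Band-restricted sets (e.g. WAMAC-only wavelengths) have a gapped
        grid; set True to relax the uniform-spacing invariant while keeping
        strict ascending order.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavelengths.ndim != 1 or self.wavelengths.size == 0:
            raise ValueError("wavelengths must be a non-empty 1-D vector")
        if self.wavelengths.size > 1:
            d = np.diff(self.wavelengths)
            if np.any(d <= 0):
                raise ValueError("wavelengths must be strictly increasing")
            if not self.allow_gaps and np.ptp(d) > _GRID_TOL:
                raise ValueError("wavelength spacing is not uniform")
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but grid has "
                f"{self.wavelengths.size} points"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        meta = self.meta.reset_index(drop=True).copy()
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if len(meta) != self.absorbance.shape[0]:
            raise ValueError(
                f"{self.absorbance.shape[0]} spectra but {len(meta)} metadata rows"
            )
        if meta["id"].duplicated().any():
            dup = meta.loc[meta["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate spectrum id: {dup!r}")
        bad = set(meta["specimen"]) - set(VALID_SPECIMEN)
        if bad:
            raise ValueError(f"unknown specimen value(s): {sorted(bad)}")
        meta["replicate"] = meta["replicate"].astype(int)
        if (meta["replicate"] < 1).any():
            raise ValueError("replicate indices must be >= 1")
        # label2 is always (re)derived: it is a pure function of label3
        meta["label2"] = label2_from_label3(meta["label3"])
        self.meta = meta

    # -- basic introspection -------------------------------------------------

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    @property
    def step(self) -> float:
        """Grid spacing in nm (smallest gap for gapped grids; 0 for 1 point)."""
        if self.n_wavelengths < 2:
            return 0.0
        return float(np.min(np.diff(self.wavelengths)))

    def labels(self, field_name: str = "label2") -> np.ndarray:
        return self.meta[field_name].to_numpy()

    # -- derived sets --------------------------------------------------------

    def with_absorbance(self, absorbance: np.ndarray, wavelengths: np.ndarray | None = None) -> "SpectraSet":
        """Same metadata, new absorbance matrix (and optionally new grid)."""
        wl = self.wavelengths if wavelengths is None else wavelengths
        return SpectraSet(np.array(wl, copy=True), np.array(absorbance, copy=True),
                          self.meta, allow_gaps=self.allow_gaps)

    def select_rows(self, index: Sequence[int] | np.ndarray) -> "SpectraSet":
        index = np.asarray(index, dtype=int)
        return SpectraSet(
            self.wavelengths.copy(),
            self.absorbance[index].copy(),
            self.meta.iloc[index],
            allow_gaps=self.allow_gaps,
        )

    def select_subjects(self, subjects: Iterable[str]) -> "SpectraSet":
        keep = set(subjects)
        mask = self.meta["subject_id"].isin(keep).to_numpy()
        if not mask.any():
            raise ValueError("no spectra for the requested subjects")
        return self.select_rows(np.flatnonzero(mask))

    def copy(self) -> "SpectraSet":
        return self.select_rows(np.arange(self.n_spectra))


# ---------------------------------------------------------------------------
# I/O


def read_spectra(path, meta_path) -> SpectraSet:
    """Read a wide spectra CSV plus its metadata CSV into a validated set.

    The spectra header row holds numeric wavelengths; columns are reordered
    to an ascending grid if needed.  Rows are aligned to metadata by ``id``;
    a spectrum without metadata (or vice versa) is an error.
    """
    wide = pd.read_csv(path, comment="#")
    if wide.shape[0] == 0:
        raise ValueError(f"no spectra in {path}")
    id_col = wide.columns[0]
    try:
        wl = np.array([float(c) for c in wide.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header cell in {path}: {exc}") from None
    if wl.size == 0:
        raise ValueError(f"no wavelength columns in {path}")
    order = np.argsort(wl)
    wl = wl[order]
    absorbance = wide.iloc[:, 1:].to_numpy(dtype=float)[:, order]
    ids = wide[id_col].astype(str)

    meta = pd.read_csv(meta_path, comment="#")
    meta["id"] = meta["id"].astype(str)
    missing_meta = set(ids) - set(meta["id"])
    if missing_meta:
        raise ValueError(f"spectra without metadata: {sorted(missing_meta)[:5]}")
    orphan_meta = set(meta["id"]) - set(ids)
    if orphan_meta:
        raise ValueError(f"metadata rows without spectra: {sorted(orphan_meta)[:5]}")
    meta = meta.set_index("id").loc[ids].reset_index()
    return SpectraSet(wl, absorbance, meta)


def write_spectra(s: SpectraSet, path, meta_path) -> None:
    """Write the wide spectra CSV and metadata CSV read by :func:`read_spectra`."""
    wide = pd.DataFrame(s.absorbance, columns=[f"{w:g}" for w in s.wavelengths])
    wide.insert(0, "id", s.meta["id"].to_numpy())
    wide.to_csv(path, index=False)
    s.meta[META_COLUMNS].to_csv(meta_path, index=False)


# ---------------------------------------------------------------------------
# Subsetting and aggregation


def subset_range(s: SpectraSet, r: WavelengthRange) -> SpectraSet:
    """Keep wavelengths with ``r.low <= lambda <= r.high`` (closed interval)."""
    mask = (s.wavelengths >= r.low) & (s.wavelengths <= r.high)
    if not mask.any():
        raise ValueError(f"range [{r.low}, {r.high}] nm does not overlap the grid")
    return SpectraSet(s.wavelengths[mask], s.absorbance[:, mask], s.meta)


@dataclass
class ClassMeans:
    """Per-class mean spectra and all pairwise difference spectra.

    ``means`` is indexed by class name over wavelength columns; ``differences``
    is indexed by ``"A-B"`` strings and holds mean(A) - mean(B).
    """

    wavelengths: np.ndarray
    means: pd.DataFrame
    differences: pd.DataFrame


def class_mean_spectra(s: SpectraSet, by: str = "label2") -> ClassMeans:
    """Arithmetic per-class mean spectra plus pairwise differences."""
    labels = s.labels(by)
    classes = sorted(set(labels))
    if not classes:
        raise ValueError("class with zero spectra: empty spectra set")
    rows = {}
    for c in classes:
        mask = labels == c
        if not mask.any():
            raise ValueError(f"class {c!r} has zero spectra")
        rows[c] = s.absorbance[mask].mean(axis=0)
    means = pd.DataFrame(rows, index=s.wavelengths).T
    diffs = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            diffs[f"{a}-{b}"] = rows[a] - rows[b]
    differences = pd.DataFrame(diffs, index=s.wavelengths).T if diffs else pd.DataFrame(
        np.empty((0, s.n_wavelengths)), columns=s.wavelengths
    )
    return ClassMeans(s.wavelengths.copy(), means, differences)


# ---------------------------------------------------------------------------
# Report output

REPORT_COLUMNS = [
    "model", "range", "pretreatment", "validation", "class",
    "sensitivity", "specificity", "total_accuracy", "standard_accuracy",
    "PCs", "r2", "rmsec", "status",
]


def write_results(report, path, seed: int | None = None) -> None:
    """Write a validation report as CSV (one row per grid cell per class).

    ``report`` may be a :class:`~aquaphot.validation.ValidationReport` or a
    DataFrame with the report columns.  Missing metrics are written as ``NA``
    (never coerced to 0).  When ``seed`` is given it is recorded in a comment
    header line so reruns are auditable.
    """
    frame = report.to_frame() if hasattr(report, "to_frame") else pd.DataFrame(report)
    if frame.shape[0] == 0:
        frame = pd.DataFrame(columns=REPORT_COLUMNS)
    for col in REPORT_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    frame = frame[REPORT_COLUMNS]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, index=False, na_rep="NA", float_format="%.3f")


def read_results(path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_results` output."""
    return pd.read_csv(path, comment="#", na_values=["NA"])
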