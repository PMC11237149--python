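"""Config-driven experiment grid.

Runs every (wavelength range x pretreatment x model x validation scheme)
cell of an experiment over one cohort — synthetic preset or CSV input —
and collects per-class sensitivity, specificity and total accuracy into a
single results table.  A failing cell (e.g. QDA on a fold where a 2-subject
class degenerates) is logged and reported as a failed row; the run
continues.  The whole grid is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import yaml

from . import synthetic
from .aquaphotomics import extract_wamac
from .preprocess import PreprocessSpec
from .spectra_io import FIRST_OVERTONE, SpectraSet, read_spectra, subset_range
from .validation import (
    ModelSpec,
    ValidationReport,
    external_validation,
    leave_one_out,
    split_calibration_test,
)

logger = logging.getLogger("aquaphot")

RANGE_TAGS = ("full_1300_1600", "wamac12")
VALIDATION_TAGS = ("loo", "external")


def _setup_logging() -> None:
    if not logger.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S"))
        logger.addHandler(h)
        logger.setLevel(logging.INFO)


@dataclass
class ExperimentConfig:
    """One experiment grid: data source plus the axes of the results table."""

    preset: str | None = "plasma_ibd"
    spectra_path: str | None = None
    meta_path: str | None = None
    label_scheme: str = "2class"            # "2class" (healthy/IBD) or "3class"
    ranges: list[str] = field(default_factory=lambda: list(RANGE_TAGS))
    pretreatments: list[PreprocessSpec] = field(
        default_factory=lambda: [PreprocessSpec([]), PreprocessSpec([("snv", {})])])
    models: list[str] = field(default_factory=lambda: ["LDA", "QDA", "SVM"])
    validations: list[str] = field(default_factory=lambda: ["loo"])
    loo_unit: str = "subject"
    test_fraction: float = 0.75
    pc_threshold: float = 99.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, values, allowed in (
            ("ranges", self.ranges, RANGE_TAGS),
            ("validations", self.validations, VALIDATION_TAGS),
        ):
            if not values:
                raise ValueError(f"{name} must be non-empty")
            bad = set(values) - set(allowed)
            if bad:
                raise ValueError(f"unknown {name} value(s): {sorted(bad)}")
        if not self.models or not self.pretreatments:
            raise ValueError("models and pretreatments must be non-empty")
        self.pretreatments = [
            p if isinstance(p, PreprocessSpec) else PreprocessSpec(p.get("steps", p))
            for p in self.pretreatments
        ]
        if self.label_scheme not in ("2class", "3class"):
            raise ValueError("label_scheme must be '2class' or '3class'")

    @property
    def label_field(self) -> str:
        return "label2" if self.label_scheme == "2class" else "label3"

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        data = yaml.safe_load(text) or {}
        if "pretreatments" in data:
            data["pretreatments"] = [
                PreprocessSpec(p.get("steps", []) if isinstance(p, dict) else p)
                for p in data["pretreatments"]
            ]
        return cls(**data)


def load_cohort(cfg: ExperimentConfig) -> SpectraSet:
    if cfg.spectra_path and cfg.meta_path:
        return read_spectra(cfg.spectra_path, cfg.meta_path)
    if cfg.preset:
        return synthetic.generate_cohort(synthetic.preset(cfg.preset, seed=cfg.seed))
    raise ValueError("config needs either a preset or spectra/meta paths")


def _ranged(s: SpectraSet, tag: str) -> SpectraSet:
    window = subset_range(s, FIRST_OVERTONE)
    return window if tag == "full_1300_1600" else extract_wamac(window)


def run_experiment(cfg: ExperimentConfig) -> ValidationReport:
    """Execute the grid and return the collected report."""
    _setup_logging()
    cohort = load_cohort(cfg)
    logger.info("cohort: %d spectra, %d subjects, seed=%d",
                cohort.n_spectra, cohort.meta["subject_id"].nunique(), cfg.seed)
    report = ValidationReport()
    ranged = {tag: _ranged(cohort, tag) for tag in cfg.ranges}
    for range_tag in cfg.ranges:
        data = ranged[range_tag]
        for pre in cfg.pretreatments:
            for model_name in cfg.models:
                mspec = ModelSpec(model_name)
                for val in cfg.validations:
                    try:
                        _run_cell(report, data, range_tag, pre, mspec, val, cfg)
                    except Exception as exc:  # failed cells are reported, not fatal
                        logger.warning("cell failed (%s, %s, %s, %s): %s",
                                       model_name, range_tag, pre.tag, val, exc)
                        report.add_failure(model_name, range_tag, pre.tag, val, str(exc))
    return report


def _run_cell(report: ValidationReport, data: SpectraSet, range_tag: str,
              pre: PreprocessSpec, mspec: ModelSpec, val: str,
              cfg: ExperimentConfig) -> None:
    from . import models as _models
    from .validation import fit_cell

    label_field = cfg.label_field
    if val == "loo":
        cm = leave_one_out(data, pre, mspec, unit=cfg.loo_unit,
                           label_field=label_field, pc_threshold=cfg.pc_threshold)
        cell = fit_cell(data, pre, mspec, label_field, cfg.pc_threshold)
        r2 = rmsec = None
        if mspec.kind == "SVM":
            r2, rmsec = _models.svm_regression_stats(
                cell.classifier, cell.calibration_scores(), data.labels(label_field))
        report.add_cell(mspec.kind, range_tag, pre.tag, "loo", cm,
                        k_pcs=cell.k, r2=r2, rmsec=rmsec)
    else:
        cal, test = split_calibration_test(data, cfg.test_fraction,
                                           seed=cfg.seed, label_field=label_field)
        cm, cell = external_validation(cal, test, pre, mspec,
                                       unit=cfg.loo_unit, label_field=label_field,
                                       pc_threshold=cfg.pc_threshold)
        r2 = rmsec = None
        if mspec.kind == "SVM":
            r2, rmsec = _models.svm_regression_stats(
                cell.classifier, cell.calibration_scores(), cal.labels(label_field))
        report.add_cell(mspec.kind, range_tag, pre.tag, "external", cm,
                        k_pcs=cell.k, r2=r2, rmsec=rmsec)
    logger.info("cell done: %s %s %s %s", mspec.kind, range_tag, pre.tag, val)
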