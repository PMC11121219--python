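"""End-to-end quantification, discrimination and index workflows.

Each workflow follows the same chemometric recipe: decimate the spectra
(keep every 10th point, 1501 -> 151), fit the pre-treatment chain on the
calibration rows only, partition samples with replicate-aware
Kennard-Stone, fit the linear SVM, and report the calibration diagnostics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .indices import augment_reference_table, index_of_mean_vs_mean_of_index
from .sampling import PartitionResult, split_spectra
from .spectra import (ParameterError, SpectraSet, TreatmentSpec, decimate_set,
                      fit_treatment, read_spectra_csv)
from .svm import (ModelSelectionCriteria, evaluate_classification,
                  evaluate_regression, fit_linear_svc, fit_linear_svr,
                  select_best_model, tune_C)

log = logging.getLogger("capranir")

__all__ = ["PipelineConfig", "run_quantification", "run_discrimination",
           "run_indices"]

DEFAULT_TREATMENTS = ("SM", "DV1", "DV2", "NORM-DV1", "MSC-SM", "MSC-DV1",
                      "SNV-SM", "ALS-SM", "SNV-DV1")
DEFAULT_TARGETS = ("pH", "L*", "a*", "b*", "protein", "IMF",
                   "C14:0", "C16:0", "C18:0", "C18:1n-9")


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from YAML."""

    spectra_csv: str | None = None
    reference_csv: str | None = None
    carcass_csv: str | None = None
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    discrimination_treatment: str = "SNV-DV1"
    decimation_step: int = 10
    n_train: int = 20
    n_test: int | None = 10
    feature_space: str = "reference"
    C_grid: tuple[float, ...] = (1.0, 10.0, 30.0, 100.0)
    svc_C: float = 1.0
    epsilon: float = 0.1
    r2_train_min: float = 0.95
    slope_train_min: float = 0.95
    r2_test_min: float = 0.90
    targets: tuple[str, ...] = DEFAULT_TARGETS
    seed: int = 42
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.treatments:
            raise ParameterError("treatment list must be non-empty")
        for t in self.treatments:
            TreatmentSpec.parse(t)  # validates codes
        TreatmentSpec.parse(self.discrimination_treatment)
        if self.decimation_step < 1:
            raise ParameterError("decimation_step must be >= 1")
        self.criteria  # validates thresholds

    @property
    def criteria(self) -> ModelSelectionCriteria:
        return ModelSelectionCriteria(
            r2_train_min=self.r2_train_min,
            slope_train_min=self.slope_train_min,
            r2_test_min=self.r2_test_min,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("treatments", "C_grid", "targets"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key in ("treatments", "C_grid", "targets"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _load_inputs(config: PipelineConfig,
                 spectra: SpectraSet | None,
                 refs: pd.DataFrame | None) -> tuple[SpectraSet, pd.DataFrame]:
    if spectra is None:
        if config.spectra_csv is None:
            raise ParameterError("no spectra provided (set spectra_csv)")
        spectra = read_spectra_csv(config.spectra_csv)
    if refs is None:
        if config.reference_csv is None:
            raise ParameterError("no reference table provided (set reference_csv)")
        refs = pd.read_csv(config.reference_csv)
    return spectra, refs


def _prepare(config: PipelineConfig, spectra: SpectraSet, refs: pd.DataFrame,
             ) -> tuple[SpectraSet, PartitionResult, np.ndarray, np.ndarray]:
    """Decimate and split; return the decimated set and train/test row indices."""
    reduced = decimate_set(spectra, config.decimation_step)
    log.info("decimated spectra: %d -> %d points",
             spectra.n_points, reduced.n_points)
    partition = split_spectra(
        reduced, refs, n_train=config.n_train, n_test=config.n_test,
        feature_space=config.feature_space,
    )
    train_rows = reduced.rows_for_samples(partition.train_sample_ids)
    test_rows = reduced.rows_for_samples(partition.test_sample_ids)
    log.info("Kennard-Stone split: %d train / %d test samples "
             "(%d / %d spectra)", len(partition.train_sample_ids),
             len(partition.test_sample_ids), train_rows.size, test_rows.size)
    return reduced, partition, train_rows, test_rows


def run_quantification(config: PipelineConfig,
                       spectra: SpectraSet | None = None,
                       refs: pd.DataFrame | None = None,
                       write: bool = True) -> dict:
    """Calibrate a linear SVR for every target variable under every treatment.

    Returns a dict with the full report table (one train and one test row
    per target x treatment), the winning (train, test) pair per target
    under the selection criteria, and the partition.
    """
    spectra, refs = _load_inputs(config, spectra, refs)
    missing = [t for t in config.targets if t not in refs.columns]
    if missing:
        raise ParameterError(f"reference table lacks target column(s): {missing}")
    reduced, partition, train_rows, test_rows = _prepare(config, spectra, refs)

    y_by_sample = refs.set_index("sample_id")
    rows = []
    pairs: dict[str, list] = {t: [] for t in config.targets}
    for treatment in config.treatments:
        treated, fitted = fit_treatment(reduced, treatment, fit_rows=train_rows)
        X_train = treated.matrix[train_rows]
        X_test = treated.matrix[test_rows]
        for target in config.targets:
            y_train = y_by_sample.loc[list(treated.sample_id[train_rows]), target].to_numpy(float)
            y_test = y_by_sample.loc[list(treated.sample_id[test_rows]), target].to_numpy(float)
            best_C = tune_C(X_train, y_train, config.C_grid, epsilon=config.epsilon)
            model = fit_linear_svr(X_train, y_train, C=best_C, epsilon=config.epsilon)
            rep_train = evaluate_regression(y_train, model.predict(X_train), "train")
            rep_test = evaluate_regression(y_test, model.predict(X_test), "test")
            for rep in (rep_train, rep_test):
                rep.treatment = treatment
                rep.best_C = best_C
                rep.parameter = target
                rows.append(rep.to_row())
            pairs[target].append((rep_train, rep_test))
            log.info("quantify %-10s %-9s C=%-5g RMSE_test=%.4f R2_test=%.4f",
                     target, treatment, best_C, rep_test.rmse, rep_test.r2)

    table = pd.DataFrame(rows)
    best = {}
    for target in config.targets:
        chosen = select_best_model(pairs[target], config.criteria)
        best[target] = chosen
        if chosen is None:
            log.info("select %-10s: no candidate met the criteria", target)
        else:
            log.info("select %-10s: %s (C=%g, RMSE_test=%.4f)", target,
                     chosen[0].treatment, chosen[0].best_C, chosen[1].rmse)

    result = {"reports": table, "best": best, "partition": partition}
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "quantification_reports.csv", index=False)
        best_rows = []
        for target, chosen in best.items():
            if chosen is None:
                best_rows.append({"Parameters": target, "Data Treatment": "none met criteria"})
            else:
                for rep in chosen:
                    best_rows.append(rep.to_row())
        pd.DataFrame(best_rows).to_csv(out / "quantification_best.csv", index=False)
        with open(out / "partition.json", "w") as fh:
            json.dump({
                "train": list(map(str, partition.train_sample_ids)),
                "test": list(map(str, partition.test_sample_ids)),
                "selection_order": list(map(str, partition.selection_order)),
            }, fh, indent=2)
    return result


def run_discrimination(config: PipelineConfig,
                       spectra: SpectraSet | None = None,
                       refs: pd.DataFrame | None = None,
                       write: bool = True) -> dict:
    """Breed discrimination with a linear SVC on pre-treated spectra."""
    spectra, refs = _load_inputs(config, spectra, refs)
    breeds = pd.unique(spectra.breed)
    if len(breeds) != 2:
        raise ParameterError(f"breed discrimination needs 2 breeds, got {len(breeds)}")
    reduced, partition, train_rows, test_rows = _prepare(config, spectra, refs)
    treated, fitted = fit_treatment(
        reduced, config.discrimination_treatment, fit_rows=train_rows)
    clf = fit_linear_svc(treated.matrix[train_rows], treated.breed[train_rows],
                         C=config.svc_C)
    rep_train = evaluate_classification(
        treated.breed[train_rows], clf.predict(treated.matrix[train_rows]), "train")
    rep_test = evaluate_classification(
        treated.breed[test_rows], clf.predict(treated.matrix[test_rows]), "test")
    log.info("discriminate %s: train %.1f%% / test %.1f%%",
             config.discrimination_treatment, rep_train.accuracy, rep_test.accuracy)
    result = {"train": rep_train, "test": rep_test, "partition": partition,
              "treatment": config.discrimination_treatment}
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([rep_train.to_row(), rep_test.to_row()]).to_csv(
            out / "discrimination_reports.csv", index=False)
    return result


def run_indices(config: PipelineConfig,
                refs: pd.DataFrame | None = None,
                carcass: pd.DataFrame | None = None,
                write: bool = True) -> dict:
    """Append derived colour/lipid/carcass columns and per-breed summaries."""
    if refs is None:
        if config.reference_csv is None:
            raise ParameterError("no reference table provided (set reference_csv)")
        refs = pd.read_csv(config.reference_csv)
    if carcass is None and config.carcass_csv is not None:
        carcass = pd.read_csv(config.carcass_csv)
    if carcass is not None:
        refs = refs.merge(
            carcass.drop(columns=[c for c in ("breed", "sex") if c in carcass.columns]),
            on="sample_id", how="left")
    augmented = augment_reference_table(refs)
    numeric = augmented.select_dtypes(include=[np.number]).columns
    by_breed = augmented.groupby("breed")[list(numeric)].mean()
    jensen = index_of_mean_vs_mean_of_index(augmented) if "C16:0" in augmented else None
    result = {"augmented": augmented, "by_breed": by_breed, "aggregation_gap": jensen}
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        augmented.to_csv(out / "reference_augmented.csv", index=False)
        by_breed.to_csv(out / "indices_by_breed.csv")
        if jensen is not None:
            jensen.to_csv(out / "indices_aggregation_gap.csv", index=False)
    return result
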