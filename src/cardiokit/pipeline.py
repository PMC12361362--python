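"""End-to-end orchestration: ingest -> select -> detect -> AF estimate -> report.

The pipeline mirrors the clinical decision flow: weighted feature selection
first, the binary detector next, and the AF-rate regression only for the rows
the detector labels positive (AF rate is only meaningful once disease is
detected).  Every stage is seeded from one configuration value, and the run
emits a JSON report holding the selected features, tuned hyperparameters,
metrics, split bookkeeping and convergence traces, so two runs with identical
configuration produce identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import adsvm, amccnet, eavsro, feature_weighting, metrics, synthetic_data
from .exceptions import DataError, MetricError
from .feature_weighting import FeatureTable

__all__ = ["PipelineConfig", "load_table", "run_pipeline"]

logger = logging.getLogger("cardiokit")


@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run."""

    input_csv: str | None = None
    output_dir: str = "cardiokit_out"
    label_col: str = "target"
    af_col: str | None = "af_rate"
    seed: int = 0
    population_size: int = 10
    max_iterations: int = 50
    selection_k: int = 10
    # hyperparameter tuning runs at a reduced budget: every candidate costs a
    # full model fit, so the tuning stages use a small population and few
    # generations while the cheap selection stage keeps the full budget
    tuning_population: int = 4
    detection_iterations: int = 3
    # the capsule regressor's trainable region (small Adam steps) is a narrow
    # slice of the tuned range, so its search screens many cheap candidates
    # (larger population, few epochs) and retrains the winner properly
    af_tuning_population: int = 10
    af_iterations: int = 4
    extractor_epochs: int = 100
    amccnet_epochs: int = 12       # candidate-screening epochs
    amccnet_final_epochs: int = 90  # winner retrain epochs
    af_max_rows: int = 320  # seeded cap on the capsule trainer's problem size
    run_selection: bool = True
    run_detection: bool = True
    run_af: bool = True
    percent: bool = True

    def optimizer_config(self, chromosome_length: int, seed_offset: int = 0,
                         max_iterations: int | None = None,
                         population_size: int | None = None) -> eavsro.OptimizerConfig:
        return eavsro.OptimizerConfig(
            population_size=population_size or self.population_size,
            max_iterations=max_iterations or self.max_iterations,
            chromosome_length=chromosome_length,
            seed=(self.seed + seed_offset) % (2**31),
        )


def load_table(path, config: PipelineConfig | None = None,
               label_col: str | None = None):
    """Read a CSV into a :class:`FeatureTable`.

    Numeric columns are coerced; missing numeric cells are filled with the
    column median (count logged); non-numeric columns are integer-encoded and
    the category mapping is returned alongside the table.  Returns
    ``(table, af_targets_or_None, encodings)``.
    """
    config = config or PipelineConfig()
    label_col = label_col or config.label_col
    frame = pd.read_csv(path)
    if frame.empty:
        raise DataError(f"{path}: empty input file")
    if label_col not in frame.columns:
        raise DataError(f"{path}: expected label column {label_col!r}; "
                        f"found {list(frame.columns)}")
    labels = frame.pop(label_col).astype(int).to_numpy()
    af = None
    if config.af_col and config.af_col in frame.columns:
        af = frame.pop(config.af_col).astype(float).to_numpy()

    encodings: dict[str, dict[str, int]] = {}
    imputed = 0
    for column in frame.columns:
        series = pd.to_numeric(frame[column], errors="coerce")
        if series.isna().all():  # fully non-numeric: categorical encoding
            codes, categories = pd.factorize(frame[column].astype(str))
            encodings[column] = {str(c): i for i, c in enumerate(categories)}
            frame[column] = codes.astype(float)
            continue
        n_missing = int(series.isna().sum())
        if n_missing:
            imputed += n_missing
            series = series.fillna(series.median())
        frame[column] = series
    if imputed:
        logger.info("imputed %d missing cells with column medians", imputed)
    table = FeatureTable(matrix=frame.to_numpy(dtype=float), labels=labels,
                         column_names=list(frame.columns))
    return table, af, encodings


def _detection_metrics(y_true, y_pred, percent: bool) -> dict:
    counts = metrics.confusion_from_labels(y_true, y_pred)
    scale = 100.0 if percent else 1.0
    report: dict = {}
    for name, fn, scaled in (("accuracy", metrics.accuracy, True),
                             ("precision", metrics.precision, True),
                             ("f1", metrics.f1, True),
                             ("mcc", metrics.mcc, False),
                             ("csi", metrics.csi, True),
                             ("fpr", metrics.fpr, True)):
        try:
            report[name] = fn(counts) * (scale if scaled else 1.0)
        except MetricError:
            report[name] = None  # undefined for this confusion pattern
    report["counts"] = {"tp": counts.tp, "tn": counts.tn,
                        "fp": counts.fp, "fn": counts.fn}
    return report


def _regression_metrics(actual, predicted, percent: bool) -> dict:
    report = {
        "rmse": metrics.rmse(actual, predicted),
        "mae": metrics.mae(actual, predicted),
        "smape": metrics.smape(actual, predicted) * (100.0 if percent else 1.0),
    }
    try:
        report["mpe"] = metrics.mpe(actual, predicted) * (100.0 if percent else 1.0)
    except MetricError:
        report["mpe"] = None  # zero actual rates present
    return report


def run_pipeline(config: PipelineConfig, table: FeatureTable | None = None,
                 af_targets: np.ndarray | None = None) -> dict:
    """Execute the configured stages and return (and persist) the report.

    Without an input table (and no ``input_csv``), a synthetic cohort with
    the default study shape is generated.  The AF stage consumes only rows the
    detector labelled positive; when there are none it is skipped with a
    logged notice.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if table is None:
        if config.input_csv:
            table, af_targets, _ = load_table(config.input_csv, config)
        else:
            spec = synthetic_data.SyntheticSpec(seed=config.seed)
            table = synthetic_data.generate_table(spec)
            af_targets = synthetic_data.attach_af_targets(table, spec)
            logger.info("no input CSV: generated the default synthetic cohort")

    report: dict = {
        "config": asdict(config),
        "n_rows": table.n_rows,
        "n_features": table.n_features,
    }

    if af_targets is not None:
        train, test, af_train, af_test = synthetic_data.split_80_20(
            table, seed=config.seed, af_targets=af_targets)
    else:
        train, test = synthetic_data.split_80_20(table, seed=config.seed)
        af_train = af_test = None
    report["split"] = {"train": train.n_rows, "test": test.n_rows}

    # stage 1: weighted optimal feature selection (on the training partition)
    if config.run_selection:
        selection = feature_weighting.select_weighted_features(
            train, config.optimizer_config(2 * config.selection_k, seed_offset=11),
            k=config.selection_k)
        report["selection"] = {
            "indices": selection.indices,
            "column_names": [table.column_names[i - 1] for i in selection.indices],
            "weights": [float(w) for w in selection.weights],
            "chi_square": float(selection.chi_square),
        }
        train_x = selection.transformed
        test_x = feature_weighting.apply_weights(
            test, selection.indices, selection.weights).transformed
    else:
        train_x, test_x = train.matrix, test.matrix

    results_paths = {}
    y_test_pred = None

    # stage 2: heart-disease detection
    if config.run_detection:
        model = adsvm.tune_adsvm(
            train_x, train.labels,
            config.optimizer_config(3, seed_offset=23,
                                    max_iterations=config.detection_iterations,
                                    population_size=config.tuning_population),
            epochs=config.extractor_epochs)
        y_test_pred = adsvm.predict(model, test_x)
        report["detection"] = {
            "hyperparams": asdict(model.hyperparams),
            "test": _detection_metrics(test.labels, y_test_pred, config.percent),
        }

    # stage 3: AF rate for predicted-positive rows only
    if config.run_af and af_train is not None:
        if y_test_pred is None:
            raise DataError("the AF stage requires the detection stage")
        positive = np.flatnonzero(y_test_pred == 1)
        if positive.size == 0:
            logger.info("no predicted positives: AF stage skipped")
            report["af"] = {"skipped": "no predicted positives"}
        else:
            af_input_train, af_input_eval = train_x, test_x[positive]
            if af_input_train.shape[1] < max(amccnet.KERNEL_SIZES):
                logger.info("selected representation narrower than the largest "
                            "stem kernel; AF stage falls back to the full matrix")
                af_input_train, af_input_eval = train.matrix, test.matrix[positive]
            af_train_used = af_train
            if af_input_train.shape[0] > config.af_max_rows:
                keep = np.random.default_rng(config.seed + 41).choice(
                    af_input_train.shape[0], size=config.af_max_rows, replace=False)
                af_input_train, af_train_used = af_input_train[keep], af_train[keep]
            af_model = amccnet.tune_amccnet(
                af_input_train, af_train_used,
                config.optimizer_config(3, seed_offset=37,
                                        max_iterations=config.af_iterations,
                                        population_size=config.af_tuning_population),
                epochs=config.amccnet_epochs,
                final_epochs=config.amccnet_final_epochs)
            af_pred = af_model.predict(af_input_eval)
            report["af"] = {
                "hyperparams": asdict(af_model.hp),
                "n_evaluated": int(positive.size),
                "test": _regression_metrics(af_test[positive], af_pred,
                                            config.percent),
            }

    report_path = out_dir / "report.json"
    with open(report_path, "w") as handle:
        json.dump(report, handle, indent=2, default=float)
    results_paths["report"] = str(report_path)
    report["paths"] = results_paths
    return report
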