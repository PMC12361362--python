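"""Weighted optimal feature selection driven by the metaheuristic.

A genome of 2K genes encodes K candidate feature indices (reals in [1, F],
rounded at decode time, duplicates dropped keeping the first occurrence) and K
matching weights in [0.01, 0.99].  The fitness of a genome is the reciprocal
of the summed chi-square association between each selected, weighted column
and the class label, so maximizing chi-square is equivalent to minimizing the
objective.  The winning genome's weights are multiplied elementwise into the
selected columns to produce the transformed matrix handed to the downstream
models.

Chi-square on a continuous column requires discretization: each weighted
column is shifted to be non-negative and binned at its quartiles (at most 4
bins; ties collapse duplicated edges).  Observed counts are the class-by-bin
contingency table; expected counts are the usual independence product of the
marginals.  Note that both the shift and the quartile binning are monotone
operations, so a positive weight cannot change a column's bin assignment: the
chi-square fitness is driven by *which* columns are selected, while the
weights scale the output representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import eavsro
from .exceptions import (ConfigurationError, DataError, DegenerateTargetError,
                         ShapeError)

__all__ = [
    "FeatureTable",
    "SelectionGenome",
    "WeightedFeatureSet",
    "WEIGHT_RANGE",
    "decode_genome",
    "chi_square_score",
    "selection_chi_square",
    "feature_fitness",
    "apply_weights",
    "select_weighted_features",
]

#: search range of the weight genes
WEIGHT_RANGE = (0.01, 0.99)

#: guard added to chi-square before taking the reciprocal
FITNESS_EPSILON = 1e-12

#: number of quantile bins used to discretize a weighted column
N_BINS = 4


@dataclass
class FeatureTable:
    """Patients-by-attributes matrix with an integer label vector.

    Labels are 0 (no disease) / 1 (disease); the severity variant allows
    0-4.  The matrix must be fully numeric and finite — imputation happens at
    the I/O layer, not here.
    """

    matrix: np.ndarray
    labels: np.ndarray
    column_names: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ShapeError("feature matrix must be 2-D")
        if self.labels.shape != (self.matrix.shape[0],):
            raise ShapeError("label length must equal the number of rows")
        if len(self.column_names) != self.matrix.shape[1]:
            raise ShapeError("one column name per matrix column required")
        if not np.all(np.isfinite(self.matrix)):
            raise DataError("feature matrix contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def take(self, row_indices) -> "FeatureTable":
        """A new table restricted to the given rows."""
        idx = np.asarray(row_indices)
        return FeatureTable(matrix=self.matrix[idx], labels=self.labels[idx],
                            column_names=list(self.column_names))


@dataclass(frozen=True)
class SelectionGenome:
    """K feature genes in [1, F] paired with K weight genes in [0.01, 0.99]."""

    feature_genes: np.ndarray
    weight_genes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "feature_genes",
                           np.asarray(self.feature_genes, dtype=float))
        object.__setattr__(self, "weight_genes",
                           np.asarray(self.weight_genes, dtype=float))
        if self.feature_genes.size == 0:
            raise ConfigurationError("genome must contain at least one gene pair")
        if self.feature_genes.shape != self.weight_genes.shape:
            raise ShapeError("feature and weight genes must have equal length")

    @property
    def k(self) -> int:
        return self.feature_genes.size


@dataclass
class WeightedFeatureSet:
    """The selection outcome: 1-based column indices, aligned weights, and the
    weighted (transformed) matrix."""

    indices: list[int]
    weights: np.ndarray
    transformed: np.ndarray
    chi_square: float | None = None
    seed: int | None = None

    def to_json(self, path) -> None:
        payload = {
            "indices": [int(i) for i in self.indices],
            "weights": [float(w) for w in self.weights],
            "chi_square": None if self.chi_square is None else float(self.chi_square),
            "seed": self.seed,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2)


def decode_genome(genome: SelectionGenome, n_features: int):
    """Round feature genes to integer column indices and drop duplicates.

    Each real-valued feature gene is rounded to the nearest integer and
    clipped into [1, n_features].  When several genes decode to the same
    index, the first occurrence (and its paired weight) is kept, so the
    selection may shrink below K but is never empty.
    """
    raw = np.clip(np.rint(genome.feature_genes).astype(int), 1, n_features)
    indices: list[int] = []
    weights: list[float] = []
    for idx, weight in zip(raw, genome.weight_genes):
        if int(idx) not in indices:
            indices.append(int(idx))
            weights.append(float(weight))
    return indices, np.asarray(weights)


def chi_square_score(observed, expected) -> float:
    """Sum of (observed - expected)^2 / expected over the cells."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ShapeError("observed and expected must have equal shape")
    bad = np.flatnonzero(expected <= 0)
    if bad.size:
        raise DataError(f"expected count must be positive (cell {int(bad[0])})")
    return float(np.sum((observed - expected) ** 2 / expected))


def _bin_column(values: np.ndarray) -> np.ndarray:
    """Quartile-bin a column (after shifting it non-negative).

    Returns integer bin ids; a constant column collapses to a single bin.
    """
    shifted = values - values.min()
    edges = np.unique(np.quantile(shifted, [0.25, 0.5, 0.75]))
    return np.digitize(shifted, edges, right=True)


def selection_chi_square(table: FeatureTable, indices, weights) -> float:
    """Summed chi-square association of each selected, weighted column with
    the label, via class-by-bin contingency tables."""
    classes = np.unique(table.labels)
    if classes.size < 2:
        raise DegenerateTargetError("chi-square needs at least two label classes")
    weights = np.asarray(weights, dtype=float)
    total = 0.0
    for idx, weight in zip(indices, weights):
        if not 1 <= idx <= table.n_features:
            raise ShapeError(f"feature index {idx} outside [1, {table.n_features}]")
        column = weight * table.matrix[:, idx - 1]
        bins = _bin_column(column)
        bin_ids = np.unique(bins)
        if bin_ids.size < 2:
            continue  # constant column: no association
        observed = np.zeros((classes.size, bin_ids.size))
        for ci, c in enumerate(classes):
            observed[ci] = np.array(
                [np.sum((table.labels == c) & (bins == b)) for b in bin_ids])
        row_tot = observed.sum(axis=1, keepdims=True)
        col_tot = observed.sum(axis=0, keepdims=True)
        expected = row_tot * col_tot / observed.sum()
        total += chi_square_score(observed.ravel(), expected.ravel())
    return total


def feature_fitness(table: FeatureTable, genome: SelectionGenome) -> float:
    """Reciprocal chi-square objective 1 / (chi2 + eps); lower is better."""
    indices, weights = decode_genome(genome, table.n_features)
    chi2 = selection_chi_square(table, indices, weights)
    return 1.0 / (chi2 + FITNESS_EPSILON)


def apply_weights(table: FeatureTable, indices, weights) -> WeightedFeatureSet:
    """Multiply each selected column by its weight to form the transformed
    matrix (one column per retained index)."""
    weights = np.asarray(weights, dtype=float)
    if len(indices) != weights.size:
        raise ShapeError("indices and weights must be aligned")
    for idx in indices:
        if not 1 <= idx <= table.n_features:
            raise ShapeError(f"feature index {idx} outside [1, {table.n_features}]")
    columns = [w * table.matrix[:, i - 1] for i, w in zip(indices, weights)]
    transformed = np.column_stack(columns) if columns else np.empty((table.n_rows, 0))
    return WeightedFeatureSet(indices=list(indices), weights=weights,
                              transformed=transformed)


def select_weighted_features(table: FeatureTable,
                             config: eavsro.OptimizerConfig | None = None,
                             k: int = 10) -> WeightedFeatureSet:
    """Optimize the 2K-gene selection problem and return the weighted set.

    Feature genes search [1, F]; weight genes search [0.01, 0.99].  The
    returned set carries the achieved chi-square and the seed for
    reproducibility.
    """
    if config is None:
        config = eavsro.OptimizerConfig()
    k = min(k, table.n_features) if k >= 1 else 1
    bounds = eavsro.Bounds(
        lower=np.concatenate([np.full(k, 1.0), np.full(k, WEIGHT_RANGE[0])]),
        upper=np.concatenate([np.full(k, float(table.n_features)),
                              np.full(k, WEIGHT_RANGE[1])]),
    )

    def objective(genes: np.ndarray) -> float:
        genome = SelectionGenome(feature_genes=genes[:k], weight_genes=genes[k:])
        return feature_fitness(table, genome)

    trace = eavsro.optimize(objective, bounds, config)
    best = trace.best_candidate.genes
    genome = SelectionGenome(feature_genes=best[:k], weight_genes=best[k:])
    indices, weights = decode_genome(genome, table.n_features)
    result = apply_weights(table, indices, weights)
    result.chi_square = selection_chi_square(table, indices, weights)
    result.seed = config.seed
    return result
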