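"""Synthetic tabular clinical fixtures with known generative structure.

The generator emulates the shape of the public heart-disease tables the
pipeline targets: ~14 numeric clinical attributes, a near-balanced binary
disease label (default exact class counts 500 absent / 526 present over 1026
rows), and an optional 5-class severity variant over 920 rows partitioned
into four source cohorts (303/294/123/200).  A small number of *informative*
columns (default 2, always the first columns) are drawn from class-conditional
normal distributions separated by a configurable effect size; all remaining
columns are class-independent standard-normal noise.  Knowing exactly which
columns carry signal is what makes feature-selection recovery testable.

Neither public dataset carries an atrial-fibrillation rate, so the AF target
is a declared synthetic construct with a documented closed form:

    af = sigmoid(0.8 * z1 + 0.6 * z2**2 - 0.5) + N(0, af_noise_sd),  clipped to [0, 1]

where z1, z2 are the standardized first two informative columns.  Tests and
parameter-recovery checks rely on this form; it stands in for a quantity the
reference datasets never define.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .exceptions import ConfigurationError
from .feature_weighting import FeatureTable

__all__ = [
    "SyntheticSpec",
    "SEVERITY_COHORTS",
    "generate_table",
    "generate_severity_table",
    "generate_separable_table",
    "attach_af_targets",
    "split_80_20",
    "af_truth",
]

# clinical-style attribute names, reused cyclically when n_features > 14
_ATTRIBUTE_NAMES = [
    "age", "trestbps", "chol", "thalach", "oldpeak", "sex", "cp", "fbs",
    "restecg", "exang", "slope", "ca", "thal", "hr_var",
]

#: source-cohort sizes of the 5-class severity variant (sum 920)
SEVERITY_COHORTS = {"cleveland": 303, "hungarian": 294, "switzerland": 123,
                    "va_long_beach": 200}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of one synthetic table."""

    n_rows: int = 1026
    n_features: int = 14
    n_informative: int = 2
    class_counts: tuple[int, int] = (500, 526)
    effect_size: float = 1.5
    noise_sd: float = 1.0
    af_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_features:
            raise ConfigurationError("n_informative cannot exceed n_features")
        if sum(self.class_counts) != self.n_rows:
            raise ConfigurationError(
                f"class counts {self.class_counts} must sum to n_rows={self.n_rows}")
        if self.n_features < 1 or self.n_rows < 2:
            raise ConfigurationError("need at least 1 feature and 2 rows")


def _column_names(n_features: int) -> list[str]:
    names = []
    for i in range(n_features):
        base = _ATTRIBUTE_NAMES[i % len(_ATTRIBUTE_NAMES)]
        names.append(base if i < len(_ATTRIBUTE_NAMES) else f"{base}_{i}")
    return names


def generate_table(spec: SyntheticSpec) -> FeatureTable:
    """Generate a binary-labelled table with exact class counts.

    The first ``spec.n_informative`` columns are informative: class 0 rows are
    drawn from N(0, noise_sd), class 1 rows from N(effect_size, noise_sd).
    All other columns are N(0, 1) regardless of class.  Row order is a seeded
    permutation, so the classes are interleaved.
    """
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.class_counts
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    matrix = rng.normal(0.0, 1.0, size=(spec.n_rows, spec.n_features))
    for j in range(spec.n_informative):
        shift = np.where(labels == 1, spec.effect_size, 0.0)
        matrix[:, j] = rng.normal(shift, spec.noise_sd)
    order = rng.permutation(spec.n_rows)
    return FeatureTable(matrix=matrix[order], labels=labels[order],
                        column_names=_column_names(spec.n_features))


def generate_severity_table(spec: SyntheticSpec | None = None,
                            seed: int = 0) -> tuple[FeatureTable, np.ndarray]:
    """5-class severity variant: 920 rows in four source cohorts.

    Returns the table (labels collapsed to binary: severity 0 vs >= 1) and the
    raw 0-4 severity vector.  Severity is the quintile bin of a latent score
    driven by the informative columns, so it correlates with them the way the
    binary label does in :func:`generate_table`.
    """
    if spec is None:
        spec = SyntheticSpec(n_rows=920, class_counts=(460, 460), seed=seed)
    rng = np.random.default_rng(spec.seed)
    n = sum(SEVERITY_COHORTS.values())
    matrix = rng.normal(0.0, 1.0, size=(n, spec.n_features))
    latent = matrix[:, :max(spec.n_informative, 1)].sum(axis=1) + rng.normal(0, 0.5, n)
    edges = np.quantile(latent, [0.2, 0.4, 0.6, 0.8])
    severity = np.digitize(latent, edges)
    for j in range(spec.n_informative):
        matrix[:, j] += spec.effect_size * (severity > 0)
    table = FeatureTable(matrix=matrix, labels=(severity > 0).astype(int),
                         column_names=_column_names(spec.n_features))
    return table, severity


def generate_separable_table(n_rows: int = 200, n_features: int = 4,
                             margin: float = 1.0, seed: int = 0) -> FeatureTable:
    """A linearly separable binary table with a guaranteed margin.

    The first column carries the separation: class 0 values lie at or below
    ``-margin / 2``, class 1 values at or above ``+margin / 2``, so the gap
    between the classes is at least ``margin``.  Remaining columns are noise.
    """
    rng = np.random.default_rng(seed)
    n1 = n_rows // 2
    n0 = n_rows - n1
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    matrix = rng.normal(0.0, 1.0, size=(n_rows, n_features))
    offset = margin / 2.0 + rng.exponential(0.5, size=n_rows)
    matrix[:, 0] = np.where(labels == 1, offset, -offset)
    order = rng.permutation(n_rows)
    return FeatureTable(matrix=matrix[order], labels=labels[order],
                        column_names=_column_names(n_features))


def af_truth(table: FeatureTable, standardize_against: FeatureTable | None = None) -> np.ndarray:
    """The noiseless AF rate implied by the generative recipe.

    Standardization statistics are taken from ``standardize_against`` when
    given (e.g. the full table when scoring a split), else from ``table``.
    """
    ref = standardize_against if standardize_against is not None else table
    z = np.empty((table.n_rows, 2))
    for j in range(2):
        mu = ref.matrix[:, j].mean()
        sd = ref.matrix[:, j].std()
        z[:, j] = (table.matrix[:, j] - mu) / sd
    logit = 0.8 * z[:, 0] + 0.6 * z[:, 1] ** 2 - 0.5
    return 1.0 / (1.0 + np.exp(-logit))


def attach_af_targets(table: FeatureTable, spec: SyntheticSpec) -> np.ndarray:
    """Draw noisy AF-rate targets for ``table`` under the documented recipe."""
    if spec.n_informative < 2:
        raise ConfigurationError("the AF recipe needs at least 2 informative columns")
    rng = np.random.default_rng(spec.seed + 1)
    clean = af_truth(table)
    noisy = clean + rng.normal(0.0, spec.af_noise_sd, size=table.n_rows)
    return np.clip(noisy, 0.0, 1.0)


def split_80_20(table: FeatureTable, seed: int = 0,
                af_targets: np.ndarray | None = None):
    """Stratified 80/20 split with train size ceil(0.8 * n).

    The ceiling rule reproduces both reference splits: 1026 -> (821, 205) and
    920 -> (736, 184).  Falls back to an unstratified split (with a warning)
    when some class has a single member.  When ``af_targets`` is given, the
    matching target splits are returned as well.
    """
    import warnings

    if table.n_rows < 5:
        raise ConfigurationError("need at least 5 rows to split 80/20")
    n_train = int(np.ceil(0.8 * table.n_rows))
    indices = np.arange(table.n_rows)
    try:
        train_idx, test_idx = train_test_split(
            indices, train_size=n_train, stratify=table.labels, random_state=seed)
    except ValueError:
        warnings.warn("stratification failed (single-member class); "
                      "falling back to an unstratified split", stacklevel=2)
        train_idx, test_idx = train_test_split(
            indices, train_size=n_train, random_state=seed)
    train = table.take(train_idx)
    test = table.take(test_idx)
    if af_targets is not None:
        af = np.asarray(af_targets, dtype=float)
        return train, test, af[train_idx], af[test_idx]
    return train, test


def table_to_csv(table: FeatureTable, path, af_targets: np.ndarray | None = None,
                 label_col: str = "target", af_col: str = "af_rate") -> None:
    """Write a table (features + label, optionally the AF target) as CSV."""
    frame = pd.DataFrame(table.matrix, columns=table.column_names)
    frame[label_col] = table.labels
    if af_targets is not None:
        frame[af_col] = af_targets
    frame.to_csv(path, index=False)
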