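# Methods

This note documents the models implemented in `cardiokit`, the assumptions
behind them, the synthetic data they are validated on, and the numerical
choices made where the design was genuinely open.

## The detection problem

The package targets tabular clinical records: one row per patient, ~14 numeric
or ordinal attributes (blood pressure, cholesterol, maximum heart rate, ...),
a binary heart-disease label, and — for patients flagged as diseased — a
continuous atrial-fibrillation (AF) rate to be estimated.  The pipeline runs
three stages in sequence: weighted optimal feature selection, binary
detection, and AF-rate regression restricted to the rows the detector labels
positive.

## EAVSRO: the ship-rescue metaheuristic

All tuning problems are solved by one population metaheuristic over bounded
real vectors.  The base move imitates a rescue ship relocating relative to
the current best ("prey") position `q`:

    x_new = x + v * (q - I * x)   if F(prey) <  F(x)
    x_new = x + v * (x - q)       otherwise

with `I` an intensity coefficient drawn uniformly from {1, 2} per gene.  The
enhancement replaces the uniform random step coefficient of the base
algorithm with a population statistic, recomputed once per generation and
shared by all candidates:

    v = worst / (mean + worst + best)

`v` always lies in [0, 1]; it is large while the population is spread out
(exploration) and shrinks as fitness values converge (exploitation).
Acceptance is greedy — a moved candidate replaces its parent only on
improvement — so the best-fitness trace is monotone non-increasing, and the
total number of objective evaluations is exactly
`population_size * (max_iterations + 1)`.

Open points resolved here (configurable or injectable where useful):

* `I` is drawn per gene, not per candidate;
* the prey is the current generation's best candidate, and its stored fitness
  is used in the branch test;
* out-of-bounds genes are clamped (projection), not reflected, for
  determinism;
* the "center" statistic is the population mean fitness;
* defaults are population 10 and 50 iterations, matching the experimental
  protocol the pipeline mirrors; a `v_mode="random"` switch restores the
  baseline uniform coefficient for comparison runs.

## Weighted optimal feature selection

A genome of 2K genes encodes K candidate column indices (reals in [1, F],
rounded at decode time; duplicates dropped keeping the first occurrence and
its paired weight) and K weights in [0.01, 0.99].  Fitness is
`1 / (chi2 + 1e-12)` where `chi2` sums, over the selected weighted columns,
the chi-square statistic `sum (O - E)^2 / E` of the class-by-bin contingency
table obtained by quartile-binning the (non-negatively shifted) weighted
column.  K defaults to 10 — the stated selection budget — and shrinks
automatically when genes collide.

Two consequences of this design are worth stating plainly:

* Binning at quartiles is invariant under multiplication by a positive
  weight, so the weight genes cannot influence the chi-square fitness.
  Selection pressure acts entirely on the index genes; the optimized weights
  scale the output representation handed to the downstream models.
* A constant column yields a single bin and contributes zero association,
  so uninformative constant features can never be preferred.

The weighted output multiplies each selected column by its weight
(elementwise), producing a matrix with one column per retained index.

## The AD-SVM detector

Detection is a two-stage hybrid.  A feed-forward binary classifier (two
hidden layers of equal width, sigmoid output, binary cross-entropy, Adam,
batch size 16) is trained first; its penultimate-layer activations are the
learned representation.  An RBF-kernel SVM (scikit-learn `SVC`) is then fit
on those activations; its decision function is the usual dual expansion over
support vectors, and the stored coefficients reproduce it exactly
(`SVMHead.decision_function_dual`).  Joint end-to-end training of the two
parts is deliberately out of scope.

Three extractor hyperparameters are exposed to the metaheuristic, with the
printed search ranges enforced at every decode:

| parameter | range | role |
| --- | --- | --- |
| learning rate | [0.01, 0.99] | Adam step size of the extractor |
| hidden neurons | [5, 255] | width of each of the two hidden layers |
| activation index | [1, 5] | 1 ReLU, 2 sigmoid, 3 tanh, 4 leaky-ReLU, 5 ELU |

The untuned extractor defaults to a base learning rate of 0.001; the tuned
gene *is* the learning rate when tuning is active.  The tuning objective is
`1/CSI + FPR` on a stratified 80/20 validation split of the training data —
minimized, with global minimum exactly 1 at a perfect classifier (CSI = 1,
FPR = 0).  A CSI of zero is guarded with a 1e-12 epsilon so failed candidates
score a large but finite objective; candidates whose training raises or
diverges score a fixed worst-possible fitness instead of aborting the search.
The epoch budget (default 300 standalone, 100 inside tuning) and optional
early stopping (patience 30 on validation loss) are this package's choices.

## AMCCNet: the capsule AF-rate regressor

The feature vector is treated as a 1-D signal.  Three parallel convolution
branches (kernel lengths 3, 5, 7 — the 1-D reading of the multi-scale stem,
since the data is tabular, not an image) cross-correlate with "same" zero
padding, pass the stem activation, and concatenate channel-wise.  A further
convolution (kernel 3) produces `8 * floor(hidden / 8)` channels that are
regrouped into 8-dimensional primary capsule poses and squashed:

    squash(e) = (|e|^2 / (1 + |e|^2)) * e / |e|,   squash(0) = 0

Dynamic routing-by-agreement (3 iterations; logits start at zero; couplings
are the per-primary softmax over digit capsules; digit inputs are the coupled
sums of prediction vectors `u_hat = z_ab @ v_a`; outputs are squashed; logits
increment by the prediction/output dot products) yields 4 digit capsules of
dimension 16.  The readout maps the digit-capsule norms through a trained
affine layer and a sigmoid to a scalar rate in [0, 1].  Capsule geometry
(8 / 16 / 4, 3 routing iterations) follows common capsule-network convention
and is configurable.  The "hidden neuron" gene is repurposed as the
primary-capsule channel budget, since capsule layers have no classical hidden
neuron count; genomes below the capsule dimension (hidden < 8) are invalid
and score worst-possible fitness during tuning.

Training minimizes mean squared error with Adam at the tuned learning rate;
the tuning objective is validation RMSE.  Because the gene range allows Adam
step sizes (e.g. 0.5) that reliably saturate the squash nonlinearity and
stall training, finding the trainable low-learning-rate region is part of
what the tuner does; candidate screening runs at a reduced epoch budget and
the winning genome is retrained longer, keeping whichever of the screened or
retrained model validates better (plain model selection on the validation
fold — a fresh longer trajectory is not guaranteed to land better).

Gradients for both networks are computed by the package's reverse-mode
numeric core (`cardiokit._autodiff`): dense float64 arrays, a fixed
topological backward sweep, and only the operations these models need.
Everything is deterministic per seed, down to bit-identical losses.

## Metrics

Classification metrics (accuracy, precision, F1, MCC, CSI, FPR) are computed
from raw confusion counts; regression metrics (RMSE, MAE, SMAPE, MPE) from
paired vectors.  All ratio metrics return fractions internally; percent
scaling is presentation-level (CLI/report flag), and MCC is never
percent-scaled.  Conventions: MCC returns 0 when a marginal is empty; a SMAPE
term with both values zero contributes 0; `mpe` is implemented as the mean of
`|predicted - actual| / actual` — an absolute percentage error, matching the
evaluation protocol this pipeline follows even though the name suggests a
signed quantity elsewhere; every other zero denominator raises a named error.

## Synthetic data: what it emulates and what it does not

`synthetic_data` emulates the *shape* of the two public heart-disease tables
the pipeline targets: 1026 rows with an exact 500/526 absence/presence split
and ~14 attributes (the default), and a 920-row 5-class severity variant in
four source cohorts of 303/294/123/200 rows.  The 80/20 split uses
`ceil(0.8 n)` training rows, which reproduces both reference splits
(821/205 and 736/184) with one rule, and stratifies by label.

Informative structure is planted explicitly: the first `n_informative`
columns (default 2) are class-conditional normals separated by an effect
size of 1.5 standard deviations — a strong but realistic univariate signal
for clinical tabular data — while all other columns are class-independent
noise.  The AF-rate target is a declared synthetic construct (no public
dataset defines one):

    af = sigmoid(0.8 z1 + 0.6 z2^2 - 0.5) + N(0, 0.05), clipped to [0, 1]

with z1, z2 the standardized informative columns.  The closed form is
exported so recovery tests know the ground truth.

What the fixtures do *not* model: physiological covariance between
attributes, measurement artifacts, missingness mechanisms, or label noise.
Passing the recovery suites therefore shows that each algorithm does what it
claims on data with known structure — not that the pipeline reaches any
particular accuracy on real clinical cohorts.

## Problem sizes and budgets

Model-fit tuning is expensive (every candidate is a full training run), so
the package screens candidates at reduced budgets by design: the pipeline
tunes the detector with population 4 over 3 generations (extractor epochs
100) and the AF regressor with population 6 over 3 generations (screening
epochs 30, final retrain 3x longer, training capped at a seeded subsample of
320 rows — the larger population reflects that the regressor's trainable
learning-rate region is a narrow slice of the tuned range), while the cheap
chi-square selection stage keeps the full population-10 / 50-iteration
budget.  The statistical test suites use 200-row cohorts and the same
reduced tuning budgets.  All of these are configuration defaults,
overridable per run.

## Known limitations

* The AF stage requires at least 7 input columns (the largest stem kernel);
  the pipeline falls back to the full feature matrix when the selected
  representation is narrower.
* Capsule training is sensitive to the Adam step size; with very few tuning
  evaluations the search can fail to leave the untrainable high-learning-rate
  region.  More tuning generations are the remedy.
* Multi-class severity is collapsed to binary (0 vs >= 1) for detection.
* The detector's two stages are trained sequentially, never jointly.
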