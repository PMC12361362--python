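"""AD-SVM detector: activation mapping, extractor, SVM head, tuning."""

import numpy as np
import pytest

from cardiokit import adsvm, eavsro, metrics
from cardiokit.exceptions import (ConfigurationError, DegenerateTargetError,
                                  MetricError, ShapeError)


class TestActivationMapping:
    @pytest.mark.parametrize("index,name", [
        (1, "relu"), (2, "sigmoid"), (3, "tanh"), (4, "leaky_relu"), (5, "elu"),
    ])
    def test_table(self, index, name):
        assert adsvm.map_activation_index(index) == name

    @pytest.mark.parametrize("index", [0, 6, -1])
    def test_out_of_range(self, index):
        with pytest.raises(ConfigurationError):
            adsvm.map_activation_index(index)

    def test_hyperparam_range_enforcement(self):
        with pytest.raises(ConfigurationError):
            adsvm.ADSVMHyperparams(hidden_neurons=300)
        with pytest.raises(ConfigurationError):
            adsvm.ADSVMHyperparams(learning_rate=0.001)

    def test_gene_decoding_respects_bounds(self, rng):
        for _ in range(50):
            genes = rng.uniform([0.01, 5, 1], [0.99, 255, 5])
            hp = adsvm.ADSVMHyperparams.from_genes(genes)
            assert 0.01 <= hp.learning_rate <= 0.99
            assert 5 <= hp.hidden_neurons <= 255
            assert 1 <= hp.activation_index <= 5


class TestExtractor:
    def test_separable_data_memorized(self, separable_table):
        hp = adsvm.ADSVMHyperparams(learning_rate=0.05, hidden_neurons=16)
        spec = adsvm.ExtractorSpec(input_dim=4, epochs=200)
        extractor = adsvm.train_extractor(separable_table.matrix,
                                          separable_table.labels,
                                          hp=hp, spec=spec, seed=0)
        accuracy = (extractor.predict(separable_table.matrix)
                    == separable_table.labels).mean()
        assert accuracy == 1.0

    def test_seed_determinism(self, separable_table):
        hp = adsvm.ADSVMHyperparams(learning_rate=0.05, hidden_neurons=8)
        spec = adsvm.ExtractorSpec(input_dim=4, epochs=30)
        losses = [adsvm.train_extractor(separable_table.matrix,
                                        separable_table.labels,
                                        hp=hp, spec=spec, seed=5).final_loss
                  for _ in range(2)]
        assert losses[0] == losses[1]

    @pytest.mark.parametrize("width", [5, 255])
    def test_width_extremes_complete(self, separable_table, width):
        hp = adsvm.ADSVMHyperparams(learning_rate=0.05, hidden_neurons=width)
        spec = adsvm.ExtractorSpec(input_dim=4, epochs=5)
        extractor = adsvm.train_extractor(separable_table.matrix,
                                          separable_table.labels,
                                          hp=hp, spec=spec, seed=1)
        deep = adsvm.extract_deep_features(extractor, separable_table.matrix)
        assert deep.shape == (separable_table.n_rows, width)

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(DegenerateTargetError):
            adsvm.train_extractor(x, np.zeros(10), seed=0)

    def test_deep_features_row_behaviour(self, separable_table):
        hp = adsvm.ADSVMHyperparams(learning_rate=0.05, hidden_neurons=8)
        spec = adsvm.ExtractorSpec(input_dim=4, epochs=10)
        extractor = adsvm.train_extractor(separable_table.matrix,
                                          separable_table.labels,
                                          hp=hp, spec=spec, seed=2)
        x = separable_table.matrix[:5]
        deep = adsvm.extract_deep_features(extractor, x)
        assert deep.shape[0] == 5
        duplicated = adsvm.extract_deep_features(extractor, np.vstack([x[0], x[0]]))
        np.testing.assert_array_equal(duplicated[0], duplicated[1])
        with pytest.raises(ShapeError):
            adsvm.extract_deep_features(extractor, x[:, :2])


class TestSVMHead:
    def test_xor_requires_kernel(self):
        x = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 1, 1, 0])
        head = adsvm.train_svm_head(x, y, penalty=10.0, kernel_width=1.0)
        np.testing.assert_array_equal(head.predict(x), y)

    def test_dual_expansion_matches_decision_function(self, separable_table):
        head = adsvm.train_svm_head(separable_table.matrix, separable_table.labels)
        np.testing.assert_allclose(
            head.decision_function_dual(separable_table.matrix),
            head.decision_function(separable_table.matrix), atol=1e-10)

    def test_large_penalty_keeps_separable_data_separated(self, separable_table):
        for penalty in (1.0, 1000.0):
            head = adsvm.train_svm_head(separable_table.matrix,
                                        separable_table.labels, penalty=penalty)
            assert (head.predict(separable_table.matrix)
                    == separable_table.labels).mean() == 1.0


class TestPredictAndFitness:
    def _trained_model(self, table):
        hp = adsvm.ADSVMHyperparams(learning_rate=0.05, hidden_neurons=16)
        spec = adsvm.ExtractorSpec(input_dim=table.n_features, epochs=100)
        extractor = adsvm.train_extractor(table.matrix, table.labels,
                                          hp=hp, spec=spec, seed=0)
        head = adsvm.train_svm_head(
            adsvm.extract_deep_features(extractor, table.matrix), table.labels)
        return adsvm.ADSVMModel(extractor=extractor, head=head, hyperparams=hp)

    def test_memorizes_separable_training_points(self, separable_table):
        model = self._trained_model(separable_table)
        predictions = adsvm.predict(model, separable_table.matrix)
        np.testing.assert_array_equal(predictions, separable_table.labels)
        assert set(np.unique(predictions)) <= {0, 1}

    def test_row_equivariance(self, separable_table, rng):
        model = self._trained_model(separable_table)
        order = rng.permutation(separable_table.n_rows)
        np.testing.assert_array_equal(
            adsvm.predict(model, separable_table.matrix[order]),
            adsvm.predict(model, separable_table.matrix)[order])

    @pytest.mark.parametrize("counts,expected", [
        (metrics.ConfusionCounts(tp=10, tn=10, fp=0, fn=0), 1.0),
        (metrics.ConfusionCounts(tp=10, tn=30, fp=10, fn=0), 2.25),
    ])
    def test_detection_fitness_values(self, counts, expected):
        assert adsvm.detection_fitness(counts) == pytest.approx(expected, abs=1e-9)

    def test_detection_fitness_monotone_in_fpr(self):
        # same CSI (tp=10, fp+fn=10), worsening FPR
        low = metrics.ConfusionCounts(tp=10, tn=90, fp=5, fn=5)
        high = metrics.ConfusionCounts(tp=10, tn=45, fp=5, fn=5)
        assert adsvm.detection_fitness(high) > adsvm.detection_fitness(low)

    def test_detection_fitness_undefined_csi(self):
        with pytest.raises(MetricError):
            adsvm.detection_fitness(metrics.ConfusionCounts(tp=0, tn=5, fp=0, fn=0))


class TestTuneADSVM:
    def test_reduced_budget_tuning(self, separable_table):
        config = eavsro.OptimizerConfig(population_size=4, max_iterations=2, seed=5)
        model = adsvm.tune_adsvm(separable_table.matrix, separable_table.labels,
                                 config, epochs=60)
        assert 5 <= model.hyperparams.hidden_neurons <= 255
        assert 0.01 <= model.hyperparams.learning_rate <= 0.99
        counts = model.training_metrics
        # separable data: tuned model classifies the validation fold perfectly
        assert counts.fp == 0 and counts.fn == 0

    def test_tuning_determinism(self, separable_table):
        config = eavsro.OptimizerConfig(population_size=3, max_iterations=1, seed=8)
        a = adsvm.tune_adsvm(separable_table.matrix, separable_table.labels,
                             config, epochs=20)
        b = adsvm.tune_adsvm(separable_table.matrix, separable_table.labels,
                             config, epochs=20)
        assert a.hyperparams == b.hyperparams
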