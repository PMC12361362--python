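"""Capsule regressor: squash, multi-scale stem, routing, training, tuning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiokit import amccnet, eavsro, metrics, synthetic_data
from cardiokit.exceptions import ConfigurationError, DataError, ShapeError


class TestSquash:
    def test_zero_maps_to_zero(self):
        np.testing.assert_array_equal(amccnet.squash(np.zeros(8)), np.zeros(8))

    @pytest.mark.parametrize("norm,expected", [(1.0, 0.5), (3.0, 0.9)])
    def test_closed_form_norms(self, norm, expected):
        vector = np.array([norm, 0.0, 0.0])
        assert np.linalg.norm(amccnet.squash(vector)) == pytest.approx(
            expected, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(DataError):
            amccnet.squash(np.array([np.nan, 1.0]))

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8))
    @settings(max_examples=150, derandomize=True)
    def test_norm_below_one_and_direction_preserved(self, values):
        vector = np.array(values)
        squashed = amccnet.squash(vector)
        assert np.linalg.norm(squashed) < 1.0
        norm = np.linalg.norm(vector)
        if norm > 1e-6:
            cosine = np.dot(squashed, vector) / (np.linalg.norm(squashed) * norm + 1e-300)
            assert cosine == pytest.approx(1.0, abs=1e-9)


class TestMultiscaleConvolve:
    def test_delta_filter_is_identity(self, rng):
        x = rng.normal(size=10)
        delta = np.zeros(3)
        delta[1] = 1.0
        out = amccnet.multiscale_convolve(x, {3: delta[None, :]})
        np.testing.assert_allclose(out.fused.ravel(), x, atol=1e-12)

    def test_zero_input_zero_output(self):
        kernels = {3: np.ones((2, 3)), 5: np.ones((1, 5)), 7: np.ones((1, 7))}
        out = amccnet.multiscale_convolve(np.zeros(9), kernels)
        assert np.all(out.fused == 0)
        assert out.fused.shape == (9, 4)  # channel counts concatenate

    def test_hand_cross_correlation(self):
        out = amccnet.multiscale_convolve(np.array([1.0, 2, 3, 4, 5]),
                                          {3: np.array([[1.0, 1, 1]])})
        np.testing.assert_allclose(out.fused.ravel(), [3, 6, 9, 12, 9])

    def test_short_input_rejected(self):
        with pytest.raises(ShapeError):
            amccnet.multiscale_convolve(np.ones(5), {7: np.ones((1, 7))})

    def test_branch_positions_align(self, rng):
        x = rng.normal(size=12)
        kernels = {k: rng.normal(size=(2, k)) for k in (3, 5, 7)}
        out = amccnet.multiscale_convolve(x, kernels, activation="relu")
        assert all(b.shape[0] == 12 for b in out.branch_outputs.values())


class TestPrimaryCapsules:
    def test_zero_map_zero_capsules(self):
        hp = amccnet.AMCCNetHyperparams(hidden_neurons=16)
        capsules = amccnet.primary_capsules(np.zeros((6, 4)), hp)
        assert np.all(capsules.capsules == 0)

    def test_norm_bound_and_grouping(self, rng):
        hp = amccnet.AMCCNetHyperparams(hidden_neurons=16)
        fused = rng.normal(size=(6, 4))
        capsules = amccnet.primary_capsules(fused, hp, rng=rng)
        # 16 // 8 = 2 capsule channels over 6 positions
        assert capsules.capsules.shape == (12, 8)
        assert np.all(capsules.norms() < 1.0)

    def test_budget_below_capsule_dim_rejected(self):
        hp = amccnet.AMCCNetHyperparams(hidden_neurons=6)
        with pytest.raises(ConfigurationError):
            amccnet.primary_capsules(np.zeros((6, 4)), hp)


class TestRouting:
    def test_single_route_collapse(self, rng):
        primary = amccnet.CapsuleSet(capsules=np.array([[0.3, 0.4]]),
                                     layer_tag="primary")
        transforms = rng.normal(size=(1, 1, 3, 2))
        for iterations in (1, 3, 5):
            digit = amccnet.route(primary, transforms, iterations=iterations)
            expected = amccnet.squash((transforms[0, 0] @ primary.capsules[0])[None])
            np.testing.assert_allclose(digit.capsules, expected, atol=1e-12)

    def test_coupling_normalization_every_iteration(self, rng):
        primary = amccnet.CapsuleSet(capsules=rng.normal(size=(5, 4)),
                                     layer_tag="primary")
        transforms = rng.normal(size=(5, 3, 6, 4))
        _, history = amccnet.route(primary, transforms, iterations=3,
                                   return_couplings=True)
        assert len(history) == 3
        for couplings in history:
            assert np.all(couplings >= 0)
            np.testing.assert_allclose(couplings.sum(axis=1), np.ones(5), atol=1e-12)

    def test_agrees_with_brute_force_loop(self, rng):
        """2 primary x 2 digit toy case against an independent step-by-step
        reimplementation of the routing iteration."""
        primary_caps = rng.normal(size=(2, 3))
        transforms = rng.normal(size=(2, 2, 4, 3))

        # brute-force oracle: explicit python loops
        u_hat = np.zeros((2, 2, 4))
        for a in range(2):
            for b in range(2):
                u_hat[a, b] = transforms[a, b] @ primary_caps[a]

        def squash_oracle(e):
            n = np.linalg.norm(e)
            return np.zeros_like(e) if n == 0 else (n**2 / (1 + n**2)) * e / n

        logits = np.zeros((2, 2))
        for _ in range(3):
            couplings = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
            v = np.zeros((2, 4))
            for b in range(2):
                e = sum(couplings[a, b] * u_hat[a, b] for a in range(2))
                v[b] = squash_oracle(e)
            for a in range(2):
                for b in range(2):
                    logits[a, b] += u_hat[a, b] @ v[b]

        digit = amccnet.route(
            amccnet.CapsuleSet(capsules=primary_caps, layer_tag="primary"),
            transforms, iterations=3)
        np.testing.assert_allclose(digit.capsules, v, atol=1e-10)

    def test_iteration_count_validated(self, rng):
        primary = amccnet.CapsuleSet(capsules=rng.normal(size=(2, 3)),
                                     layer_tag="primary")
        with pytest.raises(ConfigurationError):
            amccnet.route(primary, rng.normal(size=(2, 2, 4, 3)), iterations=0)


class TestAFReadout:
    def test_forced_zero_parameters_give_half(self):
        digit = amccnet.CapsuleSet(capsules=np.zeros((4, 16)), layer_tag="digit")
        assert amccnet.af_readout(digit).rate == pytest.approx(0.5)

    def test_codomain_and_monotonicity(self, rng):
        digit = amccnet.CapsuleSet(capsules=rng.normal(size=(4, 16)),
                                   layer_tag="digit")
        weights = rng.normal(size=4)
        low = amccnet.af_readout(digit, weights, bias=-1.0).rate
        high = amccnet.af_readout(digit, weights, bias=1.0).rate
        assert 0.0 <= low <= 1.0 and 0.0 <= high <= 1.0
        assert high > low


@pytest.fixture(scope="module")
def af_problem():
    spec = synthetic_data.SyntheticSpec(n_rows=160, class_counts=(80, 80),
                                        seed=2, af_noise_sd=0.0)
    table = synthetic_data.generate_table(spec)
    return table.matrix, synthetic_data.attach_af_targets(table, spec)


class TestTraining:
    def test_constant_target_collapse(self, rng):
        x = rng.normal(size=(40, 8))
        targets = np.full(40, 0.3)
        hp = amccnet.AMCCNetHyperparams(learning_rate=0.05, hidden_neurons=8)
        model = amccnet.train_amccnet(x, targets, hp, seed=0, epochs=40)
        assert model.final_rmse < 0.05

    def test_seed_determinism(self, af_problem):
        x, af = af_problem
        hp = amccnet.AMCCNetHyperparams(learning_rate=0.05, hidden_neurons=8)
        a = amccnet.train_amccnet(x, af, hp, seed=4, epochs=8)
        b = amccnet.train_amccnet(x, af, hp, seed=4, epochs=8)
        assert a.final_rmse == b.final_rmse

    def test_beats_constant_mean_baseline(self, af_problem):
        x, af = af_problem
        hp = amccnet.AMCCNetHyperparams(learning_rate=0.05, hidden_neurons=16)
        model = amccnet.train_amccnet(x, af, hp, seed=0, epochs=40)
        baseline = metrics.rmse(af, np.full_like(af, af.mean()))
        assert model.final_rmse < baseline

    def test_input_validation(self, rng):
        hp = amccnet.AMCCNetHyperparams(hidden_neurons=8)
        with pytest.raises(DataError):
            amccnet.train_amccnet(rng.normal(size=(30, 8)),
                                  np.linspace(-1, 0.5, 30), hp, epochs=1)
        with pytest.raises(DataError):
            amccnet.train_amccnet(rng.normal(size=(10, 8)),
                                  np.linspace(0, 1, 10), hp, epochs=1)

    def test_af_fitness_examples(self):
        assert amccnet.af_fitness([0.2, 0.4], [0.2, 0.4]) == 0.0
        assert amccnet.af_fitness([0.0, 0.0], [3.0, 4.0]) == pytest.approx(
            np.sqrt(25 / 2))
        base = amccnet.af_fitness([0.0, 0.0], [0.1, 0.2])
        assert amccnet.af_fitness([0.0, 0.0], [0.2, 0.4]) == pytest.approx(2 * base)

    def test_reduced_budget_tuning(self, af_problem):
        x, af = af_problem
        config = eavsro.OptimizerConfig(population_size=3, max_iterations=1, seed=6)
        model = amccnet.tune_amccnet(x, af, config, epochs=8)
        assert 0.01 <= model.hp.learning_rate <= 0.99
        assert 5 <= model.hp.hidden_neurons <= 255
        assert np.isfinite(model.validation_rmse)
        repeat = amccnet.tune_amccnet(x, af, config, epochs=8)
        assert repeat.hp == model.hp
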