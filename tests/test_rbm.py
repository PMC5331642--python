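import itertools

import numpy as np
import pytest

from rbpdeep.rbm import (DBNStack, RBMParams, cd_update, hidden_probs,
                         init_rbm, load_dbn, pretrain_dbn, rbm_energy,
                         rbm_free_energy, rbm_prob_brute, save_dbn, train_rbm)


def naive_energy(W, a, b, v, h):
    """Independent triple-loop evaluation of the energy function."""
    e = 0.0
    for i in range(len(v)):
        e -= a[i] * v[i]
        for j in range(len(h)):
            e -= v[i] * h[j] * W[i, j]
    for j in range(len(h)):
        e -= b[j] * h[j]
    return e


class TestEnergy:
    def test_zero_parameters_zero_energy(self):
        p = RBMParams(W=np.zeros((3, 2)), a=np.zeros(3), b=np.zeros(2))
        assert rbm_energy(p, np.array([1, 0, 1]), np.array([1, 1])) == 0.0

    def test_hand_computed_instance(self):
        p = RBMParams(W=np.array([[2.0], [0.0]]), a=np.array([1.0, 0.0]),
                      b=np.array([3.0]))
        assert rbm_energy(p, np.array([1.0, 0.0]), np.array([1.0])) == -6.0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            W, a, b = rng.normal(size=(4, 3)), rng.normal(size=4), rng.normal(size=3)
            v = rng.integers(0, 2, 4).astype(float)
            h = rng.integers(0, 2, 3).astype(float)
            p = RBMParams(W=W, a=a, b=b)
            assert rbm_energy(p, v, h) == pytest.approx(naive_energy(W, a, b, v, h))

    def test_shape_mismatch_rejected(self):
        p = RBMParams(W=np.zeros((3, 2)), a=np.zeros(3), b=np.zeros(2))
        with pytest.raises(ValueError):
            rbm_energy(p, np.zeros(2), np.zeros(2))


class TestBruteForceProbability:
    def test_zero_parameters_uniform(self):
        p = RBMParams(W=np.zeros((3, 2)), a=np.zeros(3), b=np.zeros(2))
        for v in itertools.product((0.0, 1.0), repeat=3):
            assert rbm_prob_brute(p, np.array(v)) == pytest.approx(1 / 8)

    def test_normalises_over_visible_states(self):
        rng = np.random.default_rng(2)
        p = RBMParams(W=rng.normal(size=(3, 3)), a=rng.normal(size=3),
                      b=rng.normal(size=3))
        total = sum(rbm_prob_brute(p, np.array(v))
                    for v in itertools.product((0.0, 1.0), repeat=3))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_free_energy_consistent_with_enumeration(self):
        rng = np.random.default_rng(5)
        p = RBMParams(W=rng.normal(size=(3, 2)), a=rng.normal(size=3),
                      b=rng.normal(size=2))
        v = np.array([1.0, 0.0, 1.0])
        brute = sum(np.exp(-rbm_energy(p, v, np.array(h)))
                    for h in itertools.product((0.0, 1.0), repeat=2))
        assert rbm_free_energy(p, v)[0] == pytest.approx(-np.log(brute))

    def test_large_instance_refused(self):
        p = RBMParams(W=np.zeros((15, 15)), a=np.zeros(15), b=np.zeros(15))
        with pytest.raises(ValueError, match="too large"):
            rbm_prob_brute(p, np.zeros(15))


class TestContrastiveDivergence:
    def test_zero_learning_rate_leaves_params(self):
        p = init_rbm(3, 2, rng=np.random.default_rng(0))
        q = cd_update(p, np.array([[1.0, 0.0, 1.0]]), lr=0.0,
                      rng=np.random.default_rng(1))
        np.testing.assert_array_equal(p.W, q.W)
        np.testing.assert_array_equal(p.a, q.a)

    def test_seeded_updates_are_bitwise_reproducible(self):
        data = np.array([[0.0, 0.0], [1.0, 1.0]])
        runs = []
        for _ in range(2):
            p = init_rbm(2, 2, rng=np.random.default_rng(0))
            rng = np.random.default_rng(7)
            for _ in range(50):
                p = cd_update(p, data, lr=0.1, rng=rng)
            runs.append(p.W.copy())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_non_binary_data_rejected(self):
        p = init_rbm(2, 2)
        with pytest.raises(ValueError, match="0/1"):
            cd_update(p, np.array([[0.5, 0.2]]))

    def test_cd1_increases_exact_log_likelihood(self):
        data = np.array([[0.0, 0.0], [1.0, 1.0]])

        def loglik(p):
            return sum(np.log(rbm_prob_brute(p, v)) for v in data)

        p = init_rbm(2, 2, rng=np.random.default_rng(3))
        before = loglik(p)
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = cd_update(p, data, k=1, lr=0.1, rng=rng)
        assert loglik(p) > before

    def test_gaussian_free_energy_decreases_on_training_batch(self):
        # correlated dimensions give the RBM structure to absorb; fully
        # isotropic standardized data is a saddle where CD gradients vanish
        rng = np.random.default_rng(0)
        z = rng.normal(size=(80, 1))
        data = z @ np.ones((1, 4)) + 0.3 * rng.normal(size=(80, 4))
        data = (data - data.mean(0)) / data.std(0)
        p = init_rbm(4, 3, visible_type="gaussian", rng=np.random.default_rng(1))
        before = rbm_free_energy(p, data).mean()
        srng = np.random.default_rng(2)
        for _ in range(300):
            p = cd_update(p, data, lr=0.02, rng=srng)
        assert rbm_free_energy(p, data).mean() < before - 0.1


class TestDBN:
    def test_layer_size_consistency_enforced(self):
        a = init_rbm(4, 3)
        b = init_rbm(2, 2)
        with pytest.raises(ValueError, match="mismatch"):
            DBNStack(layers=[a, b])

    @pytest.mark.parametrize("sizes,n_vis", [((768, 256), 3030), ((128, 64), 101)])
    def test_benchmark_layer_sizes(self, sizes, n_vis):
        rng = np.random.default_rng(0)
        data = (rng.random((30, n_vis)) < 0.1).astype(float)
        stack = pretrain_dbn(sizes, data, epochs=1, seed=0)
        assert stack.layer_sizes == [n_vis, *sizes]
        assert stack.transform(data).shape == (30, sizes[-1])

    def test_single_layer_stack_equals_plain_rbm_fit(self):
        rng = np.random.default_rng(1)
        data = (rng.random((40, 6)) < 0.3).astype(float)
        stack = pretrain_dbn((4,), data, epochs=5, seed=9)
        plain = train_rbm(data, 4, epochs=5, seed=9)
        np.testing.assert_array_equal(stack.layers[0].W, plain.W)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pretrain_dbn((4,), np.empty((0, 5)), epochs=1)

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        data = (rng.random((20, 8)) < 0.4).astype(float)
        stack = pretrain_dbn((5, 3), data, epochs=2, seed=1)
        save_dbn(stack, tmp_path / "dbn.npz")
        back = load_dbn(tmp_path / "dbn.npz")
        for orig, rt in zip(stack.layers, back.layers):
            np.testing.assert_array_equal(orig.W, rt.W)
            assert orig.visible_type == rt.visible_type
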