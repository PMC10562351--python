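"""MLP gradients, FedAvg algebra, protocol equivalences, privacy surface."""

import numpy as np
import pytest

from fedaki.errors import TrainingError
from fedaki.evaluation import auroc
from fedaki.federated import (AdamState, FLConfig, FLSite, MLPSpec,
                              bce_gradients, bce_loss, derive_round_seed,
                              fedavg, forward, init_weights, local_train,
                              run_fl)


def _data(n=200, d=5, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    p = 1 / (1 + np.exp(-(X[:, 0] - 0.5 * X[:, 1])))
    return X, (rng.random(n) < p).astype(float)


SPEC = MLPSpec(n_inputs=5, hidden=(8, 4))


class TestInit:
    def test_deterministic_and_seed_sensitive(self):
        a = init_weights(SPEC, 3)
        b = init_weights(SPEC, 3)
        c = init_weights(SPEC, 4)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_shapes_match_spec(self):
        w = init_weights(SPEC, 0)
        shapes = [a.shape for a in w]
        assert shapes == [(5, 8), (8,), (8, 4), (4,), (4, 1), (1,)]


class TestGradients:
    @pytest.mark.parametrize("l2", [0.0, 1e-2])
    def test_analytic_matches_finite_differences(self, l2):
        rng = np.random.default_rng(0)
        X, y = _data(24, seed=1)
        w = init_weights(SPEC, 2)
        grads = bce_gradients(w, X, y, l2=l2)
        eps = 1e-6
        for i in range(len(w)):
            flat = w[i].ravel()
            for k in rng.choice(flat.size, size=min(5, flat.size),
                                replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                up = bce_loss(w, X, y, l2=l2)
                flat[k] = orig - eps
                down = bce_loss(w, X, y, l2=l2)
                flat[k] = orig
                fd = (up - down) / (2 * eps)
                g = grads[i].ravel()[k]
                assert abs(fd - g) <= 1e-5 * max(1.0, abs(fd))


class TestLocalTrain:
    def test_zero_epochs_is_identity(self):
        X, y = _data()
        w = init_weights(SPEC, 0)
        out, _ = local_train(w, X, y, 0, 32, 1e-2, seed=1)
        assert all(np.array_equal(a, b) for a, b in zip(w, out))

    def test_loss_decreases_after_two_epochs(self):
        wins = 0
        for seed in range(10):
            X, y = _data(300, seed=seed)
            w = init_weights(SPEC, seed)
            before = bce_loss(w, X, y)
            w2, _ = local_train(w, X, y, 2, 32, 1e-2, seed=seed)
            wins += bce_loss(w2, X, y) < before
        assert wins >= 9

    def test_batch_count_arithmetic(self):
        # n=100, B=32 -> 4 mini-batches per epoch (last of size 4)
        n, B = 100, 32
        order = np.arange(n)
        batches = [order[lo:lo + B] for lo in range(0, n, B)]
        assert len(batches) == 4 and batches[-1].size == 4

    def test_empty_data_rejected(self):
        with pytest.raises(TrainingError):
            local_train(init_weights(SPEC, 0), np.empty((0, 5)),
                        np.empty(0), 1, 32, 1e-2, seed=0)


class TestFedavg:
    def test_identical_inputs_are_a_fixed_point(self):
        w = init_weights(SPEC, 1)
        out = fedavg([w, w, w], [10, 20, 30])
        assert all(np.allclose(a, b) for a, b in zip(w, out))

    def test_opposite_weights_cancel(self):
        w = init_weights(SPEC, 2)
        neg = [-a for a in w]
        out = fedavg([w, neg], [5, 5])
        assert all(np.allclose(a, 0.0) for a in out)

    def test_weighted_scalar_example(self):
        a = [np.array([0.0])]
        b = [np.array([4.0])]
        assert fedavg([a, b], [1, 3])[0][0] == pytest.approx(3.0)

    def test_permutation_invariance(self):
        ws = [init_weights(SPEC, s) for s in range(3)]
        n = [7, 11, 13]
        out1 = fedavg(ws, n)
        out2 = fedavg(ws[::-1], n[::-1])
        assert all(np.allclose(a, b) for a, b in zip(out1, out2))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fedavg([init_weights(SPEC, 0),
                    init_weights(MLPSpec(4, (8, 4)), 0)], [1, 1])


def _make_site(site_id, seed, n=300, shift=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 5)) + shift
    p = 1 / (1 + np.exp(-(X[:, 0] - shift)))
    y = (rng.random(n) < p).astype(float)
    y[:2] = [0, 1]
    Xt = rng.standard_normal((60, 5)) + shift
    yt = (rng.random(60) < 1 / (1 + np.exp(-(Xt[:, 0] - shift)))).astype(float)
    yt[:2] = [0, 1]
    return FLSite(site_id, X, y, Xt, yt, seed=seed)


class TestProtocol:
    def test_single_site_fl_equals_plain_sequential_training(self):
        """With one site, R rounds of the protocol are exactly R sequential
        local-training calls under the matched per-round seeds."""
        cfg = FLConfig(rounds=4, local_epochs=2, seed=9, l2=1e-2)
        site = _make_site("only", 1)
        result = run_fl([site], SPEC, cfg)
        # manual replay
        w = init_weights(SPEC, cfg.seed)
        Xtr, ytr = site._X_train, site._y_train
        for r in range(cfg.rounds):
            w, _ = local_train(w, Xtr, ytr, cfg.local_epochs, cfg.batch_size,
                               cfg.learning_rate,
                               derive_round_seed(cfg.seed, r, 0), l2=cfg.l2)
        # the recorded best round may be any round; replay to that round too
        w_best = init_weights(SPEC, cfg.seed)
        for r in range(result.best_round + 1):
            w_best, _ = local_train(w_best, Xtr, ytr, cfg.local_epochs,
                                    cfg.batch_size, cfg.learning_rate,
                                    derive_round_seed(cfg.seed, r, 0),
                                    l2=cfg.l2)
        for a, b in zip(result.best_weights, w_best):
            assert np.max(np.abs(a - b)) <= 1e-10

    def test_identical_sites_leave_aggregate_equal_to_local_update(self):
        cfg = FLConfig(rounds=3, local_epochs=1, seed=4)
        # same data and same per-round shuffling seeds at every site
        sites = [_make_site("a", 7), _make_site("b", 7)]
        w = init_weights(SPEC, cfg.seed)
        for r in range(cfg.rounds):
            seed = derive_round_seed(cfg.seed, r, 0)
            local_a, _ = local_train(w, sites[0]._X_train, sites[0]._y_train,
                                     1, cfg.batch_size, cfg.learning_rate,
                                     seed, l2=cfg.l2)
            local_b, _ = local_train(w, sites[1]._X_train, sites[1]._y_train,
                                     1, cfg.batch_size, cfg.learning_rate,
                                     seed, l2=cfg.l2)
            agg = fedavg([local_a, local_b],
                         [sites[0].n_train, sites[1].n_train])
            for x, y_ in zip(agg, local_a):
                assert np.allclose(x, y_, atol=1e-12)
            w = agg

    def test_best_round_has_maximal_mean_validation_score(self):
        cfg = FLConfig(rounds=5, local_epochs=1, seed=0)
        sites = [_make_site("a", 1), _make_site("b", 2, shift=0.5)]
        result = run_fl(sites, SPEC, cfg)
        assert result.round_mean_val[result.best_round] == \
            max(result.round_mean_val)
        assert len(result.round_mean_val) == 5

    def test_full_run_is_deterministic(self):
        cfg = FLConfig(rounds=3, local_epochs=1, seed=2)
        r1 = run_fl([_make_site("a", 1), _make_site("b", 2)], SPEC, cfg)
        r2 = run_fl([_make_site("a", 1), _make_site("b", 2)], SPEC, cfg)
        assert r1.best_round == r2.best_round
        assert all(np.array_equal(a, b)
                   for a, b in zip(r1.best_weights, r2.best_weights))

    def test_single_class_site_rejected_before_round_one(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 5))
        with pytest.raises(TrainingError):
            FLSite("bad", X, np.ones(50), seed=0)

    def test_server_touches_only_weights_and_scalars(self):
        """The protocol runs against a proxy exposing nothing but the weight
        and score exchange surface: no raw feature access is required."""
        class Proxy:
            def __init__(self, inner):
                self._inner = inner
                self.site_id = inner.site_id

            def local_update(self, w, cfg, r, k):
                out, n = self._inner.local_update(w, cfg, r, k)
                assert isinstance(n, int)
                assert all(isinstance(a, np.ndarray) for a in out)
                return out, n

            def validate(self, w):
                s = self._inner.validate(w)
                assert isinstance(s, float)
                return s

            @property
            def has_temporal(self):
                return False

            @property
            def best_local_weights_(self):
                return self._inner.best_local_weights_

            @property
            def best_local_round_(self):
                return self._inner.best_local_round_

        cfg = FLConfig(rounds=2, local_epochs=1, seed=1)
        sites = [Proxy(_make_site("a", 1)), Proxy(_make_site("b", 2))]
        result = run_fl(sites, SPEC, cfg)
        assert result.best_round in (0, 1)
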