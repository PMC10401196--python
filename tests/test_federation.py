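import numpy as np
import pytest

from fedrisk.dcn import DCNConfig, ModelParams, init_params
from fedrisk.federation import (
    FederationConfig,
    RoundRecord,
    fedavg_aggregate,
    local_update,
    select_best_round,
    train_federated,
    train_local,
)
from fedrisk.privacy import PrivacySpec, dp_sgd_step

from conftest import make_site


def no_dp(**kw) -> FederationConfig:
    defaults = dict(
        rounds=2,
        local_epochs=2,
        batch_size=16,
        lr=0.1,
        privacy=PrivacySpec(noise_multiplier=0.0, clip_norm=np.inf),
        seed=0,
    )
    defaults.update(kw)
    return FederationConfig(**defaults)


class TestFedavg:
    def test_weighted_mean_scalar(self):
        cfg = DCNConfig(input_dim=1, n_cross_layers=0, deep_widths=(1,), seed=0)
        n = init_params(cfg).n_params
        a = ModelParams.unflatten(cfg, np.zeros(n))
        b = ModelParams.unflatten(cfg, np.full(n, 4.0))
        out = fedavg_aggregate([(a, 1), (b, 3)])
        assert np.allclose(out.flatten(), 3.0)

    def test_identical_weights_fixed_point(self):
        cfg = DCNConfig(input_dim=3, seed=1)
        p = init_params(cfg)
        out = fedavg_aggregate([(p, 10), (p, 99)])
        assert np.allclose(out.flatten(), p.flatten(), rtol=0, atol=1e-15)

    def test_convex_combination_bounds(self):
        cfg = DCNConfig(input_dim=2, n_cross_layers=1, deep_widths=(2,), seed=0)
        n = init_params(cfg).n_params
        rng = np.random.default_rng(0)
        ps = [ModelParams.unflatten(cfg, rng.normal(size=n)) for _ in range(5)]
        out = fedavg_aggregate([(p, int(k)) for p, k in zip(ps, rng.integers(1, 50, 5))])
        stack = np.stack([p.flatten() for p in ps])
        assert np.all(out.flatten() >= stack.min(axis=0) - 1e-12)
        assert np.all(out.flatten() <= stack.max(axis=0) + 1e-12)

    def test_matches_weighted_mean_oracle_randomized(self):
        cfg = DCNConfig(input_dim=2, n_cross_layers=1, deep_widths=(3,), seed=0)
        P = init_params(cfg).n_params
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = int(rng.integers(1, 6))
            vecs = rng.normal(size=(k, P))
            ns = rng.integers(1, 1000, size=k)
            out = fedavg_aggregate(
                [(ModelParams.unflatten(cfg, v), int(n)) for v, n in zip(vecs, ns)]
            )
            oracle = (vecs * (ns / ns.sum())[:, None]).sum(axis=0)
            assert np.allclose(out.flatten(), oracle, atol=1e-12)

    def test_shape_mismatch_errors(self):
        a = init_params(DCNConfig(input_dim=2, seed=0))
        b = init_params(DCNConfig(input_dim=3, seed=0))
        with pytest.raises(ValueError):
            fedavg_aggregate([(a, 1), (b, 1)])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fedavg_aggregate([])


class TestLocalUpdate:
    def test_zero_epochs_leaves_weights(self, small_site):
        cfg = DCNConfig(input_dim=5, seed=0)
        g = init_params(cfg)
        upd, n_k, loss = local_update(g, small_site, no_dp(local_epochs=0), seed=0)
        assert np.array_equal(upd.flatten(), g.flatten())
        assert n_k == int(np.sum(small_site.split == "train"))

    def test_zero_lr_evaluates_global(self, small_site):
        cfg = DCNConfig(input_dim=5, seed=0)
        g = init_params(cfg)
        upd, _, loss = local_update(g, small_site, no_dp(lr=0.0), seed=0)
        assert np.array_equal(upd.flatten(), g.flatten())
        assert loss == pytest.approx(np.log(2), rel=1e-6)  # zero head -> p=0.5

    def test_identical_clients_same_seed_identical_weights(self):
        a = make_site(n=80, seed=5, site_id="a")
        b = make_site(n=80, seed=5, site_id="b")
        cfg = DCNConfig(input_dim=5, seed=0)
        g = init_params(cfg)
        ua, _, _ = local_update(g, a, no_dp(), seed=9)
        ub, _, _ = local_update(g, b, no_dp(), seed=9)
        assert np.array_equal(ua.flatten(), ub.flatten())

    def test_single_class_warns_but_trains(self):
        site = make_site(n=40, seed=1, informative=False, case_frac=0.0)
        cfg = DCNConfig(input_dim=5, seed=0)
        with pytest.warns(UserWarning, match="single-class"):
            local_update(init_params(cfg), site, no_dp(), seed=0)


class TestTrainFederated:
    def test_single_round_is_one_aggregation(self, small_site):
        cfg = DCNConfig(input_dim=5, seed=0)
        fc = no_dp(rounds=1)
        params, records = train_federated([small_site], cfg, fc)
        assert len(records) == 1
        assert np.array_equal(params.flatten(), records[0].params.flatten())

    def test_best_round_argmin(self):
        cfg = DCNConfig(input_dim=1, n_cross_layers=0, deep_widths=(1,), seed=0)
        p = init_params(cfg)
        losses = [0.30, 0.25, 0.27, 0.26, 0.28]
        records = [
            RoundRecord(i, {"s": l}, {"s": 10}, l, p) for i, l in enumerate(losses)
        ]
        assert select_best_round(records).round_index == 1

    def test_best_round_tie_breaks_earliest(self):
        cfg = DCNConfig(input_dim=1, n_cross_layers=0, deep_widths=(1,), seed=0)
        p = init_params(cfg)
        records = [RoundRecord(i, {}, {}, 0.5, p) for i in range(3)]
        assert select_best_round(records).round_index == 0

    def test_centralization_limit_bit_match(self, small_site):
        """One client, sigma=0: the federated trajectory equals plain SGD."""
        cfg = DCNConfig(input_dim=5, seed=0)
        fc = no_dp(rounds=3, local_epochs=2)
        _, records = train_federated([small_site], cfg, fc)

        # independent re-run: sequential epochs with the same per-round seeds
        Xtr_fm, ytr = small_site.partition("train")
        X = Xtr_fm.values.toarray()
        params = init_params(cfg)
        ss = np.random.SeedSequence(fc.seed)
        for r in range(fc.rounds):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(int(child.generate_state(1)[0] % (2**31)))
            for _ in range(fc.local_epochs):
                order = rng.permutation(X.shape[0])
                for start in range(0, X.shape[0], fc.batch_size):
                    idx = order[start : start + fc.batch_size]
                    params = dp_sgd_step(
                        params, X[idx], ytr[idx], np.inf, 0.0, fc.lr, rng
                    )
            assert np.array_equal(records[r].params.flatten(), params.flatten())

    def test_aggregated_loss_is_weighted_mean(self):
        sites = [make_site(n=60, seed=s, site_id=f"s{s}") for s in range(2)]
        cfg = DCNConfig(input_dim=5, seed=0)
        _, records = train_federated(sites, cfg, no_dp(rounds=1))
        rec = records[0]
        w = np.array([rec.client_tune_sizes[s.site_id] for s in sites], dtype=float)
        w /= w.sum()
        losses = np.array([rec.client_losses[s.site_id] for s in sites])
        assert rec.aggregated_loss == pytest.approx(float(w @ losses))

    def test_failing_client_named(self):
        good = make_site(n=60, seed=0, site_id="good")
        bad = make_site(n=60, seed=1, site_id="bad")
        bad.split[:] = "tune"  # empty train partition
        with pytest.raises(ValueError, match="bad"):
            train_federated([good, bad], DCNConfig(input_dim=5, seed=0), no_dp())


class TestTrainLocal:
    def test_single_epoch_returns_first_snapshot(self, small_site):
        cfg = DCNConfig(input_dim=5, seed=0)
        params, trace = train_local(small_site, cfg, no_dp(), epochs=1)
        assert len(trace) == 1

    def test_returns_min_loss_epoch(self, small_site):
        cfg = DCNConfig(input_dim=5, seed=0)
        fc = no_dp(lr=0.5, batch_size=8)
        params, trace = train_local(small_site, cfg, fc, epochs=8)
        # retrain to the argmin epoch and compare
        k = int(np.argmin(trace))
        params_k, trace_k = train_local(small_site, cfg, fc, epochs=k + 1)
        assert trace_k == pytest.approx(trace[: k + 1])
        assert np.array_equal(params.flatten(), params_k.flatten())
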