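"""FedAvg algebra, local training contracts, federation reductions, privacy."""

import numpy as np
import pytest

from fedlnm import cohort as ch
from fedlnm.estimators import FederatedFusionClassifier
from fedlnm.exceptions import AggregationError, InputError
from fedlnm.federated import (FederatedConfig, ModelParameters, client_arrays,
                              cross_validate_clients, fedavg, local_train,
                              run_federated)
from fedlnm.model import FusionModel, ModelConfig


def _params(**kw):
    return ModelParameters({k: np.asarray(v, dtype=float) for k, v in kw.items()})


class TestFedAvgAlgebra:
    def test_identity_on_identical_clients(self):
        p = _params(w=[1.0, 2.0], b=3.0)
        out = fedavg([p, p, p], [10, 20, 30])
        for k in p:
            assert np.allclose(out[k], p[k])

    def test_single_client_passthrough(self):
        p = _params(w=[[1.0, -2.0]])
        out = fedavg([p], [57])
        assert np.allclose(out["w"], p["w"])

    def test_weighted_mean_matches_hand_value(self):
        # scalar parameters 2.0 and 4.0 with the two published client sizes
        out = fedavg([_params(w=2.0), _params(w=4.0)], [226, 341])
        assert out["w"] == pytest.approx((226 * 2 + 341 * 4) / 567)
        assert out["w"] == pytest.approx(3.2028, abs=5e-5)

    def test_affine_equivariance(self, rng):
        ps = [_params(w=rng.normal(size=(3, 2))) for _ in range(3)]
        n = [5, 7, 9]
        a, b = 2.5, -1.0
        lhs = fedavg([ModelParameters({"w": a * p["w"] + b}) for p in ps], n)
        rhs = fedavg(ps, n)
        assert np.allclose(lhs["w"], a * rhs["w"] + b, atol=1e-12)

    def test_literal_published_scaling_shrinks_k_fold(self):
        p = _params(w=6.0)
        out = fedavg([p, p], [1, 1], literal_scaling=True)
        assert out["w"] == pytest.approx(3.0)

    def test_name_mismatch_rejected(self):
        with pytest.raises(AggregationError):
            fedavg([_params(w=1.0), _params(v=1.0)], [1, 1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(AggregationError):
            fedavg([_params(w=[1.0, 2.0]), _params(w=[[1.0]])], [1, 1])

    def test_empty_and_bad_sizes_rejected(self):
        with pytest.raises(InputError):
            fedavg([], [])
        with pytest.raises(InputError):
            fedavg([_params(w=1.0)], [0])

    def test_model_parameters_algebra(self):
        p = _params(w=[1.0, 2.0])
        q = _params(w=[3.0, 4.0])
        assert np.allclose((p + q)["w"], [4.0, 6.0])
        assert np.allclose((2.0 * p)["w"], [2.0, 4.0])
        assert p.n_elements == 2


def _text_clients(planted_cohort, n_each=30, seed=0):
    """Two equal-size text-only clients whose train split is all records."""
    pos = [r for r in planted_cohort if r.true_lnm]
    neg = [r for r in planted_cohort if not r.true_lnm]
    half = n_each // 2
    out = []
    for cid in (0, 1):
        recs = pos[cid * half:(cid + 1) * half] + neg[cid * half:(cid + 1) * half]
        c = ch.ClientDataset(client_id=cid, records=recs,
                             train_ids=tuple(r.patient_id for r in recs))
        out.append(c)
    return out


TEXT_CFG = dict(mode="text_only", seed=5,
                model=ModelConfig(mode="text_only", dtype="float64", seed=5))


class TestLocalTrain:
    def test_zero_epochs_returns_start_unchanged(self, planted_cohort):
        c = _text_clients(planted_cohort)[0]
        cfg = FederatedConfig(local_epochs=0, **TEXT_CFG)
        n_feat = client_arrays(c, "train", "text_only")["X"].shape[1]
        start = FusionModel(cfg.model_config(n_feat)).get_parameters()
        out, losses = local_train(c, start, cfg)
        assert losses == []
        for k in start:
            assert np.array_equal(out[k], start[k])

    def test_deterministic_given_seed(self, planted_cohort):
        c = _text_clients(planted_cohort)[0]
        cfg = FederatedConfig(local_epochs=2, learning_rate=0.05, **TEXT_CFG)
        n_feat = client_arrays(c, "train", "text_only")["X"].shape[1]
        start = FusionModel(cfg.model_config(n_feat)).get_parameters()
        out1, l1 = local_train(c, start, cfg, round_index=3)
        out2, l2 = local_train(c, start, cfg, round_index=3)
        assert l1 == l2
        for k in out1:
            assert np.array_equal(out1[k], out2[k])

    def test_loss_decreases_on_separable_client(self, planted_cohort):
        c = _text_clients(planted_cohort, n_each=60)[0]
        cfg = FederatedConfig(local_epochs=30, learning_rate=0.05, **TEXT_CFG)
        n_feat = client_arrays(c, "train", "text_only")["X"].shape[1]
        start = FusionModel(cfg.model_config(n_feat)).get_parameters()
        _, losses = local_train(c, start, cfg)
        assert losses[-1] < losses[0]

    def test_empty_training_split_rejected(self, planted_cohort):
        c = ch.ClientDataset(client_id=0, records=list(planted_cohort[:4]))
        cfg = FederatedConfig(**TEXT_CFG)
        with pytest.raises(InputError):
            local_train(c, {}, cfg)


class TestFederationReductions:
    def test_one_round_fullbatch_equals_centralized_step(self, planted_cohort):
        """With 1 local epoch, full-batch steps and equal client sizes, one
        federated round is algebraically one pooled gradient step."""
        clients = _text_clients(planted_cohort, n_each=30)
        cfg = FederatedConfig(n_rounds=1, local_epochs=1, batch_size=1000,
                              learning_rate=0.1, momentum=0.0, **TEXT_CFG)
        est = FederatedFusionClassifier.from_config(cfg)
        est.fit_clients(clients)

        d0 = client_arrays(clients[0], "train", "text_only")
        d1 = client_arrays(clients[1], "train", "text_only")
        X = np.concatenate([d0["X"], d1["X"]])
        y = np.concatenate([d0["y"], d1["y"]])
        central = FusionModel(cfg.model_config(X.shape[1]))
        central.loss_and_backward(X, y)
        params = central.parameter_arrays()
        grads = central.gradient_arrays()
        for k, p in params.items():
            p -= 0.1 * grads[k]
        for k, v in est.global_params_.items():
            assert np.allclose(v, params[k], atol=1e-8), k

    def test_single_client_equals_sequential_local_training(self, planted_cohort):
        client = _text_clients(planted_cohort, n_each=40)[0]
        cfg = FederatedConfig(n_rounds=3, local_epochs=1, batch_size=8,
                              learning_rate=0.05, **TEXT_CFG)
        fed_params, logs = run_federated([client], cfg)
        assert len(logs) == 3

        n_feat = client_arrays(client, "train", "text_only")["X"].shape[1]
        params = ModelParameters(FusionModel(cfg.model_config(n_feat)).get_parameters())
        for r in range(3):
            params, _ = local_train(client, params, cfg, round_index=r)
        for k in params:
            assert np.allclose(fed_params[k], params[k], atol=1e-12), k

    def test_identical_clients_are_a_fixed_point_of_aggregation(self, planted_cohort):
        base = _text_clients(planted_cohort, n_each=30)[0]
        twin = ch.ClientDataset(client_id=0, records=list(base.records),
                                train_ids=tuple(base.train_ids))
        cfg = FederatedConfig(n_rounds=2, local_epochs=1, batch_size=8,
                              learning_rate=0.05, **TEXT_CFG)
        fed_params, _ = run_federated([base, twin], cfg)
        solo_params, _ = run_federated([base], cfg)
        for k in fed_params:
            assert np.allclose(fed_params[k], solo_params[k], atol=1e-12), k

    def test_server_sees_only_parameter_mappings(self, planted_cohort, monkeypatch):
        """Privacy contract: nothing but named numeric arrays reaches FedAvg."""
        import fedlnm.estimators as est_mod
        seen = []

        def spy(params_list, n_list, **kw):
            seen.append(params_list)
            return fedavg(params_list, n_list, **kw)

        monkeypatch.setattr(est_mod, "fedavg", spy)
        clients = _text_clients(planted_cohort)
        cfg = FederatedConfig(n_rounds=2, local_epochs=1, **TEXT_CFG)
        est = FederatedFusionClassifier.from_config(cfg)
        est.fit_clients(clients)
        assert seen
        for params_list in seen:
            for p in params_list:
                assert isinstance(p, ModelParameters)
                for v in p.values():
                    assert isinstance(v, np.ndarray)


class TestCrossValidation:
    def test_published_validation_set_sizes_and_statelessness(self, planted_cohort):
        c0, c1 = ch.partition_clients(planted_cohort, seed=3)
        c0 = ch.split_train_test(c0, 0.8, seed=3)
        c1 = ch.split_train_test(c1, 0.8, seed=3)
        cfg = FederatedConfig(**TEXT_CFG)
        n_feat = client_arrays(c0, "train", "text_only")["X"].shape[1]
        params = FusionModel(cfg.model_config(n_feat)).get_parameters()
        out1 = cross_validate_clients([c0, c1], params, cfg)
        assert out1["client0"]["validation_n"] == 341
        assert out1["client1"]["validation_n"] == 226
        out2 = cross_validate_clients([c0, c1], params, cfg)
        assert np.array_equal(out1["client0"]["scores"], out2["client0"]["scores"])
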