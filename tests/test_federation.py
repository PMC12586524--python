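import copy

import numpy as np
import pytest

from fedgat.config import ExperimentConfig
from fedgat.federation import (ClientReport, ClientState, cluster_clients, fedavg,
                               gated_fusion, gated_fusion as _gf, global_objective,
                               group_average, local_train, run_federation,
                               similarity_matrix)
from fedgat.graph_data import ClientShard, FederatedDataset
from fedgat.spectral import PrivatizedClientSummary
from fedgat.synthetic_data import SyntheticSpec, generate


def report(cid, weights, n=10, loss=1.0):
    summary = PrivatizedClientSummary(np.zeros(4), 10.0, 0.1, 1.0)
    return ClientReport(cid, weights, summary, n, 0, train_loss=loss)


class TestSimilarity:
    def test_identical_summaries_all_ones(self):
        g = np.array([1.0, 2.0, 3.0])
        assert np.allclose(similarity_matrix([g, g, g]), 1.0)

    def test_orthogonal_summaries_identity(self):
        S = similarity_matrix([np.array([1.0, 0.0]), np.array([0.0, 1.0])])
        assert np.allclose(S, np.eye(2))

    def test_zero_vector_row_is_zero(self):
        S = similarity_matrix([np.zeros(3), np.ones(3)])
        assert np.all(S[0] == 0) and S[1, 1] == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        S = similarity_matrix(list(rng.standard_normal((6, 10))))
        assert np.allclose(S, S.T)
        assert np.all((S >= -1) & (S <= 1))


class TestClustering:
    def test_block_diagonal_recovers_blocks(self):
        S = np.zeros((5, 5))
        S[:3, :3] = 1.0
        S[3:, 3:] = 1.0
        ids = list("abcde")
        asg = cluster_clients(S, ids, n_groups="auto", seed=0)
        assert sorted(map(sorted, asg.groups)) == [["a", "b", "c"], ["d", "e"]]

    def test_all_ones_single_group(self):
        asg = cluster_clients(np.ones((4, 4)), list("abcd"), n_groups="auto")
        assert asg.groups == [["a", "b", "c", "d"]]

    def test_k_groups_means_singletons(self):
        asg = cluster_clients(np.ones((3, 3)), list("abc"), n_groups=3)
        assert sorted(map(tuple, asg.groups)) == [("a",), ("b",), ("c",)]

    def test_single_client(self):
        asg = cluster_clients(np.ones((1, 1)), ["only"], n_groups="auto")
        assert asg.groups == [["only"]]


class TestAggregation:
    def test_group_average_identities(self):
        w = {"a": np.array([1.0, 2.0]), "b": np.ones((2, 2))}
        reports = [report("c1", copy.deepcopy(w)), report("c2", copy.deepcopy(w))]
        avg = group_average(reports)
        assert np.array_equal(avg["a"], w["a"]) and np.array_equal(avg["b"], w["b"])

        neg = {k: -v for k, v in w.items()}
        zero = group_average([report("c1", w), report("c2", neg)])
        assert all(np.all(v == 0) for v in zero.values())

    def test_group_average_permutation_invariant_and_weighted(self):
        w1 = {"a": np.array([0.0])}
        w2 = {"a": np.array([3.0])}
        r1, r2 = report("c1", w1, n=1), report("c2", w2, n=2)
        assert group_average([r1, r2])["a"] == group_average([r2, r1])["a"]
        assert group_average([r1, r2], weighted=True)["a"] == pytest.approx(2.0)

    def test_signature_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fedavg([{"a": np.zeros(2)}, {"a": np.zeros(3)}])

    def test_single_group_fusion_is_identity(self):
        S = np.eye(3)
        from fedgat.federation import GroupAssignment

        asg = GroupAssignment([["a", "b", "c"]], np.ones((3, 3)), ["a", "b", "c"])
        w = {"p": np.array([1.0, -2.0])}
        fused, beta = gated_fusion([w], asg)
        assert np.array_equal(fused["p"], w["p"]) and np.allclose(beta, [1.0])

    def test_equal_traces_average(self):
        from fedgat.federation import GroupAssignment

        S = np.eye(4)
        asg = GroupAssignment([["a", "b"], ["c", "d"]], S, list("abcd"))
        fused, beta = gated_fusion([{"p": np.array([0.0])}, {"p": np.array([2.0])}], asg)
        assert np.allclose(beta, 0.5) and fused["p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_unit_diagonal_beta_proportional_to_group_size(self, seed):
        rng = np.random.default_rng(seed)
        K = 7
        S = rng.uniform(-1, 1, (K, K))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        ids = [f"c{i}" for i in range(K)]
        sizes = [3, 2, 2]
        groups = [ids[:3], ids[3:5], ids[5:]]
        from fedgat.federation import GroupAssignment

        asg = GroupAssignment(groups, S, ids)
        _, beta = gated_fusion([{"p": np.zeros(1)}] * 3, asg)
        assert np.allclose(beta, np.array(sizes) / K)

    def test_zero_trace_falls_back_to_uniform(self):
        from fedgat.federation import GroupAssignment

        S = np.zeros((2, 2))
        asg = GroupAssignment([["a"], ["b"]], S, ["a", "b"])
        _, beta = gated_fusion([{"p": np.zeros(1)}, {"p": np.zeros(1)}], asg)
        assert np.allclose(beta, 0.5)

    def test_global_objective_sample_weighting(self):
        r1 = report("c1", {}, n=1, loss=0.0)
        r2 = report("c2", {}, n=3, loss=4.0)
        assert global_objective([r1, r2]) == pytest.approx(3.0)


class TestLocalTraining:
    def test_zero_epochs_returns_global_weights(self, small_dataset, fast_config):
        ds, _ = small_dataset
        cfg = copy.deepcopy(fast_config)
        cfg.federation.local_epochs = 0
        st = ClientState(ds.shards[0], cfg, seed=0)
        gw = st.make_model(seed=1).state_dict()
        rep = local_train(st, gw, cfg, seed=2)
        assert all(np.array_equal(rep.weights[k], gw[k]) for k in gw)

    def test_seeded_report_reproducible(self, small_dataset, fast_config):
        ds, _ = small_dataset
        st = ClientState(ds.shards[0], fast_config, seed=0)
        gw = st.make_model(seed=1).state_dict()
        r1 = local_train(st, gw, fast_config, seed=5)
        r2 = local_train(st, gw, fast_config, seed=5)
        assert all(np.array_equal(r1.weights[k], r2.weights[k]) for k in gw)
        assert np.array_equal(r1.summary.g_tilde, r2.summary.g_tilde)

    def test_summary_length_contract(self, small_dataset, fast_config):
        ds, _ = small_dataset
        st = ClientState(ds.shards[0], fast_config, seed=0)
        gw = st.make_model(seed=1).state_dict()
        rep = local_train(st, gw, fast_config, seed=2)
        assert rep.summary.g_tilde.shape == (
            fast_config.spectral.N_max * fast_config.spectral.M,)


class TestRunFederation:
    def test_deterministic_history(self, small_dataset, fast_config):
        ds, _ = small_dataset
        h1 = run_federation(ds, copy.deepcopy(fast_config), seed=3, rounds=2)
        h2 = run_federation(ds, copy.deepcopy(fast_config), seed=3, rounds=2)
        assert h1.rounds == h2.rounds
        assert all(np.array_equal(h1.final_weights[k], h2.final_weights[k])
                   for k in h1.final_weights)

    def test_single_client_global_equals_local(self, small_dataset, fast_config):
        ds, _ = small_dataset
        solo = FederatedDataset([ds.shards[0]], ds.label_space)
        cfg = copy.deepcopy(fast_config)
        hist = run_federation(solo, cfg, seed=1, rounds=1)
        # with one client the clustered path reduces to that client's weights:
        # rerun its local training from the same initial weights and compare
        ss = np.random.SeedSequence(1)
        state_seeds, init_seed, round_entropy = ss.spawn(3)
        st = ClientState(solo.shards[0], cfg,
                         int(state_seeds.spawn(1)[0].generate_state(1)[0] % 2**31))
        gw = st.make_model(seed=int(init_seed.generate_state(1)[0] % 2**31)).state_dict()
        cseed = int(round_entropy.spawn(1)[0].spawn(2)[0].generate_state(1)[0] % 2**31)
        rep = local_train(st, gw, cfg, cseed, round_idx=0)
        assert all(np.allclose(hist.final_weights[k], rep.weights[k]) for k in gw)

    def test_asyagg_ablation_uses_plain_fedavg(self, small_dataset, fast_config):
        ds, _ = small_dataset
        cfg = copy.deepcopy(fast_config)
        cfg.ablate.asyagg = True
        hist = run_federation(ds, cfg, seed=2, rounds=1)
        assert hist.rounds[0]["aggregation"] == "fedavg"
        assert "groups" not in hist.rounds[0]

    def test_async_mode_runs_and_records_fusion_events(self, small_dataset, fast_config):
        ds, _ = small_dataset
        cfg = copy.deepcopy(fast_config)
        cfg.federation.mode = "async"
        hist = run_federation(ds, cfg, seed=4, rounds=1)
        events = hist.rounds[0]["fusion_events"]
        assert len(events) == len(hist.rounds[0]["groups"])
        for e in events:
            assert np.array(e["beta"]).sum() == pytest.approx(1.0)

    def test_identical_clients_noiseless_grouped_equals_fedavg(self, fast_config):
        # three clients holding the same shard, epsilon -> infinity: the
        # similarity matrix is all-ones, one group forms, and the clustered
        # path must match plain FedAvg to numerical identity
        spec = SyntheticSpec(K=1, n_structural_groups=1, graphs_per_client=10,
                             nodes_range=(6, 10), seed=5)
        base, _ = generate(spec, seed=5)
        shard = base.shards[0]
        shards = [ClientShard(f"c{i}", shard.graphs, shard.label_space) for i in range(3)]
        ds = FederatedDataset(shards, shard.label_space)
        cfg = copy.deepcopy(fast_config)
        cfg.spectral.epsilon = 1e12
        h_grouped = run_federation(ds, copy.deepcopy(cfg), seed=9, rounds=1)
        cfg.ablate.asyagg = True
        h_plain = run_federation(ds, cfg, seed=9, rounds=1)
        for k in h_grouped.final_weights:
            assert np.allclose(h_grouped.final_weights[k], h_plain.final_weights[k],
                               atol=1e-10)
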