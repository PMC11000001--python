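"""Off-target quantification, importance, MoA pruning and knockouts."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from drugsignet import moa
from drugsignet.moa import (MoASubnetwork, delta_tf, insilico_knockout,
                            merge_ensemble_subnetworks, node_edge_importance,
                            prune_moa_subnetwork, simplest_paths)
from drugsignet.drug_module import offtarget_mask
from drugsignet.pkn import SignalingNetwork
from drugsignet.training import Ensemble, TrainConfig, TrainedModel, build_model


class TestDeltaTF:
    def test_no_offtarget_signal_means_zero_delta(self, toy_net, ground_truth, dataset):
        """A degenerate (prior-only, bn-bypassed) drug module emits signal
        only on each drug's own prior targets, so masking changes nothing."""
        cond, _ = dataset
        cfg = TrainConfig(epochs=1, lambda_dt=float("inf"))
        model = build_model(toy_net, ground_truth.prior, ground_truth.sim, cfg, seed=0)
        model.drug_params.bn_bypass = True
        ens = Ensemble(members=[TrainedModel(model=model)])
        report = delta_tf(ens, cond)
        assert np.allclose(report["delta"], 0.0)
        assert not report["flagged"].any()

    def test_mid_activity_not_flagged_despite_large_delta(self, flagship_ensemble, dataset):
        cond, _ = dataset
        report = delta_tf(flagship_ensemble, cond)
        mid = report[(report.activity > 0.25) & (report.activity < 0.75)]
        assert not mid["flagged"].any()

    def test_constructed_offtarget_flip_is_flagged(self):
        """An off-target signal that flips a TF from ~0.8 to ~0.2 yields
        |ΔTF| ~ 0.6 and passes the flagging gates."""
        from drugsignet.chem import SimilarityMatrix
        from drugsignet.drug_module import ConditionTable
        net = SignalingNetwork(["T0", "T1", "F"], [("T0", "F", 1), ("T1", "F", -1)],
                               target_nodes=["T0", "T1"], tf_nodes=["F"])
        sim = SimilarityMatrix(["D0", "D1"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        prior = pd.DataFrame({"drug": ["D0", "D1"], "target": ["T0", "T1"],
                              "sign": [1, 1]})
        cfg = TrainConfig(epochs=1, lambda_dt=5e-3)
        model = build_model(net, prior, sim, cfg, seed=0)
        model.drug_params.bn_bypass = True
        # D0's own channel activates T0; a learned similarity weight routes
        # D0's dose onto D1's channel and thence (inhibitory edge) onto F
        model.drug_params.wdt.data[:] = [2.0, 4.0]
        model.drug_params.Wdrug.data[0, 1] = 1.2
        model.sig_params.w.data[:] = [2.0, -2.0]
        model.sig_params.b.data[:] = 0.0
        model.sig_params.wp.data[:] = 1.0
        cond = ConditionTable(["s0"], ["D0", "D1"], np.array([[1.0, 0.0]]), ["D0"])
        ens = Ensemble(members=[TrainedModel(model=model)])
        full = ens.predict(cond)[0, 0]
        report = delta_tf(ens, cond)
        masked = report["activity_masked"].iloc[0]
        assert masked >= 0.7 and full <= 0.3
        assert abs(report["delta"].iloc[0]) >= 0.4
        assert report["flagged"].iloc[0]

    def test_performance_gate(self, flagship_ensemble, dataset):
        cond, _ = dataset
        tf_ids = flagship_ensemble.members[0].model.tf_ids
        bad_perf = pd.DataFrame({"train_r": 0.1, "val_r": 0.1}, index=tf_ids)
        report = delta_tf(flagship_ensemble, cond, performance=bad_perf)
        assert not report["flagged"].any()


class TestImportance:
    def test_disconnected_node_scores_zero(self, flagship_ensemble, dataset, toy_net):
        cond, _ = dataset
        model = flagship_ensemble.members[0].model
        tf = toy_net.tf_nodes[0]
        drug = cond.drug_ids[0]
        scores = node_edge_importance(model, cond, drug, tf)
        g = toy_net.to_digraph()
        for node in toy_net.nodes:
            if node != tf and not nx.has_path(g, node, tf):
                assert scores.node_scores[node] == pytest.approx(0.0, abs=1e-12)

    def test_scores_nonnegative(self, flagship_ensemble, dataset, toy_net):
        cond, _ = dataset
        model = flagship_ensemble.members[0].model
        scores = node_edge_importance(model, cond, cond.drug_ids[0], toy_net.tf_nodes[0])
        assert (scores.node_scores >= 0).all() and (scores.edge_scores >= 0).all()

    def test_ordering_matches_finite_difference_sensitivity(self):
        """3-node chain: gradient importance ranks edges like a
        perturb-and-measure oracle."""
        net = SignalingNetwork(["T", "M", "F"], [("T", "M", 1), ("M", "F", 1)],
                               target_nodes=["T"], tf_nodes=["F"])
        import pandas as pd
        from drugsignet.chem import SimilarityMatrix
        sim = SimilarityMatrix(["D0"], np.array([[1.0]]))
        prior = pd.DataFrame({"drug": ["D0"], "target": ["T"], "sign": [1]})
        cfg = TrainConfig(epochs=1)
        model = build_model(net, prior, sim, cfg, seed=0)
        model.sig_params.w.data[:] = [0.9, 0.2]
        from drugsignet.drug_module import ConditionTable
        cond = ConditionTable(["s0"], ["D0"], np.array([[1.0]]), ["D0"])
        scores = node_edge_importance(model, cond, "D0", "F")
        # oracle: effect of zeroing each edge on the TF state
        def tf_state(w):
            m2 = build_model(net, prior, sim, cfg, seed=0)
            m2.sig_params.w.data[:] = w
            return m2.predict(cond)[0, 0]
        base = tf_state([0.9, 0.2])
        deltas = [abs(base - tf_state([0.0, 0.2])), abs(base - tf_state([0.9, 0.0]))]
        grad_order = np.argsort(scores.edge_scores.to_numpy())
        assert list(grad_order) == list(np.argsort(deltas))


def _random_dag_subnet(rng, n=10):
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.35:
                edges.append((nodes[i], nodes[j], 1))
    return nodes, edges


class TestPruning:
    def test_single_path_returned_unchanged(self, toy_net, ground_truth):
        net = SignalingNetwork(["T", "M", "F"], [("T", "M", 1), ("M", "F", -1)],
                               target_nodes=["T"], tf_nodes=["F"])
        import pandas as pd
        from drugsignet.chem import SimilarityMatrix
        sim = SimilarityMatrix(["D0"], np.array([[1.0]]))
        prior = pd.DataFrame({"drug": ["D0"], "target": ["T"], "sign": [1]})
        model = build_model(net, prior, sim, TrainConfig(epochs=1), seed=0)
        scores = moa.ImportanceScores(
            node_scores=pd.Series(1.0, index=net.nodes),
            edge_scores=pd.Series(1.0, index=pd.MultiIndex.from_tuples(
                [("T", "M"), ("M", "F")])),
            objective=0.0, drug="D0", tf="F")
        sub = prune_moa_subnetwork(model, scores, ["T"], "F")
        assert set(sub.nodes) == {"T", "M", "F"}
        assert sub.targets == ["T"]

    def test_low_importance_branch_pruned_from_diamond(self):
        net = SignalingNetwork(
            ["T", "A", "B", "F"],
            [("T", "A", 1), ("T", "B", 1), ("A", "F", 1), ("B", "F", 1)],
            target_nodes=["T"], tf_nodes=["F"])
        import pandas as pd
        from drugsignet.chem import SimilarityMatrix
        sim = SimilarityMatrix(["D0"], np.array([[1.0]]))
        prior = pd.DataFrame({"drug": ["D0"], "target": ["T"], "sign": [1]})
        model = build_model(net, prior, sim, TrainConfig(epochs=1), seed=0)
        scores = moa.ImportanceScores(
            node_scores=pd.Series({"T": 5.0, "A": 4.0, "B": 0.1, "F": 5.0}),
            edge_scores=pd.Series(1.0, index=pd.MultiIndex.from_tuples(
                [("T", "A"), ("T", "B"), ("A", "F"), ("B", "F")])),
            objective=0.0, drug="D0", tf="F")
        sub = prune_moa_subnetwork(model, scores, ["T"], "F")
        assert "B" not in sub.nodes and "A" in sub.nodes

    def test_connectivity_invariant_on_random_toys(self):
        """Pruning preserves a target -> TF path on 50 random graphs."""
        import pandas as pd
        from drugsignet.chem import SimilarityMatrix
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 50:
            nodes, edges = _random_dag_subnet(rng)
            target, tf = nodes[0], nodes[-1]
            net = SignalingNetwork(nodes, edges, target_nodes=[target], tf_nodes=[tf])
            if not nx.has_path(net.to_digraph(), target, tf):
                continue
            sim = SimilarityMatrix(["D0"], np.array([[1.0]]))
            prior = pd.DataFrame({"drug": ["D0"], "target": [target], "sign": [1]})
            model = build_model(net, prior, sim, TrainConfig(epochs=1), seed=0)
            scores = moa.ImportanceScores(
                node_scores=pd.Series(rng.random(len(nodes)), index=nodes),
                edge_scores=pd.Series(rng.random(len(edges)),
                                      index=pd.MultiIndex.from_tuples(
                                          [(s, t) for s, t, _ in edges])),
                objective=0.0, drug="D0", tf=tf)
            sub = prune_moa_subnetwork(model, scores, [target], tf)
            g = sub.to_digraph()
            assert sub.targets, "pruning disconnected the last target"
            for t in sub.targets:
                assert nx.has_path(g, t, tf)
            for node in sub.nodes:  # every retained node on a path
                assert any(nx.has_path(g, t, node) for t in sub.targets)
                assert nx.has_path(g, node, tf)
            checked += 1


class TestMergeAndSimplestPaths:
    def _subnet(self, edges, targets, tf="F", drug="D0"):
        nodes = sorted({n for e in edges for n in e[:2]})
        return MoASubnetwork(nodes=nodes, edges=[(s, t, 1) for s, t, *_ in edges],
                             targets=targets, tf=tf, drug=drug)

    def test_identical_subnets_merge_to_member(self):
        sn = self._subnet([("T", "M"), ("M", "F")], ["T"])
        merged = merge_ensemble_subnetworks([sn] * 5)
        assert set(merged.nodes) == set(sn.nodes)
        assert merged.targets == ["T"]

    def test_rare_edge_dropped_when_majority_path_exists(self):
        common = self._subnet([("T", "M"), ("M", "F")], ["T"])
        rare = self._subnet([("T", "M"), ("M", "F"), ("T", "X"), ("X", "F")], ["T"])
        merged = merge_ensemble_subnetworks([common] * 9 + [rare])
        assert ("T", "X", 1) not in merged.edges

    def test_reconnection_picks_highest_frequency_sum_path(self):
        # neither path reaches 50% but 3/10 beats 2/10
        a = self._subnet([("T", "A"), ("A", "F")], ["T"])
        b = self._subnet([("T", "B"), ("B", "F")], ["T"])
        others = [self._subnet([("T", "C")], []) for _ in range(5)]
        merged = merge_ensemble_subnetworks([a] * 3 + [b] * 2 + others)
        assert ("T", "A", 1) in merged.edges and ("A", "F", 1) in merged.edges
        assert ("T", "B", 1) not in merged.edges

    def test_simplest_path_identity_on_single_path(self):
        sn = self._subnet([("T", "M"), ("M", "F")], ["T"])
        sp = simplest_paths(sn)
        assert set(sp.edges) == set(sn.edges)

    def test_tie_broken_by_edge_frequency(self):
        sn = self._subnet([("T", "A"), ("A", "F"), ("T", "B"), ("B", "F")], ["T"])
        sn.edge_freq = {("T", "A"): 0.9, ("A", "F"): 0.9,
                        ("T", "B"): 0.2, ("B", "F"): 0.2}
        sp = simplest_paths(sn)
        assert ("T", "A", 1) in sp.edges and ("T", "B", 1) not in sp.edges

    def test_path_lengths_match_bfs_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            nodes, edges = _random_dag_subnet(rng, n=9)
            target, tf = nodes[0], nodes[-1]
            g = nx.DiGraph([(s, t) for s, t, _ in edges])
            if target not in g or tf not in g or not nx.has_path(g, target, tf):
                continue
            sn = MoASubnetwork(nodes=nodes, edges=edges, targets=[target],
                               tf=tf, drug="D0")
            sp = simplest_paths(sn)
            spg = sp.to_digraph()
            assert (nx.shortest_path_length(spg, target, tf)
                    == nx.shortest_path_length(g, target, tf))


class TestKnockout:
    def test_node_without_path_leaves_tf_unchanged(self, flagship_ensemble,
                                                   dataset, toy_net):
        cond, _ = dataset
        g = toy_net.to_digraph()
        model = flagship_ensemble.members[0].model
        base = model.predict(cond)
        for tf_j, tf in enumerate(toy_net.tf_nodes[:2]):
            upstreamless = [n for n in toy_net.nodes
                            if n != tf and not nx.has_path(g, n, tf)]
            if not upstreamless:
                continue
            ko = insilico_knockout(model, upstreamless[:1], cond, level=-10.0)
            assert np.allclose(ko[tf].to_numpy(), base[:, tf_j], atol=1e-9)

    def test_level_zero_is_identity(self, flagship_ensemble, dataset):
        cond, _ = dataset
        ko = insilico_knockout(flagship_ensemble, [flagship_ensemble.members[0]
                                                   .model.net.nodes[0]],
                               cond, level=0.0)
        assert np.allclose(ko.to_numpy(), flagship_ensemble.predict(cond))

    def test_unknown_node_raises(self, flagship_ensemble, dataset):
        cond, _ = dataset
        with pytest.raises(KeyError):
            insilico_knockout(flagship_ensemble, ["NOPE"], cond)

    def test_stronger_knockout_never_raises_activating_path_tf(self):
        """Monotonicity on a purely activating chain."""
        import pandas as pd
        from drugsignet.chem import SimilarityMatrix
        net = SignalingNetwork(["T", "M", "F"], [("T", "M", 1), ("M", "F", 1)],
                               target_nodes=["T"], tf_nodes=["F"])
        sim = SimilarityMatrix(["D0"], np.array([[1.0]]))
        prior = pd.DataFrame({"drug": ["D0"], "target": ["T"], "sign": [1]})
        model = build_model(net, prior, sim, TrainConfig(epochs=1), seed=0)
        model.sig_params.w.data[:] = [0.8, 0.8]
        model.sig_params.b.data[:] = 0.3
        from drugsignet.drug_module import ConditionTable
        cond = ConditionTable(["s0"], ["D0"], np.array([[1.0]]), ["D0"])
        acts = [insilico_knockout(model, ["M"], cond, level=lv).iloc[0, 0]
                for lv in (0.0, -1.0, -5.0, -10.0)]
        assert all(a >= b - 1e-12 for a, b in zip(acts, acts[1:]))
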