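"""Mechanism-of-action interpretation of trained models.

Covers: quantifying off-target effects as the difference between full
and prior-masked predictions (ΔTF); gradient-based node and edge
importance for one drug -> TF effect; iterative pruning of the signaling
network down to a minimal subnetwork explaining that effect; ensemble
consensus merging and simplest-path reduction of such subnetworks; and
in-silico knockouts that clamp nodes with a strongly negative input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .drug_module import ConditionTable, offtarget_mask
from .model import DrugSignalingModel
from .signaling import project_to_tf, propagate_steady_state
from .training import Ensemble

# Methods-default gates for flagging a trustworthy, large off-target effect
ACTIVITY_HIGH = 0.75
ACTIVITY_LOW = 0.25
DELTA_MIN = 0.2
MEAN_PERF_MIN = 0.5
VAL_PERF_MIN = 0.4


# ------------------------------------------------------------------ delta TF

def delta_tf(
    ensemble: Ensemble,
    conditions: ConditionTable,
    performance: pd.DataFrame | None = None,
    activity_high: float = ACTIVITY_HIGH,
    activity_low: float = ACTIVITY_LOW,
    delta_min: float = DELTA_MIN,
    mean_perf_min: float = MEAN_PERF_MIN,
    val_perf_min: float = VAL_PERF_MIN,
) -> pd.DataFrame:
    """Off-target report: ensemble-mean activity with and without the
    off-target signal, their difference, and selection flags.

    ``performance``, if given, is indexed by TF with columns ``train_r``
    and ``val_r``; TFs lacking a record are excluded from flagging with a
    warning.  A sample/TF is flagged when the activity is extreme
    (>= activity_high or <= activity_low), |Δ| >= delta_min, and the TF's
    performance passes both gates.
    """
    member = ensemble.members[0].model
    mask = offtarget_mask(member.drug_params, conditions)
    full = ensemble.predict(conditions)
    masked = np.mean([m.model.predict(conditions, signal_mask=mask)
                      for m in ensemble.members], axis=0)
    tf_ids = member.tf_ids
    rows = []
    missing_perf = set()
    for si, sample in enumerate(conditions.sample_ids):
        for tj, tf in enumerate(tf_ids):
            act, act_masked = full[si, tj], masked[si, tj]
            delta = act - act_masked
            flagged = False
            if performance is not None and tf not in performance.index:
                missing_perf.add(tf)
            elif (act >= activity_high or act <= activity_low) and abs(delta) >= delta_min:
                if performance is None:
                    flagged = True
                else:
                    tr = float(performance.loc[tf, "train_r"])
                    vr = float(performance.loc[tf, "val_r"])
                    flagged = (tr + vr) / 2 >= mean_perf_min and vr > val_perf_min
            rows.append({"sample": sample, "drug": conditions.sample_drug[si],
                         "tf": tf, "activity": act, "activity_masked": act_masked,
                         "delta": delta, "flagged": flagged})
    if missing_perf:
        warnings.warn(f"TFs without performance record excluded from flagging: "
                      f"{sorted(missing_perf)}")
    return pd.DataFrame(rows)


# ------------------------------------------------------- importance scores

@dataclass
class ImportanceScores:
    """Gradient x sensitivity importance of nodes and edges for one
    drug -> TF effect."""

    node_scores: pd.Series              # index: node id
    edge_scores: pd.Series              # index: (source, target)
    objective: float
    drug: str
    tf: str


def node_edge_importance(
    model: DrugSignalingModel,
    conditions: ConditionTable,
    drug: str,
    tf: str,
    n_fractions: int = 11,
) -> ImportanceScores:
    """Importance of every node/edge for the drug's effect on one TF.

    The drug's module-generated signal is scaled by fractions 0..1; the
    sum of the focal TF's activity over those artificial conditions is the
    objective whose gradients w.r.t. biases (db) and edge weights (dw)
    are taken.  score_b = |db| * (max - min of node activity across the
    fraction conditions); score_w = |dw| * |w|.
    """
    if tf not in model.tf_ids:
        raise KeyError(f"TF {tf!r} not in model")
    sel = [i for i, d in enumerate(conditions.sample_drug) if d == drug]
    if not sel:
        raise KeyError(f"no sample for drug {drug!r}")
    x = conditions.X[sel[np.argmax(conditions.X[sel].max(axis=1))]]
    base_signal = model.predict_signal(x[None, :])
    fractions = np.linspace(0.0, 1.0, n_fractions)
    signals = fractions[:, None] * base_signal  # (n_fractions, t)
    sp = model.sig_params
    u = model.signal_to_node_space(signals)
    h, _, _ = propagate_steady_state(u, sp)
    y = project_to_tf(h, sp.wp, sp.tf_idx)
    obj = y.take_cols(np.array([model.tf_ids.index(tf)])).sum()
    sp.w.grad = None
    sp.b.grad = None
    obj.backward()
    db = np.abs(sp.b.grad)
    node_range = h.data.max(axis=0) - h.data.min(axis=0)
    node_scores = pd.Series(db * node_range, index=model.net.nodes)
    dw = np.abs(sp.w.grad)
    edge_scores = pd.Series(
        dw * np.abs(sp.w.data),
        index=pd.MultiIndex.from_tuples(
            [(s, t) for s, t, _ in model.net.edges], names=["source", "target"]))
    return ImportanceScores(node_scores=node_scores, edge_scores=edge_scores,
                            objective=float(obj.data), drug=drug, tf=tf)


# --------------------------------------------------------- MoA subnetworks

@dataclass
class MoASubnetwork:
    """Pruned signed subgraph explaining one drug -> TF effect."""

    nodes: list[str]
    edges: list[tuple[str, str, int]]
    targets: list[str]                  # entry (drug-target) nodes retained
    tf: str
    drug: str
    node_freq: dict[str, float] = field(default_factory=dict)
    edge_freq: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s, t, sign in self.edges:
            g.add_edge(s, t, sign=sign)
        return g


def _clean(g: nx.DiGraph, targets: list[str], tf: str) -> nx.DiGraph:
    """Keep only nodes on a directed path from some target to the TF."""
    keep_targets = [t for t in targets if t in g]
    if tf not in g or not keep_targets:
        return nx.DiGraph()
    reach = set()
    for t in keep_targets:
        if t in g:
            reach.add(t)
            reach |= nx.descendants(g, t)
    back = {tf} | nx.ancestors(g, tf)
    return g.subgraph(reach & back).copy()


def prune_moa_subnetwork(
    model: DrugSignalingModel,
    scores: ImportanceScores,
    targets: list[str],
    tf: str,
) -> MoASubnetwork:
    """Iteratively remove the least-important nodes, then edges, keeping a
    target -> TF connection.

    After every removal the graph is cleaned of disconnected parts,
    nodes unreachable from any retained target and nodes that cannot
    reach the TF.  A removal that would disconnect every target from the
    TF is undone and ends that phase.  Targets losing their path are
    dropped (reported via the ``targets`` field).
    """
    g = _clean(model.net.to_digraph(), targets, tf)
    if g.number_of_nodes() == 0:
        raise ValueError(f"no target connects to {tf!r} in the network")

    def alive(graph):
        return any(t in graph and nx.has_path(graph, t, tf) for t in targets)

    # node-removal phase (never remove the TF itself)
    while True:
        candidates = sorted((n for n in g.nodes if n != tf),
                            key=lambda n: (scores.node_scores.get(n, 0.0), n))
        removed = False
        for n in candidates:
            trial = g.copy()
            trial.remove_node(n)
            trial = _clean(trial, targets, tf)
            if trial.number_of_nodes() and alive(trial):
                g = trial
                removed = True
                break
        if not removed:
            break
    # edge-removal phase
    while True:
        candidates = sorted(g.edges, key=lambda e: (scores.edge_scores.get(e, 0.0), e))
        removed = False
        for e in candidates:
            trial = g.copy()
            trial.remove_edge(*e)
            trial = _clean(trial, targets, tf)
            if trial.number_of_nodes() and alive(trial):
                g = trial
                removed = True
                break
        if not removed:
            break
    sign_of = {(s, t): sg for s, t, sg in model.net.edges}
    kept_targets = [t for t in targets if t in g and nx.has_path(g, t, tf)]
    return MoASubnetwork(
        nodes=[n for n in model.net.nodes if n in g],
        edges=[(s, t, sign_of[(s, t)]) for s, t in g.edges],
        targets=kept_targets, tf=tf, drug=scores.drug,
    )


def merge_ensemble_subnetworks(
    subnets: list[MoASubnetwork],
    threshold: float = 0.5,
) -> MoASubnetwork:
    """Consensus subnetwork: keep nodes/edges appearing in >= threshold of
    the member subnetworks.

    If thresholding disconnects every target from the TF, the target
    threshold is lowered until one survives and the TF is re-connected
    through the candidate path with the highest summed edge frequency.
    """
    if not subnets:
        raise ValueError("need >= 1 subnetwork")
    n = len(subnets)
    tf, drug = subnets[0].tf, subnets[0].drug
    node_counts: dict[str, int] = {}
    edge_counts: dict[tuple[str, str], int] = {}
    sign_of: dict[tuple[str, str], int] = {}
    target_counts: dict[str, int] = {}
    for sn in subnets:
        for nd in sn.nodes:
            node_counts[nd] = node_counts.get(nd, 0) + 1
        for s, t, sg in sn.edges:
            edge_counts[(s, t)] = edge_counts.get((s, t), 0) + 1
            sign_of[(s, t)] = sg
        for t in sn.targets:
            target_counts[t] = target_counts.get(t, 0) + 1
    node_freq = {k: v / n for k, v in node_counts.items()}
    edge_freq = {k: v / n for k, v in edge_counts.items()}
    target_freq = {k: v / n for k, v in target_counts.items()}

    union = nx.DiGraph()
    for (s, t), f in edge_freq.items():
        union.add_edge(s, t, freq=f)

    def build(thr_node, thr_target):
        g = nx.DiGraph()
        keep_nodes = {nd for nd, f in node_freq.items() if f >= thr_node} | {tf}
        for (s, t), f in edge_freq.items():
            if f >= thr_node and s in keep_nodes and t in keep_nodes:
                g.add_edge(s, t)
        targets = [t for t, f in target_freq.items() if f >= thr_target and t in g]
        return g, [t for t in targets if nx.has_path(g, t, tf)] if tf in g else []

    g, connected = build(threshold, threshold)
    thr_target = threshold
    while not connected and thr_target > 0:
        # relax the target threshold until at least one target survives
        remaining = [f for f in target_freq.values() if f < thr_target]
        if not remaining:
            break
        thr_target = max(remaining)
        g, connected = build(threshold, thr_target)
    if not connected:
        # reconnect via the union path with the highest summed edge frequency
        best = None
        for t in sorted(target_freq, key=target_freq.get, reverse=True):
            if t not in union or tf not in union:
                continue
            for path in nx.all_simple_paths(union, t, tf, cutoff=12):
                s = sum(union[a][b]["freq"] for a, b in zip(path, path[1:]))
                if best is None or s > best[0]:
                    best = (s, path)
        if best is None:
            raise ValueError("no target can be reconnected to the TF")
        for a, b in zip(best[1], best[1][1:]):
            g.add_edge(a, b)
        connected = [best[1][0]]
    g = _clean(g, connected, tf)
    return MoASubnetwork(
        nodes=sorted(g.nodes),
        edges=sorted((s, t, sign_of[(s, t)]) for s, t in g.edges),
        targets=[t for t in connected if t in g],
        tf=tf, drug=drug,
        node_freq={nd: node_freq.get(nd, 0.0) for nd in g.nodes},
        edge_freq={e: edge_freq.get(e, 0.0) for e in g.edges},
    )


def simplest_paths(subnet: MoASubnetwork) -> MoASubnetwork:
    """Union over targets of the shortest directed path (edge count) to
    the TF; ties broken by maximal summed edge frequency, then lexically."""
    g = subnet.to_digraph()
    sign_of = {(s, t): sg for s, t, sg in subnet.edges}
    kept_edges: set[tuple[str, str]] = set()
    kept_targets = []
    for t in subnet.targets:
        if t not in g or not nx.has_path(g, t, subnet.tf):
            warnings.warn(f"target {t!r} unreachable in subnetwork; omitted")
            continue
        paths = list(nx.all_shortest_paths(g, t, subnet.tf))
        scored = sorted(
            paths,
            key=lambda p: (-sum(subnet.edge_freq.get((a, b), 0.0)
                                for a, b in zip(p, p[1:])), p))
        best = scored[0]
        kept_edges.update(zip(best, best[1:]))
        kept_targets.append(t)
    nodes = sorted({n for e in kept_edges for n in e})
    return MoASubnetwork(
        nodes=nodes,
        edges=sorted((s, t, sign_of[(s, t)]) for s, t in kept_edges),
        targets=kept_targets, tf=subnet.tf, drug=subnet.drug,
        node_freq={n: subnet.node_freq.get(n, 0.0) for n in nodes},
        edge_freq={e: subnet.edge_freq.get(e, 0.0) for e in kept_edges},
    )


# ----------------------------------------------------------- knockouts

def insilico_knockout(
    ensemble: Ensemble | DrugSignalingModel,
    nodes: list[str],
    conditions: ConditionTable,
    level: float = -10.0,
    signal_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Clamp nodes with a strongly negative input and return TF activities.

    ``level`` is added to the node-space input of every listed node
    (default -10); ``signal_mask`` optionally restricts the drug signal
    (e.g. on-target-only).  Returns the ensemble-mean TF activities, one
    row per sample.
    """
    models = (ensemble.members if isinstance(ensemble, Ensemble) else None)
    first = models[0].model if models else ensemble
    index = first.net.node_index()
    for nd in nodes:
        if nd not in index:
            raise KeyError(f"unknown node {nd!r}")
    extra = np.zeros((len(conditions.sample_ids), first.net.n_nodes))
    for nd in nodes:
        extra[:, index[nd]] += level
    kwargs = dict(extra_node_input=extra, signal_mask=signal_mask)
    if models:
        preds = np.mean([m.model.predict(conditions, **kwargs) for m in models], axis=0)
    else:
        preds = first.predict(conditions, **kwargs)
    return pd.DataFrame(preds, index=conditions.sample_ids, columns=first.tf_ids)
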