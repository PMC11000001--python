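"""Seeded synthetic fixtures: toy networks, ground-truth models with
planted off-target interactions, and simulated TF-activity datasets.

The generators emulate the study design end to end without external
data: a signed signaling network in which every drug-target node reaches
a TF, a ground-truth parameterization whose recurrence is contractive by
construction, a drug-target truth table from which some interactions are
withheld ("planted off-targets") when disclosing the prior to a model,
and clustered binary fingerprints so that drugs sharing targets are
chemically similar — the mechanism that lets similarity-mediated
inference recover the withheld interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import FingerprintSet, SimilarityMatrix, similarity_matrix
from .drug_module import ConditionTable
from .exceptions import GenerationError
from .pkn import SignalingNetwork, trim_network
from .qc import scale_dose
from .signaling import (SignalingParams, default_target_rho, project_to_tf,
                        propagate_steady_state, _linear_spectral_radius)


def generate_toy_network(
    n_nodes: int = 40,
    n_targets: int = 10,
    n_tfs: int = 12,
    edge_density: float = 0.08,
    feedback_fraction: float = 0.0,
    seed: int = 0,
    activating_fraction: float = 0.7,
    max_retries: int = 50,
) -> SignalingNetwork:
    """Random signed digraph where every target reaches >= 1 TF, every TF
    is reachable, and trimming is the identity.

    Nodes are laid out targets -> hidden -> TFs; forward edges are drawn
    at ``edge_density``, then ``feedback_fraction`` of that many backward
    (cycle-forming) edges are added.  ``feedback_fraction=0`` yields a DAG.
    """
    if n_targets + n_tfs > n_nodes:
        raise ValueError("n_targets + n_tfs must be <= n_nodes")
    rng = np.random.default_rng(seed)
    targets = [f"T{i}" for i in range(n_targets)]
    n_hidden = n_nodes - n_targets - n_tfs
    hidden = [f"H{i}" for i in range(n_hidden)]
    tfs = [f"F{i}" for i in range(n_tfs)]
    order = targets + hidden + tfs  # topological layout for forward edges

    for _ in range(max_retries):
        edge_set: set[tuple[str, str]] = set()
        n = len(order)
        for i in range(n):
            for j in range(i + 1, n):
                src, dst = order[i], order[j]
                if src in tfs or dst in targets:
                    continue  # TFs are sinks, targets are sources
                if rng.random() < edge_density:
                    edge_set.add((src, dst))
        # repair: every target must reach a TF, every TF must be reachable
        for t_i, t in enumerate(targets):
            if not any(s == t for s, _ in edge_set):
                edge_set.add((t, (hidden + tfs)[rng.integers(len(hidden) + len(tfs))]))
        for f in tfs:
            if not any(d == f for _, d in edge_set):
                edge_set.add(((targets + hidden)[rng.integers(n_targets + n_hidden)], f))
        for h in hidden:
            if not any(s == h for s, _ in edge_set):
                edge_set.add((h, tfs[rng.integers(n_tfs)]))
            if not any(d == h for _, d in edge_set):
                edge_set.add((targets[rng.integers(n_targets)], h))
        n_feedback = int(round(feedback_fraction * len(edge_set)))
        pos = {nd: i for i, nd in enumerate(order)}
        # feedback edges must close actual cycles: only add a backward edge
        # a -> b when a forward path b -> ... -> a already exists
        import networkx as nx
        fwd = nx.DiGraph(list(edge_set))
        candidates = [(a, b) for a in hidden + tfs for b in hidden
                      if pos[a] > pos[b] and (a, b) not in edge_set
                      and a in fwd and b in fwd and nx.has_path(fwd, b, a)]
        if candidates and n_feedback:
            pick = rng.choice(len(candidates), size=min(n_feedback, len(candidates)),
                              replace=False)
            for i in pick:
                edge_set.add(candidates[i])
        edges = [(s, d, 1 if rng.random() < activating_fraction else -1)
                 for s, d in sorted(edge_set)]
        nodes = [nd for nd in order]
        net = SignalingNetwork(nodes=nodes, edges=edges,
                               target_nodes=targets, tf_nodes=tfs)
        try:
            trimmed = trim_network(net)
        except Exception:
            continue
        if trimmed == net:
            return net
    raise GenerationError(
        f"no trim-stable network found in {max_retries} attempts; "
        "increase edge_density or node budget")


@dataclass
class GroundTruth:
    """True model + truth/prior drug-target tables for recovery studies."""

    net: SignalingNetwork
    params: SignalingParams            # true, contractive by construction
    truth: pd.DataFrame                # columns drug, target, sign (all true)
    prior: pd.DataFrame                # truth minus planted_offtargets
    planted_offtargets: list[tuple[str, str, int]]
    fingerprints: FingerprintSet
    sim: SimilarityMatrix
    signal_gain: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0


def generate_ground_truth(
    net: SignalingNetwork,
    n_drugs: int = 10,
    n_planted: int = 1,
    weight_scale: float = 0.8,
    signal_gain: float = 2.0,
    noise_sd: float = 0.05,
    n_bits: int = 256,
    bits_per_drug: int = 40,
    shared_bit_fraction: float = 0.6,
    basal_bias_range: tuple[float, float] = (0.1, 0.4),
    min_effect: float = 0.25,
    max_attempts: int = 100,
    seed: int = 0,
) -> GroundTruth:
    """Sample a ground-truth model and drug-target tables on ``net``.

    Edge weights follow the prior signs and are rescaled so the
    linear-regime spectral radius is ``weight_scale * target_rho``; biases
    drawn from ``basal_bias_range`` give nodes basal activity so that
    inhibitory interactions are observable.  Each drug receives 1-3 true
    targets; the drug-target assignment is resampled until every truth
    interaction shifts some TF activity by at least ``min_effect`` in a
    noiseless paired simulation (an interaction with no observable effect
    cannot meaningfully be recovered or withheld).  ``n_planted``
    interactions (from drugs with >= 2 targets, preferring targets shared
    with another drug) are withheld from the disclosed prior.
    Fingerprints are clustered so drugs sharing a target are similar: the
    drug carrying a planted interaction shares ``shared_bit_fraction`` of
    its set bits with a drug whose disclosed prior contains that target.
    """
    rng = np.random.default_rng(seed)
    params = SignalingParams.from_network(net, seed=seed, weight_scale=weight_scale)
    params.b.data[:] = rng.uniform(*basal_bias_range, size=net.n_nodes)
    drugs = [f"D{i}" for i in range(n_drugs)]
    targets = list(net.target_nodes)

    # only (target, sign) combinations with a material downstream influence
    # can carry truth interactions; weak targets stay in the universe as
    # genuine negatives
    combos = []
    for t in targets:
        for s in (1, -1):
            single = pd.DataFrame({"drug": [drugs[0]], "target": [t], "sign": [s]})
            base, _ = _noiseless_activity(net, params, single.iloc[0:0], drugs[:1], signal_gain)
            pert, _ = _noiseless_activity(net, params, single, drugs[:1], signal_gain)
            if float(np.abs(base - pert).max()) >= min_effect:
                combos.append((t, s))
    if len(combos) < 2:
        raise GenerationError("network has too few influential drug targets")

    truth = planted_rows = None
    for _ in range(max_attempts):
        rows = []
        for g in drugs:
            k = int(rng.integers(1, 4))
            chosen = rng.choice(len(combos), size=min(k, len(combos)), replace=False)
            for ci in chosen:
                t, s = combos[ci]
                rows.append({"drug": g, "target": t, "sign": s})
        cand = pd.DataFrame(rows).drop_duplicates(subset=["drug", "target"])
        if _min_interaction_effect(net, params, cand, drugs, signal_gain) >= min_effect:
            truth = cand
            break
    if truth is None:
        raise GenerationError(
            f"no drug-target assignment with all effects >= {min_effect} "
            f"found in {max_attempts} attempts")
    # ensure enough multi-target drugs to withhold from
    counts = truth.groupby("drug").size()
    eligible = truth[truth["drug"].isin(counts[counts >= 2].index)]
    if len(eligible) < n_planted:
        raise GenerationError("n_planted exceeds withholdable interactions")
    # prefer withholding interactions whose target is shared with another
    # drug, so chemical similarity can mediate their recovery
    target_counts = truth.groupby("target")["drug"].nunique()
    shared = eligible[eligible["target"].isin(target_counts[target_counts >= 2].index)]
    pool = shared if len(shared) >= n_planted else eligible
    planted_rows = pool.sample(n=n_planted, random_state=int(rng.integers(2 ** 31)))
    planted = [(r["drug"], r["target"], int(r["sign"])) for _, r in planted_rows.iterrows()]
    prior = truth.drop(index=planted_rows.index).reset_index(drop=True)
    # every drug must keep >= 1 disclosed target
    if set(prior["drug"]) != set(drugs):
        raise GenerationError("withholding left a drug with no disclosed target")

    # clustered fingerprints: group drugs by shared targets; the partner of
    # a planted pair is a drug whose *disclosed* prior carries that target
    planted_by_drug = {g: t for g, t, _ in planted}
    prior_by_target: dict[str, list[str]] = {}
    for _, r in prior.iterrows():
        prior_by_target.setdefault(r["target"], []).append(r["drug"])
    bits = np.zeros((n_drugs, n_bits), dtype=np.int8)
    target_owner: dict[str, str] = {}
    assigned: set[str] = set()
    # drugs carrying a withheld interaction get their fingerprint last so
    # they can share bits with an already-assigned disclosed-prior partner
    order = ([g for g in drugs if g not in planted_by_drug]
             + [g for g in drugs if g in planted_by_drug])
    for g in order:
        gi = drugs.index(g)
        own = truth[truth["drug"] == g]["target"].tolist()
        partner = None
        if g in planted_by_drug:
            # a drug with a withheld interaction must be similar to a drug
            # whose DISCLOSED prior carries that target, or similarity
            # cannot mediate the recovery
            owners = [h for h in prior_by_target.get(planted_by_drug[g], [])
                      if h != g and h in assigned]
            if owners:
                partner = owners[0]
        if partner is None:
            for t in own:
                if t in target_owner and target_owner[t] in assigned:
                    partner = target_owner[t]
                    break
        if partner is None:
            template = rng.choice(n_bits, size=bits_per_drug, replace=False)
        else:
            ptmpl = np.flatnonzero(bits[drugs.index(partner)])
            n_shared = int(round(shared_bit_fraction * bits_per_drug))
            shared = rng.choice(ptmpl, size=min(n_shared, ptmpl.size), replace=False)
            rest = np.setdiff1d(np.arange(n_bits), ptmpl)
            fresh = rng.choice(rest, size=bits_per_drug - shared.size, replace=False)
            template = np.concatenate([shared, fresh])
        bits[gi, template] = 1
        assigned.add(g)
        for t in own:
            target_owner.setdefault(t, g)
    fps = FingerprintSet(drug_ids=drugs, bits=bits)
    sim = similarity_matrix(fps)
    return GroundTruth(net=net, params=params, truth=truth.reset_index(drop=True),
                       prior=prior, planted_offtargets=planted, fingerprints=fps,
                       sim=sim, signal_gain=signal_gain, noise_sd=noise_sd, seed=seed)


def _noiseless_activity(net, params, table: pd.DataFrame, drugs: list[str],
                        signal_gain: float,
                        doses_uM: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0)):
    """Noise-free TF activities for every (drug, dose) pair under a given
    interaction table; returns (Y, sample_drug)."""
    targets = list(net.target_nodes)
    t_index = {t: i for i, t in enumerate(targets)}
    by_drug: dict[str, list[tuple[int, int]]] = {}
    for _, r in table.iterrows():
        by_drug.setdefault(r["drug"], []).append((t_index[r["target"]], int(r["sign"])))
    sample_drug = [g for g in drugs for _ in doses_uM]
    u = np.zeros((len(sample_drug), net.n_nodes))
    for si, (g, dose) in enumerate((g, d) for g in drugs for d in doses_uM):
        for ti, sign in by_drug.get(g, []):
            u[si, params.target_idx[ti]] = scale_dose(dose) * sign * signal_gain
    h, _, _ = propagate_steady_state(u, params)
    return h.data[:, params.tf_idx], sample_drug


def _min_interaction_effect(net, params, table: pd.DataFrame, drugs: list[str],
                            signal_gain: float) -> float:
    """Smallest max-|ΔTF| over interactions when each is removed in turn."""
    base, sample_drug = _noiseless_activity(net, params, table, drugs, signal_gain)
    sample_drug = np.array(sample_drug)
    worst = np.inf
    for ri in table.index:
        reduced, _ = _noiseless_activity(net, params, table.drop(index=ri),
                                         drugs, signal_gain)
        rows = sample_drug == table.loc[ri, "drug"]
        worst = min(worst, float(np.abs(base[rows] - reduced[rows]).max()))
    return worst


def true_drug_signal(gt: GroundTruth, conditions: ConditionTable,
                     table: pd.DataFrame | None = None) -> np.ndarray:
    """(n_samples, n_targets) signal from the TRUE interaction table:
    scaled dose x sign x gain on each of the perturbing drug's targets."""
    table = gt.truth if table is None else table
    targets = list(gt.net.target_nodes)
    t_index = {t: i for i, t in enumerate(targets)}
    by_drug: dict[str, list[tuple[int, int]]] = {}
    for _, r in table.iterrows():
        by_drug.setdefault(r["drug"], []).append((t_index[r["target"]], int(r["sign"])))
    S = np.zeros((len(conditions.sample_ids), len(targets)))
    for si, g in enumerate(conditions.sample_drug):
        dose = conditions.X[si].max()
        for ti, sign in by_drug.get(g, []):
            S[si, ti] = dose * sign * gt.signal_gain
    return S


def simulate_dataset(
    gt: GroundTruth,
    doses_uM: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0),
    noise_sd: float | None = None,
    seed: int = 0,
    replicates: int = 1,
    table: pd.DataFrame | None = None,
):
    """Simulate (ConditionTable, TF-activity DataFrame) from the truth.

    Each (drug, dose) pair becomes one sample (``replicates`` rows share
    the noiseless mean and differ by iid Gaussian noise, sd
    ``noise_sd``); activities are clipped to [0, 1].
    """
    noise_sd = gt.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    drugs = list(gt.fingerprints.drug_ids)
    sample_ids, sample_drug, doses, groups = [], [], [], []
    for g in drugs:
        for dose in doses_uM:
            base = f"{g}_{dose}"
            for r in range(replicates):
                sample_ids.append(f"{base}_r{r}" if replicates > 1 else base)
                sample_drug.append(g)
                doses.append(dose)
                groups.append(base)
    X = np.zeros((len(sample_ids), len(drugs)))
    d_index = {g: i for i, g in enumerate(drugs)}
    for i, (g, dose) in enumerate(zip(sample_drug, doses)):
        X[i, d_index[g]] = scale_dose(dose)
    conditions = ConditionTable(sample_ids=sample_ids, drug_ids=drugs, X=X,
                                sample_drug=sample_drug, groups=groups)
    S = true_drug_signal(gt, conditions, table=table)
    n_nodes = gt.net.n_nodes
    u = np.zeros((len(sample_ids), n_nodes))
    u[:, gt.params.target_idx] = S
    h, _, traj = propagate_steady_state(u, gt.params)
    if not traj.converged.all():
        raise GenerationError("truth model did not converge to steady state")
    wp_true = np.ones(len(gt.net.tf_nodes))
    Y = project_to_tf(h.data, wp_true, gt.params.tf_idx)
    Y = Y + rng.normal(0.0, noise_sd, size=Y.shape)
    Y = np.clip(Y, 0.0, 1.0)
    tf_activity = pd.DataFrame(Y, index=sample_ids, columns=list(gt.net.tf_nodes))
    return conditions, tf_activity
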