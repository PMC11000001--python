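"""Prior-knowledge signaling network: data model, SIF-style I/O, trimming.

The signaling model is constrained to the edges of a curated signed,
directed protein-protein interaction network (PKN).  Before model
construction the PKN is trimmed so that every remaining node lies on a
directed path from some drug-target node to some transcription factor;
pure self-loop nodes are removed as well.  Trimming iterates to a fixed
point, and drug targets or TFs that fall off the network are reported so
the caller can drop the corresponding drugs or activity columns.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import networkx as nx

from .exceptions import EmptyModelError, NetworkParseError, SignContradictionError

_SIGN_TOKENS = {
    "1": 1, "+1": 1, "activation": 1, "+": 1,
    "-1": -1, "inhibition": -1, "-": -1,
}


@dataclass
class SignalingNetwork:
    """Signed directed signaling graph with designated targets and TFs.

    Node order is the insertion order of first appearance and determines
    all downstream weight-matrix indices, so it must be reproducible.
    """

    nodes: list[str]
    edges: list[tuple[str, str, int]]  # (source, target, sign)
    target_nodes: list[str] = field(default_factory=list)
    tf_nodes: list[str] = field(default_factory=list)

    def __post_init__(self):
        node_set = set(self.nodes)
        for s, t, sign in self.edges:
            if s not in node_set or t not in node_set:
                raise ValueError(f"edge endpoint not in nodes: {(s, t)}")
            if sign not in (1, -1):
                raise ValueError(f"edge sign must be +/-1, got {sign!r}")
        for name, subset in (("target_nodes", self.target_nodes), ("tf_nodes", self.tf_nodes)):
            missing = set(subset) - node_set
            if missing:
                raise ValueError(f"{name} not in nodes: {sorted(missing)}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s, t, sign in self.edges:
            g.add_edge(s, t, sign=sign)
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignalingNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and sorted(self.edges) == sorted(other.edges)
            and sorted(self.target_nodes) == sorted(other.target_nodes)
            and sorted(self.tf_nodes) == sorted(other.tf_nodes)
        )


def read_network(path, dialect: str = "sif3") -> SignalingNetwork:
    """Read a SIF-like TSV (source, sign, target[, source_db]).

    Duplicate (source, target) rows are deduplicated; conflicting signs on
    the same ordered pair raise :class:`SignContradictionError`.
    """
    if dialect not in ("sif3", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    nodes: list[str] = []
    seen_nodes: set[str] = set()
    edge_sign: dict[tuple[str, str], int] = {}
    edge_order: list[tuple[str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and row[0].strip().lower() == "source":
                continue  # optional header
            if len(row) < 3:
                raise NetworkParseError(f"line {lineno}: expected 3+ fields, got {len(row)}")
            src, sign_tok, tgt = row[0], row[1].strip().lower(), row[2]
            if sign_tok not in _SIGN_TOKENS:
                raise NetworkParseError(f"line {lineno}: bad sign token {row[1]!r}")
            sign = _SIGN_TOKENS[sign_tok]
            for n in (src, tgt):
                if n not in seen_nodes:
                    seen_nodes.add(n)
                    nodes.append(n)
            key = (src, tgt)
            if key in edge_sign:
                if edge_sign[key] != sign:
                    raise SignContradictionError(
                        f"line {lineno}: conflicting signs for edge {src}->{tgt}"
                    )
            else:
                edge_sign[key] = sign
                edge_order.append(key)
    edges = [(s, t, edge_sign[(s, t)]) for s, t in edge_order]
    return SignalingNetwork(nodes=nodes, edges=edges)


def write_network(net: SignalingNetwork, path) -> None:
    """Write a network as SIF-like TSV; round-trips through read_network."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "sign", "target"])
        for s, t, sign in net.edges:
            writer.writerow([s, str(sign), t])


def trim_network(
    net: SignalingNetwork,
    drug_targets: set[str] | None = None,
    tfs: set[str] | None = None,
    return_dropped: bool = False,
):
    """Restrict the network to nodes on directed drug-target -> TF paths.

    Iteratively removes (a) nodes/edges on no directed path from any
    drug-target node to any TF, (b) nodes whose only in- and out-edge is a
    self-loop, and (c) targets/TFs that fall off the network, until a fixed
    point.  Reachability ignores edge signs.  Raises
    :class:`EmptyModelError` when no target or no TF survives.
    """
    targets = list(drug_targets) if drug_targets is not None else list(net.target_nodes)
    tf_list = list(tfs) if tfs is not None else list(net.tf_nodes)
    if not targets or not tf_list:
        raise EmptyModelError("trimming requires nonempty drug-target and TF sets")

    g = net.to_digraph()
    targets = [t for t in targets if t in g]
    tf_list = [t for t in tf_list if t in g]

    while True:
        changed = False
        # nodes whose only source and only target is the node itself
        selfloop = [
            n for n in list(g.nodes)
            if g.has_edge(n, n)
            and set(g.predecessors(n)) == {n} and set(g.successors(n)) == {n}
        ]
        if selfloop:
            g.remove_nodes_from(selfloop)
            changed = True
        cur_targets = [t for t in targets if t in g]
        cur_tfs = [t for t in tf_list if t in g]
        if not cur_targets or not cur_tfs:
            raise EmptyModelError("no drug-target -> TF path remains after trimming")
        # nodes reachable from a target AND reaching a TF lie on some path
        from_targets: set[str] = set()
        for t in cur_targets:
            from_targets.add(t)
            from_targets |= nx.descendants(g, t)
        to_tfs: set[str] = set()
        for f in cur_tfs:
            to_tfs.add(f)
            to_tfs |= nx.ancestors(g, f)
        keep = from_targets & to_tfs
        drop = set(g.nodes) - keep
        if drop:
            g.remove_nodes_from(drop)
            changed = True
        if not changed:
            break

    kept = set(g.nodes)
    nodes = [n for n in net.nodes if n in kept]
    edges = [(s, t, sign) for s, t, sign in net.edges if g.has_edge(s, t)]
    kept_targets = [t for t in targets if t in kept]
    kept_tfs = [t for t in tf_list if t in kept]
    if not kept_targets or not kept_tfs:
        raise EmptyModelError("no drug-target -> TF path remains after trimming")
    trimmed = SignalingNetwork(nodes=nodes, edges=edges,
                               target_nodes=kept_targets, tf_nodes=kept_tfs)
    if return_dropped:
        dropped_targets = [t for t in targets if t not in kept]
        dropped_tfs = [t for t in tf_list if t not in kept]
        return trimmed, dropped_targets, dropped_tfs
    return trimmed
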