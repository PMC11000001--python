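"""Composite model: drug module feeding the recurrent signaling network.

The drug module turns a dose matrix into signals on target nodes; those
signals are scattered onto the signaling network's node space, propagated
to steady state, and projected to TF activities.  A trained model is
fully described by its checkpoint (network structure, every parameter
vector, batch-norm state and configuration), and reloading a checkpoint
reproduces eval-mode predictions bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .drug_module import ConditionTable, DrugModuleParams, drug_forward
from .pkn import SignalingNetwork
from .signaling import SignalingParams, StateTrajectory, project_to_tf, propagate_steady_state

CHECKPOINT_VERSION = 1


@dataclass
class ForwardResult:
    """Everything a loss evaluation needs from one forward pass."""

    tf_activity: Tensor        # (n_samples, n_tfs)
    drug_signal: Tensor        # (n_samples, n_targets)
    steady_state: Tensor       # (n_samples, n_nodes)
    preactivation: Tensor      # cached for the spectral-radius Jacobian
    trajectory: StateTrajectory


class DrugSignalingModel:
    """Drug module + signaling network over a shared trimmed PKN."""

    def __init__(self, drug_params: DrugModuleParams, sig_params: SignalingParams):
        if list(drug_params.target_ids) != list(sig_params.net.target_nodes):
            raise ValueError("drug-module targets must match the network's target nodes")
        self.drug_params = drug_params
        self.sig_params = sig_params
        n = sig_params.net.n_nodes
        t = len(drug_params.target_ids)
        proj = np.zeros((t, n))
        proj[np.arange(t), sig_params.target_idx] = 1.0
        self._target_to_node = proj

    @property
    def net(self) -> SignalingNetwork:
        return self.sig_params.net

    @property
    def tf_ids(self) -> list[str]:
        return list(self.net.tf_nodes)

    def trainable(self, include_drug_module: bool = True) -> list[Tensor]:
        params = list(self.sig_params.trainable())
        if include_drug_module:
            params.extend(self.drug_params.trainable())
        return params

    def signal_to_node_space(self, S: Tensor | np.ndarray) -> Tensor:
        if not isinstance(S, Tensor):
            S = Tensor(S)
        return S @ Tensor(self._target_to_node)

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        signal_mask: np.ndarray | None = None,
        extra_node_input: np.ndarray | None = None,
        drug_module_training: bool | None = None,
    ) -> ForwardResult:
        """Full forward pass; ``signal_mask`` (n x t) multiplies the drug
        signal (used for off-target masking and interaction removal) and
        ``extra_node_input`` is added in node space (used for in-silico
        knockouts).  ``drug_module_training`` overrides ``training`` for
        the drug module alone (frozen-drug-module retraining)."""
        dm_training = training if drug_module_training is None else drug_module_training
        S = drug_forward(X, self.drug_params, training=dm_training, rng=rng)
        if signal_mask is not None:
            S = S.mask(np.asarray(signal_mask, dtype=float))
        u = self.signal_to_node_space(S)
        if extra_node_input is not None:
            u = u + Tensor(np.asarray(extra_node_input, dtype=float))
        h, z, traj = propagate_steady_state(u, self.sig_params)
        y = project_to_tf(h, self.sig_params.wp, self.sig_params.tf_idx)
        return ForwardResult(tf_activity=y, drug_signal=S, steady_state=h,
                             preactivation=z, trajectory=traj)

    def predict_signal(self, X: np.ndarray) -> np.ndarray:
        """Deterministic eval-mode drug-module signal (numpy)."""
        return drug_forward(X, self.drug_params, training=False).data

    def predict(self, conditions: ConditionTable | np.ndarray, **kwargs) -> np.ndarray:
        """Deterministic eval-mode TF-activity prediction (numpy)."""
        X = conditions.X if isinstance(conditions, ConditionTable) else np.asarray(conditions)
        return self.forward(X, training=False, **kwargs).tf_activity.data

    # ------------------------------------------------------------ checkpoint
    def to_checkpoint(self) -> dict:
        net = self.net
        dp, sp = self.drug_params, self.sig_params
        return {
            "version": CHECKPOINT_VERSION,
            "network": {
                "nodes": net.nodes,
                "edges": [[s, t, sg] for s, t, sg in net.edges],
                "target_nodes": net.target_nodes,
                "tf_nodes": net.tf_nodes,
            },
            "drug_module": {
                "drug_ids": dp.drug_ids,
                "target_ids": dp.target_ids,
                "Wsim": dp.Wsim.tolist(),
                "Wdrug": dp.Wdrug.data.tolist(),
                "Wdrug_trainable": bool(dp.Wdrug.requires_grad),
                "wdt": dp.wdt.data.tolist(),
                "wdt_rows": dp.wdt_rows.tolist(),
                "wdt_cols": dp.wdt_cols.tolist(),
                "prior_mask": dp.prior_mask.astype(int).tolist(),
                "bn_gamma": dp.bn_gamma.data.tolist(),
                "bn_beta": dp.bn_beta.data.tolist(),
                "bn_running_mean": dp.bn_running_mean.tolist(),
                "bn_running_var": dp.bn_running_var.tolist(),
                "bn_momentum": dp.bn_momentum,
                "bn_bypass": dp.bn_bypass,
                "dropout_rate": dp.dropout_rate,
                "lambda_dt": "inf" if np.isinf(dp.lambda_dt) else dp.lambda_dt,
            },
            "signaling": {
                "w": sp.w.data.tolist(),
                "b": sp.b.data.tolist(),
                "wp": sp.wp.data.tolist(),
                "leak": sp.leak,
                "knot": sp.knot,
                "max_steps": sp.max_steps,
                "tol": sp.tol,
                "target_rho": sp.target_rho,
            },
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_checkpoint(), fh)

    @classmethod
    def from_checkpoint(cls, ckpt: dict) -> "DrugSignalingModel":
        if ckpt.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {ckpt.get('version')!r}")
        netd = ckpt["network"]
        net = SignalingNetwork(
            nodes=list(netd["nodes"]),
            edges=[(s, t, int(sg)) for s, t, sg in netd["edges"]],
            target_nodes=list(netd["target_nodes"]),
            tf_nodes=list(netd["tf_nodes"]),
        )
        dmd = ckpt["drug_module"]
        lam = float("inf") if dmd["lambda_dt"] == "inf" else float(dmd["lambda_dt"])
        dp = DrugModuleParams(
            drug_ids=list(dmd["drug_ids"]),
            target_ids=list(dmd["target_ids"]),
            Wsim=np.array(dmd["Wsim"]),
            Wdrug=Tensor(np.array(dmd["Wdrug"]), requires_grad=bool(dmd["Wdrug_trainable"])),
            wdt=Tensor(np.array(dmd["wdt"]), requires_grad=True),
            wdt_rows=np.array(dmd["wdt_rows"], dtype=int),
            wdt_cols=np.array(dmd["wdt_cols"], dtype=int),
            prior_mask=np.array(dmd["prior_mask"], dtype=bool),
            bn_gamma=Tensor(np.array(dmd["bn_gamma"]), requires_grad=True),
            bn_beta=Tensor(np.array(dmd["bn_beta"]), requires_grad=True),
            bn_running_mean=np.array(dmd["bn_running_mean"]),
            bn_running_var=np.array(dmd["bn_running_var"]),
            bn_momentum=float(dmd["bn_momentum"]),
            bn_bypass=bool(dmd["bn_bypass"]),
            dropout_rate=float(dmd["dropout_rate"]),
            lambda_dt=lam,
        )
        sgd = ckpt["signaling"]
        index = net.node_index()
        sp = SignalingParams(
            net=net,
            edge_rows=np.array([index[t] for _, t, _ in net.edges], dtype=int),
            edge_cols=np.array([index[s] for s, _, _ in net.edges], dtype=int),
            signs=np.array([sg for _, _, sg in net.edges], dtype=float),
            w=Tensor(np.array(sgd["w"]), requires_grad=True),
            b=Tensor(np.array(sgd["b"]), requires_grad=True),
            wp=Tensor(np.array(sgd["wp"]), requires_grad=True),
            tf_idx=np.array([index[t] for t in net.tf_nodes], dtype=int),
            target_idx=np.array([index[t] for t in net.target_nodes], dtype=int),
            leak=float(sgd["leak"]),
            knot=float(sgd["knot"]),
            max_steps=int(sgd["max_steps"]),
            tol=float(sgd["tol"]),
            target_rho=float(sgd["target_rho"]),
        )
        return cls(dp, sp)

    @classmethod
    def load(cls, path) -> "DrugSignalingModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_checkpoint(json.load(fh))
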