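"""Trainable drug module: doses -> signals on signaling-network targets.

The module computes  S = bn(X (Wsim o Wdrug)) WDT :  the dose matrix is
mixed across drugs by the element-wise product of the frozen chemical
similarity matrix and a trainable scaler Wdrug (initialized at the
identity), batch-normalized per drug channel, passed through dropout
during training, and projected onto target nodes by the trainable
drug-target matrix WDT.  WDT is dense over the full drug x target space:
known prior interactions are initialized at sign * 0.1 and all other
entries at 0, so that similarity-mediated training can populate
previously unknown interactions.  An L2 penalty pulling Wdrug towards
the identity (strength lambda_DT) controls how much chemical similarity
may contribute; at lambda_DT = infinity Wdrug is frozen at I and the
module degenerates to S = X WDT, i.e. prior knowledge only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .chem import SimilarityMatrix

BN_MOMENTUM = 0.6
BN_EPS = 1e-5
DROPOUT_RATE = 0.1
DEFAULT_LAMBDA_DT = 5e-3
PRIOR_INIT_MAGNITUDE = 0.1


@dataclass
class ConditionTable:
    """Samples x drugs dose matrix (log10(uM + 1) scaled) with annotations."""

    sample_ids: list[str]
    drug_ids: list[str]
    X: np.ndarray                       # (n_samples, n_drugs), scaled doses
    sample_drug: list[str]              # perturbing drug per sample
    groups: list[str] | None = None     # replicate group / cell line labels

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.sample_ids), len(self.drug_ids)):
            raise ValueError("X must be (n_samples, n_drugs)")
        if (self.X < 0).any():
            raise ValueError("scaled doses must be nonnegative")
        # all-zero rows are permitted: a zero dose of the perturbing drug
        # is a vehicle control

    @property
    def sample_drug_idx(self) -> np.ndarray:
        index = {d: i for i, d in enumerate(self.drug_ids)}
        return np.array([index[d] for d in self.sample_drug], dtype=int)

    def subset(self, sample_mask: np.ndarray) -> "ConditionTable":
        sample_mask = np.asarray(sample_mask)
        idx = np.flatnonzero(sample_mask) if sample_mask.dtype == bool else sample_mask
        return ConditionTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            drug_ids=list(self.drug_ids),
            X=self.X[idx],
            sample_drug=[self.sample_drug[i] for i in idx],
            groups=[self.groups[i] for i in idx] if self.groups is not None else None,
        )


@dataclass
class DrugModuleParams:
    """Parameters and batch-norm state of the drug module.

    WDT is sparse: one trainable value per known prior interaction
    (``wdt`` on support ``wdt_rows``/``wdt_cols``).  Signal on targets
    outside a drug's prior arises solely through the Wdrug-scaled
    similarity mixing into other drugs' prior channels.
    """

    drug_ids: list[str]
    target_ids: list[str]
    Wsim: np.ndarray                    # (d, d) frozen similarity
    Wdrug: Tensor                       # (d, d) trainable similarity scaler
    wdt: Tensor                         # prior-support values of WDT
    wdt_rows: np.ndarray                # drug index per prior interaction
    wdt_cols: np.ndarray                # target index per prior interaction
    prior_mask: np.ndarray              # (d, t) bool: known interactions
    bn_gamma: Tensor
    bn_beta: Tensor
    bn_running_mean: np.ndarray
    bn_running_var: np.ndarray
    bn_momentum: float = BN_MOMENTUM
    bn_bypass: bool = False
    dropout_rate: float = DROPOUT_RATE
    lambda_dt: float = DEFAULT_LAMBDA_DT

    def wdt_dense(self) -> Tensor:
        return self.wdt.scatter_to(self.wdt_rows, self.wdt_cols,
                                   (len(self.drug_ids), len(self.target_ids)))

    @classmethod
    def initialize(
        cls,
        sim: SimilarityMatrix,
        target_ids: list[str],
        prior: pd.DataFrame,
        lambda_dt: float = DEFAULT_LAMBDA_DT,
        bn_bypass: bool = False,
        dropout_rate: float = DROPOUT_RATE,
    ) -> "DrugModuleParams":
        """Build from a similarity matrix and a prior table with columns
        (drug, target, sign)."""
        d, t = len(sim.drug_ids), len(target_ids)
        drug_index = {x: i for i, x in enumerate(sim.drug_ids)}
        target_index = {x: i for i, x in enumerate(target_ids)}
        prior_mask = np.zeros((d, t), dtype=bool)
        rows, cols, vals = [], [], []
        for _, row in prior.iterrows():
            g, tgt, sign = str(row["drug"]), str(row["target"]), int(row["sign"])
            if g not in drug_index or tgt not in target_index:
                continue
            i, j = drug_index[g], target_index[tgt]
            if prior_mask[i, j]:
                continue
            prior_mask[i, j] = True
            rows.append(i)
            cols.append(j)
            vals.append(sign * PRIOR_INIT_MAGNITUDE)
        frozen = math.isinf(lambda_dt)
        return cls(
            drug_ids=list(sim.drug_ids),
            target_ids=list(target_ids),
            Wsim=sim.values.copy(),
            Wdrug=Tensor(np.eye(d), requires_grad=not frozen),
            wdt=Tensor(np.array(vals, dtype=float), requires_grad=True),
            wdt_rows=np.array(rows, dtype=int),
            wdt_cols=np.array(cols, dtype=int),
            prior_mask=prior_mask,
            bn_gamma=Tensor(np.ones(d), requires_grad=True),
            bn_beta=Tensor(np.zeros(d), requires_grad=True),
            bn_running_mean=np.zeros(d),
            bn_running_var=np.ones(d),
            bn_bypass=bn_bypass,
            dropout_rate=dropout_rate,
            lambda_dt=lambda_dt,
        )

    def trainable(self) -> list[Tensor]:
        params = [self.wdt, self.bn_gamma, self.bn_beta]
        if self.Wdrug.requires_grad:
            params.append(self.Wdrug)
        return params


@dataclass
class DrugSignal:
    """Signals on target nodes (n_samples x n_targets)."""

    S: np.ndarray
    target_ids: list[str]


def drug_forward(
    X: np.ndarray | Tensor,
    params: DrugModuleParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Forward pass S = bn(X (Wsim o Wdrug)) WDT as an autodiff tensor.

    Batch-norm running statistics are updated only when ``training``;
    dropout (rate 0.1) applies after batch norm, before WDT, training
    only.  Inference mode is deterministic and affine in X.
    """
    if not isinstance(X, Tensor):
        X = Tensor(X)
    mixed = X @ (params.Wdrug * Tensor(params.Wsim))
    if params.bn_bypass:
        normed = mixed
    elif training:
        mean = mixed.mean(axis=0, keepdims=True)
        var = ((mixed - mean) ** 2).mean(axis=0, keepdims=True)
        normed = (mixed - mean) / (var + BN_EPS).sqrt()
        normed = normed * params.bn_gamma + params.bn_beta
        m = params.bn_momentum
        params.bn_running_mean *= (1.0 - m)
        params.bn_running_mean += m * mean.data.ravel()
        params.bn_running_var *= (1.0 - m)
        params.bn_running_var += m * var.data.ravel()
    else:
        normed = (mixed - params.bn_running_mean) / np.sqrt(params.bn_running_var + BN_EPS)
        normed = normed * params.bn_gamma + params.bn_beta
    if training and params.dropout_rate > 0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = (rng.random(normed.shape) >= params.dropout_rate) / (1.0 - params.dropout_rate)
        normed = normed.mask(keep)
    out = normed @ params.wdt_dense()
    if not np.isfinite(out.data).all():
        raise FloatingPointError("non-finite drug-module output")
    return out


def dt_regularization(params: DrugModuleParams) -> Tensor:
    """lambda_DT * sum((Wdrug - I)^2); zero (no gradient) when frozen."""
    if math.isinf(params.lambda_dt) or not params.Wdrug.requires_grad:
        return Tensor(0.0)
    dev = params.Wdrug - Tensor(np.eye(len(params.drug_ids)))
    return (dev * dev).sum() * params.lambda_dt


def offtarget_mask(params: DrugModuleParams, conditions: ConditionTable) -> np.ndarray:
    """(n_samples, n_targets) 0/1 mask keeping only known-target columns
    of each sample's perturbing drug."""
    drug_index = {d: i for i, d in enumerate(params.drug_ids)}
    rows = []
    for g in conditions.sample_drug:
        if g not in drug_index:
            raise KeyError(f"drug {g!r} absent from the drug module")
        rows.append(params.prior_mask[drug_index[g]])
    return np.asarray(rows, dtype=float)


def mask_offtarget_signal(S: Tensor | np.ndarray, params: DrugModuleParams,
                          conditions: ConditionTable):
    """Zero every target column of S outside the perturbing drug's prior."""
    m = offtarget_mask(params, conditions)
    if isinstance(S, Tensor):
        return S.mask(m)
    return np.asarray(S) * m


# --------------------------------------------------------------------- I/O

def read_prior(path) -> pd.DataFrame:
    """Drug-target prior TSV: drug <TAB> target <TAB> sign."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["drug", "target", "sign"][: len(df.columns)]
    df["sign"] = df["sign"].astype(int)
    if not df["sign"].isin([1, -1]).all():
        raise ValueError("prior signs must be +/-1")
    return df


def write_prior(prior: pd.DataFrame, path) -> None:
    prior.to_csv(path, sep="\t", index=False)


def read_conditions(path, drug_ids: list[str] | None = None) -> ConditionTable:
    """Condition TSV: sample <TAB> drug <TAB> dose_uM <TAB> group.

    Doses are log-scaled as log10(dose + 1); the drug axis is either the
    provided ``drug_ids`` or the sorted set of drugs present.
    """
    from .qc import scale_dose

    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["sample", "drug", "dose_uM", "group"][: len(df.columns)]
    if drug_ids is None:
        drug_ids = sorted(df["drug"].unique())
    drug_index = {d: i for i, d in enumerate(drug_ids)}
    samples = list(df["sample"])
    X = np.zeros((len(samples), len(drug_ids)))
    for i, row in df.reset_index(drop=True).iterrows():
        X[i, drug_index[str(row["drug"])]] = scale_dose(float(row["dose_uM"]))
    return ConditionTable(
        sample_ids=samples,
        drug_ids=list(drug_ids),
        X=X,
        sample_drug=[str(d) for d in df["drug"]],
        groups=[str(g) for g in df["group"]] if "group" in df.columns else None,
    )


def write_conditions(cond: ConditionTable, doses_uM: np.ndarray, path) -> None:
    """Write the raw-dose condition TSV (doses in uM, not log-scaled)."""
    pd.DataFrame({
        "sample": cond.sample_ids,
        "drug": cond.sample_drug,
        "dose_uM": doses_uM,
        "group": cond.groups if cond.groups is not None else ["g0"] * len(cond.sample_ids),
    }).to_csv(path, sep="\t", index=False)
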