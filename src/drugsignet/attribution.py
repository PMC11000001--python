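"""Drug-target interaction inference from trained models.

Integrated gradients attribute each target-node signal to the drug's
dose input (baseline 0); because the drug module in eval mode is affine
in the dose, the attribution has a closed form (effective weight x
input) that any step count reproduces exactly, while a generic
trapezoid-rule path integral covers nonlinear heads.  A per-drug cutoff
on |score| is chosen from an error curve: interactions are masked in
ascending |score| order and the cutoff is the first |score| whose
cumulative removal raises the model's MAE by at least 25%.  Interactions
inferred by many models of an ensemble are scored by their frequency of
appearance, and the inferred sets are evaluated against a truth table
with confusion-matrix metrics, an exact one-tailed binomial test of
accuracy against the no-information rate, G-mean, the new-discovery rate
(NDR) and the true-positive rate over prior interactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .autodiff import Tensor
from .drug_module import BN_EPS, ConditionTable, DrugModuleParams, drug_forward
from .model import DrugSignalingModel

DEFAULT_IG_STEPS = 64
DEFAULT_MAE_INCREASE = 0.25


# ----------------------------------------------------- integrated gradients

def integrated_gradients(
    model: DrugSignalingModel | DrugModuleParams,
    drug: str,
    dose_scaled: float = 1.0,
    m: int = DEFAULT_IG_STEPS,
    exact_if_linear: bool = True,
) -> pd.Series:
    """Signed per-target attribution of the drug module's output to the
    drug's dose input (integration baseline 0).

    Negative scores indicate inhibition, positive activation.  For the
    affine eval-mode drug module the closed form is used unless
    ``exact_if_linear=False``, in which case an m-step trapezoid path
    integral is computed (m >= 2).
    """
    params = model.drug_params if isinstance(model, DrugSignalingModel) else model
    if m < 2:
        raise ValueError("integration steps m must be >= 2")
    d_index = {g: i for i, g in enumerate(params.drug_ids)}
    if drug not in d_index:
        raise KeyError(f"unknown drug {drug!r}")
    gi = d_index[drug]
    if exact_if_linear:
        # eval mode: S(x) = (x A) diag(c) WDT + const, gradient is constant
        A = params.Wdrug.data * params.Wsim
        if params.bn_bypass:
            c = np.ones(len(params.drug_ids))
        else:
            c = params.bn_gamma.data / np.sqrt(params.bn_running_var + BN_EPS)
        eff = (A * c[None, :]) @ params.wdt_dense().data   # (d, t)
        scores = dose_scaled * eff[gi]
    else:
        x = np.zeros((1, len(params.drug_ids)))
        x[0, gi] = dose_scaled
        scores = _path_integral_scores(params, x, gi, m)
    return pd.Series(scores, index=list(params.target_ids), name=drug)


def integrated_gradients_fn(f, x: np.ndarray, m: int = DEFAULT_IG_STEPS) -> np.ndarray:
    """Generic integrated gradients of a differentiable map.

    ``f`` maps a (1, d) input tensor to a (1, k) output tensor built from
    autodiff ops; the straight path from baseline 0 to ``x`` is integrated
    with an m-point trapezoid rule.  Returns a (d, k) attribution matrix
    (x_i - 0) * integral of dF_k/dx_i.
    """
    if m < 2:
        raise ValueError("integration steps m must be >= 2")
    x = np.asarray(x, dtype=float).reshape(1, -1)
    alphas = np.linspace(0.0, 1.0, m)
    weights = np.full(m, 1.0 / (m - 1))
    weights[0] = weights[-1] = 0.5 / (m - 1)
    grads = None
    for alpha, wgt in zip(alphas, weights):
        xt = Tensor(alpha * x, requires_grad=True)
        out = f(xt)
        k = out.shape[1]
        if grads is None:
            grads = np.zeros((x.shape[1], k))
        for j in range(k):
            for node in _graph_nodes(out):
                node.grad = None
            seed = np.zeros_like(out.data)
            seed[0, j] = 1.0
            out.backward(seed)
            grads[:, j] += wgt * xt.grad[0]
    return x[0][:, None] * grads


def _path_integral_scores(params: DrugModuleParams, x: np.ndarray, gi: int, m: int) -> np.ndarray:
    attr = integrated_gradients_fn(
        lambda xt: drug_forward(xt, params, training=False), x, m=m)
    return attr[gi]


def _graph_nodes(t: Tensor):
    seen, stack, nodes = set(), [t], []
    while stack:
        cur = stack.pop()
        if id(cur) in seen:
            continue
        seen.add(id(cur))
        nodes.append(cur)
        stack.extend(cur._parents)
    return nodes


def score_table(model: DrugSignalingModel, conditions: ConditionTable,
                m: int = DEFAULT_IG_STEPS) -> pd.DataFrame:
    """(drug x target) integrated-gradient scores, one row per drug, at
    each drug's maximum administered scaled dose."""
    rows = {}
    for g in conditions.drug_ids:
        doses = [conditions.X[i].max() for i, d in enumerate(conditions.sample_drug) if d == g]
        dose = max(doses) if doses else 1.0
        rows[g] = integrated_gradients(model, g, dose_scaled=dose, m=m)
    return pd.DataFrame(rows).T  # drugs x targets


# --------------------------------------------------------- error-curve cutoff

@dataclass
class InferenceResult:
    """Per-model inferred interactions with their error-curve diagnostics."""

    inferred: set[tuple[str, str]]
    cutoffs: dict[str, float | None]          # per drug; None = flat curve
    curves: dict[str, list[tuple[int, float]]]  # (n_removed, MAE) per drug
    scores: pd.DataFrame


def error_curve_cutoff(
    model: DrugSignalingModel,
    conditions: ConditionTable,
    tf_activity: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    increase: float = DEFAULT_MAE_INCREASE,
    scope: str = "global",
    focal_tf: str | None = None,
    m: int = DEFAULT_IG_STEPS,
) -> InferenceResult:
    """Infer interactions per drug by masking them in ascending |score|
    order until the MAE rises by ``increase`` (relative).

    ``scope='global'`` measures MAE across all TFs; ``scope='per_drug_tf'``
    restricts it to ``focal_tf``.  A drug whose curve never reaches the
    threshold contributes no inferred interactions (flat-curve case).
    """
    if scope not in ("global", "per_drug_tf"):
        raise ValueError("scope must be 'global' or 'per_drug_tf'")
    if scope == "per_drug_tf" and focal_tf is None:
        raise ValueError("per_drug_tf scope needs focal_tf")
    if scores is None:
        scores = score_table(model, conditions, m=m)
    tf_ids = model.tf_ids
    tf_cols = [tf_ids.index(focal_tf)] if scope == "per_drug_tf" else list(range(len(tf_ids)))
    Y = tf_activity.loc[conditions.sample_ids, tf_ids].to_numpy(dtype=float)
    target_ids = list(model.drug_params.target_ids)
    inferred: set[tuple[str, str]] = set()
    cutoffs: dict[str, float | None] = {}
    curves: dict[str, list[tuple[int, float]]] = {}
    sample_drug = np.array(conditions.sample_drug)
    for g in conditions.drug_ids:
        sel = np.flatnonzero(sample_drug == g)
        if sel.size == 0:
            continue
        Xg, Yg = conditions.X[sel], Y[np.ix_(sel, tf_cols)]
        base_pred = model.predict(Xg)[:, tf_cols]
        base_mae = float(np.abs(base_pred - Yg).mean())
        # ascending |score|, ties broken by (drug, target) lexical order
        order = sorted(target_ids, key=lambda t: (abs(scores.loc[g, t]), g, t))
        mask = np.ones((sel.size, len(target_ids)))
        curve = [(0, base_mae)]
        cutoff = None
        for k, tgt in enumerate(order, start=1):
            mask[:, target_ids.index(tgt)] = 0.0
            pred = model.predict(Xg, signal_mask=mask)[:, tf_cols]
            mae = float(np.abs(pred - Yg).mean())
            curve.append((k, mae))
            if cutoff is None and base_mae > 0 and mae >= (1.0 + increase) * base_mae:
                cutoff = float(abs(scores.loc[g, tgt]))
        curves[g] = curve
        cutoffs[g] = cutoff
        if cutoff is not None:
            for tgt in target_ids:
                # an interaction with exactly zero attribution carries no
                # drug-specific signal and is never considered inferred,
                # even when the cutoff itself is zero
                if abs(scores.loc[g, tgt]) >= cutoff and abs(scores.loc[g, tgt]) > 0:
                    inferred.add((g, tgt))
    return InferenceResult(inferred=inferred, cutoffs=cutoffs, curves=curves,
                           scores=scores)


def ensemble_frequency(inferred_sets: list[set[tuple[str, str]]]) -> pd.Series:
    """Fraction of models inferring each (drug, target) interaction."""
    if not inferred_sets:
        raise ValueError("need >= 1 model")
    counts: dict[tuple[str, str], int] = {}
    for s in inferred_sets:
        for pair in s:
            counts[pair] = counts.get(pair, 0) + 1
    n = len(inferred_sets)
    idx = pd.MultiIndex.from_tuples(sorted(counts), names=["drug", "target"])
    return pd.Series([counts[p] / n for p in sorted(counts)], index=idx, name="frequency")


# ----------------------------------------------------------------- metrics

@dataclass
class InteractionMetrics:
    """Confusion counts and derived rates for an inferred-interaction set."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    nir: float
    binom_p: float
    precision: float
    recall: float
    f1: float
    g_mean: float
    ndr: float
    tpr_prior: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def interaction_metrics(
    inferred: set[tuple[str, str]],
    truth: set[tuple[str, str]],
    universe: set[tuple[str, str]],
    prior: set[tuple[str, str]] | None = None,
) -> InteractionMetrics:
    """Evaluate an inferred set against a truth set over a (drug x target)
    universe.

    The negative class is every universe pair absent from the truth set
    (true negatives are operationally unknowable; this is the standing
    convention).  NDR counts inferred pairs outside the prior; TPR is
    recall restricted to prior interactions.
    """
    if not truth:
        raise ValueError("empty truth set: recall undefined")
    prior = set() if prior is None else prior
    inferred, truth = set(inferred) & universe, set(truth) & universe
    tp = len(inferred & truth)
    fp = len(inferred - truth)
    fn = len(truth - inferred)
    tn = len(universe) - tp - fp - fn
    total = len(universe)
    accuracy = (tp + tn) / total
    nir = max(len(truth), total - len(truth)) / total
    correct = tp + tn
    binom_p = float(stats.binomtest(correct, total, p=nir, alternative="greater").pvalue)
    precision = tp / (tp + fp) if (tp + fp) else math.nan
    recall = tp / (tp + fn) if (tp + fn) else math.nan
    f1 = (2 * precision * recall / (precision + recall)
          if (tp + fp) and (tp + fn) and (precision + recall) > 0 else 0.0)
    sens = recall
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    g_mean = math.sqrt(sens * spec) if not (math.isnan(sens) or math.isnan(spec)) else math.nan
    ndr = len(inferred - prior) / len(inferred) if inferred else 0.0
    tpr_prior = (len(inferred & prior) / len(prior & universe)
                 if prior & universe else math.nan)
    return InteractionMetrics(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy,
                              nir=nir, binom_p=binom_p, precision=precision,
                              recall=recall, f1=f1, g_mean=g_mean, ndr=ndr,
                              tpr_prior=tpr_prior)


def frequency_filtered(freq: pd.Series, threshold: float) -> set[tuple[str, str]]:
    """Interactions whose ensemble frequency is >= threshold."""
    return set(freq[freq >= threshold].index)
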