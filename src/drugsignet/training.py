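"""Training and evaluation of single models and ensembles.

The composite training loss is

    loss = fitLoss + signConstraint + biasLoss + NetWeightLoss + DTLoss
         + DTregularization + 1e-3 * spectralRadiusLoss + stateLoss
         + projectionLoss,

minimized with Adam under a one-cycle learning-rate schedule between
lr_min and lr_max.  Ensembles are independently seeded models whose
predictions are averaged.  The evaluation protocol trains a full model
on one dataset, freezes its drug module, and retrains only the
signaling network on other datasets under chemically dissimilar
train/test drug splits; per-TF Pearson correlations on held-out drugs
measure how well the drug module generalizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .autodiff import Tensor
from .chem import SimilarityMatrix, dissimilar_split
from .drug_module import ConditionTable, DrugModuleParams, dt_regularization
from .exceptions import InfeasibleSplitError
from .model import DrugSignalingModel, ForwardResult
from .pkn import SignalingNetwork
from . import signaling as sig

@dataclass
class TrainConfig:
    """Hyper-parameters of a training run."""

    epochs: int = 5000
    batch_size: int = 25
    lr_min: float = 1e-8
    lr_max: float = 2e-3
    lambda_dt: float = 5e-3
    ensemble_size: int = 50
    seed: int = 0
    warmup_fraction: float = 0.4      # one-cycle: fraction of steps warming up
    power_iterations: int = 50        # spectral-radius power iteration steps
    spectral_coef: float = sig.SPECTRAL_LOSS_COEF
    state_coef: float = sig.STATE_LOSS_COEF
    convergence_tol: float = sig.CONVERGENCE_TOL

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.ensemble_size) < 1:
            raise ValueError("epochs, batch_size, ensemble_size must be positive")
        if not self.lr_min < self.lr_max:
            raise ValueError("lr_min must be < lr_max")


@dataclass
class LossBreakdown:
    """All loss terms of one evaluation; total obeys the stated identity."""

    fitLoss: float
    signConstraint: float
    biasLoss: float
    NetWeightLoss: float
    DTLoss: float
    DTregularization: float
    spectralRadiusLoss: float
    stateLoss: float                  # already carries its 1e-5 coefficient
    projectionLoss: float
    total: float
    spectral_radius: float = math.nan

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "fitLoss", "signConstraint", "biasLoss", "NetWeightLoss", "DTLoss",
            "DTregularization", "spectralRadiusLoss", "stateLoss",
            "projectionLoss", "total", "spectral_radius")}


def one_cycle_lr(step: int, total_steps: int, lr_min: float, lr_max: float,
                 warmup_fraction: float = 0.4) -> float:
    """Linear warm-up to lr_max, then cosine decay back to lr_min."""
    warm = max(1, int(round(warmup_fraction * total_steps)))
    if step < warm:
        return lr_min + (lr_max - lr_min) * step / warm
    frac = (step - warm) / max(1, total_steps - warm)
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * frac))


class Adam:
    """Adam optimizer over a list of autodiff tensors."""

    def __init__(self, params: list[Tensor], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


def total_loss(
    result: ForwardResult,
    observed: np.ndarray,
    model: DrugSignalingModel,
    config: TrainConfig,
    spectral_seed: int = 0,
):
    """Assemble the composite loss; returns (loss tensor, LossBreakdown)."""
    sp, dp = model.sig_params, model.drug_params
    diff = result.tf_activity - Tensor(np.asarray(observed, dtype=float))
    fit = (diff * diff).mean()
    sign_l = sig.sign_constraint_loss(sp.w, sp.signs)
    bias_l, proj_l = sig.bias_projection_losses(sp.b, sp.wp)
    netw_l = sig.regularize_weights(sp.w)
    dt_l = sig.regularize_weights(dp.wdt)
    dtreg_l = dt_regularization(dp)
    rho, spectral_l = sig.spectral_radius(
        sp, result.preactivation, n_iter=config.power_iterations, seed=spectral_seed)
    state_l = sig.state_loss(result.steady_state) * config.state_coef
    loss = (fit + sign_l + bias_l + netw_l + dt_l + dtreg_l
            + spectral_l * config.spectral_coef + state_l + proj_l)
    terms = {
        "fitLoss": fit, "signConstraint": sign_l, "biasLoss": bias_l,
        "NetWeightLoss": netw_l, "DTLoss": dt_l, "DTregularization": dtreg_l,
        "spectralRadiusLoss": spectral_l, "stateLoss": state_l,
        "projectionLoss": proj_l,
    }
    values = {}
    for name, tensor in terms.items():
        v = float(tensor.data)
        if not math.isfinite(v):
            raise FloatingPointError(f"non-finite loss term: {name}")
        values[name] = v
    breakdown = LossBreakdown(total=float(loss.data), spectral_radius=float(rho.data), **values)
    return loss, breakdown


@dataclass
class TrainedModel:
    """A trained model with its per-epoch loss log and provenance."""

    model: DrugSignalingModel
    log: list[dict] = field(default_factory=list)
    seed: int = 0
    config: TrainConfig | None = None

    def predict(self, conditions, **kwargs) -> np.ndarray:
        return self.model.predict(conditions, **kwargs)


def build_model(
    net: SignalingNetwork,
    prior: pd.DataFrame,
    sim: SimilarityMatrix,
    config: TrainConfig,
    seed: int,
) -> DrugSignalingModel:
    dp = DrugModuleParams.initialize(sim, list(net.target_nodes), prior,
                                     lambda_dt=config.lambda_dt)
    sp = sig.SignalingParams.from_network(net, seed=seed, tol=config.convergence_tol)
    return DrugSignalingModel(dp, sp)


def train_model(
    conditions: ConditionTable,
    tf_activity: pd.DataFrame,
    net: SignalingNetwork | None = None,
    prior: pd.DataFrame | None = None,
    sim: SimilarityMatrix | None = None,
    config: TrainConfig | None = None,
    seed: int = 0,
    model: DrugSignalingModel | None = None,
    train_drug_module: bool = True,
    log_every: int = 1,
) -> TrainedModel:
    """Minibatch-Adam training of a (possibly pre-built) model.

    ``tf_activity`` rows must align with ``conditions.sample_ids`` and its
    columns with the network's TF nodes.  Deterministic given the seed.
    With ``train_drug_module=False`` the drug module runs in eval mode and
    its parameters (incl. batch-norm state) stay bit-identical.
    """
    config = config or TrainConfig()
    if model is None:
        if net is None or prior is None or sim is None:
            raise ValueError("provide either a model or (net, prior, sim)")
        model = build_model(net, prior, sim, config, seed)
    Y = tf_activity.loc[conditions.sample_ids, model.tf_ids].to_numpy(dtype=float)
    n = len(conditions.sample_ids)
    rng = np.random.default_rng(seed)
    params = model.trainable(include_drug_module=train_drug_module)
    opt = Adam(params)
    n_batches = max(1, math.ceil(n / config.batch_size))
    total_steps = config.epochs * n_batches
    log: list[dict] = []
    snapshot = model.to_checkpoint()
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        last_breakdown = None
        try:
            for bi in range(n_batches):
                batch = order[bi * config.batch_size:(bi + 1) * config.batch_size]
                result = model.forward(
                    conditions.X[batch], training=True, rng=rng,
                    drug_module_training=None if train_drug_module else False,
                )
                loss, breakdown = total_loss(result, Y[batch], model, config,
                                             spectral_seed=seed)
                opt.zero_grad()
                loss.backward()
                lr = one_cycle_lr(step, total_steps, config.lr_min, config.lr_max,
                                  config.warmup_fraction)
                opt.step(lr)
                step += 1
                last_breakdown = breakdown
        except FloatingPointError as err:
            warnings.warn(f"training diverged at epoch {epoch} ({err}); "
                          "restoring last good checkpoint")
            model = DrugSignalingModel.from_checkpoint(snapshot)
            break
        if epoch % log_every == 0 or epoch == config.epochs - 1:
            log.append({"epoch": epoch, **last_breakdown.as_dict()})
        if epoch % 10 == 0:
            snapshot = model.to_checkpoint()
    return TrainedModel(model=model, log=log, seed=seed, config=config)


@dataclass
class Ensemble:
    """Independently seeded trained models; prediction = member mean."""

    members: list[TrainedModel]
    failed_seeds: list[int] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.members)

    def predict(self, conditions, **kwargs) -> np.ndarray:
        preds = [m.predict(conditions, **kwargs) for m in self.members]
        return np.mean(preds, axis=0)

    def member_predictions(self, conditions, **kwargs) -> np.ndarray:
        return np.stack([m.predict(conditions, **kwargs) for m in self.members])


def train_ensemble(
    conditions: ConditionTable,
    tf_activity: pd.DataFrame,
    net: SignalingNetwork,
    prior: pd.DataFrame,
    sim: SimilarityMatrix,
    config: TrainConfig | None = None,
    seed: int | None = None,
) -> Ensemble:
    """Train ``config.ensemble_size`` models with distinct derived seeds.

    A failed member is recorded and skipped; the ensemble proceeds if at
    least 80% of members succeed."""
    config = config or TrainConfig()
    base_seed = config.seed if seed is None else seed
    members, failed = [], []
    for i in range(config.ensemble_size):
        member_seed = (base_seed * 1009 + i) % (2 ** 31)
        try:
            members.append(train_model(conditions, tf_activity, net, prior, sim,
                                       config=config, seed=member_seed))
        except Exception as err:  # noqa: BLE001 - member failure is data
            warnings.warn(f"ensemble member seed={member_seed} failed: {err}")
            failed.append(member_seed)
    if len(members) < 0.8 * config.ensemble_size:
        raise RuntimeError(
            f"only {len(members)}/{config.ensemble_size} ensemble members trained")
    return Ensemble(members=members, failed_seeds=failed)


def shuffle_null(
    conditions: ConditionTable,
    tf_activity: pd.DataFrame,
    mode: str,
    seed: int = 0,
):
    """Null-model data: permute dose rows (shuffle_X) or activity rows
    (shuffle_Y) across samples; marginals are preserved."""
    if mode not in ("shuffle_X", "shuffle_Y"):
        raise ValueError("mode must be shuffle_X or shuffle_Y")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(conditions.sample_ids))
    if mode == "shuffle_X":
        shuffled = ConditionTable(
            sample_ids=list(conditions.sample_ids),
            drug_ids=list(conditions.drug_ids),
            X=conditions.X[perm],
            sample_drug=[conditions.sample_drug[i] for i in perm],
            groups=list(conditions.groups) if conditions.groups is not None else None,
        )
        return shuffled, tf_activity
    permuted = tf_activity.loc[conditions.sample_ids].iloc[perm]
    permuted.index = conditions.sample_ids
    return conditions, permuted


def per_tf_performance(pred: np.ndarray, obs: np.ndarray, tf_ids: list[str]) -> pd.DataFrame:
    """Per-TF Pearson r, two-sided p, BH-adjusted p and rank percentile.

    Zero-variance TFs get r = NaN and are flagged, not dropped."""
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    if pred.shape[0] < 3:
        raise ValueError("need >= 3 samples for correlation")
    rows = []
    for j, tf in enumerate(tf_ids):
        if np.std(pred[:, j]) == 0 or np.std(obs[:, j]) == 0:
            rows.append({"tf": tf, "r": np.nan, "p": np.nan, "undefined": True})
            continue
        r, p = stats.pearsonr(pred[:, j], obs[:, j])
        rows.append({"tf": tf, "r": float(r), "p": float(p), "undefined": False})
    df = pd.DataFrame(rows).set_index("tf")
    ok = ~df["undefined"]
    df["p_adj"] = np.nan
    if ok.any():
        df.loc[ok, "p_adj"] = _benjamini_hochberg(df.loc[ok, "p"].to_numpy())
    # percentile rank of r (1.0 = best-correlated TF)
    df["rank_pct"] = df["r"].rank(pct=True)
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    return adj


def frozen_drug_module_cv(
    source: TrainedModel,
    datasets: dict[str, tuple[ConditionTable, pd.DataFrame]],
    sim: SimilarityMatrix,
    config: TrainConfig | None = None,
    k_folds: int = 5,
    test_fraction: float = 0.2,
    sim_threshold: float = 0.5,
    seed: int = 0,
) -> dict[str, dict]:
    """Frozen-drug-module cross-validation on additional datasets.

    For every dataset the source model's drug module is kept frozen while
    a freshly initialized signaling module is trained on ~80% of drugs;
    held-out drugs are chemically dissimilar from the training drugs.
    Returns, per dataset, the per-fold per-TF validation performance and
    a train-rank vs validation-rank table.
    """
    config = config or (source.config or TrainConfig())
    results: dict[str, dict] = {}
    for name, (conditions, tf_activity) in datasets.items():
        folds = []
        for fold in range(k_folds):
            try:
                train_ids, test_ids, achieved = dissimilar_split(
                    sim, test_fraction=test_fraction, threshold=sim_threshold,
                    seed=seed * 101 + fold)
            except InfeasibleSplitError as err:
                warnings.warn(f"{name} fold {fold}: {err}; skipped")
                continue
            train_ids = [d for d in train_ids if d in set(conditions.sample_drug)]
            test_mask = np.array([d in set(test_ids) for d in conditions.sample_drug])
            train_mask = ~test_mask
            if test_mask.sum() == 0 or train_mask.sum() < 3:
                warnings.warn(f"{name} fold {fold}: degenerate split; skipped")
                continue
            fold_model = DrugSignalingModel.from_checkpoint(source.model.to_checkpoint())
            fold_model.sig_params = sig.SignalingParams.from_network(
                fold_model.net, seed=seed * 977 + fold, tol=config.convergence_tol)
            dm_before = fold_model.drug_params.wdt.data.copy()
            trained = train_model(
                conditions.subset(train_mask), tf_activity,
                config=config, seed=seed * 977 + fold,
                model=fold_model, train_drug_module=False)
            assert np.array_equal(trained.model.drug_params.wdt.data, dm_before)
            train_perf = per_tf_performance(
                trained.predict(conditions.subset(train_mask)),
                tf_activity.loc[np.array(conditions.sample_ids)[train_mask],
                                trained.model.tf_ids].to_numpy(),
                trained.model.tf_ids)
            val_perf = per_tf_performance(
                trained.predict(conditions.subset(test_mask)),
                tf_activity.loc[np.array(conditions.sample_ids)[test_mask],
                                trained.model.tf_ids].to_numpy(),
                trained.model.tf_ids)
            folds.append({
                "fold": fold, "achieved_test_fraction": achieved,
                "train": train_perf, "validation": val_perf,
                "rank_table": pd.DataFrame({
                    "train_rank_pct": train_perf["rank_pct"],
                    "validation_rank_pct": val_perf["rank_pct"],
                }),
            })
        results[name] = {
            "folds": folds,
            "mean_validation_r": float(np.nanmean(
                [f["validation"]["r"].mean() for f in folds])) if folds else math.nan,
        }
    return results
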