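"""Quality control of TF-activity matrices with technical replicates.

Replicated activity estimates are filtered in two permutation-based
steps before modeling: (1) TFs whose variance across technical
replicates is not demonstrably smaller than the variance across randomly
regrouped profiles are dropped (one-tailed Kolmogorov-Smirnov test
against a permutation null); (2) samples whose replicates do not
correlate better than randomly drawn signature subsets are dropped
(empirical tail probability).  Surviving replicates are merged by the
per-TF median.  Dose scaling for model input is log10(uM + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ReplicateSet:
    """Replicate signatures x TFs, with a sample -> replicate grouping."""

    activity: pd.DataFrame                  # index: replicate ids, columns: TFs
    groups: dict[str, list[str]]            # sample id -> replicate ids

    def __post_init__(self):
        assigned: list[str] = []
        for reps in self.groups.values():
            assigned.extend(reps)
        if sorted(assigned) != sorted(self.activity.index):
            raise ValueError("every replicate row must belong to exactly one group")

    def group_indices(self) -> dict[str, np.ndarray]:
        pos = {r: i for i, r in enumerate(self.activity.index)}
        return {s: np.array([pos[r] for r in reps]) for s, reps in self.groups.items()}


def _per_group_variances(matrix: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """(n_groups, n_tfs) variance of each TF within each replicate group."""
    return np.stack([matrix[idx].var(axis=0) for idx in group_idx])


def filter_tfs_by_variance(
    reps: ReplicateSet,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Keep TFs whose replicate variance is stochastically smaller than a
    row-permutation null.

    The null regroups randomly permuted rows into the original group-size
    structure; the actual and null variance distributions are compared per
    TF with a one-tailed two-sample KS test.  Returns (kept TF list,
    p-value Series).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    idx_map = reps.group_indices()
    multi = [idx for idx in idx_map.values() if idx.size >= 2]
    tfs = list(reps.activity.columns)
    if len(multi) < 2:
        warnings.warn("fewer than 2 multi-replicate groups: keeping all TFs")
        return tfs, pd.Series(np.nan, index=tfs)
    matrix = reps.activity.to_numpy()
    actual = _per_group_variances(matrix, multi)       # (n_groups, n_tfs)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(multi), len(tfs)))
    for p in range(n_perm):
        perm = rng.permutation(matrix.shape[0])
        null[p] = _per_group_variances(matrix[perm], multi)
    pvals = np.empty(len(tfs))
    for j in range(len(tfs)):
        # alternative='greater': CDF of the actual variances dominates the
        # null CDF, i.e. actual variances are stochastically smaller
        pvals[j] = stats.ks_2samp(actual[:, j], null[:, :, j].ravel(),
                                  alternative="greater").pvalue
    pseries = pd.Series(pvals, index=tfs)
    kept = [tf for tf in tfs if pseries[tf] <= alpha]
    return kept, pseries


def filter_replicates_by_correlation(
    reps: ReplicateSet,
    n_samples: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Drop samples whose replicates correlate no better than random
    signature subsets.

    For each group size k, the null is the mean pairwise Pearson r of
    ``n_samples`` random k-subsets of all signatures; a sample's p-value
    is the fraction of null draws >= its observed mean pairwise r.
    Singleton groups are kept unconditionally.  Returns (kept sample
    list, p-value Series).
    """
    matrix = reps.activity.to_numpy()
    n_rows = matrix.shape[0]
    if n_rows < 3:
        raise ValueError("need >= 3 signatures to build a correlation null")
    corr = np.corrcoef(matrix)
    rng = np.random.default_rng(seed)
    idx_map = reps.group_indices()
    sizes = sorted({idx.size for idx in idx_map.values() if idx.size >= 2})
    null_by_size: dict[int, np.ndarray] = {}
    iu_cache = {k: np.triu_indices(k, 1) for k in sizes}
    for k in sizes:
        draws = np.empty(n_samples)
        iu = iu_cache[k]
        for i in range(n_samples):
            pick = rng.choice(n_rows, size=k, replace=False)
            draws[i] = corr[np.ix_(pick, pick)][iu].mean()
        null_by_size[k] = draws
    pvals: dict[str, float] = {}
    kept: list[str] = []
    for sample, idx in idx_map.items():
        if idx.size < 2:
            pvals[sample] = np.nan
            kept.append(sample)
            continue
        iu = iu_cache[idx.size]
        observed = corr[np.ix_(idx, idx)][iu].mean()
        p = float((null_by_size[idx.size] >= observed).sum()) / n_samples
        pvals[sample] = p
        if p <= alpha:
            kept.append(sample)
    return kept, pd.Series(pvals)


def merge_replicates(reps: ReplicateSet) -> pd.DataFrame:
    """Per-sample element-wise median across its replicate rows."""
    idx_map = reps.group_indices()
    matrix = reps.activity.to_numpy()
    rows = {s: np.median(matrix[idx], axis=0) for s, idx in idx_map.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=reps.activity.columns)


def scale_dose(dose_uM):
    """log10(dose + 1) scaling of a nonnegative dose in micromolar."""
    dose = np.asarray(dose_uM, dtype=float)
    if (dose < 0).any():
        raise ValueError("doses must be nonnegative")
    out = np.log10(dose + 1.0)
    return float(out) if np.isscalar(dose_uM) or out.ndim == 0 else out
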