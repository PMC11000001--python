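"""Chemical similarity and chemically dissimilar train/test splitting.

Drugs are represented by fixed-length binary fingerprints (ECFP4-style,
2048 bits by default).  Pairwise Tanimoto similarity between the
fingerprints feeds the drug module (as the frozen similarity matrix) and
the evaluation protocol, which holds out drugs that are chemically
dissimilar from every training drug to prevent memorization of similar
structures from inflating validation performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InfeasibleSplitError, UndefinedSimilarityError


@dataclass
class FingerprintSet:
    """Ordered drug ids with one binary fingerprint vector per drug."""

    drug_ids: list[str]
    bits: np.ndarray  # (d, n_bits) 0/1

    def __post_init__(self):
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2 or len(self.drug_ids) != self.bits.shape[0]:
            raise ValueError("bits must be (n_drugs, n_bits)")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0/1")


@dataclass
class SimilarityMatrix:
    """Symmetric d x d Tanimoto similarity matrix with unit diagonal."""

    drug_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        d = len(self.drug_ids)
        if self.values.shape != (d, d):
            raise ValueError("similarity matrix shape must match drug_ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("similarity diagonal must be 1")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b| for two equal-length binary vectors."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("fingerprints must have equal length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise UndefinedSimilarityError("Tanimoto of two all-zero fingerprints is undefined")
    return float(np.logical_and(a, b).sum() / union)


def similarity_matrix(fps: FingerprintSet) -> SimilarityMatrix:
    """All-pairs Tanimoto similarity, vectorized via bit-count algebra."""
    bits = fps.bits.astype(np.float64)
    popcount = bits.sum(axis=1)
    if (popcount == 0).any():
        raise UndefinedSimilarityError("all-zero fingerprint in set")
    inter = bits @ bits.T
    union = popcount[:, None] + popcount[None, :] - inter
    values = inter / union
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(drug_ids=list(fps.drug_ids), values=values)


def dissimilar_split(
    sim: SimilarityMatrix,
    test_fraction: float = 0.2,
    threshold: float = 0.5,
    seed: int = 0,
    max_attempts: int = 1000,
):
    """Greedy seeded split with every test drug below `threshold` similarity
    to every train drug.

    Returns ``(train_ids, test_ids, achieved_fraction)``.  The achieved
    test fraction may undershoot the request when the constraint binds; if
    no attempt yields a nonempty test set an
    :class:`InfeasibleSplitError` is raised.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    d = len(sim.drug_ids)
    n_test_goal = max(1, int(round(test_fraction * d)))
    rng = np.random.default_rng(seed)

    # A test drug must be dissimilar to EVERY train drug, so connected
    # components of the "similarity >= threshold" graph can never be split
    # across train and test; feasible test sets are unions of components.
    from scipy.sparse.csgraph import connected_components

    adjacency = (sim.values >= threshold).astype(np.int8)
    n_comp, labels = connected_components(adjacency, directed=False)
    components = [np.flatnonzero(labels == c) for c in range(n_comp)]

    best: list[int] | None = None
    for _ in range(max_attempts):
        order = rng.permutation(n_comp)
        test: list[int] = []
        for c in order:
            if len(test) >= n_test_goal:
                break
            comp = components[c]
            if len(test) + comp.size >= d:  # train side must stay nonempty
                continue
            test.extend(int(i) for i in comp)
        if test and (best is None or abs(len(test) - n_test_goal) < abs(len(best) - n_test_goal)):
            best = test
        if best is not None and len(best) >= n_test_goal:
            break
    if best is None:
        raise InfeasibleSplitError(
            f"no nonempty dissimilar test set found in {max_attempts} attempts"
        )
    test_set = set(best)
    train_ids = [sim.drug_ids[i] for i in range(d) if i not in test_set]
    test_ids = [sim.drug_ids[i] for i in sorted(best)]
    return train_ids, test_ids, len(test_ids) / d


# --------------------------------------------------------------------- I/O

def read_fingerprints(path) -> FingerprintSet:
    """Read a fingerprint CSV: drug_id column followed by 0/1 bit columns."""
    df = pd.read_csv(path, index_col=0)
    return FingerprintSet(drug_ids=[str(i) for i in df.index], bits=df.to_numpy())


def write_fingerprints(fps: FingerprintSet, path) -> None:
    pd.DataFrame(fps.bits, index=fps.drug_ids).to_csv(path)


def read_similarity(path) -> SimilarityMatrix:
    """Read a square similarity CSV with matching header row and column."""
    df = pd.read_csv(path, index_col=0)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError("similarity CSV header row and index must match")
    return SimilarityMatrix(drug_ids=ids, values=df.to_numpy())


def write_similarity(sim: SimilarityMatrix, path) -> None:
    pd.DataFrame(sim.values, index=sim.drug_ids, columns=sim.drug_ids).to_csv(path)


def fingerprints_from_smiles(smiles: dict[str, str], n_bits: int = 2048, radius: int = 2) -> FingerprintSet:
    """Optional adapter: ECFP4 (Morgan radius 2) fingerprints from SMILES.

    Requires rdkit; the rest of the module works on precomputed bit
    vectors without any chemistry dependency.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    ids, rows = [], []
    for drug_id, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for {drug_id!r}: {smi!r}")
        fp = gen.GetFingerprintAsNumPy(mol)
        ids.append(drug_id)
        rows.append(np.asarray(fp, dtype=np.int8))
    return FingerprintSet(drug_ids=ids, bits=np.vstack(rows))


def read_smiles(path) -> dict[str, str]:
    """Read a two-column TSV: drug_id <TAB> smiles."""
    df = pd.read_csv(path, sep="\t", header=None, names=["drug_id", "smiles"], comment="#")
    return dict(zip(df["drug_id"].astype(str), df["smiles"].astype(str)))
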