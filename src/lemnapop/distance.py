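"""Pairwise genetic distances from diploid-model genotype calls.

The allele-sharing distance between two samples is the mean, over sites where
both have calls, of |dosage_i - dosage_j| / 2 with dosage(0/0)=0,
dosage(0/1)=1, dosage(1/1)=2 — the fraction of alleles that differ, with
unphased het-vs-het counted as no difference. Kinship matrices (e.g. from the
k-mer path) convert to distances as 1 - kinship.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix over named samples.

    ``values[i, j]`` is NaN for pairs with no usable shared sites (flagged,
    never silently zero); ``n_sites_used`` records the per-pair site count
    (zeros for matrices not derived from genotype tables).
    """

    ids: list[str]
    values: np.ndarray
    n_sites_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids length must match matrix size")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly zero")
        with np.errstate(invalid="ignore"):
            if np.any(v[~np.isnan(v)] < 0):
                raise ValueError("distances must be nonnegative")
        self.values = v
        if self.n_sites_used is None:
            self.n_sites_used = np.zeros_like(v, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def has_missing_pairs(self) -> bool:
        return bool(np.isnan(self.values).any())

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in ids]
        return DistanceMatrix(
            list(ids), self.values[np.ix_(idx, idx)],
            self.n_sites_used[np.ix_(idx, idx)],
        )

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def pairwise_allele_distance(table, min_shared_sites: int = 1) -> DistanceMatrix:
    """Allele-sharing distance over sites with pairwise-complete calls.

    Pairs sharing fewer than ``min_shared_sites`` called sites get NaN.
    """
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    if table.n_sites < 1:
        raise ValueError("need at least one site")
    gt = table.gt.astype(float)
    called = table.gt >= 0
    gt_z = np.where(called, gt, 0.0)
    c = called.astype(float)

    # mean |d_i - d_j| / 2 over shared sites; |d_i-d_j| decomposes over
    # genotype-pair counts, computed via matrix products per dosage level
    n = table.n_samples
    diff_sum = np.zeros((n, n))
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            ia = (table.gt == a).astype(float)
            ib = (table.gt == b).astype(float)
            diff_sum += abs(a - b) * (ia.T @ ib)
    shared = c.T @ c
    with np.errstate(invalid="ignore", divide="ignore"):
        d = diff_sum / 2.0 / shared
    d[shared < min_shared_sites] = np.nan
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # symmetrize exactly against float jitter
    del gt_z
    return DistanceMatrix(list(table.samples), d, shared.astype(np.int64))


def kinship_to_distance(kinship: np.ndarray, ids: list[str] | None = None) -> DistanceMatrix:
    """Convert a kinship/similarity matrix to distances, D = 1 - K.

    The diagonal is forced to zero; negative entries (kinship > 1) are
    floored at zero with a warning.
    """
    k = np.asarray(kinship, dtype=float)
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise ValueError("kinship matrix must be square")
    if not np.allclose(k, k.T):
        raise ValueError("kinship matrix must be symmetric")
    d = 1.0 - k
    np.fill_diagonal(d, 0.0)
    n_neg = int((d < 0).sum())
    if n_neg:
        warnings.warn(f"floored {n_neg} negative distance entries at 0", stacklevel=2)
        d = np.maximum(d, 0.0)
    d = (d + d.T) / 2
    if ids is None:
        ids = [f"S{i + 1}" for i in range(k.shape[0])]
    return DistanceMatrix(list(ids), d)


def _to_newick(node, ids: list[str]) -> str:
    if node.is_leaf():
        return ids[node.id]
    left = _to_newick(node.get_left(), ids)
    right = _to_newick(node.get_right(), ids)
    bl = node.dist  # height of this merge
    lb = bl - node.get_left().dist
    rb = bl - node.get_right().dist
    return f"({left}:{lb:.6g},{right}:{rb:.6g})"


def cluster_samples(
    dm: DistanceMatrix, linkage: str = "average", height: float | None = None
) -> tuple[str, dict[str, int] | None]:
    """Agglomerative clustering; returns a newick string and, if ``height``
    is given, a flat sample -> group assignment cut at that height.

    Pairs with missing distances must be imputed or removed first.
    """
    if dm.has_missing_pairs():
        raise ValueError(
            "distance matrix has missing-distance pairs; impute or drop those samples first"
        )
    if dm.n == 1:
        newick = f"{dm.ids[0]};"
        return newick, ({dm.ids[0]: 1} if height is not None else None)
    z = hierarchy.linkage(dm.condensed(), method=linkage)
    tree = hierarchy.to_tree(z)
    newick = _to_newick(tree, dm.ids) + ";"
    groups = None
    if height is not None:
        flat = hierarchy.fcluster(z, t=height, criterion="distance")
        groups = {s: int(g) for s, g in zip(dm.ids, flat)}
    return newick, groups
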