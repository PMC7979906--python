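"""Group discovery: identity-by-state distances, UPGMA clustering, genotype PCA.

IBS similarity between two individuals at a site is the fraction of shared
alleles, 1 - |g_i - g_j| / 2 for allele-count genotypes; the distance is one
minus the mean similarity over sites called in both (complete-case per
pair).  Clustering is average-linkage (UPGMA) on that distance matrix.  PCA
uses Patterson normalisation: per-site centering by twice the sample allele
frequency and scaling by sqrt(p(1-p)), with missing calls mean-imputed —
the convention of the standard genotype-PCA toolchain, under which
eigenvalue contribution ratios are comparable across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    samples: list[str]
    d: np.ndarray  # symmetric N x N in [0, 1]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.samples)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("nonzero diagonal")
        if not np.isfinite(self.d).all():
            raise ValueError("non-finite distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.samples, columns=self.samples)

    def pair(self, a: str, b: str) -> float:
        return float(self.d[self.samples.index(a), self.samples.index(b)])


@dataclass
class PCAResult:
    """Scores (N x K), eigenvalues and per-axis contribution ratios.

    Contribution ratio k = eigenvalue k / sum of positive eigenvalues;
    scores are eigenvectors scaled by sqrt(eigenvalue).
    """

    samples: list[str]
    scores: np.ndarray
    eigenvalues: np.ndarray
    contribution_ratios: np.ndarray

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.samples, columns=cols)


@dataclass
class Dendrogram:
    """UPGMA merge tree (scipy linkage encoding) over named samples."""

    samples: list[str]
    linkage: np.ndarray  # (N-1) x 4 scipy linkage matrix

    def cut(self, k: int) -> dict[str, int]:
        """Cut into k groups; returns sample id -> group label (1..k)."""
        flat = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return {s: int(g) for s, g in zip(self.samples, flat)}

    def leaf_order(self) -> list[str]:
        return [self.samples[i] for i in sch.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = sch.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.samples[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.6g}"

        left = rec(tree.left, tree.dist)
        right = rec(tree.right, tree.dist)
        return f"({left},{right});"


def ibs_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise identity-by-state distances, complete-case per pair.

    Raises if any pair has zero co-called sites (distance undefined).
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = gm.calls.astype(float)
    called = gm.calls != MISSING
    g[~called] = 0.0
    c = called.astype(float)
    # sum over co-called sites of |g_i - g_j| decomposes over genotype codes:
    # handled directly by looping over the three code values of one sample.
    n_co = c @ c.T
    if (n_co == 0).any():
        ii, jj = np.nonzero(n_co == 0)
        off = ii != jj
        if off.any():
            a, b = gm.samples[ii[off][0]], gm.samples[jj[off][0]]
            raise ValueError(f"no co-called sites for pair ({a}, {b})")
    # |gi - gj| summed over co-called sites via indicator matrices per code
    ind = {v: ((gm.calls == v) & called).astype(float) for v in (0, 1, 2)}
    absdiff = np.zeros_like(n_co)
    for vi in (0, 1, 2):
        for vj in (0, 1, 2):
            if vi == vj:
                continue
            absdiff += abs(vi - vj) * (ind[vi] @ ind[vj].T)
    with np.errstate(invalid="ignore"):
        d = (absdiff / 2.0) / np.maximum(n_co, 1)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(samples=list(gm.samples), d=d)


def upgma_cluster(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomerative clustering.

    Ties are broken deterministically by scipy's ordering, which follows
    sample input order.
    """
    if len(dm.samples) < 2:
        raise ValueError("need at least 2 samples to cluster")
    z = sch.linkage(squareform(dm.d, checks=False), method="average")
    return Dendrogram(samples=list(dm.samples), linkage=z)


def genotype_pca(
    gm: GenotypeMatrix, n_axes: int = 10, scale: bool = True
) -> PCAResult:
    """Genotype PCA with Patterson normalisation.

    Sites monomorphic over non-missing calls are excluded (their scaling is
    undefined).  ``scale=False`` gives an unscaled centred-covariance PCA
    for sensitivity checks.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    called = gm.calls != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, gm.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    poly = (n_alleles > 0) & (p > 0) & (p < 1)
    p = p[poly]
    x = gm.calls[:, poly].astype(float)
    miss = ~called[:, poly]
    x -= 2.0 * p  # mean centering; missing become 0 afterwards
    if scale:
        x /= np.sqrt(p * (1.0 - p))
    x[miss] = 0.0

    cov = (x @ x.T) / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals, 0.0, None)
    total = pos.sum()
    contrib = pos / total if total > 0 else pos
    k = min(n_axes, len(evals))
    scores = evecs[:, :k] * np.sqrt(pos[:k])
    return PCAResult(
        samples=list(gm.samples),
        scores=scores,
        eigenvalues=evals[:k],
        contribution_ratios=contrib[:k],
    )
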