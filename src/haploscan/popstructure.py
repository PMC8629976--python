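"""Population structure: p-distance NJ tree, PCA, LD pruning, group calling.

These are the analyses used to define the subpopulations that all the
two-group statistics compare: a neighbor-joining tree under p-distances,
principal components of the genotype matrix, windowed LD pruning of the SNP
set, and a k-means partition of the PCA scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj
from sklearn.cluster import KMeans

from .variant_io import GroupAssignment, HaploidGenotypes


@dataclass
class DistanceMatrix:
    """Pairwise p-distances (proportion of differing sites) between samples."""

    matrix: np.ndarray
    samples: list[str]

    def validate(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("p-distances must lie in [0, 1]")


@dataclass
class PCAResult:
    """Sample scores on the top components plus variance-explained shares."""

    scores: np.ndarray          # (n_samples, k)
    variance_fraction: np.ndarray
    samples: list[str]

    def to_frame(self) -> pd.DataFrame:
        k = self.scores.shape[1]
        df = pd.DataFrame(self.scores, columns=[f"PC{i+1}" for i in range(k)])
        df.insert(0, "sample", self.samples)
        return df


def p_distance_matrix(g: HaploidGenotypes) -> DistanceMatrix:
    """Pairwise p-distance: mismatches / pairwise-complete sites.

    Missing calls are excluded pairwise; a pair of samples with zero
    jointly-called sites is an error.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    a = g.alleles
    called = (a >= 0)
    n = g.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        both = called[:, i][:, None] & called[:, i + 1:]
        diff = (a[:, i][:, None] != a[:, i + 1:]) & both
        denom = both.sum(axis=0)
        if np.any(denom == 0):
            j = i + 1 + int(np.argmax(denom == 0))
            raise ValueError(f"samples {g.samples[i]!r} and {g.samples[j]!r} share no called sites")
        d[i, i + 1:] = d[i + 1:, i] = diff.sum(axis=0) / denom
    dm = DistanceMatrix(d, list(g.samples))
    dm.validate()
    return dm


def nj_tree(d: DistanceMatrix) -> str:
    """Saitou–Nei neighbor joining; returns an unrooted newick string.

    Negative branch lengths (an NJ artifact on non-additive matrices) are
    clamped to zero.
    """
    if len(d.samples) < 3:
        raise ValueError("NJ requires at least 3 taxa")
    tree = _skbio_nj(_SkbioDM(d.matrix, ids=d.samples), neg_as_zero=True)
    return str(tree).strip()


def pca(g: HaploidGenotypes, k: int = 10) -> PCAResult:
    """PCA of the genotype matrix via SVD of the site-centered data.

    Missing cells are mean-imputed per site; zero-variance sites are
    dropped. Variance fractions are relative to the total variance, so they
    sum to 1 over all components.
    """
    x = g.alleles.astype(float).T  # samples x sites
    x[x < 0] = np.nan
    mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mean, inds[1])
    x -= x.mean(axis=0)
    keep = x.std(axis=0) > 0
    x = x[:, keep]
    rank = min(x.shape)
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank}")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s ** 2
    return PCAResult(
        scores=u[:, :k] * s[:k],
        variance_fraction=var[:k] / var.sum(),
        samples=list(g.samples),
    )


def _r2_matrix(block: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between rows (sites), pairwise-complete."""
    m = block.shape[0]
    out = np.zeros((m, m))
    called = block >= 0
    x = block.astype(float)
    for i in range(m):
        for j in range(i + 1, m):
            ok = called[i] & called[j]
            if ok.sum() < 2:
                continue
            xi, xj = x[i, ok], x[j, ok]
            vi, vj = xi.var(), xj.var()
            if vi == 0 or vj == 0:
                continue
            c = ((xi - xi.mean()) * (xj - xj.mean())).mean()
            out[i, j] = out[j, i] = c * c / (vi * vj)
    return out


def ld_prune(g: HaploidGenotypes, window_sites: int = 50, step_sites: int = 10,
             r2_max: float = 0.8) -> HaploidGenotypes:
    """Windowed greedy LD pruning at an r² threshold.

    Within each sliding window of ``window_sites`` consecutive sites, the
    later member of any pair with r² > ``r2_max`` is removed; the window
    then advances by ``step_sites``. Deterministic given input site order.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    removed = np.zeros(g.n_sites, dtype=bool)
    for ci in range(len(g.contigs)):
        sites = np.nonzero(g.contig_index == ci)[0]
        start = 0
        while start < sites.size:
            win = sites[start:start + window_sites]
            alive = [s for s in win if not removed[s]]
            r2 = _r2_matrix(g.alleles[alive])
            for bi in range(len(alive)):
                if removed[alive[bi]]:
                    continue
                for bj in range(bi + 1, len(alive)):
                    if not removed[alive[bj]] and r2[bi, bj] > r2_max:
                        removed[alive[bj]] = True
            if start + window_sites >= sites.size:
                break
            start += step_sites
    return g.take_sites(np.nonzero(~removed)[0])


def assign_groups(scores: PCAResult, k_groups: int, seed: int = 0,
                  n_components: int | None = None, n_init: int = 10) -> GroupAssignment:
    """Partition samples by k-means on the top PCA components.

    Labels are ``group1``, ``group2``, ... ordered by descending group size
    (ties broken by first member index) so they are stable across runs with
    the same seed.
    """
    n = len(scores.samples)
    if k_groups > n:
        raise ValueError("more groups than samples")
    if k_groups == 1:
        return GroupAssignment({s: "group1" for s in scores.samples})
    x = scores.scores if n_components is None else scores.scores[:, :n_components]
    km = KMeans(n_clusters=k_groups, random_state=seed, n_init=n_init).fit(x)
    raw = km.labels_
    order = sorted(
        range(k_groups),
        key=lambda c: (-(raw == c).sum(), int(np.argmax(raw == c))),
    )
    relabel = {c: f"group{i+1}" for i, c in enumerate(order)}
    return GroupAssignment({s: relabel[c] for s, c in zip(scores.samples, raw)})
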