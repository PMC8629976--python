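"""Pairwise linkage disequilibrium, decay curves, and the LD50 rule.

Haploid genotypes are phased by nature, so two-locus haplotype frequencies
are read directly off the genotype matrix (pairwise-complete samples).
The decay summary bins all same-contig pairs by distance; LD50 is the
distance at which the binned mean r² first falls to half its maximum,
evaluated by the "closest point above half-max" rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .variant_io import HaploidGenotypes


@dataclass
class LDDecayCurve:
    """Binned LD decay: per distance bin, the mean r² and pair count."""

    bin_start: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    bin_size: int
    smoothed: np.ndarray | None = None

    def occupied(self) -> np.ndarray:
        return self.n_pairs > 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "bin_start": self.bin_start,
            "mean_r2": self.mean_r2,
            "n_pairs": self.n_pairs,
        })
        if self.smoothed is not None:
            df["smoothed"] = self.smoothed
        return df


def two_locus_ld(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """(r², D') for two haploid loci; None if uninformative.

    Uses pairwise-complete samples; loci monomorphic in that subset are
    skipped. D = p_AB - p_A p_B; r² = D²/(p_A q_A p_B q_B); D' = D/D_max
    with the sign-dependent D_max.
    """
    ok = (x >= 0) & (y >= 0)
    if ok.sum() < 4:
        return None
    xi, yi = x[ok].astype(float), y[ok].astype(float)
    pa, pb = xi.mean(), yi.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return None
    pab = np.mean(xi * yi)
    d = pab - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        return r2, 0.0
    return r2, abs(d) / dmax


def pairwise_r2(g: HaploidGenotypes, sample_idx: np.ndarray | None = None,
                max_dist: int = 10_000) -> pd.DataFrame:
    """All same-contig SNP pairs within ``max_dist`` bp: distance, r², D'.

    Pairs where either locus is monomorphic in the pairwise-complete sample
    subset are skipped.
    """
    a = g.alleles if sample_idx is None else g.alleles[:, sample_idx]
    dists: list[int] = []
    r2s: list[float] = []
    dps: list[float] = []
    for ci in range(len(g.contigs)):
        sites = np.nonzero(g.contig_index == ci)[0]
        pos = g.positions[sites]
        for ii in range(sites.size):
            jj = ii + 1
            while jj < sites.size and pos[jj] - pos[ii] <= max_dist:
                res = two_locus_ld(a[sites[ii]], a[sites[jj]])
                if res is not None:
                    dists.append(int(pos[jj] - pos[ii]))
                    r2s.append(res[0])
                    dps.append(res[1])
                jj += 1
    return pd.DataFrame({"dist": dists, "r2": r2s, "dprime": dps})


def subsample_sites(g: HaploidGenotypes, n_sites: int, seed: int) -> HaploidGenotypes:
    """Random SNP subsample (without replacement, position order kept).

    Used to compare LD decay between groups at an identical number of SNPs,
    so the group with denser segregating sites does not get finer pair
    resolution for free.
    """
    if n_sites >= g.n_sites:
        return g
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(g.n_sites, size=n_sites, replace=False))
    return g.take_sites(idx)


def ld_decay_curve(pairs: pd.DataFrame, bin_size: int = 100,
                   max_dist: int | None = None) -> LDDecayCurve:
    """Bin pairs by distance and average r² per bin.

    Bins are [k*bin_size+1, (k+1)*bin_size] covering 1..max_dist; empty
    bins carry NaN means and zero counts.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if max_dist is None:
        max_dist = int(pairs["dist"].max()) if len(pairs) else bin_size
    nbins = int(np.ceil(max_dist / bin_size))
    starts = np.arange(nbins) * bin_size + 1
    which = np.clip((pairs["dist"].to_numpy() - 1) // bin_size, 0, nbins - 1)
    counts = np.bincount(which, minlength=nbins)
    sums = np.bincount(which, weights=pairs["r2"].to_numpy(), minlength=nbins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(starts, means, counts, bin_size)


def loess_smooth(curve: LDDecayCurve, span: float = 0.3) -> np.ndarray:
    """Loess (tricube local linear) smoothing of the occupied bin means.

    Returns a full-length array with NaN at empty bins; also stored on the
    curve as ``smoothed``.
    """
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    occ = curve.occupied() & np.isfinite(curve.mean_r2)
    if occ.sum() < 5:
        raise ValueError("need at least 5 occupied bins")
    x = curve.bin_start[occ].astype(float)
    y = curve.mean_r2[occ]
    sm = _sm_lowess(y, x, frac=span, return_sorted=False)
    out = np.full(curve.bin_start.shape, np.nan)
    out[occ] = sm
    curve.smoothed = out
    return out


def ld50(curve: LDDecayCurve, use_smoothed: bool = False) -> tuple[int, bool]:
    """Distance to 50% LD decay: (bin start, decayed flag).

    Let m be the maximum binned mean r². Among points with value strictly
    above m/2, return the bin start of the one closest to m/2. If every
    occupied point is above m/2 the curve has not decayed within range: the
    last occupied bin start is returned with ``decayed=False``.
    """
    vals = curve.smoothed if use_smoothed else curve.mean_r2
    if vals is None:
        raise ValueError("no smoothed values; run loess_smooth first")
    occ = curve.occupied() & np.isfinite(vals)
    if not occ.any():
        raise ValueError("empty curve")
    v = vals[occ]
    starts = curve.bin_start[occ]
    m = v.max()
    if m <= 0:
        raise ValueError("curve maximum must be positive")
    half = m / 2.0
    decayed = bool((v <= half).any())
    if not decayed:
        return int(starts[-1]), False
    above = v > half
    i = int(np.argmin(v[above] - half))
    return int(starts[above][i]), True


def region_ld_matrix(g: HaploidGenotypes, sample_idx: np.ndarray | None,
                     contig: str, start: int, end: int):
    """Full pairwise r² and D' matrices over a region's SNPs.

    SNPs are ordered by position; the diagonal is 1. Intended for LD
    heatmaps around candidate sweep regions.
    """
    ci = g.contig_names.index(contig)
    sel = np.nonzero((g.contig_index == ci) & (g.positions >= start) & (g.positions <= end))[0]
    if sel.size < 2:
        raise ValueError("region contains fewer than 2 SNPs")
    a = g.alleles if sample_idx is None else g.alleles[:, sample_idx]
    m = sel.size
    r2 = np.full((m, m), np.nan)
    dp = np.full((m, m), np.nan)
    np.fill_diagonal(r2, 1.0)
    np.fill_diagonal(dp, 1.0)
    for i in range(m):
        for j in range(i + 1, m):
            res = two_locus_ld(a[sel[i]], a[sel[j]])
            if res is not None:
                r2[i, j] = r2[j, i] = res[0]
                dp[i, j] = dp[j, i] = res[1]
    return pd.DataFrame(r2, index=g.positions[sel], columns=g.positions[sel]), \
        pd.DataFrame(dp, index=g.positions[sel], columns=g.positions[sel])
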