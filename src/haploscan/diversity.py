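"""Windowed nucleotide diversity, Watterson's theta, SFS, and Tajima's D.

All statistics operate on haploid allele counts. Per-site effective sample
size is the number of non-missing calls; Tajima's normalizing constants are
evaluated at the modal effective n of each window, so moderately missing
data does not bias the variance term.

Windows are 1-based inclusive ``[start, start+size-1]`` tiles with a fixed
step; the defaults (10-kbp windows, 1-kbp step) are the standard overlapping
scan used for fungal population panels with ~100 SNPs per window.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .variant_io import HaploidGenotypes


@dataclass(frozen=True)
class WindowSpec:
    """One window: 1-based inclusive coordinates on a contig."""

    contig: str
    start: int
    size: int            # actual bp length (terminal windows may be shorter)
    truncated: bool

    @property
    def end(self) -> int:
        return self.start + self.size - 1


@dataclass(frozen=True)
class TajimaConstants:
    """The a1..e2 normalizing constants of Tajima's D for sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    @lru_cache(maxsize=None)
    def for_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError("Tajima constants need n >= 2")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i ** 2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
        e1 = c1 / a1
        e2 = c2 / (a1 ** 2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class SFS:
    """Site-frequency spectrum: counts per allele-frequency class.

    ``counts[j]`` for j in 1..n-1 (unfolded, alternate-allele counts) or
    1..n//2 (folded, minor-allele counts); index 0 is unused padding so the
    class index equals the allele count.
    """

    counts: np.ndarray
    n: int
    folded: bool

    @property
    def classes(self) -> np.ndarray:
        hi = self.n // 2 if self.folded else self.n - 1
        return np.arange(1, hi + 1)

    def normalized(self) -> np.ndarray:
        c = self.counts[1:].astype(float)
        return c / c.sum()

    def fold(self) -> "SFS":
        if self.folded:
            return self
        hi = self.n // 2
        out = np.zeros(hi + 1)
        for j in range(1, self.n):
            out[min(j, self.n - j)] += self.counts[j]
        return SFS(out, self.n, True)


def make_windows(contig_lengths: dict[str, int], size: int = 10_000,
                 step: int = 1_000) -> list[WindowSpec]:
    """Overlapping windows tiling each contig.

    Starts at 1, 1+step, ...; terminal windows shorter than ``size`` are
    included (flagged ``truncated``) as long as they span at least ``step``
    bp, so every position is covered.
    """
    if not (size >= step >= 1):
        raise ValueError("need size >= step >= 1")
    out = []
    for contig, length in contig_lengths.items():
        start = 1
        while length - start + 1 >= step:
            w = min(size, length - start + 1)
            out.append(WindowSpec(contig, start, w, truncated=w < size))
            start += step
    return out


def site_pi(alt: np.ndarray, called: np.ndarray) -> np.ndarray:
    """Per-site heterozygosity 2c(n-c)/(n(n-1)); 0 where n < 2.

    This is the unbiased per-site nucleotide diversity for haploid samples:
    the probability that two distinct sampled haplotypes differ at the site.
    """
    alt = np.asarray(alt, dtype=float)
    n = np.asarray(called, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * alt * (n - alt) / (n * (n - 1.0))
    pi[n < 2] = 0.0
    return pi


def theta_pi(alt: np.ndarray, called: np.ndarray, window_bp: int) -> tuple[float, float]:
    """Nucleotide diversity over a window: (absolute, per-bp).

    ``alt``/``called`` are the per-site alternate and non-missing counts of
    the window's sites; sites with fewer than 2 calls are skipped. The
    per-bp value divides by the full window length (monomorphic positions
    included), i.e. diversity per base.
    """
    absolute = float(np.sum(site_pi(alt, called)))
    return absolute, absolute / window_bp


def theta_w(alt: np.ndarray, called: np.ndarray, window_bp: int,
            n: int | None = None) -> tuple[float, float]:
    """Watterson's estimator S/a1 over a window: (absolute, per-bp).

    ``n`` defaults to the modal per-site effective sample size among the
    window's segregating sites.
    """
    alt = np.asarray(alt)
    called = np.asarray(called)
    seg = (alt > 0) & (alt < called) & (called >= 2)
    s = int(seg.sum())
    if s == 0:
        return 0.0, 0.0
    if n is None:
        n = modal_n(called[seg])
    absolute = s / TajimaConstants.for_n(n).a1
    return absolute, absolute / window_bp


def modal_n(called: np.ndarray) -> int:
    """Modal effective sample size (largest value on ties)."""
    vals, cnt = np.unique(np.asarray(called, dtype=int), return_counts=True)
    return int(vals[cnt == cnt.max()].max())


def tajimas_d(alt: np.ndarray, called: np.ndarray, n: int | None = None) -> float:
    """Tajima's D for one window; NaN when undefined (S = 0 or n < 4).

    D = (theta_pi - S/a1) / sqrt(e1 S + e2 S (S-1)), with the constants at
    the window's (modal) effective sample size.
    """
    alt = np.asarray(alt)
    called = np.asarray(called)
    seg = (alt > 0) & (alt < called) & (called >= 2)
    s = int(seg.sum())
    if s == 0:
        return float("nan")
    if n is None:
        n = modal_n(called[seg])
    if n < 4:
        return float("nan")
    k = TajimaConstants.for_n(n)
    pi_abs = float(np.sum(site_pi(alt, called)))
    var = k.e1 * s + k.e2 * s * (s - 1)
    if var <= 0:
        return float("nan")
    return (pi_abs - s / k.a1) / np.sqrt(var)


def _hypergeom_project(alt: int, called: int, m: int) -> np.ndarray:
    """Expected class weights of a site projected to sample size m."""
    from scipy.stats import hypergeom
    j = np.arange(0, m + 1)
    return hypergeom.pmf(j, called, alt, m)


def compute_sfs(g: HaploidGenotypes, sample_idx: np.ndarray | None = None,
                folded: bool = True, project_n: int | None = None) -> SFS:
    """Site-frequency spectrum of a sample set.

    Sites are binned by alternate-allele count (unfolded) or minor-allele
    count (folded). With missing data, either restrict to sites called in
    exactly ``n`` samples (default: the modal effective n) or pass
    ``project_n`` to downsample every site hypergeometrically to a common
    size, accumulating expected (real-valued) class weights.
    """
    alt, called = g.allele_counts(sample_idx)
    seg = (alt > 0) & (alt < called) & (called >= 2)
    alt, called = alt[seg], called[seg]
    if alt.size == 0:
        raise ValueError("no segregating sites")
    if project_n is None:
        n = modal_n(called)
        use = called == n
        counts = np.bincount(alt[use], minlength=n + 1).astype(float)[:n]
        counts[0] = 0.0
    else:
        n = project_n
        counts = np.zeros(n + 1)
        for a, c in zip(alt, called):
            if c < n:
                continue
            counts += _hypergeom_project(int(a), int(c), n)
        counts[0] = 0.0
        counts[n] = 0.0
        counts = counts[:n]
    sfs = SFS(counts, n, folded=False)
    return sfs.fold() if folded else sfs


def window_sites(positions: np.ndarray, windows: list[WindowSpec],
                 contig_index: np.ndarray, contig_names: list[str]):
    """Yield (window, slice) of site indices for each window.

    Sites must be position-sorted within contigs. Slices index into the
    global site arrays.
    """
    by_contig = {}
    for ci, name in enumerate(contig_names):
        idx = np.nonzero(contig_index == ci)[0]
        by_contig[name] = (idx, positions[idx])
    for w in windows:
        if w.contig not in by_contig:
            yield w, np.empty(0, dtype=int)
            continue
        idx, pos = by_contig[w.contig]
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        yield w, idx[lo:hi]


def window_diversity(g: HaploidGenotypes, sample_idx: np.ndarray | None,
                     windows: list[WindowSpec]) -> pd.DataFrame:
    """Per-window S, theta_pi, theta_w, and Tajima's D for one sample set."""
    alt, called = g.allele_counts(sample_idx)
    rows = []
    for w, idx in window_sites(g.positions, windows, g.contig_index, g.contig_names):
        a, c = alt[idx], called[idx]
        seg = (a > 0) & (a < c) & (c >= 2)
        s = int(seg.sum())
        pi_abs, pi_bp = theta_pi(a, c, w.size)
        tw_abs, tw_bp = theta_w(a, c, w.size)
        d = tajimas_d(a, c)
        rows.append((w.contig, w.start, w.end, w.truncated, s,
                     pi_abs, pi_bp, tw_abs, tw_bp, d))
    return pd.DataFrame(rows, columns=[
        "contig", "start", "end", "truncated", "S",
        "theta_pi_abs", "theta_pi", "theta_w_abs", "theta_w", "tajima_d",
    ])


def genome_summary(wt: pd.DataFrame, include_truncated: bool = False) -> dict:
    """Genome-wide means of the per-window statistics.

    Truncated terminal windows are excluded by default so short tails do not
    distort per-bp averages.
    """
    use = wt if include_truncated else wt[~wt["truncated"]]
    return {
        "theta_pi": float(use["theta_pi"].mean()),
        "theta_w": float(use["theta_w"].mean()),
        "tajima_d": float(use["tajima_d"].mean(skipna=True)),
        "n_windows": int(len(use)),
    }
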