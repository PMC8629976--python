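"""Positive-selection machinery: permutation-calibrated Tajima's D, an
SFS-based composite likelihood ratio (CLR) sweep scan, and the
multi-evidence genomic-island caller.

The permutation null rebuilds pseudo-windows by resampling segregating
sites genome-wide (matched on the observed per-window S distribution),
which preserves the site-frequency spectrum while destroying spatial
clustering; a window is a selection candidate only when its Tajima's D
falls below the 5th percentile of BOTH the permutation null and the
observed genomic distribution.

The CLR scan follows the single-population SFS sweep model: near a sweep
each sampled lineage escapes via recombination with probability
``1 - exp(-alpha * d)`` (d = distance to the putative sweep site); escaped
lineages carry alleles drawn from the genomic background spectrum while all
non-escaped lineages coalesce into the swept haplotype, whose allelic state
is that of one extra background draw. Site probabilities condition on
polymorphism in the sample; folded spectra are supported (and the default,
as no outgroup polarization is assumed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diversity import SFS, WindowSpec, modal_n, tajimas_d, window_diversity
from .variant_io import HaploidGenotypes


@dataclass
class PermutationNull:
    """Empirical null for windowed Tajima's D.

    ``threshold_null`` is the 5th percentile of D over resampled
    pseudo-windows; ``threshold_genomic`` the 5th percentile of the observed
    windowed D. Candidates must fall below both.
    """

    replicates: np.ndarray
    threshold_null: float
    threshold_genomic: float
    seed: int
    percentile: float = 5.0

    def is_candidate(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        with np.errstate(invalid="ignore"):
            return (d < self.threshold_null) & (d < self.threshold_genomic)


@dataclass
class CLRResult:
    """CLR scan output: per grid position, the likelihood-ratio statistic
    and the sweep-strength estimate (alpha, per bp; inf = background)."""

    table: pd.DataFrame          # contig, pos, clr, alpha_hat, n_sites
    top1_cutoff: float
    background: SFS

    @property
    def argmax(self) -> tuple[str, int]:
        row = self.table.loc[self.table["clr"].idxmax()]
        return str(row["contig"]), int(row["pos"])


@dataclass
class GenomicIsland:
    """A merged run of outlier windows with its selection evidence."""

    contig: str
    start: int
    end: int
    n_windows: int
    mean_zfst: float
    min_tajima_d: float
    max_clr: float = float("nan")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def permutation_null_tajima(g: HaploidGenotypes, sample_idx: np.ndarray | None,
                            windows: list[WindowSpec], B: int = 1000,
                            seed: int = 0, percentile: float = 5.0) -> PermutationNull:
    """Empirical permutation null for windowed Tajima's D.

    Each replicate draws S* (sampled from the observed per-window S
    distribution) segregating sites uniformly with replacement from the
    sample set's genome-wide segregating sites and computes D on the
    pseudo-window.
    """
    if B < 200:
        raise ValueError("B must be >= 200")
    if len(windows) < 100:
        raise ValueError("need at least 100 genome windows")
    alt, called = g.allele_counts(sample_idx)
    seg = (alt > 0) & (alt < called) & (called >= 2)
    if seg.sum() < 50:
        raise ValueError("fewer than 50 segregating sites in group")
    alt_seg, called_seg = alt[seg], called[seg]

    wt = window_diversity(g, sample_idx, windows)
    obs_d = wt["tajima_d"].to_numpy()
    obs_s = wt.loc[wt["S"] > 0, "S"].to_numpy()

    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    for b in range(B):
        s_star = int(rng.choice(obs_s))
        pick = rng.integers(0, alt_seg.size, size=s_star)
        reps[b] = tajimas_d(alt_seg[pick], called_seg[pick])
    reps = reps[np.isfinite(reps)]
    return PermutationNull(
        replicates=reps,
        threshold_null=float(np.percentile(reps, percentile)),
        threshold_genomic=float(np.nanpercentile(obs_d, percentile)),
        seed=seed,
        percentile=percentile,
    )


def _unfold(background: SFS) -> np.ndarray:
    """Unfolded class probabilities q_1..q_{n-1} from a background SFS.

    A folded background is unfolded symmetrically (each folded class split
    equally between j and n-j), the neutral-agnostic choice when no
    polarization is available.
    """
    n = background.n
    q = np.zeros(n + 1)
    if background.folded:
        for j, c in zip(background.classes, background.counts[1:]):
            j = int(j)
            if j == n - j:
                q[j] = c
            else:
                q[j] += c / 2.0
                q[n - j] += c / 2.0
    else:
        q[1:n] = background.counts[1:n]
    tot = q.sum()
    if tot <= 0 or np.count_nonzero(q) < 2:
        raise ValueError("degenerate background SFS")
    return q[1:n] / tot


def sweep_class_matrix(background: SFS) -> np.ndarray:
    """P(final sample count = j | k lineages escape), rows k=0..n, cols j=0..n.

    With k escapees, a background sample of size k+1 is drawn (hypergeometric
    projection of the background spectrum from n); one of its lineages,
    chosen uniformly, is the swept-haplotype ancestor whose allele is
    carried by all n-k non-escaped lineages.
    """
    n = background.n
    q = _unfold(background)  # classes 1..n-1
    js = np.arange(1, n)
    m_full = np.zeros((n + 1, n + 1))
    m_full[n, 1:n] = q
    for k in range(n):
        size = k + 1
        ms = np.arange(0, size + 1)
        # project background (size n) to size k+1
        proj = np.zeros(size + 1)
        for j, qj in zip(js, q):
            proj += qj * hypergeom.pmf(ms, n, j, size)
        for m in ms:
            pm = proj[m]
            if pm == 0:
                continue
            p_anc = m / size
            if p_anc > 0:
                m_full[k, m - 1 + n - k] += pm * p_anc
            m_full[k, m] += pm * (1 - p_anc)
    return m_full


def _site_log_probs(j_obs: np.ndarray, dist: np.ndarray, alphas: np.ndarray,
                    m_full: np.ndarray, n: int, folded: bool) -> np.ndarray:
    """Log P(site class | alpha) for each (site, alpha); conditioned on
    polymorphism. Shapes: j_obs, dist (s,); alphas (a,); returns (s, a)."""
    pe = 1.0 - np.exp(-np.outer(dist, alphas))          # (s, a)
    pe = np.clip(pe, 1e-12, 1.0 - 1e-12)
    k = np.arange(n + 1)
    from scipy.special import gammaln
    logc = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    with np.errstate(divide="ignore"):
        logw = logc + k * np.log(pe)[..., None] + (n - k) * np.log1p(-pe)[..., None]
    w = np.exp(logw)                                     # (s, a, n+1)
    probs = w @ m_full                                   # (s, a, n+1) over final counts
    norm = 1.0 - probs[..., 0] - probs[..., n]
    norm = np.maximum(norm, 1e-300)
    s_idx = np.arange(len(j_obs))
    if folded:
        jj = np.minimum(j_obs, n - j_obs)
        p1 = probs[s_idx[:, None], np.arange(len(alphas))[None, :], jj[:, None]]
        other = (n - jj)
        p2 = probs[s_idx[:, None], np.arange(len(alphas))[None, :], other[:, None]]
        p2 = np.where((jj == other)[:, None], 0.0, p2)
        p_site = p1 + p2
    else:
        p_site = probs[s_idx[:, None], np.arange(len(alphas))[None, :], j_obs[:, None]]
    return np.log(np.maximum(p_site, 1e-300)) - np.log(norm)


def _background_log_probs(j_obs: np.ndarray, background: SFS, folded: bool) -> np.ndarray:
    n = background.n
    q = _unfold(background)
    full = np.zeros(n + 1)
    full[1:n] = q
    if folded:
        jj = np.minimum(j_obs, n - j_obs)
        p = full[jj] + np.where(jj == n - jj, 0.0, full[n - jj])
    else:
        p = full[j_obs]
    return np.log(np.maximum(p, 1e-300))


def _seg_prob(dist: np.ndarray, alphas: np.ndarray, m_full: np.ndarray, n: int) -> np.ndarray:
    """P(site still polymorphic | alpha, d): the sweep's retention probability."""
    pe = 1.0 - np.exp(-np.outer(dist, alphas))
    pe = np.clip(pe, 1e-12, 1.0 - 1e-12)
    k = np.arange(n + 1)
    from scipy.special import gammaln
    logc = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    w = np.exp(logc + k * np.log(pe)[..., None] + (n - k) * np.log1p(-pe)[..., None])
    probs = w @ m_full
    return np.maximum(1.0 - probs[..., 0] - probs[..., n], 1e-300)


def default_alpha_grid(n_points: int = 32, lo: float = 1e-5, hi: float = 1e-2) -> np.ndarray:
    """Log-spaced sweep-strength grid (per-bp recombination escape rates)."""
    return np.geomspace(lo, hi, n_points)


def clr_scan(g: HaploidGenotypes, sample_idx: np.ndarray | None, background: SFS,
             grid_spacing: int = 2_000, window_bp: int = 10_000,
             alpha_grid: np.ndarray | None = None, folded: bool = True,
             min_snps: int = 3, include_density: bool = True) -> CLRResult:
    """Composite likelihood ratio sweep scan over a position grid.

    At each grid point the composite log-likelihood of the surrounding
    window's site classes is maximized over the sweep-strength grid and
    compared to the genomic-background likelihood:
    ``CLR = 2 (max_alpha l_sweep - l_background)``. The background model is
    the alpha -> infinity limit of the sweep model and is included as a
    candidate, so CLR >= 0 everywhere. Sites are restricted to those called
    in exactly ``background.n`` samples so classes are comparable.

    With ``include_density=True`` (the default) the likelihood also uses the
    local density of segregating sites: usable sites are treated as a Poisson
    process whose intensity under the sweep model is the genome-wide rate
    scaled by the retention probability r(d) = P(polymorphic | alpha, d).
    Relative to the background this adds ``sum_i log r(d_i) +
    rho * integral(1 - r(d)) dd`` to the sweep log-likelihood, rewarding the
    trough of segregating sites a real sweep leaves. Both extra terms vanish
    as alpha -> infinity, so the background nesting (CLR >= 0) is preserved.
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    n = background.n
    m_full = sweep_class_matrix(background)
    alt, called = g.allele_counts(sample_idx)
    usable = (called == n) & (alt > 0) & (alt < called)

    if include_density:
        rho = usable.sum() / sum(g.contigs.values())
        dgrid = np.linspace(0.0, window_bp / 2.0, 64)
        r_grid = _seg_prob(dgrid, alpha_grid, m_full, n)      # (64, a)
        # expected deficit of sites in the +-window_bp/2 window, per alpha
        deficit = rho * 2.0 * np.trapezoid(1.0 - r_grid, dgrid, axis=0)
    else:
        deficit = np.zeros(len(alpha_grid))

    rows = []
    clrs = []
    for ci, contig in enumerate(g.contig_names):
        length = g.contigs[contig]
        mask = (g.contig_index == ci) & usable
        pos = g.positions[mask]
        j_all = alt[mask].astype(int)
        if length < grid_spacing:
            continue
        for x in range(grid_spacing // 2, int(length), grid_spacing):
            lo = np.searchsorted(pos, x - window_bp // 2)
            hi = np.searchsorted(pos, x + window_bp // 2)
            jw = j_all[lo:hi]
            if jw.size < min_snps:
                rows.append((contig, x, np.nan, np.nan, int(jw.size)))
                continue
            dist = np.abs(pos[lo:hi] - x).astype(float)
            l_bg = float(np.sum(_background_log_probs(jw, background, folded)))
            l_sweep = _site_log_probs(jw, dist, alpha_grid, m_full, n, folded).sum(axis=0)
            if include_density:
                l_sweep = l_sweep + np.log(_seg_prob(dist, alpha_grid, m_full, n)).sum(axis=0) + deficit
            best = int(np.argmax(l_sweep))
            if l_sweep[best] > l_bg:
                clr = 2.0 * (l_sweep[best] - l_bg)
                alpha_hat = float(alpha_grid[best])
            else:
                clr, alpha_hat = 0.0, float("inf")
            rows.append((contig, x, clr, alpha_hat, int(jw.size)))
            clrs.append(clr)
    table = pd.DataFrame(rows, columns=["contig", "pos", "clr", "alpha_hat", "n_sites"])
    finite = table["clr"].to_numpy()
    finite = finite[np.isfinite(finite)]
    cutoff = float(np.percentile(finite, 99)) if finite.size else float("nan")
    return CLRResult(table=table, top1_cutoff=cutoff, background=background)


def call_islands(wt: pd.DataFrame, null: PermutationNull,
                 clr: CLRResult | None = None, gap_tolerance: int = 1,
                 step: int = 1_000, require_clr: bool = False) -> list[GenomicIsland]:
    """Merge multi-evidence outlier windows into genomic islands.

    A window is flagged when it is a ZFst outlier (95th percentile) AND its
    Tajima's D lies below both 5th-percentile cutoffs; with
    ``require_clr=True`` it must additionally contain a CLR grid point at or
    above the top-1% cutoff. Flagged windows on the same contig whose starts
    are within ``gap_tolerance`` window steps are merged.

    ``wt`` needs columns contig, start, end, tajima_d, outlier_5pct.
    """
    flags = wt["outlier_5pct"].to_numpy() & null.is_candidate(wt["tajima_d"].to_numpy())
    if require_clr:
        if clr is None:
            raise ValueError("require_clr=True needs a CLRResult")
        cmax = np.full(len(wt), np.nan)
        for ci, sub in clr.table.groupby("contig"):
            pos = sub["pos"].to_numpy()
            val = sub["clr"].to_numpy()
            sel = wt["contig"] == ci
            for i in np.nonzero(sel.to_numpy())[0]:
                inwin = (pos >= wt["start"].iat[i]) & (pos <= wt["end"].iat[i])
                if inwin.any():
                    cmax[i] = np.nanmax(val[inwin])
        flags &= cmax >= clr.top1_cutoff

    islands: list[GenomicIsland] = []
    fl = wt[flags].sort_values(["contig", "start"])
    for contig, sub in fl.groupby("contig", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        zs = sub["zfst"].to_numpy() if "zfst" in sub else np.full(len(sub), np.nan)
        ds = sub["tajima_d"].to_numpy()
        run = [0]
        for i in range(1, len(sub)):
            if starts[i] - starts[i - 1] <= gap_tolerance * step:
                run.append(i)
            else:
                islands.append(_make_island(contig, starts, ends, zs, ds, run))
                run = [i]
        if run:
            islands.append(_make_island(contig, starts, ends, zs, ds, run))
    return islands


def _make_island(contig, starts, ends, zs, ds, run) -> GenomicIsland:
    r = np.asarray(run)
    return GenomicIsland(
        contig=str(contig),
        start=int(starts[r].min()),
        end=int(ends[r].max()),
        n_windows=len(run),
        mean_zfst=float(np.nanmean(zs[r])),
        min_tajima_d=float(np.nanmin(ds[r])),
    )


def islands_to_frame(islands: list[GenomicIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        [(i.contig, i.start, i.end, i.n_windows, i.mean_zfst, i.min_tajima_d) for i in islands],
        columns=["contig", "start", "end", "n_windows", "mean_zfst", "min_tajima_d"],
    )
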