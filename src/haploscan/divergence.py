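"""Two-group differentiation: windowed Fst and Dxy, ZFst outliers, and the
shared/fixed SNP classification.

Two Fst estimators are provided. The default is Hudson's ratio-of-averages,
which is well behaved for windowed scans (window Fst = sum of per-site
numerators / sum of per-site denominators, never an average of ratios). A
Weir–Cockerham variant for haploid allele counts is included for
compatibility with genotype-matrix packages that report WC theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import WindowSpec, window_sites
from .variant_io import GroupAssignment, HaploidGenotypes


@dataclass
class SnpSharingTable:
    """Counts of SNPs by sharing pattern between two groups.

    Categories partition the SNPs segregating in the union of the groups:
    polymorphic in both; reciprocally fixed for different alleles ("fixed in
    both"); fixed in group 1 but polymorphic in group 2; and vice versa.
    """

    polymorphic_both: int
    fixed_both: int
    fixed_group1: int
    fixed_group2: int

    @property
    def total(self) -> int:
        return self.polymorphic_both + self.fixed_both + self.fixed_group1 + self.fixed_group2

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("polymorphic_in_both", self.polymorphic_both),
            ("fixed_in_both", self.fixed_both),
            ("fixed_in_group1", self.fixed_group1),
            ("fixed_in_group2", self.fixed_group2),
        ]
        df = pd.DataFrame(rows, columns=["category", "snps"])
        df["percent"] = 100.0 * df["snps"] / max(self.total, 1)
        return df


def _group_counts(g: HaploidGenotypes, groups: GroupAssignment, pair: tuple[str, str]):
    idx1 = groups.indices(g.samples, pair[0])
    idx2 = groups.indices(g.samples, pair[1])
    if idx1.size < 2 or idx2.size < 2:
        raise ValueError("both groups need n >= 2")
    a1, n1 = g.allele_counts(idx1)
    a2, n2 = g.allele_counts(idx2)
    return a1, n1, a2, n2


def hudson_fst_components(a1, n1, a2, n2):
    """Per-site Hudson numerator and denominator.

    N_s = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D_s = p1(1-p2) + p2(1-p1)

    Sites with fewer than 2 calls in either group get NaN components.
    """
    a1 = np.asarray(a1, float); n1 = np.asarray(n1, float)
    a2 = np.asarray(a2, float); n2 = np.asarray(n2, float)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = a1 / n1, a2 / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    return num, den


def wc_fst_components(a1, n1, a2, n2):
    """Weir–Cockerham theta components for haploid (allele-count) data.

    Two-level ANOVA of allele indicators over r=2 groups:
    MSP = sum n_i (p_i - pbar)^2 / (r-1),
    MSG = sum n_i p_i (1-p_i) / sum (n_i - 1),
    numerator a = MSP - MSG, denominator = MSP + (nc - 1) MSG, with
    nc = (N - sum n_i^2 / N) / (r-1).
    """
    a1 = np.asarray(a1, float); n1 = np.asarray(n1, float)
    a2 = np.asarray(a2, float); n2 = np.asarray(n2, float)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = a1 / n1, a2 / n2
        ntot = n1 + n2
        pbar = (a1 + a2) / ntot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
        nc = ntot - (n1 ** 2 + n2 ** 2) / ntot
        num = msp - msg
        den = msp + (nc - 1) * msg
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    return num, den


def site_dxy(a1, n1, a2, n2):
    """Per-site absolute divergence p1(1-p2) + p2(1-p1); NaN if a group is uncalled."""
    a1 = np.asarray(a1, float); n1 = np.asarray(n1, float)
    a2 = np.asarray(a2, float); n2 = np.asarray(n2, float)
    ok = (n1 >= 1) & (n2 >= 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = a1 / n1, a2 / n2
        d = p1 * (1 - p2) + p2 * (1 - p1)
    return np.where(ok, d, np.nan)


def window_fst(g: HaploidGenotypes, groups: GroupAssignment, windows: list[WindowSpec],
               pair: tuple[str, str] = ("group1", "group2"),
               estimator: str = "hudson") -> pd.DataFrame:
    """Ratio-of-averages Fst per window; NaN (flagged) where no site informs it."""
    if estimator not in ("hudson", "wc"):
        raise ValueError("estimator must be 'hudson' or 'wc'")
    a1, n1, a2, n2 = _group_counts(g, groups, pair)
    comp = hudson_fst_components if estimator == "hudson" else wc_fst_components
    num, den = comp(a1, n1, a2, n2)
    rows = []
    for w, idx in window_sites(g.positions, windows, g.contig_index, g.contig_names):
        nw, dw = num[idx], den[idx]
        ok = np.isfinite(nw) & np.isfinite(dw)
        dsum = float(np.sum(dw[ok]))
        if ok.sum() == 0 or dsum == 0:
            fst = np.nan
        else:
            fst = float(np.sum(nw[ok])) / dsum
        rows.append((w.contig, w.start, fst, int(ok.sum())))
    return pd.DataFrame(rows, columns=["contig", "start", "fst", "n_sites_fst"])


def genome_fst(g: HaploidGenotypes, groups: GroupAssignment,
               pair: tuple[str, str] = ("group1", "group2"),
               estimator: str = "hudson") -> float:
    """Genome-wide ratio-of-averages Fst over all sites."""
    a1, n1, a2, n2 = _group_counts(g, groups, pair)
    comp = hudson_fst_components if estimator == "hudson" else wc_fst_components
    num, den = comp(a1, n1, a2, n2)
    ok = np.isfinite(num) & np.isfinite(den)
    return float(np.nansum(num[ok]) / np.nansum(den[ok]))


def window_dxy(g: HaploidGenotypes, groups: GroupAssignment, windows: list[WindowSpec],
               pair: tuple[str, str] = ("group1", "group2")) -> pd.DataFrame:
    """Per-window Dxy: sum of per-site divergence over window bp.

    Monomorphic (unascertained) positions contribute 0, so the value is an
    absolute per-bp divergence comparable across windows.
    """
    a1, n1, a2, n2 = _group_counts(g, groups, pair)
    d = site_dxy(a1, n1, a2, n2)
    rows = []
    for w, idx in window_sites(g.positions, windows, g.contig_index, g.contig_names):
        dv = d[idx]
        rows.append((w.contig, w.start, float(np.nansum(dv)) / w.size))
    return pd.DataFrame(rows, columns=["contig", "start", "dxy"])


def zfst(fst_values: np.ndarray) -> pd.DataFrame:
    """Z-transform windowed Fst and flag empirical outliers.

    Z = (Fst - mean) / sd over finite windows; flags mark windows at or
    above the 99th and 95th empirical percentiles of the finite values.
    NaN windows stay NaN and are never flagged.
    """
    v = np.asarray(fst_values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite Fst values")
    mu = v[finite].mean()
    sd = v[finite].std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance in Fst values")
    z = (v - mu) / sd
    q95, q99 = np.percentile(v[finite], [95, 99])
    return pd.DataFrame({
        "zfst": z,
        "outlier_5pct": finite & (v >= q95),
        "outlier_1pct": finite & (v >= q99),
    })


def classify_shared_snps(g: HaploidGenotypes, groups: GroupAssignment,
                         pair: tuple[str, str] = ("group1", "group2")) -> SnpSharingTable:
    """Classify each SNP by its sharing pattern between two groups.

    Restricted to sites segregating in the union of the two groups and with
    at least one call per group; each such site falls in exactly one
    category.
    """
    a1, n1, a2, n2 = _group_counts(g, groups, pair)
    called = (n1 >= 1) & (n2 >= 1)
    au, nu = a1 + a2, n1 + n2
    seg_union = (au > 0) & (au < nu)
    use = called & seg_union
    poly1 = (a1 > 0) & (a1 < n1)
    poly2 = (a2 > 0) & (a2 < n2)
    fixed_diff = ~poly1 & ~poly2  # both fixed; union segregates => different alleles
    return SnpSharingTable(
        polymorphic_both=int(np.sum(use & poly1 & poly2)),
        fixed_both=int(np.sum(use & fixed_diff)),
        fixed_group1=int(np.sum(use & ~poly1 & poly2)),
        fixed_group2=int(np.sum(use & poly1 & ~poly2)),
    )
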