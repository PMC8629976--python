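"""Two-population haploid simulators with ground truth.

The SNP generator uses the Balding–Nichols model: each site has an
ancestral frequency p drawn from a neutral-spectrum-shaped density
(proportional to 1/x, so sample allele counts follow the 1/j neutral SFS),
and each subpopulation g draws its own frequency from
Beta(p (1-F_g)/F_g, (1-p)(1-F_g)/F_g). F_g is that group's divergence from
the ancestral pool; with both groups at F the expected genome-wide Hudson
Fst is approximately F, and within-group heterozygosity shrinks by (1-F_g),
so unequal F values reproduce group-asymmetric diversity. Short-range LD is
induced phenomenologically by making consecutive sites within small blocks
copy the previous site's sample pattern with a set probability.

Defaults emulate a 29-isolate fungal panel: two major groups (n=15, n=12)
plus a minor third group (n=2), strong differentiation (genome Fst ~ 0.5
via F1=0.3, F2=0.75), 2% SNP density, and LD on the 10^2-10^3 bp scale.

Sweeps are injected at the site-pattern level (diversity thinning plus
singleton excess in the swept group) — sufficient to exercise Tajima's D,
the CLR scan, and the island caller without forward simulation. CNV depth
is simulated as negative-binomial read counts per 1-kbp bin around
group-specific integer copy-number segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cnv_popgen import DepthMatrix
from .variant_io import ANNOTATION_FIELDS, GroupAssignment, HaploidGenotypes


@dataclass
class SweepSpec:
    """A localized hard-sweep signature to inject into one group."""

    contig: str
    center: int
    width: int = 20_000
    reduction: float = 10.0      # diversity-reduction factor within the interval
    singleton_fraction: float = 0.8  # retained polymorphic sites converted to singletons
    group: str = "group1"

    @property
    def start(self) -> int:
        return self.center - self.width // 2

    @property
    def end(self) -> int:
        return self.center + self.width // 2 - 1


@dataclass
class CNVSegment:
    """Ground-truth CNV segment: copy number per group over an interval."""

    contig: str
    start: int
    end: int
    cn_group1: int
    cn_group2: int


@dataclass
class SimConfig:
    """Study-scale defaults for the two-population haploid simulator."""

    n1: int = 15
    n2: int = 12
    n3: int = 2
    contig_lengths: dict[str, int] = field(default_factory=lambda: {"contig1": 500_000})
    snp_density: float = 0.02        # candidate segregating sites per bp
    F1: float = 0.3
    F2: float = 0.75
    F3: float = 0.5
    missing_rate: float = 0.02
    ld_block_bp: int = 400           # block length for phenomenological LD
    ld_copy_prob: float = 0.9        # P(site copies previous site's pattern within a block)
    p_min: float = 1e-3              # lower truncation of the 1/x ancestral-frequency density
    sweep: SweepSpec | None = None
    cnv_segments: list[CNVSegment] = field(default_factory=list)
    depth_mean: float = 30.0         # mean reads per bin at CN=1
    depth_dispersion: float = 0.1    # NB overdispersion: var = mu + disp * mu^2
    bin_size: int = 1_000
    seed: int = 0

    def validate(self) -> None:
        for f in (self.F1, self.F2, self.F3):
            if not (0 <= f < 1):
                raise ValueError("F parameters must lie in [0, 1)")
        if self.snp_density <= 0 or self.missing_rate < 0 or self.depth_mean <= 0:
            raise ValueError("rates must be positive")

    def group_sizes(self) -> dict[str, int]:
        out = {"group1": self.n1, "group2": self.n2}
        if self.n3 > 0:
            out["group3"] = self.n3
        return out


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data."""

    groups: GroupAssignment
    ancestral_freq: np.ndarray | None = None
    group_freq: dict[str, np.ndarray] | None = None
    sweep: SweepSpec | None = None
    cnv_segments: list[CNVSegment] = field(default_factory=list)

    def cnv_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.contig, s.start, s.end, s.cn_group1, s.cn_group2) for s in self.cnv_segments],
            columns=["contig", "start", "end", "cn_group1", "cn_group2"],
        )


def _ancestral_freqs(rng: np.random.Generator, n: int, p_min: float) -> np.ndarray:
    """Draw from the density proportional to 1/x on [p_min, 1-p_min].

    Integrating this density against the binomial sampling kernel gives the
    neutral 1/j sample spectrum (up to the truncation at p_min).
    """
    u = rng.random(n)
    a, b = p_min, 1.0 - p_min
    return a * (b / a) ** u


def _bn_group_freq(rng, p, F):
    if F == 0:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return rng.beta(np.maximum(a, 1e-8), np.maximum(b, 1e-8))


def simulate_two_pop_snps(cfg: SimConfig) -> tuple[HaploidGenotypes, SimTruth]:
    """Simulate a Balding–Nichols two(/three)-population haploid SNP panel.

    Candidate sites are placed uniformly at ``snp_density`` per bp; each
    site draws per-group frequencies around a shared ancestral frequency
    and haploid alleles Bernoulli(p_g). Sites monomorphic across all
    samples (after missingness) are dropped, so every emitted site
    segregates. Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.group_sizes()
    fs = {"group1": cfg.F1, "group2": cfg.F2, "group3": cfg.F3}
    samples = []
    mapping = {}
    for gname, n in sizes.items():
        for i in range(n):
            s = f"{gname.replace('group', 'G')}_{i+1:02d}"
            samples.append(s)
            mapping[s] = gname
    groups = GroupAssignment(mapping)

    all_ci, all_pos, all_rows = [], [], []
    anc_all, gfreq_all = [], {g: [] for g in sizes}
    contig_names = list(cfg.contig_lengths)
    for ci, (contig, length) in enumerate(cfg.contig_lengths.items()):
        n_sites = rng.poisson(cfg.snp_density * length)
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=min(n_sites, length), replace=False))
        p_anc = _ancestral_freqs(rng, pos.size, cfg.p_min)
        gfreq = {g: _bn_group_freq(rng, p_anc, fs[g]) for g in sizes}
        block = pos // max(cfg.ld_block_bp, 1)
        prev_row = None
        prev_block = None
        rows = np.empty((pos.size, len(samples)), dtype=np.int8)
        col0 = 0
        col_slices = {}
        for g, n in sizes.items():
            col_slices[g] = slice(col0, col0 + n)
            col0 += n
        for i in range(pos.size):
            row = np.empty(len(samples), dtype=np.int8)
            for g in sizes:
                sl = col_slices[g]
                row[sl] = rng.random(sizes[g]) < gfreq[g][i]
            if (cfg.ld_copy_prob > 0 and prev_row is not None
                    and prev_block == block[i] and rng.random() < cfg.ld_copy_prob):
                # copy the previous site's sample pattern (or its complement)
                row = prev_row.copy()
            rows[i] = row
            prev_row = row
            prev_block = block[i]
        if cfg.missing_rate > 0:
            miss = rng.random(rows.shape) < cfg.missing_rate
            rows[miss] = -1
        all_ci.append(np.full(pos.size, ci))
        all_pos.append(pos)
        all_rows.append(rows)
        anc_all.append(p_anc)
        for g in sizes:
            gfreq_all[g].append(gfreq[g])

    contig_index = np.concatenate(all_ci)
    positions = np.concatenate(all_pos).astype(np.int64)
    alleles = np.vstack(all_rows)
    anc = np.concatenate(anc_all)
    gfreq = {g: np.concatenate(v) for g, v in gfreq_all.items()}

    # keep only sites segregating across the full sample set
    alt = (alleles == 1).sum(axis=1)
    called = (alleles >= 0).sum(axis=1)
    seg = (alt > 0) & (alt < called)
    contig_index, positions, alleles = contig_index[seg], positions[seg], alleles[seg]
    anc = anc[seg]
    gfreq = {g: v[seg] for g, v in gfreq.items()}

    nsites = positions.size
    ann = pd.DataFrame({f: np.full(nsites, np.nan) for f in ANNOTATION_FIELDS})
    ann["QD"] = 25.0
    ann["QUAL"] = 1000.0
    refs = np.array(["A"] * nsites, dtype=object)
    alts_nt = np.array(["T"] * nsites, dtype=object)
    g = HaploidGenotypes(
        samples=samples,
        contigs=dict(cfg.contig_lengths),
        contig_index=contig_index,
        positions=positions,
        alleles=alleles,
        annotations=ann,
        ref=refs,
        alt=alts_nt,
    )
    truth = SimTruth(groups=groups, ancestral_freq=anc, group_freq=gfreq)
    return g, truth


def inject_sweep(g: HaploidGenotypes, truth: SimTruth, sweep: SweepSpec,
                 seed: int = 0) -> tuple[HaploidGenotypes, SimTruth]:
    """Overlay a hard-sweep signature on one group within an interval.

    Sites segregating in the swept group inside [start, end] are
    "homogenized" (the group set to its majority allele) with probability
    1 - 1/reduction, thinning its diversity by the reduction factor; of the
    sites left polymorphic, ``singleton_fraction`` are converted to
    singletons (one random carrier of the minor allele), skewing the local
    SFS toward rare variants. Sites monomorphic over all samples afterwards
    are dropped. Other groups are untouched.
    """
    if sweep.contig not in g.contigs:
        raise ValueError(f"unknown contig {sweep.contig!r}")
    if sweep.start < 1 or sweep.end > g.contigs[sweep.contig]:
        raise ValueError("sweep interval outside contig")
    rng = np.random.default_rng(seed)
    idx_g = truth.groups.indices(g.samples, sweep.group)
    a = g.alleles.copy()
    ci = g.contig_names.index(sweep.contig)
    inwin = (g.contig_index == ci) & (g.positions >= sweep.start) & (g.positions <= sweep.end)
    for i in np.nonzero(inwin)[0]:
        col = a[i, idx_g]
        calls = col[col >= 0]
        if calls.size == 0 or calls.min() == calls.max():
            continue
        n_alt = int((calls == 1).sum())
        major = 1 if n_alt * 2 >= calls.size else 0
        if sweep.reduction > 1 and rng.random() < 1.0 - 1.0 / sweep.reduction:
            col[col >= 0] = major
        elif rng.random() < sweep.singleton_fraction:
            col[col >= 0] = major
            carriers = np.nonzero(col >= 0)[0]
            col[rng.choice(carriers)] = 1 - major
        a[i, idx_g] = col
    g2 = replace(g, alleles=a)
    alt, called = g2.allele_counts()
    seg = (alt > 0) & (alt < called)
    g2 = g2.take_sites(np.nonzero(seg)[0])
    return g2, replace(truth, sweep=sweep,
                       ancestral_freq=None if truth.ancestral_freq is None else truth.ancestral_freq[seg],
                       group_freq=None if truth.group_freq is None else {k: v[seg] for k, v in truth.group_freq.items()})


def simulate_cnv_depth(cfg: SimConfig) -> tuple[DepthMatrix, SimTruth]:
    """Simulate binned read counts with group-specific CNV segments.

    Counts are negative-binomial with mean coverage x CN and overdispersion
    ``depth_dispersion`` (variance mu + disp mu^2); CN=0 bins draw at a 5%
    residual rate to mimic mismapping. Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    sizes = cfg.group_sizes()
    samples, mapping = [], {}
    for gname, n in sizes.items():
        for i in range(n):
            s = f"{gname.replace('group', 'G')}_{i+1:02d}"
            samples.append(s)
            mapping[s] = gname
    groups = GroupAssignment(mapping)

    bin_rows = []
    for contig, length in cfg.contig_lengths.items():
        for start in range(1, length + 1, cfg.bin_size):
            end = min(start + cfg.bin_size - 1, length)
            if end - start + 1 == cfg.bin_size:
                bin_rows.append((contig, start, end))
    bins = pd.DataFrame(bin_rows, columns=["contig", "start", "end"])
    nb, ns = len(bins), len(samples)

    cn = np.ones((nb, ns), dtype=float)
    for seg in cfg.cnv_segments:
        inb = ((bins["contig"] == seg.contig) & (bins["start"] >= seg.start)
               & (bins["end"] <= seg.end)).to_numpy()
        for gname, cn_val in (("group1", seg.cn_group1), ("group2", seg.cn_group2)):
            cols = groups.indices(samples, gname)
            cn[np.ix_(inb, cols)] = cn_val

    # per-sample coverage jitter around the nominal mean
    sample_cov = cfg.depth_mean * rng.uniform(0.8, 1.2, size=ns)
    mu = np.maximum(cn, 0.05) * sample_cov[None, :]
    disp = cfg.depth_dispersion
    if disp > 0:
        r = 1.0 / disp
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mu)
    dm = DepthMatrix(counts=counts.astype(float), bins=bins, samples=samples)
    truth = SimTruth(groups=groups, cnv_segments=list(cfg.cnv_segments))
    return dm, truth
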