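"""Reading, filtering, and writing haploid SNP matrices.

The central container is :class:`HaploidGenotypes`: a sites x samples matrix
of 0/1 alleles (with a missing sentinel) over 1-based positions, plus the
per-site VCF quality annotations needed for hard filtering.

Genotypes are haploid, as in fungal resequencing panels; homozygous
diploid-coded calls (``0/0``, ``1/1``) are accepted and collapsed to the
haploid allele. Heterozygous calls in a nominally haploid VCF are either
rejected (the whole record is dropped, the default) or set to missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

#: INFO/QUAL annotations used by the hard filter, in canonical order.
ANNOTATION_FIELDS = ("QD", "FS", "MQ", "SOR", "MQRankSum", "ReadPosRankSum", "QUAL")

#: GATK-style hard-filter thresholds: a site FAILS if any clause is true.
DEFAULT_HARD_FILTERS = {
    "QD": ("<", 2.0),
    "FS": (">", 80.0),
    "MQ": ("<", 20.0),
    "SOR": (">", 3.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
    "QUAL": ("<", 40.0),
}


@dataclass
class HaploidGenotypes:
    """Biallelic haploid SNP matrix with per-site annotations.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (column order of ``alleles``).
    contigs : dict
        Ordered mapping contig name -> length in bp.
    contig_index : ndarray of int
        Per-site index into ``contigs`` keys.
    positions : ndarray of int
        1-based site coordinates; strictly increasing within a contig.
    alleles : ndarray of int8, shape (n_sites, n_samples)
        0 = reference, 1 = alternate, -1 = missing.
    annotations : pandas.DataFrame or None
        One row per site, columns from :data:`ANNOTATION_FIELDS`;
        NaN marks an absent annotation (distinguishable from 0).
    ref, alt : ndarray of str or None
        REF/ALT bases, kept for VCF round-tripping.
    """

    samples: list[str]
    contigs: dict[str, int]
    contig_index: np.ndarray
    positions: np.ndarray
    alleles: np.ndarray
    annotations: pd.DataFrame | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[1]

    @property
    def contig_names(self) -> list[str]:
        return list(self.contigs)

    def contig_sites(self, name: str) -> np.ndarray:
        """Indices of sites on the named contig."""
        ci = self.contig_names.index(name)
        return np.nonzero(self.contig_index == ci)[0]

    def take_sites(self, idx: np.ndarray) -> "HaploidGenotypes":
        """Subset to the given site indices (order preserved)."""
        idx = np.asarray(idx)
        return replace(
            self,
            contig_index=self.contig_index[idx],
            positions=self.positions[idx],
            alleles=self.alleles[idx],
            annotations=None if self.annotations is None else self.annotations.iloc[idx].reset_index(drop=True),
            ref=None if self.ref is None else self.ref[idx],
            alt=None if self.alt is None else self.alt[idx],
        )

    def take_samples(self, names: list[str]) -> "HaploidGenotypes":
        """Subset columns to the named samples, in the given order."""
        cols = [self.samples.index(s) for s in names]
        return replace(self, samples=list(names), alleles=self.alleles[:, cols])

    def allele_counts(self, sample_idx: np.ndarray | None = None):
        """Per-site (alt count, called count) over the given sample columns."""
        a = self.alleles if sample_idx is None else self.alleles[:, sample_idx]
        called = (a >= 0).sum(axis=1)
        alt = (a == 1).sum(axis=1)
        return alt, called

    def validate(self) -> None:
        """Raise if the container's structural invariants are violated."""
        if self.alleles.shape != (len(self.positions), len(self.samples)):
            raise ValueError("alleles shape inconsistent with positions/samples")
        for ci in range(len(self.contigs)):
            pos = self.positions[self.contig_index == ci]
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError("positions not strictly increasing within contig")
        if not np.isin(self.alleles, [-1, 0, 1]).all():
            raise ValueError("alleles must be in {-1, 0, 1}")


@dataclass
class GroupAssignment:
    """Partition of samples into subpopulations."""

    mapping: dict[str, str]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g, None)
        return list(seen)

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == group]

    def sizes(self) -> dict[str, int]:
        return {g: len(self.members(g)) for g in self.groups}

    def indices(self, samples: list[str], group: str) -> np.ndarray:
        """Column indices of a group's samples in the given sample order."""
        mem = set(self.members(group))
        return np.array([i for i, s in enumerate(samples) if s in mem], dtype=int)

    def validate(self, samples: list[str] | None = None) -> None:
        if samples is not None:
            missing = set(samples) - set(self.mapping)
            if missing:
                raise ValueError(f"samples without group label: {sorted(missing)}")

    @classmethod
    def read_tsv(cls, path) -> "GroupAssignment":
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["sample", "group"], dtype=str)
        return cls(dict(zip(df["sample"], df["group"])))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, g in self.mapping.items():
                fh.write(f"{s}\t{g}\n")


def read_sample_list(path) -> list[str]:
    """Plain-text sample list, one name per line; '#' comments allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def _parse_gt(alleles_tuple, het_policy: str):
    """Map a pysam GT tuple to a haploid allele code.

    Returns (code, drop_record): haploid or homozygous-diploid calls map to
    the single allele; heterozygous diploid calls follow ``het_policy``.
    """
    vals = [a for a in alleles_tuple if a is not None]
    if not vals:
        return MISSING, False
    if len(set(vals)) > 1:  # heterozygous in a haploid VCF
        if het_policy == "reject":
            return MISSING, True
        return MISSING, False
    return np.int8(vals[0]), False


def read_vcf(path, sample_subset: list[str] | None = None, het_policy: str = "reject") -> HaploidGenotypes:
    """Read a haploid SNP VCF into a :class:`HaploidGenotypes`.

    Only biallelic SNP records are kept; multiallelic sites and indels are
    dropped (counts logged). ``./.`` and ``.`` become missing. ``het_policy``
    controls heterozygous diploid-coded calls: ``"reject"`` drops the record,
    ``"missing"`` masks the call.

    Parameters
    ----------
    path : str
        VCF (optionally bgzip-compressed) path.
    sample_subset : list of str, optional
        Restrict to these samples (must all be present in the header).
    """
    if het_policy not in ("reject", "missing"):
        raise ValueError("het_policy must be 'reject' or 'missing'")
    vf = pysam.VariantFile(str(path))
    header_samples = list(vf.header.samples)
    if sample_subset is not None:
        unknown = set(sample_subset) - set(header_samples)
        if unknown:
            raise ValueError(f"samples not in VCF header: {sorted(unknown)}")
        samples = list(sample_subset)
    else:
        samples = header_samples

    contigs: dict[str, int] = {}
    for name, rec in vf.header.contigs.items():
        contigs[name] = rec.length or 0

    contig_idx: list[int] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    ann_rows: list[list[float]] = []
    refs: list[str] = []
    alts: list[str] = []
    n_skipped_nonsnp = 0
    n_skipped_het = 0

    declared_info = set(vf.header.info.keys())
    contig_order = {c: i for i, c in enumerate(contigs)}
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_skipped_nonsnp += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            n_skipped_nonsnp += 1
            continue
        row = np.empty(len(samples), dtype=np.int8)
        drop = False
        for j, s in enumerate(samples):
            code, rec_drop = _parse_gt(rec.samples[s].get("GT", (None,)), het_policy)
            if rec_drop:
                drop = True
                break
            row[j] = code
        if drop:
            n_skipped_het += 1
            continue
        if rec.chrom not in contig_order:
            contig_order[rec.chrom] = len(contig_order)
            contigs[rec.chrom] = 0
        contig_idx.append(contig_order[rec.chrom])
        positions.append(rec.pos)
        rows.append(row)
        refs.append(ref)
        alts.append(alt)
        ann = []
        for f in ANNOTATION_FIELDS:
            if f == "QUAL":
                v = rec.qual
            elif f in declared_info:
                v = rec.info.get(f, None)
                if isinstance(v, tuple):
                    v = v[0]
            else:
                v = None
            ann.append(np.nan if v is None else float(v))
        ann_rows.append(ann)
    vf.close()
    if n_skipped_nonsnp or n_skipped_het:
        logger.info(
            "read_vcf: dropped %d non-biallelic/non-SNP and %d heterozygous records",
            n_skipped_nonsnp, n_skipped_het,
        )

    g = HaploidGenotypes(
        samples=samples,
        contigs=contigs,
        contig_index=np.asarray(contig_idx, dtype=int),
        positions=np.asarray(positions, dtype=np.int64),
        alleles=np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8),
        annotations=pd.DataFrame(ann_rows, columns=list(ANNOTATION_FIELDS)),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
    )
    g.validate()
    return g


def write_vcf(g: HaploidGenotypes, path) -> None:
    """Write a :class:`HaploidGenotypes` as an uncompressed VCF v4.2."""
    header = pysam.VariantHeader()
    header.add_line('##source=haploscan')
    for f in ANNOTATION_FIELDS:
        if f != "QUAL":
            header.add_line(f'##INFO=<ID={f},Number=1,Type=Float,Description="{f}">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for name, length in g.contigs.items():
        if length:
            header.add_line(f"##contig=<ID={name},length={length}>")
        else:
            header.add_line(f"##contig=<ID={name}>")
    for s in g.samples:
        header.add_sample(s)

    contig_names = g.contig_names
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(g.n_sites):
            rec = out.new_record(
                contig=contig_names[g.contig_index[i]],
                start=int(g.positions[i]) - 1,
                stop=int(g.positions[i]),
                alleles=(
                    str(g.ref[i]) if g.ref is not None else "A",
                    str(g.alt[i]) if g.alt is not None else "T",
                ),
            )
            if g.annotations is not None:
                ann = g.annotations.iloc[i]
                qual = ann["QUAL"]
                if np.isfinite(qual):
                    rec.qual = float(qual)
                for f in ANNOTATION_FIELDS:
                    if f != "QUAL" and np.isfinite(ann[f]):
                        rec.info[f] = float(ann[f])
            for j, s in enumerate(g.samples):
                a = g.alleles[i, j]
                rec.samples[s]["GT"] = (None,) if a < 0 else (int(a),)
            out.write(rec)


def apply_hard_filters(g: HaploidGenotypes, thresholds: dict | None = None) -> HaploidGenotypes:
    """Remove sites failing any hard-filter clause.

    A site is removed iff ANY clause (e.g. ``QD < 2.0``) is true. Sites with
    an absent annotation pass that clause — absence of evidence is not
    failure, matching common hard-filter semantics. Clauses use strict
    inequalities, so boundary values are retained.

    ``thresholds`` overrides individual clauses of
    :data:`DEFAULT_HARD_FILTERS`; map a field to ``None`` to disable it.
    """
    th = dict(DEFAULT_HARD_FILTERS)
    if thresholds:
        th.update(thresholds)
    if g.annotations is None:
        return g
    fail = np.zeros(g.n_sites, dtype=bool)
    for f, clause in th.items():
        if clause is None:
            continue
        op, cut = clause
        vals = g.annotations[f].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            this = (vals < cut) if op == "<" else (vals > cut)
        this &= np.isfinite(vals)
        fail |= this
    kept = np.nonzero(~fail)[0]
    logger.info("apply_hard_filters: removed %d of %d sites", int(fail.sum()), g.n_sites)
    return g.take_sites(kept)


def remove_singletons(g: HaploidGenotypes) -> HaploidGenotypes:
    """Drop singleton and monomorphic sites.

    The minor-allele count is taken over non-missing calls; sites where it
    is <= 1 (singletons, and sites monomorphic after subsetting) are removed.
    """
    alt, called = g.allele_counts()
    mac = np.minimum(alt, called - alt)
    kept = np.nonzero(mac >= 2)[0]
    logger.info("remove_singletons: removed %d of %d sites", g.n_sites - kept.size, g.n_sites)
    return g.take_sites(kept)
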