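"""End-to-end scan orchestration: filter -> structure -> diversity ->
divergence -> LD -> selection -> CNV, from a single config.

Every output TSV carries a comment header recording the package version,
the seed, the config hash, and the coordinate convention, so a rerun with
the same config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cnv_popgen, divergence, diversity, linkage, popstructure, selection_scan, variant_io

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Pipeline settings; defaults are the standard scan parameters
    (10-kbp/1-kbp windows, r² = 0.8 pruning, top 1%/5% ZFst outliers,
    5th-percentile Tajima's D rule, FDR < 0.01, 1-kbp CNV bins)."""

    vcf: str | None = None
    depth_tsv: str | None = None
    group_file: str | None = None
    gene_bed: str | None = None
    out_dir: str = "scan_out"

    pair: tuple[str, str] = ("group1", "group2")
    window_size: int = 10_000
    window_step: int = 1_000
    fst_estimator: str = "hudson"
    prune_r2: float = 0.8
    zfst_percentiles: tuple[float, float] = (95.0, 99.0)
    d_percentile: float = 5.0
    permutation_B: int = 1_000
    clr_grid_spacing: int = 2_000
    fdr: float = 0.01
    bin_size: int = 1_000
    ld_max_dist: int = 10_000
    ld_bin_size: int = 100
    seed: int = 0
    run_cnv: bool = True
    run_ld: bool = True
    run_clr: bool = True

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: ScanConfig, convention: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# haploscan {__version__} seed={cfg.seed} config={cfg.hash()}\n")
        fh.write(f"# coordinates: {convention}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".", float_format="%.6g")


def run_scan(cfg: ScanConfig, g: variant_io.HaploidGenotypes | None = None,
             groups: variant_io.GroupAssignment | None = None,
             depth: cnv_popgen.DepthMatrix | None = None) -> dict:
    """Run the configured scan stages; returns the output bundle.

    Inputs may be passed in memory (``g``, ``groups``, ``depth``) or read
    from the paths in the config. Stage failures raise with the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    try:
        if g is None:
            g = variant_io.read_vcf(cfg.vcf)
            g = variant_io.apply_hard_filters(g)
            g = variant_io.remove_singletons(g)
        logger.info("filter: %d sites x %d samples", g.n_sites, g.n_samples)
    except Exception as e:
        raise RuntimeError(f"stage 'filter' failed: {e}") from e

    try:
        if groups is None:
            if cfg.group_file:
                groups = variant_io.GroupAssignment.read_tsv(cfg.group_file)
            else:
                pruned = popstructure.ld_prune(g, r2_max=cfg.prune_r2)
                pc = popstructure.pca(pruned, k=min(5, g.n_samples - 1))
                groups = popstructure.assign_groups(pc, k_groups=2, seed=cfg.seed)
        groups.validate(g.samples)
        bundle["groups"] = groups
    except Exception as e:
        raise RuntimeError(f"stage 'structure' failed: {e}") from e

    windows = diversity.make_windows(g.contigs, cfg.window_size, cfg.window_step)
    idx1 = groups.indices(g.samples, cfg.pair[0])
    idx2 = groups.indices(g.samples, cfg.pair[1])

    try:
        wt1 = diversity.window_diversity(g, idx1, windows)
        wt2 = diversity.window_diversity(g, idx2, windows)
        wt = wt1.rename(columns={c: f"{c}_g1" for c in wt1.columns if c not in ("contig", "start", "end", "truncated")})
        for c in ("S", "theta_pi_abs", "theta_pi", "theta_w_abs", "theta_w", "tajima_d"):
            wt[f"{c}_g2"] = wt2[c]
    except Exception as e:
        raise RuntimeError(f"stage 'diversity' failed: {e}") from e

    try:
        fst = divergence.window_fst(g, groups, windows, cfg.pair, cfg.fst_estimator)
        dxy = divergence.window_dxy(g, groups, windows, cfg.pair)
        wt["fst"] = fst["fst"]
        wt["dxy"] = dxy["dxy"]
        ztab = divergence.zfst(wt["fst"].to_numpy())
        wt = pd.concat([wt, ztab], axis=1)
        bundle["sharing"] = divergence.classify_shared_snps(g, groups, cfg.pair)
    except Exception as e:
        raise RuntimeError(f"stage 'divergence' failed: {e}") from e

    if cfg.run_ld:
        try:
            pairs = linkage.pairwise_r2(g, idx1, cfg.ld_max_dist)
            curve = linkage.ld_decay_curve(pairs, cfg.ld_bin_size, cfg.ld_max_dist)
            if curve.occupied().sum() >= 5:
                linkage.loess_smooth(curve)
            bundle["ld_curve"] = curve
            _write_tsv(curve.to_frame(), out / "ld_decay.tsv", cfg, "distance bins, bp")
        except Exception as e:
            raise RuntimeError(f"stage 'ld' failed: {e}") from e

    try:
        null1 = selection_scan.permutation_null_tajima(
            g, idx1, windows, B=cfg.permutation_B, seed=cfg.seed, percentile=cfg.d_percentile)
        bundle["null_group1"] = null1
        clr_res = None
        if cfg.run_clr:
            background = diversity.compute_sfs(g, idx1, folded=True)
            clr_res = selection_scan.clr_scan(
                g, idx1, background, grid_spacing=cfg.clr_grid_spacing,
                window_bp=cfg.window_size)
            bundle["clr"] = clr_res
            _write_tsv(clr_res.table, out / "clr.tsv", cfg, "1-based grid positions")
        wt_sel = wt.rename(columns={"tajima_d_g1": "tajima_d"})
        islands = selection_scan.call_islands(
            wt_sel, null1, clr_res, step=cfg.window_step, require_clr=False)
        bundle["islands"] = islands
        _write_tsv(selection_scan.islands_to_frame(islands), out / "islands.tsv", cfg,
                   "1-based inclusive")
        bed = selection_scan.islands_to_frame(islands).copy()
        if len(bed):
            bed["start"] = bed["start"] - 1  # BED is 0-based half-open
        bed.to_csv(out / "islands.bed", sep="\t", index=False, header=False,
                   columns=["contig", "start", "end"])
    except Exception as e:
        raise RuntimeError(f"stage 'selection' failed: {e}") from e

    if cfg.run_cnv and (depth is not None or cfg.depth_tsv):
        try:
            if depth is None:
                depth = cnv_popgen.DepthMatrix.read_tsv(cfg.depth_tsv)
            cnm = cnv_popgen.estimate_copy_number(depth)
            i1 = groups.indices(depth.samples, cfg.pair[0])
            i2 = groups.indices(depth.samples, cfg.pair[1])
            vst_vals = cnv_popgen.vst(cnm.cn, i1, i2)
            pic1 = cnv_popgen.pic(cnm.cn[:, i1])
            pic2 = cnv_popgen.pic(cnm.cn[:, i2])
            cn_table = cnm.bins.copy()
            cn_table["vst"] = vst_vals
            cn_table["pic_group1"] = pic1
            cn_table["pic_group2"] = pic2
            bundle["cn"] = cnm
            bundle["cn_table"] = cn_table
            _write_tsv(cn_table, out / "cnv_stats.tsv", cfg, "1-based inclusive bins")
            _write_tsv(cnm.segments(), out / "cnv_segments.tsv", cfg, "1-based inclusive")
        except Exception as e:
            raise RuntimeError(f"stage 'cnv' failed: {e}") from e

    bundle["windows"] = wt
    _write_tsv(wt, out / "windows.tsv", cfg, "1-based inclusive [start, end]")
    _write_tsv(bundle["sharing"].to_frame(), out / "snp_sharing.tsv", cfg, "site categories")
    return bundle
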