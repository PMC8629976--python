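# haploscan

Divergence and selection scans for panels of haploid genomes.

`haploscan` implements the population-genomic toolkit used to compare two
diverged groups of haploid (e.g. fungal) isolates from a SNP panel and
binned read depth:

- **Variant I/O and filtering** — biallelic-SNP VCF reader/writer for
  haploid calls, GATK-style hard filters, singleton removal.
- **Population structure** — p-distance matrices, neighbor-joining trees,
  PCA, LD pruning, k-means group assignment.
- **Diversity** — sliding-window θπ, Watterson's θ, Tajima's D, and
  site-frequency spectra (folded/unfolded, hypergeometric projection).
- **Divergence** — Hudson (ratio-of-averages) and Weir–Cockerham Fst,
  Dxy, ZFst outliers, and SNP-sharing classification between groups.
- **Linkage disequilibrium** — r²/D′, distance-binned decay curves with
  lowess smoothing, LD50.
- **Selection scans** — a permutation-calibrated Tajima's D rule, an
  SFS-based composite-likelihood-ratio (CLR) sweep scan with an
  invariant-site density term, and a multi-evidence genomic-island caller.
- **Copy number** — per-sample HMM copy-number calls from binned depth,
  Vst, PIC, and differential copy-number tests with FDR control.
- **Synthetic data** — a seeded Balding–Nichols two-population simulator
  with ground truth, sweep injection, and negative-binomial CNV depth.

The statistical models, parameter defaults, and design decisions are
documented in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a 29-isolate two-group panel with a hard sweep injected at
position 200,000 of a 400-kbp contig, then run the standard scan. Output
shown is from an actual session.

```text
$ haploscan simulate --out-dir sim --seed 42 --contig-length 400000 --sweep-center 200000
wrote 3127 SNPs x 29 samples to sim

$ haploscan filter sim/sim.vcf --out filtered.vcf
3127 -> 2539 sites

$ haploscan structure filtered.vcf --out-dir struct
variance explained: [0.3389 0.0752 0.0389 0.0374 0.0373]

$ haploscan ld filtered.vcf --groups sim/groups.tsv --out ld.tsv
LD50 = 201 bp (decayed)

$ haploscan scan --vcf filtered.vcf --groups sim/groups.tsv --depth sim/depth.tsv --out-dir scan
windows: 400; islands: 2
```

The island caller recovers the injected sweep — both reported islands
bracket the true center at 200,000:

```text
$ cat scan/islands.tsv
# haploscan 0.1.0 seed=0 config=0e25d932875f
# coordinates: 1-based inclusive
contig	start	end	n_windows	mean_zfst	min_tajima_d
contig1	193001	204000	2	2.18604	-1.15945
contig1	197001	212000	6	2.50718	-1.685
```

`scan/windows.tsv` holds the per-window statistics for both groups
(θπ, θw, Tajima's D, Fst, Dxy, ZFst and outlier flags); `scan/clr.tsv`
the CLR grid; `scan/cnv_stats.tsv` and `scan/cnv_segments.tsv` the
copy-number results. Every output carries a header with the package
version, seed, and config hash, and reruns with the same inputs are
byte-identical.

The same steps are available as library calls; see
`haploscan.pipeline.run_scan` and the per-module APIs
(`diversity.window_diversity`, `divergence.window_fst`,
`selection_scan.clr_scan`, `cnv_popgen.estimate_copy_number`, …).

## Full-data reproduction

For a real multi-isolate VCF plus group assignments, the
`haploscan reproduce-dryad` subcommand runs the standard scan with the
Weir–Cockerham Fst option under both filter orders (hard filters before
or after singleton removal), writing one output bundle per order.

## License

MIT.
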