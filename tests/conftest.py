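import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from haploscan.variant_io import ANNOTATION_FIELDS, HaploidGenotypes


def make_genotypes(rng, n_sites=50, n_samples=8, contig_len=100_000,
                   missing_rate=0.0, n_contigs=1, segregating=True):
    """Random HaploidGenotypes for unit tests (all sites segregating)."""
    contigs = {f"c{i+1}": contig_len for i in range(n_contigs)}
    ci = np.sort(rng.integers(0, n_contigs, size=n_sites))
    pos = np.empty(n_sites, dtype=np.int64)
    for c in range(n_contigs):
        k = int((ci == c).sum())
        pos[ci == c] = np.sort(rng.choice(np.arange(1, contig_len + 1), size=k, replace=False))
    a = (rng.random((n_sites, n_samples)) < rng.uniform(0.1, 0.9, size=(n_sites, 1))).astype(np.int8)
    if missing_rate:
        a[rng.random(a.shape) < missing_rate] = -1
    if segregating:
        for i in range(n_sites):
            calls = a[i][a[i] >= 0]
            if calls.size < 2 or calls.min() == calls.max():
                a[i, 0], a[i, 1] = 0, 1
    ann = pd.DataFrame({f: np.full(n_sites, np.nan) for f in ANNOTATION_FIELDS})
    ann["QUAL"] = 100.0
    g = HaploidGenotypes(
        samples=[f"s{j+1}" for j in range(n_samples)],
        contigs=contigs,
        contig_index=ci,
        positions=pos,
        alleles=a,
        annotations=ann,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
    )
    g.validate()
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
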