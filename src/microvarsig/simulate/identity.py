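"""Planted-cluster per-marker identity matrices for dereplication tests.

Genomes are partitioned into planted clusters; for each unordered genome
pair and each single-copy marker gene, a percent identity is drawn
uniformly from the within-cluster range (same cluster) or the
between-cluster range (different clusters).  The ranges must straddle the
ANI threshold with no overlap, so downstream threshold clustering is
guaranteed to be able to recover the partition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig

__all__ = ["simulate_identity_matrix"]


def simulate_identity_matrix(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, list[list[str]]]:
    """Returns (long-form identity table, planted partition)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    cp = config.cluster_plan
    ids = [f"g{i + 1:04d}" for i in range(config.n_genomes)]
    clusters: list[list[str]] = []
    k = 0
    for size in cp.sizes:
        clusters.append(ids[k : k + size])
        k += size
    membership = {g: ci for ci, c in enumerate(clusters) for g in c}
    markers = [f"M{m + 1:02d}" for m in range(config.n_marker_genes)]

    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            lo, hi = cp.within if membership[a] == membership[b] else cp.between
            vals = rng.uniform(lo, hi, size=len(markers))
            for m, v in zip(markers, vals):
                rows.append(dict(genome_a=a, genome_b=b, marker_id=m,
                                 identity_pct=float(v)))
    return pd.DataFrame(rows), clusters
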