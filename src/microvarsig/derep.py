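"""Reference-genome dereplication via a marker-gene ANI proxy.

For every genome pair, the median percent identity over their shared
single-copy marker genes stands in for whole-genome average nucleotide
identity (ANI).  Genomes are clustered at an operational 95% identity
threshold — by default single linkage, i.e. connected components of the
graph with an edge wherever the proxy meets the threshold, the only flat
thresholding that is independent of input order — and each cluster is
represented by its genome with the highest mapped read coverage
(lexicographically smallest id on ties).  Pairs with no shared marker have
an undefined proxy and conservatively contribute no edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

__all__ = [
    "AniMatrix",
    "ClusterSet",
    "compute_ani_proxy",
    "cluster_genomes",
    "select_representatives",
    "read_identity_table",
    "kmer_identity",
]


@dataclass
class AniMatrix:
    """Pairwise ANI proxies from per-marker identities.

    ``ani`` maps an ordered (min, max) genome-id pair to the median marker
    identity; pairs with no shared marker are absent (undefined).
    """

    genome_ids: list[str]
    ani: dict[tuple[str, str], float]
    per_marker: pd.DataFrame | None = None

    def proxy(self, a: str, b: str) -> float | None:
        if a == b:
            return 100.0
        return self.ani.get((min(a, b), max(a, b)))


@dataclass
class ClusterSet:
    """A flat genome partition with optional per-cluster representatives."""

    clusters: list[list[str]]
    representative: dict[int, str] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for members in self.clusters:
            dup = seen & set(members)
            if dup:
                raise ValueError(f"genomes in multiple clusters: {sorted(dup)}")
            seen |= set(members)
        for ci, rep in self.representative.items():
            if rep not in self.clusters[ci]:
                raise ValueError(f"representative {rep} not in cluster {ci}")

    @property
    def n_genomes(self) -> int:
        return sum(len(c) for c in self.clusters)

    def partition(self) -> dict[str, int]:
        return {g: i for i, members in enumerate(self.clusters) for g in members}

    def as_sets(self) -> set[frozenset]:
        return {frozenset(c) for c in self.clusters}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, members in enumerate(self.clusters):
            rep = self.representative.get(ci)
            for g in sorted(members):
                rows.append(
                    dict(genome_id=g, cluster_id=f"C{ci:04d}",
                         is_representative=int(g == rep))
                )
        return pd.DataFrame(rows)


def read_identity_table(path: str | Path) -> pd.DataFrame:
    """Read a long-form per-marker identity TSV
    (genome_a, genome_b, marker_id, identity_pct)."""
    df = pd.read_csv(path, sep="\t")
    required = {"genome_a", "genome_b", "marker_id", "identity_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"identity table missing columns: {sorted(missing)}")
    return df


def compute_ani_proxy(
    per_marker_identity: pd.DataFrame, genome_ids: list[str] | None = None
) -> AniMatrix:
    """Median per-pair marker identity as the ANI proxy.

    Input is long-form with columns genome_a, genome_b, marker_id,
    identity_pct.  Identities outside [0, 100] are a validation error;
    missing markers are simply absent rows; self-pairs are fixed at 100.
    """
    df = per_marker_identity
    vals = df["identity_pct"].to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 100)) or np.any(np.isnan(vals)):
        raise ValueError("identity_pct values must lie in [0, 100]")
    a = df["genome_a"].astype(str)
    b = df["genome_b"].astype(str)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    key = pd.DataFrame({"lo": lo, "hi": hi, "identity_pct": vals})
    key = key[key["lo"] != key["hi"]]
    med = key.groupby(["lo", "hi"])["identity_pct"].median()
    ani = {(l, h): float(v) for (l, h), v in med.items()}
    ids = sorted(set(genome_ids or []) | set(a) | set(b))
    return AniMatrix(genome_ids=ids, ani=ani, per_marker=df)


def cluster_genomes(
    ani: AniMatrix, threshold: float = 95.0, linkage: str = "single"
) -> ClusterSet:
    """Flat clustering of genomes at an ANI-proxy threshold.

    ``single`` (default): connected components over edges with proxy >=
    threshold.  ``complete`` is available for sensitivity analysis via
    agglomerative complete linkage on 100 - proxy (undefined pairs treated
    as maximally distant).  Clusters are emitted sorted by smallest member
    id for determinism.
    """
    ids = sorted(ani.genome_ids)
    n = len(ids)
    if n == 0:
        return ClusterSet(clusters=[])
    idx = {g: i for i, g in enumerate(ids)}
    if linkage == "single":
        rows, cols = [], []
        for (a, b), v in ani.ani.items():
            if v >= threshold and a in idx and b in idx:
                rows += [idx[a], idx[b]]
                cols += [idx[b], idx[a]]
        graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        _, labels = connected_components(graph, directed=False)
    elif linkage == "complete":
        if n == 1:
            labels = np.zeros(1, dtype=int)
        else:
            dist = np.full((n, n), 200.0)
            np.fill_diagonal(dist, 0.0)
            for (a, b), v in ani.ani.items():
                if a in idx and b in idx:
                    dist[idx[a], idx[b]] = dist[idx[b], idx[a]] = 100.0 - v
            Z = _scipy_linkage(squareform(dist, checks=False), method="complete")
            labels = fcluster(Z, t=100.0 - threshold, criterion="distance") - 1
    else:
        raise ValueError("linkage must be 'single' or 'complete'")
    groups: dict[int, list[str]] = {}
    for g, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(g)
    clusters = sorted((sorted(m) for m in groups.values()), key=lambda c: c[0])
    return ClusterSet(clusters=clusters)


def select_representatives(
    clusters: ClusterSet, coverage: dict[str, float]
) -> ClusterSet:
    """Pick the highest-coverage genome per cluster (missing coverage = 0;
    ties broken by lexicographically smallest genome id)."""
    reps = {}
    for ci, members in enumerate(clusters.clusters):
        reps[ci] = sorted(members, key=lambda g: (-coverage.get(g, 0.0), g))[0]
    return ClusterSet(
        clusters=clusters.clusters, representative=reps, coverage=dict(coverage)
    )


def kmer_identity(seq_a: str, seq_b: str, k: int = 15) -> float:
    """Rough percent-identity estimate from k-mer set overlap.

    A Mash-style transform of the Jaccard index of k-mer sets; intended
    only as a convenience for synthetic genomes (this is not an alignment
    identity and is no substitute for BLASTn-derived values).
    """
    sa = {seq_a[i : i + k] for i in range(len(seq_a) - k + 1)}
    sb = {seq_b[i : i + k] for i in range(len(seq_b) - k + 1)}
    if not sa or not sb:
        raise ValueError("sequences shorter than k")
    j = len(sa & sb) / len(sa | sb)
    if j == 0:
        return 0.0
    if j == 1:
        return 100.0
    d = -1.0 / k * np.log(2 * j / (1 + j))
    return float(max(0.0, min(100.0, 100.0 * (1.0 - d))))
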