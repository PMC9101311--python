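"""RPKM-like gene abundance, per-gene SNP density, and enrichment tests.

Abundance: for gene G_i the length-normalised read count NG_i = reads_i /
length_i is renormalised within each sample to the relative abundance
RNG_i = NG_i / sum_j NG_j, which sums to 1 per sample.

Density: per-gene kept-SNP counts per kilobase, computed only where the
gene has valid coverage (mean depth >= 10x by default); densities are
compared between paired timepoints per subject with the Wilcoxon
signed-rank test (exact null for n <= 25 without ties, normal
approximation otherwise; zero differences dropped), BH-adjusted across
genes.  KO/pathway over-representation uses the upper-tail hypergeometric
test, BH-adjusted across pathways.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .selection import fdr_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "gene_abundance",
    "snp_density",
    "paired_density_test",
    "wilcoxon_signed_rank",
    "ko_enrichment",
]


def gene_abundance(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Relative gene abundance table (genes x samples).

    ``counts`` is a gene x sample read-count table; ``lengths`` gives gene
    length in bp (index must cover all genes).  Returns RNG values; samples
    whose counts are all zero come back as NaN columns with a logged flag
    rather than silent zeros.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing gene lengths: {missing[:5]}...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    ng = counts.div(lengths, axis=0)
    totals = ng.sum(axis=0)
    dead = totals[totals == 0].index.tolist()
    if dead:
        logger.warning("samples with zero total counts (RNG undefined): %s", dead)
    rng = ng.div(totals.replace(0, np.nan), axis=1)
    return rng


def snp_density(
    genes: pd.DataFrame,
    snp_counts: pd.DataFrame,
    depth: pd.DataFrame,
    min_depth: float = 10.0,
) -> pd.DataFrame:
    """Per-gene per-sample SNP density with the valid-coverage rule.

    ``genes``: index gene_id, column ``length_bp``; ``snp_counts`` and
    ``depth``: gene x sample tables.  Density (SNPs per kb) is reported
    only where depth >= ``min_depth`` (boundary inclusive); other cells
    are NaN with ``included`` False in the long-form output.
    """
    if (genes["length_bp"] <= 0).any():
        raise ValueError("gene lengths must be positive")
    snp_counts = snp_counts.reindex(index=genes.index).fillna(0.0)
    depth = depth.reindex(index=genes.index, columns=snp_counts.columns)
    kb = genes["length_bp"] / 1000.0
    dens = snp_counts.div(kb, axis=0)
    included = depth >= min_depth
    out = (
        dens.where(included)
        .stack(future_stack=True)
        .rename("density_per_kb")
        .reset_index()
    )
    out.columns = ["gene_id", "sample_id", "density_per_kb"]
    out["snp_count"] = snp_counts.stack(future_stack=True).to_numpy()
    out["depth"] = depth.stack(future_stack=True).to_numpy()
    out["included"] = included.stack(future_stack=True).to_numpy()
    return out


def wilcoxon_signed_rank(differences) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank p for paired differences.

    Zero differences are dropped before ranking; ties get midranks.  The
    exact null distribution is used for n <= 25 when the absolute
    differences are tie-free, the continuity-corrected normal
    approximation otherwise.  Returns (W_plus, p, n_used); an all-zero
    vector yields (0, 1.0, 0), flagged by n_used == 0.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, 0
    ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not ties) else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", alternative="two-sided",
        correction=(method == "approx"), method=method,
    )
    return float(res.statistic), float(res.pvalue), n


def paired_density_test(
    day0: pd.DataFrame, day30: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene paired Wilcoxon test of SNP densities between timepoints.

    ``day0`` and ``day30`` are gene x subject density tables with matching
    labels; NaN cells (genes excluded by the coverage rule in a sample)
    drop that subject pair for that gene.  p-values are BH-adjusted
    across genes.
    """
    subjects = day0.columns.intersection(day30.columns)
    genes = day0.index.intersection(day30.index)
    rows = []
    for g in genes:
        a = day0.loc[g, subjects].to_numpy(dtype=float)
        b = day30.loc[g, subjects].to_numpy(dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 1:
            rows.append(dict(gene_id=g, n_pairs=0, statistic=np.nan, p_value=np.nan))
            continue
        w, p, n_used = wilcoxon_signed_rank(b[ok] - a[ok])
        rows.append(dict(gene_id=g, n_pairs=int(ok.sum()), statistic=w, p_value=p))
    df = pd.DataFrame(rows)
    tested = df["p_value"].notna().to_numpy()
    q = np.full(len(df), np.nan)
    if tested.any():
        qv, _ = fdr_adjust(df.loc[tested, "p_value"].to_numpy(), alpha=alpha)
        q[tested] = qv
    df["adjusted_p"] = q
    df["significant"] = df["adjusted_p"] < alpha
    return df


def ko_enrichment(
    significant: set[str],
    background: set[str],
    pathway_map: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric pathway over-representation test.

    ``pathway_map`` is long-form (ko_id, pathway_id).  With N background
    KOs, K of them in a pathway and n significant KOs of which k are in
    the pathway, p = P(X >= k), X ~ Hypergeom(N, K, n); BH across
    pathways.  Pathways with no background member are skipped and logged.
    """
    if not significant <= background:
        raise ValueError("significant KOs must be a subset of the background")
    N = len(background)
    n = len(significant)
    rows = []
    for pw, sub in pathway_map.groupby("pathway_id", sort=True):
        members = set(sub["ko_id"]) & background
        K = len(members)
        if K == 0:
            logger.info("pathway %s has no background members; skipped", pw)
            continue
        k = len(members & significant)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(pathway_id=pw, n_in_pathway=K, n_significant=n,
                         n_overlap=k, p_value=p))
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    q, rej = fdr_adjust(df["p_value"].to_numpy(), alpha=alpha)
    df["adjusted_p"] = q
    df["significant"] = rej
    return df.sort_values("adjusted_p", kind="stable").reset_index(drop=True)
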