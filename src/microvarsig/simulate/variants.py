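"""Per-sample variant simulation with planted spectra and filter violations.

For every sample, SNV positions are drawn uniformly over each genome; the
reference allele is the genome base at that position and the alternate is
drawn from the sample condition's 12-type substitution weights restricted
to the three types with that source base (renormalised).  Allele
frequencies follow the configured Beta model above the filter floor, read
support is Poisson around the configured depth and split between strands
binomially with both strands kept positive for clean calls.

Planted filter violations (disjoint subsets): low-AF SNPs (below the 1%
rule), low-support SNPs (5 reads or fewer), single-strand InDels, and
structural variants with fewer than 3 supporting reads.  False SNV calls
are additionally injected inside single-copy marker-gene regions, pass all
filters, and are excluded from the true-variant list — they are what the
marker-based false-positive-rate estimator is meant to catch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..spectrum import SUBSTITUTION_TYPES
from ..variants import VariantCall
from .config import ConfigurationError, SimConfig
from .genomes import Genome
from .truth import SimTruth

__all__ = [
    "sample_table",
    "draw_alt_codes",
    "simulate_variant_sets",
]

_BASES = "ACGT"
# alternate bases for each reference base code, in 12-type order
_ALTS = [[b for b in range(4) if b != r] for r in range(4)]


def sample_table(config: SimConfig) -> pd.DataFrame:
    """Sample metadata: ids, subjects (paired across timepoints), condition."""
    rows = []
    k = 0
    for spec in config.groups:
        for i in range(spec.n_samples):
            k += 1
            rows.append(
                dict(
                    sample_id=f"S{k:03d}",
                    subject_id=f"{spec.group}-P{i + 1:02d}",
                    group=spec.group,
                    timepoint=spec.timepoint,
                    condition=spec.condition,
                )
            )
    return pd.DataFrame(rows)


def draw_alt_codes(
    ref_codes: np.ndarray, weights: list[float], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw alternate-base codes conditioned on reference bases.

    ``weights`` are the 12 ordered type weights; at a site with reference
    base X the alternate is drawn from the three types with source X,
    renormalised.  Returns (alt_codes, type_indices).
    """
    w = np.asarray(weights, dtype=float)
    alt = np.empty(ref_codes.size, dtype=np.int64)
    tidx = np.empty(ref_codes.size, dtype=np.int64)
    for r in range(4):
        mask = ref_codes == r
        k = int(mask.sum())
        if k == 0:
            continue
        wr = w[3 * r : 3 * r + 3]
        tot = wr.sum()
        if tot <= 0:
            raise ConfigurationError(
                f"all-zero substitution weights for ref base {_BASES[r]}"
            )
        pick = rng.choice(3, size=k, p=wr / tot)
        alt[mask] = np.asarray(_ALTS[r])[pick]
        tidx[mask] = 3 * r + pick
    return alt, tidx


def _clean_af(n: int, config: SimConfig, rng) -> np.ndarray:
    m = config.af_model
    return m.floor + (1 - m.floor) * rng.beta(m.alpha, m.beta, size=n)


def _clean_depth(n: int, config: SimConfig, rng) -> np.ndarray:
    d = config.depth_model
    return d.min_passing + rng.poisson(max(d.mean_depth - d.min_passing, 0.0), size=n)


def _clean_strands(total: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    # both strands >= 1 for clean calls (totals are >= min_passing >= 2)
    fwd = 1 + rng.binomial(np.maximum(total - 2, 0), 0.5)
    return fwd, total - fwd


def _marker_positions(genome: Genome) -> np.ndarray:
    parts = [np.arange(s, e + 1) for s, e in genome.marker_regions()]
    return np.concatenate(parts) if parts else np.array([], dtype=int)


def simulate_variant_sets(
    genomes: list[Genome],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[VariantCall]], SimTruth, pd.DataFrame]:
    """Simulate per-sample variant calls for the whole cohort.

    Returns (calls per sample, SimTruth, sample metadata).  Everything is
    deterministic under a fixed seed/generator.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    meta = sample_table(config)
    truth = SimTruth(
        marker_regions={g.genome_id: g.marker_regions() for g in genomes}
    )
    genomes = sorted(genomes, key=lambda g: g.genome_id)
    codes = {g.genome_id: g.codes() for g in genomes}
    marker_pos = {g.genome_id: _marker_positions(g) for g in genomes}
    viol = config.violations

    calls_by_sample: dict[str, list[VariantCall]] = {}
    for row in meta.itertuples(index=False):
        sid = row.sample_id
        weights = config.weights_for(row.condition)
        calls: list[VariantCall] = []
        spectrum = np.zeros(12, dtype=int)
        book = dict(kept=0, rejected_low_af=0, rejected_low_support=0,
                    rejected_single_strand=0, rejected_low_sv_support=0)

        for g in genomes:
            gid = g.genome_id
            L = g.length
            kb = L / 1000.0
            gcodes = codes[gid]
            n_snp = int(rng.poisson(config.snp_rate * kb))
            mpos = marker_pos[gid]
            n_fp = int(rng.poisson(config.fp_marker_rate * mpos.size / 1000.0))
            n_fp = min(n_fp, mpos.size)

            fp_sites = rng.choice(mpos, size=n_fp, replace=False) if n_fp else np.array([], dtype=int)
            pool = np.setdiff1d(np.arange(1, L + 1), fp_sites, assume_unique=False)
            n_snp = min(n_snp, pool.size)
            snp_sites = rng.choice(pool, size=n_snp, replace=False)

            # --- true SNVs ---------------------------------------------------
            ref = gcodes[snp_sites - 1]
            alt, tidx = draw_alt_codes(ref, weights, rng)
            af = _clean_af(n_snp, config, rng)
            dp = _clean_depth(n_snp, config, rng).astype(int)
            u = rng.random(n_snp)
            low_af = u < viol.low_af_snp
            low_dp = (u >= viol.low_af_snp) & (u < viol.low_af_snp + viol.low_support_snp)
            af[low_af] = rng.uniform(0.001, 0.009, size=int(low_af.sum()))
            dp[low_dp] = rng.integers(2, 6, size=int(low_dp.sum()))
            fwd, rev = _clean_strands(dp, rng)
            for i in range(n_snp):
                c = VariantCall(
                    sample_id=sid, genome_id=gid, contig_id=gid,
                    pos=int(snp_sites[i]),
                    ref_allele=_BASES[ref[i]], alt_allele=_BASES[alt[i]],
                    vtype="SNP", allele_frequency=float(af[i]),
                    support_total=int(dp[i]), support_fwd=int(fwd[i]),
                    support_rev=int(rev[i]),
                )
                calls.append(c)
                spectrum[tidx[i]] += 1
                truth.true_variants.append(
                    dict(
                        sample_id=sid, genome_id=gid, pos=c.pos,
                        ref_allele=c.ref_allele, alt_allele=c.alt_allele,
                        vtype="SNP", condition=row.condition,
                        violates="low_af" if low_af[i]
                        else ("low_support" if low_dp[i] else ""),
                    )
                )
                if low_af[i]:
                    book["rejected_low_af"] += 1
                elif low_dp[i]:
                    book["rejected_low_support"] += 1
                else:
                    book["kept"] += 1

            # --- injected false calls in marker regions ----------------------
            if n_fp:
                ref_fp = gcodes[fp_sites - 1]
                alt_fp, tidx_fp = draw_alt_codes(ref_fp, [1.0] * 12, rng)
                af_fp = _clean_af(n_fp, config, rng)
                dp_fp = _clean_depth(n_fp, config, rng).astype(int)
                fwd_fp, rev_fp = _clean_strands(dp_fp, rng)
                for i in range(n_fp):
                    calls.append(
                        VariantCall(
                            sample_id=sid, genome_id=gid, contig_id=gid,
                            pos=int(fp_sites[i]),
                            ref_allele=_BASES[ref_fp[i]],
                            alt_allele=_BASES[alt_fp[i]],
                            vtype="SNP", allele_frequency=float(af_fp[i]),
                            support_total=int(dp_fp[i]),
                            support_fwd=int(fwd_fp[i]), support_rev=int(rev_fp[i]),
                        )
                    )
                    spectrum[tidx_fp[i]] += 1
                    book["kept"] += 1

            # --- InDels and SVs ---------------------------------------------
            for vclass, rate, lo, hi in (
                ("INDEL", config.indel_rate, 1, 50),
                ("SV", config.sv_rate, 51, 150),
            ):
                n_v = int(rng.poisson(rate * kb))
                for _ in range(n_v):
                    ln = int(rng.integers(lo, hi + 1))
                    pos = int(rng.integers(1, L - ln))
                    anchor = _BASES[gcodes[pos - 1]]
                    if rng.random() < 0.5:  # deletion
                        refal = anchor + "".join(
                            _BASES[b] for b in gcodes[pos : pos + ln]
                        )
                        altal = anchor
                    else:  # insertion
                        refal = anchor
                        altal = anchor + "".join(
                            _BASES[b] for b in rng.integers(0, 4, size=ln)
                        )
                    af_v = float(_clean_af(1, config, rng)[0])
                    if vclass == "SV":
                        bad = rng.random() < viol.low_support_sv
                        dp_v = int(rng.integers(1, 3)) if bad else int(
                            3 + rng.poisson(config.depth_model.mean_depth)
                        )
                        fwd_v = int(rng.binomial(dp_v, 0.5))
                        violates = "low_sv_support" if bad else ""
                        book["rejected_low_sv_support" if bad else "kept"] += 1
                    else:
                        dp_v = int(_clean_depth(1, config, rng)[0])
                        bad = rng.random() < viol.single_strand_indel
                        if bad:
                            fwd_v = dp_v if rng.random() < 0.5 else 0
                            violates = "single_strand"
                            book["rejected_single_strand"] += 1
                        else:
                            fwd_v = int(_clean_strands(np.array([dp_v]), rng)[0][0])
                            violates = ""
                            book["kept"] += 1
                    calls.append(
                        VariantCall(
                            sample_id=sid, genome_id=gid, contig_id=gid,
                            pos=pos, ref_allele=refal, alt_allele=altal,
                            vtype=vclass, allele_frequency=af_v,
                            support_total=dp_v, support_fwd=fwd_v,
                            support_rev=dp_v - fwd_v,
                        )
                    )
                    truth.true_variants.append(
                        dict(
                            sample_id=sid, genome_id=gid, pos=pos,
                            ref_allele=refal, alt_allele=altal, vtype=vclass,
                            condition=row.condition, violates=violates,
                        )
                    )

        calls_by_sample[sid] = calls
        truth.planted_spectra[sid] = spectrum.tolist()
        truth.filter_expectations[sid] = book

    return calls_by_sample, truth, meta
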