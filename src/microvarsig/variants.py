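"""Variant parsing, size classification, filtering and bookkeeping.

Variants are classified by allele lengths into SNPs, short InDels
(length difference 1-50 bp inclusive) and structural variants (>50 bp).
The filter policy follows the study design this package implements:

* SNPs and InDels are kept only with allele frequency strictly above 1%
  and read support strictly above 5 reads ("more than five reads");
* InDels additionally require at least one supporting read on each strand;
* structural variants require at least 3 supporting reads;
* a genome enters downstream analyses only with >= 3 kept SNPs.

A truth-based false-positive-rate estimator over single-copy marker-gene
regions is provided for synthetic runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "VariantCall",
    "FilterPolicy",
    "classify_variant",
    "decompose_mnp",
    "read_variant_calls",
    "filter_variants",
    "genomes_passing",
    "estimate_false_positive_rate",
    "write_vcf",
]

_DNA = set("ACGT")


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one sample against one reference genome."""

    sample_id: str
    genome_id: str
    contig_id: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    vtype: str  # SNP | INDEL | SV
    allele_frequency: float
    support_total: int
    support_fwd: int
    support_rev: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.support_fwd + self.support_rev != self.support_total:
            raise ValueError(
                f"strand support {self.support_fwd}+{self.support_rev} "
                f"!= total {self.support_total}"
            )


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds for variant retention; defaults mirror the study rules."""

    min_af: float = 0.01  # strict: AF must exceed this
    min_support: int = 5  # strict: "more than five reads"
    indel_strand_rule: bool = True  # >=1 read on each strand (InDels)
    sv_min_support: int = 3  # inclusive: "at least three reads"
    min_snps_per_genome: int = 3  # inclusive: "at least three SNPs"
    snp_strand_rule: bool = False  # sensitivity option, off by default

    def __post_init__(self):
        if self.min_af < 0 or self.min_support < 0 or self.sv_min_support < 0:
            raise ValueError("thresholds must be non-negative")


def classify_variant(ref_allele: str, alt_allele: str) -> str:
    """SNP / INDEL / SV by allele lengths; equal-length multi-base -> 'MNP'.

    Length difference d: 1 <= d <= 50 is an InDel (inclusive at 50),
    d > 50 a structural variant.  MNPs are decomposed into per-base SNPs
    by :func:`decompose_mnp` at read time.
    """
    ref, alt = ref_allele.upper(), alt_allele.upper()
    if not ref or not alt or not (set(ref) <= _DNA and set(alt) <= _DNA):
        raise ValueError(f"alleles must be non-empty DNA strings: {ref!r} {alt!r}")
    d = abs(len(ref) - len(alt))
    if d == 0:
        return "SNP" if len(ref) == 1 else "MNP"
    return "INDEL" if d <= 50 else "SV"


def decompose_mnp(call: VariantCall) -> list[VariantCall]:
    """Split an equal-length multi-base substitution into per-base SNPs."""
    out = []
    for i, (r, a) in enumerate(zip(call.ref_allele, call.alt_allele)):
        if r != a:
            out.append(
                replace(call, pos=call.pos + i, ref_allele=r, alt_allele=a, vtype="SNP")
            )
    return out


def read_variant_calls(
    vcf_path: str | Path,
    sample_id: str,
    contig_to_genome: dict[str, str] | None = None,
    af_key: str = "AF",
    dp_key: str = "DP",
    srf_key: str = "SRF",
    srr_key: str = "SRR",
) -> list[VariantCall]:
    """Parse a VCF into :class:`VariantCall` objects, one per ALT allele.

    Multi-allelic records are split; MNPs are decomposed into SNPs (logged).
    When ``af_key`` is absent, AF falls back to AD (alt depth / total
    depth); a record with neither is a hard error naming the record.
    Malformed records are skipped and counted in the log.
    """
    calls: list[VariantCall] = []
    skipped = 0
    decomposed = 0
    with pysam.VariantFile(str(vcf_path)) as vf:
        header_keys = set(vf.header.info.keys())

        def _info(rec, key, default=None):
            # pysam raises on keys absent from the header
            return rec.info.get(key, default) if key in header_keys else default

        for rec in vf:
            if not rec.alts:
                skipped += 1
                continue
            genome = (contig_to_genome or {}).get(rec.chrom, rec.chrom)
            afs = _info(rec, af_key)
            if afs is None:
                ad = _info(rec, "AD")
                if ad is None:
                    raise ValueError(
                        f"{vcf_path}: record {rec.chrom}:{rec.pos} lacks "
                        f"{af_key} and has no AD fallback"
                    )
                total = sum(ad)
                afs = tuple(a / total for a in ad[1:]) if total else (0.0,) * len(rec.alts)
            if not isinstance(afs, (tuple, list)):
                afs = (afs,) * len(rec.alts)
            dp = int(_info(rec, dp_key, 0) or 0)
            srf = int(_info(rec, srf_key, dp) or 0)
            srr = int(_info(rec, srr_key, dp - srf) or 0)
            if srf + srr != dp:
                srr = dp - srf
            for alt, af in zip(rec.alts, afs):
                try:
                    vtype = classify_variant(rec.ref, alt)
                except ValueError:
                    skipped += 1
                    continue
                call = VariantCall(
                    sample_id=sample_id,
                    genome_id=genome,
                    contig_id=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref.upper(),
                    alt_allele=alt.upper(),
                    vtype=vtype if vtype != "MNP" else "MNP",
                    allele_frequency=float(af),
                    support_total=dp,
                    support_fwd=srf,
                    support_rev=srr,
                )
                if vtype == "MNP":
                    snps = decompose_mnp(call)
                    decomposed += 1
                    calls.extend(snps)
                else:
                    calls.append(call)
    if skipped:
        logger.warning("%s: skipped %d malformed/ALT-less records", vcf_path, skipped)
    if decomposed:
        logger.info("%s: decomposed %d MNP records into SNPs", vcf_path, decomposed)
    if not calls:
        logger.warning("%s: no usable variant records", vcf_path)
    return calls


#: rejection reasons, in the order rules are checked
REASON_AF = "low_allele_frequency"
REASON_SUPPORT = "low_support"
REASON_STRAND = "single_strand"
REASON_SV_SUPPORT = "low_sv_support"


def filter_variants(
    calls: list[VariantCall], policy: FilterPolicy = FilterPolicy()
) -> tuple[list[VariantCall], list[tuple[VariantCall, str]]]:
    """Apply the retention rules; returns (kept, rejected-with-reason).

    Filtering is total: every input call lands in exactly one output, and
    each rejection carries the first failing rule in documented order
    (AF, support, strand, SV support).
    """
    kept: list[VariantCall] = []
    rejected: list[tuple[VariantCall, str]] = []
    for c in calls:
        if c.vtype == "SV":
            if c.support_total >= policy.sv_min_support:
                kept.append(c)
            else:
                rejected.append((c, REASON_SV_SUPPORT))
            continue
        if c.allele_frequency <= policy.min_af:
            rejected.append((c, REASON_AF))
        elif c.support_total <= policy.min_support:
            rejected.append((c, REASON_SUPPORT))
        elif (
            (c.vtype == "INDEL" and policy.indel_strand_rule)
            or (c.vtype == "SNP" and policy.snp_strand_rule)
        ) and (c.support_fwd < 1 or c.support_rev < 1):
            rejected.append((c, REASON_STRAND))
        else:
            kept.append(c)
    return kept, rejected


def genomes_passing(
    kept_calls: list[VariantCall], policy: FilterPolicy = FilterPolicy()
) -> set[str]:
    """Genomes with at least ``min_snps_per_genome`` kept SNPs (cohort-wide)."""
    counts: dict[str, int] = {}
    for c in kept_calls:
        if c.vtype == "SNP":
            counts[c.genome_id] = counts.get(c.genome_id, 0) + 1
    return {g for g, n in counts.items() if n >= policy.min_snps_per_genome}


def _validate_regions(marker_regions: dict[str, list[tuple[int, int]]]) -> None:
    for genome, intervals in marker_regions.items():
        prev_end = 0
        for start, end in sorted(intervals):
            if start < 1 or end < start:
                raise ValueError(f"{genome}: invalid marker interval ({start}, {end})")
            if start <= prev_end:
                raise ValueError(f"{genome}: overlapping marker intervals")
            prev_end = end


def estimate_false_positive_rate(
    kept_calls: list[VariantCall],
    marker_regions: dict[str, list[tuple[int, int]]],
    truth_keys: set[tuple],
) -> float | None:
    """Truth-based FP rate over single-copy marker-gene regions.

    ``truth_keys`` holds (sample_id, genome_id, pos, ref, alt) tuples of the
    planted true variants.  The rate is the fraction of kept calls falling
    inside marker regions that are absent from the truth.  Returns None
    (with a warning) when no kept call lies in a marker region.
    """
    _validate_regions(marker_regions)
    in_marker = 0
    false_in_marker = 0
    for c in kept_calls:
        intervals = marker_regions.get(c.genome_id)
        if not intervals:
            continue
        if not any(s <= c.pos <= e for s, e in intervals):
            continue
        in_marker += 1
        key = (c.sample_id, c.genome_id, c.pos, c.ref_allele, c.alt_allele)
        if key not in truth_keys:
            false_in_marker += 1
    if in_marker == 0:
        warnings.warn("no kept calls inside marker regions; FP rate undefined")
        return None
    return false_in_marker / in_marker


def write_vcf(
    calls: list[VariantCall],
    path: str | Path,
    contig_lengths: dict[str, int],
) -> None:
    """Write calls as an uncompressed VCF 4.2 with AF/DP/SRF/SRR INFO keys."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=microvarsig",
    ]
    for cid, ln in sorted(contig_lengths.items()):
        lines.append(f"##contig=<ID={cid},length={ln}>")
    lines += [
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Supporting read depth">',
        '##INFO=<ID=SRF,Number=1,Type=Integer,Description="Supporting reads, forward strand">',
        '##INFO=<ID=SRR,Number=1,Type=Integer,Description="Supporting reads, reverse strand">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in sorted(calls, key=lambda v: (v.contig_id, v.pos, v.alt_allele)):
        info = (
            f"AF={c.allele_frequency:.6f};DP={c.support_total};"
            f"SRF={c.support_fwd};SRR={c.support_rev}"
        )
        lines.append(
            f"{c.contig_id}\t{c.pos}\t.\t{c.ref_allele}\t{c.alt_allele}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
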