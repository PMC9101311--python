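"""Variant classification, filtering rules, and FP-rate bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from microvarsig.variants import (
    REASON_AF,
    REASON_STRAND,
    REASON_SUPPORT,
    REASON_SV_SUPPORT,
    FilterPolicy,
    VariantCall,
    classify_variant,
    decompose_mnp,
    estimate_false_positive_rate,
    filter_variants,
    genomes_passing,
    read_variant_calls,
    write_vcf,
)


def make_call(**kw):
    base = dict(
        sample_id="S1", genome_id="g1", contig_id="g1", pos=100,
        ref_allele="C", alt_allele="T", vtype="SNP",
        allele_frequency=0.1, support_total=20, support_fwd=11, support_rev=9,
    )
    base.update(kw)
    return VariantCall(**base)


class TestClassification:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("C", "T", "SNP"),
            ("A", "A" + "C" * 50, "INDEL"),  # 50 bp insertion: inclusive edge
            ("A", "A" + "C" * 51, "SV"),  # 51 bp insertion
            ("A" + "G" * 50, "A", "INDEL"),
            ("A" + "G" * 60, "A", "SV"),
            ("AC", "GT", "MNP"),
        ],
    )
    def test_size_boundaries(self, ref, alt, expected):
        assert classify_variant(ref, alt) == expected

    def test_invalid_alleles(self):
        with pytest.raises(ValueError):
            classify_variant("", "A")
        with pytest.raises(ValueError):
            classify_variant("AN", "AT")

    def test_mnp_decomposition(self):
        call = make_call(ref_allele="ACG", alt_allele="ATG", vtype="MNP")
        snps = decompose_mnp(call)
        assert len(snps) == 1
        assert snps[0].pos == 101 and snps[0].ref_allele == "C" and snps[0].alt_allele == "T"


class TestFilterRules:
    def test_low_af_rejected_even_with_support(self):
        kept, rejected = filter_variants([make_call(allele_frequency=0.005)])
        assert not kept and rejected[0][1] == REASON_AF

    def test_support_rule_is_strict(self):
        # "more than five reads": exactly 5 fails, 6 passes
        kept, rej = filter_variants(
            [make_call(support_total=5, support_fwd=3, support_rev=2)]
        )
        assert rej[0][1] == REASON_SUPPORT
        kept, rej = filter_variants(
            [make_call(support_total=6, support_fwd=3, support_rev=3)]
        )
        assert kept and not rej

    def test_af_rule_is_strict_at_boundary(self):
        kept, rej = filter_variants([make_call(allele_frequency=0.01)])
        assert rej[0][1] == REASON_AF

    def test_indel_single_strand_rejected(self):
        call = make_call(
            ref_allele="A", alt_allele="ACCT", vtype="INDEL",
            support_total=8, support_fwd=8, support_rev=0,
        )
        kept, rej = filter_variants([call])
        assert rej[0][1] == REASON_STRAND
        kept, rej = filter_variants([call], FilterPolicy(indel_strand_rule=False))
        assert kept

    def test_sv_uses_support_three(self):
        sv = make_call(
            ref_allele="A", alt_allele="A" + "C" * 60, vtype="SV",
            support_total=3, support_fwd=3, support_rev=0,
        )
        kept, rej = filter_variants([sv])
        assert kept  # >= 3 is inclusive; no strand/AF rule for SVs
        sv2 = make_call(
            ref_allele="A", alt_allele="A" + "C" * 60, vtype="SV",
            support_total=2, support_fwd=2, support_rev=0,
        )
        kept, rej = filter_variants([sv2])
        assert rej[0][1] == REASON_SV_SUPPORT

    def test_partition_and_idempotence(self, small_cohort):
        calls = [c for v in small_cohort[0].values() for c in v]
        kept, rejected = filter_variants(calls)
        assert len(kept) + len(rejected) == len(calls)
        kept2, rejected2 = filter_variants(kept)
        assert kept2 == kept and not rejected2

    @given(
        min_af=st.floats(0.0, 0.2),
        min_support=st.integers(0, 40),
        seed=st.integers(0, 10),
    )
    def test_tightening_never_grows_kept_set(self, min_af, min_support, seed):
        rng = np.random.default_rng(seed)
        calls = []
        for i in range(60):
            total = int(rng.integers(1, 40))
            fwd = int(rng.integers(0, total + 1))
            calls.append(
                make_call(
                    pos=i + 1,
                    allele_frequency=float(rng.uniform(0, 0.3)),
                    support_total=total, support_fwd=fwd, support_rev=total - fwd,
                )
            )
        base_kept, _ = filter_variants(calls)
        tight, _ = filter_variants(
            calls, FilterPolicy(min_af=0.01 + min_af, min_support=5 + min_support)
        )
        assert set(map(id, tight)) <= set(map(id, base_kept))


class TestGenomeInclusion:
    def test_three_snp_boundary(self):
        calls2 = [make_call(pos=p, genome_id="gA") for p in (1, 2)]
        calls3 = [make_call(pos=p, genome_id="gB") for p in (1, 2, 3)]
        assert genomes_passing(calls2 + calls3) == {"gB"}

    def test_empty(self):
        assert genomes_passing([]) == set()

    def test_indels_do_not_count(self):
        indels = [
            make_call(pos=p, ref_allele="A", alt_allele="AT", vtype="INDEL")
            for p in (1, 2, 3)
        ]
        assert genomes_passing(indels) == set()


class TestFalsePositiveRate:
    regions = {"g1": [(50, 150)]}

    def test_rate_from_formula(self):
        truth = {("S1", "g1", p, "C", "T") for p in range(50, 146)}
        calls = [make_call(pos=p) for p in range(50, 150)]  # 4 not in truth
        assert estimate_false_positive_rate(calls, self.regions, truth) == pytest.approx(0.04)

    def test_truth_complete_run_is_zero(self):
        calls = [make_call(pos=p) for p in (60, 70)]
        truth = {("S1", "g1", 60, "C", "T"), ("S1", "g1", 70, "C", "T")}
        assert estimate_false_positive_rate(calls, self.regions, truth) == 0.0

    def test_no_marker_calls_undefined(self):
        with pytest.warns(UserWarning):
            rate = estimate_false_positive_rate(
                [make_call(pos=500)], self.regions, set()
            )
        assert rate is None

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError):
            estimate_false_positive_rate(
                [], {"g1": [(10, 50), (40, 80)]}, set()
            )


class TestVcfRoundTrip:
    def test_write_then_read_preserves_calls(self, tmp_path):
        calls = [
            make_call(pos=10),
            make_call(pos=20, ref_allele="A", alt_allele="ACT", vtype="INDEL",
                      support_total=9, support_fwd=5, support_rev=4),
        ]
        path = tmp_path / "s.vcf"
        write_vcf(calls, path, {"g1": 1000})
        back = read_variant_calls(path, sample_id="S1")
        assert len(back) == 2
        assert back[0].pos == 10 and back[0].vtype == "SNP"
        assert back[1].vtype == "INDEL"
        assert back[0].allele_frequency == pytest.approx(0.1, abs=1e-5)
        assert back[1].support_fwd == 5 and back[1].support_rev == 4

    def test_multiallelic_split_and_mnp(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=g1,length=1000>\n'
            '##INFO=<ID=AF,Number=A,Type=Float,Description="af">\n'
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            '##INFO=<ID=SRF,Number=1,Type=Integer,Description="srf">\n'
            '##INFO=<ID=SRR,Number=1,Type=Integer,Description="srr">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "g1\t5\t.\tC\tT,G\t.\tPASS\tAF=0.2,0.1;DP=30;SRF=16;SRR=14\n"
            "g1\t50\t.\tAC\tGT\t.\tPASS\tAF=0.3;DP=30;SRF=15;SRR=15\n"
        )
        calls = read_variant_calls(vcf, sample_id="S1")
        snvs = [c for c in calls if c.pos == 5]
        assert len(snvs) == 2 and {c.alt_allele for c in snvs} == {"T", "G"}
        mnp_snps = [c for c in calls if c.pos in (50, 51)]
        assert len(mnp_snps) == 2 and all(c.vtype == "SNP" for c in mnp_snps)

    def test_missing_af_falls_back_to_ad(self, tmp_path):
        vcf = tmp_path / "ad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=g1,length=1000>\n'
            '##INFO=<ID=AD,Number=R,Type=Integer,Description="ad">\n'
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "g1\t5\t.\tC\tT\t.\tPASS\tAD=90,10;DP=100\n"
        )
        calls = read_variant_calls(vcf, sample_id="S1")
        assert calls[0].allele_frequency == pytest.approx(0.1)

    def test_missing_af_and_ad_is_hard_error(self, tmp_path):
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=g1,length=1000>\n'
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "g1\t5\t.\tC\tT\t.\tPASS\tDP=100\n"
        )
        with pytest.raises(ValueError, match="g1:5"):
            read_variant_calls(vcf, sample_id="S1")

    def test_empty_vcf_gives_empty_list(self, tmp_path):
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=g1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        assert read_variant_calls(vcf, sample_id="S1") == []


def test_strand_support_consistency_enforced():
    with pytest.raises(ValueError):
        make_call(support_total=10, support_fwd=4, support_rev=4)
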