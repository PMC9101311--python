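"""Synthetic-data generators: determinism, planted truth, recovery bounds."""

import numpy as np
import pytest
from Bio.Seq import Seq

from microvarsig.codon import decode_codons
from microvarsig.simulate import (
    ClusterPlan,
    GroupSpec,
    SimConfig,
    SimTruth,
    draw_alt_codes,
    evolve_family_codes,
    simulate_codon_families,
    simulate_genomes,
    simulate_identity_matrix,
    simulate_variant_sets,
    write_fasta,
    write_gff3,
)
from microvarsig.simulate.config import ConfigurationError, SizingError
from microvarsig.spectrum import SUBSTITUTION_TYPES
from microvarsig.variants import filter_variants, write_vcf, read_variant_calls


def tiny_config(**kw):
    base = dict(
        seed=1,
        n_genomes=3,
        genome_length=50_000,
        n_genes_per_genome=40,
        n_marker_genes=40,
        groups=[GroupSpec("A", "day0", 2), GroupSpec("A", "day30", 2)],
        cluster_plan=ClusterPlan(sizes=[2, 1]),
        omega_map={"K00001": 0.1},
        n_codons_per_family=40,
        n_seqs_per_family=4,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenomes:
    def test_byte_identical_outputs_under_fixed_seed(self, tmp_path):
        cfg = tiny_config()
        for run in ("a", "b"):
            genomes = simulate_genomes(cfg)
            write_fasta(genomes, tmp_path / f"{run}.fna")
            write_gff3(genomes, tmp_path / f"{run}.gff3")
        assert (tmp_path / "a.fna").read_bytes() == (tmp_path / "b.fna").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_exactly_forty_marker_genes_per_genome(self):
        for g in simulate_genomes(tiny_config()):
            markers = [x for x in g.genes if x.marker_id]
            assert len(markers) == 40
            assert {m.marker_id for m in markers} == {f"M{i:02d}" for i in range(1, 41)}

    def test_gene_models_well_formed(self):
        for g in simulate_genomes(tiny_config()):
            prev_end = 0
            for gene in sorted(g.genes, key=lambda x: x.start):
                assert gene.start > prev_end  # non-overlapping
                assert gene.length % 3 == 0
                assert 1 <= gene.start <= gene.end <= g.length
                assert gene.strand in "+-"
                prev_end = gene.end

    def test_gc_content_recovered_at_one_megabase(self):
        cfg = tiny_config(n_genomes=1, genome_length=1_000_000,
                          n_genes_per_genome=10, n_marker_genes=10,
                          cluster_plan=ClusterPlan(sizes=[1]))
        (g,) = simulate_genomes(cfg)
        gc = (g.seq.count("G") + g.seq.count("C")) / g.length
        assert abs(gc - 0.5) < 0.01  # +-6 sigma binomial bound

    def test_too_short_genome_raises_sizing_error(self):
        with pytest.raises(SizingError):
            tiny_config(genome_length=5_000).validate()


class TestVariantSets:
    def test_ref_allele_matches_genome_for_every_call(self, small_config, small_genomes, small_cohort):
        calls, truth, meta = small_cohort
        seq = {g.genome_id: g.seq for g in small_genomes}
        for cc in calls.values():
            for c in cc:
                assert seq[c.genome_id][c.pos - 1 : c.pos - 1 + len(c.ref_allele)] == c.ref_allele

    def test_truth_spectra_match_vcf_retally(self, small_genomes, small_cohort, tmp_path):
        calls, truth, meta = small_cohort
        lengths = {g.genome_id: g.length for g in small_genomes}
        sid = sorted(calls)[0]
        write_vcf(calls[sid], tmp_path / "s.vcf", lengths)
        back = read_variant_calls(tmp_path / "s.vcf", sample_id=sid)
        tally = np.zeros(12, dtype=int)
        for c in back:
            if c.vtype == "SNP":
                tally[SUBSTITUTION_TYPES.index(f"{c.ref_allele}>{c.alt_allele}")] += 1
        assert tally.tolist() == truth.planted_spectra[sid]

    def test_filter_bookkeeping_exact(self, small_cohort):
        calls, truth, meta = small_cohort
        for sid, cc in calls.items():
            kept, rejected = filter_variants(cc)
            book = truth.filter_expectations[sid]
            assert len(kept) == book["kept"]
            reasons = {}
            for _, r in rejected:
                reasons[r] = reasons.get(r, 0) + 1
            assert reasons.get("low_allele_frequency", 0) == book["rejected_low_af"]
            assert reasons.get("low_support", 0) == book["rejected_low_support"]
            assert reasons.get("single_strand", 0) == book["rejected_single_strand"]
            assert reasons.get("low_sv_support", 0) == book["rejected_low_sv_support"]

    def test_planted_low_af_calls_all_fail_filter(self, small_cohort):
        calls, truth, meta = small_cohort
        low_af = {
            (v["sample_id"], v["genome_id"], v["pos"])
            for v in truth.true_variants
            if v["violates"] == "low_af"
        }
        assert low_af  # the fixture plants some
        for cc in calls.values():
            kept, _ = filter_variants(cc)
            for c in kept:
                assert (c.sample_id, c.genome_id, c.pos) not in low_af

    def test_determinism(self, small_config, small_genomes):
        a = simulate_variant_sets(small_genomes, small_config)
        b = simulate_variant_sets(small_genomes, small_config)
        assert a[0] == b[0]
        assert a[1].planted_spectra == b[1].planted_spectra

    def test_uniform_weights_realised_shares(self, rng):
        """10,000 draws at uniform weights: every type within 1/12 +- 0.01."""
        ref = rng.choice(4, size=10_000)
        _, tidx = draw_alt_codes(ref, [1.0] * 12, rng)
        shares = np.bincount(tidx, minlength=12) / 10_000
        assert np.all(np.abs(shares - 1 / 12) < 0.01)

    def test_spectrum_recovery_l1(self, rng):
        """Planted vs realised type frequencies: L1 <= 0.03 at >= 5k SNPs."""
        n = 20_000
        weights = np.arange(1.0, 13.0)
        base_p = np.full(4, 0.25)
        ref = rng.choice(4, size=n, p=base_p)
        _, tidx = draw_alt_codes(ref, weights.tolist(), rng)
        realised = np.bincount(tidx, minlength=12) / n
        planted = np.zeros(12)
        for r in range(4):
            w = weights[3 * r : 3 * r + 3]
            planted[3 * r : 3 * r + 3] = base_p[r] * w / w.sum()
        assert np.abs(realised - planted).sum() <= 0.03

    def test_all_zero_weights_for_base_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            draw_alt_codes(np.array([0]), [0.0, 0.0, 0.0] + [1.0] * 9, rng)

    def test_planted_transversion_shift_direction(self, small_genomes):
        """x1.5 transversion weights on day 30 force a lower Ts/Tv."""
        from microvarsig.simulate.config import default_spectrum_weights, scale_transversions

        base = default_spectrum_weights()
        cfg = tiny_config(
            spectrum_weights={
                "default": base,
                "A:day30": scale_transversions(base, 1.5),
            },
            snp_rate=10.0,
        )
        genomes = simulate_genomes(cfg)
        calls, truth, meta = simulate_variant_sets(genomes, cfg)
        ts_idx = [SUBSTITUTION_TYPES.index(t) for t in ("A>G", "G>A", "C>T", "T>C")]
        ratios = {}
        for r in meta.itertuples(index=False):
            counts = np.array(truth.planted_spectra[r.sample_id])
            ts = counts[ts_idx].sum()
            ratios.setdefault(r.timepoint, []).append(ts / (counts.sum() - ts))
        assert np.mean(ratios["day30"]) < np.mean(ratios["day0"])


class TestCodonFamilies:
    def test_omega_zero_preserves_protein(self, rng):
        codes = evolve_family_codes(rng, 8, 100, omega=0.0, mu=0.5)
        proteins = {
            str(Seq(decode_codons(c)).translate(table=11)) for c in codes
        }
        assert len(proteins) == 1
        # sequences did diverge synonymously
        assert len({decode_codons(c) for c in codes}) > 1

    def test_no_stop_codons_ever(self, rng):
        codes = evolve_family_codes(rng, 10, 200, omega=2.0, mu=0.6)
        assert (codes >= 0).all()
        for c in codes:
            assert "*" not in str(Seq(decode_codons(c)).translate(table=11))

    def test_negative_omega_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            evolve_family_codes(rng, 2, 10, omega=-0.5)

    def test_family_dict_and_true_omega(self):
        cfg = tiny_config(omega_map={"K00001": 0.1, "K00002": 5.0})
        fams, true_omega = simulate_codon_families(cfg)
        assert set(fams) == {"K00001", "K00002"}
        assert true_omega["K00002"] == 5.0
        aln = fams["K00001"]
        assert aln.n_sequences == cfg.n_seqs_per_family
        assert aln.n_codons == cfg.n_codons_per_family

    def test_gap_injection_codon_aligned(self):
        cfg = tiny_config(gap_fraction=0.1)
        fams, _ = simulate_codon_families(cfg)
        seq = fams["K00001"].sequences[0]
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            assert codon == "---" or "-" not in codon


class TestIdentityMatrix:
    def test_planted_partition_matches_plan(self):
        cfg = tiny_config()
        table, planted = simulate_identity_matrix(cfg)
        assert [len(c) for c in planted] == [2, 1]
        assert len(table) == 3 * cfg.n_marker_genes  # 3 unordered pairs

    def test_single_genome_single_cluster(self):
        cfg = tiny_config(n_genomes=1, cluster_plan=ClusterPlan(sizes=[1]))
        table, planted = simulate_identity_matrix(cfg)
        assert planted == [["g0001"]] and table.empty

    def test_identity_values_within_planted_ranges(self):
        cfg = tiny_config()
        table, planted = simulate_identity_matrix(cfg)
        member = {g: i for i, c in enumerate(planted) for g in c}
        for row in table.itertuples(index=False):
            lo, hi = (
                cfg.cluster_plan.within
                if member[row.genome_a] == member[row.genome_b]
                else cfg.cluster_plan.between
            )
            assert lo <= row.identity_pct <= hi


class TestConfigValidation:
    def test_equal_ranges_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(
                cluster_plan=ClusterPlan(sizes=[2, 1], within=(90, 96), between=(90, 96))
            ).validate()

    def test_duplicate_group_labels_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(
                groups=[GroupSpec("A", "day0", 2), GroupSpec("A", "day0", 3)]
            ).validate()

    def test_negative_omega_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(omega_map={"K1": -1.0}).validate()

    def test_yaml_roundtrip(self, tmp_path):
        cfg = tiny_config()
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimConfig.from_yaml(tmp_path / "c.yaml")
        assert back.to_dict() == cfg.to_dict()
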