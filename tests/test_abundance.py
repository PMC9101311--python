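"""Gene abundance normalisation, SNP density, and exact-test oracles."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from microvarsig.abundance import (
    gene_abundance,
    ko_enrichment,
    paired_density_test,
    snp_density,
    wilcoxon_signed_rank,
)


class TestAbundance:
    def test_formula_example(self):
        counts = pd.DataFrame({"s1": [10, 30]}, index=["gA", "gB"])
        lengths = pd.Series([1000, 3000], index=["gA", "gB"])
        rng_tab = gene_abundance(counts, lengths)
        assert rng_tab["s1"].tolist() == pytest.approx([0.5, 0.5])

    def test_single_gene_is_one(self):
        out = gene_abundance(
            pd.DataFrame({"s1": [7]}, index=["g"]), pd.Series([500], index=["g"])
        )
        assert out.loc["g", "s1"] == 1.0

    def test_sums_to_one_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.poisson(20, size=(30, 4)),
            index=[f"g{i}" for i in range(30)],
            columns=list("abcd"),
        )
        lengths = pd.Series(rng.integers(200, 2000, 30), index=counts.index)
        out = gene_abundance(counts, lengths)
        assert np.allclose(out.sum(axis=0), 1.0, atol=1e-9)
        scaled = gene_abundance(counts * 17, lengths)
        pd.testing.assert_frame_equal(out, scaled)

    def test_all_zero_sample_flagged_nan(self, caplog):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
        out = gene_abundance(counts, pd.Series([100, 100], index=["a", "b"]))
        assert out["s1"].isna().all()

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            gene_abundance(
                pd.DataFrame({"s1": [1]}, index=["a"]), pd.Series([0], index=["a"])
            )


class TestDensity:
    genes = pd.DataFrame({"length_bp": [2000]}, index=["gA"])

    def _run(self, depth):
        sc = pd.DataFrame({"s1": [4]}, index=["gA"])
        dp = pd.DataFrame({"s1": [depth]}, index=["gA"])
        return snp_density(self.genes, sc, dp).iloc[0]

    def test_density_value_and_inclusion(self):
        row = self._run(30)
        assert row["density_per_kb"] == pytest.approx(2.0) and row["included"]

    def test_depth_nine_excluded_ten_included(self):
        assert not self._run(9)["included"]
        assert self._run(10)["included"]  # boundary inclusive

    def test_density_monotone_in_count(self):
        sc = pd.DataFrame({"s1": [2], "s2": [8]}, index=["gA"])
        dp = pd.DataFrame({"s1": [30], "s2": [30]}, index=["gA"])
        out = snp_density(self.genes, sc, dp)
        d = out.set_index("sample_id")["density_per_kb"]
        assert d["s2"] > d["s1"]


def wilcoxon_oracle(diffs):
    """Full sign-assignment enumeration (no ties, n <= 12)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.empty(n)
    order = np.argsort(np.abs(d))
    ranks[order] = np.arange(1, n + 1)
    w_obs = ranks[d > 0].sum()
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(sum(r for s, r in zip(signs, ranks) if s))
    dist = np.array(dist)
    p_low = (dist <= w_obs).mean()
    p_high = (dist >= w_obs).mean()
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_three_positive_differences(self):
        w, p, n = wilcoxon_signed_rank([1, 2, 3])
        assert p == pytest.approx(0.25)  # 2/8 sign assignments as extreme

    def test_all_zero_flagged(self):
        w, p, n = wilcoxon_signed_rank([0.0, 0.0])
        assert p == 1.0 and n == 0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for trial in range(25):
            n = int(rng.integers(4, 13))
            d = rng.normal(0.3, 1.0, n)
            _, p, _ = wilcoxon_signed_rank(d)
            assert p == pytest.approx(wilcoxon_oracle(d), rel=1e-12), d


class TestPairedDensityTest:
    def test_zero_difference_genes_flagged_p1(self):
        d0 = pd.DataFrame({"p1": [1.0], "p2": [1.0], "p3": [1.0]}, index=["g"])
        res = paired_density_test(d0, d0.copy())
        assert res.loc[0, "p_value"] == 1.0

    def test_planted_density_shift_power(self):
        """10 of 200 genes with 3x day-30 SNP density, 20 subjects:
        at least 8 of the 10 recovered at raw p < 0.05 in >= 9/10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            base = rng.poisson(5.0, size=(200, 20)).astype(float)
            day30 = rng.poisson(5.0, size=(200, 20)).astype(float)
            day30[:10] = rng.poisson(15.0, size=(10, 20))
            cols = [f"p{i}" for i in range(20)]
            idx = [f"g{i}" for i in range(200)]
            res = paired_density_test(
                pd.DataFrame(base, index=idx, columns=cols),
                pd.DataFrame(day30, index=idx, columns=cols),
            )
            sig = set(res.loc[res["p_value"] < 0.05, "gene_id"])
            if len(sig & {f"g{i}" for i in range(10)}) >= 8:
                hits += 1
        assert hits >= 9

    def test_nan_pairs_dropped(self):
        d0 = pd.DataFrame({"p1": [1.0], "p2": [np.nan], "p3": [2.0], "p4": [1.5]},
                          index=["g"])
        d30 = d0 + 1.0
        res = paired_density_test(d0, d30)
        assert res.loc[0, "n_pairs"] == 3


def hypergeom_tail(k, N, K, n):
    return float(
        sum(
            Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
            for x in range(k, min(K, n) + 1)
        )
    )


class TestEnrichment:
    def _map(self, assignments):
        return pd.DataFrame(
            [(ko, pw) for ko, pw in assignments], columns=["ko_id", "pathway_id"]
        )

    def test_matches_exact_tail(self):
        background = {f"K{i}" for i in range(100)}
        pathway = self._map([(f"K{i}", "P1") for i in range(10)])
        significant = {f"K{i}" for i in range(5)} | {f"K{i}" for i in range(50, 65)}
        res = ko_enrichment(significant, background, pathway)
        assert res.loc[0, "p_value"] == pytest.approx(
            hypergeom_tail(5, 100, 10, 20), rel=1e-12
        )

    def test_significant_equals_background_gives_p1(self):
        background = {f"K{i}" for i in range(20)}
        pathway = self._map([(f"K{i}", "P1") for i in range(4)])
        res = ko_enrichment(set(background), background, pathway)
        assert res["p_value"].tolist() == [1.0]

    def test_fully_hit_small_pathway(self):
        background = {f"K{i}" for i in range(50)}
        pathway = self._map([("K0", "P1"), ("K1", "P1"), ("K2", "P1")])
        significant = {"K0", "K1", "K2"}
        res = ko_enrichment(significant, background, pathway)
        assert res.loc[0, "p_value"] == pytest.approx(
            hypergeom_tail(3, 50, 3, 3), rel=1e-12
        )

    def test_not_subset_rejected(self):
        with pytest.raises(ValueError):
            ko_enrichment({"X"}, {"Y"}, self._map([("Y", "P1")]))
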