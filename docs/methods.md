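# Methods

This note documents the models and procedures implemented in
`microvarsig`, the choices made where the design was genuinely open, and
what the synthetic-data validation does and does not establish.

## Reference dereplication by marker-gene ANI proxy

Whole-genome ANI is approximated by the median, over shared single-copy
marker genes, of per-marker percent identities (`derep.compute_ani_proxy`).
The median is robust to a few aberrant markers; pairs sharing no marker
have an undefined proxy and are conservatively treated as below threshold
(they contribute no clustering edge).

Clustering at the operational 95% species threshold is **single linkage**
— connected components of the graph with an edge wherever the proxy meets
the threshold.  Rationale: a flat partition obtained from a bare threshold
admits several agglomeration rules; single linkage is the only one that is
invariant to input order and needs no merge schedule, and it has the clean
monotonicity property that raising the threshold can only split clusters.
Complete linkage is available (`linkage="complete"`) for sensitivity
analysis.  Representatives are the highest-coverage member per cluster,
ties broken by lexicographically smallest genome id for determinism.

The package consumes per-marker identity tables; computing identities
(e.g. with BLASTn) is out of scope.  A k-mer Jaccard estimator
(`derep.kmer_identity`) is provided for synthetic genomes only and is
clearly not an alignment identity.

## Variant classification and filtering

Variants are classified by allele-length difference *d*: *d* = 0 with
single bases → SNP; 1 ≤ *d* ≤ 50 → InDel (inclusive at 50); *d* > 50 →
structural variant.  Equal-length multi-base substitutions (MNPs) are
decomposed into per-base SNPs at read time (the spectrum needs
single-nucleotide events); decomposition is logged.

Retention rules (all in the `study_defaults` config block):

| rule | default | boundary |
|---|---|---|
| allele frequency | > 0.01 | strict ("larger than 1%") |
| read support (SNP/InDel) | > 5 reads | strict ("more than five reads") |
| InDel strand rule | ≥ 1 read per strand | on by default, SNP variant optional |
| SV support | ≥ 3 reads | inclusive |
| genome inclusion | ≥ 3 kept SNPs | inclusive, cohort-wide |

Rejections carry the first failing rule in the documented order (AF,
support, strand, SV support), so bookkeeping against planted truth is
exact.  Genome inclusion is evaluated cohort-wide by default (a per-sample
evaluation is a caller-side variation); the upstream calling chain
(realignment, haplotype calling, SV breakpointing) is treated as
authoritative input.

The false-positive-rate estimator is defined against simulation truth:
the fraction of kept calls inside single-copy marker-gene regions that are
absent from the planted truth.  With no kept marker-region calls the rate
is undefined (None), never silently 0.  On real data the corresponding
quantity requires an invariant-site assumption that this package does not
supply.

## Substitution spectra and shift tests

Spectra use the 12 ordered ref>alt classes without reverse-complement
collapsing (a 6-class collapsed view is available for comparison with the
wider literature).  The per-kilobase denominator is the total length of
the genomes passing the ≥ 3-SNP inclusion rule for the sample set under
analysis; this choice is recorded in output metadata.  An alternative —
restricting to positions above a stated depth — is supported when a depth
track is supplied.

Group shifts are tested per metric (transition rate, transversion rate,
Ts/Tv, or any single type rate) with the classic pooled-variance
two-sample Student t-test; Welch is one flag away.  Comparisons are
unpaired by default with a paired option.  All metric × comparison tests
emitted in one batch form a single Benjamini–Hochberg family; the family
definition matters and is therefore fixed and visible.  Degenerate inputs
are given explicit values rather than NaNs: identical constant sides give
t = 0, p = 1; constant sides with different means give p = 0.  Ts/Tv with
zero transversions is reported as undefined (flagged), not infinity.

## Abundance, SNP density, and enrichment

Relative gene abundance follows the RPKM-like formula RNG_i = NG_i / Σ_j
NG_j with NG_i = reads_i / length_i; RNG sums to 1 per sample by
construction (all-zero samples are flagged undefined, not silently 0) and
is invariant under uniform count rescaling.

SNP density is kept-SNP count per gene kilobase, computed only where the
gene's depth is ≥ 10× in that sample (inclusive boundary; mean depth over
the gene span by default, median optional).  Paired day 0/day 30 densities
per subject are compared per gene with the two-sided Wilcoxon signed-rank
test: zero differences dropped before ranking (Wilcoxon's original
treatment; Pratt-style handling is a documented alternative), midranks for
ties, the exact null distribution for n ≤ 25 when absolute differences are
tie-free, and the continuity-corrected normal approximation otherwise.
BH adjustment runs across genes; the enrichment step uses the raw p < 0.05
gene set (mirroring how such gene lists are typically carried forward)
against the full KO background with an upper-tail hypergeometric test per
pathway, BH across pathways.

## Dn/Ds selection scan

Codon counting is tree-free, NG86-style, on translation table 11
(bacteria/archaea):

- **Sites** (`count_sites`): each of a codon's 9 single-nucleotide
  neighbours is classified synonymous/nonsynonymous by translation; stop
  neighbours are excluded from the denominator; s = 3 × (synonymous
  fraction), n = 3 − s.
- **Changes** (`count_codon_changes`): all orderings of the differing
  positions (≤ 3! = 6) are enumerated, each single-nucleotide step is
  classified by translation, orderings passing through a stop codon are
  discarded, and (dn, ds) is the average over survivors; dn + ds equals
  the nucleotide distance exactly.  In table 11 no codon pair loses all
  its orderings, but the exclusion logic is exercised and pairs that
  would lose all paths are dropped and counted.
- **Families** (`family_counts`): changes are summed over all unordered
  sequence pairs and codon columns gap-free in both members (gapped
  columns are skipped pairwise, the in-repo surrogate for discarding
  low-confidence alignment columns); site totals are the per-column mean
  over usable codons, summed over columns; ω = (Dn/N)/(Ds/S), undefined
  (flagged) when Ds = 0.

These are pairwise counting estimates, deliberately labelled NG86-style;
maximum-likelihood codon models, branch/site models and tree inference
are out of scope.

**Fisher screen.**  Each family's (Dn, Ds) is tested one-sided (greater)
against the summed background of all *other* families (leave-one-out by
default — including the focal family dilutes its own signal; `all` is
available), with BH FDR at α = 5%.  Two numerical points matter:

1. *Count scale.*  Summed pairwise counts replicate every underlying
   mutation across roughly n − 1 sequence pairs.  Feeding those inflated
   sums to an exact test that assumes independent events makes it wildly
   anticonservative (in neutral simulations at 20 sequences it flagged
   ~28% of families).  `analyze_families` therefore divides each family's
   summed counts by its number of pairs before the exact test
   (`count_scale="per_pair"`), which is on (a conservative lower bound
   of) the scale of independent change events; measured neutral
   false-flag rates are then ≈ 0 while planted ω = 5 families remain
   detected in 100% of sweeps.  Raw sums are always preserved in the
   output and available to the test via `count_scale="total"`.
2. *Rounding.*  Fractional path-averaged counts are rounded
   half-away-from-zero to integers only for the exact test.

The exact one-sided Fisher p is computed as the upper hypergeometric tail
(mathematically identical); tests verify it against rational-arithmetic
enumeration and against an independent Fisher implementation.  Because
"under positive selection" can reasonably combine the Fisher/FDR flag
with above/below-mean Dn/Ds comparisons, both flags and their conjunction
(`positive_strict`) are reported separately.

## The synthetic-data generator

The generator's defaults encode the emulated study conditions: three drug
groups (5-FU n = 7, 5-FU+Oxi n = 13, Oxi n = 17 subjects) each sampled at
day 0 and day 30; a baseline 12-type spectrum dominated by C>T and G>A; a
×1.5 transversion weight in the Oxi day-30 condition and ×0.7 in the 5-FU
day-30 condition; a background of purifying KO families (ω = 0.1) with
two planted at ω = 5; and six genomes in three planted ANI clusters with
within-cluster identities in [96, 99.5]% and between-cluster in [80, 90]%.

Key mechanisms and defaults:

- **Genomes**: i.i.d. bases at the target GC (0.5), 60 non-overlapping
  CDS genes of 300–900 bp (multiples of 3) per 60 kb genome on random
  strands, exactly 40 marker-flagged genes with matched marker ids across
  genomes.  Coordinates are 1-based inclusive everywhere (VCF/GFF3
  convention) to avoid off-by-one drift.
- **SNVs**: positions uniform without replacement; the reference allele
  is the genome base; the alternate is drawn from the three spectrum
  types with that source base, renormalised — this guarantees reference
  consistency and honours the 12-type target marginally under uniform
  base composition.  3 SNPs/kb/sample (≈ 1,080 per sample over 360 kb).
- **Allele frequency**: floor + (1 − floor)·Beta(0.8, 4) with floor 0.02.
  The Beta shape is a stand-in — the AF distribution of real metagenome
  calls is not modelled here — the floor simply keeps clean calls above
  the 1% filter so that bookkeeping is exact.
- **Read support**: 6 + Poisson(mean − 6) with mean depth 30; strand
  split Binomial(total, 0.5) with both strands forced ≥ 1 for clean
  calls.
- **Planted violations** (disjoint subsets): 5% low-AF SNPs (< 1%), 5%
  low-support SNPs (≤ 5 reads), 20% single-strand InDels, 20%
  low-support SVs — each guaranteed to fail exactly its filter.
- **False calls**: injected uniformly inside marker-gene regions at
  0.1/marker-kb/sample, passing all filters and absent from the truth
  list; with the defaults this yields a marker-region FP rate in the low
  single-digit percent range, the scale reported for real cohorts.
- **Codon families**: sequences descend independently from a stop-free
  random ancestor; proposals (0.3 per codon per sequence, applied in 8
  vectorised Bernoulli rounds) are rejected if they create stops,
  accepted with probability 1 if synonymous and ω if nonsynonymous (for
  ω > 1, probabilities are rescaled by 1/ω — only the ratio matters).
  Gap injection is off by default; when on, gaps are codon-aligned.
- **InDels/SVs**: 0.1 and 0.02 per kb per sample, lengths 1–50 and
  51–150 bp, insertions and deletions equally likely.

Everything is deterministic under a fixed seed, to the byte, including
all written FASTA/GFF3/VCF/TSV/JSON outputs.

One subtlety the generator exposes: under ω = 0 every accepted mutation
is synonymous, so all sequences translate identically — but path-averaged
*pairwise* counting can still attribute fractional nonsynonymous changes
to a pair whose two synonymous derivatives of the ancestor are connected
only through mixed paths (e.g. TTA vs CTC in the leucine block).  The
forced invariant is protein identity, and that is what is tested.

### What the simulation does not emulate

No read-level simulation (no FASTQ, mapping or assembly), no sequencing
error model, no strain mixtures within a species, no linkage between
variants, no gene gain/loss, and uniform — not gene-content-driven —
placement of variants.  Passing tests therefore demonstrate that the
*analysis machinery* is correct and calibrated under the stated
generative model; they do not validate upstream calling accuracy or
guarantee calibration under real-data artefacts such as mapping bias or
batch effects.

## Validation problem sizes

The validation suite uses: all 61 sense codons and 61 × 61 ordered codon
pairs (exact oracle equivalence); 100-seed sweeps of 200 neutral families
at 500 codons × 20 sequences (per-seed median ω within [0.8, 1.25], mean
flagged fraction ≤ 7%); 100-seed power sweeps of 5 families at ω = 5
against 50 background families at ω = 0.1 (200 codons × 10 sequences);
100-seed spectrum sweeps at 20 vs 20 samples with ≈ 1,080 SNPs each
(×1.5 transversion shift detected in ≥ 90%, null any-rejection ≤ 7%);
100 random 12-genome matrices against a brute-force component oracle; and
bit-identity of the full 74-sample demo rerun.

## Known limitations

- The ANI proxy depends on marker-gene choice and is noisier than
  whole-genome ANI; single linkage can chain distinct species through
  intermediates in dense genome sets.
- Per-pair averaging before the Fisher test is conservative; weak
  positive selection (ω modestly above the background) will be missed at
  small family sizes.
- The Wilcoxon exact path requires tie-free absolute differences; with
  heavy ties the normal approximation is used even at small n.
- The spectrum denominator ties rates to the genome-inclusion rule;
  comparing cohorts filtered to different genome sets changes
  denominators and must be done deliberately.
- ω estimates from pairwise counting are biased downward at high
  divergence (multiple hits), visible already at ω = 5 (estimated ≈ 3.8
  in the demo); the positive-selection *flag* is robust to this, the
  point estimate is not an ML estimate.
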