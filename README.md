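# microvarsig

Genomic-variation signatures in gut metagenomes: a tested, reusable
implementation of the analysis framework used to ask how perturbations
(here, chemotherapy drugs such as 5-fluorouracil and oxaliplatin) reshape
the *mutational* landscape of the gut microbiota — not just its taxonomic
composition.  It is aimed at microbiome researchers who want the
variant-level half of such a study as a library: reference dereplication,
variant filtering, substitution spectra, SNP density, and per-family
dN/dS selection scans, all exercised end-to-end on synthetic communities
with planted ground truth.

## What it computes

- **Reference dereplication.** Per genome pair, the median percent
  identity over ~40 universal single-copy marker genes is used as a proxy
  for average nucleotide identity (ANI); genomes are clustered at the
  operational 95% species threshold (single linkage = connected
  components; complete linkage available), and each cluster is
  represented by its highest-read-coverage genome.
- **Variant filtering.** SNPs and short InDels (1–50 bp) are kept with
  allele frequency > 1% and support > 5 reads; InDels additionally need a
  read on each strand; structural variants (> 50 bp) need ≥ 3 supporting
  reads; a genome enters downstream analyses only with ≥ 3 kept SNPs.
- **Substitution spectra.** Kept SNPs are tallied into the 12 ordered
  ref>alt classes per sample, normalised per kilobase of included
  reference; transition/transversion rates and Ts/Tv are compared between
  conditions with Student t-tests, Benjamini–Hochberg adjusted.
- **Abundance and SNP density.** RPKM-like relative gene abundance
  RNG_i = NG_i / Σ_j NG_j with NG_i = reads_i / length_i; per-gene SNP
  densities under a ≥ 10× valid-coverage rule, compared between paired
  timepoints with exact Wilcoxon signed-rank tests; hypergeometric
  KO/pathway enrichment of the shifted genes.
- **Selection scan.** Per KO family, synonymous (Ds) and nonsynonymous
  (Dn) changes are counted over all sequence pairs of a codon alignment
  with NG86-style path averaging (all orderings of the differing codon
  positions, stop-passing paths excluded), sites are counted per codon
  with stop neighbours excluded, ω = (Dn/N)/(Ds/S), and families enriched
  in Dn vs the leave-one-out background are flagged with a one-sided
  Fisher exact test at FDR 5%.
- **Synthetic cohorts.** A first-class simulator generates genomes and
  gene models (FASTA/GFF3), per-sample VCFs drawn from configurable
  12-type spectrum weights with group×timepoint effects, planted filter
  violations and marker-region false calls, planted-cluster identity
  tables, and codon alignments evolved at known dN/dS — with the complete
  ground truth serialised for verification.

## Worked example

Run the bundled demo cohort (74 samples: 7 5-FU, 13 5-FU+Oxi and 17 Oxi
subjects sampled at day 0 and day 30, over six ~60 kb genomes in three
planted species clusters):

```bash
microvarsig run --seed 0 --out-dir results/demo
```

or step by step with the numbered drivers:

```bash
python analysis/01_simulate_community.py --seed 0 --out-dir results/run
python analysis/02_dereplicate.py       --out-dir results/run
python analysis/03_filter_variants.py   --out-dir results/run
python analysis/04_spectrum_shifts.py   --out-dir results/run
python analysis/05_density_abundance.py --out-dir results/run
python analysis/06_selection_scan.py    --out-dir results/run
```

With seed 0 this prints, among other things:

```
3 clusters at 95.0% ANI proxy
planted partition recovered exactly: True
84072 input records -> 75319 kept, 8753 rejected
marker-gene false-positive rate vs truth: 3.39%
```

and the shift tests recover exactly the planted mutational effects — a
transversion-rate *decrease* after 5-FU (t = 11.2 day 0 vs day 30,
adjusted p = 2.2 × 10⁻⁷), an *increase* after oxaliplatin (t = −10.9,
adjusted p = 7.7 × 10⁻¹²), and nothing in the combination group — while
the selection scan flags exactly the two families simulated at ω = 5
(estimated ω ≈ 3.8, q < 10⁻¹²) against the ω = 0.1 background:

```
 ko_id  dn_changes  ds_changes    omega     fisher_p      q_value  positive  true_omega
K10001 1196.833333   99.166667 3.785167 2.041533e-15 4.083066e-14      True         5.0
K10000 1124.333333  115.666667 3.767163 3.738433e-14 3.738433e-13      True         5.0
K10002  147.500000  403.500000 0.109936 9.163150e-01 9.909165e-01     False         0.1
```

Every analysis threshold lives in one `study_defaults` config block
(95% ANI, 1% AF, > 5 reads, ≥ 3 SV reads, ≥ 3 SNPs/genome, ≥ 10× depth,
α = 5%), and the run manifest records the config snapshot, seed and
SHA-256 checksum of every output, so reruns are verifiably bit-identical.

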