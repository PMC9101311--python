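#!/usr/bin/env python
"""Gene abundance, per-gene SNP density, and pathway enrichment.

Computes RPKM-like relative abundances (RNG), per-gene SNP densities with
the >= 10x valid-coverage rule, paired day0/day30 Wilcoxon signed-rank
tests per gene across subjects, and hypergeometric KO/pathway enrichment
of the shifted genes.
"""

import argparse
from pathlib import Path

import pandas as pd

from microvarsig.pipeline import STUDY_DEFAULTS, stage_abundance, stage_density


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    a = stage_abundance(args.out_dir)
    print(f"RNG abundance for {a['n_genes']} genes (sums to 1 per sample)")
    d = stage_density(args.out_dir, STUDY_DEFAULTS["min_depth"], STUDY_DEFAULTS["alpha"])
    print(
        f"{d['n_genes_tested']} genes density-tested; "
        f"{d['n_significant_raw']} with raw p < 0.05 day0 vs day30"
    )
    enrich = pd.read_csv(args.out_dir / "ko_enrichment.tsv", sep="\t")
    if not enrich.empty:
        print(enrich.head(10).to_string(index=False))


if __name__ == "__main__":
    main()
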