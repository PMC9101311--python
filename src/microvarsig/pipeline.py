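"""End-to-end orchestration: simulate -> derep -> filter -> spectrum ->
abundance -> density -> dnds, with a reproducibility manifest.

A run is driven by one YAML config with a ``sim`` block (see
:class:`microvarsig.simulate.SimConfig`) and a ``study_defaults`` block
holding every analysis threshold in one visible place (95% ANI, 1% allele
frequency, >5 supporting reads, >=3 SV reads, >=3 SNPs per genome, >=10x
depth, alpha = 5%).  Each stage is a plain function reading and writing
files under the run directory, so the numbered analysis drivers can run
them one at a time; :func:`run_pipeline` chains them and records a
manifest with the config snapshot, seed, per-stage record counts and
SHA-256 checksums of every output, so a rerun with the same seed can be
verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import gene_abundance, ko_enrichment, paired_density_test, snp_density
from .derep import compute_ani_proxy, cluster_genomes, read_identity_table, select_representatives
from .selection import analyze_families, family_counts, load_codon_alignment
from .simulate import (
    SimConfig,
    simulate_codon_families,
    simulate_genomes,
    simulate_identity_matrix,
    simulate_variant_sets,
    write_fasta,
    write_gff3,
)
from .simulate.config import ConfigurationError
from .simulate.genomes import read_fasta_lengths, read_gff3_genes
from .simulate.truth import SimTruth
from .spectrum import compare_groups, spectrum_table, tally_spectrum
from .variants import (
    FilterPolicy,
    estimate_false_positive_rate,
    filter_variants,
    genomes_passing,
    read_variant_calls,
    write_vcf,
)

logger = logging.getLogger(__name__)

__all__ = [
    "STUDY_DEFAULTS",
    "validate_config",
    "load_config",
    "policy_from_defaults",
    "stage_simulate",
    "stage_derep",
    "stage_filter",
    "stage_spectrum",
    "stage_abundance",
    "stage_density",
    "stage_dnds",
    "stage_fp_rate",
    "run_pipeline",
]

#: the study's analysis thresholds, kept in one block so deviations are
#: visible in the run manifest
STUDY_DEFAULTS = dict(
    ani_threshold=95.0,
    min_af=0.01,
    min_support=5,
    sv_min_support=3,
    min_snps_per_genome=3,
    min_depth=10.0,
    alpha=0.05,
)

_KNOWN_TOP_KEYS = {"sim", "study_defaults", "spectrum", "selection", "density"}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def policy_from_defaults(defaults: dict) -> FilterPolicy:
    return FilterPolicy(
        min_af=defaults["min_af"],
        min_support=defaults["min_support"],
        sv_min_support=defaults["sv_min_support"],
        min_snps_per_genome=defaults["min_snps_per_genome"],
    )


def validate_config(config: dict | str | Path) -> tuple[list[str], list[str]]:
    """Validate a pipeline config; returns (violations, warnings).

    Every violation names the offending field, its value and the
    constraint; unknown top-level keys are warnings (forward
    compatibility), not errors.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    violations: list[str] = []
    warnings_: list[str] = []
    for key in config:
        if key not in _KNOWN_TOP_KEYS:
            warnings_.append(f"unknown config key {key!r} ignored")
    try:
        SimConfig.from_dict(config.get("sim", {}))
    except (ConfigurationError, TypeError) as exc:
        violations.append(f"sim: {exc}")
    pd_block = {**STUDY_DEFAULTS, **config.get("study_defaults", {})}
    if not 0 <= pd_block["min_af"] < 1:
        violations.append(
            f"study_defaults.min_af={pd_block['min_af']}: must lie in [0, 1)"
        )
    for key in ("min_support", "sv_min_support", "min_snps_per_genome", "min_depth"):
        if pd_block[key] < 0:
            violations.append(
                f"study_defaults.{key}={pd_block[key]}: must be non-negative"
            )
    if not 0 <= pd_block["ani_threshold"] <= 100:
        violations.append(
            f"study_defaults.ani_threshold={pd_block['ani_threshold']}: "
            "must lie in [0, 100]"
        )
    if not 0 < pd_block["alpha"] < 1:
        violations.append(
            f"study_defaults.alpha={pd_block['alpha']}: must lie in (0, 1)"
        )
    if "spectrum_weights" in config.get("sim", {}) and not config["sim"]["spectrum_weights"]:
        violations.append("sim.spectrum_weights: empty mapping")
    return violations, warnings_


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# stages: each reads its inputs from, and writes its outputs to, the run dir
# ---------------------------------------------------------------------------


def stage_simulate(sim: SimConfig, out: Path) -> dict:
    """Generate every input of the analysis: genomes + gene models,
    per-sample VCFs with planted truth, marker identity table, coverage,
    per-gene read counts and depths, pathway map, codon alignments."""
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sim.seed)
    genomes = simulate_genomes(sim, rng)
    write_fasta(genomes, out / "genomes.fna")
    write_gff3(genomes, out / "genes.gff3")

    identity, planted = simulate_identity_matrix(sim, np.random.default_rng(sim.seed + 3))
    _write_tsv(identity, out / "marker_identity.tsv")
    coverage = pd.DataFrame(
        {
            "genome_id": [g.genome_id for g in genomes],
            "coverage": np.round(rng.uniform(5, 50, len(genomes)), 3),
        }
    )
    _write_tsv(coverage, out / "coverage.tsv")

    calls_by_sample, truth, meta = simulate_variant_sets(
        genomes, sim, np.random.default_rng(sim.seed + 1)
    )
    truth.planted_clusters = planted
    _write_tsv(meta, out / "metadata.tsv")
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    contig_lengths = {g.genome_id: g.length for g in genomes}
    for sid in sorted(calls_by_sample):
        write_vcf(calls_by_sample[sid], vcf_dir / f"{sid}.vcf", contig_lengths)

    families, true_omega = simulate_codon_families(
        sim, np.random.default_rng(sim.seed + 2)
    )
    truth.true_omega = true_omega
    aln_dir = out / "codon_alignments"
    aln_dir.mkdir(exist_ok=True)
    for ko, aln in families.items():
        with open(aln_dir / f"{ko}.fna", "w") as fh:
            for sid_, seq in zip(aln.ids, aln.sequences):
                fh.write(f">{sid_}\n{seq}\n")
    truth.to_json(out / "truth.json")

    # per-gene read counts and mean depths; a lognormal per-gene intensity
    # gives the heavy-tailed abundance profile typical of metagenomes
    all_genes = [(g.genome_id, gene) for g in genomes for gene in g.genes]
    gene_ids = [gene.gene_id for _, gene in all_genes]
    sample_ids = sorted(calls_by_sample)
    lam = rng.lognormal(mean=3.0, sigma=1.0, size=len(gene_ids))
    counts = pd.DataFrame(
        rng.poisson(lam[:, None], size=(len(gene_ids), len(sample_ids))),
        index=gene_ids, columns=sample_ids,
    )
    depth = pd.DataFrame(
        np.round(rng.gamma(2.0, sim.depth_model.mean_depth / 2.0,
                           size=(len(gene_ids), len(sample_ids))), 3),
        index=gene_ids, columns=sample_ids,
    )
    _write_tsv(counts.rename_axis("gene_id").reset_index(), out / "gene_counts.tsv")
    _write_tsv(depth.rename_axis("gene_id").reset_index(), out / "gene_depth.tsv")

    all_kos = sorted({gene.ko_id for _, gene in all_genes})
    pw_rng = np.random.default_rng(sim.seed + 4)
    pathway_map = pd.DataFrame(
        {
            "ko_id": all_kos,
            "pathway_id": [
                f"P{pw_rng.integers(1, sim.n_pathways + 1):03d}" for _ in all_kos
            ],
        }
    )
    _write_tsv(pathway_map, out / "pathway_map.tsv")
    return {
        "n_genomes": len(genomes),
        "n_samples": len(sample_ids),
        "n_variant_records": int(sum(len(v) for v in calls_by_sample.values())),
        "n_families": len(families),
    }


def stage_derep(out: Path, threshold: float = 95.0, linkage: str = "single") -> dict:
    """ANI-proxy clustering of the simulated genomes with coverage-based
    representative selection; writes clusters.tsv."""
    identity = read_identity_table(out / "marker_identity.tsv")
    lengths = read_fasta_lengths(out / "genomes.fna")
    ani = compute_ani_proxy(identity, genome_ids=sorted(lengths))
    clusters = cluster_genomes(ani, threshold=threshold, linkage=linkage)
    cov_df = pd.read_csv(out / "coverage.tsv", sep="\t")
    clusters = select_representatives(
        clusters, dict(zip(cov_df["genome_id"], cov_df["coverage"]))
    )
    _write_tsv(clusters.to_frame(), out / "clusters.tsv")
    result = {"n_clusters": len(clusters.clusters)}
    truth_path = out / "truth.json"
    if truth_path.exists():
        planted = SimTruth.from_json(truth_path).planted_clusters
        if planted:
            result["recovered_planted"] = clusters.as_sets() == {
                frozenset(c) for c in planted
            }
    return result


def stage_filter(out: Path, policy: FilterPolicy) -> dict:
    """Apply the retention rules to every per-sample VCF; writes
    vcf_kept/<sample>.vcf and rejected.tsv."""
    lengths = read_fasta_lengths(out / "genomes.fna")
    kept_dir = out / "vcf_kept"
    kept_dir.mkdir(exist_ok=True)
    reject_rows = []
    n_in = n_kept = 0
    for vcf in sorted((out / "vcf").glob("*.vcf")):
        sid = vcf.stem
        calls = read_variant_calls(vcf, sample_id=sid)
        kept, rejected = filter_variants(calls, policy)
        n_in += len(calls)
        n_kept += len(kept)
        write_vcf(kept, kept_dir / f"{sid}.vcf", lengths)
        for c, reason in rejected:
            reject_rows.append(
                dict(sample_id=sid, genome_id=c.genome_id, pos=c.pos,
                     vtype=c.vtype, reason=reason)
            )
    _write_tsv(pd.DataFrame(reject_rows), out / "rejected.tsv")
    return {"n_input": n_in, "n_kept": n_kept, "n_rejected": len(reject_rows)}


def _read_kept(out: Path) -> dict[str, list]:
    return {
        vcf.stem: read_variant_calls(vcf, sample_id=vcf.stem)
        for vcf in sorted((out / "vcf_kept").glob("*.vcf"))
    }


def stage_spectrum(out: Path, policy: FilterPolicy, alpha: float,
                   welch: bool = False) -> dict:
    """Tally per-sample 12-type spectra over genomes passing the >= 3-SNP
    rule and test group x timepoint shifts; writes spectrum.tsv and
    shift_tests.tsv."""
    lengths = read_fasta_lengths(out / "genomes.fna")
    meta = pd.read_csv(out / "metadata.tsv", sep="\t")
    kept = _read_kept(out)
    included = genomes_passing([c for cc in kept.values() for c in cc], policy)
    inc_lengths = {g: lengths[g] for g in sorted(included)}
    spectra = [
        tally_spectrum(kept[sid], inc_lengths, sample_id=sid) for sid in sorted(kept)
    ]
    _write_tsv(spectrum_table(spectra), out / "spectrum.tsv")
    shift = compare_groups(spectra, meta, alpha=alpha, welch=welch)
    _write_tsv(shift, out / "shift_tests.tsv")
    return {
        "n_included_genomes": len(included),
        "n_tests": int((~shift["skipped"]).sum()) if not shift.empty else 0,
    }


def stage_abundance(out: Path) -> dict:
    """RPKM-like RNG table from the per-gene read counts."""
    counts = pd.read_csv(out / "gene_counts.tsv", sep="\t", index_col=0)
    genes = read_gff3_genes(out / "genes.gff3").set_index("gene_id")
    rng_table = gene_abundance(counts, genes["length_bp"])
    _write_tsv(rng_table.rename_axis("gene_id").reset_index(), out / "abundance_rng.tsv")
    return {"n_genes": len(rng_table)}


def stage_density(out: Path, min_depth: float, alpha: float) -> dict:
    """Per-gene SNP densities under the valid-coverage rule, paired
    day0/day30 Wilcoxon tests per subject, and KO pathway enrichment of
    the shifted genes; writes density.tsv, density_tests.tsv,
    ko_enrichment.tsv."""
    genes = read_gff3_genes(out / "genes.gff3")
    depth = pd.read_csv(out / "gene_depth.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(out / "metadata.tsv", sep="\t").set_index("sample_id")
    kept = _read_kept(out)
    sample_ids = sorted(kept)

    gene_frame = genes.set_index("gene_id")[["length_bp"]]
    snp_counts = pd.DataFrame(0.0, index=gene_frame.index, columns=sample_ids)
    by_genome = {
        gid: sub.sort_values("start")
        for gid, sub in genes.groupby("genome_id")
    }
    for sid in sample_ids:
        for c in kept[sid]:
            if c.vtype != "SNP":
                continue
            sub = by_genome.get(c.genome_id)
            if sub is None:
                continue
            i = int(np.searchsorted(sub["start"].to_numpy(), c.pos, side="right")) - 1
            if i >= 0 and c.pos <= sub["end"].iat[i]:
                snp_counts.at[sub["gene_id"].iat[i], sid] += 1

    dens = snp_density(gene_frame, snp_counts, depth, min_depth=min_depth)
    _write_tsv(dens, out / "density.tsv")

    wide = dens.pivot(index="gene_id", columns="sample_id", values="density_per_kb")
    day0 = [s for s in sample_ids if meta.loc[s, "timepoint"] == "day0"]
    day30 = [s for s in sample_ids if meta.loc[s, "timepoint"] == "day30"]
    d0 = wide[day0].rename(columns=dict(zip(day0, meta.loc[day0, "subject_id"])))
    d30 = wide[day30].rename(columns=dict(zip(day30, meta.loc[day30, "subject_id"])))
    dtest = paired_density_test(d0, d30, alpha=alpha)
    _write_tsv(dtest, out / "density_tests.tsv")

    ko_of_gene = dict(zip(genes["gene_id"], genes["ko_id"]))
    pathway_map = pd.read_csv(out / "pathway_map.tsv", sep="\t")
    sig_genes = set(dtest.loc[dtest["p_value"] < 0.05, "gene_id"])
    bg_kos = set(genes["ko_id"])
    sig_kos = {ko_of_gene[g] for g in sig_genes} & bg_kos
    enrich = ko_enrichment(sig_kos, bg_kos, pathway_map, alpha=alpha)
    _write_tsv(enrich, out / "ko_enrichment.tsv")
    return {
        "n_genes_tested": int(dtest["p_value"].notna().sum()),
        "n_significant_raw": len(sig_genes),
    }


def stage_dnds(out: Path, alpha: float, background: str = "loo") -> dict:
    """NG86-style Dn/Ds per KO family with Fisher/BH positive-selection
    flags; writes selection.tsv."""
    counts = []
    for path in sorted((out / "codon_alignments").glob("*.fna")):
        aln = load_codon_alignment(path)
        if aln.n_sequences < 2:
            logger.warning("%s: fewer than 2 sequences, skipped", aln.ko_id)
            continue
        counts.append(family_counts(aln))
    seltab = analyze_families(counts, alpha=alpha, background=background)
    _write_tsv(seltab, out / "selection.tsv")
    return {"n_families": len(seltab), "n_positive": int(seltab["positive"].sum())}


def stage_fp_rate(out: Path) -> dict:
    """Truth-based false-positive rate over marker-gene regions."""
    truth = SimTruth.from_json(out / "truth.json")
    kept = [c for cc in _read_kept(out).values() for c in cc]
    fp = estimate_false_positive_rate(kept, truth.marker_regions, truth.truth_keys())
    return {"marker_fp_rate": None if fp is None else round(fp, 6)}


def run_pipeline(config: dict | str | Path, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run all stages on one synthetic cohort; returns the manifest dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    violations, warn = validate_config(config)
    for w in warn:
        logger.warning(w)
    if violations:
        raise ConfigurationError("; ".join(violations))

    sim_dict = dict(config.get("sim", {}))
    if seed is not None:
        sim_dict["seed"] = int(seed)
    sim = SimConfig.from_dict(sim_dict)
    defaults = {**STUDY_DEFAULTS, **config.get("study_defaults", {})}
    policy = policy_from_defaults(defaults)
    alpha = defaults["alpha"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "microvarsig",
        "version": __version__,
        "seed": sim.seed,
        "config": {**config, "sim": sim.to_dict(), "study_defaults": defaults},
        "stages": {},
        "outputs": {},
    }
    stages = [
        ("simulate", lambda: stage_simulate(sim, out)),
        ("derep", lambda: stage_derep(out, threshold=defaults["ani_threshold"])),
        ("filter", lambda: stage_filter(out, policy)),
        ("spectrum", lambda: stage_spectrum(
            out, policy, alpha,
            welch=config.get("spectrum", {}).get("welch", False))),
        ("abundance", lambda: stage_abundance(out)),
        ("density", lambda: stage_density(out, defaults["min_depth"], alpha)),
        ("dnds", lambda: stage_dnds(
            out, alpha, background=config.get("selection", {}).get("background", "loo"))),
        ("fp_rate", lambda: stage_fp_rate(out)),
    ]
    for name, fn in stages:
        logger.info("stage %s", name)
        try:
            manifest["stages"][name] = fn()
        except Exception:
            manifest["stages"][name] = {"failed": True}
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=1, sort_keys=True, default=str)
            )
            raise

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    return manifest
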