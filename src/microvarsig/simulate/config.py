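"""Simulation configuration with planted ground truth settings.

The defaults emulate the statistical structure of a chemotherapy
gut-microbiome cohort: three drug groups (5-FU n=7, 5-FU+Oxi n=13, Oxi
n=17) sampled at day 0 and day 30, a C>T/G>A-dominated baseline
substitution spectrum, an elevated transversion weight after oxaliplatin
and a reduced one after 5-FU, mostly-purifying KO families with a couple
of positively selected ones, and genome clusters separated around the 95%
ANI species boundary.  Sizes are desk-scale: a handful of ~60 kb genomes
rather than thousands of real ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from ..spectrum import SUBSTITUTION_TYPES, TRANSVERSION_TYPES

__all__ = [
    "ConfigurationError",
    "SizingError",
    "GroupSpec",
    "AfModel",
    "DepthModel",
    "ViolationRates",
    "ClusterPlan",
    "SimConfig",
    "default_spectrum_weights",
    "scale_transversions",
]

MIN_GENE_LENGTH = 300  # bp, multiple of 3


class ConfigurationError(ValueError):
    """A simulation setting is internally inconsistent."""


class SizingError(ConfigurationError):
    """The genome is too short for the requested gene complement."""


def default_spectrum_weights() -> list[float]:
    """Baseline 12-type weights: C>T/G>A dominant, transitions elevated."""
    w = {t: 0.5 for t in SUBSTITUTION_TYPES}
    w["C>T"] = w["G>A"] = 3.0
    w["A>G"] = w["T>C"] = 1.0
    return [w[t] for t in SUBSTITUTION_TYPES]


def scale_transversions(weights: list[float], factor: float) -> list[float]:
    """Scale the 8 transversion weights by ``factor`` (transitions fixed)."""
    return [
        w * factor if t in TRANSVERSION_TYPES else w
        for t, w in zip(SUBSTITUTION_TYPES, weights)
    ]


@dataclass
class GroupSpec:
    group: str
    timepoint: str
    n_samples: int

    @property
    def condition(self) -> str:
        return f"{self.group}:{self.timepoint}"


@dataclass
class AfModel:
    """Beta allele-frequency model rescaled above the filter floor.

    AF = floor + (1 - floor) * Beta(alpha, beta); the floor keeps clean
    (non-violating) calls above the 1% allele-frequency filter.  The Beta
    shape is a stand-in, not a claim about real call AF distributions.
    """

    alpha: float = 0.8
    beta: float = 4.0
    floor: float = 0.02


@dataclass
class DepthModel:
    """Read-support model; strand split is Binomial(total, 0.5) with both
    strands forced >= 1 for clean calls."""

    mean_depth: float = 30.0
    min_passing: int = 6  # clean calls stay strictly above the 5-read rule


@dataclass
class ViolationRates:
    """Fractions of planted calls that deliberately violate each filter."""

    low_af_snp: float = 0.05
    low_support_snp: float = 0.05
    single_strand_indel: float = 0.2
    low_support_sv: float = 0.2


@dataclass
class ClusterPlan:
    """Planted genome clusters with identity ranges straddling the
    species threshold."""

    sizes: list[int] = field(default_factory=lambda: [3, 2, 1])
    within: tuple[float, float] = (96.0, 99.5)
    between: tuple[float, float] = (80.0, 90.0)


def _default_groups() -> list[GroupSpec]:
    out = []
    for group, n in (("5-FU", 7), ("5-FU+Oxi", 13), ("Oxi", 17)):
        for tp in ("day0", "day30"):
            out.append(GroupSpec(group, tp, n))
    return out


def _default_weights() -> dict[str, list[float]]:
    base = default_spectrum_weights()
    return {
        "default": base,
        # oxaliplatin raises, 5-FU lowers, the transversion weight
        "Oxi:day30": scale_transversions(base, 1.5),
        "5-FU:day30": scale_transversions(base, 0.7),
    }


def _default_omega_map() -> dict[str, float]:
    omega = {f"K{10000 + i:05d}": 0.1 for i in range(20)}
    omega["K10000"] = 5.0
    omega["K10001"] = 5.0
    return omega


@dataclass
class SimConfig:
    """All knobs of the synthetic community, variant and selection study."""

    seed: int = 0
    n_genomes: int = 6
    genome_length: int = 60_000
    gc_content: float = 0.5
    n_genes_per_genome: int = 60
    n_marker_genes: int = 40
    groups: list[GroupSpec] = field(default_factory=_default_groups)
    spectrum_weights: dict[str, list[float]] = field(default_factory=_default_weights)
    snp_rate: float = 3.0  # expected SNPs per kb per sample
    indel_rate: float = 0.1  # per kb per sample
    sv_rate: float = 0.02  # per kb per sample
    fp_marker_rate: float = 0.1  # false calls per marker kb per sample
    af_model: AfModel = field(default_factory=AfModel)
    depth_model: DepthModel = field(default_factory=DepthModel)
    violations: ViolationRates = field(default_factory=ViolationRates)
    omega_map: dict[str, float] = field(default_factory=_default_omega_map)
    n_codons_per_family: int = 120
    n_seqs_per_family: int = 8
    family_divergence: float = 0.3  # expected mutation proposals per codon
    gap_fraction: float = 0.0
    cluster_plan: ClusterPlan = field(default_factory=ClusterPlan)
    ani_threshold: float = 95.0
    ko_pool_size: int = 20
    n_pathways: int = 5

    def validate(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ConfigurationError(f"gc_content must be in (0,1): {self.gc_content}")
        if self.n_marker_genes > self.n_genes_per_genome:
            raise ConfigurationError("n_marker_genes exceeds n_genes_per_genome")
        if self.genome_length < self.n_genes_per_genome * MIN_GENE_LENGTH:
            raise SizingError(
                f"genome_length {self.genome_length} cannot hold "
                f"{self.n_genes_per_genome} genes of >= {MIN_GENE_LENGTH} bp"
            )
        labels = [(g.group, g.timepoint) for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate (group, timepoint) labels")
        for cond, w in self.spectrum_weights.items():
            if len(w) != 12:
                raise ConfigurationError(f"{cond}: need 12 weights, got {len(w)}")
            if any(x < 0 for x in w):
                raise ConfigurationError(f"{cond}: negative spectrum weight")
            if sum(w) <= 0:
                raise ConfigurationError(f"{cond}: weights sum to zero")
            for b in range(4):
                if sum(w[3 * b : 3 * b + 3]) <= 0:
                    raise ConfigurationError(
                        f"{cond}: all-zero weights for ref base {'ACGT'[b]}"
                    )
        for ko, om in self.omega_map.items():
            if om < 0:
                raise ConfigurationError(f"{ko}: omega must be >= 0, got {om}")
        cp = self.cluster_plan
        if sum(cp.sizes) != self.n_genomes:
            raise ConfigurationError(
                f"cluster sizes {cp.sizes} do not sum to n_genomes {self.n_genomes}"
            )
        if cp.within[0] > cp.within[1] or cp.between[0] > cp.between[1]:
            raise ConfigurationError("identity ranges must be (low, high)")
        if cp.between[1] >= cp.within[0]:
            raise ConfigurationError(
                "between-cluster identity range overlaps within-cluster range"
            )
        if not (cp.between[1] < self.ani_threshold <= cp.within[0]):
            raise ConfigurationError(
                "identity ranges must straddle the ANI threshold"
            )

    def weights_for(self, condition: str) -> list[float]:
        if condition in self.spectrum_weights:
            return self.spectrum_weights[condition]
        if "default" in self.spectrum_weights:
            return self.spectrum_weights["default"]
        raise ConfigurationError(f"no spectrum weights for condition {condition!r}")

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = [asdict(g) for g in self.groups]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "groups" in d:
            d["groups"] = [GroupSpec(**g) for g in d["groups"]]
        for key, sub in (
            ("af_model", AfModel),
            ("depth_model", DepthModel),
            ("violations", ViolationRates),
            ("cluster_plan", ClusterPlan),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "cluster_plan" in d and isinstance(d["cluster_plan"], ClusterPlan):
            cp = d["cluster_plan"]
            cp.within = tuple(cp.within)
            cp.between = tuple(cp.between)
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
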