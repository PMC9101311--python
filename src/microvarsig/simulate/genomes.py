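"""Synthetic prokaryotic genomes with non-overlapping CDS gene models.

Each genome is an i.i.d. base sequence at a target GC content carrying
``n_genes_per_genome`` non-overlapping coding genes on random strands,
every gene length a multiple of 3.  Exactly ``n_marker_genes`` genes per
genome are flagged as universal single-copy markers (ids M01.., matched
across genomes so pairwise per-marker identities are meaningful), and each
gene carries a KO family label drawn from a configurable pool.  Output is
writable as FASTA + GFF3 and is byte-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import MIN_GENE_LENGTH, SimConfig, SizingError

__all__ = [
    "GeneModel",
    "Genome",
    "simulate_genomes",
    "write_fasta",
    "write_gff3",
    "read_gff3_genes",
    "read_fasta_lengths",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GeneModel:
    """One CDS gene; coordinates are 1-based inclusive as in GFF3."""

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    ko_id: str
    marker_id: str | None = None  # M01.. for single-copy markers

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    genome_id: str
    seq: str
    genes: list[GeneModel] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.seq)

    def marker_regions(self) -> list[tuple[int, int]]:
        return sorted((g.start, g.end) for g in self.genes if g.marker_id)

    def codes(self) -> np.ndarray:
        """Sequence as uint8 base codes 0..3 (ACGT)."""
        raw = np.frombuffer(self.seq.encode(), dtype=np.uint8)
        out = np.empty(raw.size, dtype=np.uint8)
        for code, b in enumerate(_BASES):
            out[raw == b] = code
        return out


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return _BASES[codes].tobytes().decode()


def simulate_genomes(config: SimConfig, rng: np.random.Generator | None = None) -> list[Genome]:
    """Generate the synthetic community defined by ``config``."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_genes = config.n_genes_per_genome
    ko_pool = sorted(config.omega_map) + [
        f"K{20000 + i:05d}" for i in range(config.ko_pool_size)
    ]

    genomes: list[Genome] = []
    for gi in range(config.n_genomes):
        gid = f"g{gi + 1:04d}"
        seq = _random_sequence(rng, config.genome_length, config.gc_content)

        # gene lengths: multiples of 3 between MIN_GENE_LENGTH and 3x that
        lengths = (rng.integers(MIN_GENE_LENGTH // 3, MIN_GENE_LENGTH, n_genes) * 3)
        slack = config.genome_length - int(lengths.sum())
        if slack < 0:
            raise SizingError(
                f"{gid}: genes ({lengths.sum()} bp) exceed genome length"
            )
        # distribute the slack as random inter-genic gaps
        cuts = np.sort(rng.integers(0, slack + 1, n_genes + 1))
        gaps = np.diff(np.concatenate(([0], cuts, [slack])))[: n_genes + 1]

        marker_slots = set(rng.choice(n_genes, size=config.n_marker_genes, replace=False).tolist())
        genes: list[GeneModel] = []
        pos = 0
        marker_no = 0
        for k in range(n_genes):
            pos += int(gaps[k])
            start = pos + 1
            end = pos + int(lengths[k])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            if k in marker_slots:
                marker_no += 1
                marker = f"M{marker_no:02d}"
                ko = f"K{90000 + marker_no:05d}"  # markers get their own KOs
            else:
                marker = None
                ko = ko_pool[int(rng.integers(0, len(ko_pool)))]
            genes.append(
                GeneModel(
                    gene_id=f"{gid}_gene{k + 1:04d}",
                    start=start,
                    end=end,
                    strand=strand,
                    ko_id=ko,
                    marker_id=marker,
                )
            )
        genomes.append(Genome(genome_id=gid, seq=seq, genes=genes))
    return genomes


def write_fasta(genomes: list[Genome], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.genome_id}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3_genes(path: str | Path):
    """Read gene models written by :func:`write_gff3` into a DataFrame
    (gene_id, genome_id, start, end, strand, ko_id, marker_id, length_bp)."""
    import pandas as pd

    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9 or fields[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            start, end = int(fields[3]), int(fields[4])
            rows.append(
                dict(
                    gene_id=attrs.get("ID", ""),
                    genome_id=fields[0],
                    start=start,
                    end=end,
                    strand=fields[6],
                    ko_id=attrs.get("ko_id", ""),
                    marker_id=attrs.get("marker", None),
                    length_bp=end - start + 1,
                )
            )
    return pd.DataFrame(rows)


def write_gff3(genomes: list[Genome], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genomes:
        lines.append(f"##sequence-region {g.genome_id} 1 {g.length}")
    for g in genomes:
        for gene in g.genes:
            attrs = f"ID={gene.gene_id};ko_id={gene.ko_id}"
            if gene.marker_id:
                attrs += f";marker={gene.marker_id}"
            lines.append(
                "\t".join(
                    [
                        g.genome_id, "microvarsig", "CDS",
                        str(gene.start), str(gene.end), ".",
                        gene.strand, "0", attrs,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
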