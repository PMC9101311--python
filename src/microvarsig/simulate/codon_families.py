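"""Codon-alignment evolution at known dN/dS (the selection-scan oracle).

Each KO family descends from a random stop-free ancestor of sense codons.
Sequences accumulate proposed single-nucleotide codon changes; a proposal
is rejected outright if it creates a stop codon, accepted with probability
1 if synonymous and probability omega if nonsynonymous (for omega > 1 the
acceptance probabilities are rescaled so nonsynonymous changes are fixed
with probability 1 and synonymous ones with probability 1/omega — only the
ratio matters for dN/dS).  Alignments are gap-free by construction; when
gap injection is enabled, gaps are codon-aligned.

The mutation process is applied in a fixed number of rounds with
vectorised per-codon Bernoulli proposals, which keeps large seed sweeps
cheap while remaining an honest sequential mutation process per codon.
"""

from __future__ import annotations

import numpy as np

from ..codon import NEIGHBOR_IDX, NEIGHBOR_SYN, decode_codons
from ..selection import CodonAlignment
from .config import ConfigurationError, SimConfig

__all__ = ["evolve_family_codes", "simulate_codon_families"]


def evolve_family_codes(
    rng: np.random.Generator,
    n_seqs: int,
    n_codons: int,
    omega: float,
    mu: float = 0.3,
    rounds: int = 8,
    ancestor: np.ndarray | None = None,
) -> np.ndarray:
    """Evolve ``n_seqs`` sequences from a common ancestor at dN/dS ``omega``.

    ``mu`` is the expected number of mutation proposals per codon per
    sequence.  Returns an (n_seqs, n_codons) codon-code matrix.
    """
    if omega < 0:
        raise ConfigurationError(f"omega must be >= 0, got {omega}")
    if ancestor is None:
        ancestor = rng.integers(0, 61, size=n_codons)
    state = np.tile(np.asarray(ancestor, dtype=np.int16), (n_seqs, 1))

    scale = max(1.0, omega)
    p_nonsyn = omega / scale
    p_syn = 1.0 / scale
    q = mu / rounds
    for _ in range(rounds):
        mask = rng.random(state.shape) < q
        k = int(mask.sum())
        if k == 0:
            continue
        cur = state[mask]
        direction = rng.integers(0, 9, size=k)
        nb = NEIGHBOR_IDX[cur, direction]
        syn = NEIGHBOR_SYN[cur, direction]
        accept_p = np.where(syn, p_syn, p_nonsyn)
        accept = (nb >= 0) & (rng.random(k) < accept_p)
        cur[accept] = nb[accept]
        state[mask] = cur
    return state


def simulate_codon_families(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, CodonAlignment], dict[str, float]]:
    """Simulate one codon alignment per KO family in ``config.omega_map``."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    families: dict[str, CodonAlignment] = {}
    for ko in sorted(config.omega_map):
        omega = config.omega_map[ko]
        codes = evolve_family_codes(
            rng,
            n_seqs=config.n_seqs_per_family,
            n_codons=config.n_codons_per_family,
            omega=omega,
            mu=config.family_divergence,
        )
        if config.gap_fraction > 0:
            gaps = rng.random(codes.shape) < config.gap_fraction
            codes = np.where(gaps, -1, codes)
        families[ko] = CodonAlignment(
            ko_id=ko,
            ids=[f"{ko}_seq{i + 1:03d}" for i in range(codes.shape[0])],
            sequences=[decode_codons(c) for c in codes],
        )
    return families, dict(config.omega_map)
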