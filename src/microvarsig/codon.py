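"""Codon-level machinery shared by the selection scan and the codon simulator.

Everything here is defined on the bacterial/archaeal genetic code
(translation table 11), whose amino-acid assignments are taken from
Biopython's codon tables.  The module precomputes, once at import:

* the 61 sense codons in lexicographic order and their integer codes,
* per-codon synonymous/nonsynonymous site counts (``N_SITES``/``S_SITES``),
  with single-nucleotide neighbours that are stop codons excluded from the
  denominator,
* path-averaged change counts ``DN_TAB``/``DS_TAB`` for every ordered codon
  pair: all orderings of the differing positions are enumerated, orderings
  passing through a stop codon are discarded, and (dn, ds) is the average
  over the surviving orderings — the classic tree-free NG86-style counting.
* the 9 single-nucleotide neighbours of each codon, used by the mutation
  simulator (stop neighbours are marked so proposals into stops can be
  rejected).

For any codon pair with at least one surviving ordering, dn + ds equals the
nucleotide (Hamming) distance between the codons exactly.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "BASES",
    "SENSE_CODONS",
    "STOP_CODONS",
    "CODON_INDEX",
    "AMINO_ACID",
    "count_codon_changes",
    "count_sites",
    "encode_codons",
    "decode_codons",
    "AllPathsBlockedError",
    "StopCodonError",
]

BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[11]

SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID: dict[str, str] = dict(_TABLE.forward_table)

N_SENSE = len(SENSE_CODONS)  # 61


class StopCodonError(ValueError):
    """A stop codon was supplied where a sense codon is required."""


class AllPathsBlockedError(ValueError):
    """Every mutational ordering between two codons passes through a stop."""


def _check_sense(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"not a DNA codon: {codon!r}")
    if codon in STOP_CODONS:
        raise StopCodonError(f"stop codon not allowed here: {codon}")
    return codon


def count_sites(codon: str) -> tuple[float, float]:
    """Nonsynonymous and synonymous site counts of one sense codon.

    Each of the 9 single-nucleotide neighbours is classified by translation;
    neighbours that are stop codons are excluded from the denominator.  The
    synonymous fraction of the remaining neighbours is scaled to the 3
    nucleotide positions: ``s_sites = 3 * syn / (syn + nonsyn)`` and
    ``n_sites = 3 - s_sites``.

    Returns ``(n_sites, s_sites)``.
    """
    codon = _check_sense(codon)
    aa = AMINO_ACID[codon]
    syn = nonsyn = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1 :]
            if nb in STOP_CODONS:
                continue
            if AMINO_ACID[nb] == aa:
                syn += 1
            else:
                nonsyn += 1
    s = 3.0 * syn / (syn + nonsyn)
    return 3.0 - s, s


def count_codon_changes(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Path-averaged (dn, ds) between two sense codons.

    Enumerates every ordering of the differing positions (at most 3! = 6),
    classifies each single-nucleotide step as synonymous or nonsynonymous by
    translation, discards orderings whose intermediate codons are stops, and
    averages over the survivors.  Symmetric in its arguments.

    Raises :class:`AllPathsBlockedError` when no ordering survives (possible
    only for 2- and 3-step pairs).
    """
    a = _check_sense(codon_a)
    b = _check_sense(codon_b)
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    surviving: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = a
        dn = ds = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if AMINO_ACID[cur] == AMINO_ACID[nxt]:
                ds += 1
            else:
                dn += 1
            cur = nxt
        if ok:
            surviving.append((dn, ds))
    if not surviving:
        raise AllPathsBlockedError(f"all paths {a}->{b} pass through a stop codon")
    m = len(surviving)
    return (sum(p[0] for p in surviving) / m, sum(p[1] for p in surviving) / m)


def _build_tables():
    n_sites = np.empty(N_SENSE)
    s_sites = np.empty(N_SENSE)
    for i, c in enumerate(SENSE_CODONS):
        n_sites[i], s_sites[i] = count_sites(c)

    dn_tab = np.zeros((N_SENSE, N_SENSE))
    ds_tab = np.zeros((N_SENSE, N_SENSE))
    pair_ok = np.ones((N_SENSE, N_SENSE), dtype=bool)
    for i, a in enumerate(SENSE_CODONS):
        for j in range(i + 1, N_SENSE):
            b = SENSE_CODONS[j]
            try:
                dn, ds = count_codon_changes(a, b)
            except AllPathsBlockedError:
                pair_ok[i, j] = pair_ok[j, i] = False
                continue
            dn_tab[i, j] = dn_tab[j, i] = dn
            ds_tab[i, j] = ds_tab[j, i] = ds

    # neighbour tables for the mutation simulator: 9 single-base neighbours
    # per codon, in a fixed (position, base) order; stops get index -1
    nb_idx = np.full((N_SENSE, 9), -1, dtype=np.int16)
    nb_syn = np.zeros((N_SENSE, 9), dtype=bool)
    for i, c in enumerate(SENSE_CODONS):
        k = 0
        for pos in range(3):
            for b in BASES:
                if b == c[pos]:
                    continue
                nb = c[:pos] + b + c[pos + 1 :]
                if nb not in STOP_CODONS:
                    nb_idx[i, k] = CODON_INDEX[nb]
                    nb_syn[i, k] = AMINO_ACID[nb] == AMINO_ACID[c]
                k += 1
    return n_sites, s_sites, dn_tab, ds_tab, pair_ok, nb_idx, nb_syn


(
    N_SITES,
    S_SITES,
    DN_TAB,
    DS_TAB,
    PAIR_OK,
    NEIGHBOR_IDX,
    NEIGHBOR_SYN,
) = _build_tables()


def encode_codons(seq: str) -> np.ndarray:
    """Encode a gapped DNA string into codon codes.

    Returns an int16 array of length ``len(seq) // 3``: 0..60 for sense
    codons, -1 for anything else (gap-containing, ambiguous, or stop codons).
    Sequence length must be a multiple of 3.
    """
    if len(seq) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    seq = seq.upper()
    out = np.empty(len(seq) // 3, dtype=np.int16)
    for i in range(0, len(seq), 3):
        out[i // 3] = CODON_INDEX.get(seq[i : i + 3], -1)
    return out


def decode_codons(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_codons`; code -1 becomes a gap codon '---'."""
    return "".join(SENSE_CODONS[c] if c >= 0 else "---" for c in codes)
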