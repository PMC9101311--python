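"""Per-family Dn/Ds selection scan over codon alignments.

For each KO gene family the module counts synonymous (Ds) and nonsynonymous
(Dn) changes over all unordered sequence pairs and all codon columns that
are gap-free in both sequences of a pair, using tree-free NG86-style
path-averaged counting (see :mod:`microvarsig.codon`).  Site totals are the
per-column mean over sequences of each codon's nonsynonymous/synonymous
site counts, summed over columns.  The site-normalised ratio is

    omega = (Dn / N) / (Ds / S)

Families are screened for positive selection with a one-sided (greater)
Fisher exact test of the family's (Dn, Ds) against the background totals of
all other families (leave-one-out by default), followed by
Benjamini-Hochberg FDR control.  Estimates are pairwise NG86-style counts,
not maximum-likelihood codon-model estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .codon import (
    DN_TAB,
    DS_TAB,
    N_SITES,
    PAIR_OK,
    S_SITES,
    encode_codons,
)

__all__ = [
    "CodonAlignment",
    "FamilyCounts",
    "SelectionResult",
    "load_codon_alignment",
    "family_counts",
    "positive_selection_test",
    "fdr_adjust",
    "analyze_families",
    "write_selection_table",
]


@dataclass
class CodonAlignment:
    """A gap-aware codon alignment for one KO family."""

    ko_id: str
    ids: list[str]
    sequences: list[str]
    n_ambiguous_codons_masked: int = 0

    def __post_init__(self):
        widths = {len(s) for s in self.sequences}
        if len(widths) > 1:
            raise ValueError(f"{self.ko_id}: unequal sequence lengths {sorted(widths)}")
        if widths and next(iter(widths)) % 3:
            raise ValueError(f"{self.ko_id}: alignment width not a multiple of 3")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3 if self.sequences else 0

    def codes(self) -> np.ndarray:
        """(n_sequences, n_codons) codon-code matrix; -1 = unusable codon."""
        return np.vstack([encode_codons(s) for s in self.sequences])


def load_codon_alignment(path: str | Path, ko_id: str | None = None) -> CodonAlignment:
    """Read one per-KO codon alignment FASTA (convention ``<ko_id>.fna``).

    Codons containing characters other than ACGT- are masked to gaps and
    counted in ``n_ambiguous_codons_masked``.
    """
    path = Path(path)
    if ko_id is None:
        ko_id = path.stem
    ids, seqs = [], []
    masked = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        clean = []
        for i in range(0, len(s) - len(s) % 3, 3):
            cod = s[i : i + 3]
            if any(ch not in "ACGT-" for ch in cod):
                masked += 1
                cod = "---"
            clean.append(cod)
        ids.append(rec.id)
        seqs.append("".join(clean))
    return CodonAlignment(ko_id=ko_id, ids=ids, sequences=seqs, n_ambiguous_codons_masked=masked)


@dataclass
class FamilyCounts:
    """Aggregated change and site counts for one family."""

    ko_id: str
    dn_changes: float
    ds_changes: float
    n_sites: float
    s_sites: float
    n_pairs: int
    blocked_codon_pairs: int = 0

    @property
    def omega(self) -> float | None:
        """Site-normalised Dn/Ds; None (flagged) when Ds or S is zero."""
        if self.ds_changes == 0 or self.s_sites == 0 or self.n_sites == 0:
            return None
        return (self.dn_changes / self.n_sites) / (self.ds_changes / self.s_sites)


def family_counts(alignment: CodonAlignment | np.ndarray, ko_id: str = "") -> FamilyCounts:
    """Sum path-averaged (dn, ds) over all unordered sequence pairs.

    Codon columns with a gap/stop/ambiguity in either member of a pair are
    skipped for that pair (the in-repo surrogate for discarding
    low-confidence alignment columns).  Pairs of codons whose every
    mutational ordering is blocked by stops are dropped and counted.

    Accepts either a :class:`CodonAlignment` or a pre-encoded
    (n_sequences, n_codons) code matrix.
    """
    if isinstance(alignment, CodonAlignment):
        codes = alignment.codes()
        ko_id = ko_id or alignment.ko_id
    else:
        codes = np.asarray(alignment)
    n_seq = codes.shape[0]
    if n_seq < 2:
        raise ValueError(f"{ko_id or 'family'}: need at least 2 usable sequences")

    valid = codes >= 0
    safe = np.where(valid, codes, 0)

    dn_sum = 0.0
    ds_sum = 0.0
    blocked = 0
    n_pairs = 0
    for i in range(n_seq - 1):
        a = safe[i]
        rest = safe[i + 1 :]
        mask = valid[i] & valid[i + 1 :]
        ok = PAIR_OK[a, rest] & mask
        blocked += int((mask & ~ok).sum())
        dn_sum += float(DN_TAB[a, rest][ok].sum())
        ds_sum += float(DS_TAB[a, rest][ok].sum())
        n_pairs += rest.shape[0]

    # site totals: per-column mean over sequences with a usable codon,
    # summed over columns (columns with no usable codon contribute 0)
    counts = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_col = np.where(valid, N_SITES[safe], 0.0).sum(axis=0)
        s_col = np.where(valid, S_SITES[safe], 0.0).sum(axis=0)
        n_mean = np.where(counts > 0, n_col / np.maximum(counts, 1), 0.0)
        s_mean = np.where(counts > 0, s_col / np.maximum(counts, 1), 0.0)

    return FamilyCounts(
        ko_id=ko_id,
        dn_changes=dn_sum,
        ds_changes=ds_sum,
        n_sites=float(n_mean.sum()),
        s_sites=float(s_mean.sum()),
        n_pairs=n_pairs,
        blocked_codon_pairs=blocked,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def positive_selection_test(
    family: tuple[float, float], background: tuple[float, float]
) -> float:
    """One-sided (greater) Fisher exact p for Dn enrichment of a family.

    ``family`` is the family's (dn, ds); ``background`` the comparison
    totals (Dn_bg, Ds_bg).  Fractional path-averaged counts are rounded
    half-away-from-zero before the exact test.  The one-sided Fisher p of
    the 2x2 table [[dn, ds], [Dn_bg, Ds_bg]] equals the upper hypergeometric
    tail P(X >= dn) with population dn+ds+Dn_bg+Ds_bg, successes dn+Dn_bg
    and draws dn+ds.  Zero-margin tables return p = 1.
    """
    dn, ds = (_round_half_away(v) for v in family)
    dn_bg, ds_bg = (_round_half_away(v) for v in background)
    if min(dn, ds, dn_bg, ds_bg) < 0:
        raise ValueError("counts must be non-negative")
    total = dn + ds + dn_bg + ds_bg
    succ = dn + dn_bg
    draws = dn + ds
    if total == 0 or succ == 0 or draws == 0 or succ == total or draws == total:
        return 1.0
    return float(stats.hypergeom.sf(dn - 1, total, succ, draws))


def fdr_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(q_values, rejected)`` where ``rejected`` marks hypotheses
    with q <= alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


@dataclass
class SelectionResult:
    """Selection-scan record for one KO family."""

    ko_id: str
    dn_changes: float
    ds_changes: float
    n_sites: float
    s_sites: float
    omega: float | None
    fisher_p: float
    q_value: float
    positive: bool
    dn_above_mean: bool = False
    ds_below_mean: bool = False
    positive_strict: bool = False


def analyze_families(
    counts: list[FamilyCounts],
    alpha: float = 0.05,
    background: str = "loo",
    count_scale: str = "per_pair",
) -> pd.DataFrame:
    """Fisher + BH positive-selection screen over a set of family counts.

    ``background='loo'`` (default) compares each family against the summed
    counts of all *other* families; ``'all'`` includes the focal family in
    the background.  Besides the Fisher/FDR flag (``positive``), families
    are also flagged for having Dn above and Ds below the across-family
    means, and the conjunction is reported as ``positive_strict``.

    ``count_scale='per_pair'`` (default) divides each family's summed
    (dn, ds) by its number of sequence pairs before the exact test: summed
    pairwise counts replicate every underlying mutation across roughly
    n - 1 pairs, which would grossly violate the Fisher test's
    independence assumption and flag noise as selection; per-pair averages
    put the counts back on (a conservative lower bound of) the scale of
    independent change events.  ``'total'`` uses the raw sums.  Reported
    dn/ds columns are always the raw sums.
    """
    if background not in ("loo", "all"):
        raise ValueError("background must be 'loo' or 'all'")
    if count_scale not in ("per_pair", "total"):
        raise ValueError("count_scale must be 'per_pair' or 'total'")
    if not counts:
        return pd.DataFrame(
            columns=[
                "ko_id", "dn_changes", "ds_changes", "n_sites", "s_sites",
                "omega", "fisher_p", "q_value", "positive",
                "dn_above_mean", "ds_below_mean", "positive_strict",
            ]
        )
    dn = np.array([c.dn_changes for c in counts])
    ds = np.array([c.ds_changes for c in counts])
    if count_scale == "per_pair":
        pairs = np.array([max(c.n_pairs, 1) for c in counts], dtype=float)
        dn_t, ds_t = dn / pairs, ds / pairs
    else:
        dn_t, ds_t = dn, ds
    dn_tot, ds_tot = dn_t.sum(), ds_t.sum()
    p = np.empty(len(counts))
    for k in range(len(counts)):
        if background == "loo":
            bg = (dn_tot - dn_t[k], ds_tot - ds_t[k])
        else:
            bg = (dn_tot, ds_tot)
        p[k] = positive_selection_test((dn_t[k], ds_t[k]), bg)
    q, rejected = fdr_adjust(p, alpha=alpha)
    dn_above = dn > dn.mean()
    ds_below = ds < ds.mean()
    df = pd.DataFrame(
        {
            "ko_id": [c.ko_id for c in counts],
            "dn_changes": dn,
            "ds_changes": ds,
            "n_sites": [c.n_sites for c in counts],
            "s_sites": [c.s_sites for c in counts],
            "omega": [c.omega for c in counts],
            "fisher_p": p,
            "q_value": q,
            "positive": rejected,
            "dn_above_mean": dn_above,
            "ds_below_mean": ds_below,
            "positive_strict": rejected & dn_above & ds_below,
        }
    )
    return df.sort_values("q_value", kind="stable").reset_index(drop=True)


def write_selection_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
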