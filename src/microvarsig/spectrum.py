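"""12-type substitution spectra and group/timepoint shift tests.

Single-nucleotide substitutions are tallied into the 12 ordered ref>alt
classes (4 bases x 3 alternatives, no strand collapsing), normalised per
kilobase of included reference sequence, and aggregated into transition
(A>G, G>A, C>T, T>C) and transversion counts.  Shifts between sample
groups (e.g. pre- vs post-treatment under one drug) are tested per metric
with a two-sample Student t-test (pooled variance by default, Welch by
flag) and Benjamini-Hochberg adjustment across all metric x comparison
tests emitted in one batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .selection import fdr_adjust

__all__ = [
    "SUBSTITUTION_TYPES",
    "TRANSITION_TYPES",
    "TRANSVERSION_TYPES",
    "SubstitutionSpectrum",
    "tally_spectrum",
    "merge_spectra",
    "ts_tv_ratio",
    "collapse_strand",
    "spectrum_table",
    "compare_groups",
    "plot_spectra",
]

_BASES = "ACGT"
SUBSTITUTION_TYPES: tuple[str, ...] = tuple(
    f"{r}>{a}" for r in _BASES for a in _BASES if r != a
)
TRANSITION_TYPES: frozenset[str] = frozenset({"A>G", "G>A", "C>T", "T>C"})
TRANSVERSION_TYPES: frozenset[str] = frozenset(SUBSTITUTION_TYPES) - TRANSITION_TYPES
TYPE_INDEX: dict[str, int] = {t: i for i, t in enumerate(SUBSTITUTION_TYPES)}
_TS_MASK = np.array([t in TRANSITION_TYPES for t in SUBSTITUTION_TYPES])


@dataclass
class SubstitutionSpectrum:
    """Counts and per-kb rates of the 12 ordered substitution types."""

    sample_id: str
    counts: np.ndarray  # length 12, ordered as SUBSTITUTION_TYPES
    denominator_kb: float
    n_skipped_ambiguous: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (12,):
            raise ValueError("counts must have length 12")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def ts_count(self) -> float:
        return float(self.counts[_TS_MASK].sum())

    @property
    def tv_count(self) -> float:
        return float(self.counts[~_TS_MASK].sum())

    @property
    def rates_per_kb(self) -> np.ndarray:
        return self.counts / self.denominator_kb

    @property
    def ts_rate(self) -> float:
        return self.ts_count / self.denominator_kb

    @property
    def tv_rate(self) -> float:
        return self.tv_count / self.denominator_kb

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SUBSTITUTION_TYPES, self.counts))


def tally_spectrum(
    snp_calls,
    included_genome_lengths: dict[str, int],
    sample_id: str = "",
) -> SubstitutionSpectrum:
    """Tally kept SNPs of one sample into the 12-type spectrum.

    ``snp_calls`` is an iterable of objects with ``genome_id``,
    ``ref_allele``, ``alt_allele`` and ``vtype`` attributes; only SNPs whose
    genome is in ``included_genome_lengths`` are tallied.  Calls with
    ambiguous bases (anything outside ACGT) are skipped and counted.  The
    per-kb denominator is the total length of the included genomes.
    """
    counts = np.zeros(12)
    skipped = 0
    for c in snp_calls:
        if getattr(c, "vtype", "SNP") != "SNP":
            continue
        if c.genome_id not in included_genome_lengths:
            continue
        key = f"{c.ref_allele.upper()}>{c.alt_allele.upper()}"
        idx = TYPE_INDEX.get(key)
        if idx is None:
            skipped += 1
            continue
        counts[idx] += 1
    denom_kb = sum(included_genome_lengths.values()) / 1000.0
    if denom_kb <= 0:
        raise ValueError("included genome set has zero total length")
    return SubstitutionSpectrum(
        sample_id=sample_id, counts=counts, denominator_kb=denom_kb,
        n_skipped_ambiguous=skipped,
    )


def merge_spectra(a: SubstitutionSpectrum, b: SubstitutionSpectrum) -> SubstitutionSpectrum:
    """Component-wise merge; denominators add (use for disjoint genome sets
    or pooled samples over matching sets, as documented by the caller)."""
    return SubstitutionSpectrum(
        sample_id=f"{a.sample_id}+{b.sample_id}",
        counts=a.counts + b.counts,
        denominator_kb=a.denominator_kb + b.denominator_kb,
        n_skipped_ambiguous=a.n_skipped_ambiguous + b.n_skipped_ambiguous,
    )


def ts_tv_ratio(spectrum: SubstitutionSpectrum) -> float | None:
    """Transition/transversion ratio; None (flagged) when tv count is 0."""
    if spectrum.tv_count == 0:
        return None
    return spectrum.ts_count / spectrum.tv_count


def collapse_strand(spectrum: SubstitutionSpectrum) -> dict[str, float]:
    """6-class strand-collapsed view (pyrimidine-reference convention)."""
    comp = str.maketrans("ACGT", "TGCA")
    out: dict[str, float] = {}
    for t, n in spectrum.as_dict().items():
        r, a = t.split(">")
        if r in "AG":
            t = f"{r.translate(comp)}>{a.translate(comp)}"
        out[t] = out.get(t, 0.0) + n
    return out


def spectrum_table(spectra: list[SubstitutionSpectrum]) -> pd.DataFrame:
    """Sample x type table of counts, rates, and Ts/Tv aggregates."""
    rows = []
    for s in spectra:
        row = {"sample_id": s.sample_id, "denominator_kb": s.denominator_kb}
        row.update({f"count_{t}": c for t, c in s.as_dict().items()})
        row.update(
            {f"rate_{t}": r for t, r in zip(SUBSTITUTION_TYPES, s.rates_per_kb)}
        )
        row["ts_count"] = s.ts_count
        row["tv_count"] = s.tv_count
        row["ts_rate"] = s.ts_rate
        row["tv_rate"] = s.tv_rate
        tstv = ts_tv_ratio(s)
        row["ts_tv"] = np.nan if tstv is None else tstv
        rows.append(row)
    return pd.DataFrame(rows)


_METRICS = {
    "transition_rate": lambda s: s.ts_rate,
    "transversion_rate": lambda s: s.tv_rate,
    "ts_tv": lambda s: (np.nan if ts_tv_ratio(s) is None else ts_tv_ratio(s)),
}


def _metric_value(spectrum: SubstitutionSpectrum, metric: str) -> float:
    if metric in _METRICS:
        return _METRICS[metric](spectrum)
    if metric.startswith("rate_") and metric[5:] in TYPE_INDEX:
        return float(spectrum.rates_per_kb[TYPE_INDEX[metric[5:]]])
    raise ValueError(f"unknown metric {metric!r}")


def _student_t(x: np.ndarray, y: np.ndarray, welch: bool) -> tuple[float, float]:
    # degenerate guard: scipy yields nan when both sides are constant
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return np.inf if x.mean() > y.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def compare_groups(
    spectra: list[SubstitutionSpectrum],
    metadata: pd.DataFrame,
    metrics: tuple[str, ...] = ("transition_rate", "transversion_rate", "ts_tv"),
    within: str = "group",
    between: str = "timepoint",
    welch: bool = False,
    paired: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test per-sample spectrum metrics for shifts between conditions.

    ``metadata`` needs columns ``sample_id``, ``within`` (e.g. drug group)
    and ``between`` (e.g. timepoint).  Within each level of ``within``, the
    two levels of ``between`` are compared per metric; all emitted tests are
    BH-adjusted as one family.  Comparisons with fewer than two samples on
    either side are skipped with a warning column in the output.
    """
    by_id = {s.sample_id: s for s in spectra}
    rows = []
    for g, sub in metadata.groupby(within, sort=True):
        levels = sorted(sub[between].unique())
        if len(levels) != 2:
            continue
        a_ids = sub.loc[sub[between] == levels[0], "sample_id"].tolist()
        b_ids = sub.loc[sub[between] == levels[1], "sample_id"].tolist()
        for metric in metrics:
            x = np.array([_metric_value(by_id[i], metric) for i in a_ids if i in by_id])
            y = np.array([_metric_value(by_id[i], metric) for i in b_ids if i in by_id])
            x = x[~np.isnan(x)]
            y = y[~np.isnan(y)]
            label = f"{g}: {levels[0]} vs {levels[1]}"
            if len(x) < 2 or len(y) < 2:
                rows.append(
                    dict(comparison=label, metric=metric, statistic=np.nan,
                         p_value=np.nan, skipped=True)
                )
                continue
            if paired:
                n = min(len(x), len(y))
                d = x[:n] - y[:n]
                if np.ptp(d) == 0:
                    t, p = (0.0, 1.0) if d.mean() == 0 else (np.inf, 0.0)
                else:
                    t, p = (float(v) for v in stats.ttest_rel(x[:n], y[:n]))
            else:
                t, p = _student_t(x, y, welch)
            rows.append(
                dict(comparison=label, metric=metric, statistic=t, p_value=p,
                     skipped=False)
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    tested = df.loc[~df["skipped"], "p_value"].to_numpy()
    q = np.full(len(df), np.nan)
    if tested.size:
        qv, _ = fdr_adjust(tested, alpha=alpha)
        q[~df["skipped"].to_numpy()] = qv
    df["adjusted_p"] = q
    df["significant"] = df["adjusted_p"] < alpha
    return df


def plot_spectra(spectra, metadata, path, within="group", between="timepoint"):
    """Grouped per-kb barplot of the 12 substitution types (one panel)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = spectrum_table(spectra).merge(metadata, on="sample_id")
    cond = tab[within].astype(str) + " " + tab[between].astype(str)
    rates = tab[[f"rate_{t}" for t in SUBSTITUTION_TYPES]]
    means = rates.groupby(cond).mean()
    x = np.arange(12)
    width = 0.8 / max(len(means), 1)
    fig, ax = plt.subplots(figsize=(10, 4))
    for k, (name, row) in enumerate(means.iterrows()):
        ax.bar(x + k * width, row.to_numpy(), width, label=name)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(SUBSTITUTION_TYPES, rotation=45)
    ax.set_ylabel("substitutions per kb")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
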