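"""Reusable simulation experiments: power, calibration and recovery sweeps.

These functions wire the simulators to the analysis machinery for the
repeated-seed experiments the package is validated with: neutral Dn/Ds
recovery and false-flag calibration, positive-selection power, substitution
-spectrum shift power and null calibration, and planted-cluster recovery.
They are used by the analysis drivers, the test suite and the acceptance
script alike, always through the public package API.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .derep import AniMatrix, cluster_genomes, compute_ani_proxy
from .selection import analyze_families, family_counts
from .simulate import (
    SimConfig,
    evolve_family_codes,
    simulate_identity_matrix,
)
from .simulate.variants import draw_alt_codes
from .spectrum import SubstitutionSpectrum, compare_groups

__all__ = [
    "neutral_selection_run",
    "neutral_selection_sweep",
    "selection_power_run",
    "selection_power_sweep",
    "simulate_spectra_two_groups",
    "spectrum_shift_run",
    "spectrum_shift_sweep",
    "planted_cluster_recovery",
]


# --- Dn/Ds calibration and power -----------------------------------------


def neutral_selection_run(
    seed: int,
    n_families: int = 200,
    n_codons: int = 500,
    n_seqs: int = 20,
    mu: float = 0.3,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """One all-neutral cohort (every family at omega = 1).

    Returns (median family omega, fraction of families flagged positive at
    the given FDR level).
    """
    rng = np.random.default_rng(seed)
    counts = [
        family_counts(
            evolve_family_codes(rng, n_seqs, n_codons, omega=1.0, mu=mu),
            f"F{i:04d}",
        )
        for i in range(n_families)
    ]
    tab = analyze_families(counts, alpha=alpha)
    omegas = np.array([o for o in tab["omega"] if o is not None], dtype=float)
    return float(np.median(omegas)), float(tab["positive"].mean())


def neutral_selection_sweep(n_seeds: int, seed0: int = 0, **kw) -> pd.DataFrame:
    rows = [
        dict(seed=s, median_omega=m, flagged_fraction=f)
        for s in range(seed0, seed0 + n_seeds)
        for m, f in [neutral_selection_run(s, **kw)]
    ]
    return pd.DataFrame(rows)


def selection_power_run(
    seed: int,
    n_background: int = 50,
    n_positive: int = 5,
    omega_background: float = 0.1,
    omega_positive: float = 5.0,
    n_codons: int = 200,
    n_seqs: int = 10,
    mu: float = 0.3,
    alpha: float = 0.05,
) -> float:
    """One cohort with planted positively selected families.

    Returns the fraction of planted omega >= ``omega_positive`` families
    flagged positive at the FDR level (detection rate for this seed).
    """
    rng = np.random.default_rng(seed)
    counts = []
    planted = set()
    for i in range(n_positive):
        ko = f"POS{i:03d}"
        planted.add(ko)
        counts.append(
            family_counts(
                evolve_family_codes(rng, n_seqs, n_codons, omega_positive, mu=mu), ko
            )
        )
    for i in range(n_background):
        counts.append(
            family_counts(
                evolve_family_codes(rng, n_seqs, n_codons, omega_background, mu=mu),
                f"BG{i:03d}",
            )
        )
    tab = analyze_families(counts, alpha=alpha)
    hit = tab.loc[tab["ko_id"].isin(planted), "positive"]
    return float(hit.mean())


def selection_power_sweep(n_seeds: int, seed0: int = 0, **kw) -> pd.DataFrame:
    return pd.DataFrame(
        dict(seed=s, detection_rate=selection_power_run(s, **kw))
        for s in range(seed0, seed0 + n_seeds)
    )


# --- substitution-spectrum shifts ----------------------------------------


def simulate_spectra_two_groups(
    rng: np.random.Generator,
    weights_a: list[float],
    weights_b: list[float],
    n_per_group: int = 20,
    mean_snps: float = 1080.0,
    denominator_kb: float = 360.0,
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[list[SubstitutionSpectrum], pd.DataFrame]:
    """Draw per-sample 12-type spectra for two conditions of one group.

    Reference bases are drawn from ``base_composition`` and alternates from
    the condition's 12-type weights conditioned on the reference base —
    the same sampling scheme the full variant simulator uses, without the
    per-call plumbing, for seed sweeps.
    """
    spectra: list[SubstitutionSpectrum] = []
    meta_rows = []
    p = np.asarray(base_composition, dtype=float)
    p = p / p.sum()
    for cond, weights, tp in ((0, weights_a, "day0"), (1, weights_b, "day30")):
        for i in range(n_per_group):
            sid = f"T{cond}_{i:03d}"
            n = int(rng.poisson(mean_snps))
            ref = rng.choice(4, size=n, p=p)
            _, tidx = draw_alt_codes(ref, weights, rng)
            counts = np.bincount(tidx, minlength=12).astype(float)
            spectra.append(
                SubstitutionSpectrum(sample_id=sid, counts=counts,
                                     denominator_kb=denominator_kb)
            )
            meta_rows.append(dict(sample_id=sid, group="G", timepoint=tp))
    return spectra, pd.DataFrame(meta_rows)


def spectrum_shift_run(
    seed: int,
    factor: float = 1.5,
    n_per_group: int = 20,
    mean_snps: float = 1080.0,
    alpha: float = 0.05,
) -> tuple[bool, bool]:
    """One two-condition cohort with the transversion weights scaled by
    ``factor`` in the second condition (1.0 = null).

    Returns (transversion-rate shift detected at adjusted p < alpha,
    any metric rejected at adjusted p < alpha).
    """
    from .simulate.config import default_spectrum_weights, scale_transversions

    rng = np.random.default_rng(seed)
    base = default_spectrum_weights()
    shifted = scale_transversions(base, factor)
    spectra, meta = simulate_spectra_two_groups(
        rng, base, shifted, n_per_group=n_per_group, mean_snps=mean_snps
    )
    res = compare_groups(spectra, meta, alpha=alpha)
    tv = res[res["metric"] == "transversion_rate"]
    detected = bool((tv["adjusted_p"] < alpha).any())
    any_rejection = bool((res["adjusted_p"] < alpha).any())
    return detected, any_rejection


def spectrum_shift_sweep(
    n_seeds: int, seed0: int = 0, factor: float = 1.5, **kw
) -> pd.DataFrame:
    rows = []
    for s in range(seed0, seed0 + n_seeds):
        detected, any_rej = spectrum_shift_run(s, factor=factor, **kw)
        rows.append(dict(seed=s, detected=detected, any_rejection=any_rej))
    return pd.DataFrame(rows)


# --- dereplication --------------------------------------------------------


def planted_cluster_recovery(seed: int, config: SimConfig | None = None) -> bool:
    """Simulate a planted identity matrix and check exact recovery."""
    config = config or SimConfig()
    table, planted = simulate_identity_matrix(config, np.random.default_rng(seed))
    ani = compute_ani_proxy(table, genome_ids=[g for c in planted for g in c])
    clusters = cluster_genomes(ani, threshold=config.ani_threshold)
    return clusters.as_sets() == {frozenset(c) for c in planted}
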