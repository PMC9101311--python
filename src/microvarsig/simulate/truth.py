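"""Ground-truth bookkeeping for synthetic runs (the test oracle)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = ["SimTruth"]


@dataclass
class SimTruth:
    """Everything the simulator planted, for downstream verification.

    ``true_variants`` lists planted real variants (violating calls
    included, with their violation flags); injected false calls are *not*
    listed here — that is what makes the marker-region false-positive-rate
    estimator informative.  ``planted_spectra`` tallies every emitted SNV
    record per sample (true, violating and false alike) so it can be
    compared exactly against a re-tally of the written VCF.
    """

    true_variants: list[dict] = field(default_factory=list)
    planted_spectra: dict[str, list[int]] = field(default_factory=dict)
    planted_clusters: list[list[str]] = field(default_factory=list)
    true_omega: dict[str, float] = field(default_factory=dict)
    marker_regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    filter_expectations: dict[str, dict[str, int]] = field(default_factory=dict)

    def truth_keys(self) -> set[tuple]:
        """(sample, genome, pos, ref, alt) keys of all planted real variants."""
        return {
            (v["sample_id"], v["genome_id"], v["pos"], v["ref_allele"], v["alt_allele"])
            for v in self.true_variants
        }

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["marker_regions"] = {
            g: [list(iv) for iv in ivs] for g, ivs in self.marker_regions.items()
        }
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        d["marker_regions"] = {
            g: [tuple(iv) for iv in ivs] for g, ivs in d["marker_regions"].items()
        }
        return cls(**d)
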