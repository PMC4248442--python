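"""Fixture configuration for the synthetic-data generators.

The defaults mirror the study conditions the pipeline is built for: a
6,761-gene two-replicate expression array with 99% shared signal variance,
338 pathways split 257 feasible / 14 inactive / 57 partially expressed /
10 mostly expressed, 24 duplicate-gene sets with exactly one above-median
member, three 96-well PM plates totalling 284 test wells split 167 high /
96 moderate / 21 no growth, and 135 network-mapped conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: PM plate layouts: total test wells must sum to 284.
PLATE_LAYOUT: dict[str, dict] = {
    "PM1": {"controls": ["A1"], "kind": "carbon"},
    "PM3": {"controls": ["A1"], "kind": "nitrogen"},
    "PM5": {"controls": ["A1", "A2"], "kind": "supplement"},
}
N_TEST_WELLS = 284


def _default_pathway_composition() -> dict[str, int]:
    return {
        "feasible": 257,
        "inactive": 14,
        "partially_expressed": 57,
        "mostly_expressed": 10,
    }


def _default_pm_composition() -> dict[str, int]:
    return {"high": 167, "moderate": 96, "none": 21}


@dataclass
class FixtureConfig:
    """Knobs of the synthetic fixtures; defaults are the study conditions."""

    seed: int = 42
    n_genes: int = 6761
    n_pathways: int = 338
    pathway_composition: dict[str, int] = field(default_factory=_default_pathway_composition)
    n_duplicate_sets: int = 24
    replicate_noise_ratio_expr: float = 0.01
    pm_composition: dict[str, int] = field(default_factory=_default_pm_composition)
    pm_noise_ratio: float = 0.07
    n_mapped_compounds: int = 135
    expressed_percentile: float = 25.0
    # proteome stand-in (desk scale)
    n_ref_proteins: int = 48
    ortholog_mutation_rate: float = 0.15
    paralog_mutation_rate: float = 0.05

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_genes < 2 * self.n_duplicate_sets:
            raise ValueError("too few genes to embed the duplicate sets")
        if sum(self.pathway_composition.values()) != self.n_pathways:
            raise ValueError("pathway_composition must sum to n_pathways")
        if sum(self.pm_composition.values()) != N_TEST_WELLS:
            raise ValueError(f"pm_composition must sum to {N_TEST_WELLS}")
        for name in ("replicate_noise_ratio_expr", "pm_noise_ratio"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0 <= self.n_mapped_compounds <= N_TEST_WELLS:
            raise ValueError("n_mapped_compounds must lie in [0, 284]")
        for name in ("ortholog_mutation_rate", "paralog_mutation_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
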