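"""Ground-truth labels carried alongside every synthetic fixture."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GroundTruth:
    """Recovery oracle for the generators: one label per generated entity."""

    # expression
    duplicate_sets: dict[str, list[str]] = field(default_factory=dict)
    active_paralog_by_set: dict[str, str] = field(default_factory=dict)
    # pathways
    pathway_status_by_id: dict[str, str] = field(default_factory=dict)
    # PM plates
    growth_class_by_well: dict[tuple[str, str], str] = field(default_factory=dict)
    growth_class_by_condition: dict[str, str] = field(default_factory=dict)
    # compound map
    mapped_compounds: set[str] = field(default_factory=set)
    transporter_loci: list[str] = field(default_factory=list)
    expressed_transporters: set[str] = field(default_factory=set)
    # proteomes
    ortholog_pairs: dict[str, str] = field(default_factory=dict)
    protein_paralog_sets: dict[str, list[str]] = field(default_factory=dict)
    category_by_locus: dict[str, str] = field(default_factory=dict)
    ortholog_target_identity: dict[str, float] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        for name in self.__dataclass_fields__:
            mine, theirs = getattr(self, name), getattr(other, name)
            if isinstance(mine, dict):
                mine.update(theirs)
            elif isinstance(mine, set):
                mine |= theirs
            elif isinstance(mine, list):
                mine.extend(theirs)
        return self
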