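"""Synthetic fixtures with known ground truth for the whole pipeline.

Every generator takes a :class:`FixtureConfig` and draws from its own
seeded stream (``numpy.random.default_rng([stream_id, seed])``), so the
fixtures are deterministic given the config, independent of each other and
of global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..annotation import ProteinRecord
from ..feasibility import PathwayDefinition
from ..integration import CompoundMapping
from ..phenome import PlateSet
from ..transcriptome import ExpressionArray, normalize_expression
from .compounds import generate_compound_map
from .config import N_TEST_WELLS, PLATE_LAYOUT, FixtureConfig
from .expression import generate_expression
from .pathways import generate_pathways
from .plates import CLASS_PARAMS, GLUCOSE_CONDITION, TIME_GRID_H, generate_pm_plates
from .proteomes import generate_proteomes
from .truth import GroundTruth

__all__ = [
    "FixtureConfig",
    "GroundTruth",
    "FixtureBundle",
    "generate_expression",
    "generate_pathways",
    "generate_pm_plates",
    "generate_compound_map",
    "generate_proteomes",
    "generate_all",
    "PLATE_LAYOUT",
    "N_TEST_WELLS",
    "CLASS_PARAMS",
    "TIME_GRID_H",
    "GLUCOSE_CONDITION",
]


@dataclass
class FixtureBundle:
    """Everything the pipeline consumes, plus the merged ground truth."""

    config: FixtureConfig
    expression: ExpressionArray  # normalized, with norm_avg
    pathways: list[PathwayDefinition]
    plates: PlateSet
    compound_map: dict[str, CompoundMapping]
    query_proteome: list[ProteinRecord]
    ref_proteome: list[ProteinRecord]
    truth: GroundTruth


def generate_all(config: FixtureConfig | None = None) -> FixtureBundle:
    """Generate the full default fixture set in dependency order."""
    config = config or FixtureConfig()
    expr, truth = generate_expression(config)
    expr = normalize_expression(expr)
    pathways, pw_truth = generate_pathways(config, expr, expr_truth=truth)
    plates, pm_truth = generate_pm_plates(config)
    compound_map, cm_truth = generate_compound_map(config, pm_truth, expr)
    query, ref, prot_truth = generate_proteomes(config, expr_truth=truth)
    for extra in (pw_truth, pm_truth, cm_truth, prot_truth):
        truth.merge(extra)
    return FixtureBundle(
        config=config,
        expression=expr,
        pathways=pathways,
        plates=plates,
        compound_map=compound_map,
        query_proteome=query,
        ref_proteome=ref,
        truth=truth,
    )
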