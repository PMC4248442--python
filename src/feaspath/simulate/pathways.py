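"""Pathway-definition fixture with exact, known feasibility labels.

Pathways are built *after* the expression fixture so that each pathway's
intended status holds exactly under the coverage rules: covered steps get at
least one expressed gene, uncovered steps get only unexpressed genes, and
the covered-step count is chosen to land in the intended coverage band
(feasible: 1, mostly: [0.75, 1), partial: (0, 0.75), inactive: 0).

The duplicate-gene sets from the expression fixture are planted as
alternative-gene steps of feasible pathways, mirroring isoenzyme boxes in a
pathway diagram.
"""

from __future__ import annotations

import numpy as np

from ..feasibility import PathwayDefinition, PathwayStep
from ..transcriptome import ExpressionArray, expression_flags, normalize_expression
from .config import FixtureConfig
from .truth import GroundTruth

_STREAM = 1
_PATHWAY_THEMES = (
    "biosynthesis",
    "degradation",
    "salvage",
    "interconversion",
    "assimilation",
)


def _coverage_count(status: str, n_steps: int, rng: np.random.Generator) -> int:
    if status == "feasible":
        return n_steps
    if status == "inactive":
        return 0
    if status == "mostly_expressed":
        valid = [c for c in range(1, n_steps) if 0.75 <= c / n_steps < 1.0]
    else:  # partially_expressed
        valid = [c for c in range(1, n_steps) if 0.0 < c / n_steps < 0.75]
    return int(rng.choice(valid))


def generate_pathways(
    config: FixtureConfig,
    expr: ExpressionArray,
    expr_truth: GroundTruth | None = None,
) -> tuple[list[PathwayDefinition], GroundTruth]:
    """Generate pathway definitions whose status labels hold by construction."""
    config.validate()
    rng = np.random.default_rng([_STREAM, config.seed])
    if expr.normalization_percentile is None:
        expr = normalize_expression(expr)
    flags = expression_flags(expr, expressed_percentile=config.expressed_percentile)
    expressed_pool = np.asarray(flags.index[flags["expressed"]])
    unexpressed_pool = np.asarray(flags.index[~flags["expressed"]])
    if len(expressed_pool) == 0 or len(unexpressed_pool) == 0:
        raise ValueError("expression fixture must contain both expressed and unexpressed genes")

    statuses = [
        status
        for status, count in sorted(config.pathway_composition.items())
        for _ in range(count)
    ]
    rng.shuffle(statuses)

    truth = GroundTruth()
    pathways: list[PathwayDefinition] = []
    feasible_ids: list[int] = []
    for i, status in enumerate(statuses):
        pid = f"PWY_{i + 1:04d}"
        n_steps = int(rng.integers(4, 16)) if status == "mostly_expressed" else int(
            rng.integers(3, 16)
        )
        covered = _coverage_count(status, n_steps, rng)
        covered_steps = set(rng.choice(n_steps, size=covered, replace=False).tolist())
        steps = []
        for s in range(n_steps):
            n_alt = int(rng.integers(1, 4))
            if s in covered_steps:
                genes = [str(rng.choice(expressed_pool))]
                genes += [str(g) for g in rng.choice(unexpressed_pool, size=n_alt - 1)]
            else:
                genes = [str(g) for g in rng.choice(unexpressed_pool, size=n_alt)]
            ec = (
                f"{rng.integers(1, 7)}.{rng.integers(1, 21)}"
                f".{rng.integers(1, 31)}.{rng.integers(1, 100)}"
            )
            steps.append(PathwayStep(step_index=s + 1, genes=sorted(set(genes)), ec=ec))
        name = f"{_PATHWAY_THEMES[i % len(_PATHWAY_THEMES)]} pathway {i + 1}"
        pathways.append(PathwayDefinition(pathway_id=pid, name=name, steps=steps))
        truth.pathway_status_by_id[pid] = status
        if status == "feasible":
            feasible_ids.append(i)

    # plant the duplicate-gene sets as alternative-gene steps of feasible
    # pathways: one member is above median (hence expressed), so the step
    # stays covered and the paralog resolver has something to resolve
    if expr_truth is not None and feasible_ids:
        for j, (_set_id, members) in enumerate(sorted(expr_truth.duplicate_sets.items())):
            pw = pathways[feasible_ids[j % len(feasible_ids)]]
            step = pw.steps[j % len(pw.steps)]
            step.genes = sorted(members)
    return pathways, truth
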