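"""Compound-to-network map fixture with class-consistent evidence.

Exactly ``n_mapped_compounds`` of the 284 PM conditions carry a network
entry metabolite (unique per compound); the rest are unmapped.  The
evidence attached to each mapped compound is consistent with its
ground-truth growth class under the utilization rules:

* high / moderate -- an annotated transporter plus expressed utilizing
  enzymes, or (for a minority) an inducible system whose enzymes are silent
  in the reference condition;
* none -- either no transporter at all or utilizing enzymes that are not
  expressed (and not inducible).

A transporter annotation list is generated alongside: 282 loci of which
exactly 60 are expressed in the reference condition.
"""

from __future__ import annotations

import numpy as np

from ..integration import CompoundMapping
from ..transcriptome import ExpressionArray, expression_flags, normalize_expression
from .config import FixtureConfig
from .plates import GLUCOSE_CONDITION
from .truth import GroundTruth

_STREAM = 3
N_TRANSPORTERS = 282
N_EXPRESSED_TRANSPORTERS = 60
_INDUCIBLE_FRACTION = 0.15


def generate_compound_map(
    config: FixtureConfig,
    plates_truth: GroundTruth,
    expr: ExpressionArray,
) -> tuple[dict[str, CompoundMapping], GroundTruth]:
    """Generate the compound map, transporter list and their ground truth."""
    config.validate()
    rng = np.random.default_rng([_STREAM, config.seed])
    if expr.normalization_percentile is None:
        expr = normalize_expression(expr)
    flags = expression_flags(expr, expressed_percentile=config.expressed_percentile)
    expressed_pool = np.asarray(flags.index[flags["expressed"]])
    unexpressed_pool = np.asarray(flags.index[~flags["expressed"]])

    conditions = sorted(plates_truth.growth_class_by_condition)
    if config.n_mapped_compounds > len(conditions):
        raise ValueError("n_mapped_compounds exceeds the number of test conditions")

    expressed_t = rng.choice(expressed_pool, size=N_EXPRESSED_TRANSPORTERS, replace=False)
    silent_t = rng.choice(
        unexpressed_pool, size=N_TRANSPORTERS - N_EXPRESSED_TRANSPORTERS, replace=False
    )
    transporters = sorted(np.concatenate([expressed_t, silent_t]).tolist())

    mapped_list = sorted(
        rng.choice(conditions, size=config.n_mapped_compounds, replace=False).tolist()
    )
    if config.n_mapped_compounds and GLUCOSE_CONDITION not in mapped_list:
        mapped_list[0] = GLUCOSE_CONDITION
    mapped = set(mapped_list)

    truth = GroundTruth(
        mapped_compounds=set(mapped),
        transporter_loci=transporters,
        expressed_transporters=set(str(t) for t in expressed_t),
    )

    table: dict[str, CompoundMapping] = {}
    for cond in conditions:
        if cond not in mapped:
            table[cond] = CompoundMapping(condition=cond)
            continue
        cls = plates_truth.growth_class_by_condition[cond]
        entry = [f"met:{cond.replace(' ', '-')}"]
        steps = int(rng.integers(1, 4)) if rng.random() < 0.2 else 0
        if cls in ("high", "moderate"):
            transporter = [str(rng.choice(transporters))]
            if rng.random() < _INDUCIBLE_FRACTION:
                enzymes = sorted(
                    str(g) for g in rng.choice(unexpressed_pool, size=2, replace=False)
                )
                rec = CompoundMapping(cond, entry, transporter, enzymes, True, steps)
            else:
                enzymes = sorted(
                    str(g) for g in rng.choice(expressed_pool, size=int(rng.integers(1, 4)), replace=False)
                )
                rec = CompoundMapping(cond, entry, transporter, enzymes, False, steps)
        else:  # no growth: break one clause of the utilization rule
            if rng.random() < 0.5:
                rec = CompoundMapping(
                    cond,
                    entry,
                    [],
                    sorted(str(g) for g in rng.choice(unexpressed_pool, size=2, replace=False)),
                    False,
                    steps,
                )
            else:
                rec = CompoundMapping(
                    cond,
                    entry,
                    [str(rng.choice(transporters))],
                    sorted(str(g) for g in rng.choice(unexpressed_pool, size=2, replace=False)),
                    False,
                    steps,
                )
        table[cond] = rec
    return table, truth
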