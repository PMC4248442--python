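"""Expression-coverage pathway feasibility calls and paralog resolution.

A metabolic pathway is an ordered list of reaction steps, each carrying one
or more alternative gene loci (isoenzymes / duplicate genes).  A step is
satisfied when at least one of its alternatives is expressed; pathway
coverage is the satisfied fraction of steps.  Status rules (thresholds
configurable):

* ``inactive``             -- no member gene of any step is expressed;
* ``feasible``             -- coverage == 1 (every step satisfied);
* ``mostly_expressed``     -- 0.75 <= coverage < 1;
* ``partially_expressed``  -- otherwise (0 < coverage < 0.75).

This is purely expression-based feasibility: no stoichiometry and no flux
assumptions.  Loci missing from the expression table count as not expressed
(absence of evidence penalizes coverage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .transcriptome import ExpressionArray, expression_flags

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayStep",
    "PathwayDefinition",
    "FeasibilityCall",
    "ParalogCall",
    "PathwayFeasibilityClassifier",
    "classify_pathway",
    "resolve_paralogs",
    "feasibility_report",
    "transporter_screen",
    "STATUSES",
]

FEASIBLE = "feasible"
MOSTLY = "mostly_expressed"
PARTIAL = "partially_expressed"
INACTIVE = "inactive"
STATUSES = (FEASIBLE, MOSTLY, PARTIAL, INACTIVE)


@dataclass
class PathwayStep:
    step_index: int
    genes: list[str]
    ec: str | None = None

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"step {self.step_index} has an empty gene list")


@dataclass
class PathwayDefinition:
    pathway_id: str
    name: str
    steps: list[PathwayStep]

    def __post_init__(self):
        if not self.steps:
            raise ValueError(f"pathway {self.pathway_id} has no steps")
        indices = [s.step_index for s in self.steps]
        if indices != list(range(1, len(self.steps) + 1)):
            raise ValueError(
                f"pathway {self.pathway_id}: step indices must be contiguous from 1"
            )

    @property
    def genes(self) -> set[str]:
        return {g for s in self.steps for g in s.genes}


@dataclass
class FeasibilityCall:
    pathway_id: str
    coverage: float
    status: str
    active_gene_per_step: dict[int, str] = field(default_factory=dict)  # step -> locus or "none"


@dataclass
class ParalogCall:
    """Active gene(s) resolved for one alternative-gene set."""

    loci: list[str]
    status: str  # "resolved", "ambiguous" (several above median) or "unresolved"


def _flag_row(flags: pd.DataFrame, locus: str) -> tuple[bool, bool, float]:
    """(expressed, above_median, norm_avg) with unmeasured loci not expressed."""
    if locus not in flags.index:
        logger.warning("locus %s absent from expression table; treated as not expressed", locus)
        return False, False, float("-inf")
    row = flags.loc[locus]
    return bool(row["expressed"]), bool(row["above_median"]), float(row["norm_avg"])


def resolve_paralogs(step_genes: list[str], flags: pd.DataFrame) -> ParalogCall:
    """Pick the active gene(s) from a set of alternatives for one reaction.

    All above-median loci are returned (more than one means the cell keeps
    several duplicates switched on simultaneously).  If none is above median
    but some are expressed, the single highest-expressed locus is returned.
    Ties are broken lexicographically, so the call is deterministic.
    """
    if not step_genes:
        raise ValueError("empty gene list")
    info = {g: _flag_row(flags, g) for g in sorted(step_genes)}
    above = [g for g, (_e, a, _v) in info.items() if a]
    if above:
        status = "resolved" if len(above) == 1 else "ambiguous"
        return ParalogCall(loci=above, status=status)
    expressed = [g for g, (e, _a, _v) in info.items() if e]
    if expressed:
        top = max(expressed, key=lambda g: (info[g][2], g))
        # max with (value, locus) key: on exact value ties the later locus
        # wins, so flip to lexicographic-first deterministically
        tied = [g for g in expressed if info[g][2] == info[top][2]]
        return ParalogCall(loci=[min(tied)], status="resolved")
    return ParalogCall(loci=[], status="unresolved")


def classify_pathway(
    pw: PathwayDefinition,
    flags: pd.DataFrame,
    mostly_min: float = 0.75,
) -> FeasibilityCall:
    """Coverage-based feasibility call for one pathway.

    ``flags`` is the per-locus table from
    :func:`feaspath.transcriptome.expression_flags`.
    """
    covered = 0
    active: dict[int, str] = {}
    any_expressed = False
    for step in pw.steps:
        call = resolve_paralogs(step.genes, flags)
        if call.loci:
            covered += 1
            any_expressed = True
            active[step.step_index] = call.loci[0]
        else:
            active[step.step_index] = "none"
    coverage = covered / len(pw.steps)
    if not any_expressed:
        status = INACTIVE
    elif coverage == 1.0:
        status = FEASIBLE
    elif coverage >= mostly_min:
        status = MOSTLY
    else:
        status = PARTIAL
    return FeasibilityCall(
        pathway_id=pw.pathway_id,
        coverage=coverage,
        status=status,
        active_gene_per_step=active,
    )


class PathwayFeasibilityClassifier(BaseEstimator):
    """Classify pathway feasibility from a normalized expression array.

    ``fit`` derives per-gene expression flags from the array (expressed =
    averaged normalized value strictly above the ``expressed_percentile``
    cutoff); ``predict`` maps pathway definitions to status strings and
    ``decision_calls`` returns the full per-pathway calls.

    Parameters
    ----------
    expressed_percentile : float, default 25.0
        Percentile of the averaged normalized values above which a gene
        counts as expressed.
    mostly_min : float, default 0.75
        Minimum coverage for the ``mostly_expressed`` status.
    """

    def __init__(self, expressed_percentile: float = 25.0, mostly_min: float = 0.75):
        self.expressed_percentile = expressed_percentile
        self.mostly_min = mostly_min

    def fit(self, X: ExpressionArray, y=None):
        if not 0 < self.mostly_min < 1:
            raise ValueError("mostly_min must lie in (0, 1)")
        self.flags_ = expression_flags(X, expressed_percentile=self.expressed_percentile)
        return self

    def decision_calls(self, pathways: list[PathwayDefinition]) -> list[FeasibilityCall]:
        check_is_fitted(self, "flags_")
        return [classify_pathway(pw, self.flags_, self.mostly_min) for pw in pathways]

    def predict(self, pathways: list[PathwayDefinition]) -> list[str]:
        return [c.status for c in self.decision_calls(pathways)]


def feasibility_report(calls: list[FeasibilityCall]) -> tuple[dict[str, int], pd.DataFrame]:
    """Status counts plus a per-pathway table of coverage and active genes."""
    ids = [c.pathway_id for c in calls]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate pathway_id in feasibility calls")
    counts = {s: 0 for s in STATUSES}
    for c in calls:
        counts[c.status] += 1
    table = pd.DataFrame(
        {
            "pathway_id": ids,
            "coverage": [c.coverage for c in calls],
            "status": [c.status for c in calls],
            "active_genes": [
                ";".join(f"{k}:{v}" for k, v in sorted(c.active_gene_per_step.items()))
                for c in calls
            ],
        }
    )
    return counts, table


def transporter_screen(transporters: list[str], flags: pd.DataFrame) -> list[str]:
    """Subset of transporter loci whose expressed flag is true.

    Loci absent from the expression table are logged and treated as not
    expressed.
    """
    return [t for t in transporters if _flag_row(flags, t)[0]]
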