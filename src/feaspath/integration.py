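"""Nutrient-to-network mapping, utilization prediction and species comparison.

A PM condition can be rationalized when its nutrient maps onto the metabolic
network (it is a network metabolite, or a few conversion steps away).  For a
mapped compound, whether it supports growth is predicted from two pieces of
evidence: (a) an annotated transporter for uptake, and (b) expression of the
utilizing enzymes -- with an explicit ``inducible`` escape hatch for
transporter/enzyme systems that are silent in the reference condition but
induced by their substrate (e.g. the fructose PTS cluster or the mannitol
transporter).  Predictions are compared against the observed growth calls,
and utilization matrices of two species are compared row-wise, excluding
rows with missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .feasibility import FeasibilityCall

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundMapping",
    "MappingLookup",
    "UtilizationPredictor",
    "map_compound",
    "count_mapped",
    "predict_utilization",
    "concordance",
    "compare_species",
    "network_overlay",
    "load_utilization_matrix",
    "packaged_mtb_msm_table",
]

GROWTH = "Y"
NO_GROWTH = "X"
NOT_AVAILABLE = "NA"
_CALL_ALIASES = {"✓": GROWTH, "Y": GROWTH, "X": NO_GROWTH, "NA": NOT_AVAILABLE}


@dataclass
class CompoundMapping:
    """How one PM nutrient enters the metabolic network."""

    condition: str
    entry_metabolites: list[str] = field(default_factory=list)
    transporter_loci: list[str] = field(default_factory=list)
    enzyme_loci: list[str] = field(default_factory=list)
    inducible: bool = False
    steps_to_network: int = 0

    @property
    def mapped(self) -> bool:
        return bool(self.entry_metabolites)


@dataclass
class MappingLookup:
    condition: str
    mapped: bool
    record: CompoundMapping | None


def _norm_name(name: str) -> str:
    """Exact matching after case-folding and whitespace normalization."""
    return " ".join(name.split()).casefold()


def map_compound(condition: str, table: dict[str, CompoundMapping]) -> MappingLookup:
    """Look one condition up in the compound map.

    A condition present in the table with no entry metabolites is *unmapped*;
    a condition absent from the table altogether is a lookup error.
    """
    index = {_norm_name(k): v for k, v in table.items()}
    rec = index.get(_norm_name(condition))
    if rec is None:
        raise KeyError(f"condition {condition!r} absent from the compound map")
    return MappingLookup(condition=condition, mapped=rec.mapped, record=rec if rec.mapped else None)


def count_mapped(table: dict[str, CompoundMapping]) -> int:
    return sum(1 for rec in table.values() if rec.mapped)


class UtilizationPredictor(BaseEstimator):
    """Rule-based growth-support prediction for mapped nutrients.

    ``fit`` takes the per-gene expression flags (from
    :func:`feaspath.transcriptome.expression_flags`) and, optionally, the
    set of loci annotated as transporters.  ``predict`` applies, per
    compound:

    ``supported``  iff  at least one transporter locus is annotated
                   AND (at least one utilizing enzyme is expressed OR the
                   system is flagged inducible);
    ``not_supported`` otherwise, with a rationale naming the failed clause;
    ``unknown`` for unmapped compounds.
    """

    def __init__(self):
        pass

    def fit(self, flags: pd.DataFrame, transporter_annotation=None):
        self.flags_ = flags
        self.transporter_annotation_ = (
            set(transporter_annotation) if transporter_annotation is not None else None
        )
        return self

    def _transporter_ok(self, rec: CompoundMapping) -> bool:
        loci = rec.transporter_loci
        if not loci:
            return False
        if self.transporter_annotation_ is None:
            return True
        return any(t in self.transporter_annotation_ for t in loci)

    def _enzymes_expressed(self, rec: CompoundMapping) -> list[str]:
        idx = self.flags_.index
        return [
            g
            for g in rec.enzyme_loci
            if g in idx and bool(self.flags_.loc[g, "expressed"])
        ]

    def predict_one(self, rec: CompoundMapping) -> tuple[str, str]:
        check_is_fitted(self, "flags_")
        if not rec.mapped:
            return "unknown", "compound not mapped onto the metabolic network"
        if not self._transporter_ok(rec):
            return "not_supported", "no annotated transporter for uptake"
        expressed = self._enzymes_expressed(rec)
        if expressed:
            return "supported", f"transporter annotated; utilizing enzyme(s) expressed: {','.join(expressed)}"
        if rec.inducible:
            return "supported", "transporter annotated; utilization system flagged inducible"
        return "not_supported", "utilizing enzymes virtually non-expressed"

    def predict(self, mappings) -> pd.DataFrame:
        if isinstance(mappings, dict):
            mappings = list(mappings.values())
        rows = []
        for rec in mappings:
            pred, why = self.predict_one(rec)
            rows.append((rec.condition, pred, why))
        return pd.DataFrame(rows, columns=["condition", "prediction", "rationale"])


def predict_utilization(
    mapping: CompoundMapping, flags: pd.DataFrame, transporter_annotation=None
) -> tuple[str, str]:
    """Predict one compound; returns (prediction, rationale)."""
    return (
        UtilizationPredictor()
        .fit(flags, transporter_annotation=transporter_annotation)
        .predict_one(mapping)
    )


def concordance(predictions: pd.DataFrame, growth_calls: pd.DataFrame) -> dict:
    """Agreement between rule-based predictions and observed growth calls.

    ``supported`` is scored against observed growth in {high, moderate},
    ``not_supported`` against no growth; ``unknown`` (unmapped) rows are
    excluded and counted separately.  Returns the 2x2 table, the agreement
    fraction over mapped conditions, and the unmapped count.
    """
    obs = growth_calls.set_index("condition")["growth_class"]
    merged = predictions.set_index("condition").join(obs, how="inner")
    known = merged[merged["prediction"] != "unknown"]
    grows = known["growth_class"].isin(["high", "moderate"])
    supported = known["prediction"] == "supported"
    table = {
        "supported_grows": int((supported & grows).sum()),
        "supported_no_growth": int((supported & ~grows).sum()),
        "not_supported_grows": int((~supported & grows).sum()),
        "not_supported_no_growth": int((~supported & ~grows).sum()),
    }
    n = len(known)
    agreement = (table["supported_grows"] + table["not_supported_no_growth"]) / n if n else float("nan")
    return {
        "table": table,
        "agreement": agreement,
        "n_mapped": n,
        "n_unmapped": int((merged["prediction"] == "unknown").sum()),
    }


def _canonical_call(value: str) -> str:
    v = str(value).strip()
    call = _CALL_ALIASES.get(v, _CALL_ALIASES.get(v.upper()))
    if call is None:
        raise ValueError(f"unrecognized utilization call {value!r}")
    return call


def load_utilization_matrix(source) -> pd.DataFrame:
    """Read a species x nutrient utilization matrix from TSV.

    Expected columns: ``source``, ``type`` (carbon/nitrogen), one
    ``<species>_call`` column per species with cells in {Y or ✓, X, NA}, and
    optionally ``differential``.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    for col in df.columns:
        if col.endswith("_call"):
            df[col] = df[col].map(_canonical_call)
    if "differential" in df.columns:
        df["differential"] = df["differential"].str.lower().isin(["true", "1", "yes"])
    return df


def packaged_mtb_msm_table() -> pd.DataFrame:
    """The packaged Mtb-vs-Msm nutrient-utilization matrix."""
    ref = resources.files("feaspath.data").joinpath("mtb_msm_utilization.tsv")
    with resources.as_file(ref) as path:
        return load_utilization_matrix(path)


def compare_species(matrix: pd.DataFrame, species_a: str, species_b: str) -> dict:
    """Row-wise comparison of growth calls between two species.

    Rows with NA for either species are excluded from every count.
    ``common`` counts rows where both grow; ``unique_a``/``unique_b`` count
    rows where exactly one grows; ``both_no_growth`` rows support neither.
    The differential rows (one-sided growth) are returned for reporting.
    """
    cols = {}
    for sp in (species_a, species_b):
        col = f"{sp.lower()}_call"
        if col not in matrix.columns:
            raise ValueError(f"species {sp!r} not present in the utilization matrix")
        cols[sp] = col
    a, b = matrix[cols[species_a]], matrix[cols[species_b]]
    usable = (a != NOT_AVAILABLE) & (b != NOT_AVAILABLE)
    m = matrix[usable]
    a, b = a[usable], b[usable]
    common = (a == GROWTH) & (b == GROWTH)
    unique_a = (a == GROWTH) & (b == NO_GROWTH)
    unique_b = (b == GROWTH) & (a == NO_GROWTH)
    both_no = (a == NO_GROWTH) & (b == NO_GROWTH)
    return {
        "common": int(common.sum()),
        "unique_a": int(unique_a.sum()),
        "unique_b": int(unique_b.sum()),
        "both_no_growth": int(both_no.sum()),
        "n_usable": int(usable.sum()),
        "differential": m[unique_a | unique_b][["source", "type"]].assign(
            grows=[species_a if ua else species_b for ua in unique_a[unique_a | unique_b]]
        ),
    }


def network_overlay(
    calls: list[FeasibilityCall], compound_table: dict[str, CompoundMapping]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for a Fig-6-style network rendering.

    Nodes are entry metabolites of mapped PM compounds (flagged as PM-probed
    entry points); edges are pathway reaction steps with the resolved active
    gene and an expressed flag.  The tables are plain DataFrames importable
    by standard graph tools; see :func:`overlay_graph` for a networkx view.
    """
    node_rows = []
    for rec in compound_table.values():
        for met in rec.entry_metabolites:
            node_rows.append((met, rec.condition, True, True))
    nodes = pd.DataFrame(
        node_rows, columns=["metabolite", "condition", "pm_probed", "entry_point"]
    )
    edge_rows = []
    for call in calls:
        for step, gene in sorted(call.active_gene_per_step.items()):
            edge_rows.append(
                (call.pathway_id, step, gene, gene != "none", call.status)
            )
    edges = pd.DataFrame(
        edge_rows,
        columns=["pathway_id", "step_index", "gene", "expressed", "pathway_status"],
    )
    return nodes, edges


def overlay_graph(nodes: pd.DataFrame, edges: pd.DataFrame) -> nx.Graph:
    """Assemble the overlay tables into a networkx graph for rendering."""
    g = nx.Graph()
    for r in nodes.itertuples():
        g.add_node(r.metabolite, kind="metabolite", pm_probed=r.pm_probed, condition=r.condition)
    for r in edges.itertuples():
        u = f"{r.pathway_id}:s{r.step_index}"
        v = f"{r.pathway_id}:s{r.step_index + 1}"
        g.add_edge(u, v, gene=r.gene, expressed=r.expressed, pathway=r.pathway_id)
    return g
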