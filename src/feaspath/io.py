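"""Readers and writers for the pipeline's plain-text formats.

Formats: TSV expression tables, JSON pathway definitions, long-format CSV
plate kinetics with a CSV plate map, TSV compound maps, TSV utilization
matrices, FASTA proteomes with a TSV annotation sidecar, and a JSON dump of
fixture ground truth.  All writers are deterministic: the same in-memory
objects produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import ProteinRecord
from .feasibility import FeasibilityCall, PathwayDefinition, PathwayStep
from .integration import CompoundMapping
from .phenome import PlateSet
from .simulate.truth import GroundTruth
from .transcriptome import ExpressionArray

__all__ = [
    "write_expression_tsv",
    "read_expression_tsv",
    "write_pathways_json",
    "read_pathways_json",
    "write_kinetics_csv",
    "write_plate_map_csv",
    "read_plate_set",
    "write_compound_map_tsv",
    "read_compound_map_tsv",
    "write_proteome_fasta",
    "read_proteome_fasta",
    "write_annotation_sidecar",
    "write_ground_truth_json",
    "write_feasibility_report",
]

_LIST_SEP = ";"


def write_expression_tsv(array: ExpressionArray, path) -> None:
    array.data.to_csv(path, sep="\t", index=True)


def read_expression_tsv(path) -> ExpressionArray:
    data = pd.read_csv(path, sep="\t", index_col="gene_locus")
    norm_cols = tuple(c for c in data.columns if c.startswith("norm_rep"))
    raw_cols = tuple(c for c in data.columns if c.startswith("raw_rep"))
    return ExpressionArray(
        data=data,
        normalization_percentile=None if not norm_cols else -1,
        raw_columns=raw_cols,
        norm_columns=norm_cols or ("norm_rep1", "norm_rep2"),
    )


def write_pathways_json(pathways: list[PathwayDefinition], path) -> None:
    payload = [
        {
            "pathway_id": pw.pathway_id,
            "name": pw.name,
            "steps": [
                {"step_index": s.step_index, "ec": s.ec, "genes": s.genes}
                for s in pw.steps
            ],
        }
        for pw in pathways
    ]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_pathways_json(path) -> list[PathwayDefinition]:
    payload = json.loads(Path(path).read_text())
    return [
        PathwayDefinition(
            pathway_id=p["pathway_id"],
            name=p.get("name", p["pathway_id"]),
            steps=[
                PathwayStep(step_index=s["step_index"], genes=s["genes"], ec=s.get("ec"))
                for s in p["steps"]
            ],
        )
        for p in payload
    ]


def write_kinetics_csv(plate_set: PlateSet, path) -> None:
    plate_set.kinetics.to_csv(path, index=False)


def write_plate_map_csv(plate_set: PlateSet, path) -> None:
    plate_set.plate_map.to_csv(path, index=False)


def read_plate_set(kinetics_path, plate_map_path) -> PlateSet:
    return PlateSet(
        kinetics=pd.read_csv(kinetics_path),
        plate_map=pd.read_csv(plate_map_path),
    )


def write_compound_map_tsv(table: dict[str, CompoundMapping], path) -> None:
    rows = [
        {
            "condition": rec.condition,
            "entry_metabolites": _LIST_SEP.join(rec.entry_metabolites),
            "transporter_loci": _LIST_SEP.join(rec.transporter_loci),
            "enzyme_loci": _LIST_SEP.join(rec.enzyme_loci),
            "inducible": rec.inducible,
            "steps_to_network": rec.steps_to_network,
        }
        for _cond, rec in sorted(table.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _split(cell) -> list[str]:
    if pd.isna(cell) or not str(cell):
        return []
    return str(cell).split(_LIST_SEP)


def read_compound_map_tsv(path) -> dict[str, CompoundMapping]:
    df = pd.read_csv(path, sep="\t")
    table = {}
    for r in df.itertuples():
        table[r.condition] = CompoundMapping(
            condition=r.condition,
            entry_metabolites=_split(r.entry_metabolites),
            transporter_loci=_split(r.transporter_loci),
            enzyme_loci=_split(r.enzyme_loci),
            inducible=bool(r.inducible),
            steps_to_network=int(r.steps_to_network),
        )
    return table


def write_proteome_fasta(proteome: list[ProteinRecord], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.locus, description="")
        for p in proteome
    ]
    SeqIO.write(records, path, "fasta")


def read_proteome_fasta(path, annotation_sidecar=None) -> list[ProteinRecord]:
    ann = {}
    if annotation_sidecar is not None:
        side = pd.read_csv(annotation_sidecar, sep="\t")
        for r in side.itertuples():
            coords = None
            if not pd.isna(r.start):
                coords = (int(r.start), int(r.end), str(r.strand))
            ann[r.locus] = {
                "category": r.category if not pd.isna(r.category) else "unassigned",
                "ec": None if pd.isna(r.ec) else str(r.ec),
                "coordinates": coords,
            }
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        extra = ann.get(rec.id, {})
        out.append(
            ProteinRecord(
                locus=rec.id,
                sequence=str(rec.seq),
                category=extra.get("category", "unassigned"),
                ec=extra.get("ec"),
                coordinates=extra.get("coordinates"),
            )
        )
    return out


def write_annotation_sidecar(proteome: list[ProteinRecord], path) -> None:
    rows = []
    for p in proteome:
        start, end, strand = p.coordinates if p.coordinates else (None, None, None)
        rows.append(
            {
                "locus": p.locus,
                "category": p.category,
                "ec": p.ec,
                "start": start,
                "end": end,
                "strand": strand,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {
            (k if isinstance(k, str) else "|".join(map(str, k))): _jsonable(v)
            for k, v in sorted(obj.items())
        }
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        name: _jsonable(getattr(truth, name))
        for name in truth.__dataclass_fields__
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def write_feasibility_report(
    counts: dict[str, int], table: pd.DataFrame, report_path, summary_path
) -> None:
    table.to_csv(report_path, sep="\t", index=False)
    Path(summary_path).write_text(json.dumps(counts, indent=1, sort_keys=True) + "\n")
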