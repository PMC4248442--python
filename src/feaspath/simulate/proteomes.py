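"""Desk-scale proteome pair fixture for annotation transfer.

A reference proteome (annotated with functional categories and EC numbers)
and a query proteome containing: one point-mutated ortholog per reference
protein, paralog pairs (a second, lightly mutated within-proteome copy of
some orthologs, named after the expression fixture's duplicate-gene sets
when available), and a few unmatchable random sequences.  Substitution-only
mutation keeps the target identity of each pair analytic: 100 x (1 - rate)
in expectation, with the realized value recorded in the ground truth.
"""

from __future__ import annotations

import numpy as np

from ..annotation import ProteinRecord
from .config import FixtureConfig
from .truth import GroundTruth

_STREAM = 4
_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_CATEGORIES = (
    "intermediary metabolism and respiration",
    "cell wall and cell processes",
    "lipid metabolism",
    "information pathways",
    "regulatory proteins",
    "conserved hypotheticals",
)
_MIN_LEN, _MAX_LEN = 60, 120
_GENOME_BP = 7_000_000
_N_UNMATCHABLE = 6


def _random_protein(rng: np.random.Generator) -> str:
    length = int(rng.integers(_MIN_LEN, _MAX_LEN + 1))
    return "".join(rng.choice(_AA20, size=length))


def _mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    allowed: np.ndarray | None = None,
    at_least_one: bool = False,
) -> tuple[str, float, np.ndarray]:
    """Substitute residues at ``rate``; returns (sequence, identity %, hit mask).

    ``allowed`` restricts the positions eligible for substitution (used so a
    paralog copy only touches positions its template left intact, keeping its
    identity to the original reference strictly lower than the template's).
    """
    residues = np.array(list(seq))
    hit = rng.random(len(residues)) < rate
    if allowed is not None:
        hit &= allowed
    if at_least_one and not hit.any():
        pool = np.flatnonzero(allowed) if allowed is not None else np.arange(len(residues))
        hit[rng.choice(pool)] = True
    for i in np.flatnonzero(hit):
        choices = _AA20[_AA20 != residues[i]]
        residues[i] = rng.choice(choices)
    identity = 100.0 * (1.0 - hit.sum() / len(residues))
    return "".join(residues), identity, hit


def generate_proteomes(
    config: FixtureConfig, expr_truth: GroundTruth | None = None
) -> tuple[list[ProteinRecord], list[ProteinRecord], GroundTruth]:
    """Generate (query, reference) proteomes plus ground truth."""
    config.validate()
    rng = np.random.default_rng([_STREAM, config.seed])
    truth = GroundTruth()

    ref: list[ProteinRecord] = []
    for i in range(config.n_ref_proteins):
        ec = None
        if rng.random() < 0.4:
            ec = (
                f"{rng.integers(1, 7)}.{rng.integers(1, 21)}"
                f".{rng.integers(1, 31)}.{rng.integers(1, 100)}"
            )
        start = int(rng.integers(1, _GENOME_BP))
        ref.append(
            ProteinRecord(
                locus=f"MTB_{i + 1:04d}",
                sequence=_random_protein(rng),
                category=_CATEGORIES[i % len(_CATEGORIES)],
                ec=ec,
                coordinates=(start, start + 3000, "+" if rng.random() < 0.5 else "-"),
            )
        )

    n_par = config.n_duplicate_sets
    if expr_truth is not None and expr_truth.duplicate_sets:
        pair_names = [
            tuple(members)
            for _sid, members in sorted(expr_truth.duplicate_sets.items())
        ][:n_par]
    else:
        pair_names = [
            (f"MSMEG_D{2 * s + 1:03d}", f"MSMEG_D{2 * s + 2:03d}") for s in range(n_par)
        ]
    if len(pair_names) < n_par:
        raise ValueError("not enough duplicate sets to embed the paralog pairs")
    if config.n_ref_proteins < n_par:
        raise ValueError("need at least as many reference proteins as paralog sets")

    query: list[ProteinRecord] = []
    for i, r in enumerate(ref):
        if i < n_par:
            locus_a, locus_b = pair_names[i]
        else:
            locus_a = f"MSMEG_Q{i + 1:03d}"
        seq_a, ident_a, hit_a = _mutate(r.sequence, config.ortholog_mutation_rate, rng)
        start = int(rng.integers(1, _GENOME_BP))
        query.append(
            ProteinRecord(locus=locus_a, sequence=seq_a, coordinates=(start, start + 3000, "+"))
        )
        truth.ortholog_pairs[locus_a] = r.locus
        truth.ortholog_target_identity[locus_a] = ident_a
        truth.category_by_locus[locus_a] = r.category
        if i < n_par:
            seq_b, ident_b, _hit_b = _mutate(
                seq_a, config.paralog_mutation_rate, rng, allowed=~hit_a, at_least_one=True
            )
            start_b = int(rng.integers(1, _GENOME_BP))
            query.append(
                ProteinRecord(
                    locus=locus_b, sequence=seq_b, coordinates=(start_b, start_b + 3000, "+")
                )
            )
            truth.protein_paralog_sets[f"dup_{i + 1:02d}"] = sorted([locus_a, locus_b])
            truth.ortholog_target_identity[locus_b] = ident_b
            truth.category_by_locus[locus_b] = "unassigned"

    for u in range(_N_UNMATCHABLE):
        locus = f"MSMEG_U{u + 1:02d}"
        query.append(ProteinRecord(locus=locus, sequence=_random_protein(rng)))
        truth.category_by_locus[locus] = "unassigned"

    return query, ref, truth
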