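"""Two-replicate expression-array fixture with embedded duplicate-gene sets.

Each gene's log2 intensity is a shared standard-normal signal plus
independent per-replicate Gaussian noise; the noise fraction of the total
variance is ``replicate_noise_ratio_expr``, so the expected Pearson
correlation between replicates equals the signal fraction (0.99 by
default).  Raw intensities are obtained by exponentiation around a log2
centre of 8, hence always strictly positive.

The duplicate-gene sets are pairs of loci planted well above (+2 sd) and
well below (-2 sd) the signal centre, so exactly one member of each set
ends up above the array median.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..transcriptome import ExpressionArray
from .config import FixtureConfig
from .truth import GroundTruth

_LOG2_CENTER = 8.0
_DUP_OFFSET = 2.0
_DUP_SPREAD = 0.3
_STREAM = 0  # rng stream id for this generator


def gene_loci(n_genes: int) -> list[str]:
    return [f"MSMEG_{i:04d}" for i in range(1, n_genes + 1)]


def generate_expression(config: FixtureConfig) -> tuple[ExpressionArray, GroundTruth]:
    """Generate the replicate expression arrays and their ground truth."""
    config.validate()
    rng = np.random.default_rng([_STREAM, config.seed])
    n = config.n_genes
    ratio = config.replicate_noise_ratio_expr
    signal_sd = np.sqrt(1.0 - ratio)
    noise_sd = np.sqrt(ratio)

    loci = gene_loci(n)
    signal = rng.normal(0.0, signal_sd, n)

    truth = GroundTruth()
    k = config.n_duplicate_sets
    dup_idx = rng.choice(n, size=2 * k, replace=False)
    for s in range(k):
        i_active, i_silent = int(dup_idx[2 * s]), int(dup_idx[2 * s + 1])
        signal[i_active] = _DUP_OFFSET + abs(rng.normal(0.0, _DUP_SPREAD))
        signal[i_silent] = -_DUP_OFFSET - abs(rng.normal(0.0, _DUP_SPREAD))
        set_id = f"dup_{s + 1:02d}"
        members = sorted([loci[i_active], loci[i_silent]])
        truth.duplicate_sets[set_id] = members
        truth.active_paralog_by_set[set_id] = loci[i_active]

    noise = rng.normal(0.0, noise_sd, (n, 2)) if noise_sd > 0 else np.zeros((n, 2))
    log2 = _LOG2_CENTER + signal[:, None] + noise
    raw = np.exp2(log2)

    data = pd.DataFrame(
        {
            "probe_id": [f"P{i:05d}" for i in range(1, n + 1)],
            "raw_rep1": raw[:, 0],
            "raw_rep2": raw[:, 1],
        },
        index=pd.Index(loci, name="gene_locus"),
    )
    return ExpressionArray(data=data), truth
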