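# Methods

This note records the models, parameter choices and numerical conventions
behind `feaspath`, and what the synthetic fixtures do and do not establish
about real data.

## Percentile normalization and expression flags

Arrays are assumed to arrive as processed positive intensities (dye
normalization and background subtraction already applied upstream). The
package log2-transforms and centres each array at the p-th percentile of its
own log-intensity distribution, p ∈ {25, 50, 75}. Percentiles use linear
interpolation between order statistics (the 0-based index p·(n−1)/100 of the
sorted values, numpy's default). This estimator is the reason the
"count above the 90th percentile of 6,761 distinct values" is exactly 676:
0.9·6760 is an integer, the percentile equals an order statistic, and the
strict count above it is n − 1 − 6084. The log base is a convention; any
fixed base yields the same flags because the centring removes it as a shift.

Replicates are averaged arithmetically after per-array centring. Two per-gene
flags gate the downstream modules, both strict comparisons so constant
arrays yield all-False:

* `expressed`: averaged value > 25th-percentile cutoff. The choice of the
  25th cut as the detection threshold is deliberately permissive (an array
  quantile, not an absolute intensity) and is exposed as
  `expressed_percentile` everywhere it is consumed, because reasonable
  pipelines differ here and the feasibility counts are sensitive to it.
* `above_median`: averaged value > median; used only for picking the active
  member of a duplicate-gene set.

Ties are resolved by strict `>` throughout, and loci missing from the
expression table count as not expressed rather than being excluded, so
missing evidence penalizes pathway coverage (conservative feasibility).

## Pathway feasibility

Coverage is the fraction of steps with at least one expressed alternative;
statuses are: inactive (no member gene expressed at all), feasible
(coverage 1), mostly_expressed (coverage ∈ [0.75, 1)), partially_expressed
otherwise. The 0.75 boundary is a package default (`mostly_min`), chosen to
give the "most genes expressed" band a concrete meaning; it is configurable
because the verbal categories it formalizes have no canonical cutoffs.
A step with any expressed alternative counts as fully satisfied — alternate
genes at a step are isoenzymes, one suffices.

Paralog resolution returns every above-median alternative (several
simultaneously expressed duplicates are reported as `ambiguous`, not
collapsed), falls back to the single highest-expressed locus when no
alternative clears the median, and reports `unresolved` otherwise.
Lexicographic tie-breaks make the calls deterministic.

## Homology and annotation transfer

Pairwise identity is computed from an explicit Needleman–Wunsch global
alignment with match +1, mismatch −1, linear gap −2 (Biopython's
`PairwiseAligner`); identity = identical columns / full alignment length.
BLAST-style heuristics are deliberately avoided at this scale: the DP
alignment is exact and reproducible across versions. Two conventions are
worth spelling out:

* *Identity, not similarity.* The 30%/50% homology thresholds are applied to
  percent identity; no substitution matrix is used.
* *Symmetry.* Co-optimal alignments can disagree in matched-column count, so
  the implementation canonicalizes argument order (lexicographic) before
  aligning; the reported value is therefore symmetric and deterministic.

Bidirectional best hits require each partner to be the other's *unique*
top-identity hit, with ties declared when identities agree after rounding to
4 decimals; tied tops disqualify the locus. Category transfer gives unpaired
loci "unassigned" and resolves multi-category conflicts by a fixed priority
list (specific metabolism first, mobile elements last) — a deterministic
stand-in for manual curation. Paralog sets are connected components of the
all-vs-all identity graph at or above the threshold (50% default), with
genomic separation in bp reported when coordinates are available.

## PM kinetics, discretization and clustering

Each curve is reduced without fitting: max signal, trapezoidal AUC on the
native grid, linearly interpolated 48-h value, lag = first time above 10% of
max (undefined for curves that never leave zero). A logistic fit is not
needed for classification and is deliberately not on the critical path.

Discretization compares each condition's replicate-mean metrics with the
plate negative control and the D-glucose well of the carbon plate (the
canonical validation well): none if max − max_neg < Δ_none = 50 OU, high if
AUC ≥ ρ_high = 0.6 × anchor AUC, moderate otherwise. Both thresholds are
package defaults — OmniLog's own cutoffs are proprietary — and sit roughly
mid-band on the synthetic fixture: the moderate/high AUC ratio is ≈0.41 and
the weakest high well reaches ≈0.86 of the anchor, so ρ_high tolerates
roughly ±40% perturbation; Δ_none tolerates far more. The classifier is
monotone: pointwise-raising a curve can only promote its class.

Condition clustering uses distance 1 − Pearson r with average linkage
(scipy), flat labels by `maxclust`, and Newick export via scikit-bio.
Because the Pearson distance is shape-based, raw 15-min point noise would
dominate it for low-signal wells; `condition_features` therefore averages
the replicate-mean curves into 4-h bins before clustering. Constant
profiles have no defined correlation and are dropped with a warning.

## Utilization rules and species comparison

A mapped compound is predicted supported iff (a) at least one transporter
locus is annotated and (b) at least one utilizing enzyme is expressed or the
system is flagged `inducible`. The inducible flag exists because some
transporter/enzyme systems are silent in the reference condition yet induced
by their substrate; vetoing them on reference-condition expression would be
wrong, so induction is modelled as prior knowledge in the compound map, not
inferred from expression. Unmapped compounds yield "unknown", never an
error. The prediction is monotone in evidence.

Species comparison over a utilization matrix excludes any row with an NA
call for either species from *all* counts (common, unique and both-no);
this row-exclusion convention is what makes the packaged matrix's printed
totals (31 common, 9 differential) exact. Nutrient names are matched
exactly after case-folding and whitespace normalization — no fuzzy
chemistry matching.

## Synthetic fixtures: what they emulate

All generators draw from `numpy.random.default_rng([stream, seed])` with a
fixed stream id per generator — no global random state, byte-identical
outputs for identical configs.

**Expression** (6,761 genes, 2 replicates): per-gene log2 value = shared
standard-normal signal + independent Gaussian noise, with the noise fraction
of total variance set by `replicate_noise_ratio_expr` (0.01), so the
expected replicate correlation is the signal fraction 0.99. Intensities are
exponentials around a log2 centre of 8, hence strictly positive and almost
surely distinct. 24 duplicate-gene pairs are planted at ±2 sd (±0.3 sd
spread), putting exactly one member per set above the array median with
overwhelming margin.

**Pathways** (338; 257/14/57/10 across the four statuses): built after the
expression fixture so labels hold *exactly* — covered steps draw at least
one expressed gene, uncovered steps draw only unexpressed genes, and the
covered-step count is placed in the intended coverage band. The duplicate
pairs are planted as alternative-gene steps of feasible pathways. The
composition's 10 "mostly expressed" pathways complete the 338 total left
open by the published 257/14/57 split.

**PM plates** (PM1/PM3/PM5; 95+95+94 test wells; 167/96/21): growth wells
follow logistics with class parameters high (A = 250 OU, k = 0.15 /h,
t0 = 18 h) and moderate (120, 0.10, 30); no-growth wells and negative
controls follow a basal dye-settling transient 5 + 25·exp(−t/20 h) OU — the
inoculum's residual respiration decaying to baseline. The transient (rather
than an exactly flat line) matters for clustering: it gives no-growth wells
a common shape to correlate on. Per-well jitter (A ±5%, t0 ±1.5 h) is
shared between replicates; replicate noise is additive Gaussian with a
per-well sd proportional to the well's signal amplitude (readout noise
grows with signal), scaled so the mean noise variance across wells is
`pm_noise_ratio/(1−pm_noise_ratio)` of the cross-well 48-h signal variance —
hence an expected 48-h cross-replicate correlation of 1 − 0.07 = 0.93.
Signals are clipped at 0 OU. D-glucose occupies PM1 A2 and is always high.

**Compound map** (135 mapped of 284): each mapped condition carries one
unique entry metabolite and evidence consistent with its growth class under
the utilization rules (growing: annotated transporter + expressed enzymes,
~15% instead inducible with silent enzymes; non-growing: a missing
transporter or silent, non-inducible enzymes). A transporter annotation list
of 282 loci is generated alongside, exactly 60 of them expressed.

**Proteomes** (48 reference proteins; query = 48 orthologs + 24 paralog
partners + 6 unmatchable; lengths 60–120 aa): orthologs are
substitution-only mutants at rate 0.15 (~85% identity — comfortably above
the 30% transfer threshold, far from the random-sequence floor), paralog
partners re-mutate only positions the ortholog left intact at rate 0.05
(at least one substitution), which keeps the partner's identity to the
reference *strictly* below the ortholog's and the best-hit pairing
unambiguous. Paralog partners reuse the expression fixture's duplicate-set
locus names so the two views of gene redundancy line up.

What passing on these fixtures does **not** show: robustness to
hybridization artifacts, dye bias or spatial array effects (not simulated);
correctness of any particular expression-detection threshold on real
arrays; OmniLog-software-equivalent growth calls (their cutoffs are
unpublished); or BLAST-equivalent homology on full proteomes. The fixtures
establish that the machinery is self-consistent and recovers known
structure at realistic noise levels — not that the thresholds are right for
any specific real dataset.

## Problem sizes and numerics

Default runs use the full fixture sizes (6,761 genes, 338 pathways, 284
wells at 385 time points × 2 replicates, 78 + 48 proteins); the
replicate-correlation calibrations average 100 regenerations. The whole
test suite and the acceptance script each complete in well under a minute
on a single CPU. Degenerate inputs are errors, not silent defaults:
non-positive intensities (named locus), zero-variance correlation inputs,
unsorted time grids, empty pathways, compositions that do not sum to their
totals. Floating-point ties in best-hit identities are compared after
rounding to 4 decimals; all other ties break lexicographically.
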