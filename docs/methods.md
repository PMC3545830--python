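# Methods

This note documents the models, defaults and numerical choices behind
vitiseq, and what the synthetic test-bed does and does not establish about
real data.

## Study layout

Four developmental stages (EL31, EL35, EL36, EL38 on the modified
Eichhorn–Lorenz scale), one library per stage, no replicates. Every
statistic in the package is therefore descriptive: stage-specificity is a
fold-change classification, not a hypothesis test, and clustering operates
on the single 4-vector each transcript has. The two veraison stages, one
week apart, act as de facto near-replicates in the original design; the
package reproduces the veraison-pair call that exploits this.

## Quantification model

Counting is transcript-space: the package consumes alignment *candidates*
(read ↔ transcript hits with a percent identity and an aligned fraction),
never raw sequence. Filters are applied in order:

1. **Read QC** — keep reads with trimmed length ≥ 60 nt and ≤ 2 ambiguous
   bases (both boundaries inclusive on the keep side).
2. **Alignment acceptance** — keep candidates with identity > 0.98 and
   aligned fraction > 0.5. Both inequalities are *strict*; a candidate at
   exactly 98% identity is rejected.

Allocation is two-pass and deliberately not an EM iteration: unique counts
are frozen first, then each multi-candidate read is split with weights
`unique(t) / Σ unique(t')` over its candidates. When every candidate has
zero unique reads the read is split equally — the proportional rule is
undefined at 0/0 and the equal split is the unique choice that preserves
read conservation. Conservation is exact: per stage, Σ allocated equals the
number of reads with ≥ 1 accepted candidate. A consequence worth noting:
the "fractional vs integer total reads" question for the RPKM denominator
is moot, because the allocated total *is* the integer count of counted
reads. Fractional allocated counts are carried as reals into RPKM; nothing
is rounded.

Detection: RPKM ≥ 0.5, or ≥ 5 unique reads when RPKM is below the floor.
Abundance bins are ">200" (strict), "10–200" = [10, 200],
"0.5–10" = [0.5, 10), plus the rescued-by-unique-reads trace bin; the
boundaries are arguments, not constants.

## Stage-specificity

`floored_fold_change(a, b) = max(a, 0.1) / max(b, 0.1)`. The floor applies
to both operands; this is what makes the pair (0.02, 1.00) a 10-fold change
and also what makes folds exactly reciprocal
(`fold(a,b) · fold(b,a) = 1`), which in turn guarantees a transcript can be
called at most at one stage. The call threshold (≥ 3) and the bin edges
(3, 10, 50; half-open bins) are inclusive at the lower edge. The magnitude
reported for a call is the *minimum* fold versus the other three stages —
the conservative choice where a maximum or next-highest convention would
also have been defensible; class membership is identical either way.

The veraison-pair call requires all four folds (each veraison stage versus
young and versus ripe) to reach the threshold, binned by their minimum.

## Clustering

Normalization follows the scale → center → range-filter order: discard rows
with all four RPKM < 0.5; scale each row by `1/√Σx²` (the unit
sum-of-squares contract is asserted pre-centering — centering necessarily
breaks it); subtract the row mean; drop rows with normalized range < 0.5.
Centering shifts all four values equally, so the range filter is identical
before and after it; a `range_on_normalized=False` switch instead filters
on the raw RPKM range for users who want regulation measured in absolute
units.

k-means is an in-package Lloyd loop: initialization draws k distinct
profiles uniformly per restart from a seeded generator; an empty cluster is
re-seeded with the point currently farthest from its centroid; iteration
stops when assignments are stable (cap 300). Restarts (default 1000) are
grouped by final objective at 10⁻⁸ relative tolerance; the best solution is
returned with `times_found`, and a count below `required_repeats`
(default 3) warns rather than fails — on rugged landscapes a best solution
found once is a finding to report, not an error. The per-iteration
objective trace is exposed for the monotonicity property test.

Centroid labelling computes Pearson correlation against the ten archetype
templates (normalized the same way), labels at ≥ 0.8, breaks exact ties
alphabetically, and leaves anything below threshold "unlabeled". The 0.8
threshold and the tie rule are artifact conventions: template amplitudes
are free parameters, only the shapes matter.

## GO enrichment and group scores

One-sided hypergeometric upper-tail p-value per term
(`P(X ≥ k)` for k annotated cluster members out of n drawn from N
background with K annotated), for every term with ≥ 1 annotated member;
Benjamini–Hochberg adjustment per cluster across the tested terms. "FDR"
here means BH on exact hypergeometric p-values — the plain reading of an
FDR cutoff applied to an enrichment tool's output. Term-to-process grouping
is an explicit input mapping (the synthetic ontology provides one per
planted process); semantic-similarity grouping of terms is out of scope,
because the quantitative claim being reproduced is the aggregation formula,
not the grouping heuristic. Group value = Σ over member terms of
`100 · (−log10 FDR)` over terms at FDR ≤ 0.05; an FDR that underflows to 0
is clamped to 10⁻³⁰⁰ first. Any included term therefore contributes at
least `100 · (−log10 0.05) ≈ 130.1`.

## Platform comparison

Probesets are excluded for cross-hybridisation suffixes (`_s`, `_x`, `_a`)
or a non-zero probeset-to-transcript match e-value. When several probesets
survive for one transcript, the one whose 4-stage pattern best
Spearman-correlates with the transcript's log RPKM pattern is kept — note
the mild circularity: the selection criterion favours agreement with the
RNA-Seq side, so multi-probeset transcripts are biased toward higher
pattern correlations. Expression floors: probeset mean intensity at or
above the 25th percentile of the cohort at hand (recomputed, never the
published array-specific value of 4.0) and mean RPKM ≥ 0.5, both inclusive;
a `per_stage` switch applies both floors stage-wise instead of to the
means. Correlations are Spearman with average ranks on ties — the
intensity-to-abundance response of an array is monotone but not linear, so
rank correlation is the right invariant (it is unchanged under any strictly
monotone transform of either axis). On 4-point patterns, tie-free Spearman
can only take the eleven values {0, ±0.2, …, ±1}; constant patterns have
undefined ρ and are counted in a dedicated histogram bin.

## Synthetic data: what it emulates, and what it does not

The generator plants ten archetype shapes as raw 4-vectors (amplitudes are
design parameters chosen for mutual separation of the normalized shapes —
the two decreasing shapes get distinct curvature) at fractions proportioned
after the cluster sizes the real study resolved, leaving ~62% flat
background whose stage wobble is bounded (max/min < 3, so flat transcripts
can never pass the 3-fold call on their true values). Per-transcript
abundance is log-normal (median ≈ 4.5 RPKM, heavy right tail), reads are
multinomial with weights `true_rpkm × length` — the sampling model under
which RPKM is the natural estimand. Defaults: 10,000 transcripts, 50,000
reads per stage, multi-map rate 0.15 (matching the ~85% unique-mapping rate
of the real libraries), QC-failure rate 0.02, alignment-failure rate 0.05.
Multi-mapped reads draw their candidates from randomly partnered homology
groups of 2–4 transcripts — the grouped multi-mapping of large
near-identical gene families, without claiming a generative model for them;
the 2–4 multiplicity is a default, not a claim.

GO planting is deterministic within the archetype (`max(5, 50%)` of
members) with a 5% Bernoulli background, which guarantees the ≥ 5-carrier
invariant and makes planted terms reliably significant at archetype sizes
≥ 10. Probeset intensities are affine in log2(RPKM+1) plus Gaussian noise;
when no noise SD is given it is solved numerically (bisection on the
retained-pair Spearman, using the very noise draw that will be added) so
the planted platform correlation is hit on the *retained* pairs after the
expression floors — a closed-form bivariate-normal calibration
overshoots because flooring truncates the range.

What passing tests therefore show: the analysis chain recovers planted
partitions (adjusted Rand index > 0.9 at normalized-space noise SD 0.05
with k = 10), planted enrichment (FDR ≤ 0.05 in > 95% of seeded
replicates), and a planted cross-platform correlation (0.7 ± 0.05 at 2,000
pairs) under a faithful but idealized sampling model. What they do not
show: robustness to positional read bias, fragment-length effects,
reference misannotation, batch effects between platforms, or biological
replicate variance — none of which the generator models (no base-level
errors, no quality strings, no FASTQ).

One consequence visible in full pipeline runs: the platform correlation
measured against *estimated* RPKM (sampled reads) is lower than the planted
target measured against true RPKM, because sequencing sampling noise is a
second, uncalibrated noise source on the RNA-Seq axis.

## Problem sizes and determinism

Every stochastic operation takes a seed and is reproducible bit-for-bit;
the pipeline derives per-stage seeds from the run seed. Test and
demonstration sizes are chosen so the suite settles in minutes on one core:
recovery tests use 600-transcript catalogs with 40 k-means restarts,
enrichment recovery uses 20 seeds at 400 transcripts, platform-correlation
recovery uses 2,000 pairs over 3 seeds; the full default pipeline (10,000
transcripts, 4 × 50,000 reads, k = 20, 1000 restarts) completes in about a
minute. The acceptance script reports the exactly-checkable worked examples
(group score, floored fold, scaling contract) computed fresh from the
package's own operations.

## Known limitations

- No statistical testing of differential expression (the design has no
  replicates); calls are fold-change classifications.
- Duplicated isogenes above 98% identity are genuinely confounded in
  transcript-space counting; proportional allocation redistributes but
  cannot resolve them.
- The Cluster 3.0 initialization is not reproduced exactly; run-stability
  semantics (grouping by objective) are.
- The enrichment background is the full catalog, not the expressed subset;
  processes correlated with overall expression level will show inflated
  enrichment, as they do in the original design.
- The "best-correlating probeset" tie rule biases multi-probeset
  transcripts toward agreement between platforms (see above).
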