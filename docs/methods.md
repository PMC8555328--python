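# Methods

## The placement model

`lodemap` treats marker placement as a two-step decision driven entirely by
linkage disequilibrium between an unmapped marker and the markers of an
existing ("anchor") genetic map.

**LD statistic.** For markers *i*, *j* with genotype allele counts
gᵢ, gⱼ ∈ {0,1,2}, r² is the squared Pearson correlation computed over
samples where both calls are present. No haplotype-frequency or EM
estimator is provided: the genotype-count r² converges to the gametic r²
for large samples, needs no phasing, and is the only statistic that
remains meaningful under pseudo-diploid coding of polyploids (all
heterozygous dosage classes collapsed to 1). A pair's r² is *undefined*
(NaN, never 0) when fewer than `min_complete_pairs` (default 10) complete
observations remain — small overlaps produce spuriously high r² — or when
either restricted vector is constant.

**Step 1 — linkage-group assignment.** Anchors with r² strictly greater
than the threshold (default 0.1) are ranked; the top two must agree on a
linkage group. Fewer than two supra-threshold anchors, or disagreement,
leaves the marker unplaced with an explicit reason
(`no_anchor_above_threshold`, `single_anchor_only`, `top_two_disagree`,
`undefined_ld`). The strict `>` is deliberate and exposed as a parameter;
at realistic thresholds the boundary case is measure-zero.

**Step 2 — position.** The estimate is the r²-weighted mean position of
*all* supra-threshold anchors on the assigned group, not only the top two.
Multi-point anchoring is the point of the design: with LD decaying smoothly
in cM, the weights concentrate on the true neighbourhood and a single
spurious anchor cannot dominate. Weights are the r² values themselves.
Consequences that are tested as invariants: the estimate is convex (always
inside the contributing anchors' span), deterministic (ties broken first
toward the top anchor's group, then by smallest marker id), and monotone
in the threshold (raising it can only shrink the placed set, since both
the top-two candidates and the anchor set shrink).

Placements are independent: markers placed in a run never become anchors
within that run, so results are order-invariant. Iterative/transitive
placement is out of scope.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `r2_threshold` | 0.1 | minimum LD for an anchor to count; strict `>` |
| `maf_min` | 0.01 | candidates need maf > this (strict); low-MAF markers carry too little LD signal |
| `call_rate_min` | 0.9 | marker inclusion filter (inclusive ≥) |
| `min_complete_pairs` | 10 | pairwise-complete sample floor for a defined r² |
| `max_distance` | 100 cM | intra-chromosomal pairs beyond this are excluded from decay analysis |
| `loess_span` | 0.5 | LOESS fraction for the decay curve (`smoother="bins"` with 1 cM bins is the alternative) |
| `folds` | 20 | masking cross-validation fold count |

The threshold of 0.1 is the conventional floor for a significant pairwise
association; the sweep machinery (`threshold_sweep`, grid 0.01–0.5) exists
precisely to examine the efficiency/accuracy trade-off around it, reusing
one fold partition and one set of per-fold r² profiles so that differences
are attributable to the cutoff alone.

## LD decay

Intra-chromosomal pairs (same linkage group, ≤ 100 cM apart, defined r²)
are smoothed by LOESS (statsmodels `lowess`, span 0.5) on a uniform
200-point distance grid. The **decay distance** is the first grid distance
at which the smoothed curve falls to or below the threshold; if it never
crosses, the profile is flagged rather than extrapolated. "First crossing
of the smoothed curve" is one of two defensible readings of a mean
distance at an empirical threshold; the alternative (averaging distances
of pairs near the threshold) is not implemented. The reported percentile
of the threshold is computed over all intra-chromosomal pairs pooled, not
per chromosome.

## Evaluation

`cross_validate` partitions the mapped markers into k random near-equal
folds (seeded; sizes differ by at most one), masks each fold in turn,
places it against the reduced map, and scores efficiency (% of masked
markers placed), accuracy (% of placed markers on the true group) and
precision (mean and SD of |known − estimated| cM) plus the Pearson
correlation of known vs estimated positions. Distance and correlation are
computed only over markers placed on the *correct* group: a cM difference
across different chromosomes has no meaning. Wrong-group placements still
count fully against accuracy. Aggregates are unweighted means over folds
(fold sizes are near-equal, so weighting is immaterial). A fold that
leaves a linkage group with fewer than two anchors is evaluated anyway,
with a logged warning.

## The synthetic population

The simulator emulates the setting in which LD-based map completion is
used in practice: a breeding population descended from a handful of elite
founders, where intra-chromosomal LD is strong and decays smoothly with
map distance.

* Marker positions are uniform within each linkage group, then sorted.
* **Founder haplotypes carry distance-correlated alleles**: along each
  chromosome the allele at a marker copies the previous marker's allele
  with probability exp(−d / `founder_block_cm`) (default 15 cM) and is
  otherwise drawn fresh at that marker's base frequency (uniform in
  (0.1, 0.9)). This Markov copy chain is a minimal stand-in for the long
  shared haplotype blocks of a narrow elite gene pool; without it, a
  handful of founders with independently drawn alleles would produce only
  drift-level LD (E[r²] ≈ 1/(2·n_founders) ≈ 0.06 at *any* distance),
  far below the 0.1 working threshold, and no distance signal at all.
* **Random mating with recombination**: each generation, two parents are
  drawn uniformly with replacement; each gamete follows a recombination
  walk where the switch probability between adjacent markers at distance
  d cM is the Haldane map function (1 − e^(−2d/100))/2 — no crossover
  interference (Kosambi would only reshape the test fixture, not the
  method under test) — and ½ at linkage-group boundaries (independent
  assortment). Five generations over 500 individuals steepen the founder
  decay and erase inter-chromosomal associations.
* Diploid only: the placement method consumes pseudo-diploid 0/1/2 codes,
  so higher ploidy would collapse to the same representation anyway.
* Missing calls are injected independently at `missing_rate` (default
  0.02); no structured missingness model is claimed.

Defaults (3 linkage groups × 100 cM × 200 markers, 8 founders, 5
generations, 500 samples) yield, at seed 1: monotone binned mean r²
(≈ 0.59 at 0–5 cM, ≈ 0.01 at 20–25 cM, inter-group ≈ 0.003), a LOESS
decay distance of ≈ 17 cM at r² = 0.1, the threshold near the 80th
percentile of observed r², no monomorphic markers, and realized MAF
well inside [0, 0.5].

**What passing tests do and do not show.** The simulation has clean
biallelic calls, uniform missingness, a single unstructured population,
exact marker order and error-free anchor positions. Real array data add
genotyping error, segregation distortion, population structure and
admixture, uneven marker coverage, dosage uncertainty in polyploids, and
anchor maps that are themselves approximate. Recovery rates near 100%
here therefore validate the *algorithmic* pipeline (bookkeeping, LD
arithmetic, weighting, threshold logic), not field performance; on real
crop data efficiency and precision will be lower, and placement
resolution is bounded by the population's LD decay distance.

## Numerical choices and degenerate inputs

* Missing genotype sentinel is −1 in memory, `NA`/`N`/`-9`/empty on input,
  `NA` on output. Map positions serialize at 6 decimals, making
  write→read→write round-trips byte-stable.
* r² is clipped to ≤ 1 against floating-point overshoot; variances below
  1e−12 count as zero.
* Vectorized r² blocks (masked cross-products, a handful of matrix
  multiplies) are exercised against the scalar path to 1e−10 in tests;
  the placement fast path and the public per-profile functions share one
  implementation.
* All-missing or monomorphic candidates are reported `undefined_ld` with
  the specific cause in `detail`, never silently dropped; the candidate
  MAF filter uses the same strict `>` as the study-level filter.
* Multi-allelic VCF records are skipped (counted, logged), not split;
  polyploid GT fields collapse to 0 (all ref), 2 (all alt), 1 (mixed),
  missing if any allele is missing.
* Fold assignment sorts marker ids before the seeded shuffle, so
  partitions depend only on the id *set* and the seed.

## Problem sizes

Tests and the acceptance script run the default population (600 markers ×
500 samples, 20-fold CV, a 7-point threshold sweep, ≈ 60k LD pairs for
the decay profile). These sizes give stable metrics (across seeds the CV
aggregates move by well under a percentage point) while a full run stays
around a minute on one core; larger populations only sharpen already
saturated recovery rates.

## Known limitations

* No dosage-aware polyploid LD model; the pseudo-diploid collapse
  underestimates heterozygosity in high polyploids by construction.
* No D′ or other LD statistics; no per-sample QC; no Hardy–Weinberg
  filtering; no LD pruning.
* The anchor map is trusted as-is: the method approximates positions
  *relative to the given map* and cannot correct anchor errors.
* Placed markers are never promoted to anchors, so markers whose only
  strong LD partners are other unplaced markers stay unplaced.
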