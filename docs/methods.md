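# Methods

`trimfold` re-implements, as a tested pipeline, a classic bespoke analysis
chain for single-channel spotted oligonucleotide arrays in which every gene
is printed as five identical replicate spots and each biological condition
is a single pooled hybridization: cross-array scale-factor normalization,
trimmed-mean probe summarization, signed fold-change calling, hypergeometric
term over-representation, and comparative-CT qPCR cross-validation.  A
synthetic-data generator with recorded ground truth stands in for the
deposited arrays so that every stage is testable end to end.

## Array model and processing chain

The design emulated throughout is a 5,003-gene bacterial genome array
(*Clostridium beijerinckii* NCIMB 8052 under furfural stress) with five
identical 45–47-mer probe replicates per gene and, per growth phase
(acidogenic and solventogenic), exactly two arrays: one pooled control and
one pooled furfural-challenged sample.  The pipeline's entry point is the
spot-level median feature intensity; image acquisition and feature
extraction are upstream and out of scope.

**Scale factor.**  For each phase the two arrays are put on a common scale
with a single multiplicative factor

```
SF = mu_control / mu_treatment
```

where `mu` is the arithmetic mean of all spot median intensities on an
array.  Every treatment spot is multiplied by SF; afterwards the two array
means agree to floating-point precision.  The mean is taken over all loaded
spots by default; `compute_scale_factor(..., exclude_genes=...)` removes
named spots (control oligos, spike-ins) from both means, since arrays of
this design typically carry ~1% control features that should not drive the
normalization.

A known property of this one-number normalization, reproduced faithfully
here: because the array mean is intensity-weighted, heavy *asymmetric*
differential expression leaks into SF itself.  Under the default
solventogenic simulation (14% of genes spiked, up to 54-fold) the fitted SF
is ~0.39 where the true slide-scale ratio is 0.8, shrinking all ratios and
costing sensitivity near the call threshold.  Model-based multi-array
normalization would fix this but is deliberately out of scope — the method
implemented is the single scale factor.

**Trimmed mean.**  Each gene's five *adjusted* replicate signals are
summarized by discarding exactly one occurrence of the maximum and one of
the minimum and averaging the remaining three.  Ties lose only one value
per extreme.  Degraded groups follow the same intent: four values drop max
and min (average of two); three values are averaged untrimmed; fewer than
three cannot be trimmed and the gene is excluded for that array, with a
warning.  Order of operations is fixed as scale-then-trim — the trim is
defined on adjusted signals.  This summary ignores any single arbitrarily
large (or small) spot per group by construction.

**Ratios and signed folds.**  The expression ratio is
`treatment_summary / control_summary`.  Fold change uses the symmetric
reporting convention: ratio ≥ 1 is reported as-is, ratio < 1 as −1/ratio,
so |fold| ≥ 1 always and down-regulation reads −k-fold.  `log2_ratio` is
log2 of the ratio.  DE calls are threshold-only (default: strictly more
than 3-fold in either direction; an inclusive mode exists because a
published gene count cannot disambiguate `>` from `≥`).  With one pooled
array per condition there is no replicate variance, hence no p-value —
exactly the limitation of the original design.

Degenerate signals are governed by a configurable positive intensity floor
(default 1 unit): a control summary at or below the floor leaves the ratio
undefined (gene excluded, logged); a treatment summary at or below the
floor is clipped up to the floor and flagged, so strong repression is
reported as a bounded fold rather than dropped.

**Over-representation.**  For each annotation term the upper hypergeometric
tail P(X ≥ k) is computed for k of n DE genes overlapping a K-gene term in
an N-gene background; `method="ease"` substitutes max(k−1, 0) for k (the
conservative EASE variant, offered because annotation tools of that era
used either).  The background defaults to the genes with a defined
expression ratio, not the full array — genes lost to QC cannot be called
DE.  Benjamini–Hochberg step-up adjustment (via statsmodels) controls FDR;
0.05 is the default reporting threshold.  No ontology-graph propagation is
performed; term sets are supplied (or simulated) as flat gene sets.

**Comparative CT.**  qPCR wells are averaged per (gene, condition); then
ΔCT = CT_target − CT_reference per condition, ΔΔCT = ΔCT_treatment −
ΔCT_control, and relative expression 2^−ΔΔCT, assuming perfect doubling per
cycle (no efficiency calibration, matching the comparative method).  A
reference-stability check reports the largest between-condition drift of
the reference gene's mean CT against a configurable tolerance (default 0.5
cycles; the emulated study used 16S rRNA after confirming constancy).
Adding a constant to every CT of one condition cancels exactly.

**Concordance.**  Platform agreement is the Pearson correlation R between
microarray and qPCR values on the signed-fold scale by default (the scale
of the usual validation scatter plot); a log2 mode is provided because
Pearson on signed folds is dominated by the largest folds.  The slope and
intercept of the least-squares line are reported alongside R and n.

## Synthetic-data generator

Spot intensities follow a multiplicative log-normal model:

```
signal(g, r, a) = scale(a) * 2^( baseline(g) + fc(g)*[a=treatment]
                                 + affinity(g, r) + outlier(g, r, a)
                                 + eps(g, r, a) )
```

- `baseline(g) ~ N(10, 1.5^2)` log2 units: a broad, strictly positive
  intensity distribution.  The real arrays' distribution is unpublished;
  these are conventions, not estimates.
- `fc(g)`: per phase, fractions (1.1%, 7.2%) of genes are spiked up and the
  same down — ~110 and ~720 DE genes, the scale of the emulated study —
  with |log2 fc| uniform between log2 3 and the largest reported folds
  (16-fold acidogenic, 54-fold solventogenic).  Uniformity in log2 is a
  choice; no spike distribution was published.
- `affinity(g, r) ~ N(0, 0.25^2)`, fixed per physical probe across arrays:
  sequence-dependent hybridization efficiency, which cancels between
  arrays when the same replicates survive trimming.
- `eps ~ N(0, 0.2^2)` per spot: scanner/hybridization noise (multiplicative
  on the raw scale, as scanner noise classically is).
- outliers: probability 0.01 per spot of a ±4 log2-unit shift, symmetric so
  the trim is exercised both ways.
- `scale(a)`: per-array multiplicative factors, default (1.0, 0.8) and
  (1.0, 1.25) per phase, so the SF step has real work.
- signals are clamped to a positive floor (default 1.0; hits are logged);
  non-finite signals abort generation.

Annotations: 50 terms of 10–80 genes; per phase, 5 terms draw members with
20× weight on that phase's DE genes (enriched ground truth), the rest
uniformly.  qPCR plates: per phase, a panel (19 and 23 genes, the emulated
validation panels) drawn ~40/40/20 across up/down/unchanged strata, with
CT(target) = 30 − log2(expression) + N(0, 0.15²) in triplicate wells and a
constant-CT reference gene at 12 cycles.  The CT offsets are conventions
placing CTs in the usual 15–30 cycle range; they cancel exactly in ΔΔCT.
All randomness derives from one seed through named substreams, so a fixed
configuration reproduces every table bit-identically, down to the written
TSV text (17-significant-digit floats, which round-trip IEEE doubles
exactly).

**What the generator does not emulate**, and hence what green tests do not
show about real arrays: spatial artifacts and print-tip effects,
intensity-dependent (banana-shaped) bias, correlated noise between
neighboring spots, cross-hybridization, dye/labeling chemistry, and
realistic annotation structure (term overlap, ontology hierarchy).
Recovery rates measured here characterize the pipeline's arithmetic, not
field performance.

## Numerical choices and edge cases

- Trimming with ties removes exactly one occurrence per extreme
  (sort-based), so the summary always lies between the group min and max.
- The signed-fold map is discontinuous at ratio 1 (jumping −1 ↔ +1).
  Zero-noise exactness tests therefore use power-of-two slide scales, under
  which the normalization arithmetic cancels without rounding and unchanged
  genes land on ratio 1.0 exactly; with arbitrary scales a one-ulp
  deviation flips the fold sign, which is cosmetic (both mean "unchanged")
  but breaks exact-identity assertions.
- Zero-noise recovery tests also exclude the spiked genes from the SF mean
  (the control-oligo exclusion mechanism) because the intensity-weighted
  mean otherwise absorbs part of the DE signal (see above) and exact
  recovery is impossible by construction.
- Hypergeometric tails come from `scipy.stats.hypergeom.sf` and are tested
  against exhaustive integer-combinatorics enumeration for every
  (N ≤ 30, K, n, k) to 1e−12.
- Result tables are written with fixed 6-decimal floats for stable diffs;
  spot/CT tables with 17 significant digits for exact round-trips.
- Test and validation problem sizes: the full 5,003-gene design is used
  where a criterion depends on it (zero-noise recovery, noisy recovery over
  10 seeds); concordance-degradation and calibration checks use 300–500
  gene designs with 50 replicates per condition, sizes at which the
  measured quantities are stable to well within the asserted margins.

## Known limitations

- Mean-based SF normalization is biased under heavy asymmetric DE (see
  above); this is a property of the method, preserved on purpose.
- Threshold-only DE calling has no error control; counts depend on the
  threshold convention (strict vs inclusive) near the boundary.
- The EASE/fisher choice changes borderline terms; neither is "the" correct
  historical statistic without knowing the annotation tool's version.
- Pearson R on signed folds is leverage-dominated by the largest folds;
  the log2 mode is preferable for skewed panels but is not the default
  because the validation-plot convention is fold-scale.
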