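# Methods

## Variant model and coordinates

Residue positions are 1-based and inclusive in every interface and file
format. A deletion or complex indel spans `start..end` on the wildtype
sequence and its `deleted_seq` must match the sequence there. A pure
insertion is anchored "after residue p" with `p ∈ [0, L]`; `p = 0` is an
N-terminal insertion. This convention is forced by conservation windows
that start "from the first residue prior to the insertion site".

Two impacted-residue windows are deliberately distinct:

* **impact mode** (per-variant significance): the deleted range plus three
  flanking residues on each side. For pure insertions the window is three
  residues on each side of the insertion boundary (`p−2..p+3`, clipped);
  the symmetric reading was chosen because only the deletion case is fully
  specified by the source methodology.
* **enrichment mode** (cohort statistics): the deleted range only; for
  insertions, the two residues on either side of the insertion point.
  Complex indels use the deleted range, grouped with deletions.

Terminal clipping to `[1, L]` is silent everywhere; property tests place
variants at the termini to enforce this.

## Features

Window composition uses the ten wildtype residues on either side of the
variant span, *excluding* deleted residues (they are what the variant
removes), normalized by the residues actually present so terminal variants
still yield proper frequency vectors. Homolog counts are cumulative at
identity thresholds 50, 55, …, 95%: "10 counts from 50 to 100%" is
arithmetically inconsistent with 11 inclusive endpoints, so a 100%-identity
homolog falls in the ≥ 95 bin. The single-amino-acid repeat length is the
longest run containing any deleted residue (for insertions: the larger run
containing either residue flanking the insertion point), and equals 1
outside repeats. Conservation is aggregated as the maximum index over the
deleted range; for an insertion of k residues after p, over `p..p+k−1`
clipped (when clipping empties the window — a single-residue N-terminal
insertion — the nearest terminal residue is used). A PSSM-derived
per-position vector may be supplied as an additional conservation-style
track and aggregated by the same rule. Gene-level function scores are
passed through unchanged as a fixed-length block.

Optional groups (homolog counts, gene scores) are imputed as zeros when a
protein lacks the data; per-group presence-flag features can be enabled
(`FeatureConfig.presence_flags`) but are off by default so the documented
feature layout (e.g. 51 features for 2 mechanisms + 1 conservation index +
homologs, no gene block) holds exactly.

## Classifier

An ensemble of 100 two-layer networks, 10 tanh hidden units, sigmoid
output, mean-of-members score. Each member trains on a balanced bag: all
minority-class examples plus a uniform undersample (without replacement,
fresh draw per member from one seeded stream) of the majority class; 25% of
the bag is held out for early stopping (patience 10 epochs, max 150,
best-weights restore). Training uses full-batch resilient propagation
(iRprop−: step sizes ×1.2 on stable gradient sign, ×0.5 on flips, steps in
[1e−6, 50], initial 0.1). Rprop was chosen because it is the training
method of the reference design, has no learning-rate hyperparameter, and is
deterministic given the seed; the contract is statistical equivalence of
any early-stopped gradient method, not bit-level reproduction of a
particular toolbox.

Preprocessing (fitted on training folds only): Welch two-sample t-test per
feature with the minimally restrictive threshold P < 0.5 (constant features
dropped first), z-scoring, PCA retaining ≥ 99% cumulative variance
(scikit-learn, full SVD). Welch's variant was chosen since the two classes
have no reason to share variances.

Published cutoffs 0.546 / 0.672 / 0.85 (10/5/1% FPR) are exposed as
reporting constants only; a retrained model anchors its own cutoffs with
`threshold_at_fpr`, the least cutoff whose empirical FPR on the neutral
scores is at or below the nominal level (ties resolved by stepping just
above a score where needed). A percentile mode (default 95th) supports the
cohort "predicted" rule, which is distinct from P < 0.05 significance.

## Cross-validation protocols

Per-protein folds keep all variants of a protein together; per-cluster
folds additionally keep ≥ 50%-identity proteins together (single-linkage
transitive closure). Percent identity is computed from the global
(Needleman–Wunsch) edit distance d as `100·(1 − d/max(len))`: equal-length
point-substituted homologs score exactly their conserved fraction, and
unrelated random proteins score ~14%, far from the 50% threshold. Groups
are dealt largest-first to the lightest fold after a seeded shuffle, which
balances fold sizes; fold assignment fails loudly if any training partition
would be single-class. Named experiment presets reproduce the standard
ablations (include-singletons, canonical-only, per-kind training,
leave-one-feature-group-out).

## Impact and enrichment statistics

The empirical P-value is the literal fraction of the neutral null at or
above the observed impact score and may be exactly 0; an optional
`(k+1)/(n+1)` mode exists for users needing positive P. α defaults to 0
(P′ = P) when no prior is configured or estimable — conservative toward the
uncorrected P-value. The provided prior estimator is an Elkan–Noto-style
ratio of mean classifier scores (unlabeled over labeled-positive), capped
at 0.99; a configured α always wins. Ties among mechanisms with equal P′
break toward the larger impact score, then the mechanism name, making the
top-5 report invariant to input order.

Fisher tests are two-sided by the point-probability criterion; this
convention reproduces the published worked examples to three significant
figures (3.89e−21, 5.76e−28), so no one-sided fallback is needed. The
one-sided value is still exposed for diagnosis. Bonferroni correction
multiplies by the number of mechanisms tested and caps at 1. The trend
value E is undefined (NaN) when both fractions are zero and is reported as
missing rather than forced to 0.

## Synthetic studies

The generator emulates the study conditions end to end: 300 proteins
(length 60–300, 30% carrying a single-amino-acid repeat segment of 4–10
residues), 4 mechanism tracks with contiguous planted sites covering ~10%
of residues, background scores Beta(2, 8) and site scores Beta(8, 2) with
the confident threshold at the background's analytic 90th percentile
(mirroring 10%-FPR cutoffs), conservation mixed with the site indicator
(weight 0.6), and 700 pathogenic + 1300 neutral variants dominated by
single-residue events (65%). Pathogenic variants hit planted sites with
probability 0.9 and concentrate (probability 0.85) in a 30% subset of
disease-associated proteins; neutral variants avoid sites with probability
0.6, reflecting the observed segregation of population indels into
disordered/low-function regions. Optional knobs: label noise (hidden
positives inside the neutral set), isoform duplicates at 95% identity that
share sites, homologs and disease status (these are what make per-protein
cross-validation optimistic relative to per-cluster, as with real
alternative isoforms), and controlled-identity homolog families.

What passing on this generator shows — and does not: the pipeline recovers
a planted association between variant placement and per-residue functional
evidence under realistic noise, with honest grouped cross-validation. It
does not certify performance on real clinical variation, where tracks are
predictions with correlated errors, mechanisms co-occur nonrandomly, and
cohort ascertainment is biased in ways the generator does not model.

## Problem sizes and numerics

The test-suite and the reproduction script run the full default study
(2000 variants, 100-network ensembles inside 10-fold CV) in minutes on one
CPU; the affinity-trend and protocol-comparison experiments use reduced
cohorts (≈100/60 proteins, 30-network ensembles) since they compare
configurations rather than certify absolute performance. All randomness
flows from explicit seeds through `numpy` generators (per-member seeds
spawned via `SeedSequence`), making every reported number bit-reproducible.
Degenerate inputs fail loudly: single-class preprocessing, minority class
< 4, empty cohorts, empty nulls, non-finite features, α outside [0, 1).
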