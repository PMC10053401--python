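# Methods

## Problem setting

The package implements a biomarker-discovery workflow for redox-targeting
(ROS-inducing) cancer drugs. The working hypothesis is that sensitivity is
not marked by overexpression of the drug target but by coordinated *low*
expression of a set of antioxidant-capacity genes (the ACB set: NADPH
regeneration, glutathione/thioredoxin antioxidation and detoxification
enzymes). The pipeline therefore (i) associates every gene's expression and
protein level with per-cell-line drug sensitivity, (ii) combines the two
omics layers by rank aggregation and selects a signature, (iii) scores
samples by mean signature expression, (iv) searches a compound library for
drugs whose activity profile matches the reference compound's in
"signature-correlation space", and (v) provides the assay-level metrics
(4PL EC50, GR, OxD) these analyses consume.

## Association and selection

For each feature *g* in a layer, the Pearson coefficient
r_g = corr(x_g, ln EC50) is computed over shared samples after pairwise
deletion of missing values; the two-sided p-value uses the exact
transformation t = r√((n−2)/(1−r²)) on n−2 degrees of freedom. Sensitivity
enters on the natural-log scale by default (EC50 distributions are
log-normal across panels; the flag `transform="identity"` disables this,
e.g. for AUC). Features with fewer than 4 complete pairs or constant values
are skipped with a logged reason — reporting them as r = 0 would silently
bias rank aggregation.

Within each layer features are ranked by ascending p (average ranks at
ties). Expression and proteomics are combined by **re-ranking within the
feature universe shared by both layers** and averaging the two ranks; this
makes the combination symmetric and insensitive to features quantified in
only one layer. (The alternative reading — rank within each full layer
first, then restrict — gives nearly identical orderings when the overlap is
large but is not symmetric under feature dropout; we use the overlap
universe.) Selection takes every feature with average rank strictly below a
cutoff (default 38). No multiple-testing correction enters selection, which
is rank-based by construction; a Benjamini–Hochberg column is available for
reporting.

A convention worth making explicit: a signature that is *repressed* in
*sensitive* (low-EC50) lines has **positive** gene-level correlation with
ln EC50 — low expression co-occurs with low EC50. All planted-truth tests
assert positive r, and the synthetic generator's `target_r` is the signed
expected correlation between signature score and ln EC50.

## Signature scoring, reduction, responder fractions

The score is the unweighted arithmetic mean of signature-gene expression on
the log2(TPM+1) scale. It is deliberately *not* z-scaled: cross-cohort
comparisons (tumor scores against a sensitive cell line's level) require a
common absolute unit, and callers harmonize units first
(`rpkm_to_log2tpm`). Z-scaling (`zscore_genes`, n−1 denominator) exists for
display/clustering only.

`reduce_signature` is a greedy backward elimination: at each step remove
the single gene whose removal maximizes |corr(score, ln EC50)|, ties broken
by gene symbol, stopping when no removal improves |r| or two genes remain.
The |r| trace is therefore non-decreasing by construction. The iteration
rule is our reconstruction of "eliminate components with minor contribution
to the sensitivity correlation" — the original procedure is not specified
beyond its outcome (a 15 → 11 gene reduction); greedy backward search is
the simplest deterministic rule consistent with it.

`responder_fraction` counts, per cancer entity, the fraction of tumors with
score ≤ a reference score (ties are responders): an estimate of how many
patients express the signature at or below the level of a drug-sensitive
reference line.

Descriptive structure uses complete-linkage agglomeration on Euclidean
distances (SciPy linkage; items are sorted lexicographically before
clustering so tie handling is deterministic) and pooled-centered PCA: the
cohorts are concatenated, centered on pooled per-gene means and projected
on eigenvectors of the pooled covariance, which makes coordinates invariant
to cohort order; each component's sign is fixed by making its
largest-magnitude loading positive.

## Compound similarity and enrichment

Each compound is summarized by its correlation vector: one Pearson r per
signature gene against the compound's response (AUC; the reference uses its
own EC50-based vector — the two metrics are deliberately mixed, matching
how a bespoke reference screen meets a public AUC screen). Similarity is
the Euclidean distance between correlation vectors; the library is ranked
by ascending distance to the reference (reference excluded, ties by
compound id). Compounds whose vector is undefined (constant response) are
dropped and logged, not imputed — Euclidean distance on partial vectors has
no agreed definition. "Relative distance" (distance / max observed
distance) is reported but never used for cutoffs.

Enrichment of the reactive annotation along the ranking is reported two
ways: the per-rank curve (rank fraction, recall, precision — recall and
precision being the two defensible readings of a "percentage of identified
reactive compounds" axis) and a scalar `roc_auc`. The scalar is the
standard trapezoidal ROC area (x = false-positive rate), which is 1 for a
reactive-first ranking and maps to 1 − AUC when the ranking is reversed; a
rank-fraction trapezoid has neither property. Fold enrichment at a distance
cutoff is (reactive_in_set / set_size) / (total_reactive / total) over the
strict distance-< set; an empty set leaves the fold undefined rather than 0.

## Dose-response metrics

* 4PL: v(c) = bottom + (top − bottom)/(1 + 10^(hill·(log10 c − log10 EC50))),
  fitted by trust-region least squares on (log10 EC50, hill, top, bottom).
  Initialization: top/bottom from the extremes of mean viability, EC50 from
  the concentration nearest half-range, hill = 1; EC50 bounded to
  [min c/100, max c×100] — robust on partial curves where only one shoulder
  is sampled. Data whose mean-viability range is below 1e-6 raise "no dose
  response" instead of returning an arbitrary sigmoid. If the optimizer
  returns top < bottom the equivalent (top↔bottom, hill→−hill)
  parameterization is reported, so top ≥ bottom always holds. EC50 is in
  input concentration units; rescaling concentrations by k rescales EC50 by
  exactly k.
* GR = 2^(log2(x_c/x0)/log2(x_ctrl/x0)) − 1 from treated/control/day-0
  nuclei counts; requires a growing control. GR50-style curve fitting over
  GR values is out of scope.
* OxD = (r − r_red)/(r_ox − r_red), clipped to [0, 1]: the two-point
  normalization between DTT (fully reduced) and diamide (fully oxidized)
  controls. Instrument-factor-corrected OxD equations are not implemented;
  the probe ratio r is a user-supplied quantity.

## Synthetic data: what it emulates, and what it does not

`generate_panel` plants a block of k co-regulated genes from one latent
Gaussian factor f per sample: gene_j = μ + σ(√w·f + √(1−w)·ε_j) with
μ = 6, σ = 1.2 on the log2(TPM+1) scale (floored at 0), so planted genes
have pairwise correlation ≈ w (`within_block_r`). ln EC50 loads on the same
factor: ln EC50 = ln 2 + 1.2(ρ_f·f + √(1−ρ_f²)·η), with ρ_f chosen
**analytically** so that the expected corr(block mean, ln EC50) equals
`target_r`: since corr(score, f) = √(w/(w + (1−w)/k)), we set
ρ_f = target_r / corr(score, f) and reject configurations where |ρ_f| > 1
as unreachable. No rejection sampling; identical (config, seed) reproduce
byte-identical tables (per-component generator streams derive from the
master seed by fixed offsets). Background genes are independent Gaussians
with baseline means uniform on [0.5, 8]; proteomics is expression plus
i.i.d. noise (sd 0.5 by default, coarsely emulating the lower precision of
MS protein quantification).

Defaults are the study conditions: 31 samples × 2000 genes, 15 planted
genes, target_r = 0.86, and a 543-compound library with 125 reactive
members (`frac_reactive = 125/543`). Reactive compounds' AUC vectors are
the standardized signature score plus Gaussian noise (`compound_noise_sd`,
default 1.0 — "moderate": attenuates the compound–score correlation to
≈ 0.7); inert compounds are pure noise; the reference compound's response
is the panel's own ln EC50 rescaled to the AUC range.

What the generator does **not** emulate — hence what passing tests cannot
show about real data: heavy-tailed/bimodal expression, mean–variance
coupling and dropout of real RNA-seq; correlated background modules (only
the planted block is correlated, so false-positive behaviour of rank
selection is optimistic); batch structure between cohorts; realistic
methylation β distributions; non-monotone or partial dose-response shapes
beyond 4PL + Gaussian noise.

## Scenario sizes used by the test suite and acceptance script

Chosen so each check is decisively powered at desk scale: recovery and null
calibration use 25 × (200 × 2000) and 1 × (31 × 2000) panels; compound
screens use the full 543/125 library; 4PL recovery uses 8-point curves,
3 replicates, 20 seeds; decoy elimination uses 20 seeds of a 400-sample,
within_block_r = 0.5 panel — at w = 0.7 and n = 100 the marginal
contribution of one of four block genes (~0.01 in expected |r|) is below
r's sampling noise and the "exact decoy removal" property is not decidable;
at w = 0.5, n = 400 it is, stably across neighbouring (n, w).

## Known limitations

* The reduction rule is a reconstruction (see above); other elimination
  orders can reach different local optima on real data.
* Cross-platform score comparability (e.g. RPKM-converted cohorts against
  log2(TPM+1) references) is the caller's responsibility; no cross-cohort
  normalization beyond unit conversion is applied.
* `pearson_with_p` assumes the nominal t null; for strongly non-normal
  data the permutation agreement shown in tests holds only approximately.
* Reactive-group annotation is consumed as given; no chemical-structure
  reasoning is performed.
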