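# Methods

## Information estimation

All information quantities are plug-in (histogram) estimates on
discretized columns, in bits (base-2 logs; rankings are base-invariant).
Dosages in [0,2] are cut at 1.0 — non-carrier vs carrier of at least one
imputed allele copy; principal components at 0; age of onset (aao) into
the closed integer ranges 0–20, 21–40, 41–60, 61–80, 81–100 years on
rounded values, with out-of-range values clipped to the nearest bin.
Interval ends are half-open on the left ([0,1) vs [1,2], (−∞,0) vs
[0,∞)); a boundary value goes to the upper bin. Empty cells contribute
0 (0·log 0 = 0) and no smoothing is applied. Joint quantities are
computed through entropy identities, e.g. I(X;Z|Y) = H(X,Y) + H(Z,Y) −
H(X,Z,Y) − H(Y); the test suite checks these against direct
cell-by-cell summation oracles to 1e−12 and the chain rule to 1e−10.

The greedy selection loop uses a vectorized pairwise cache (one-hot
cross-tabulation per selected feature against all candidates). Caching
is an implementation detail: tests assert the cached scores equal the
plain per-column scorer.

Degenerate inputs: constant columns have entropy 0 and never win a
selection step on merit; exact score ties break by ascending feature
name everywhere, so results are bit-reproducible across platforms.

## Selection criteria

Seven greedy forward-selection criteria share one loop (see README for
the formulas). Conventions where the formulas are silent:

* Empty S: sums are 0 and the CMIM max is 0, so MIM/MIFS/mRMR/CMIM/ICAP
  score I(X_k;Y) for the first pick. JMI's literal empty sum would tie
  every candidate at 0, so it too falls back to I(X_k;Y) — the standard
  first step in the criterion literature. DISR keeps its normalisation
  idea and uses I(X_k;Y)/H(X_k,Y).
* MIFS β defaults to 1.0 (the canonical setting; exposed as
  `mifs_beta`).
* ICAP caps each pairwise interaction term at 0 from below:
  max(0, I(X_k;X_j) − I(X_k;X_j|Y)).

## Synthetic cohorts

The generator emulates a PsA (case) vs cutaneous-only psoriasis
(control) cohort and, crucially, the *mechanism* of its confounding:
onset-biased control recruitment, not a direct allele→label effect.

Per candidate sample: latent ancestry u ~ N(0,1) with pc1 = u + 0.5·ε
and pc2 pure noise; allele dosages from block-exchangeable latent
Gaussians (blocks of 5, ρ = 0.4) cut at Hardy–Weinberg genotype
quantiles of each allele frequency shifted by 0.05·u, plus ±0.05
clipped jitter to mimic imputed dosages; case status logistic in
0.6·dosage(HLA_B_27) + 0.2·pc1; aao ~ N(45, 15) − 12·dosage(HLA_C_06)
clipped to [1,99]; cases sampled uniformly, controls accepted with
probability exp(−aao/15). The defaults are the package's study
conditions: 1300 cases / 1200 controls (n = 2500, mirroring a mildly
case-enriched clinic cohort), 70 allele features with frequencies drawn
in (0.02, 0.40), causal frequency 0.15 and confounded frequency 0.20 —
plausible values for B\*27-type and C\*06-type alleles. Under these
conditions the confounded allele's marginal MI with the label exceeds
the causal allele's in most realizations, and aao differs by ~17 years
between classes.

What the generator does **not** emulate: realistic MHC haplotype
structure (LD is block-exchangeable), 4-digit/amino-acid features,
genotyping or imputation error, or phenotype misclassification. Passing
tests therefore demonstrate that the pipeline removes *this* confounding
mechanism and ranks *this* causal structure correctly — not that it
would achieve any particular AUC on real HLA data.

## Mitigation

Strata are the cross-product of the three binned confounders, balanced
once (the joint grid controls all three simultaneously and is
order-invariant; a `sequential` mode — aao, then pc1, then pc2,
rebalancing after each — exists for fidelity experiments). The minority
class within each two-class stratum is upsampled with replacement;
single-class strata are dropped with a warning; originals of retained
strata are always kept. Upsampling (never downsampling) preserves every
observed sample. After balancing, P(Y=1 | stratum) = 1/2 exactly, so
the binned confounders carry zero information about the label; residual
confounding survives only within bins (20-year aao bins are coarse).

Two costs of the resampling are worth knowing. Duplicated rows shrink
the effective sample size, adding variance to every downstream
estimate; occasionally (about 1 replicate in 10 at the default
conditions) a null or LD-partner allele overtakes the causal allele at
the top of the post-mitigation ranking for this reason. And when the
mitigated data enter cross-validation, copies of one source row can
fall on both sides of a fold split, which makes CV AUC mildly
optimistic relative to the untouched hold-out — visible in the worked
example (KNN cv 0.73 vs external 0.53).

In deployment order, the hold-out split happens *before* mitigation;
mitigation, feature selection and tuning see training rows only.

## Bootstrap aggregation

Bootstraps are class-stratified (each resample draws within each class
as many rows as the class has), so no resample can lose a class; all
criteria share the same B resamples. R averages only over the
bootstraps in which the feature entered the top K; a feature never
selected has V = 0 and no R. Cross-criterion: ABV keeps the number of
criteria (7) as its denominator; ABR averages over criteria where R is
defined (the formula's denominator is unspecified for never-selected
features; this convention is ours and is documented, not asserted as
canonical). The overall sort is (Technique Vote desc, ABV desc, ABR
asc, name asc). Vote conservation (ΣV = B·K per criterion) is asserted
in tests.

The headline pre/post-mitigation contrast ranks the same allele-only
candidate set in both arms. Ranking the confounders alongside the
alleles in the raw arm is available as the exploratory view
(`pre_include_confounders=True`); there aao itself takes the top slot
with ABV 100, and its redundancy legitimately discounts the confounded
allele under the multivariate criteria — the confounding flows through
aao, so conditioning on it absorbs the induced signal.

## Evaluation

Stratified 5-fold outer / 2-fold inner nested CV; inner grid search
maximises mean inner AUC; outer-fold metrics are averaged. Metrics: AUC
(rank statistic, midrank ties), plus accuracy/precision/recall/F1 at
the 0.5 probability threshold with the 0-convention for empty
denominators. Hyperparameter grids per family follow the defaults in
`stratifs.evaluation.DEFAULT_GRIDS`; for the gradient-boosted trees the
regularizers gamma = 2, lambda = 0.5, alpha = 0.5 are fixed and the
learning rate is searched (a single learning-rate parameter — the
boosting step size — cannot be both fixed and searched). `max_features`
values exceeding a cell's feature count are filtered at fit time.
Gaussian NB has no grid; its tuned step is a plain refit. Best cell per
family = maximal mean CV AUC, ties toward fewer features then
criterion name. External validation requires every selected feature to
exist in the external table; missing features are an error, not a
silent subset. The full default grid is 7 criteria × 8 feature counts
× 7 models = 392 cells (an optional no-selection arm adds one
all-features cell per model); the analysis drivers and the acceptance
script run representative slices (3×3×4 and 2×3×3 cells, B = 50) so a
single core finishes in minutes, with per-family grids reduced
alikewise — the slice sizes are stated in each driver.

## Determinism

One master seed spawns named child seeds per stage (simulate, holdout,
mitigation, bootstrap, cv, model, permute) via `SeedSequence`, so any
stage can be reproduced in isolation and two identical runs produce
byte-identical output tables (asserted in tests).

## Leakage guard

The strongest whole-pipeline check permutes the labels once and runs
feature selection plus nested CV unchanged: the mean outer AUC must stay
near 0.5. Note a subtlety: because the bootstrap-vote ranking is
computed once on the full training data (as in the deployed design, not
re-run inside each outer fold), the selected features carry a little
spurious association into the CV folds; at n = 2500 this feature-
selection optimism is ~0.03 AUC, visibly inside the [0.45, 0.55] band,
but at a few hundred samples it reaches ~0.08 — a useful reminder that
this design's CV estimate is not fully unbiased at small n.

## Known limitations

* Plug-in MI is biased upward on small/duplicated samples; no
  bias-corrected or continuous (k-NN) estimators are provided.
* The mitigation bound is only as fine as the confounder bins; residual
  within-bin confounding is reduced, not eliminated (~90–99% MI
  suppression at the default conditions, never exactly 100%).
* The aggregate ranking can legitimately prefer an LD partner of the
  causal allele; stability voting does not break LD ties by causality.
* PCs are taken as given inputs; the package does not compute them.
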