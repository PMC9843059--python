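# Methods

`tmepipe` quantifies the tumor microenvironment (TME) of lung-adenocarcinoma
H&E slides from nuclei centroid maps, predicts which patients benefit from
EGFR tyrosine-kinase-inhibitor (TKI) therapy, and links the predictive image
features to gene expression. The package consumes the output of an upstream
nuclei-classification model (one row per nucleus: position and one of six
classes — tumor, stroma, lymphocyte, red blood cell, macrophage,
karyorrhexis); it does not perform segmentation itself.

## Image features

A slide is reduced to 12 features plus the tumor/stroma ratio (TSR):

1. **Tumor region of interest.** The slide is partitioned into 500 × 500 px
   tiles (0.25 µm/px); a tile belongs to the tumor region iff it contains at
   least 10 tumor nuclei. Edge tiles narrower than the tile size use the
   same absolute count threshold (no area proration); this slightly
   disfavors border tiles and is logged.
2. **Patch sampling.** Up to 100 patches of 1024 × 1024 px are sampled,
   each centered on a distinct tumor tile drawn uniformly without
   replacement and clamped into the slide. Patches may overlap.
3. **Densities.** Per patch, the count of nuclei of each of the six classes;
   the slide feature is the unweighted mean over patches.
4. **Interactions.** Per patch, the Delaunay triangulation of all member
   nuclei defines the neighbor graph. The tumor–X interaction is

       I(tumor, X) = #edges(tumor–X) / #edges incident to ≥1 tumor cell,

   with tumor–tumor edges counted once in numerator and denominator. The six
   fractions therefore sum to 1 whenever any tumor-incident edge exists and
   each lies in [0, 1]. They are invariant under translation, rotation and
   uniform scaling of the coordinates (the triangulation is combinatorial).
   Patches with < 3 non-collinear cells or no tumor-incident edge carry
   undefined interactions and are excluded from the interaction average but
   still contribute to densities.
5. **Aggregation.** Slide = mean over patches; patient = mean over slides
   with a tumor region. Slides with no tumor tile are flagged and excluded.
   TSR = tumor count / stroma count inside the selected tiles (undefined
   when the region holds no stroma).

Design choices worth noting: each patch is triangulated independently
(cells outside a patch contribute no edges; the boundary effect is accepted
and shrinks with patch size), and densities are reported as per-patch mean
counts — the ~100-patch sample makes this equivalent, up to a constant, to a
per-100-patch unit, which downstream standardization removes anyway.

## Survival-benefit model

`BenefitCoxModel.fit()` regresses overall survival of TKI-treated patients
on the 12 features with an elastic-net-penalized Cox partial likelihood
(mixing weight α = 0.5 by default; coordinate-descent path via
scikit-survival's coxnet). Features are standardized internally; reported
coefficients are rescaled to original units. The penalty strength λ is
chosen by k-fold (default 5) cross-validated partial-likelihood deviance
(Verweij–van Houwelingen: each fold's contribution is the full-data
log-likelihood of the fold-trained coefficients minus the training-fold
term, with Breslow tie handling — the same objective coxnet optimizes).
Each fold's deviance curve is centered on its own null-model (largest-λ)
value, so the fold-to-fold spread measures variation in *improvement*
rather than in the absolute deviance level of the fold's split; without
this, the 1-SE band is inflated by fold composition and the rule collapses
to the empty model. Two selection rules are exposed: `"min"` (default, best
cross-validated fit) and `"1se"` (sparsest model within one standard error
— the natural choice when the goal is a short feature list, and the rule
used by the feature-recovery study).

A patient's **risk score** is Σ βⱼ fⱼ on the original feature scale; higher
score = predicted-not-to-benefit. Cohorts are dichotomized at their own
median score; ties at the median go to the benefit group. For interaction
fractions, hazard ratios are reported per 10-percentage-point increment:
HR₁₀ = exp(0.1 β).

Validation statistics are thin wrappers over lifelines: two-group log-rank
with tidy Kaplan–Meier tables, univariate Cox HRs (Efron ties, Wald 95%
CIs), and the treatment-by-group interaction model with main effects and
the clinical adjusters age, sex, smoking status and surgery (categorical
adjusters dummy-coded, constant adjusters dropped with a warning,
complete-case on missing values).

## Image-genomic association

Genes expressed as zero in more than 20% of patients are removed. Every
remaining gene is correlated with an image feature by Spearman rank
correlation (average-rank ties; large-sample t approximation for per-gene
p). The rho-descending gene list feeds a preranked GSEA: ES is the signed
extremum of the weighted Kolmogorov–Smirnov running sum with weight
|rho|^1; the null distribution draws random same-size gene sets from the
ranked universe (gene-label permutation — appropriate because the ranking
statistic is a precomputed correlation, not a per-sample phenotype);
p = (b+1)/(n+1) over sign-matched null scores; NES divides ES by the mean
magnitude of sign-matched nulls; Benjamini–Hochberg adjustment is applied
across the sets of one analysis. The permutation count (default 10 000)
bounds the attainable adjusted p: with ~40 sets and 1000 permutations the
floor (~0.057) already exceeds 0.05, so significance calls need ≥ ~5000
permutations. The negative control permutes the patient axis of the
feature vector and reruns the full ranking + GSEA. One caveat of the
gene-label null is inherited from every random-gene-set GSEA: genes that
share a latent driver are mutually correlated and move together in any
ranking, so a set of co-expressed genes has a wider ES distribution than
random sets of independent genes. After the patient shuffle the planted
set is therefore occasionally still called significant (the measured
non-significant rate hovers around 0.8–0.9 across seeds rather than
1 − α); this anti-conservatism for internally correlated sets is a known
property of the preranked/gene-permutation regime, not an implementation
artifact. Marker-panel summaries
bin patients by feature quantile and report mean z-scored expression per
bin for curated panels (fibroblast/endothelial, HGF/MET, EGFR/ERBB3, PI3K
adaptors, mesenchymal, epithelial).

## Synthetic data

The generators produce data with exactly the structure the analysis
assumes, so every stage can be validated without the (non-public) clinical
cohorts. Passing these studies demonstrates internal correctness and
calibration — not performance on real slides, which add staining artifacts,
segmentation errors and spatial heterogeneity the generators do not model.

* **Cell maps** — marked point patterns on a 4000 × 4000 px slide: four
  circular tumor nests (radius 500 px) with in-nest tumor intensity
  2 × 10⁻³ cells/px² (≈ one nucleus per 22 px, a dense nest at 0.25 µm/px),
  background stroma at 5 × 10⁻⁵/px² outside the nests, and the four minor
  classes at 10⁻⁵/px² each. The mixing parameter θ ∈ [0, 1] relocates that
  fraction of stroma into the nests: θ = 0 gives pure nests (tumor–stroma
  contact only at nest borders, measured mean I(tumor, stroma) ≈ 0.01),
  θ = 1 fully mixed (≈ 0.20). Counts are Poisson; everything is a pure
  function of (params, seed).
* **Cohorts** — exponential proportional hazards with linear predictor
  βᵀf (centered), baseline rate 0.03/month (median OS ≈ 23 months),
  independent exponential censoring (default rate 0.01 ≈ 25% censored),
  Bernoulli treatment assignment. Planted effects use the per-10%
  convention: a per-10% HR of h is β = ln(h)/0.1 on the 0–1 fraction scale.
  Treatment benefit can be restricted to the true benefit group (linear
  predictor below the cohort median), which creates the
  treatment-by-group interaction the evaluation stage tests.
  A direct per-patient feature generator (Dirichlet interactions with a
  tumor-dominant mean composition and concentration 30; independent gamma
  densities, CV 0.4) supports cohort-scale studies without re-running the
  image pipeline.
* **Expression** — planted genes track the feature through a Gaussian
  copula: gene = exp(a·z_f + √(1−a²)·ε) with a = 2 sin(π ρ_s/6) for target
  Spearman ρ_s (default 0.6), null genes independent log-normal, a small
  zero-inflated block to exercise the filter, one planted set among
  same-size decoy sets.

## Study sizes and numerical choices

The validation studies use: 100 random patches (conservation/invariance),
50 patches ≤ 100 cells against the brute-force O(n⁴) empty-circumcircle
oracle (exact agreement required; random coordinates make cocircular ties
measure-zero), a 0–20 count sweep for the tile threshold, 5 θ-levels × 20
slides for mixing monotonicity, 50 cohorts of n = 400 for feature
selection, 2 × 100 cohorts of n = 1000 for CI coverage (one planted effect
per replicate — with both effects planted the compositional negative
correlation between the two fractions would confound a *univariate* fit),
1000 + 100 cohorts of n = 600 for interaction-test size and power, 20
replicates of 60 patients × 500 genes for GSEA recovery and its shuffle
control, and an 80-patient end-to-end study with per-patient θ ~ U(0, 1).
These sizes give binomial standard errors comfortably inside the asserted
bands while keeping each study in the seconds-to-minutes range.

Known limitations: no intra-slide heterogeneity maps; the per-patch
triangulation ignores cross-patch edges; an end-to-end fit on a small
heterogeneous cohort may select density features that proxy the planted
interaction effects (the features co-vary along the mixing gradient) —
feature-level identifiability is established by the dedicated selection
study at n = 400, not by the 80-patient demonstration pipeline; exact
Spearman p-values for tiny n are not implemented (t approximation).
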