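# Methods

This note records the models, parameter choices and numerical decisions
behind `rarebin`, and what the synthetic-data generator does and does not
emulate.

## Study design being modelled

Two case-control cohorts of severe, treatment-resistant ("atypical")
schizophrenia, sequenced over a single candidate gene: a discovery cohort
of 380 cases / 380 ancestry-matched controls and a replication cohort of
477 cases / 479 controls. Qualifying alleles are ultra-rare (folded
MAF < 0.1%, implying singleton carriers at these sample sizes)
non-synonymous variants, each of which has been scored in a zebrafish in
vivo complementation assay: a morpholino (MO) suppresses the orthologous
transcript, enlarging the hindbrain ventricle; co-injection of wild-type
human mRNA rescues the phenotype, and each variant mRNA is scored against
those two poles.

## Genotype and sample QC

* **Call rate**: non-missing fraction per variant. The default inclusion
  threshold is call rate > 0.15, matching the source analysis as printed;
  the value is unusually permissive (0.85 would be conventional) and is
  config-exposed (`call_rate_min`) for that reason.
* **MAF**: folded alternate-allele frequency over non-missing diploid
  calls, computed on analyzed cases + controls jointly (the analysis that
  motivated this package computed MAF in-study rather than against an
  external reference). Strata (5%, 1%, 0.1%) are nested by construction.
* **Missingness policy**: missing calls are excluded from call-rate/MAF
  denominators, mean-imputed per variant for PCA, and treated as
  non-carrier for carrier counting and association scores. A missing call
  is never evidence of carriage.
* **IBS**: mean of `1 − |d_i − d_j|/2` over pairwise-complete variants.
  Duplicate pairs at IBS ≥ 0.99, first-degree relatives at ≥ 0.85; the
  member with the lower call rate is excluded. These cutoffs are package
  choices (the motivating analysis reports outcomes, not thresholds).
  Inside the pipeline, IBS uses common markers only (MAF > 5%): ultra-rare
  sites are reference-homozygous in almost every pair and would drag all
  pairwise IBS toward 1. Relative calling is additionally disabled below
  200 common markers — with a handful of markers the unrelated-pair IBS
  distribution overlaps the first-degree range, so only duplicate calling
  (which needs near-exact identity) remains reliable.
* **PCA outliers**: common variants, mean-imputed, centered, unit-scaled;
  scores from SVD. A sample is flagged when any of the top 10 component
  scores is more than 6 robust SDs (1.4826 × MAD) from the component
  median — the usual smartpca-style rule. Flags are invariant to component
  sign. An `ld_prune` (window 50, step 5, r² 0.2) helper is provided for
  real panels; simulated variants are independent, so the common-variant
  subset already is the pruned set.

## Allele classification from rescue measurements

Per-embryo ventricular areas are normalized by the mean control-arm area
of the same injection batch (so control mean ≡ 1 per batch, and batches
with different absolute scales pool correctly). For each allele, two-sided
Welch t-tests compare the MO+variant arm against the MO-alone and MO+WT
arms of its batch:

* `p_vs_wt ≥ α` → **benign** (indistinguishable from full rescue);
* else `p_vs_mo ≥ α` or variant mean ≥ MO mean → **lof** (alleles more
  severe than the morphant are folded into lof — no separate antimorph
  class is kept);
* else → **hypomorph**.

α = 0.05 per allele, uncorrected, mirroring per-allele scoring with
reported per-variant p-values; a Bonferroni option exists
(`classify_assay_table(..., bonferroni=True)`). Welch rather than pooled-
variance t is used because arm variances are not assumed equal. Degenerate
zero-variance arms compare by exact equality (identical constant arms give
p = 1, different constants p = 0), keeping the rule total. The rule is
exhaustive and ordered: sliding the variant mean from the rescue mean to
the morphant mean traverses benign → hypomorph → lof.

Binarization maps hypomorph and lof to **pathogenic**; concordance between
two assays (e.g., ventricle size vs convergent-extension) is the fraction
of alleles with the same binarized score, with within-pathogenic
disagreements listed but not counted discordant.

## Association

Permutation SKAT-O as described in the README: per-variant score
statistics, the ρ-grid {0, 0.01, 0.04, 0.09, 0.25, 0.5, 1}, and a min-p
correction in which the observed minimum over ρ is referred to the
permutation distribution of each permutation's own minimum. Permutation
replaces the Davies/Liu quadratic-form asymptotics deliberately: with
singleton variants and a few hundred subjects the asymptotic null is at
its worst, while label permutation is exact at any n. The price is a
resolution floor of 1/(B+1); B defaults to 9,999 and results record a
warning when B < 999. Tie handling counts permuted statistics within
1e-12 relative tolerance as ≥ observed, which keeps the all-zero-genotype
case at p = 1 exactly. Ties in the best ρ resolve to the first grid
entry.

Both unweighted (w = 1) and Madsen–Browning-weighted p-values are always
reported side by side, since the motivating report prints an "unweighted
p" next to weighted analyses. Multiplying all weights by a constant
provably leaves every permutation p unchanged (both branches of Q scale by
the square).

**Meta-analysis** is pooled-genotype analysis with permutation stratified
by cohort (per-cohort case counts are preserved exactly in every
permutation), not an inverse-variance combination: the pooled counts in
the motivating tables equal the per-cohort sums, consistent with pooling.
Each subset and run label derives its own permutation stream from the run
seed via a CRC fold, so stage-level reruns reproduce bit-identically.

Variants without an assay label default to **benign** in binning — every
control-only allele that was assayed scored benign, making that the
conservative default for association in the pathogenic direction.

## Firth effect sizes

The penalized likelihood `l*(β) = l(β) + ½ log det(XᵀWX)` is maximized by
damped Newton iteration on Firth's modified score
`U* = Xᵀ(k − np + h(½ − p))`, with step-halving, a step cap of 5 per
iteration, and convergence at score ∞-norm < 1e-8 or an outstanding
Newton step < 1e-9. Because XᵀWX omits the penalty's curvature, the
ascent is linearly convergent near degenerate optima and can stall at the
objective's noise floor; a quasi-Newton (BFGS) polish on the exact
gradient then finishes the fit. Rank-deficient designs are rejected with
the offending column named.

For a saturated 2×2 table the maximizer is closed-form — the
Haldane-corrected cross-product ratio — because the penalized likelihood
equals (up to a constant) the binomial likelihood of the table with ½
added to each cell. `firth_2x2` uses this fast path and agrees with the
Newton fit to < 1e-6; the same identity handles the doubly-degenerate
no-carrier table `(0, n, 0, m)` (OR = 1) where the expanded design is
rank-deficient.

Confidence intervals invert the penalized likelihood-ratio statistic at
χ²₁(0.95), profiling nuisance parameters under the full-model penalty;
bracket expansion (×1.6) followed by Brent root-finding locates each
bound. The penalty forces `l* → −∞` as |β| → ∞, so profile bounds are
finite even under complete separation; upper bounds above 999 on the OR
scale are reported as 999 with `ci_capped=True`, matching the reporting
convention of the motivating tables.

Effect-size denominators default to the analyzed (post-QC) cohort sizes;
the worked example uses the pre-QC totals (380/380, 477/479, 857/859)
because post-QC totals were not published — reproduced ORs therefore
carry a documented ±10% tolerance, and denominators are config-exposed.
The summary tables report both summed per-variant carrier counts (the
"N variants" convention, identical for singletons) and, internally for
the 2×2 fits, distinct carrier individuals.

## Synthetic-data generator

`simulate_cohort` draws, per cohort: ultra-rare variants as
exact-carrier-count events (default one het carrier) whose carrier is a
case with a per-class probability (benign 0.5, hypomorph 1.0, lof 1.0 by
default — in the motivating data every hypomorph/lof carrier was a case
and benign carriers split evenly), plus common variants
(MAF ~ U(0.05, 0.45), Hardy-Weinberg dosages) shared across cohorts as a
marker backbone for PCA/IBS. Missingness, when enabled, is uniform at
random per variant (no informative-missingness mechanism is modelled
because none was described). Exact carrier counts rather than binomial
draws reflect that MAF < 0.1% at these sample sizes means singletons.
`two_cohort_spec()` reproduces the study conditions: 380/380 + 477/479
samples; 6+6 lof, 5+5 hypomorph, 10+6 benign singletons.

`simulate_assay` draws per-embryo areas as Normal(class mean, σ) clipped
to positive, with one shared control / MO / MO+WT arm per batch (one
injection round). Defaults: control 1.0, MO 1.6, WT rescue 1.05,
hypomorph 1.30, σ = 0.15, 30 embryos per arm. The means follow the
normalized scale of the motivating figure (morphant enlargement ~1.6×);
σ and per-arm n are package choices picked to be realistic for embryo
imaging, since per-embryo variance was not published.

What the generator does **not** emulate: LD between variants, population
stratification (beyond what PCA flags by chance), batch effects or
non-Gaussian tails in the assay, genotyping error, and informative
missingness. Passing recovery/power tests therefore demonstrate that the
statistical machinery behaves as designed under its own assumptions — not
that those assumptions hold in any particular real dataset.

## Problem sizes used in the checks

The acceptance-style tests run: an exhaustive Newton-vs-grid sweep over
all ~243k 2×2 tables with margins ≤ 30; 200 null cohorts (380/380, 20
singletons, B = 999) for type-I calibration; 500 simulated alleles for
classifier recovery; and 100 full-pipeline replicates at the two-cohort
study sizes (B = 999) for power in the pooled pathogenic bin. These sizes
give Monte-Carlo error comfortably inside the asserted bounds while
keeping the suite quick on a laptop.

## Known limitations

* No covariate-adjusted SKAT (the motivating analysis reported none); the
  Firth fit accepts extra design columns (e.g., cohort) but the pipeline's
  default pooled effect sizes are unadjusted, matching the pooled-count
  convention.
* The analytic SKAT-O machinery (Davies' method, small-sample moment
  corrections) is intentionally absent; p-values have permutation
  resolution 1/(B+1).
* The CE (convergent-extension) assay enters only as a second label
  vector for concordance; its image-derived measurements are not
  modelled.
* `ld_prune` is a greedy reference implementation suitable for panel-
  sized data, not an optimized genome-wide pruner.
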