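# Methods

This note documents the statistical model behind `mitomethyl`, the synthetic
data it is validated on, the numerical choices made where the design was
genuinely open, and the known limitations.

## Data model and filtering

Input is one Bismark-style cytosine report per sample (tab-delimited:
position, strand, methylated count, unmethylated count, context,
trinucleotide), with 1-based positions on the canonical, unpadded circular
mitochondrial reference. `+` maps to the heavy (H) chain and `-` to the
light (L) chain; the mapping is configurable. Counts are assumed
base-quality-filtered upstream (Q ≥ 30 read trimming happens before
alignment); this package starts at the count level.

The methylation level at cytosine *i* is `100 · numCᵢ / (numCᵢ + numTᵢ)`
percent. Two filters define the analysis matrix:

- **coverage**: a call needs `numC + numT ≥ 30` (the methylKit
  `filterByCoverage(lo.count = 30)` convention);
- **presence**: a site enters the matrix only if it passes the coverage
  filter in *every* sample of that brain area, so the grid has no missing
  cells.

Context is classified from the two bases downstream of the cytosine on its
own strand, with circular wraparound: next base G → CpG, else
next-but-one G → CHG, else CHH. On the L chain, "downstream" means
decreasing plus-strand coordinates with complementation.

## Per-site tests

- **Brain-area contrast** — Wilcoxon signed-rank on within-individual
  NAcc−PFC differences. Zeros are dropped (Wilcoxon's rule) and ties
  mid-ranked. The null distribution is exact — tie-aware, computed by
  convolution over sign assignments — whenever ≤ 25 non-zero differences
  remain, and a tie-corrected normal approximation (variance Σrᵢ²/4, no
  continuity correction) otherwise. The reported effect is the natural-log
  fold change of group site means with a 0.01-percent pseudocount guarding
  zero means (far below the ~2% working regime, so it never dominates).
- **Drug-use contrast** — one logistic regression per site:
  `group ~ level + age + batch + collector + alcohol + PMI class`, returning
  the level coefficient (log-OR per percentage point) and its two-sided Wald
  *P*. Perfect separation, rank deficiency, or unstable fits (|β| > 50 or
  SE > 100) yield *flagged* results that are excluded from selection rather
  than emitted as infinities. Fitting one model per site is the only viable
  reading at n ≈ 53; a joint model over thousands of sites is not estimable.
- **Age association** — one linear model per site:
  `level ~ age + batch + collector + alcohol + PMI class`; the age
  coefficient (percent per year) is both the test statistic's effect and the
  index weight. With no covariates it equals r·(s_level/s_age), i.e. the
  slope implied by the Pearson correlation, which reconciles
  "slope-from-correlation" weighting with a covariate-adjusted fit.

Site **selection is raw P < α with no multiple-testing adjustment** — a
deliberate design mirror of Manhattan-plot thresholding; α (default 0.05,
with 0.02 and 0.005 in the sensitivity sweep) is a first-class parameter.
Expect roughly 5% of null sites to enter each index; the indices are
aggregate signatures, not site-level discoveries.

## Indices, clock, classifier

Each index is `Σ βᵢ·Mᵢ` with Mᵢ **in percent** (documented to prevent silent
fraction/percent mismatches). Weights are copied verbatim from the per-site
results. The clock is a univariate OLS of chronological age on the Age-index
score, trained on controls only; drug-use samples are scored with the frozen
model, and age acceleration = predicted − chronological age. Heroin-positive
individuals are excluded from acceleration contrasts (heroin is reported to
rejuvenate rather than accelerate the epigenetic clock); ketamine and
ATS subgroup contrasts reuse the same acceleration vector under subgroup
masks. Group contrasts use Mann–Whitney (exact when m+n ≤ 20 without ties,
tie-corrected normal otherwise).

The drug-use threshold is `mean + 1.96·SD` of control scores with the n−1
sample SD (the denominator is not dictated by the formula; n−1 is chosen and
documented). Classification is strict `score > threshold`; ties at the
threshold are negative calls, preserving the one-sided 97.5% null
specificity of the 1.96 rule. PPV/NPV are undefined (reported as null) when
no positive/negative calls exist. ROC points are swept over all distinct
score thresholds; the trapezoidal AUC then equals the tie-adjusted
Mann–Whitney U/(n₁n₂), which the test suite checks to 1e-12. Both the fixed
threshold's confusion matrix and the full ROC are reported.

Power for the design question "can n = 39 detect r ≥ 0.5" uses the Fisher-z
two-sided formula Φ(δ − z_{1−α/2}) + Φ(−δ − z_{1−α/2}), δ = √(n−3)·atanh(r);
the opposite-tail term is negligible at real effect sizes but keeps the
r → 0 limit equal to α.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
raw reads (no FASTQ simulation, no bisulfite-conversion-error model, no
nuclear-mitochondrial decoys — alignment is out of scope):

- **Reference**: random circular sequence, default 16,569 bp at GC 0.44,
  standing in for the human mitochondrial genome.
- **Cohort**: default 39 controls + 14 drug users, male-forensic-style
  covariates: ages truncated-normal with an 18-year floor (the pre-truncation
  location is solved so the observed means hit 54.9/37.5 years with SD
  21.5/12.0), drug-type mix 2:5:3:4 (heroin / ATS-only / ketamine-only /
  ATS+ketamine), alcohol and PMI-class frequencies per group, uniform batch
  and collector labels, group-specific cause-of-death mix. One drug
  individual (heroin users first) lacks a PFC sample; that individual is
  dropped pairwise from paired analyses and retained in NAcc-only analyses.
- **Methylation**: per-site baseline means drawn from a beta distribution
  with mean 0.02, capped at 0.08. Effects are additive on the **logit**
  scale — a brain-area shift (NAcc only), a per-year age slope applied to
  centered age, a drug-group shift, and lognormal individual noise — which
  keeps probabilities in (0,1) at low baselines. Planted site sets are
  pairwise disjoint; 80% of planted effects take the direction the analysis
  expects (NAcc-hyper, age-hyper, drug-hyper), the rest the opposite.
  An optional `du_age_shift_years` adds a fixed epigenetic-age offset to the
  drug group's age-site methylation for acceleration-recovery experiments.
- **Coverage**: negative-binomial around strand mean × lognormal site factor
  × lognormal sample factor. Shared site factors make L-chain dropout
  consistent across samples, so the presence rule removes mostly L-chain
  sites — the strand asymmetry seen in real data (H default 100×, L 40×).
- **Counts**: methylated reads binomial given coverage and the assembled
  probability. One RNG stream per dataset component, spawned
  deterministically from the config seed; fixed seed ⇒ byte-identical files.

What the generator does **not** model: linkage between neighboring sites,
sequence-dependent methylation propensity, population substructure or
polymorphism-induced miscalls, batch effects on methylation itself (batch is
a pure noise covariate). Passing recovery tests therefore demonstrates that
the pipeline's statistics behave as designed under its assumed model, not
that the biological findings replicate.

## In-sample clock R², honestly

Because index sites are selected *and* weighted on the same individuals the
clock is then fit on, the in-sample clock R² is strongly inflated by
selection: with ~3,700 candidate sites and n = 39, even effect-free data
yield a substantial in-sample fit (the test suite's recovery harness
documents this: a 1,200-bp universe with a weak planted age signal lands at
median R² ≈ 0.46). The default synthetic study reports in-sample R² ≈ 0.9.
Any out-of-sample claim about a clock built this way requires independent
validation data; the package deliberately reproduces the in-sample protocol
and flags the caveat rather than silently substituting cross-validation.

## Problem sizes and numerical choices

- Default study: full 16,569-bp genome, 105 samples, ~3,500–3,800 retained
  sites per area; a complete pipeline run takes ~2 minutes on one CPU.
  Unit and property tests run on a 3,000-bp, 30-individual study; recovery
  experiments use 8,000-bp genomes; null calibration uses 2,200 sites of the
  full genome.
- Wilcoxon exactness boundary at 25 non-zero pairs: the tie-aware
  convolution is O(n·Σrᵢ²) and instant there; beyond it the mid-rank normal
  approximation is accurate.
- Logistic fits: Newton iterations capped at 200; non-finite or separated
  fits are flagged, never selected.
- Degenerate inputs hard-error early: zero-coverage levels, constant clock
  scores, empty selections (with advice to loosen α), fewer than 2 control
  scores for the threshold, zero chi-square marginals.
- The sensitivity sweep treats an empty index at a strict α as a reported
  outcome, not a failure, and verifies selected-site nesting across α.

## Open interpretation choices

- "log" in fold change and odds ratio is the natural log (the native scale
  of logistic regression; the indices only need sign/scale consistency).
- Wald *P* values are reported for the per-site logistic fits (vs LRT/score:
  unstated in the protocol being mirrored; Wald is documented).
- Fold changes are computed on per-site group means, not per-pair ratios.
- The clock's confidence band, where emitted, is the mean-response CI of the
  OLS line, flagged as an interpretation.
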