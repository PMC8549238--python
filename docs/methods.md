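# Methods

## Overview

`dietnet` implements a network view of dietary patterns. Food-group
intakes (g/d, typically derived from a food frequency questionnaire) are
modelled as a Gaussian graphical model (GGM): subjects' standardized
intakes are treated as multivariate normal, and the sparse precision
(inverse covariance) matrix Ω encodes which food groups are conditionally
dependent given all others. Edges of the resulting graph carry partial
correlations ρ_ij = −ω_ij / √(ω_ii ω_jj); |ρ| ≥ 0.20 is flagged "strong".
Overlapping communities of edges summarize the graph, connected unions of
communities with ≥ 3 food groups form *dietary networks* interpreted as
dietary patterns, subjects are scored on each network, and network-score
tertiles are related to general and abdominal obesity by logistic
regression.

## Sparse precision estimation

The graphical lasso maximizes

    log det Ω − tr(SΩ) − λ Σ_{i≠j} |ω_ij|

over positive-definite Ω, with S the sample correlation matrix of the
standardized intakes. Estimation is on the correlation scale because
network scores standardize intakes anyway and partial correlations are the
reported quantity.

Numerical choices:

- Block coordinate descent (one lasso subproblem per row/column of the
  working covariance W), converged when the maximum elementwise change of
  W per sweep falls below 1e−6 (500-sweep cap; inner lasso tolerance one
  decade tighter).
- The penalty applies to off-diagonal entries only. Consequences used as
  invariants: λ = 0 returns inv(S) exactly (error if S is singular, with
  advice to use a positive penalty), and λ ≥ max_{i≠j}|S_ij| returns an
  exactly diagonal Ω with ω_ii = 1/s_ii.
- Edge existence: |ω_ij| > 1e−10.
- Penalty selection: extended BIC, EBIC(λ) = −2·loglik + k·log n +
  4·k·γ·log p with k the nonzero upper-triangle count and γ = 0.5 by
  default, minimized over a 30-point descending log grid from
  λ_max = max|S_ij| spanning two decades, with warm starts along the
  grid. Ties keep the larger (sparser) λ. A fixed-λ override exists.

## Link communities and dietary networks

Communities are detected on edges, so a food group can belong to several
communities. Adjacent edges (i,k), (j,k) are scored by the Jaccard
similarity of the inclusive neighborhoods n⁺(i), n⁺(j) of their unshared
endpoints (n⁺(x) = {x} ∪ neighbors(x)); non-adjacent pairs score 0.
Single-linkage agglomeration over edges gives a dendrogram — the canonical
choice for this similarity, and deterministic here with lexicographic
tie-breaking. Every distinct merge height is a candidate cut, scored by
partition density

    D = (2/M) Σ_c m_c (m_c − n_c + 1) / ((n_c − 2)(n_c − 1)),

where community c has m_c edges over n_c nodes and M is the total edge
count; communities with n_c = 2 contribute 0. The cut maximizing D is
returned; ties go to the higher similarity (more, smaller communities),
and the all-singletons partition (D = 0) is the baseline, so the returned
D is never negative. By default all nonzero-partial edges enter
clustering; a "strong-only" mode restricts to |ρ| ≥ 0.20.

Dietary networks are the connected components of the union of community
edge sets with at least three food groups; smaller components are dropped
(a lone conditional dependence is not a pattern). A network's central food
maximizes the number of communities it belongs to, with ties broken by the
largest summed |ρ| over incident edges. Networks are named by size rank
and can be renamed by the analyst (healthy / unhealthy / saturated fats in
typical applications).

## Network scores and tertiles

Per network, loadings are the first principal component of the network
columns' correlation matrix, scaled by √(leading eigenvalue)
(factor-loading convention), with the sign oriented so the central food
loads nonnegatively — this anchors an otherwise arbitrary eigenvector
sign. PCA runs per network on that network's columns. A subject's score is
Σ_j loading_j · z_j over the network's food groups. An exactly tied
leading eigenpair (within 1e−8) raises a degeneracy error rather than
returning an arbitrary direction.

Scores are categorized into rank-based tertiles (T1 = lowest): stable sort
by score, group sizes as equal as possible with the remainder assigned to
the lower tertiles, ties resolved by input order. Because tertiles are
rank-based, any positive rescaling of the loadings (including the
eigenvector-vs-loading scale ambiguity) leaves the analysis unchanged.

## Outcomes and association models

General adiposity is BMI ≥ 30 kg/m² (inclusive); abdominal adiposity is
waist circumference > 102 cm (men) / > 88 cm (women), or waist-to-hip
ratio > 0.90 (men) / > 0.85 (women) (strict bounds). Odds ratios across
tertiles (T1 reference) come from maximum-likelihood logistic regression
with Wald 95% CIs (exp(β ± z_{1−α/2}·SE)); the crude model has tertile
indicators only, the adjusted model adds the configured covariates
(default: age, sex, occupation, smoking, education, marital status,
menopausal status, physical activity, energy intake). Energy enters as a
model covariate, not by the residual method. The P-for-trend refits the
model with the tertile index (1, 2, 3) as a single continuous term and
reports its Wald p-value — the standard nutrition-epidemiology coding.

Menopausal status is entered as a single post-menopausal indicator. The
three observed levels (pre, post, not applicable) are exactly collinear
with sex, since non-applicability encodes being a man; the single
indicator keeps the design full-rank with men and pre-menopausal women as
the shared reference.

Descriptive tables report mean ± SD per tertile with one-way ANOVA
p-values for continuous covariates and percent per level with Pearson χ²
(no continuity correction) for categoricals; single-level categoricals are
flagged and skipped. Separated or unstable logistic fits (non-finite SEs
or |β| > 20) raise an error rather than returning meaningless CIs.

The design-stage sample-size formula for a prevalence study is also
provided: n = p(1−p)z²/E², z the standard-normal 1 − α/2 quantile,
optionally multiplied by a design effect (e.g. 65% prevalence, E = 0.04,
α = 0.05 → 546; design effect 1.5 → 819).

## Synthetic cohort generator

The generator plants known structure so every stage can be validated:

- **Structure.** Disjoint blocks of food groups form partial-correlation
  cliques (equal within-block partials); optional single "bridge" edges
  join blocks into larger networks. The default: 35 food groups, six
  5-food blocks at within-block partial 0.2, bridged pairwise (partial
  0.1) into three 10-food networks — 30 foods in communities, five
  unstructured. A k-clique of equal partials is positive definite only for
  ρ < 1/(k−1); 0.2 respects the bound for k = 5 so planted values are
  achieved exactly. Infeasible requests trigger diagonal loading in 0.05
  steps (error beyond δ = 10), and the achieved (shrunk) partials are
  re-reported rather than assumed.
- **Intakes.** Rows are drawn from the multivariate normal with covariance
  inv(Ω). The `exponential-shift` transform maps latent z to
  50·exp(0.5·z) g/d — nonnegative, right-skewed, median ≈ 50 g/d —
  emulating FFQ-style marginals while preserving ranks. The monotone map
  attenuates Pearson correlations slightly; the pipeline standardizes
  downstream, and this distortion is accepted and visible in recovery
  experiments.
- **Covariates.** Age N(44.7, 10.8) clipped to 20–59 y, 69% women, 63%
  low physical activity (< 3000 MET-min/week), 5.2% current smokers,
  80.9% married, energy N(2586, 1140) kcal/d, post-menopause in 27.8% of
  women; men carry an explicit not-applicable menopause code, never a
  missing value.
- **Outcomes.** Bernoulli draws with logit = intercept + Σ log-OR ×
  tertile indicator of the *planted* (equal-weight) network scores. The
  default links the third planted network to abdominal adiposity by WHR
  (T3 vs T1 OR 1.5) and the second, weakly, to abdominal adiposity by
  waist circumference (OR 1.35), with general adiposity null — the
  qualitative pattern reported for saturated-fat and unhealthy dietary
  networks; baseline prevalence ≈ 30%.

Everything is a pure function of (inputs, seed).

### What the generator does and does not emulate

It reproduces the conditional-dependence geometry, sample size, covariate
mix and outcome effect sizes of an adult FFQ cohort. It does not emulate
item-level (e.g. 168-item) questionnaires, measurement error, energy
mis-reporting, intake zero-inflation, or covariate–intake confounding
(covariates are drawn independently of intakes). Passing recovery tests
therefore shows the pipeline is correct and well-calibrated under its own
model assumptions — not that any particular real cohort's networks are
right.

### Observed recovery behavior

At n = 850 with skewed marginals, EBIC-selected graphs carry a handful of
weak false-positive edges. These rarely harm edge-level recovery (median
F1 ≈ 0.85 for 3 planted 4-food cliques at partial 0.3) but can chain
separate planted networks into one connected component, so
assembled-network node sets typically match planted blocks with Jaccard
≈ 0.8 rather than 1.0. This is inherent to the connected-component
assembly rule at epidemiological sample sizes and is why central-food and
community structure, not component boundaries, should carry the
interpretation in small cohorts.

## Problem sizes

Validation uses the generator's stated conditions: 850-subject cohorts
over 35 food groups (20 replicate seeds for structure recovery), 200
replicates for CI coverage and null type-I error, and a single
100 000-subject cohort for large-sample OR recovery. The full test suite
runs in well under two minutes on one CPU.

## Known limitations

- No nonparanormal/copula GGM extensions and no bootstrap edge-stability
  assessment; skewed marginals are handled only by the optional
  log(x + 1) transform.
- No weighted (|ρ|-scaled) edge-similarity variant is enabled by default;
  the unweighted Jaccard on the thresholded edge set is used.
- Wald CIs and p-values only (no profile likelihood or exact tests); no
  multiple-testing correction across networks and outcomes.
- The connected-component network-assembly rule can merge communities
  linked by spurious weak edges (see above).
- Tertile-median trend coding is not implemented; the ordinal index
  coding is the single supported choice.
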