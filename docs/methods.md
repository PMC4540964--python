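# Methods

`crmou` treats a per-region quantitative signal — a homotypic CRM score
computed from sequence, or a normalized chromatin/binding measurement —
as a trait evolving on a phylogeny, and asks on which lineage, if any,
the trait's optimum has shifted.

## Homotypic cluster score

For a PWM *M* of length *L* and a region *S*, the CRM score is a log2
likelihood ratio between a *cluster model* and a background model,
maximized over subsegments of the region:

    score(S) = max over [a,b) of log2 Σ_parses Π_sites (q/2)·odds(site)
               · (1-q)^(# background bases in [a,b))

where a *parse* places any number of non-overlapping motif occurrences
(either strand, hence the 1/2) inside the subsegment, `odds` is the
PWM-versus-background likelihood ratio of the site sequence, and
`q = 1/(1 + g)` with `g` the expected gap so that inter-site gap lengths
are geometric with mean `g`. The sum over parses is computed exactly by a
forward recursion; the maximization over subsegments is exact as well (the
recursion carries all candidate segment starts at once, O(n²) with
vectorized inner steps — milliseconds at enhancer lengths). The empty
parse of the empty segment has ratio 1, so the score is floored at exactly
0, and a single strong match scores as a one-site cluster.

Parameters and defaults:

* `pseudocount = 0.375` per count cell before normalizing a PWM (the
  Cluster-Buster-compatible convention).
* `gap = 35` bp expected background gap between sites within a cluster.
  Both are conventions rather than quantities estimated from data, and
  both are configurable.
* Background model: 0th-order base frequencies estimated from the scored
  region itself (lightly smoothed, +1 per base), switchable to uniform or
  explicit genome-wide frequencies. `N` bases contribute a factor of 1 to
  both models (score-neutral); note that a site *partially* overlapping an
  N run is still considered with the N positions neutral, so masking
  context can only add parses, never remove evidence.

The score is symmetric under reverse complement and, for a zero-information
PWM on a uniform background, identically 0.

## Trait models on the tree

All models describe a trait X(t) along a rooted tree with branch lengths:

* **BM**: dX = σ dB(t). Tip covariance σ²·t_ij with t_ij the root-to-MRCA
  distance; free parameters x0, σ² (k = 2).
* **Single-optimum OU (M0)**: dX = α(θ − X)dt + σ dB(t) — stabilizing
  selection toward one optimum θ (k = 3: α, σ², θ).
* **Branch-shift (Hansen) models**: the branches of a designated clade
  (including its stem — the optimum changes on the lineage leading to the
  clade) carry their own optimum θ_shift (k = 4).

Conventions that change likelihood values and are therefore stated
explicitly:

* The root state is pinned to the root regime's optimum, not estimated.
  This keeps the branch-shift vs M0 comparison at one degree of freedom.
* The process starts at the root with zero variance (no stationary-root
  option in this version).
* Tip moments use the exact path integrals
  E[X_i] = x0·e^(−α·s_i) + Σ_b θ_b·(e^(−α(s_i−t_end)) − e^(−α(s_i−t_start))),
  V_ij = σ²/(2α)·e^(−α(s_i+s_j−2t_ij))·(1 − e^(−2α·t_ij));
  `expm1` keeps everything stable down to α = 1e−10, where the model
  agrees with BM to < 1e−5 in log-likelihood (no explicit series switch).
* Missing species are pruned and the regimes re-derived on the induced
  subtree; a branch-shift model whose shift clade (or base set) is
  entirely missing is reported `untestable` rather than silently refit.
* A near-constant trait floors σ̂² at 1e−12 and flags the fit `degenerate`.

**Fitting.** For fixed α the tip means are linear in the optima, so the
optima are solved by generalized least squares and σ² in closed form; the
profile likelihood is maximized over α ∈ [1e−8, 100/tree-height] by a
17-point log-spaced grid scan refined with bounded Brent search around the
best bracket (tolerance 1e−6 in log α), plus refinement around any
caller-supplied α (the pipelines seed branch-shift fits with M0's α̂,
which also enforces the nesting inequality loglik(Mx) ≥ loglik(M0) in
practice). The grid-plus-refinement scheme was chosen over a small
multi-start because α is weakly identified on 12 tips: under BM-generated
data the fitted α concentrates at negligible values with a point mass at
the lower bound, and a dense scan is cheap (structure factorizations are
cached per α and shared across regions).

## Model choice

* **LR test** (branch-shift vs M0, nested, df = 1): LR = 2(ℓ_x − ℓ_0),
  clipped at 0, referred to χ²(1).
* **Akaike weights**: w_i = exp(−Δ_i/2)/Σ exp(−Δ_r/2), Δ_i = AIC_i − min
  AIC, computed in shifted form. Pairwise (Mx vs M0) is the default
  comparison — a region is divergent under Mx iff w(Mx) > 0.5, with exact
  ties going to the simpler M0; because the models differ by one
  parameter this is the same decision as LR > 2. "Triple" (BM/M0/Mx) and
  "all-models" comparisons are provided and are more stringent.
* **Direction**: gain iff θ̂_shift > θ̂_base (indeterminate below 1e−9).
* **BH adjustment** is available across regions × models for trait-table
  screens.

**Small-sample caveat (important).** The χ²(1) reference is asymptotic.
On a 12-tip tree with ML σ² and profiled α, the LR under the
single-optimum null is stochastically larger than χ²(1): the exact
fixed-α analogue of the test (one extra GLS mean parameter, n = 12) already
rejects at ~8% for a nominal 5%, and α profiling pushes the measured rate
to ~10%. The package therefore ships the parametric bootstrap (below) as
the calibrated route for regions that matter; the χ² p-values are best
used as a ranking score, as the genome-wide screens here do.

## Parametric bootstrap (phylogenetic Monte Carlo)

For two candidate models a and b on one region: fit both; simulate
`n_boot` (default 1,000) data sets under each fitted model by the exact
per-branch transition recursion; refit *both* models to every simulated
set; record δ = 2(log L_a − log L_b). The two δ distributions locate the
observed δ (quantiles reported) and their overlap — computed as 1 minus
the total-variation distance on pooled Freedman–Diaconis bins; the choice
of overlap statistic is a convention, as overlap is usually only displayed
graphically —
measures the power of model choice (overlap ≈ 1: no power). Failed refits
are counted and skipped, never replaced by the generating parameters.

## Divergent-motif discovery

Divergence calls per (PWM, model, direction) form a database of region
sets. An input set of experimentally divergent regions (cross-species
ChIP-Seq fold-change > 2, STARR-Seq p ≤ 0.001 & ≥ 3-fold, or open-chromatin
gains/losses — helpers implement these presets) is tested against every
non-empty set with the upper-tail hypergeometric distribution on a fixed
region universe N (default: the supplied region catalog size; overridable,
e.g. 136,353 for the full regulatory-region partition), Bonferroni
corrected over all performed tests. Direction matching is deliberately not
enforced: a gain input may legitimately enrich for losses in the out-group
lineage.

An optional minimum-score filter (`filter_by_max_score`; off by default in
the API, `--min-score` on the CLI) retains calls only for regions whose
score reaches a threshold in at least one species — 6 in the published
case-study setting, which the discovery benchmark also uses. The filter
matters because score rows floored near 0 have tiny fitted σ², so a single
chance background hit in one species can produce a spuriously enormous LR;
requiring one real cluster somewhere removes that artifact class.

Ranking is by (p_adj, p), then larger overlap k, then smaller set size K.
One further tie-break is needed in practice: a strong gain in clade X
produces nearly the same *call sets* as a loss in a complementary clade,
and with saturated signals the two can tie exactly. The database therefore
stores each call's AIC evidence margin (AIC_M0 − AIC_Mx, which keeps
discriminating after Akaike weights saturate at 1), and exact ties rank
the set with the larger mean margin first — the true scenario strictly
dominates its complement there, because the complement mis-fits the
species in neither clade.

## Synthetic data

The generators define the package's test conditions:

* **Traits**: simulated under any painted model by the exact pre-order
  recursion; pure functions of (parameters, seed).
* **Sequence panels**: per-species background drawn i.i.d. from a stated
  composition (uniform by default; AT-rich configurable), with
  PWM-sampled sites planted in clade species only ("gain"), in all but
  the clade ("loss"), or everywhere/nowhere 50/50 ("conserved"). Sites
  are clustered within a window of 3× the expected gap (guaranteeing
  single-cluster structure), non-overlapping, random strand. Sequence
  evolution is **not** modeled along the tree — species backgrounds are
  independent draws. This exercises the scorer and the trait models, but
  it is a non-phylogenetic sequence null: passing tests show the pipeline
  recovers planted signals above independent backgrounds, not that it is
  robust to correlated ortholog divergence, alignment error, or
  compositional heterogeneity of real genomes.
* **Benchmarks**: the panel's divergent regions (optionally noised)
  against a universe padded with inert background ids, standing in for
  the experimental sets of a real discovery run.

Default synthetic conditions, used by the test suite and the acceptance
script: the packaged 12-species Drosophila chronogram (height 63 My;
round literature dates, user-replaceable); OU selection half-life 20 My (α ≈ 0.035/My);
stationary SD 1.2 score units around a base optimum of 3.0; shifts quoted
in stationary SDs (the "strong shift" condition is +5 SDs); synthetic
PWMs of length 8 with 85% consensus dominance (~9 bits); 3 sites per
planted cluster in 300-bp regions. Problem sizes in the acceptance
script (600 calibration replicates, 200 recovery regions, 25 benchmark
runs of 20 regions × 3 PWMs × 10 shift models) are desk-scale choices;
the genome-wide analyses the method targets (136K regions × thousands of
PWMs) require external data and cluster time and are out of scope here.

## Known limitations

* Exactly two regimes per fit (base + shift); no multi-optimum fits,
  no measurement-error variance, no multivariate traits.
* No stationary-root option; likelihoods are not comparable with
  implementations that use one.
* χ²(1) LR p-values are anti-conservative at 12 tips (see above).
* The sequence generator's independence assumption understates the
  difficulty of real cross-species scoring.
* Heterotypic (multi-PWM) clusters and higher-order backgrounds are out
  of scope for the scorer.
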