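# Methods

## Scope and data model

The package analyses a two-timepoint (baseline, day-91), two-arm
randomized trial of a multi-task neurocognitive battery. The battery is
declared, not hard-coded: each variable carries its task, modality,
score direction, and whether norms exist (`BatterySpec`); contrast
scores are declared as differences of two oriented raw scores. The
shipped default battery models an ANT/Wechsler/Rey-style paediatric set
(18 raw variables, 3 contrasts) grouped into eight theoretical domains:
processing speed, response inhibition, visual and auditory attentional
shifting, verbal and visual working memory, verbal and visual list
learning. All tabular I/O is plain CSV; missing cells stay missing —
there is no imputation anywhere, and every analysis is complete-case
per variable with its own n.

Orientation (sign-flipping lower-is-better variables) is a guarded,
once-only operation: it is an involution on values, so silent double
application would corrupt everything downstream; the dataset carries a
flag and a second application raises.

## Synthetic trial generator

The generator is the package's stand-in for trial data and defines the
conditions under which everything is tested.

* **Demographics** (defaults): 41 + 42 participants, age ~ N(10.5, 2.4²)
  years, 73.5% male, FSIQ ~ N(104.1, 18²). Draws are untruncated so the
  sample moments match these targets exactly in expectation; the rare
  simulated age outside the 7–15 recruitment window simply falls outside
  norm-table coverage, which is also how the per-variable n variation of
  a real battery (norms often stop at ~12–13 y) is reproduced.
* **Latent model**: one standard-normal ability per domain per child;
  observed standardized score = λ·ability + √(1−λ²)·unique noise with
  λ = 0.8 by default (block loading structure; a full loading matrix can
  be supplied, and λ-rows summing to 1 in squared loadings are the legal
  noiseless boundary). Scores are emitted on natural scales (ms, counts,
  spans) with direction metadata so orientation is always exercised.
* **Day-91**: latent(d91) = r·latent(baseline) + √(1−r²)·innovation with
  test–retest r = 0.7, a typical stability for paediatric RT/memory
  measures over three months.
* **Deficit structure**: a per-variable mean shift (oriented SD units)
  that the generated norm tables exclude, so the deviance rate of a
  variable with shift δ is Φ(−1−δ) by construction. The defaults encode
  a heterogeneous profile: severe inhibition deficits (false alarms
  δ = −1.05 → ~52% deviant), moderate memory deficits, and *faster*
  but error-prone go/no-go responding (δ = +0.88 → ~3% deviant) — the
  speed/accuracy trade-off pattern that motivates network-level
  analysis.
* **Treatment effects**: `effect_mean` adds a shift to chosen latent
  domain means at day-91 in the active arm (the classic ANCOVA target);
  `effect_network` couples the active arm's day-91 unique innovations
  within each domain via the variance-preserving mixture
  √(1−m)·u + √m·η_domain with m = 1 − 1/effect_network, raising
  within-domain similarity of normalized scores — and hence network
  modularity — without moving any marginal mean or variance.
* **Missingness**: optional MCAR mask (default 1% per cell).
* A single `numpy` Generator seeded from the mandatory config seed
  drives every draw; identical config + seed is bit-reproducible.

What the generator does **not** emulate: item-level response processes,
practice effects, non-normal score distributions (floor/ceiling effects
in error counts), informative dropout, or the true covariance of any
particular battery. Passing tests therefore demonstrate that the
pipeline's machinery is correct and calibrated under a plausible latent
structure, not that any specific clinical result generalizes.

## Deficit profiling

z = (oriented score − oriented norm mean) / norm SD, using the norm band
covering the participant's age (bands are half-open, `age_min ≤ age <
age_max`); no band → missing. The deviance cutoff z ≤ −1 is inclusive.
The test against the norm expectation p₀ = 0.16 is the two-cell Pearson
goodness-of-fit statistic with 1 df and no continuity correction — the
uncorrected statistic reproduces published worked values of this test
exactly from integer counts (e.g. 20 of 68 → 9.10). Deviant counts
reconstructed from rounded percentages are computed as k = round(rate·n).

## Domain extraction

Correlation-matrix PCA (the battery mixes units) on listwise-complete
oriented baseline rows. Component count: smallest k with cumulative
explained variance ≥ 0.70; the scree elbow (maximum second difference)
is reported as a diagnostic, not used for selection — a fixed rule is
reproducible, an eyeballed elbow is not. Varimax with Kaiser row
normalization, tolerance 1e-8, maximum 1000 iterations, deterministic
start from the unrotated solution; component signs are fixed (dominant
loading positive) and columns ordered by explained variance. η² is
operationalized as the squared structure loading — for standardized
variables this is exactly the share of the variable's variance the
component carries. Member sets are cut at the largest consecutive η²
drop, ties resolved toward the earlier (larger-η²) boundary.

Two views of the solution are exposed: `components_` (rotated
orthonormal axes; orthogonal to 1e-8 — note that varimax-rotated
*structure* loadings R'ΛR are not column-orthogonal, so the
orthogonality contract is stated on the axes) and `loadings_`
(structure loadings, used for η² and labelling).

Scoring freezes baseline constants: variables are standardized by
baseline mean/SD, projected through the structure loadings, and the raw
component scores standardized by their baseline mean/SD, so day-91
domain scores are on the baseline metric and change is interpretable.
A missing variable contributes nothing and the remaining weights are
rescaled by total/available absolute weight.

## Individual networks

Connectivity between variables i and j for one child is
w = 1/(1 + |z_i − z_j|) with z normalized by pooled baseline mean/SD.
This form is bounded in (0, 1], defined at zero difference, and
order-equivalent to a raw inverse difference. Construction is:

1. **Skeleton** (population admissibility): Pearson correlations over
   the pooled baseline sample (arm-blind by construction), pairwise
   complete; admissible = r > 0 and two-sided p < α (default 0.05,
   unadjusted; both the positivity restriction and α are parameters).
   After orientation, meaningful population coupling is positive; pairs
   with fewer than 4 complete observations are inadmissible.
2. **Proportional thresholding**: keep the top ⌈density · n_admissible⌉
   admissible edges by weight (default density 0.20), ties broken by
   lexicographic node pair. Density thresholding equalizes edge counts
   across individuals, which absolute cutoffs do not.
3. **MST closure**: union with the maximum-weight spanning tree of the
   *full* connectivity matrix (Kruskal on distance 1 − w, lexicographic
   tie-break), guaranteeing a connected result; closure edges are
   flagged `mst_closure` so they can be distinguished from thresholded
   ones.

Participants missing more than 20% of variables are dropped with a
warning; fewer than 3 usable nodes skips the network. Zero-variance
variables are excluded at fit time.

## Graph metrics

All metrics operate on the symmetric weight matrix; path-based ones use
distance 1 − w (an alternative 1/w ordering is equivalent for MST
purposes and not separately exposed).

* **Strength**: sum of edge weights.
* **Modularity**: weighted Newman Q of a deterministically detected
  partition. Detection is exact — global maximum by dynamic programming
  over vertex subsets, O(3ⁿ) — for networks of ≤ 12 nodes, and a
  deterministic move/merge heuristic (fixed node order and tie-breaks,
  no randomness) beyond that. A trial endpoint must not depend on a
  random restart; the exact small-n path also gives the test suite an
  enumeration-verifiable target.
* **Assortativity**: edge-weighted Pearson correlation of endpoint
  strengths; NaN for degenerate (regular) graphs.
* **Characteristic path length**: mean shortest-path distance over all
  node pairs (Dijkstra on an explicit sparse graph so that w = 1 edges
  — distance 0 — are preserved).
* **Transitivity**: geometric-mean triangle intensity over connected
  triples with weights normalized by the maximum (a weighted global
  clustering coefficient in [0, 1]; 1 for a complete unit-weight graph).
* **Smallworldness**: (C/C_rand)/(L/L_rand) against degree-preserving
  rewired references (connected double edge swaps, original weight
  multiset permuted onto the rewired edges), n_random = 20 by default;
  the only seed-consuming metric. Per-network seeds are derived from the
  run seed and the participant/timepoint key, so results are independent
  of processing order. NaN when a reference ratio is undefined.
* **Hubness**: mean of min–max-normalized strength, betweenness,
  closeness and eigenvector centralities (the eigenvector is the Perron
  vector of the symmetric weight matrix, computed by dense symmetric
  eigendecomposition for determinism). A metric that is constant across
  nodes contributes 0.5 to every node, with a warning. Group-level hub
  analyses use the top ⌈0.20 · n_vars⌉ variables by mean baseline
  hubness, ties lexicographic.

The composite hubness score and the exact/heuristic modularity hybrid
are this package's documented choices; published individual-network
studies describe analogous quantities without printing reproducible
formulas, and printed magnitudes of modularity or smallworldness from
such studies are not comparable across scalings — only directions and
standardized effects are.

## Treatment-effect estimation

Gaussian identity-link model (equivalently OLS ANCOVA):
`d91 ~ arm + sex + baseline + age`, complete-case, at least 3
participants per arm. The arm coefficient with its Wald 95% CI is the
adjusted mean difference; the default sign convention reports
placebo − active, so negative values favour the active arm on
higher-is-better outcomes (the convention is a parameter). Estimated
marginal means evaluate the fit per arm at design-column means. SMD =
|adjusted MD| / baseline pooled SD (variances weighted by n − 1);
change-score SD scaling is deliberately not the default because
baseline pooling reproduces the conventional trial effect size.
Interactions are tested by likelihood ratio on the OLS (MLE)
log-likelihood, 1 df per added term. Change–behaviour associations use
Spearman's ρ with midrank tie handling, requiring ≥ 4 pairs. A constant
outcome short-circuits to difference 0, p = 1. No multiplicity
correction is applied by default, matching an exploratory analysis
plan; `benjamini_hochberg` is available.

## Pipeline and determinism

`run_pipeline` executes simulate/load → orient/contrast → profile →
domains → networks → metrics → effects from one validated JSON config
(exactly one of an input CSV or a simulate block; seed mandatory).
Outputs are CSV (and GraphML per network), written with a fixed float
format; the manifest records a hash of the scientific config (output
location excluded), the seed, package version, per-table row counts and
all warnings. No timestamps enter any artifact, so identical config +
seed yields byte-identical output trees. Exit codes: 0 success, 2
validation failure, 3 runtime failure.

## Problem sizes used in the test suite

The suite verifies calibration by simulation at sizes chosen to make
Monte-Carlo error small relative to the tolerance being asserted:
1000 null replicates at n = 41/42 for type-I error (binomial 3 SE
≈ 0.02 around 0.05); 200 replicates at n = 200/arm for bias (≤ 0.05)
and CI coverage (92–98%); 100 simulated trials for direction recovery
of the network-coupling effect; 50 random graphs of 4–10 nodes for
exact agreement with exhaustive shortest-path/triangle/partition
oracles; 1000 constructed networks for the connectedness guarantee.
The strong-coupling demonstration uses effect_network = 50 (98% of
within-domain unique variance shared): the injected phenomenon is made
unambiguous so that the readout — the sign of the arm difference in
mean modularity — isolates the pipeline's ability to transmit it, not
the sample size of the simulated trial.

## Known limitations

* The skeleton uses unadjusted pairwise significance; with ~200 variable
  pairs some admissible edges are false positives (rate ≈ α/2 under the
  positivity rule). This mirrors a deliberately liberal admissibility
  mask; a corrected option is a one-line config change away
  (`positive_only`, `alpha`).
* Heuristic modularity above 12 nodes is a local optimum; it is
  deterministic and consistent across arms, so arm contrasts are
  unbiased, but absolute Q values may be slightly conservative.
* Estimated marginal means use design-column means (including the sex
  proportion), not balanced factor weighting.
* Norm tables are piecewise-constant in age; real test manuals smooth
  norms continuously.
* The ANCOVA assumes Gaussian residuals; count-like outcomes with floors
  are only approximately served. Residual diagnostics are the user's
  responsibility.
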