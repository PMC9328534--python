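# Methods

This note documents the models and procedures implemented in `calseg`, the
defaults chosen where the design was open, and what the synthetic
experiments do and do not demonstrate.

## Calendar parsing and the analysis window

A DHS contraceptive calendar is a string with one character per month,
leftmost character = interview month, later characters reaching back in
time; dates are century-month codes (CMC = months since January 1900).
`calseg` recodes characters to five states — no use (N), short-term modern
(S), long-acting/permanent (L), traditional (T), pregnancy/birth/
termination (P) — using a code map that is *data*, not code: the shipped
default follows the DHS-7 recode manual (pill, injectable, male/female
condom, diaphragm, foam/jelly, LAM, emergency contraception, Standard Days,
other modern → S; IUD, implant, male/female sterilization → L; rhythm,
withdrawal, abstinence, other traditional → T). Survey dialects can supply
their own map. Female condom and foam/jelly are counted as short-term
modern by default; surveys that classify them differently should override
the map.

The analysis window is the **59 months ending at the interview month**,
stored with month 1 earliest. The window anchor is the interview month
because it is the only month every calendar is guaranteed to cover.
Records that cannot span the window are excluded and logged. Missing
months inside the window are resolved by a configurable policy —
`carry_backward` (default; copy the next observed later month), `none`
(recode to no-use), or `error`. DHS calendars are near-complete, so the
policy is rarely exercised; counts are logged whenever it is.

Eligibility keeps women aged 15–44 in completed years (floor of the month
difference divided by 12, the standard demographic convention) at the
window start.

## Optimal-matching distance

The dissimilarity between two sequences is the minimum total cost of
substitutions and insertions/deletions transforming one into the other,
computed by the standard (|a|+1)×(|b|+1) dynamic program. The default is
the canonical constant scheme — every substitution costs 2, indels cost 1
— exposed in configuration and recorded in logs and output metadata,
since a "constant cost matrix" does not pin down the constants.

Identical sequences are deduplicated before the O(u²·59²) pairwise stage
and their survey weights summed. This is exact: every weighted statistic
downstream (PAM objective, silhouettes, descriptives) is invariant to
replacing duplicated observations by one observation with the summed
weight, a property the test suite checks end to end.

For constant schemes with substitution ≥ 2·indel, an optimal alignment
never substitutes (a substitution can be replaced by delete+insert at no
extra cost), so the distance reduces to `indel·(|a|+|b|−2·LCS(a,b))`. The
pairwise kernel exploits this with a bit-parallel longest-common-
subsequence routine (59 months fit one machine word); the general dynamic
program remains the defining implementation, is used for any other cost
scheme, and the two routes are cross-checked in the tests. An exhaustive
recursive oracle (lengths ≤ 8) provides an independent check of the DP
itself.

## Weighted k-medoids and quality metrics

PAM minimizes the weighted sum of distances of each unique sequence to its
nearest medoid. BUILD seeds greedily by largest weighted cost reduction;
SWAP repeatedly applies the single best strictly-improving medoid/
non-medoid exchange. Because SWAP is a local search, it is run from three
deterministic seedings — BUILD, a farthest-point spread seeding, and the k
largest-weight sequences — and the best final objective is kept (BUILD
wins ties). This removes almost all of the rare local optima of plain
BUILD+SWAP at negligible cost while keeping the algorithm fully
deterministic: every tie (seeding candidates, equal swaps, nearest-medoid
assignment) breaks to the lowest index. SWAP is capped at 500 iterations
as a guard against cycling under exact ties; convergence is logged.

Three quality metrics guide the number of clusters, all weighted and all
in [−1, 1]:

* **ASW** — mean silhouette width, `s_i = (b_i − a_i)/max(a_i, b_i)`.
  With weights, `a_i` is the weighted mean distance to the sequence's own
  cluster with the sequence's own weight mass excluded from the
  denominator (`Σ_j w_j d_ij / (W_c − w_i)`), and `b_i` the smallest
  weighted mean distance to another cluster. This form is invariant to
  rescaling all weights by a constant, which we treat as the governing
  requirement (weights are continuous survey masses, not duplicate
  counts); the alternative `(W_c − 1)` denominator would instead make ASW
  exactly match duplicated unit-weight data but lose scale invariance.
  Singleton clusters get width 0.
* **PBC** — weighted Pearson correlation between the pairwise distances
  and the different-cluster indicator over unique-sequence pairs (i < j,
  pair weight w_i·w_j), so better-separated partitions score higher.
* **HG** — Hubert's Γ, `(s⁺ − s⁻)/(s⁺ + s⁻)` over weighted
  (within-pair, between-pair) distance comparisons; computed by sorting
  the between-cluster distances and accumulating weights, which keeps it
  O(P log P).

`select_k` fits PAM over a k range, reports all three metrics, and selects
the argmax of the configured criterion (default ASW; the three are always
reported together because no single canonical choice exists). Degenerate
inputs — a single unique sequence, or all pairwise distances equal — make
every split arbitrary; the metrics are defined as 0 with a warning and
selection abstains.

## Cluster descriptives

For every cluster: the weighted state distribution at each month (rows sum
to 1), mean months per state (column sums of the distribution; always sums
to 59), the month-by-month cross-sectional Shannon entropy normalized by
log 5 (so 0 = everyone identical, 1 = uniform over states; the raw value
is a trivial rescaling), the weighted mean turbulence, the medoid
sequence, and the weighted membership share.

Turbulence follows Elzinga: `T(x) = log2(φ(x)·(s²_max+1)/(s²+1))`, where
φ(x) is the number of distinct subsequences — empty subsequence included —
of the distinct-successive-states (DSS) form of x, computed by the
doubling dynamic program with last-occurrence correction and verified
against exhaustive enumeration in the tests; s² is the population variance
of spell durations and `s²_max = (d−1)(t̄−1)²` its maximum given the spell
count d and mean duration t̄ (one spell absorbing all slack). A constant
sequence has φ = 2 and zero variances, hence T = 1 exactly.

Descriptives are computed over all cluster members, not only medoids, and
are invariant to weight rescaling.

## Design-based membership models

For each cluster c, membership `1[cluster = c]` is regressed on
categorical covariates by weighted maximum pseudo-likelihood (IRLS,
convergence when the relative deviance change falls below 1e-8, 100
iteration cap with the deviance trace reported on failure). Every
categorical term has one explicit reference level (defaults mirror the
conventional codings: education ref none, knowledge ref low, fertility
desire ref wants-within-2-years, age ref 30–34, …); empty cells raise
before fitting, and diverging coefficients or an unbounded linear
predictor raise a separation error advising cell inspection.

Variance is by Taylor linearization: per-observation score contributions
`w_i (y_i − μ_i) x_i` are summed to PSU totals, their covariance is
estimated within strata with the `m_h/(m_h − 1)` correction, the total is
scaled by `(n − 1)/(n − p)`, and the sandwich is completed with the
inverse expected information. Wald tests use a t reference with the
design degrees of freedom (#PSUs − #strata). With one PSU per observation
in a single stratum this reduces exactly to the classical
heteroskedasticity-robust sandwich times n/(n − p), which the tests verify
against an independent optimizer. Strata left with a single PSU are
collapsed into the nearest stratum id with a logged warning (the usual
certainty-unit fix). Point estimates depend on weights only through
relative magnitudes.

`fit_all_clusters` fits one model per cluster and assembles a combined
table (one row per non-reference level, one OR/p pair per cluster); a
failure in one cluster is recorded without stopping the others. A
multinomial model over all clusters jointly is out of scope (the separate
per-cluster binary models are the analysis of record; a multinomial logit
was only a robustness check there). `collinearity_check` reports VIFs and
the scaled design-matrix condition number with warning thresholds 10
and 30.

## The synthetic generator

The generator defines the study conditions for every test and experiment.

* **Archetypes.** Six default archetypes: all non-use; two family-building
  profiles with two 9-month pregnancy spells at different timings
  (boundaries at months 5–13/31–39 versus 17–25/40–48); and three
  post-pregnancy method adopters (pregnancy months 11–19, method from
  month 25 to 59: short-term modern, long-acting, traditional). The
  states and their ordering follow the published cluster descriptions; the
  exact boundary months are package defaults (the source figure prints no
  numbers) and live in configuration, not code.
* **Mixture.** Default weights (.415, .249, .181, .076, .056, .023), the
  published cluster distribution.
* **Within-cluster heterogeneity.** Each spell boundary is shifted by an
  independent uniform integer in [−jitter_max, +jitter_max] (clamped so
  every spell keeps ≥ 1 month), then each month is substituted by a
  uniformly random *other* state with probability `noise_sub_prob`.
  Defaults: jitter 2, noise 0.03 — chosen once so that recovery is
  non-trivial (most realized sequences are unique) yet achievable; the
  real within-cluster heterogeneity is reported only qualitatively in the
  source, so these are not calibrated to unpublished statistics.
* **Covariates and membership.** Default covariates: education
  (none/primary/secondary+, marginals .448/.368/.184) and contraceptive
  knowledge (low/medium/high, .292/.266/.442) from the published sample
  profile; fertility desire (soon/after2/unsure/nomore, .25/.35/.15/.25)
  is a package default because no marginal is printed for it. In the
  default *mixture* mode, labels are drawn directly from the mixture
  weights and covariates are independent of membership, so the generating
  shares are exactly the configured weights. In *binary* mode, membership
  in a focal cluster is Bernoulli through a logistic link whose
  coefficients are exactly known; the shipped preset mirrors the published
  focal-cluster model (education OR 3.68/1.10, knowledge OR 0.70,
  fertility-desire ORs 4.21/0.35/0.35), with the intercept solved by
  bisection over the covariate cell distribution so the marginal share
  hits the target (0.415). Non-members are spread over the remaining
  archetypes by renormalized mixture weights.
* **Survey design.** Women are dealt round-robin across
  strata × PSUs-per-stratum PSUs (default 10 × 20 × 50 = 10,000 women, the
  scale of the desk experiments; the design is fully configurable up to
  survey scale) and receive independent lognormal weights with mean 1 and
  CV 0.3, a typical DHS weight dispersion. Because weights are independent
  of membership and covariates, weighted estimators are unbiased — the
  design exercises the estimators' weighting and variance machinery, not
  informative sampling.
* **Emission.** Sequences are emitted as DHS-order calendar strings
  (leftmost = interview month, pregnancy spells terminated by a birth
  code, padded to 80 columns) so the generator's output exercises the real
  parser; round-tripping is bit-exact by construction and by test. All
  randomness flows through one seeded generator recorded in the truth
  sidecar.

**What passing does and does not show.** The generator draws sequences
from archetypes with independent month noise; real calendars contain
switching, discontinuation episodes, and serially correlated reporting
error that it deliberately omits (profiles of that kind were too rare in
the source data to form clusters). Recovery of mixture shares and odds
ratios on this generator validates the *pipeline* — parsing, distances,
weighted clustering, design-based estimation — not the substantive
clustering of any real population.

## Chance-adjusted recovery score

`truth_assignment_accuracy` is the adjusted Rand index (scikit-learn
implementation): 1 iff the partitions coincide, expectation ≈ 0 under
random labeling, invariant to label permutations.

## Problem sizes and numerical choices

The test suite and the acceptance script run the k-selection sweep at
~800 unique sequences, the share-recovery experiment at n = 10,000 with
k = 6, and the odds-ratio recovery at n = 10,000 × 20 replicates — sizes at
which every sampling tolerance used in the checks (±3 and ±1.5 percentage
points on shares; ±15% on mean ORs) comfortably exceeds the Monte-Carlo
error, while the full run stays within a few minutes on one CPU.
Distances are stored at full precision with no length normalization (all
sequences have length 59). PAM accepts a swap only when it improves the
objective by more than 1e-12 (floating-point guard). The dissimilarity
matrix for n = 10,000 women deduplicates to roughly 8,000 unique
sequences (~0.5 GB dense).

## Known limitations

* Native DHS binary/fixed-width formats are not read; export to delimited
  text first. The discontinuation-reason calendar column is not parsed.
* OM variants (transition-rate costs, localized OM) are not implemented
  beyond user-supplied substitution matrices.
* PAM multi-start removes almost all, not provably all, local optima.
* The linearized variance assumes with-replacement sampling of PSUs within
  strata (no finite-population correction), the convention of the major
  survey packages.
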