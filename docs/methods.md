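# Methods

## The model

Connectome-predictive modelling treats a participant's functional
connectome — the symmetric matrix of Fisher-z transformed Pearson
correlations between regional BOLD timecourses — as a feature bank for
predicting a behavioral phenotype in unseen individuals. The protocol is
deliberately simple and fully cross-validated:

1. **Edge selection.** On the training sample, each valid edge is
   Pearson-correlated with the z-scored behavioral score; edges with
   two-tailed p < α_sel (default 0.01, exact r-to-t conversion,
   `t = r·√((n−2)/(1−r²))`) are retained and partitioned by the sign of r.
   Positive-tail and negative-tail networks are always modelled separately;
   they are interpreted differently (connectivity that increases vs
   decreases with the behavior score) and there is no combined model.
2. **Network strength.** Per participant, the Fisher-z values over a tail's
   edge set are summed (a raw sum, not a mean; an empty set sums to 0).
3. **Linear model.** Ordinary least squares from network strength to
   behavior. Prediction for a held-out participant is
   `intercept + slope · strength`.

Selection, strength computation and fitting are all redone inside every
training fold of every cross-validation scheme, so no information from a
test participant reaches the model that predicts them — with one deliberate
exception, confound masking, described below.

### Assumptions

- Brain–behavior associations are linear and dimensional: one line relates
  summed connectivity to the score across diagnostic groups. Categorical
  (group-mean) structure can masquerade as dimensional signal, which is why
  the specificity checks evaluate within-group correlations separately.
- Edges contribute additively; the sum collapses the selected network to a
  single degree of freedom per tail.
- Behavioral scores are exchangeable across participants under the null —
  the justification for permutation inference.

## Cohort filtering

Exclusion rules, applied in a fixed order (each participant gets the first
reason that fires): missing behavior score, questionnaire inconsistency
score > 7, head motion > 4 mm maximum absolute displacement, behavioral
score > 3 SD from the sample mean. All thresholds are strict inequalities.
The outlier rule uses the sample that survives the earlier rules (the
sample the model is otherwise built on), with mean and sample SD (n−1
denominator) computed in a single pass, candidate included; the rule is not
iterated. The rule order affects only the recorded reason, never the
retained set. The outlier rule is per-measure, so a child can be excluded
from one behavioral domain's analysis and retained for another; the
analogous rule for social-symptom (SRS) scores applies only where SRS
enters a computation (the specificity table's SRS cell).

## Confound masking

Before modelling, every edge that correlates with z-scored head motion
across participants (Pearson, two-tailed p < 0.05) or differs between the
two acquisition sites (Welch two-sample t, two-tailed p < 0.05) is marked
invalid; masks compose by logical AND, with motion recorded first in the
provenance of doubly-removed edges. No multiple-comparison correction is
applied — the step is meant to be aggressive about confounds.

Masks are computed **once on the full analysis sample** before
cross-validation (`mask_scope: global`). This mildly leaks test-sample
information into the feature pool and is kept as the default because it is
the protocol's published behaviour; the permutation test is run through the
same masked pipeline, so the inference remains internally consistent.
Welch's t is the default for the site test because the site samples are
markedly unbalanced (82 vs 194 in the emulated design); a pooled-variance
variant is available (`welch: false`).

Degenerate inputs: constant motion across participants removes nothing (a
warning is logged); a site with fewer than two participants, or more than
two site labels, is an error.

## Cross-validation and inference

- **Leave-one-out.** N folds; per fold the training behavior is z-scored
  (training mean and sample SD only — since OLS commutes exactly with
  affine transforms of its target, the implementation equivalently fits raw
  behavior and the two routes agree to machine precision, which a
  brute-force per-fold oracle test confirms). A fold whose selection is
  empty, or whose strengths are constant, predicts the training-fold mean
  and is counted as a degeneracy; this keeps the cross-validation loop
  total without inventing a model. Performance is the Spearman rank
  correlation (midrank ties) between observed and predicted scores across
  all folds. Cohorts under 10 participants are refused as uninterpretable.
- **The gate.** The parametric p of the LOO Spearman correlation badly
  overstates significance because folds are not independent; it is used
  only as a screen (rs > 0 and p < 0.05) deciding which models proceed to
  permutation testing or cross-sample prediction.
- **Permutation test.** The raw behavior vector is shuffled n_perm times
  (seeded generator) and the entire pipeline — per-fold z-scoring,
  selection, fitting, prediction — is re-run per shuffle
  (`perm_loo: full`; a cheaper `strength_refit` mode freezes the
  observed-data fold selections and only refits the strength model per
  shuffle — its null is narrower because the selection step's overfitting
  is not replayed, so it is an approximation, not the default). The
  p-value is exact and one-tailed:
  `p = (1 + #{null rs ≥ observed rs}) / (n_perm + 1)`, so its minimum is
  1/(n_perm+1) and ties count as exceedances.
- **Stratified split-half.** The cohort is halved at random preserving the
  per-site-per-group stratum counts (odd strata donate their extra member
  to the halves alternately, in sorted stratum order). Within each half a
  confound mask is computed and a LOO gate run; the cross-half model is
  then trained once on the entire half (selection + fit) and predicts every
  member of the other half. Training once per half, rather than aggregating
  per-fold LOO models, is this package's choice where the protocol sequence
  is ambiguous; the gate result is attached to each direction's report.
- **Site-to-site.** Per direction, a within-source-site LOO gate (motion
  mask only — a single site cannot have a site mask) must pass before
  cross-site prediction is attempted; a failed gate flags the direction
  not-attempted. This reproduces the practical failure mode of
  single-site model building in unbalanced multi-site cohorts.

### A note on the null behaviour of LOO-CPM

Under a true null, the LOO Spearman statistic is *not* centred at zero:
folds with empty selections predict the training mean, which is strictly
anticorrelated with the held-out score, while non-empty folds overfit
selection noise; at the 90-node / n=200 experiment scale the net bias
measured about +0.11. This is precisely the fold-dependence problem that
motivates permutation inference, and the permutation p absorbs it: across
200 no-signal cohorts the measured type-I error at 0.05 was 0.05–0.06 with
p-values indistinguishable from uniform. Consequently, tests of the null
assert the calibrated permutation p, never the raw rs magnitude — and the
parametric gate should be expected to pass occasionally under the null
(which the site-to-site failure-mode analysis accounts for by judging the
mode over repeated cohorts).

## Specificity checks

All on the *same* pooled cross-validated predictions, with no refitting:
within-group Spearman correlations (TD and ASD separately); a
cross-correlation table of predicted scores against motion before and after
cleaning, full-scale IQ, SRS total, the other observed behavioral domains,
and age, each cell carrying its uncorrected p and a significance flag at
α = 0.05/7 ≈ 0.007 (seven comparisons per model); and a partial rank
correlation controlling for diagnosis (TD = 0, ASD = 1). "Partial
Spearman" is implemented as midrank transformation followed by the
first-order partial-Pearson formula on the rank correlations — the most
common reading — and a residualize-the-ranks oracle in the tests confirms
the equivalence. A constant covariate reduces exactly to the plain
Spearman correlation; a rank-collinear covariate leaves the partial
undefined (NaN with a warning). Age correlations are exploratory: the
behavioral scores are age-normed T-scores, so age associations speak to
residual developmental signal in the connectivity models, not the scores.
The SRS column drops SRS outliers (> 3 SD) and missing values cell-wise.

## The synthetic cohort generator

The generator produces seeded cohorts with the statistical structure the
pipeline assumes; it emulates a 276-child two-site pediatric design.

| parameter | default | meaning |
|---|---|---|
| `n_per_site_group` | GU-TD 46, GU-ASD 36, KK-TD 145, KK-ASD 49 | site × group cell sizes (n = 276) |
| `node_count` | 268 | parcellation nodes (90 used by the repeated-cohort experiments) |
| `behavior_mean`, `behavior_sd` | TD 44 (7), ASD 60 (12) | T-score distribution of the modelled measure |
| `n_signal_edges`, `beta_signal` | 120, 0.0516 | planted negative-tail network; per-unit-z decrease of edge z. With `noise_sd_edge` 0.2 the planted edge–behavior correlation is ≈ −0.25, a realistic single-edge effect size |
| `n_motion_edges`, `beta_motion` | 200, 0.115 | motion-coupled edges (r ≈ 0.5 with z-scored motion) |
| `n_site_edges`, `delta_site` | 300, 0.15 | edges mean-shifted at the second site (Cohen's d 0.75) |
| `noise_sd_edge` | 0.2 | between-participant SD of an edge around its baseline |
| `baseline_mean`, `baseline_sd` | 0.25, 0.35 | per-edge baseline Fisher-z values (fixed across participants) |
| `motion_mean`, `motion_sd` | TD 1.2, ASD 1.5; 0.9 | maximum absolute displacement (mm), truncated to (0.05, 4.0] |
| `rho_other_domains`, `rho_srs` | 0.7 | within-group correlation of the other behavioral columns (and SRS) with the modelled measure |

Each participant's edge vector is
`baseline + beta_signal·(−z_behavior)·[signal] + beta_motion·z_motion·[motion]
+ delta_site·[site edge, second site] + N(0, noise_sd_edge)`, with planted
sets drawn without replacement and disjoint by default. Behavioral draws
are truncated at ±2.5 group SD and deterministically re-drawn if the
combined sample would flag them as > 3 SD outliers, so a default cohort
passes the exclusion rules untouched. A single global seed feeds a
hierarchical seed-splitting scheme (phenotype / edge placement / edge noise
/ timecourses), so modules can be exercised in isolation reproducibly.

Timecourse generation inverts the profile: the target correlation matrix is
`tanh` of the planted Fisher-z profile, projected to the nearest positive
semi-definite matrix (eigenvalue clipping, diagonal renormalised) and
sampled through its Cholesky factor for the site-specific number of volumes
(GU 154, KK 128 by default). Randomly assembled targets need not be valid
correlation matrices, so the projection introduces a small bias that
shrinks as the edge dispersion shrinks; a target with |r| = 1 between
distinct nodes is refused as infeasible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatial structure and community organisation of
real connectomes (edges are conditionally independent given the planted
effects), non-Gaussian and heavy-tailed edge distributions, scanner-specific
covariance (site differences are pure mean shifts), realistic head-motion
dynamics (motion enters only as one scalar per participant), and
measurement properties of the behavioral instruments beyond their group
means, SDs and inter-scale correlations.

## Numerical choices

- |r| is clamped at 1 − 1e−7 before `atanh`, so perfectly correlated
  timecourses map to a finite edge (z ≈ 8.4) and network sums stay finite.
- The diagonal of a connectivity matrix is stored as NaN and never read;
  all edge iteration uses the strict upper triangle, 0-based, i < j, in
  `numpy.triu_indices` row-major order — one canonical edge enumeration
  shared by every module and by the TSV mask / edge-list formats.
- A node with zero temporal variance is an error, not a silent NaN: it
  identifies a degenerate participant or parcel, and the protocol gives no
  rule for it.
- The leave-one-out engine applies the selection threshold as an
  equivalent bound on r² (the t statistic is monotone in |r| at fixed df),
  and obtains every fold's per-edge statistics from one set of sufficient
  statistics by subtracting the held-out participant's contribution; a
  per-fold scalar-loop oracle verifies equality to ≤ 1e−10.
- Selection uses strict `p < α`; exact ties sit on a measure-zero boundary
  and resolve to non-selection.
- The experiment drivers run at 90 nodes (4005 edges) with n = 200–276
  cohorts: large enough that edge selection, masking rates and permutation
  calibration behave as at full scale, while repeated-cohort experiments
  (200 null replicates × 200 permutations, each a full LOO pipeline)
  remain tractable on a single CPU.

## Known limitations

- `mask_scope: global` leaks test information into the edge pool by
  design (protocol fidelity); a strictly nested variant would recompute
  masks per training fold at substantial cost.
- The consensus network (edges selected in 100% of LOO folds, threshold
  configurable) is a reporting convention, not part of the predictive
  model; fold-aggregation of displayed networks is genuinely
  underdetermined by the protocol.
- Site-to-site prediction inherits the anticonservative parametric gate;
  its not-attempted flag is therefore a stochastic outcome near the null,
  and analyses of the failure mode should average over cohorts.
- The generator's effect sizes make the planted network far more
  predictable (r_s ≈ 0.9 at default settings) than real brain-behavior
  effects (r_s ≈ 0.2); the tests exercise machinery and calibration, not
  realistic effect-size regimes.
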