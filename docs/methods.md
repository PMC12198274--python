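# Methods

## Moderated network model

The network is a Markov random field over the 18 symptom items, estimated
by nodewise penalized regressions. All items are z-scored and treated as
continuous Gaussian nodes; this is the practical regime of mixed
graphical model estimators for 0–3 Likert scales and matches the fact
that each group's network is reported as a real-valued weighted graph.
Full ordinal/categorical node likelihoods are deliberately out of scope.

For node *s* the design contains the 17 other items, G−1 moderator-group
dummies (reference group omitted), and one interaction column per
(item, non-reference group) pair. The moderator is reference-coded with
the largest group as reference (lexicographic tie-break, so fits are
invariant to participant order); this matches the observation that the
two unmoderated groups share an identical conditioned network, which
reference coding yields by construction. Interaction columns are the
product of the standardized item and the raw 0/1 dummy, standardized
*after* forming the product so all penalized columns face the penalty on
a comparable scale (configurable). Covariates (age, sex, site) enter as
main-effect adjustment columns in every nodewise regression when the
sensitivity toggle is on; they are not interacted with the moderator and
are not reported as network nodes.

The LASSO path has 50 log-spaced values from the per-node λ_max
(`max |x_jᵀy|/n`) down to λ_max·10⁻⁴, solved by coordinate descent
(scikit-learn's `lasso_path`, duality-gap tolerance 10⁻¹⁰; solutions are
oracle-checked against ordinary least squares at λ→0 and against the
soft-threshold closed form on orthonormal designs). Path coefficients
below 10⁻¹⁰ in magnitude are treated as exact zeros so that solver
round-off never counts as support. λ is selected per node by
EBIC = n·ln(RSS/n) + k·ln(n) + 2γk·ln(P) with γ = 0.5, k the number of
nonzero coefficients, and P the number of candidate predictors; ties
resolve to the larger λ.

Aggregation: an undirected edge (i, j) is kept under the OR-rule if the
coefficient is nonzero in either of its two nodewise regressions; its
weight is the mean of the two absolute coefficients carrying the common
sign. If the two selected coefficients disagree in sign, the mean of the
signed values is kept and the edge flagged. The AND-rule is available
for sensitivity. Moderation increments are aggregated identically over
the two interaction coefficients per (edge, group). Conditioning on a
group adds its increments to the base network, so group networks differ
only on edges carrying a stored increment and the reference group's
network equals the base exactly.

With m multiply-imputed datasets, the model is fit on each completed
copy and all selected parameters are averaged element-wise (unselected
parameters count as zero); a first-dataset-only mode exists. Averaging
is simple and symmetric but leaves small fractional increments from
effects selected in a minority of copies — readers should interpret
increment magnitude jointly with bootstrap stability.

## Preprocessing

Participants missing ≥ 50 % of item scores are excluded (threshold
configurable; the boundary is inclusive). Remaining gaps are filled by
chained-equations multiple imputation with predictive mean matching:
each incomplete item is regressed linearly on all other items, and a
missing entry receives the observed value of one of the 5 nearest
donors by predicted mean, for 10 sweeps and m = 5 chains (conventional
defaults). PMM guarantees imputations stay in the observed support
{0,1,2,3} without an ordinal model. Observed values are never altered.

## Bootstrap stability

"Block" resampling is interpreted as stratified-by-group: each group is
resampled with replacement at exactly its own size, preserving the
quantity the moderated model conditions on. λ is re-selected by EBIC
inside every replicate (full-procedure bootstrap). An effect's presence
proportion over B replicates maps to good (≥ 0.80, boundary inclusive),
moderate ([0.50, 0.80)) or insufficient stability.

## Local network metrics

Node strength is the sum of absolute incident weights. The weighted
local clustering coefficient defaults to the Zhang–Horvath form on
absolute weights scaled by the network maximum,
`C_i = Σ_{j≠k} w̃_ij w̃_jk w̃_ik / (s̃_i² − Σ_j w̃_ij²)`, with Onnela and
Barrat variants selectable; all three reduce to the unweighted
coefficient on binary graphs (tested against triangle counting).
Absolute weights are observationally neutral when all edges are
positive, the empirically typical case. Standardized metrics are
z-scores across the 18 nodes of one network. Clustering is invariant to
scaling all weights by c > 0 because the max-scaling cancels c.

## Cohort statistics

2×2 tables use the chi-squared test with a clamped Yates correction:
each |O−E| is reduced by min(0.5, |O−E|) before summing (O−E)²/E, so a
table at its expected counts scores exactly 0 and the corrected
statistic never exceeds the uncorrected one. This clamped form (not the
unclamped adjustment some libraries apply) reproduces published
characteristics-table values at printed precision. Continuous measures
use pooled or Welch two-sample t-tests (both provided; reports state
which). Ordinal scores use the Mann–Whitney statistic in the
first-sample orientation — W counts pairs with x > y, ties ½ — with a
tie-corrected normal approximation; W(x,y) + W(y,x) = n₁n₂. Medians and
IQRs use linear-interpolation quantiles.

## Treatment trajectories

Monthly mean dose from birth month to assessment month: a month's value
is the summed prescribed mg/day over its covered days divided by the
calendar length of the month; overlapping prescriptions add.
Dexamphetamine is converted at factor 2 to methylphenidate-equivalents
(configurable). Onset/stop age and total dose (monthly dose × calendar
days, an exact day-count integral) come from the raw series; duration,
maximum dose and dose SD from a cubic smoothing spline with
GCV-selected penalty evaluated on a fine age grid. Duration counts time
above 1 mg/day because a smoothed curve never returns exactly to zero;
the maximum is floored at 0; the SD is taken over the treated span.
A constant series bypasses the spline (which reproduces constants
anyway) to avoid a degenerate GCV problem. Series shorter than 8 months
are rejected.

Subgrouping: the six features are z-scored column-wise, participant
similarity is the Pearson correlation between feature profiles with
negative values set to zero, and Louvain (resolution 1, seeded,
networkx implementation) maximizes weighted modularity Q. Communities
smaller than 10 members are flagged excluded rather than reassigned,
mirroring the exclusion of very small treatment-trajectory subgroups in
practice. The similarity construction is a declared convention — the
similarity metric and z-scoring of the original analyses are not
specified — so Q and subgroup sizes are not comparable across studies.

## Synthetic data

Items are generated through a latent Gaussian copula: the precision
matrix has unit diagonal and off-diagonal entries equal to minus the
group's partial correlations (positive-definiteness is checked and
violations are rejected naming the group), latent scores are drawn from
the implied correlation matrix and cut at per-item thresholds (default
standard-normal cutpoints 0.5/1.0/1.5, giving ≈ 69 % zeros — the
right-skew typical of community symptom scales). Moderation is planted
as an additive delta on one group's partial correlation.

The canonical study condition (`default_ground_truth`) is a positive
two-cluster base network (within-domain chains at partial correlations
0.10–0.25) shared by three groups, with one +0.25 increment on the
existing run–motor edge of the stimulant-exposed group. Planting the
moderation on an existing edge mirrors the empirical pattern in
moderated symptom-network analyses, where moderation strengthens
already-present associations between hyperactive-impulsive symptoms.
Discretization attenuates latent associations by roughly a factor 0.5–0.6
at the default cutpoints, so recovered weights are smaller than the
planted latent values; recovery tests therefore assert selection, not
weight equality. Missingness is injected completely at random (MCAR)
only; covariates are independent plumbing (age ≈ N(16.7, 3.9²) clipped
to 7–29, balanced sex and site). Not emulated: informant effects,
comorbidity structure, longitudinal waves, MAR/MNAR missingness, and
any dependence of symptoms on the trajectory features — passing recovery
tests shows the estimator recovers copula-generated ground truth, not
that real symptom data satisfy the copula.

Prescription archetypes: early-and-intense (onset U(6,9) yr, dose
U(30,60) mg/day, duration U(4,8) yr) versus late-and-moderate (onset
U(12,16), dose U(10,25), duration U(1,4)); assessment age U(20,26) so
courses end before assessment. The onset supports are disjoint by
design, making archetype recovery a clean planted-partition problem.

## Problem sizes and determinism

Recovery studies use 18 nodes, n = 500 per group and 20 seeds; the
bootstrap-stability study uses one planted +0.30 moderation at n = 1000
per group with B = 200 (bootstrap replicates carry ≈ 63 % unique
participants, so stability demands larger samples than one-shot
detection — at n = 500 per group the same planted effect reaches only a
minority of replicates). Archetype recovery uses 100 + 100 histories.
All randomness flows through numpy Generators seeded from a single
user-supplied seed; repeated runs are byte-identical. Unit tests scale
the same designs down to keep the suite fast.

## Known limitations

- Gaussian treatment of ordinal items biases recovered weights toward
  zero (attenuation); no polychoric correction is applied.
- Covariate nodes are adjustment columns, not reported network nodes.
- The imputation-averaging rule for m > 1 is a declared convention; how
  multiply-imputed datasets should enter regularized network estimation
  has no canonical answer.
- Louvain similarity construction (Pearson on z-scored features,
  negatives clipped) is one reasonable choice among several; modularity
  values depend on it.
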