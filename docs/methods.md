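# Methods

## Model

The package models a cohort of patients, each observed over `T` yearly
slices of care for `C` binary chronic-condition indicators, together with a
categorical demographic profile (default schema: race 6 levels, gender 2,
marital status 2, age group 4, education 6). The joint distribution is a
Bayesian network over `T·C` condition nodes plus one node per demographic
variable, `P(X_1..X_n) = ∏ P(X_i | Pa(X_i))`, under three layer constraints:
demographic nodes have no parents and no edges among themselves; condition
edges never point backwards in time; and cross-slice condition edges span at
most `window` slices (default 1, i.e. consecutive years only — the model is
first-order Markov in years unless the window is widened). Same-condition
persistence edges (`X_t → X_{t+1}`) are admissible and, in practice,
dominant.

## Structure learning

**Unsupervised.** For each slice, pairwise mutual information between the
`C` condition indicators is estimated by plug-in empirical probabilities in
nats (`0·ln 0 := 0`); a maximum-weight spanning tree of the complete MI graph
is built by Kruskal's algorithm. The tree is used *only* to order nodes: the
ordering is a breadth-first traversal from the root, and tree edges are not
forced into the final DAG. Per-slice orderings are concatenated by slice into
one total ordering, and a K2 greedy search then assigns parents: for each
node in order, the admissible predecessor (same slice, or within the
temporal window) whose addition most increases the family score is added
until no addition improves the score or the parent cap (default 3) is
reached.

Determinism is guaranteed throughout: spanning-tree ties break on
lexicographic node-name pairs, the root is the node with maximal MI row-sum
(ties lexicographic), breadth-first children are visited by descending edge
MI then name, and K2 ties break on node sort order. Learning involves no
random number generator.

**Family score.** The default is the Cooper–Herskovits marginal likelihood
`∏_j (r−1)!/(N_j+r−1)! ∏_k N_jk!`, evaluated in log space with log-gamma.
Because the method is sometimes described as likelihood-driven while citing
K2, a BIC-penalised maximum log-likelihood score is provided as an explicit
option (`score="bic"`); the default everywhere is the Cooper–Herskovits
score.

**Semi-supervised / supervised.** A user-supplied node ordering (fed to the
same K2 search) or a user-supplied DAG (validated against the layer
invariants and returned unchanged).

**Demographic level.** Added after condition-level learning by connecting
every demographic variable to every condition node, bypassing the parent
cap. Because this layer is identical by construction across learning modes,
the structure-similarity measures (cosine and Pearson correlation of the
flattened binary adjacency vectors, reported as percentages) are computed
over condition nodes only.

## Parameters and inference

CPTs are estimated as `(N(x, pa) + α) / (N(pa) + α·r)`. The default `α = 1`
matters for the demographic-augmented model: a condition node has up to
1,152 demographic parent configurations times up to 8 condition-parent
configurations, which is sparse at realistic cohort sizes. `α = 0` gives the
pure MLE with a uniform fallback (and a logged warning) for unobserved
parent configurations.

Queries are answered exactly: the network is pruned to the ancestors of
evidence ∪ targets (barren-node removal), factors are reduced by the
evidence, and remaining variables are summed out along a min-fill
elimination order. The largest default network (25 binary + 5 categorical
nodes) is comfortably tractable, so no approximate inference is provided.
Evidence with probability zero under the model raises a dedicated error
rather than returning NaN. A full-enumeration routine with the same contract
(`brute_force_marginals`, ≤ 22 nodes) serves as the independent oracle in
tests.

Prediction queries condition on every condition flag of the evidence years
*and* the full demographic profile — demographics are observed covariates.
State-transition tables condition each row exactly on (row state, profile)
and marginalise everything else; rows whose state has probability zero are
flagged, not fabricated.

## Trajectories

For trajectory mining, condition-condition edges are weighted with the
empirical co-activation log-probability `ln[(N(u=1, v=1)+1)/(N(u=1)+2)]`
(add-one smoothing keeps weights finite for never-active parents), so a
path's weight is the log of a product of conditional probabilities and the
maximum-weight path is the most likely sequence. This empirical scheme is a
deliberate design choice — the alternative of deriving edge weights from the
fitted CPTs is left as an extension point, since CPT entries condition on
full parent configurations rather than single predecessors. A dummy source
node wired to every first-year condition (weight = log smoothed first-year
prevalence) reduces "from any comorbidity" queries to single-source longest
path; the symmetric dummy sink carries zero-weight edges so that the arrival
probability is not double-counted. The longest path is computed by dynamic
programming over a topological order; ties break on shorter path, then
lexicographic node sequence. Path support is the fraction of patients
positive at the path's final condition-year whose panels are positive at
every node of the path.

## Evaluation protocol

Patient-level, unstratified, seeded k-fold cross-validation (default
k = 10). Per fold, structure (optionally) and parameters are re-estimated on
the training patients; held-out patients are scored by exact posterior
probability of each future condition; scores are pooled across folds (one
ROC per cell rather than per-fold averaging) and summarised by the
Mann–Whitney AUC with half-credit for ties. Confusion matrices threshold the
scores at 50% with ties predicted positive; the metric panel implements the
standard epidemiological definitions (TPR, FNR, FPR, TNR, PPV, FDR, NPV,
FOR, LR+, LR−, DOR, accuracy, prevalence), each reported as NaN when its
denominator is zero.

## Synthetic cohorts

The generator draws a ground-truth network obeying all layer invariants:
persistence edges always present (when retention is configured),
within-slice edges under a random per-slice ordering at density 0.2,
cross-condition consecutive-slice edges at density 0.1, at most 3 condition
parents per node, demographics wired to every condition. Condition CPTs are
parameterised on the log-odds scale — a baseline intercept plus one additive
effect per active parent, squashed through the logistic — with each
condition-parent effect offset by the parent's expected activation and each
demographic effect vector centred under that variable's marginal
distribution. With this offset the configured `baseline_prevalence` is
approximately the condition's marginal prevalence, which keeps per-year
frequencies stable across structure draws (only a mild upward drift remains,
from the convexity of the logistic at low prevalence — itself realistic for
accumulating chronic conditions).

The `va_like` preset emulates the shape of a large veteran cohort: C = 5
conditions over T = 5 years; demographic marginals taken from the published
cross-tabulation (race 65.0/18.5/11.5/2.6/1.5/1.0%, male 85.5%, married
46.0%, age 54.5/22.5/18.0/5.0%, education 1.4/1.2/77.9/10.0/7.1/2.4%);
baseline prevalences (TBI .05, PTSD .20, BaPa .20, SuAb .06, Depr .13) and
retention 0.65 calibrated so the per-year no-comorbidity share lands near
the published magnitudes (≈ 0.5 in year one, ≈ 0.35–0.40 in later years);
within/cross effect sizes 1.2/1.0 log-odds with ±20% jitter and demographic
effects of scale 0.3. The `independence_config` preset zeroes every effect
and density, giving a cohort in which no condition predicts any other —
the negative control for the evaluation protocol.

What the generator does **not** emulate: dropout and censoring (the real
cohort restricts to patients in care every year, a selection the generator
sidesteps by construction), diagnostic error, within-patient correlation
beyond the network's edges, and secular trends in incidence. Tests passing
on these cohorts therefore validate the algorithms and their
implementation, not clinical conclusions about any real population.

## Experiment sizes and numerical choices

Pipeline-recovery experiments use cohorts of 20,000 patients for structure
learning and 50,000 for parameter estimation, averaging edge-F1 over three
generator replicates because a single structure draw leaves noticeable
topology luck (demographic confounding induces genuine marginal dependence
between conditions that condition-level search legitimately picks up as
extra edges, and the parent cap can then displace a true parent).
Cross-validation protocol checks use 3-condition, 3-year cohorts of 10,000
patients with 5 folds, sized so pooled-AUC sampling noise (sd ≈ 0.009) is
small against the ±0.03 chance band being asserted. CPT rows are validated
to sum to one within 1e-12; exact and brute-force marginals agree within
1e-9; percentages are rounded half-to-even to two decimals to match
conventional table printing.

## Known limitations

- Parameter-recovery accuracy on parent configurations observed only ~100
  times is limited by binomial noise (standard error up to 0.05), not by the
  estimator; tight recovery claims are meaningful only for configurations
  observed thousands of times.
- The temporal window default of one year cannot represent skip-year
  dependence; widen `window` where that matters.
- Trajectory edge weights are pairwise-empirical, not model-derived; paths
  are descriptive, not causal.
- Structure learning is greedy given the ordering; it inherits K2's
  sensitivity to the ordering in the semi-supervised mode.
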