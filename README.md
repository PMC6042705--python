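# mtbn — multi-level temporal Bayesian networks for multimorbidity

`mtbn` models how multiple chronic conditions (for example traumatic brain
injury, post-traumatic stress disorder, back pain, substance abuse and
depression) co-occur and evolve over yearly slices of care, and how patient
demographics shape that evolution. It is aimed at epidemiologists and
biostatisticians working with longitudinal diagnosis panels: one binary flag
per (condition, year) per patient, plus categorical covariates such as race,
gender, marital status, age group and education.

## The model

A multi-level temporal Bayesian network (MTBN) is a directed acyclic graph
with one binary node per (condition, year) pair and one categorical node per
demographic variable, factorising the joint distribution as

    P(X_1, ..., X_n) = ∏_i P(X_i | Pa(X_i))

with one conditional probability table (CPT) per node. Within-slice edges
capture same-year comorbidity, consecutive-slice edges capture emergence and
persistence (including `SuAb_t → SuAb_{t+1}` retention edges), and the
demographic level is wired top-down: every demographic node points at every
condition node, demographic nodes have no parents.

The structure is learned in stages:

1. **Per-slice ordering** — a maximum-weight spanning tree (Chow–Liu tree) on
   the pairwise mutual information of each year's conditions yields a
   within-slice node ordering (breadth-first from the most connected node).
2. **Temporal integration** — per-slice orderings are concatenated by year
   into a single topological ordering.
3. **K2 greedy search** — under that ordering, each node greedily acquires
   the parents that maximise the Cooper–Herskovits marginal likelihood
   (a BIC-penalised likelihood score is available as an option), capped at
   3 parents and a one-year temporal window.

Besides this *unsupervised* mode there is a *semi-supervised* mode (an
expert-supplied ordering feeds K2) and a *supervised* mode (an
expert-supplied DAG is used as-is). Parameters are estimated by (optionally
Dirichlet-smoothed) maximum likelihood; predictive queries are answered by
exact variable elimination; and the most likely comorbidity sequence between
two condition-years is mined as a longest path over empirical
log-conditional edge weights (a dummy source node supports "from any
comorbidity" queries). A k-fold cross-validated ROC/AUC protocol and a full
confusion-matrix metric panel (sensitivity, specificity, predictive values,
likelihood ratios, diagnostic odds ratio) cover evaluation, and a synthetic
cohort generator with a veteran-like preset makes the whole pipeline
reproducible without access to protected records.

## Worked example

```python
import mtbn
from mtbn import condition_node

# a veteran-like synthetic cohort: 5 conditions, 5 years, 20k patients
net = mtbn.random_mtbn(mtbn.va_like(seed=7))
cohort = mtbn.sample_cohort(net, 20000, seed=8)
table = mtbn.state_frequency_table(cohort)
zero = tuple([0] * 5)
print("no-comorbidity share, year 1:", table.loc[zero, ("year_1", "percent")], "%")
print("no-comorbidity share, year 5:", table.loc[zero, ("year_5", "percent")], "%")

dag = mtbn.learn_structure(cohort, mode="unsupervised")
model = mtbn.fit_cpts(mtbn.add_demographic_level(dag, cohort.demographic_schema),
                      cohort, alpha=1.0)

evidence = mtbn.profile_evidence(model, {"gender": "Male", "age_group": "18-30",
                                         "race": "White", "marital": "Unmarried",
                                         "education": "<HighSchool"})
evidence[condition_node("SuAb", 0)] = 1
prob = mtbn.predictive_marginals(model, evidence, [condition_node("SuAb", 1)])
print("P(SuAb in year 2 | SuAb in year 1, profile) =",
      round(prob[condition_node("SuAb", 1)], 3))

wdag = mtbn.edge_weights(model.structure, cohort)
path = mtbn.longest_path(wdag, condition_node("SuAb", 0), condition_node("SuAb", 4))
print("most likely trajectory:", " -> ".join(str(n) for n in path.nodes))
print("support among year-5 SuAb patients:",
      round(100 * mtbn.path_support(cohort, path), 1), "%")
```

prints

```
no-comorbidity share, year 1: 48.02 %
no-comorbidity share, year 5: 34.96 %
P(SuAb in year 2 | SuAb in year 1, profile) = 0.75
most likely trajectory: SuAb_y1 -> SuAb_y2 -> SuAb_y3 -> SuAb_y4 -> SuAb_y5
support among year-5 SuAb patients: 10.9 %
```

Roughly half the simulated cohort carries no diagnosis in year one, eroding
to ~35% by year five as conditions accumulate. Given a first-year substance
abuse diagnosis and a young unmarried profile, the fitted network puts the
one-year retention probability at 0.75, and the dominant trajectory into
year-5 substance abuse is recurrent substance abuse itself — a path followed
by about one in ten of the patients who end up with the year-5 diagnosis.

The same steps are scriptable from the shell:

```bash
mtbn simulate --preset va_like --n 20000 --seed 7 --out cohort.csv
mtbn learn cohort.csv --mode unsupervised --out edges.csv
mtbn fit cohort.csv edges.csv --alpha 1.0 --out net.json
mtbn predict cohort.csv net.json --evidence-years 1,2 --out scores.csv
mtbn evaluate cohort.csv --folds 10 --seed 1 --evidence-years 1 \
     --auc-out auc.csv --metrics-out metrics.json
mtbn trajectory cohort.csv edges.csv --from-any --to SuAb@5
```

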