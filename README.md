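# modnet

Moderated symptom-network analysis for ordinal symptom scales.

`modnet` estimates how the conditional-dependence network over 18 ADHD
symptom items (DSM-IV inattentive and hyperactive-impulsive criteria,
scored 0–3 on a parent-rated Likert scale) differs between moderator
groups — non-ADHD controls (NAC), stimulant-naive ADHD participants
(ADHD-nostim) and stimulant-exposed ADHD participants (ADHD-stim). It is
written for researchers in psychometric network analysis who need a
tested, reproducible pipeline: exclusion and multiple imputation of
missing item scores, the moderated network fit itself, bootstrap
stability of moderation effects, local network metrics, cohort
descriptive statistics, and subgrouping of participants by their
lifetime stimulant-treatment trajectories. Because clinical symptom data
are typically under controlled access, the package ships a synthetic-data
generator with known ground-truth networks so every stage can be
validated by parameter recovery.

## The model

For each item *s*, a nodewise regression is fit on standardized scores:

    x_s ~ Σ_{t≠s} β_{s,t} x_t  +  Σ_g α_{s,g} d_g  +  Σ_{t≠s, g} γ_{s,t,g} (x_t · d_g)

where `d_g` are dummies for the non-reference moderator groups. Each
regression is LASSO-penalized along a 50-step λ path, and λ is selected
by the Extended Bayesian Information Criterion

    EBIC = n·ln(RSS/n) + k·ln(n) + 2γ·k·ln(P),  γ = 0.5.

Nodewise coefficients are aggregated into undirected edges by the OR-rule
(keep an edge if either β_{s,t} or β_{t,s} is selected; weight = signed
mean of the absolute coefficients), and the interaction coefficients
analogously yield per-group moderation increments. Conditioning on group
*g* adds its increments to the shared base network; groups without
moderation effects therefore share an identical network.

Moderation-effect stability is assessed by refitting the whole procedure
on B bootstrap resamples drawn with replacement within each group:
effects present in ≥ 80 % of replicates have *good* stability, in
[50 %, 80 %) *moderate*, and below that *insufficient* stability for
interpretation.

Local metrics per group network: node strength `s_i = Σ_j |w_ij|` and the
Zhang–Horvath weighted clustering coefficient
`C_i = Σ_{j≠k} w̃_ij w̃_jk w̃_ik / (s̃_i² − Σ_j w̃_ij²)` on max-scaled
absolute weights (Onnela and Barrat variants available).

Treatment trajectories are reconstructed as day-weighted monthly mean
doses (mg/day, dexamphetamine ×2 as methylphenidate-equivalents), six
features are extracted (onset age, stop age, total dose from the raw
series; duration, maximum dose, dose SD from a GCV-penalized cubic
smoothing spline), and participants are partitioned by Louvain community
detection on the nonnegative Pearson similarity of their z-scored
feature vectors, with modularity Q reported and communities below a
minimum size flagged excluded.

## Worked example

```python
from modnet import (default_ground_truth, generate_symptom_data, inject_missingness,
                    apply_missingness_filter, impute_items, fit_moderated_mgm,
                    EstimatorConfig, compute_local_metrics, compare_metrics)

truth = default_ground_truth()            # 3 groups, one planted moderation
data = generate_symptom_data(truth, n_per_group=500, seed=1)
data = inject_missingness(data, rate=0.02, seed=2)

filtered, log = apply_missingness_filter(data)       # drop >= 50% missing
completed = impute_items(filtered, m=5, seed=3)      # chained-equations PMM
model = fit_moderated_mgm(completed, EstimatorConfig(gamma=0.5, reference_group="NAC"))

print({k: round(v, 3) for k, v in model.moderation.items() if abs(v) >= 0.01})
for g in model.groups:
    s = compute_local_metrics(model.condition_on_group(g), model.nodes, g).summary()
    print(g, round(s["strength_mean"], 2), "+/-", round(s["strength_sd"], 2))
```

prints

```
{('run', 'motor', 'ADHD-stim'): 0.148, ('instruct', 'org', 'ADHD-stim'): 0.021,
 ('fidget', 'motor', 'ADHD-nostim'): 0.014, ('org', 'run', 'ADHD-nostim'): 0.017}
NAC 0.17 +/- 0.06
ADHD-nostim 0.17 +/- 0.06
ADHD-stim 0.19 +/- 0.1
```

The planted run–motor moderation in the stimulant-exposed group is
recovered with increment 0.148 (ground truth: +0.25 on the latent
partial correlation, attenuated by discretizing the latent scores to a
0–3 scale); the handful of tiny spurious increments come from averaging
over five imputed datasets, in which they were selected at most once.
Mean node strength is higher in the moderated (ADHD-stim) network, while
its node-strength profile stays highly correlated with the other groups
(r = 0.94 here) — differences in association strength, not in local
network structure.

The same pipeline runs from the shell:

```sh
modnet simulate --seed 1 --out sim/           # writes symptoms.csv, prescriptions.csv
modnet run --config run.yaml --seed 1 --out results/
```

with a YAML config naming the input CSVs, group levels, bootstrap size,
sensitivity toggles (covariate nodes, complete cases) and output
directory. Outputs are CSV/JSON/GraphML plus a run log with all seeds.

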