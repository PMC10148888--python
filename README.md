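# pwmmrm

Propensity-weighted MMRM analysis of placebo-controlled trials in major
depressive disorder.

## The problem

Randomized antidepressant trials routinely fail because of large,
heterogeneous placebo response. Randomization balances arms only *on
average*: each subject carries an unobserved propensity to improve under any
intervention, and when many subjects have a high propensity, the measurable
drug–placebo difference shrinks and the trial loses power. `pwmmrm`
implements an analysis strategy that estimates each subject's probability of
responding to placebo **from data collected before randomization** and uses
its inverse as an observation weight in the primary longitudinal analysis,
so that subjects likely to improve regardless of treatment contribute less
to the treatment-effect estimate — without excluding anyone.

The package is aimed at biostatisticians and pharmacometricians analyzing
(or simulating) parallel-group rating-scale trials — HAMD-17 or MADRS
primary endpoints, a screening visit followed by a baseline visit, and
weekly total scores thereafter.

## The method

Five steps, each an importable component:

1. **Label** placebo-arm subjects as end-of-study responders or not.
   Response is a clinically anchored fractional reduction of the baseline
   total score (defaults: 38% on MADRS, 41% on HAMD-17 — the HAMD-17 value
   is the equipercentile equivalent of the MADRS one; the CGI-I anchor and
   equipercentile-linking machinery in `pwmmrm.labeling` makes the
   derivation auditable).
2. **Train** a multilayer perceptron mapping the 17 screening→baseline
   item changes Δx ∈ ℤ¹⁷ to the response probability, on a stratified 75%
   split of the placebo arm. Topology is grid-searched (1–3 hidden layers,
   1–17 nodes); training is deterministic full-batch gradient descent with
   backtracking line search.
3. **Validate** on the held-out 25% by the ROC AUC with a case-resampling
   bootstrap confidence interval.
4. **Score** every randomized subject: `p_i = f(Δx_i)`, and weight
   `w_i = 1 / clip(p_i, p_min, p_max)` (default clip `[0.05, 1]`).
5. **Fit** the weighted mixed model for repeated measures on the change
   from baseline `y_ij`:

   `y_i ~ N(X_i β, Σ_obs(i) / w_i)`

   with visit-specific intercepts, treatment×visit interaction (placebo
   reference), centered baseline and baseline×visit terms, and an
   unstructured T×T covariance Σ estimated by REML (log-Cholesky
   parameterization, analytic gradient, Newton polish). The treatment
   effect TE is the LS-mean difference (active − placebo) at the final
   visit; the effect size is `|TE| / (SE / sqrt(1/n₁ + 1/n₂))`.

A sensitivity grid refits `{weighted, unweighted} × {all subjects,
propensity < 0.2 removed, propensity > 0.8 removed}` and summarizes each
scheme's robustness with the mean percent absolute deviation
`B = mean |TE_subset − TE_all| / |TE_all|`.

Because no public trial dataset with item-level pre-randomization data
exists, `pwmmrm.simulate` generates trials in which a latent propensity
π_i ~ Beta(a, b) drives both a pre-randomization item-score drift and the
placebo component of the post-baseline trajectory, with the drug effect
attenuated in high-propensity subjects — the confounding structure the
weighting is designed to undo.

## Worked example

```python
from pwmmrm import RunConfig, run_pipeline
from pwmmrm.simulate import confounded_config

cfg = RunConfig(sim=confounded_config(), candidates=[(8,), (12, 6)], seed=1)
print(run_pipeline(cfg).render())
```

```
Propensity-weighted trial analysis
==================================================
arm census         : {'active_12.5mg': 156, 'active_25mg': 154, 'placebo': 149}
response threshold : 41% reduction from baseline
labeled placebo    : 126 (excluded, missing EOS: 23)
train/validation   : 94/32
selected topology  : (8,)
validation AUC     : 0.725 (95% CI 0.531-0.914)

Treatment effects at the final visit (active - placebo)
--------------------------------------------------
unweighted active_12.5mg_vs_placebo     TE   -1.330  p 0.02779  ES 0.258
unweighted active_25mg_vs_placebo       TE   -2.317  p 0.0001133  ES 0.452
weighted   active_12.5mg_vs_placebo     TE   -4.819  p 2.862e-14  ES 0.922
weighted   active_25mg_vs_placebo       TE   -5.216  p 9.765e-18  ES 1.041

sensitivity bias B : unweighted 1.520, weighted 0.554
seed 1   config c6f53eb779329e63   pwmmrm 0.1.0
```

Reading the output: the simulated trial is heavily confounded (most
subjects have latent propensity above 0.8), so the conventional unweighted
analysis sees a small drug–placebo separation (TE −1.3 and −2.3 points,
effect sizes 0.26/0.45). The network trained on pre-randomization item
drift ranks placebo responders clearly better than chance (validation AUC
0.73), and weighting by the inverse predicted probability recovers a much
larger treatment effect (−4.8 and −5.2 points) — the drug signal carried by
the subjects who were *not* going to improve on their own. The bias summary
B shows the weighted analysis is far more stable than the unweighted one
when the propensity extremes are removed.

The same pipeline runs from the shell:

```bash
pwmmrm simulate --seed 1 --out trial.csv        # synthetic trial + truth
pwmmrm analyze  --config run.yaml               # five-step analysis
pwmmrm sensitivity --data trial.csv --propensity out/propensity.csv
pwmmrm report --report out/report.json
```

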