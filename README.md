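# pragsub

Two-step **pragmatic subgroup discovery** for heterogeneous treatment effect
(HTE) analysis of two-arm randomized trials with a binary outcome.

**Step 1 — model-driven effect estimation.** Per-subject conditional average
treatment effects (CATEs) on the risk-difference scale are estimated from the
full raw covariate set by a pluggable estimator (reference implementation: an
honest T-learner — per-arm ensembles of weighted regression trees whose
splits and leaf means come from disjoint bootstrap halves), with
inverse-probability-of-censoring weights (IPCW) for covariate-dependent loss
to follow-up. Calibration is assessed with the Qini curve/coefficient and the
C-for-benefit concordance statistic (bootstrap CI): Qini > 0 and
C-for-benefit > 0.5 indicate better-than-chance calibration.

**Step 2 — interpretable subgroup discovery.** Raw covariates are recoded
declaratively into interpretable categories (guideline cutpoints; clinically
irrelevant scales removed), a depth-limited CART regression tree is fitted to
the estimated CATEs over the interpretable covariates, and each discovered
subgroup's average effect is validated with an augmented inverse probability
weighting (AIPW) risk difference and 95% CI.

A built-in synthetic trial generator with planted, subgroup-structured
effects (and the oracle effects exposed) supports testing and end-to-end
demonstration; real data can be ingested as CSV with a YAML schema sidecar,
and externally produced CATE estimates (e.g., from a Bayesian causal forest
fitted elsewhere) can be imported to drive Step 2.

## Command line

Each pipeline stage is exposed as a subcommand of `pragsub`:

```sh
pragsub simulate --config sim.yaml --out data.csv --seed 7
pragsub estimate --data data.csv --settings est.yaml --seed 7 --out cate.csv
pragsub calibrate --data data.csv --cate cate.csv --out calib.json --curve qini_curve.csv
pragsub recode   --data data.csv --out recoded.csv          # shipped default ruleset
pragsub discover --cate cate.csv --recoded recoded.csv --max-depth 2 --min-leaf 50 \
                 --out tree.json --rules rules.txt
pragsub effects  --data data.csv --cate cate.csv --tree tree.json \
                 --recoded recoded.csv --out effects.csv
```

or run everything from one config:

```sh
pragsub run --config examples/pipeline.yaml --seed 7
```

which writes `data.csv`, `cate.csv`, `calib.json`, `qini_curve.csv`,
`recoded.csv`, `tree.json`, `rules.txt`, `effects.csv` and a consolidated
`report.json` (with seeds and a config hash for reproducibility) into the
configured output directory.

## Python API sketch

```python
from pragsub import (
    lookahead_like_config, simulate_trial, fit_censoring_weights, estimate_cate,
)
from pragsub.calibration import qini_curve, qini_coefficient, c_for_benefit
from pragsub.recoding import default_ruleset, apply_recoding
from pragsub.tree import fit_tree, assign_groups, rules_text
from pragsub.effects import aipw_scores, group_ate_table

ds = simulate_trial(lookahead_like_config(n_subjects=4600, seed=7))
w = fit_censoring_weights(ds)
est = estimate_cate(ds, weights=w, seed=7)
print(qini_coefficient(qini_curve(est, ds, weights=w)))
print(c_for_benefit(est, ds, seed=7).statistic)

analytic = ds.retained_subset()
cov = apply_recoding(analytic, default_ruleset())
cov.index = analytic.subject_id.to_numpy()
tree = fit_tree(est, cov, max_depth=2, min_leaf=50)
print(rules_text(tree))
groups, _ = assign_groups(tree, cov)
print(group_ate_table(aipw_scores(ds, est, 0.5, w), groups.to_numpy()))
```

## Data formats

- **Trial dataset**: CSV with header `subject_id, treatment, outcome,
  retained, <covariates...>` plus a sidecar `<name>.schema.yaml` declaring
  each covariate's kind (`continuous`/`binary`/`categorical`, with level
  order). The outcome is reverse-coded (1 = event-free), so larger effects
  mean larger benefit; outcome is empty for non-retained subjects.
- **CATE estimates**: CSV `subject_id, tau_hat[, mu0_hat, mu1_hat]`; the arm
  predictions are required for AIPW.
- **Recoding ruleset**: YAML mapping each variable to
  `{action: keep|categorize|remove, cutpoints, labels}`; categorization is
  left-closed/right-open on the cutpoints. The shipped default
  (`src/pragsub/data/table2_lookahead.yaml`) covers the default 47-covariate
  synthetic roster and retains 42 interpretable covariates.

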