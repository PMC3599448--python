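# gxratio

Two-gene expression-ratio classifiers for blood qPCR cohort data.

The package implements a complete, seeded pipeline for discriminating
subject cohorts (CTRL / IBS / CD / UC / CeD) from threshold-cycle (CT)
tables:

1. **`synthetic_data`** — seeded synthetic qPCR cohorts on a 47-probe
   low-density array (GAPDH normaliser, duplicate probes GNB5-1/-2 and
   TP53-1/-2), with disease effects planted as fold changes carried per
   subject with a given penetrance.
2. **`expression_io`** — TSV reading/writing of CT tables and conversion to
   relative expression `2**(ct[GAPDH] − ct[target])`.
3. **`diffexpr`** — per-probe Welch tests against the control cohort with
   Bonferroni correction and an up/down/ns direction table.
4. **`ratioscore`** — the ratio-score method: a resampled search over all
   ordered two-gene ratios ranked by how many case subjects exceed the
   control-group maximum, greedy selection of a small covering panel,
   control-max thresholds, and per-subject binary n-tuple scoring (subject
   positive iff its score ≥ 1; training controls score 0 by construction).
5. **`classifiers`** — soft-margin kernel classifiers (RBF width β or
   polynomial degree, cost C) on the same ratio features, trained either by
   random-subset grid search judged on the full set, or by a holdout split
   with 10-fold cross-validated tuning; plus a pairwise-voting three-class
   extension and a tiered IBD-vs-IBS → CD-vs-UC cascade.
6. **`evaluation`** — confusion tables, sensitivity/specificity, Fisher's
   exact test, ROC/AUC, and TSV report layouts.

## CLI

The `ratioscore` entry point drives the pipeline on TSV files (CT table
with a `subject_id` first column; metadata with `subject_id` and `group`):

```sh
ratioscore simulate --kind paperlike --seed 1 --out ct.tsv --meta meta.tsv
ratioscore diffexpr --table ct.tsv --meta meta.tsv --out diff.tsv
ratioscore search --table ct.tsv --meta meta.tsv \
    --case-label CD --control-label CTRL --seed 1 \
    --reps 200 --top-k 500 --panel-out panel.json
ratioscore score --table ct.tsv --meta meta.tsv --panel panel.json --out scores.tsv
ratioscore train-svm --table ct.tsv --meta meta.tsv --panel panel.json \
    --protocol cv-holdout --kernel rbf --train-frac 0.6 --seed 1 \
    --model-out model.json --report-out accuracy.tsv
ratioscore evaluate --truth meta.tsv --pred scores.tsv \
    --positive-label CD --roc roc.tsv
```

## Library example

```python
import gxratio as gx

table = gx.make_fixture("paperlike", seed=1)
expr = gx.ct_to_relative(table)                 # GAPDH-normalised levels

sub = expr.subset([s for s in expr.subject_ids
                   if expr.groups[s] in ("CD", "CTRL")])
cands = gx.search_candidates(sub, "CD", "CTRL", reps=200, top_k=500, seed=1)
panel = gx.select_panel(cands[:100], sub, "CD", "CTRL")
results = gx.score_subjects(panel, sub, sub.subjects_in("CD"))
print(len(panel), gx.coverage(results))
```
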