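# tepseq

Tumour-educated platelet (TEP) RNA-seq classification with batch-confounding
diagnostics.

Blood platelets take up and splice tumour-associated mRNA, so their
transcriptome ("tumour-educated platelets") has been proposed as a liquid
biopsy for cancer detection. Classifiers trained on platelet
intron-spanning read counts can look excellent on internally held-out
samples and still fail completely on the next batch, because the collection
centre (hospital of origin) imprints a strong technical signature on
platelet activation genes — and in multicentre case–control studies the
centre is usually confounded with disease status. `tepseq` implements the
full classification pipeline for this setting *and* the diagnostics that
expose the confounding, together with a synthetic-data generator that
reproduces the confounded multicentre structure so every stage can be
exercised and tested without access to patient data.

## What is implemented

- **QC** — gene filter (drop genes with <30 reads in >90% of samples),
  detected-RNA sample filter (<750 detected RNAs), and leave-one-sample-out
  cross-correlation outlier removal (Pearson r < 0.3 against the median
  profile of the remaining samples, on log2 cpm).
- **Normalisation** — subset-aware TMM: the trimmed-mean-of-M-values
  reference and the factor normaliser are derived from the *training*
  samples only, so validation data can never leak into training factors;
  cpm-log2 transform; RUV factor estimation by SVD with the dual-threshold
  retention rule (a factor is regressed out iff p(factor vs class) > 0.01
  **and** p(factor vs some nuisance covariate — age, library size,
  hospital) < 0.01).
- **Partitioning** — stage-stratified 40/30/30 case allocation
  (largest-remainder rounding) and greedy nearest-age control matching
  without replacement; unmatched controls form the internal-validation arm.
- **Classifiers** — a PSO-SVM (particle swarm over the two RUV thresholds,
  the number of top-ranked genes, and SVM cost/gamma, minimising 1−AUC on
  the evaluation partition; 100 particles × 10 iterations by default) and a
  penalised logistic elastic net (α/λ grid by cross-validated AUC, 10-fold
  or LOOCV, optional majority-class down-sampling inside the CV loop).
- **Evaluation** — AUC as the normalised Mann–Whitney statistic, DeLong
  confidence intervals, threshold confusion metrics, stage-stratified
  summaries (early I–II / late III–IV).
- **Batch analysis** — per-gene linear mixed model variance partitioning
  (`~ age + (1|hospital) + (1|cancer)`), NB-GLM quasi-likelihood
  differential expression with TMM offsets, parametric empirical-Bayes
  ComBat, hypergeometric over-representation tests on user gene sets, and
  marker-based contamination scores.
- **Synthetic data** — negative-binomial counts with a hospital batch
  effect confined to a "platelet activation" module, a disjoint biomarker
  case signal, library-size/age variation, a skewed case–control-by-centre
  design, and optional erythrocyte/lymphocyte marker spiking. Biology and
  batch randomness are seeded separately, so a "fresh batch" (new hospital
  effect, same biology) is one seed away.

See `docs/methods.md` for model details, parameter defaults, and the design
choices behind each stage.

## Worked example

Run the full multicentre experiment on the confounded synthetic recipe
(reduced swarm for speed), then validate the trained models blind on a
fresh single-centre batch:

```python
from tepseq.pipeline import (default_recipe, run_multicentre_experiment,
                             make_external_set, run_blinded_validation,
                             link_and_evaluate)

cfg = default_recipe(confounded=True) | {"pso": {"n_particles": 20, "n_iterations": 5}}
report = run_multicentre_experiment(cfg, seed=1, run_variance_partition=False)
for name, sets in report.metrics.items():
    print(name, "internal AUC:", round(sets["internal_all"]["auc"], 3))

counts_ext, meta_ext = make_external_set(dict(cfg) | {"base_seed": 1}, seed=3001)
for name in ("pso_svm", "elastic_net"):
    preds = run_blinded_validation(report.models[name], counts_ext,
                                   meta_ext.drop(columns=["group"]))
    metrics = link_and_evaluate(preds, meta_ext[["sample_id", "group", "stage"]])
    print(name, "external AUC:", round(metrics["external_all"]["auc"], 3))
```

prints (seed 1):

```
pso_svm internal AUC: 0.802
elastic_net internal AUC: 0.889
pso_svm external AUC: 0.603
elastic_net external AUC: 0.529
```

Both classifiers look strong on the internal validation set of the
confounded cohort — but most of what they learned is the hospital
signature, which the skewed design makes predictive of case status. On an
external cohort from a fresh batch the hospital signature is redrawn, and
performance collapses towards chance: the multicentre-confounding failure
mode in miniature. Running the same experiment with
`default_recipe(confounded=False)` (balanced design, no hospital effect,
strong case signal) gives external AUCs ≥ 0.95 — the pipeline itself
transfers fine when the signal is real.

The same stages are scriptable from the shell via the `tep` CLI
(`tep simulate | qc | split | normalize | train-pso-svm | train-en |
predict | evaluate | variance-partition | de | combat | ora |
contamination | report`).

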