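# phenocriteria

Ontology-aware construction and evaluation of pediatric diagnostic criteria
for nevoid basal cell carcinoma syndrome (NBCCS), built around the Human
Phenotype Ontology (HPO):

- **ontology** — OBO 1.2/1.4 parsing (`is_a` only), ancestor/descendant
  closures, HPOA-style annotation tables, annotation-frequency information
  content (IC).
- **similarity** — Resnik term similarity (MICA), symmetric best-match-average
  profile similarity, deterministic top-k disease ranking.
- **control_simulation** — simulated control individuals sampled from disease
  annotation profiles (uniform feature-count model), descendant-aware feature
  presence.
- **classifier** — Bernoulli naive Bayes in log space with Laplace smoothing,
  stratified k-fold cross-validation, per-feature probability ratios.
- **criteria** — the existing major/minor criteria (both published decision-rule
  variants) and the proposed 3/2/1-point criteria (threshold 6, family history
  as a standalone trigger), evaluated descendant-aware at any age in months.
- **cohort_synthesis** — synthetic 48-participant survey cohorts calibrated to
  the published per-feature prevalences and median onset ages (lognormal onset
  model, optional Gaussian-copula feature correlation).
- **evaluation** — monthly sensitivity curves (birth to 18 years), median age
  at meeting criteria, Monte-Carlo specificity TN/(TN+FP), and an end-to-end
  pipeline with a JSON report.

A ~40-term miniature ontology (`mini_hp.obo`) containing every term used by
the criteria, and a 10-disease annotation table (`mini_annotations.tsv`), ship
as package data so everything is runnable offline.

## CLI

All functionality is exposed through one entry point:

```sh
# rank diseases by Resnik profile similarity to a target term set
phenocriteria rank-diseases --ontology hp.obo --annotations annotations.tsv \
    --target-terms targets.txt -k 500 --exclude OMIM:109400 --out ranked.tsv

# sample simulated controls from the top-ranked diseases
phenocriteria simulate-controls --ontology hp.obo --annotations annotations.tsv \
    --subset ranked.tsv -n 50000 --seed 1 --out controls.tsv

# synthesize a survey-like cohort and evaluate criteria
phenocriteria synth-cohort --seed 1 -n 48 --out cohort.tsv
phenocriteria score --cohort cohort.tsv --ontology hp.obo --criteria proposed
phenocriteria sensitivity-curve --cohort cohort.tsv --ontology hp.obo \
    --family-history off --out curves.tsv
phenocriteria specificity --controls controls.tsv --ontology hp.obo --criteria proposed

# train the Bernoulli NBC and inspect feature ratios
phenocriteria train-nbc --cases cohort.tsv --controls controls.tsv \
    --ontology hp.obo --folds 10 --seed 1 \
    --out-model model.json --out-ratios ratios.tsv

# full pipeline from a YAML config
phenocriteria run --config pipeline.yaml --seed 1 --outdir out/
```

`--criteria` accepts `existing` (alias `existing-methods`), `existing-table`,
`proposed`, or a path to a JSON criteria definition
(`CriteriaDefinition.to_json` documents the schema).

### Full-scale mode

The shipped fixtures are miniatures. To reproduce the full-scale analysis
qualitatively, point a pipeline config at a real `hp.obo` and a
`disease_id<TAB>hpo_id` table extracted from `phenotype.hpoa`
(`database_id` is accepted as a column alias):

```yaml
ontology: hp.obo
annotations: omim_annotations.tsv
k_similar: 500
n_controls: 50000
exclude_diseases: [OMIM:109400]
synthetic_cohort: {n: 48, seed: 1}
```

`phenocriteria run` then prints the Monte-Carlo specificity of both criteria
sets for comparison with published values. Exact reproduction is not expected:
it depends on the ontology/annotation release and on the similarity
aggregation used for the top-500 ranking (configurable via `aggregation:
bma | max | mean-pairwise`), and the cohort-level sensitivity figures depend
on unshared individual-level survey data.

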