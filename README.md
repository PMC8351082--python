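# strscreen

Ensemble screening of pathogenic short-tandem-repeat (STR) expansions in
next-generation sequencing cohorts.

Repeat expansion disorders (fragile X syndrome, Huntington disease,
myotonic dystrophy, Friedreich ataxia, the spinocerebellar ataxias, ...)
are caused by alleles whose repeat count at a known disease STR locus
crosses a pathogenic *full-mutation* threshold.  No single short-read STR
analysis tool detects all such expansions reliably: genotypers
(ExpansionHunter, GangSTR, TREDPARSE, spanning-read callers) under-size
GC-rich expansions, while case-control outlier tests (STRetch, exSTRa)
detect but do not size them, and both families produce false positives.
`strscreen` implements a first-tier screening pipeline that combines them:

1. **catalog** — a disease-STR locus catalog (hg19 coordinates, motif, and
   the repeat-count geometry of the allelic classes: normal, intermediate,
   premutation, borderline, and full-mutation with reduced/full penetrance
   bands), with validation and per-allele / per-sample classification.
2. **harmonize** — parsers for the tools' output dialects, multiple-testing
   adjustment of outlier p-values (Benjamini–Hochberg by default), and
   binarization into per-tool flags: for a genotyper, 1 iff at least one
   allele is full-mutation; for an outlier test, 1 iff the adjusted
   p-value is < 0.05.  Flags assemble into a labeled (sample × locus) × tool
   matrix; rows with missing flags are dropped and counted.
3. **ensemble** — a from-scratch CART decision tree over the binary flags
   (Gini impurity, `gini = 1 − Σ p_c²`), stratified 80/20 splitting,
   repeated stratified k-fold CV (5 × 10 = 50 splits), exhaustive
   feature-subset selection by mean validation ROC AUC, grid-search
   hyper-parameter tuning, and full evaluation (precision = TP/(TP+FP),
   recall = TP/(TP+FN), accuracy, F1 = 2PR/(P+R), ROC/PR curves,
   normalized Gini feature importances).
4. **screen** — applies a trained model (or the published fixed rule:
   EH_v3 + STRetch + exSTRa consensus) to cohort calls, annotates
   candidates with allelic class and penetrance band, resolves trio
   inheritance (parental origin, repeat-count delta, stability), checks
   clinically negative loci, and summarises allele-length distributions.
5. **synthetic** — a seeded generator of labeled cohorts and tool-dialect
   fixture files (EH-style JSON, VCF, TSV) with configurable per-tool
   sensitivity, false-positive rate, undersizing and missingness, standing
   in for the access-restricted benchmark and patient data.

## Worked example

```python
import strscreen as s

by_id = s.catalog_by_id(s.default_catalog())

# a benchmark-like cohort: 86 expansion carriers + 32 unaffected samples
config = s.ega_like_config(seed=1)
cohort = s.simulate_cohort(config, s.default_tool_profiles())

unified = s.binarize_all(cohort.genotype_calls + cohort.outlier_results, by_id)
matrix = s.build_labeled_matrix(
    unified, cohort.truth,
    ("eh_v2", "eh_v3", "gangstr", "tredparse", "stretch", "exstra"))
train, test = s.stratified_split(matrix, 0.2, seed=1)

scheme = s.CVScheme(k=10, repeats=5, seed=1)
subset, table = s.exhaustive_feature_selection(train, scheme=scheme)
print("selected tools:", subset)

hp = s.grid_search(train, subset, None, scheme)
sub = s.LabeledMatrix(train.data[list(subset)], train.labels, subset)
tree = s.fit_tree(sub, hp)
X = test.data[list(subset)].to_numpy()
report = s.evaluate(test.y, tree.predict(X), tree.predict_score(X))
fm = report.per_class["full_mutation"]
print(f"test precision {fm['precision']:.2f} recall {fm['recall']:.2f} "
      f"F1 {fm['f1']:.2f}")
```

prints

```
selected tools: ('eh_v3', 'stretch')
test precision 1.00 recall 1.00 F1 1.00
```

The selection lands inside the strong tool tier (the generator's default
profiles give EH_v3, STRetch and exSTRa full sensitivity with independent
false positives, and the weak tier their default-parameter sensitivities),
and the ensemble reaches perfect test recall while out-precising every
single tool — a tree over two tools can require agreement before calling
an expansion, which independent false positives rarely achieve.

The same workflow is available from the shell:

```bash
strscreen simulate  --out cohort --seed 1 --trios
strscreen harmonize --calls cohort --truth cohort/truth.tsv --out mat
strscreen select    --matrix mat/matrix.tsv --out sel
strscreen train     --matrix mat/matrix.tsv --tools eh_v3,stretch --out mdl
strscreen screen    --calls cohort --model mdl/model.json --out hits
strscreen trio      --trios cohort/trios.tsv --out tx
```

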