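# Methods

## Problem and model

Short tandem repeats (STRs) are tandem arrays of 1–6 bp motifs; at a few
dozen disease loci, alleles above a locus-specific repeat-count threshold
(a *full-mutation*) cause Mendelian disease.  Short-read sequencing can
interrogate all of these loci at once, but each analysis tool sees
expansions through a different and imperfect lens.  `strscreen` treats the
tools' outputs as binary experts — "does this sample carry a full-mutation
at this locus?" — and learns a decision-tree combination of experts whose
sensitivity and precision beat any single one.

The classifier is a binary CART: at each node, the binary tool flag with
the largest weighted Gini impurity decrease splits the rows (flag 0 left,
flag 1 right), where the impurity of a node with class counts
`(n_fm, n_non)` is `1 − (n_fm/n)² − (n_non/n)²`.  Growth stops at purity,
at a depth/sample-count bound, or when no split achieves a strictly
positive decrease.  A leaf predicts its majority class, with ties going to
the full-mutation class (the screening-conservative choice).  Because the
tree emits hard labels, ROC and precision-recall curves are computed from
the *leaf full-mutation fraction* as a score; the ROC AUC is evaluated via
the Mann–Whitney concordance identity (ties count ½).

Model selection follows the study design the package reproduces: the
labeled matrix is split 80/20 stratified by class (test size is the
ceiling, so 1176 rows give 940 train / 236 test); every non-empty tool
subset is scored by mean validation AUC over 50 train-validation splits
(5 repeats of stratified 10-fold CV) on the training part; the winning
subset's hyper-parameters are grid-searched with the same splits.

## Allelic classification

A locus definition carries the repeat-count geometry of its allelic
classes.  `fm_threshold` is always the *smallest count classified
full-mutation* (≥ semantics); where the conventional clinical figure is a
"greater-than" bound, the printed figure is kept in `fm_threshold_printed`
and the effective minimum is printed + 1 (FMR1/FMR2: printed 200,
effective 201; DMPK: printed 50, effective 51; ATXN8: printed 200,
effective 201).  The sensitised ("lowered") screening thresholds for the
GC-rich fragile-X loci follow the same encoding: FMR1 printed 54 /
effective 55 (so the 45–54 intermediate band stays intermediate and
premutation alleles of 55–200 repeats are flagged), FMR2 printed 60 /
effective 61.

Within the full-mutation region, penetrance bands annotate the class:
HTT 36–39 reduced / ≥ 40 full (so a 37-repeat HTT allele is a
reduced-penetrance full-mutation even though the conventional printed
threshold is 39 — the effective minimum is set to the reduced band's lower
bound); ATXN2 33–34 reduced, 35–36 borderline (between the bands),
≥ 37 full; AR ≥ 38 full.  Loci whose intermediate/premutation ranges are
not defensibly documented ship without them; counts below the
full-mutation region that fall in no band classify as normal.  With this
layout, classification is an exhaustive partition of the non-negative
integers, class rank is monotone in repeat count, and default-mode
full-mutations are always flagged in lowered mode (all three are property
tested).

Coordinates are 1-based inclusive hg19 (the region-string convention of
the genotyper catalogs, e.g. `13:70713516-70713560` for ATXN8); half-open
0-based conversion happens only at BED-style I/O boundaries.  Off-target
site lists are carried as opaque metadata — they configure external
genotypers, which this package does not re-implement.

## Harmonization choices

* The multiple-testing method for outlier p-values is configurable
  (BH / Holm / Bonferroni); BH is the default since both upstream outlier
  tools are FDR-oriented, and only the 0.05 cutoff is fixed.  "p < 0.05"
  is a strict inequality.  Adjustment is applied per tool across all
  sample × locus tests of a run; STRetch-style inputs arriving already
  adjusted pass through unchanged.
* Tool dialects are minimal field contracts (which JSON keys / VCF FORMAT
  fields / TSV columns carry sample, locus, alleles, p-values), documented
  in `strscreen.harmonize`, rather than re-implementations of each tool's
  full format: EH-style JSON (`Genotype` "a1/a2"), GangSTR-style VCF
  (`REPCN`), TREDPARSE/spanning-caller VCF (`GB`), STRetch TSV (`p_adj`),
  exSTRa TSV (`p`).  VCF I/O goes through pysam, tables through pandas,
  and p-value adjustment through statsmodels; the test suite checks BH
  against an independent step-up implementation and AUC against both pair
  counting and scikit-learn.
* Hemizygous X-linked calls are single-allele genotypes; the "at least one
  full-mutation allele" rule applies unchanged.

## Determinism and tie rules

All randomness flows from one explicit seed through
`numpy.random.default_rng`; each CV repeat derives its stream from
`(seed, repeat)`.  Split ties prefer the highest impurity decrease, then
the lowest feature index in the supplied tool order.  Subset-selection
ties prefer fewer tools, then lexicographic position in the tool order.
Grid ties prefer the simplest model (smallest `max_depth`, then largest
`min_samples_leaf`).  The default grid is `max_depth` 1–6,
`min_samples_split` {2, 5, 10}, `min_samples_leaf` {1, 5, 10},
`min_impurity_decrease` {0, 1e-4}: with at most a dozen binary features,
useful depth is small, and the grid is fully configurable.  Stratified
allocation uses largest-remainder rounding, so per-class proportions are
preserved to rounding in every split and fold.  A CV fold whose training
or validation part is single-class contributes AUC 0.5 with a logged
warning.  Floating-point comparisons in tie-breaking use a 1e-12
tolerance.

## Screening

A serialized tree (JSON nodes with per-node class counts, tool order, and
run metadata) or the fixed published rule screens harmonized cohort calls.
The fixed rule encodes the selected BWA-alignment tool trio
(EH_v3, STRetch, exSTRa) as an any-positive consensus; it is materialized
by fitting the CART on the 8-row exhaustive truth table of that rule so
node statistics are well defined without retraining.  Sample-locus pairs
missing a model tool's flag are reported as not-evaluable (negative
verdict, review flag), never silently dropped.  Ensemble-positive pairs
become candidates whose verdict follows the best genotyper estimate's
class (full-mutation with penetrance band, borderline, or
intermediate/premutation when only sub-threshold estimates accompany an
outlier-driven flag); a candidate supported by exactly one genotyper and
neither outlier test is flagged "review recommended", since such calls
have a record of failing orthogonal validation.

Trio inheritance assigns the transmitting parent as the one carrying the
allele closest in repeat count to the proband's expanded allele, matching
by allelic class first and falling back to any expanded (non-normal)
parental allele (transmitted expansions can cross a class boundary, e.g.
an intermediate mother transmitting a premutation).  Two equidistant
parents, or none, resolve to "unresolved", which also covers apparent
de-novo expansions.  Stability labels the repeat-count delta:
negative = contracted, zero = stable, positive = expanded.

## Synthetic cohorts

The generator reproduces the composition of the reference benchmark: 86
samples each carrying exactly one molecularly characterized expansion
(per-locus counts AR 1, ATN1 2, ATXN1 3, ATXN3 1, C9orf72 3, DMPK 17,
FMR1 18, FMR2 3, FXN 25, HTT 13) plus 32 unaffected samples, 10 catalog
loci per sample.  Normal alleles follow a truncated two-sided geometric
distribution around literature modal values; expansions are drawn
uniformly above the locus threshold (up to a configurable excess, default
400 repeats); X-linked loci are hemizygous in samples drawn male.

Tool error is phenomenological: per-locus detection sensitivity,
false-positive rate, missingness, and (for genotypers) undersizing.
Missed expansions are re-drawn *below* the threshold — mirroring the
observed failure mode of read-based genotypers on GC-rich loci, where
every missed full-mutation is under-sized rather than uncalled.  Outlier
p-values are a two-component mixture: the significant component
(uniform below 1e-6) fires with exactly the configured sensitivity or
false-positive rate, and the rest is the non-significant part of the
uniform null, so downstream adjustment cannot flip a configured flag.
The default profiles emulate the post-optimisation benchmark picture:
EH_v3, STRetch and exSTRa at sensitivity 1.0, the remaining genotypers at
their default-parameter sensitivities (0.74 / 0.38 / 0.72), and per-tool
false-positive rates from the benchmark tallies (0.005–0.032).

What the generator does **not** model: reads, alignment, coverage,
GC-bias mechanics, repeat interruptions, stutter, or correlated errors
between tools (false positives are independent across tools, which is
favourable to conjunctive ensembles).  Passing tests therefore establish
that the pipeline's logic and statistics behave as specified under the
benchmark's composition — not that the specific tool combination would
transfer to a new sequencing context, where correlated failure modes
(e.g. shared alignment artefacts) can erode the ensemble advantage.

Trio simulation draws a transmission delta from the configured range
(default +1 to +15 repeats), assigns a random transmitting parent whose
expanded allele is the proband's minus the delta (kept above threshold so
the origin stays resolvable), and inherits the proband's normal allele
from the other parent.

## Problem sizes and verification

The test suite and acceptance script run on the benchmark-scale cohort
(118 samples × 10 loci × 6 tools, ~1170 matrix rows), with 50-split CV
over all 63 tool subsets and a 108-point hyper-parameter grid; oracle
equivalence suites use 50 random 60-row, 5-feature datasets.  These sizes
match the study design being reproduced; everything completes in seconds
on one CPU.  Brute-force oracles (pure-Python greedy CART with identical
tie rules, pairwise AUC counting, step-up BH) are kept in the test suite,
structurally independent of the implementation.

## Known limitations

* The exact published tree topology and its printed test metrics depend
  on a private 80/20 split of restricted data; the package reproduces the
  arithmetic identities those metrics obey and the selection behaviour on
  synthetic cohorts, not the bit-level figures.
* Catalog coordinates for loci other than ATXN8 are standard hg19 values
  carried as metadata; the package never extracts reference sequence and
  performs no liftover.
* Intermediate/premutation ranges are shipped only where a documented
  range abuts the full-mutation boundary; elsewhere sub-threshold counts
  classify as normal.
* Whether subset selection should score validation AUC with hard labels
  or leaf fractions is underdetermined; both are supported
  (`use_scores`), leaf fractions by default, since hard labels collapse
  the ROC to a single operating point.
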