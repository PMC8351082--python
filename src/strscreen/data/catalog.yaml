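# Default disease-STR locus catalog (hg19, 1-based inclusive coordinates).
#
# Thresholds follow the convention documented in LocusDefinition:
# `fm_threshold` is the smallest repeat count classified full-mutation
# (>= semantics); `fm_threshold_printed` preserves the conventional
# clinical threshold figure where the two differ (e.g. FMR1 "> 200"
# is stored as fm_threshold 201 / fm_threshold_printed 200).
# Intermediate/premutation ranges are only populated where a defensible
# published range abuts the full-mutation boundary; otherwise they are
# left absent and counts fall back to the normal class.
loci:
  - locus_id: AR
    chrom: chrX
    start: 66765159
    end: 66765228
    motif: CAG
    inheritance: X_linked
    normal_max: 34
    fm_threshold: 37
    fm_threshold_printed: 37
    full_penetrance_min: 38

  - locus_id: ATN1
    chrom: chr12
    start: 7045880
    end: 7045938
    motif: CAG
    inheritance: autosomal_dominant
    normal_max: 35
    fm_threshold: 47
    fm_threshold_printed: 47

  - locus_id: ATXN1
    chrom: chr6
    start: 16327865
    end: 16327955
    motif: CAG
    inheritance: autosomal_dominant
    normal_max: 35
    fm_threshold: 38
    fm_threshold_printed: 38

  - locus_id: ATXN2
    chrom: chr12
    start: 112036754
    end: 112036823
    motif: CAG
    inheritance: autosomal_dominant
    normal_max: 31
    fm_threshold: 33
    reduced_penetrance_range: [33, 34]
    borderline_range: [35, 36]
    full_penetrance_min: 37

  - locus_id: ATXN3
    chrom: chr14
    start: 92537355
    end: 92537396
    motif: CAG
    inheritance: autosomal_dominant
    normal_max: 44
    fm_threshold: 59
    fm_threshold_printed: 59

  - locus_id: ATXN8
    chrom: chr13
    start: 70713516
    end: 70713560
    motif: CTG
    locus_structure: "(CTG)*"
    inheritance: autosomal_dominant
    normal_max: 50
    fm_threshold: 201
    fm_threshold_printed: 200

  - locus_id: C9orf72
    chrom: chr9
    start: 27573483
    end: 27573544
    motif: GGCCCC
    inheritance: autosomal_dominant
    normal_max: 30
    fm_threshold: 60
    fm_threshold_printed: 60

  - locus_id: DMPK
    chrom: chr19
    start: 46273463
    end: 46273524
    motif: CTG
    inheritance: autosomal_dominant
    normal_max: 34
    premutation_range: [35, 50]
    fm_threshold: 51
    fm_threshold_printed: 50

  - locus_id: FMR1
    chrom: chrX
    start: 146993569
    end: 146993628
    motif: CGG
    inheritance: X_linked
    normal_max: 44
    intermediate_range: [45, 54]
    premutation_range: [55, 200]
    fm_threshold: 201
    fm_threshold_printed: 200
    lowered_threshold: 55
    lowered_threshold_printed: 54

  - locus_id: FMR2
    chrom: chrX
    start: 147582125
    end: 147582273
    motif: GCC
    inheritance: X_linked
    normal_max: 30
    fm_threshold: 201
    fm_threshold_printed: 200
    lowered_threshold: 61
    lowered_threshold_printed: 60

  - locus_id: FXN
    chrom: chr9
    start: 71652202
    end: 71652220
    motif: GAA
    inheritance: autosomal_recessive
    normal_max: 33
    fm_threshold: 65
    fm_threshold_printed: 65

  - locus_id: HTT
    chrom: chr4
    start: 3076604
    end: 3076660
    motif: CAG
    inheritance: autosomal_dominant
    normal_max: 26
    intermediate_range: [27, 35]
    fm_threshold: 36
    fm_threshold_printed: 39
    reduced_penetrance_range: [36, 39]
    full_penetrance_min: 40
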