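# Benchmark full-mutation detection counts on the reference cohort of 86
# samples with one molecularly characterized expansion each (default tool
# parameters, per aligner).  `truth` gives the number of true full-mutation
# samples per locus; each tool row gives the per-locus true-positive counts
# followed by the tool's false-positive total.  Sensitivity is recomputed
# from these counts, never stored.
locus_order: [AR, ATN1, ATXN1, ATXN3, C9orf72, DMPK, FMR1, FMR2, FXN, HTT]
truth: [1, 2, 3, 1, 3, 17, 18, 3, 25, 13]
aligners:
  isaac:
    eh_v2:     {tp: [1, 2, 2, 1, 3, 17, 1, 0, 25, 13], fp: 6}
    eh_v3:     {tp: [1, 2, 3, 0, 3, 17, 0, 0, 25, 13], fp: 5}
    gangstr:   {tp: [0, 2, 2, 0, 0, 16, 0, 0, 16, 11], fp: 8}
    tredparse: {tp: [1, 2, 1, 0, 3, 17, 0, 0, 25, 13], fp: 3}
    stretch:   {tp: [1, 2, 3, 1, 3, 17, 2, 3, 20, 13], fp: 26}
    exstra:    {tp: [1, 2, 3, 0, 3, 17, 1, 3, 5, 13], fp: 33}
  bwa:
    eh_v2:     {tp: [1, 2, 2, 1, 3, 17, 0, 0, 25, 13], fp: 6}
    eh_v3:     {tp: [1, 2, 3, 0, 3, 17, 0, 0, 25, 13], fp: 5}
    gangstr:   {tp: [1, 2, 2, 1, 1, 16, 0, 0, 0, 10], fp: 8}
    tredparse: {tp: [1, 2, 1, 0, 3, 17, 0, 0, 25, 13], fp: 10}
    stretch:   {tp: [1, 2, 3, 1, 3, 17, 2, 3, 20, 13], fp: 26}
    exstra:    {tp: [1, 2, 3, 1, 3, 16, 9, 3, 25, 13], fp: 35}
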