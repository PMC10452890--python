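# Published cascade counts of the study cohort, used as report inputs
# (the raw cohort itself was never deposited). Values are transcribed from
# the small-variant and SV filtering summary tables.
small_variants:
  vqsr_total: 9876341
  snps: 7836438
  indels: 2039903
  af_filter: 2334312
  cadd_filter: 80905
  coding_total: 2824
  noncoding_total: 78081
  coding_consensus: 1961
  noncoding_consensus: 9826
  coding_shared_all: 79
  coding_shared_within: {HRLS: 37, IRLS: 27, LRLS: 15}
  noncoding_shared_within: {HRLS: 4171, IRLS: 2820, LRLS: 2835}
  noncoding_exclusive: {HRLS: 2, IRLS: 3, LRLS: 14}
  regulomedb_pass: {LRLS: 4}
sv:
  called: {DEL: 4120, DUP: 194, BND: 6560, INV: 297}
  af_filter: {DEL: 1122, DUP: 105, BND: 5492, INV: 137}
  ranking_filter: {DEL: 164, DUP: 17, BND: 274, INV: 18}
  length_filter: {DEL: 140, DUP: 17, BND: null, INV: 18}
  shared_all: {BND: 154, DEL: 133, DUP: 4, INV: 13}
  shared_within_group: {BND: 35, DEL: 18, DUP: 2, INV: 2}
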