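# Packaged fixtures

Transcriptions of the study's published per-variant tables plus supporting
inputs, used by the tests and the acceptance checks.

- `pedigree.ped` — **synthetic** pedigree constructed to mirror the study
  family's sequenced structure (4 generations; 13 sequenced members
  stratifying into 3 HRLS, 4 IRLS, 6 LRLS under the triplet rule). The
  published pedigree is only available as a figure, and its stated total
  membership is internally inconsistent (37 vs 39 members; 11 sequenced
  members vs group sizes 3+4+6=13), so only the sequenced group structure
  is mirrored here.
- `table3_small_variants.tsv` — the 49 prioritized small-variant rows
  (45 coding, 4 noncoding) across 39 distinct genes, with per-group
  sharing flags, allele frequency, region code (EX/INT/NA), and the four
  cancer-classification cells. `bold=1` marks the rows the source table
  printed in bold (previously described cancer associations).
  Known transcription caveats, preserved as printed:
  - the IRLS "Yes" flags sum to 26 while the summary table prints
    "IRLS: 27"; IRLS coding totals are therefore never asserted;
  - four rows print no rsid (`NA`), and their classification cells are NA;
  - one gene is called TAS2R19 in the text but PRH1-TAS2R14 in the table;
    the table spelling is used.
- `table5_svs.tsv` — the 57 prioritized SV rows (35 BND, 18 DEL, 2 DUP,
  2 INV; 48 overlapping 43 distinct genes, 9 with no gene). Column order
  of the sharing flags follows the printed header (LRLS, IRLS, HRLS).
  Caveat: the SV summary table attributes 23 within-group BNDs to HRLS
  while the first (LRLS-labelled) column of this table holds 23 BND rows —
  the two printed labelings conflict. Both are preserved as printed; only
  label-independent totals are asserted.
- `knowledgebase.tsv` — local cancer-association table transcribed from
  the bold rows of the two variant tables (rsid-keyed entries for small
  variants, gene-keyed for SVs), standing in for the OncoKB /
  My Cancer Genome / CGI / GAD web queries.
- `printed_cascade_counts.yaml` — the published per-stage survivor counts
  of both cascades, consumed as report inputs (the raw cohort was never
  deposited, so these counts are not recomputable from data).
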