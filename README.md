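# riskcluster

Familial "variant risk cluster" analysis for pedigree sequencing cohorts:
a two-track germline variant prioritization cascade (SNPs/indels and
structural variants) over a multi-sample Lynch-syndrome pedigree, followed
by familial sharing classification into risk-group clusters and
cross-referencing against a local cancer knowledgebase.

## The problem

In a colorectal-cancer (CRC) pedigree with Lynch syndrome (LS), sequenced
members are stratified by the *immediate triplet* rule (the subject and
both parents) into three familial risk groups:

* **HRLS** — high risk: the subject is affected;
* **IRLS** — intermediate risk: the subject is unaffected and at least one
  parent is affected;
* **LRLS** — low risk: subject and both parents unaffected.

Annotated germline variants are then pushed through a prioritization
cascade. Small variants must be rare in two reference panels
(AF < 0.01 in 1000 Genomes ALL and non-TCGA ExAC ALL, missing = novel =
pass), probably deleterious (CADD scaled score > 10), and — after
stratification into coding (exonic) and noncoding — called deleterious by
at least 3 of 4 predictors (MutationTaster, PolyPhen2, PROVEAN, SIFT).
SVs must pass a duphold depth-validation gate (DEL/DUP only), the same
dual-panel rarity filter (1000 Genomes + gnomAD), an AnnotSV ranking > 3
gate, and a total length >= 50 bp gate (BND exempt). Breakends are
counted per record; mate pairs are never merged.

Each surviving variant's presence vector over the sequenced subjects is
reduced to its *sharing class*: shared by all subjects, shared by every
member of a risk group (possibly several groups at once), or exclusive to
one group — the per-group clusters of co-shared variants are the "variant
risk clusters". Group-exclusive noncoding variants additionally face a
RegulomeDB rank < 4 gate. Finally, genes and rsids are cross-referenced
against a packaged cancer knowledgebase (standing in for OncoKB,
My Cancer Genome, CGI and GAD queries) to attach cancer-type, CRC
relatedness, oncogenic class and tumor-driver calls.

Because the original cohort was never deposited, the package ships (a)
transcriptions of the study's two prioritized-variant tables as fixtures
and (b) a synthetic cohort generator that plants, for every simulated
record, the first cascade stage it should fail and its sharing class, so
every pipeline stage is testable against ground truth.

## Worked example

```bash
riskcluster all --seed 7 --n-small 100 --n-svs 50 --outdir /tmp/demo
head -4 /tmp/demo/report/small_cascade_trace.tsv
```

prints

```
stage	surviving	pct_of_previous
input	100	
af	61	61.00
cadd	26	42.62
```

i.e. of 100 simulated small variants, 61 were rare in both panels
(61.00 % of the input) and 26 of those had CADD > 10 (42.62 % of the 61).
The same run writes the SV trace, the noncoding region cross-tabulation,
the per-variant tables with sharing flags and cancer cells, the per-group
cancer-gene summary, and a manifest. The numbered drivers under
`analysis/` run the same steps over a larger simulated cohort and the
packaged fixtures, writing their tables under `results/`; for example
`python analysis/05_reproduce_study_tables.py` prints

```
rarity filter kept 23.63% of called variants; CADD kept 3.46% of those
coding sharing occurrences: {'HRLS': 37, 'IRLS': 26, 'LRLS': 15} (39 genes over 49 rows)
CRC-associated small-variant genes: ['MLH1', 'PRH1-TAS2R14']
within-group shared SVs by type: {'BND': 35, 'DEL': 18, 'INV': 2, 'DUP': 2}
digestive/CRC-related SV genes: ['FOXP1', 'IRS2', 'RELN']; other: ['RRAS2']
```

— the published tallies recomputed from the packaged fixtures.

## Layout

* `src/riskcluster/` — the library: `pedigree` (PED parsing, risk
  groups), `variants` (record model, VCF/TSV I/O), `small_variants` and
  `svs` (the two cascades), `sharing` (sharing classes and counting),
  `knowledgebase` (cancer cross-referencing), `simulate` (synthetic
  cohorts with planted truth), `report` (orchestration and rendering),
  `cli`, and `fixtures/` (packaged tables, see its README).
* `analysis/` — numbered narrative drivers over the library.
* `tests/` — unit, property and acceptance suites.
* `docs/methods.md` — model, parameters, design choices, limitations.
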