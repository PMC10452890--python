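# Methods

## Risk-group model

Sequenced pedigree members are labelled by the immediate-triplet rule:
affected → HRLS; unaffected with ≥1 affected parent → IRLS; unaffected
with both parents unaffected → LRLS. Affection dominates (an affected
subject is HRLS regardless of parental status), and the three labels
partition the sequenced subjects. A missing parent slot on a declared
founder contributes no affection; an *unknown* affection status — of the
subject, or of a parent when the subject is unaffected — makes the
subject unclassifiable and is raised as an error naming the subject
rather than guessed (married-in spouses of unknown status are the typical
case). PED affection coding is 1 = unaffected, 2 = affected, 0/−9 =
unknown, with an optional seventh column flagging sequenced subjects.

The packaged pedigree fixture is synthetic: the source family is only
available as a figure and its stated membership is internally
inconsistent (37 vs 39 total members; "11 sequenced" vs group sizes
3 + 4 + 6 = 13). The fixture mirrors the only structurally actionable
statement — four generations and sequenced group sizes 3/4/6 derived
from the rule — and nothing else about the family. Group sizes are always
derived from the rule, never hard-coded.

## Prioritization cascades

All thresholds follow their printed operators and are strict unless the
operator itself is inclusive:

| stage | rule | missing value |
|---|---|---|
| small-variant rarity | AF < 0.01 in both panels | passes (novel) |
| small-variant CADD | scaled score > 10 | fails (no evidence) |
| region split | coding = exonic, everything else noncoding | → noncoding with warning |
| predictor consensus | ≥ 3 of 4 deleterious calls | call counts as non-deleterious |
| RegulomeDB | rank < 4, group-exclusive noncoding only | fails |
| SV depth | duphold flag true, DEL/DUP only | fails (DEL/DUP); BND/INV exempt |
| SV rarity | AF < 0.01 in both panels | passes |
| SV ranking | AnnotSV class > 3 (so 4–5 survive) | fails |
| SV length | end − start ≥ 50 bp, BND exempt | — |

Asymmetric missing-value handling is deliberate: a frequency absent from
a panel is evidence of rarity, while an absent deleteriousness score is
absence of evidence. The predictor-consensus stage is applied to the
noncoding track as well as the coding track — biologically unusual for
protein-level predictors, but it is what the published coding/noncoding
survivor split implies. The RegulomeDB gate sits downstream of sharing
classification and touches only group-exclusive noncoding survivors.
The two percentage cells of the cascade trace are truncated (not rounded)
to two decimals; that is the arithmetic the published summary table
actually uses (2,334,312/9,876,341 → 23.63, not the half-up 23.64).
Zero denominators render NA.

Multi-allelic sites are split per ALT allele and filtered independently.
Presence means at least one copy of the ALT allele; a missing genotype is
absence. No genotype-quality threshold is applied. Breakends are handled
strictly per record: n breakend lines yield n records; mates are linked
via MATEID/ALT coordinates but never merged, so all per-type counts are
per-breakend. VCF coordinates are 1-based inclusive throughout, and SV
ids render `chrom_start_end_TYPE_n` exactly as read.

## Sharing classification

For each variant the carrier set over the sequenced roster yields a set
of classes: `shared_all_samples` (carriers = roster);
`shared_within_group(g)` (all of g carries, regardless of presence
elsewhere — a variant can be shared within several groups); and
`exclusive_to_group(g)` (≥ 1 carrier, all inside g). Exclusivity
deliberately does not require the whole group: the published exclusive
counts describe variants "detected only in a particular group", and the
strict reading would collide with the separate shared rows. The strict
conjunction (carriers exactly = group) is exposed separately as
`is_exclusive_and_shared`. A variant absent from everyone classifies as
`other` and is flagged, never dropped. Summary counting follows the
published convention of summing per-group shared occurrences with
multiplicity (a variant shared in all three groups counts once per
group).

## Knowledgebase

Web queries are replaced by a packaged, versioned TSV keyed by gene
symbol (case-insensitive) or rsid (exact), with semicolon-separated
cancer-type and CRC-type lists, a stored CRC-relatedness boolean (never
inferred from string matching), an oncogenic class and a tumor-driver
flag, and a source tag resolved by a configurable priority list
(OncoKB > My Cancer Genome > CGI > GAD > SNPnexus). rsid entries beat
gene entries. No-hit defaults are track-dependent: coding records with an
rsid default to Passenger/non-driver, noncoding records to
"Not protein-affecting", and records with no queryable key at all stay
unknown (rendered NA). The schema carries a `crc_types` column beyond the
boolean because the published tables print CRC-relatedness as text
(e.g. "CRC; Intestinal; Stomach"), which a boolean cannot reproduce.
Annotation is a pure function of (record, knowledgebase) and therefore
idempotent and invariant under row permutation.

## Synthetic cohort generator

The generator defines the study conditions the suites run under: a
3/4/6-member three-group pedigree (HRLS members affected founders; IRLS
members given an affected father; LRLS members two unaffected parents)
and two variant tracks in which every record carries a planted
first-failing stage and a planted sharing pattern, realized exactly in
its annotations and presence vector. Defaults: 500 small variants and
200 SVs per cohort; first-failure mixture 50 % rarity / 30 % CADD / 12 %
consensus / 8 % survivors for small variants and 15 % depth / 40 %
rarity / 28 % ranking / 5 % length / 12 % survivors for SVs (chosen so
every stage stays well populated at test sizes — the study's real
attrition would leave almost no survivors at simulable n); SV type mix
0.587 BND / 0.369 DEL / 0.017 DUP / 0.027 INV, matching the published
called proportions. Frequencies are a rare-uniform [0, 0.009] /
common-uniform [0.05, 0.5] mixture with 25 % missing — only
threshold-crossing behaviour matters to the cascades, so no attempt is
made at a realistic site-frequency spectrum. Sharing patterns are planted
by direct presence-vector assignment, not transmission simulation: the
analysis tests set algebra over carriers, not inheritance. Infeasible
configs (an exclusive pattern for an empty group, an `other` pattern
without two groups of size ≥ 2) fail before generation. BNDs are
generated as mate pairs but counted per record.

Consequently, passing tests demonstrate correctness of the filtering,
sharing and counting logic under controlled annotations; they say
nothing about upstream calling quality, annotation accuracy, linkage
between sites, or genotype error, none of which the generator models.

## Numerical and I/O choices

CADD values for planted consensus-stage and survivor records are drawn
from [10.001, 40] so the strict > 10 comparison survives rounding and
the 32-bit float storage of VCF INFO fields; for the same reason the
round-trip tests compare floats at a relative tolerance of 1e-6 while
all other fields must match exactly. Annotation INFO keys are
configurable via a YAML mapping (annotator dialects vary); the defaults
are the keys the packaged writers emit. Determinism: a single integer
seed drives one `numpy` generator; two runs of the same config are
byte-identical, and the config is echoed into the output headers and the
truth table.

## Problem sizes

The shared test cohort uses 600 small variants and 300 SVs; the
acceptance property suite runs the sharing brute-force at 10,000 random
carrier sets over 13 subjects and planted-truth recovery at 5,000
records per track; the acceptance script simulates 2,000 + 1,000
records. These sizes keep the whole suite in seconds while leaving every
cascade stage populated by hundreds of records.

## Known limitations

* The published tables are internally inconsistent in places (IRLS
  coding occurrences 26 vs a printed 27; conflicting group attribution
  between the SV summary and the SV table's column header; pedigree
  member totals). The fixtures preserve the printed cells, the fixture
  README documents each conflict, and the affected quantities are not
  asserted.
* Absolute discovery counts (e.g. 7,836,438 SNPs) are not recomputable
  without the undeposited cohort; the published stage counts are
  consumed as report inputs only.
* Upstream steps — alignment, calling, VQSR, score computation (CADD,
  the four predictors, RegulomeDB, AnnotSV, duphold) — are out of scope;
  all scores arrive as input annotations.
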