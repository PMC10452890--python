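#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes a pedigree (3 HRLS / 4 IRLS / 6 LRLS sequenced members), annotated
small-variant and SV VCFs, and the planted truth table under
results/cohort/.
"""

from pathlib import Path

from riskcluster.simulate import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"

if __name__ == "__main__":
    config = SimulationConfig(seed=1, n_small_variants=2000, n_svs=1000)
    cohort = simulate_cohort(config, OUT)
    print(f"cohort of {len(cohort.subject_order)} sequenced subjects "
          f"({ {g: len(m) for g, m in cohort.groups.items()} })")
    print(f"{len(cohort.small_records)} small variants -> {cohort.small_vcf}")
    print(f"{len(cohort.sv_records)} SVs -> {cohort.sv_vcf}")
    print(f"truth table -> {cohort.truth_path}")
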