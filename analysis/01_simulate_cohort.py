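"""Simulate a study-scale breeding cohort and summarise it.

Builds a colony at the scale of the real one — one carrier founder dam,
seven wild-type boars, eleven founder litters, then carrier daughters
recruited until ~100 affected males exist — and writes the genotype,
pedigree and phenotype artifacts plus the survival/genotype tallies.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

from pathlib import Path

import pandas as pd

from cldla import genoio
from cldla.simcohort import (SimConfig, cohort_summary, inject_missingness,
                             make_marker_map, simulate_haplotypes,
                             simulate_pedigree, simulate_phenotype)

OUT = Path("results/cohort")
OUT.mkdir(parents=True, exist_ok=True)

config = SimConfig(seed=20_15, n_chromosomes=2, markers_per_chromosome=1200,
                   chromosome_length_bp=60_000_000, n_litters=11,
                   n_cases_target=98, max_generations=6,
                   missing_rate=0.01, genotype_error_rate=0.001)

ped = simulate_pedigree(config)
markers = make_marker_map(config)
panel = simulate_haplotypes(ped, markers, config)
phen = simulate_phenotype(ped, panel, config)
g = inject_missingness(panel, config)

genoio.write_plink(g, ped, OUT / "cohort.ped", OUT / "cohort.map")
genoio.write_vcf_phased(panel, OUT / "cohort.true.vcf")
genoio.write_pedigree(ped, OUT / "cohort.pedigree.tsv")
genoio.write_phenotypes(phen, OUT / "cohort.phen.tsv")

summary = cohort_summary(ped, phen)
rows = []
for cls, count in summary.genotype_counts.items():
    rows.append({"table": "genotype", "class": cls, "count": count})
labels = ["died <1 week", "died <1 month", "1-5 months", ">5 months"]
for lab, count, pct in zip(labels, summary.survival_counts,
                           summary.survival_percentages()):
    rows.append({"table": "survival", "class": lab, "count": count,
                 "pct": pct})
pd.DataFrame(rows).to_csv(OUT / "cohort_summary.tsv", sep="\t", index=False)

print(f"cohort: {len(ped)} individuals, {len(phen)} phenotyped cases, "
      f"{markers.n_markers} markers")
print(f"genotype classes (offspring): {summary.genotype_counts}")
print("survival tallies:", dict(zip(labels, summary.survival_counts)),
      "->", summary.survival_percentages(), "%")
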