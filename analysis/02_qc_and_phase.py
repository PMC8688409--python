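"""Quality-control and trio-phase the simulated cohort.

Reads the PLINK files written by 01_simulate_cohort.py, applies the
marker and individual filters with the protocol's strict boundaries,
phases the survivors against the pedigree, and reports the QC tallies
plus the phasing accuracy against the simulator's truth panel.

Run after 01:  python analysis/02_qc_and_phase.py
"""

import json
from pathlib import Path

import numpy as np

from cldla import genoio
from cldla.pedigree import UNKNOWN
from cldla.qcphase import filter_individuals, filter_markers, trio_phase

OUT = Path("results/cohort")

g, markers, _ = genoio.read_plink(OUT / "cohort.ped", OUT / "cohort.map")
ped = genoio.read_pedigree(OUT / "cohort.pedigree.tsv")
truth, _ = genoio.read_vcf_phased(OUT / "cohort.true.vcf")

g, markers, mreport = filter_markers(g, markers)
g, ireport = filter_individuals(g)
print(f"QC: removed {mreport.removed_unknown_position} unknown-position, "
      f"{mreport.removed_maf} low-MAF, {mreport.removed_call_rate} low-call-rate "
      f"markers; {mreport.n_markers_out} markers and "
      f"{ireport.n_individuals_out} individuals remain")

panel = trio_phase(g, ped, seed=20_15)
genoio.write_vcf_phased(panel, OUT / "cohort.phased.vcf")

# phasing accuracy vs truth at surviving heterozygous sites of non-founders
truth_ids = {ind: k for k, ind in enumerate(truth.ids)}
marker_pos = {m: k for k, m in enumerate(truth.markers.ids)}
cols = np.array([marker_pos[m] for m in panel.markers.ids])
correct = total = 0
non_founders = set(ped.table.loc[ped.table["sire"] != UNKNOWN, "id"])
for i, ind in enumerate(panel.ids):
    if ind not in non_founders:
        continue
    t = truth_ids[ind]
    th = truth.haps[2 * t][cols]
    td = th + truth.haps[2 * t + 1][cols]
    het = td == 1
    correct += int((panel.haps[2 * i][het] == th[het]).sum())
    total += int(het.sum())
acc = correct / total
print(f"phasing: {total} heterozygous sites, {acc:.4f} phased correctly")

report = {**mreport.as_dict(), "individuals_removed": ireport.removed_individuals,
          "individuals_out": ireport.n_individuals_out,
          "het_sites": total, "phase_accuracy": acc,
          "mendel_conflicts_masked": panel.n_mendel_conflicts}
(OUT / "qc_phase_report.json").write_text(json.dumps(report, indent=2))
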