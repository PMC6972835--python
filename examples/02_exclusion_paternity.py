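"""Exclusion analysis of one clutch: paternal alleles, sibships, MP call.

Subtracts the mother's alleles from each sampled hatchling, partitions
the clutch into the minimum number of paternal sibships, and applies the
conservative multiple-paternity rule (3+ paternal alleles at 2+ loci).
"""

from clutchkin import simdata
from clutchkin.paternity import (
    call_multiple_paternity,
    min_father_partition,
    paternal_allele_sets,
)

study = simdata.sim_study(seed=1)
# pick a clutch with several true fathers
sc = max(study.sim_clutches, key=lambda s: s.true_father_count)
mother = study.mothers[sc.clutch.mother_id]

table = paternal_allele_sets(mother, list(sc.clutch.hatchlings))
assign = min_father_partition(table, method="exact")
mp = call_multiple_paternity(table)

print(f"mother {mother.individual_id}, clutch {sc.clutch.order}, "
      f"n = {sc.clutch.n} sampled hatchlings")
print(f"true father count: {sc.true_father_count}")
print(f"inferred minimum father count: {assign.father_count} "
      f"(pigeonhole lower bound {assign.lower_bound})")
print(f"multiple paternity: {mp.is_mp}, supported by {list(mp.supporting_loci)}")
print("siring proportions:", [round(f, 2) for f in assign.proportions])
# The inferred count is the fewest diploid fathers that can explain the
# paternal alleles; proportions are sibship sizes over the sample size.
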