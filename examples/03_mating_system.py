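"""Sperm storage vs. remating: compare a female's consecutive clutches.

A male is planted to enter the second clutch at 60% (a remating event).
The example reconstructs fathers in both clutches, computes the Sørensen
similarity QS of the father sets, and tests each disappearance/appearance
with p_f = (1 - f)^n.
"""

from clutchkin.matingsys import classify_transitions, sorensen_qs
from clutchkin.paternity import (
    match_fathers,
    min_father_partition,
    paternal_allele_sets,
)
from clutchkin.simdata import MatingPlan, gen_allele_freqs, sim_adults, sim_clutches

freqs = gen_allele_freqs(7, (14, 25), 1.0, seed=12)
(mother,), males = sim_adults(freqs, 1, 3, seed=3)
m = [g.individual_id for g in males]
plan = MatingPlan(
    mother.individual_id,
    tuple(m),
    (
        {m[0]: 0.5, m[1]: 0.5, m[2]: 0.0},   # first clutch: two mates
        {m[0]: 0.2, m[1]: 0.2, m[2]: 0.6},   # second: a new male at 60%
    ),
)
clutches = sim_clutches(plan, mother, {g.individual_id: g for g in males},
                        clutch_sizes=[100, 100], sample_n=20, seed=3)

assigns = [
    min_father_partition(paternal_allele_sets(mother, list(sc.clutch.hatchlings)))
    for sc in clutches
]
match = match_fathers(*assigns)
qs = sorensen_qs(match.a_count, match.b_count, match.shared)
print(f"clutch 1: {match.a_count} fathers, clutch 2: {match.b_count}, "
      f"shared: {match.shared}, QS = {qs:.0f}%")
for rec in classify_transitions(*assigns, alpha=0.05):
    if rec.p_f is None:
        print(f"  {rec.father}: {rec.classification}")
    else:
        print(f"  {rec.father}: {rec.status}, f = {rec.f:.2f}, "
              f"p_f = {rec.p_f:.2g} -> {rec.classification}")
# p_f below 0.05 means chance sampling from well-mixed stored sperm cannot
# explain the father's appearance/disappearance: evidence of remating.
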