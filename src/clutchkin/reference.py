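"""Worked-example inputs: one season of a southwest-Florida loggerhead
nesting assemblage (16 renesting females, 36 sampled clutches, 634
beach-wide nests).

These printed per-clutch father counts and season parameters serve as the
package's running example for the breeding-sex-ratio and extrapolation
computations; they are inputs, not outputs, of the analysis.
"""

from __future__ import annotations

#: minimum father count per clutch, by female id: (primary, secondary[, tertiary])
CLUTCH_FATHER_COUNTS: dict[str, tuple[int, ...]] = {
    "SSA714": (1, 1, 1),
    "LLZ512": (1, 1),
    "LLZ588": (3, 2),
    "LLZ526": (1, 1, 1),
    "LLZ650": (1, 1, 1),
    "LLZ506": (1, 1),
    "LLZ670": (1, 1),
    "LLZ678": (1, 1),
    "LLZ692": (1, 1),
    "LLZ912": (1, 1),
    "LLZ918": (1, 1),
    "LLZ591": (5, 5),
    "LLZ930": (1, 1, 1),
    "LLZ948": (3, 2),
    "LLZ963": (2, 2),
    "LLZ640": (1, 1),
}

#: father counts of each female's primary clutch
FIRST_CLUTCH_FATHER_COUNTS: dict[str, int] = {
    female: counts[0] for female, counts in CLUTCH_FATHER_COUNTS.items()
}

#: per-clutch father counts flattened over all 36 clutches
ALL_CLUTCH_FATHER_COUNTS: list[int] = [
    c for counts in CLUTCH_FATHER_COUNTS.values() for c in counts
]

#: loggerhead nests laid beach-wide in the example season
TOTAL_NESTS = 634

#: regional clutch frequency (nests per female per season), low/high bounds
CLUTCH_FREQUENCY_RANGE = (3.9, 5.4)

#: all-clutch breeding sex ratio reported for the example season (input for
#: the extrapolation example; see the methods note on its accounting)
BSR_ALL_CLUTCHES = 1.46

#: female LLZ963's father sets: {N, O} in her first clutch, {O, P} in her
#: second -> A = 2, B = 2, C = 1 shared
LLZ963_CLUTCH_PAIR = {"A": 2, "B": 2, "C": 1}
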