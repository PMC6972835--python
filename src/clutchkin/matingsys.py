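"""Mating-system inference from per-clutch paternity assignments.

Sequential clutches of one female are compared through the Sørensen
similarity of their father sets, ``QS = 2C / (A + B) x 100%``.  A father
seen in one clutch but absent from the other is assessed with the
chance-nonappearance probability ``p_f = (1 - f)^n`` — the probability
that a male siring fraction ``f`` of the sperm pool leaves no offspring in
a sample of ``n`` hatchlings.  ``p_f`` below the significance level means
the disappearance (or appearance) is unlikely under well-mixed stored
sperm, i.e. consistent with sperm depletion having been ruled out and a
mating between nesting events (remating) instead.

The assemblage-level breeding sex ratio (BSR, males per female actually
contributing gametes) and its extrapolation from a beach-wide nest count
complete the population summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .paternity import FatherAssignment, MatchResult, match_fathers

__all__ = [
    "sorensen_qs",
    "prob_nonappearance",
    "TransitionRecord",
    "classify_transitions",
    "detection_power",
    "count_distinct_fathers",
    "breeding_sex_ratio",
    "breeding_sex_ratio_from_counts",
    "multiple_paternity_rate",
    "extrapolate_population",
    "compare_bsr_fisher",
]

CHANCE_OR_DEPLETION = "chance or sperm depletion"
UNLIKELY_BY_CHANCE = "unlikely due to chance"
RETAINED = "retained"


def sorensen_qs(a: int, b: int, c: int) -> float:
    """Sørensen similarity of two clutches' father sets, as a percentage.

    ``a`` and ``b`` are the father counts of the two clutches and ``c`` the
    number of fathers shared between them.
    """
    if a < 1 or b < 1:
        raise ValueError("each clutch must have at least one father")
    if c < 0 or c > min(a, b):
        raise ValueError(f"shared fathers ({c}) cannot exceed min(A, B)")
    return 2.0 * c / (a + b) * 100.0


def prob_nonappearance(f: float, n: int) -> float:
    """Probability a father siring fraction ``f`` is absent from ``n`` samples.

    ``p_f = (1 - f)^n`` under independent sampling of hatchlings from a
    well-mixed sperm store.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("siring fraction must be in [0, 1]")
    if n < 1:
        raise ValueError("sample size must be at least 1")
    return (1.0 - f) ** n


@dataclass(frozen=True)
class TransitionRecord:
    """One father's fate between two consecutive clutches."""

    father: str  # label like "A.1" (clutch.group) or matched pair label
    status: str  # "retained" | "disappeared" | "appeared"
    f: float | None
    n: int | None
    p_f: float | None
    f_mode: str | None
    classification: str


def classify_transitions(
    assign1: FatherAssignment,
    assign2: FatherAssignment,
    alpha: float = 0.05,
    f_mode: str = "first-clutch",
    match: MatchResult | None = None,
) -> list[TransitionRecord]:
    """Classify each father's between-clutch fate as chance or remating.

    Fathers are matched across the two clutches by reconstructed genotype.
    A father absent from clutch 2 is tested with ``p_f = (1 - f)^n2`` where
    ``f`` is his siring fraction estimated per ``f_mode``: from the first
    clutch alone (well-mixed stored sperm) or from both clutches combined.
    A father newly appearing in clutch 2 is tested symmetrically with the
    combined-estimate ``f`` against the clutch-1 sample size.  ``p_f``
    below ``alpha`` marks the transition as unlikely under chance sampling
    from stored sperm (consistent with remating); otherwise chance or
    sperm depletion cannot be excluded.
    """
    if f_mode not in ("first-clutch", "combined"):
        raise ValueError(f"unknown f_mode {f_mode!r}")
    n1, n2 = assign1.n, assign2.n
    if n1 == 0 or n2 == 0:
        raise ValueError("both clutches need at least one sampled hatchling")
    if match is None:
        match = match_fathers(assign1, assign2)
    matched_a = {i: j for i, j in match.pairs}
    matched_b = {j: i for i, j in match.pairs}
    records = []
    for i in range(assign1.father_count):
        size1 = len(assign1.groups[i])
        if i in matched_a:
            records.append(
                TransitionRecord(
                    father=f"c1.{i + 1}", status=RETAINED, f=None, n=None,
                    p_f=None, f_mode=None, classification=RETAINED,
                )
            )
            continue
        if f_mode == "first-clutch":
            f = size1 / n1
        else:
            f = size1 / (n1 + n2)  # absent from clutch 2: no extra offspring
        p = prob_nonappearance(f, n2)
        records.append(
            TransitionRecord(
                father=f"c1.{i + 1}",
                status="disappeared",
                f=f,
                n=n2,
                p_f=p,
                f_mode=f_mode,
                classification=UNLIKELY_BY_CHANCE if p < alpha else CHANCE_OR_DEPLETION,
            )
        )
    for j in range(assign2.father_count):
        if j in matched_b:
            continue
        size2 = len(assign2.groups[j])
        # a new father's sperm-pool share is best estimated from all
        # offspring observed; his absence is tested against clutch 1
        f = size2 / (n1 + n2)
        p = prob_nonappearance(f, n1)
        records.append(
            TransitionRecord(
                father=f"c2.{j + 1}",
                status="appeared",
                f=f,
                n=n1,
                p_f=p,
                f_mode="combined",
                classification=UNLIKELY_BY_CHANCE if p < alpha else CHANCE_OR_DEPLETION,
            )
        )
    return records


def detection_power(
    proportions: Sequence[float],
    n: int,
    mode: str = "analytic",
    reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Probability that a sample of ``n`` hatchlings reveals multiple sires.

    With sires at fractions ``f_1..f_k``, a sample misses multiple
    paternity exactly when all ``n`` hatchlings share one father, so the
    analytic power is ``1 - sum_i f_i^n``.  ``mode='simulation'`` estimates
    the same probability by seeded multinomial sampling.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    if n < 1:
        raise ValueError("sample size must be at least 1")
    if len(p) == 1:
        return 0.0  # a single sire can never show multiple paternity
    if mode == "analytic":
        return float(1.0 - np.sum(p**n))
    if mode == "simulation":
        rng = np.random.default_rng(seed)
        draws = rng.multinomial(n, p, size=reps)
        return float(np.mean((draws > 0).sum(axis=1) >= 2))
    raise ValueError(f"unknown mode {mode!r}")


def count_distinct_fathers(
    assignments: Sequence[FatherAssignment], max_mismatch_loci: int = 0
) -> int:
    """Distinct fathers across assignments after genotype matching.

    Builds a roster of reconstructed father genotypes; each assignment's
    fathers are matched one-to-one against the roster (so two sibships of
    the same clutch can never merge), compatible matches are merged, and
    unmatched fathers are appended as new males.
    """
    roster: list[dict[str, frozenset]] = []
    for assign in assignments:
        loci = sorted({l for g in assign.father_genotypes for l in g} | {
            l for r in roster for l in r
        })
        cand = []
        for i, ga in enumerate(assign.father_genotypes):
            for j, gr in enumerate(roster):
                mm = sum(
                    1
                    for l in loci
                    if len(ga.get(l, frozenset()) | gr.get(l, frozenset())) > 2
                )
                if mm <= max_mismatch_loci:
                    cand.append((mm, i, j))
        cand.sort()
        used_i: set[int] = set()
        used_j: set[int] = set()
        for mm, i, j in cand:
            if i in used_i or j in used_j:
                continue
            used_i.add(i)
            used_j.add(j)
            merged = dict(roster[j])
            for l, s in assign.father_genotypes[i].items():
                merged[l] = merged.get(l, frozenset()) | s
            roster[j] = merged
        for i, ga in enumerate(assign.father_genotypes):
            if i not in used_i:
                roster.append(dict(ga))
    return len(roster)


def breeding_sex_ratio(
    per_female: Mapping[str, Sequence[FatherAssignment]],
    scope: str = "all-clutches",
    max_mismatch_loci: int = 0,
) -> float:
    """Breeding sex ratio: contributing males per nesting female.

    Within each female, fathers are matched across her clutches so a male
    using stored sperm counts once; reconstructed males are then matched
    across females so a male mating with several females also counts once.
    ``scope='first-clutch-only'`` restricts to each female's primary
    clutch.
    """
    if scope not in ("all-clutches", "first-clutch-only"):
        raise ValueError(f"unknown scope {scope!r}")
    if not per_female:
        raise ValueError("at least one female is required")
    pooled: list[FatherAssignment] = []
    for female in sorted(per_female):
        assigns = sorted(
            per_female[female], key=lambda a: (a.clutch_order or 0)
        )
        if scope == "first-clutch-only":
            assigns = assigns[:1]
        pooled.extend(assigns)
    total_fathers = count_distinct_fathers(pooled, max_mismatch_loci)
    return total_fathers / len(per_female)


def breeding_sex_ratio_from_counts(father_counts: Iterable[int]) -> float:
    """BSR from already-tallied distinct-father counts, one per female."""
    counts = list(father_counts)
    if not counts:
        raise ValueError("at least one female is required")
    if any(c < 0 for c in counts):
        raise ValueError("father counts must be non-negative")
    return sum(counts) / len(counts)


def multiple_paternity_rate(father_counts_per_clutch: Iterable[int]) -> float:
    """Fraction of clutches sired by two or more males."""
    counts = list(father_counts_per_clutch)
    if not counts:
        raise ValueError("at least one clutch is required")
    return sum(1 for c in counts if c >= 2) / len(counts)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def extrapolate_population(
    total_nests: int,
    clutch_freq_low: float,
    clutch_freq_high: float,
    bsr: float,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Extrapolate female and male counts from a beach-wide nest total.

    Females = nests / clutch frequency (the higher frequency gives the
    lower female bound); males = females x BSR.  Both are rounded to the
    nearest integer.  Returns ``((females_low, females_high),
    (males_low, males_high))``.
    """
    if total_nests <= 0 or clutch_freq_low <= 0 or clutch_freq_high <= 0 or bsr <= 0:
        raise ValueError("all inputs must be positive")
    if clutch_freq_low > clutch_freq_high:
        raise ValueError("clutch frequency bounds are inverted")
    females_low = _round_half_up(total_nests / clutch_freq_high)
    females_high = _round_half_up(total_nests / clutch_freq_low)
    males_low = _round_half_up(females_low * bsr)
    males_high = _round_half_up(females_high * bsr)
    return (females_low, females_high), (males_low, males_high)


def compare_bsr_fisher(
    fathers_a: int, females_a: int, fathers_b: int, females_b: int
) -> float:
    """Fisher's exact comparison of two breeding-sex-ratio estimates.

    The 2x2 table pairs each estimate's inferred father count with its
    female count; returns the two-sided p-value.
    """
    table = [[fathers_a, females_a], [fathers_b, females_b]]
    return float(stats.fisher_exact(table)[1])
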