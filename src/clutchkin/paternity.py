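"""Exclusion-based paternity analysis of mother-hatchling genotype data.

Given the known maternal genotype, each hatchling's paternal allele at a
locus is recovered by subtraction: if exactly one of the hatchling's
alleles can have come from the mother, the other is paternal (certain); if
both could be maternal, either could be paternal (ambiguous candidate
set); if neither matches the mother, the locus is flagged as a mismatch.

Hatchlings of one clutch are then partitioned into paternal sibships: the
fewest groups such that within each group the (resolved) paternal alleles
at every locus fit one diploid father, i.e. at most two distinct alleles
per locus.  Ambiguous candidates are resolved *during* the partition
search (the search branches over both options), not greedily beforehand.
The exact method is a branch-and-bound over group assignments; a greedy
first-fit is available for comparison and as the search's upper bound.

Multiple paternity is called by the conservative rule used for
microsatellite clutch data: at least three paternal alleles at two or more
loci, with a single offending locus attributed to mutation instead.
Reconstructed fathers can be compared across clutches and across females
to identify shared males.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .genotype_io import MISSING, Genotype

__all__ = [
    "PaternalAlleleTable",
    "FatherAssignment",
    "MPCall",
    "MatchResult",
    "paternal_allele_sets",
    "pigeonhole_lower_bound",
    "min_father_partition",
    "call_multiple_paternity",
    "match_fathers",
]

#: mismatch loci beyond which a hatchling is considered not this mother's
FOREIGN_MISMATCH_THRESHOLD = 2


@dataclass(frozen=True)
class PaternalAlleleTable:
    """Candidate paternal alleles per hatchling per locus for one clutch.

    ``candidates[hid][locus]`` is a frozenset of 1 (certain) or 2
    (ambiguous) alleles, or ``None`` when the locus is uninformative for
    that hatchling (missing call or maternal-incompatibility mismatch).
    Mismatch loci are carried explicitly in ``mismatches``; hatchlings with
    more than :data:`FOREIGN_MISMATCH_THRESHOLD` mismatch loci are excluded
    from ``hatchling_ids`` and listed in ``foreign``.
    """

    mother_id: str
    loci: tuple[str, ...]
    hatchling_ids: tuple[str, ...]
    candidates: Mapping[str, Mapping[str, frozenset | None]]
    mismatches: Mapping[str, tuple[str, ...]]
    foreign: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return len(self.hatchling_ids)

    def certain_alleles(self, locus: str, exclude_locus: str | None = None) -> set[int]:
        """Distinct certain (unambiguous) paternal alleles at a locus."""
        if locus == exclude_locus:
            return set()
        out = set()
        for hid in self.hatchling_ids:
            s = self.candidates[hid].get(locus)
            if s is not None and len(s) == 1:
                out.update(s)
        return out


def paternal_allele_sets(mother: Genotype, hatchlings: Sequence[Genotype]) -> PaternalAlleleTable:
    """Subtract the maternal contribution from each hatchling genotype.

    A hatchling allele is a paternal candidate when its partner allele is
    found in the mother.  Hatchlings incompatible with the mother at more
    than two loci are reported as candidate foreign hatchlings and excluded
    with a warning.
    """
    loci = tuple(mother.loci)
    candidates: dict[str, dict[str, frozenset | None]] = {}
    mismatches: dict[str, tuple[str, ...]] = {}
    foreign = []
    included = []
    for h in hatchlings:
        cand: dict[str, frozenset | None] = {}
        mm = []
        for locus in loci:
            ma, mb = mother.alleles(locus)
            ha, hb = h.calls.get(locus, (MISSING, MISSING))
            if ma == MISSING and mb == MISSING:
                cand[locus] = None  # mother uninformative here
                continue
            mom = {a for a in (ma, mb) if a != MISSING}
            if ha == MISSING and hb == MISSING:
                cand[locus] = None
                continue
            if ha == MISSING or hb == MISSING:
                x = hb if ha == MISSING else ha
                # the missing call could be the maternal allele; the observed
                # one is certainly paternal only if the mother lacks it
                cand[locus] = frozenset({x}) if x not in mom else None
                continue
            c = set()
            if hb in mom:
                c.add(ha)
            if ha in mom:
                c.add(hb)
            if not c:
                mm.append(locus)
                cand[locus] = None
            else:
                cand[locus] = frozenset(c)
        if len(mm) > FOREIGN_MISMATCH_THRESHOLD:
            warnings.warn(
                f"hatchling {h.individual_id} mismatches mother {mother.individual_id} "
                f"at {len(mm)} loci; excluded as candidate foreign hatchling"
            )
            foreign.append(h.individual_id)
            continue
        included.append(h.individual_id)
        candidates[h.individual_id] = cand
        mismatches[h.individual_id] = tuple(mm)
    return PaternalAlleleTable(
        mother_id=mother.individual_id,
        loci=loci,
        hatchling_ids=tuple(included),
        candidates=candidates,
        mismatches=mismatches,
        foreign=tuple(foreign),
    )


@dataclass(frozen=True)
class MPCall:
    """Multiple-paternity call with the loci supporting it."""

    is_mp: bool
    supporting_loci: tuple[str, ...]
    note: str = ""


def call_multiple_paternity(table: PaternalAlleleTable) -> MPCall:
    """Conservative multiple-paternity rule.

    MP is called when at least two loci each carry three or more distinct
    certain paternal alleles.  A single such locus is attributed to
    mutation and MP is not called.
    """
    hot = tuple(
        locus for locus in table.loci if len(table.certain_alleles(locus)) >= 3
    )
    if len(hot) >= 2:
        return MPCall(True, hot)
    if len(hot) == 1:
        return MPCall(
            False, hot, note=f"3+ paternal alleles at {hot[0]} only; attributed to mutation"
        )
    return MPCall(False, ())


def pigeonhole_lower_bound(table: PaternalAlleleTable, exclude_locus: str | None = None) -> int:
    """Lower bound on father count: ceil(certain alleles / 2), max over loci."""
    if table.n == 0:
        return 0
    lb = 1
    for locus in table.loci:
        k = len(table.certain_alleles(locus, exclude_locus))
        lb = max(lb, math.ceil(k / 2))
    return lb


def _locus_feasible(sets: list[frozenset]) -> bool:
    """Can one diploid father explain these per-hatchling candidate sets?

    True iff some allele pair {x, y} (x may equal y) intersects every set.
    """
    if not sets:
        return True
    distinct = set().union(*sets)
    if len(distinct) <= 2:
        return True
    forced = set()
    for s in sets:
        if len(s) == 1:
            forced.update(s)
    if len(forced) > 2:
        return False
    if len(forced) == 2:
        return all(s & forced for s in sets)
    pool = sorted(distinct)
    for x, y in combinations(pool, 2):
        pair = {x, y}
        if forced <= pair and all(s & pair for s in sets):
            return True
    return False


def _group_feasible(
    members: list[str],
    candidate: str,
    table: PaternalAlleleTable,
    exclude_locus: str | None,
) -> bool:
    for locus in table.loci:
        if locus == exclude_locus:
            continue
        sets = []
        for hid in members:
            s = table.candidates[hid].get(locus)
            if s is not None:
                sets.append(s)
        s = table.candidates[candidate].get(locus)
        if s is not None:
            sets.append(s)
        if not _locus_feasible(sets):
            return False
    return True


def _greedy_partition(
    table: PaternalAlleleTable, order: Sequence[str], exclude_locus: str | None = None
) -> list[list[str]]:
    groups: list[list[str]] = []
    for hid in order:
        placed = False
        for g in groups:
            if _group_feasible(g, hid, table, exclude_locus):
                g.append(hid)
                placed = True
                break
        if not placed:
            groups.append([hid])
    return groups


def _update_pairs(pairs: frozenset, cand: frozenset | None) -> frozenset | None:
    """Fold one hatchling's candidate set into a group-locus pair state.

    ``pairs`` is the set of allele pairs (frozensets of size <= 2) that
    cover every candidate set seen so far at this locus; folding in a new
    set keeps pairs that intersect it and extends under-full pairs with
    its alleles.  Returns None when no diploid father remains possible.
    """
    if cand is None:
        return pairs
    out = set()
    for p in pairs:
        if p & cand:
            out.add(p)
        elif len(p) < 2:
            for y in cand:
                out.add(p | {y})
    return frozenset(out) if out else None


_EMPTY_PAIR_STATE = frozenset({frozenset()})


def _exact_partition(
    table: PaternalAlleleTable,
    exclude_locus: str | None = None,
    max_nodes: int = 500_000,
) -> list[list[str]]:
    """Minimum partition by iterative deepening from the pigeonhole bound.

    For k = lower bound, lower bound + 1, ... a depth-first search looks
    for the first partition into at most k sibships, assigning hatchlings
    in sorted-id order (so the result is independent of input order and
    deterministic).  Per group and locus the search keeps the set of
    still-viable paternal allele pairs, updated incrementally, so
    feasibility checks are O(pairs x alleles).  A node cap bounds
    pathological weakly-constrained instances; hitting it advances k, so
    the result is then an upper bound on the true minimum (and still
    deterministic).
    """
    order = sorted(table.hatchling_ids)
    if not order:
        return []
    loci = [l for l in table.loci if l != exclude_locus]
    cands = {
        hid: [table.candidates[hid].get(l) for l in loci] for hid in order
    }
    n_loci = len(loci)
    lb = pigeonhole_lower_bound(table, exclude_locus)

    def try_k(k: int) -> list[list[str]] | None:
        groups: list[list[str]] = []
        states: list[list[frozenset]] = []  # per group, per locus pair state
        nodes = 0

        def dfs(i: int) -> bool:
            nonlocal nodes
            if nodes >= max_nodes:
                return False
            nodes += 1
            if i == len(order):
                return True
            hid = order[i]
            cand = cands[hid]
            for gi in range(len(groups)):
                new_state = []
                ok = True
                for li in range(n_loci):
                    upd = _update_pairs(states[gi][li], cand[li])
                    if upd is None:
                        ok = False
                        break
                    new_state.append(upd)
                if not ok:
                    continue
                old_state = states[gi]
                states[gi] = new_state
                groups[gi].append(hid)
                if dfs(i + 1):
                    return True
                groups[gi].pop()
                states[gi] = old_state
            if len(groups) < k:
                state = []
                for li in range(n_loci):
                    upd = _update_pairs(_EMPTY_PAIR_STATE, cand[li])
                    if upd is None:
                        return False  # a lone hatchling is always feasible
                    state.append(upd)
                groups.append([hid])
                states.append(state)
                if dfs(i + 1):
                    return True
                groups.pop()
                states.pop()
            return False

        if dfs(0):
            return [list(g) for g in groups]
        return None

    for k in range(lb, len(order) + 1):
        res = try_k(k)
        if res is not None:
            return res
    return [[hid] for hid in order]  # unreachable: singletons always feasible


def _attributed_genotype(
    members: Sequence[str], table: PaternalAlleleTable, exclude_locus: str | None
) -> dict[str, frozenset]:
    """Alleles attributable to the group's father with certainty.

    Per locus, the intersection of all minimal covering allele pairs: an
    allele is attributed only if every feasible resolution of the
    ambiguities gives it to this father.
    """
    geno: dict[str, frozenset] = {}
    for locus in table.loci:
        if locus == exclude_locus:
            geno[locus] = frozenset()
            continue
        sets = [
            table.candidates[hid][locus]
            for hid in members
            if table.candidates[hid].get(locus) is not None
        ]
        if not sets:
            geno[locus] = frozenset()
            continue
        distinct = sorted(set().union(*sets))
        covers = []
        for size in (1, 2):
            for combo in combinations(distinct, size):
                pair = set(combo)
                if all(s & pair for s in sets):
                    covers.append(pair)
        if not covers:
            geno[locus] = frozenset()  # infeasible locus (shouldn't happen)
            continue
        # an allele is certain if it appears in every covering pair, plus
        # every certain (singleton) candidate is attributed outright
        certain = set.intersection(*covers) if covers else set()
        for s in sets:
            if len(s) == 1:
                certain.update(s)
        geno[locus] = frozenset(certain)
    return geno


@dataclass(frozen=True)
class FatherAssignment:
    """Partition of a clutch's hatchlings into paternal sibships."""

    mother_id: str
    groups: tuple[tuple[str, ...], ...]
    father_genotypes: tuple[Mapping[str, frozenset], ...]
    proportions: tuple[float, ...]
    mp: MPCall
    method: str
    mutation_locus: str | None = None
    lower_bound: int = 1
    clutch_order: int | None = None

    @property
    def father_count(self) -> int:
        return len(self.groups)

    @property
    def n(self) -> int:
        return sum(len(g) for g in self.groups)


def min_father_partition(
    table: PaternalAlleleTable,
    method: str = "exact",
    max_mutation_loci: int = 1,
    max_nodes: int = 500_000,
) -> FatherAssignment:
    """Minimum number of fathers consistent with the paternal allele table.

    ``method='exact'`` runs a branch-and-bound over sibship assignments;
    ``method='greedy'`` first-fits each hatchling into the first compatible
    group.  With ``max_mutation_loci=1`` (the conservative default) the
    partition may additionally designate a single locus as carrying a
    mutation and ignore it, when doing so strictly lowers the father
    count — mirroring the rule that three paternal alleles at one locus
    only are attributed to mutation.
    """
    if method not in ("exact", "greedy"):
        raise ValueError(f"unknown method {method!r}")

    def solve(exclude: str | None) -> list[list[str]]:
        if method == "exact":
            return _exact_partition(table, exclude, max_nodes)
        return _greedy_partition(table, list(table.hatchling_ids), exclude)

    groups = solve(None)
    mutation_locus = None
    if max_mutation_loci >= 1 and len(groups) > 1:
        for locus in table.loci:
            alt = solve(locus)
            if len(alt) < len(groups):
                groups, mutation_locus = alt, locus
    n = sum(len(g) for g in groups)
    groups_t = tuple(tuple(g) for g in groups)
    genos = tuple(
        _attributed_genotype(g, table, mutation_locus) for g in groups_t
    )
    props = tuple(len(g) / n for g in groups_t) if n else ()
    return FatherAssignment(
        mother_id=table.mother_id,
        groups=groups_t,
        father_genotypes=genos,
        proportions=props,
        mp=call_multiple_paternity(table),
        method=method,
        mutation_locus=mutation_locus,
        lower_bound=pigeonhole_lower_bound(table, mutation_locus),
    )


@dataclass(frozen=True)
class MatchResult:
    """Shared reconstructed fathers between two assignments (for QS)."""

    pairs: tuple[tuple[int, int], ...]  # (index in A, index in B)
    a_count: int
    b_count: int

    @property
    def shared(self) -> int:
        return len(self.pairs)


def _father_mismatch_loci(
    ga: Mapping[str, frozenset], gb: Mapping[str, frozenset], loci: Iterable[str]
) -> int:
    """Loci where the two attributed allele sets cannot be one genotype."""
    bad = 0
    for locus in loci:
        sa = ga.get(locus, frozenset())
        sb = gb.get(locus, frozenset())
        if len(sa | sb) > 2:
            bad += 1
    return bad


def match_fathers(
    assign_a: FatherAssignment,
    assign_b: FatherAssignment,
    max_mismatch_loci: int = 0,
) -> MatchResult:
    """Pair up reconstructed fathers whose genotypes are compatible.

    Two fathers match when their attributed allele sets are
    non-contradictory (jointly at most two alleles per locus) at all but at
    most ``max_mismatch_loci`` loci.  Matching is one-to-one, resolved
    greedily by fewest mismatching loci then index order, so the shared
    count never exceeds min(A, B).
    """
    loci = {l for g in assign_a.father_genotypes for l in g}
    loci |= {l for g in assign_b.father_genotypes for l in g}
    loci = sorted(loci)
    cand = []
    for i, ga in enumerate(assign_a.father_genotypes):
        for j, gb in enumerate(assign_b.father_genotypes):
            mm = _father_mismatch_loci(ga, gb, loci)
            if mm <= max_mismatch_loci:
                cand.append((mm, i, j))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for mm, i, j in cand:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    return MatchResult(
        pairs=tuple(sorted(pairs)),
        a_count=assign_a.father_count,
        b_count=assign_b.father_count,
    )
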