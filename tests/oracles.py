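"""Independent brute-force oracles used to validate closed forms.

Everything here is deliberately naive — full enumerations over genotype
space or partition space — and shares no code with the implementation it
checks.
"""

from __future__ import annotations

from itertools import combinations, product
from math import ceil


def _genotypes(alleles):
    return [(i, j) for idx, i in enumerate(alleles) for j in alleles[idx:]]


def _gprob(g, p):
    i, j = g
    return p[i] ** 2 if i == j else 2 * p[i] * p[j]


def pi_oracle(p: dict) -> float:
    """P(two random individuals share a genotype) by genotype enumeration."""
    alleles = sorted(p)
    return sum(_gprob(g, p) ** 2 for g in _genotypes(alleles))


def pe2_oracle(p: dict) -> float:
    """Second-parent exclusion by full mother/offspring/candidate enumeration."""
    alleles = sorted(p)
    genos = _genotypes(alleles)
    total = 0.0
    for gm in genos:
        pm = _gprob(gm, p)
        for mat in gm:  # maternal allele, each with prob 1/2
            for pat in alleles:
                off = tuple(sorted((mat, pat)))
                a, b = off
                cand = set()
                if b in gm:
                    cand.add(a)
                if a in gm:
                    cand.add(b)
                p_excl = sum(
                    _gprob(gc, p) for gc in genos if not (set(gc) & cand)
                )
                total += pm * 0.5 * p[pat] * p_excl
    return total


def pe3_oracle(p: dict) -> float:
    """Parent-pair exclusion: P(random pair cannot produce a random offspring)."""
    alleles = sorted(p)
    genos = _genotypes(alleles)
    total = 0.0
    for off in genos:
        po = _gprob(off, p)
        p_excl = 0.0
        for g1 in genos:
            for g2 in genos:
                can = any(
                    tuple(sorted((x, y))) == off for x in g1 for y in g2
                )
                if not can:
                    p_excl += _gprob(g1, p) * _gprob(g2, p)
        total += po * p_excl
    return total


def _set_partitions(items):
    """All set partitions (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def _group_ok_bruteforce(members, candidates, loci) -> bool:
    """Can one diploid father sire these hatchlings?  Brute force over all
    resolutions of the ambiguous candidate sets."""
    for locus in loci:
        sets = [
            sorted(candidates[hid][locus])
            for hid in members
            if candidates[hid].get(locus) is not None
        ]
        if not sets:
            continue
        if not any(
            len(set(choice)) <= 2 for choice in product(*sets)
        ):
            return False
    return True


def min_fathers_oracle(hatchling_ids, candidates, loci) -> int:
    """Exhaustive minimum-sibship count over all set partitions.

    ``candidates[hid][locus]`` follows the implementation's convention
    (frozenset of 1-2 paternal candidate alleles, or None).  Group
    feasibility is memoised on the member subset.
    """
    ids = sorted(hatchling_ids)
    if not ids:
        return 0
    cache: dict[frozenset, bool] = {}

    def ok(members) -> bool:
        key = frozenset(members)
        if key not in cache:
            cache[key] = _group_ok_bruteforce(members, candidates, loci)
        return cache[key]

    best = len(ids)
    for part in _set_partitions(ids):
        if len(part) >= best:
            continue
        if all(ok(g) for g in part):
            best = len(part)
    return best


def pigeonhole_oracle(hatchling_ids, candidates, loci) -> int:
    """max over loci of ceil(distinct certain alleles / 2), floored at 1."""
    if not hatchling_ids:
        return 0
    lb = 1
    for locus in loci:
        certain = set()
        for hid in hatchling_ids:
            s = candidates[hid].get(locus)
            if s is not None and len(s) == 1:
                certain |= set(s)
        lb = max(lb, ceil(len(certain) / 2))
    return lb


def ellipsoid_area_numeric(a: float, b: float, c: float, n: int = 400) -> float:
    """Full ellipsoid surface area by numerical surface integration."""
    import numpy as np

    theta = (np.arange(n) + 0.5) * np.pi / n
    phi = (np.arange(2 * n) + 0.5) * np.pi / n
    t, f = np.meshgrid(theta, phi, indexing="ij")
    st, ct = np.sin(t), np.cos(t)
    sf, cf = np.sin(f), np.cos(f)
    # |r_theta x r_phi| for r = (a st cf, b st sf, c ct)
    ex = b * c * st**2 * cf
    ey = a * c * st**2 * sf
    ez = a * b * st * ct
    dA = np.sqrt(ex**2 + ey**2 + ez**2)
    return float(dA.sum() * (np.pi / n) * (np.pi / n))
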