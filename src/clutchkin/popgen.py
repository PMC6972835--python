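"""Locus-quality statistics for a microsatellite parentage panel.

Covers the standard marker diagnostics run before a parentage analysis:
observed/expected heterozygosity, a Monte-Carlo exact Hardy-Weinberg test,
the probability of identity (PI), single-parent and parent-pair exclusion
probabilities (PE2: one parent known; PE3: neither known), and a
duplicate-genotyping error rate.

The PI/PE closed forms are the classical allele-frequency polynomials.
They are not taken on faith: the test suite checks them against a
brute-force Mendelian enumeration of all trio genotype combinations.

Notation: ``a_k = sum_i p_i^k`` over the allele frequencies ``p_i`` of one
locus.

* ``PI_l   = 2 a_2^2 - a_4``
* ``PE2_l  = 1 - 2 a_2 + a_3 + 2 a_4 - 3 a_5 - 2 a_2^2 + 3 a_2 a_3``
* ``PE3_l  = 1 + 4 a_4 - 4 a_5 - 3 a_6 - 8 a_2^2 + 8 a_2 a_3 + 2 a_3^2``

Combined across loci: PI multiplies; PE combines as
``1 - prod_l (1 - PE_l)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, Genotype
from .simdata import PopulationFrequencies

__all__ = [
    "prob_identity",
    "prob_exclusion",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "hwe_exact_test",
    "genotyping_error_rate",
    "PopGenSummary",
    "summarize",
]


def _moments(p: Iterable[float], upto: int) -> list[float]:
    p = list(p)
    return [sum(v**k for v in p) for k in range(upto + 1)]


def prob_identity(freqs: PopulationFrequencies) -> tuple[dict[str, float], float]:
    """Probability two random individuals share a genotype, per locus and combined.

    ``PI_l = 2(sum p_i^2)^2 - sum p_i^4``; loci combine multiplicatively
    (independent loci).
    """
    per_locus = {}
    for locus in freqs.loci:
        a = _moments(freqs.freqs[locus].values(), 4)
        per_locus[locus] = 2.0 * a[2] ** 2 - a[4]
    combined = math.prod(per_locus.values())
    return per_locus, combined


def prob_exclusion(
    freqs: PopulationFrequencies, mode: str = "one-parent-known"
) -> tuple[dict[str, float], float]:
    """Probability a random non-parent is excluded, per locus and combined.

    ``mode='one-parent-known'`` (PE2) excludes a candidate second parent when
    the first parent's genotype is known; ``mode='no-parent-known'`` (PE3)
    excludes a candidate parent *pair* when neither parent is known.
    Combined across loci as ``1 - prod(1 - PE_l)``.
    """
    per_locus = {}
    for locus in freqs.loci:
        a = _moments(freqs.freqs[locus].values(), 6)
        if mode == "one-parent-known":
            pe = (
                1.0
                - 2.0 * a[2]
                + a[3]
                + 2.0 * a[4]
                - 3.0 * a[5]
                - 2.0 * a[2] ** 2
                + 3.0 * a[2] * a[3]
            )
        elif mode == "no-parent-known":
            pe = (
                1.0
                + 4.0 * a[4]
                - 4.0 * a[5]
                - 3.0 * a[6]
                - 8.0 * a[2] ** 2
                + 8.0 * a[2] * a[3]
                + 2.0 * a[3] ** 2
            )
        else:
            raise ValueError(
                f"unknown mode {mode!r}; use 'one-parent-known' or 'no-parent-known'"
            )
        per_locus[locus] = pe
    combined = 1.0 - math.prod(1.0 - pe for pe in per_locus.values())
    return per_locus, combined


def expected_heterozygosity(freqs: PopulationFrequencies) -> dict[str, float]:
    """Gene diversity ``He = 1 - sum p_i^2`` per locus."""
    return {
        locus: 1.0 - sum(v**2 for v in freqs.freqs[locus].values())
        for locus in freqs.loci
    }


def observed_heterozygosity(genotypes: Sequence[Genotype]) -> dict[str, float]:
    """Fraction of fully called individuals that are heterozygous, per locus."""
    out: dict[str, float] = {}
    if not genotypes:
        return out
    for locus in genotypes[0].loci:
        het = n = 0
        for g in genotypes:
            a, b = g.calls.get(locus, (MISSING, MISSING))
            if a == MISSING or b == MISSING:
                continue
            n += 1
            het += a != b
        out[locus] = het / n if n else math.nan
    return out


def _genotype_counts(genotypes: Sequence[Genotype], locus: str) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for g in genotypes:
        a, b = g.calls.get(locus, (MISSING, MISSING))
        if a == MISSING or b == MISSING:
            continue
        key = (a, b)
        counts[key] = counts.get(key, 0) + 1
    return counts


def _hwe_chi2(counts: Mapping[tuple[int, int], int]) -> float:
    """Chi-square distance of genotype counts from their HWE expectation."""
    n = sum(counts.values())
    allele_counts: dict[int, int] = {}
    for (a, b), c in counts.items():
        allele_counts[a] = allele_counts.get(a, 0) + c
        allele_counts[b] = allele_counts.get(b, 0) + c
    total = 2 * n
    p = {al: c / total for al, c in allele_counts.items()}
    alleles = sorted(p)
    stat = 0.0
    for i, ai in enumerate(alleles):
        for aj in alleles[i:]:
            exp = n * (p[ai] ** 2 if ai == aj else 2 * p[ai] * p[aj])
            obs = counts.get((ai, aj), 0)
            if exp > 0:
                stat += (obs - exp) ** 2 / exp
    return stat


def hwe_exact_test(
    counts: Mapping[tuple[int, int], int], reps: int = 10_000, seed: int = 0
) -> tuple[float, int]:
    """Monte-Carlo exact Hardy-Weinberg test for one locus.

    Permutes the observed alleles into random diploid pairings (which holds
    allele counts fixed, the exact-test null) and compares the chi-square
    distance from HWE proportions of each permuted table to the observed
    one.  Returns ``(p_value, reps)``.  Chosen over the asymptotic
    chi-square because microsatellite genotype tables are sparse.
    """
    counts = {tuple(sorted(k)): v for k, v in counts.items()}
    alleles_present = {a for pair in counts for a in pair}
    if len(alleles_present) < 2:
        raise ValueError("Hardy-Weinberg test needs at least 2 observed alleles")
    n = sum(counts.values())
    if n < 2:
        warnings.warn("too few genotypes for a meaningful Hardy-Weinberg test")
        return math.nan, 0
    observed = _hwe_chi2(counts)
    pool = np.array(
        [a for (x, y), c in counts.items() for a in (x, y) * c], dtype=np.int64
    )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        rng.shuffle(pool)
        perm: dict[tuple[int, int], int] = {}
        for i in range(0, len(pool), 2):
            key = (int(pool[i]), int(pool[i + 1]))
            if key[0] > key[1]:
                key = (key[1], key[0])
            perm[key] = perm.get(key, 0) + 1
        if _hwe_chi2(perm) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (reps + 1), reps


def genotyping_error_rate(
    pairs: Sequence[tuple[Genotype, Genotype]],
) -> tuple[float, int]:
    """Duplicate-genotyping discordance: mismatched calls / calls compared.

    For each duplicate pair and locus, the two unordered allele pairs are
    aligned to maximise agreement (multiset intersection); the mismatch
    count is ``2 - |intersection|``.  Loci with any missing call in either
    duplicate are skipped.  Returns ``(rate, n_calls_compared)``; the rate
    is NaN (flagged) when nothing was comparable.
    """
    if not pairs:
        raise ValueError("at least one duplicate pair is required")
    mismatches = compared = 0
    for g1, g2 in pairs:
        for locus in g1.loci:
            if locus not in g2.calls:
                continue
            p1 = g1.calls[locus]
            p2 = g2.calls[locus]
            if MISSING in p1 or MISSING in p2:
                continue
            shared = len(set(p1) & set(p2))
            # multiset intersection of two 2-element multisets
            if p1 == p2:
                inter = 2
            elif shared >= 1:
                inter = 1
            else:
                inter = 0
            mismatches += 2 - inter
            compared += 2
    if compared == 0:
        warnings.warn("no comparable calls between duplicates; rate undefined")
        return math.nan, 0
    return mismatches / compared, compared


@dataclass(frozen=True)
class PopGenSummary:
    """Per-locus quality statistics plus combined panel values."""

    table: pd.DataFrame  # one row per locus + a "combined" row
    error_rate: float | None

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def summarize(
    genotypes: Sequence[Genotype],
    freqs: PopulationFrequencies | None = None,
    duplicate_pairs: Sequence[tuple[Genotype, Genotype]] | None = None,
    hwe_reps: int = 10_000,
    seed: int = 0,
) -> PopGenSummary:
    """Full panel summary: Ho, He, HWE p, PI, PE2, PE3 per locus and combined.

    Frequencies default to direct counting from ``genotypes``; pass
    ``freqs`` to use an external (e.g. multi-year) estimate instead.
    """
    from .genotype_io import estimate_allele_freqs

    if freqs is None:
        freqs = estimate_allele_freqs(genotypes)
    ho = observed_heterozygosity(genotypes)
    he = expected_heterozygosity(freqs)
    pi_l, pi_comb = prob_identity(freqs)
    pe2_l, pe2_comb = prob_exclusion(freqs, "one-parent-known")
    pe3_l, pe3_comb = prob_exclusion(freqs, "no-parent-known")
    rng = np.random.default_rng(seed)
    rows = []
    for locus in freqs.loci:
        counts = _genotype_counts(genotypes, locus)
        try:
            p_hwe, _ = hwe_exact_test(counts, reps=hwe_reps, seed=int(rng.integers(2**31)))
        except ValueError:
            p_hwe = math.nan
        rows.append(
            {
                "locus": locus,
                "n_alleles": freqs.n_alleles(locus),
                "Ho": ho.get(locus, math.nan),
                "He": he[locus],
                "hwe_p": p_hwe,
                "PI": pi_l[locus],
                "PE2": pe2_l[locus],
                "PE3": pe3_l[locus],
            }
        )
    rows.append(
        {
            "locus": "combined",
            "n_alleles": sum(freqs.n_alleles(l) for l in freqs.loci),
            "Ho": math.nan,
            "He": math.nan,
            "hwe_p": math.nan,
            "PI": pi_comb,
            "PE2": pe2_comb,
            "PE3": pe3_comb,
        }
    )
    err = None
    if duplicate_pairs:
        err, _ = genotyping_error_rate(duplicate_pairs)
    return PopGenSummary(table=pd.DataFrame(rows), error_rate=err)
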