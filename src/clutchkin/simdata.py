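"""Synthetic populations, matings and clutches for pipeline testing.

The generator emulates the statistical structure the downstream parentage
analysis assumes: adults in Hardy-Weinberg equilibrium at a small panel of
highly polymorphic microsatellite loci (7 loci, 14-25 alleles each by
default), females laying one to three clutches in a season, one to five
fathers per female with explicit siring proportions, optional between-clutch
remating, single-step mutation on allele transmission, and per-call
genotyping error.  Every hatchling carries a truth label (its true father)
so recovery of the mating system can be scored exactly.

All randomness flows from a single integer root seed through
``numpy.random.SeedSequence`` spawn streams, so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, Clutch, Genotype
from .clutchmetrics import NestInventory

__all__ = [
    "REPEAT_UNIT",
    "PopulationFrequencies",
    "MatingPlan",
    "SimClutch",
    "StudyData",
    "gen_allele_freqs",
    "sim_adults",
    "sim_clutches",
    "sim_study",
    "write_truth_labels",
    "read_truth_labels",
]

#: microsatellite size-class step (bp) for single-step mutation
REPEAT_UNIT = 4


@dataclass(frozen=True)
class PopulationFrequencies:
    """Per-locus allele relative frequencies of the breeding population."""

    loci: Sequence[str]
    freqs: Mapping[str, Mapping[int, float]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        norm = {}
        for locus in self.loci:
            f = dict(self.freqs[locus])
            if len(f) < 2:
                raise ValueError(f"locus {locus}: needs at least 2 alleles")
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"locus {locus}: frequencies sum to {total}, not 1")
            if any(v < 0 for v in f.values()):
                raise ValueError(f"locus {locus}: negative frequency")
            norm[locus] = f
        object.__setattr__(self, "freqs", norm)

    def alleles(self, locus: str) -> tuple[int, ...]:
        return tuple(self.freqs[locus])

    def n_alleles(self, locus: str) -> int:
        return len(self.freqs[locus])


@dataclass(frozen=True)
class MatingPlan:
    """Which males sire a female's clutches, and in what proportions.

    ``proportions`` holds one mapping per clutch, father id -> siring
    fraction ``f``; fractions are non-negative and sum to 1 within each
    clutch.  A father whose fraction is 0 in every clutch before some index
    and positive from there on models sperm from a mating between nesting
    events (remating).
    """

    female_id: str
    father_ids: tuple[str, ...]
    proportions: tuple[Mapping[str, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "father_ids", tuple(self.father_ids))
        norm = []
        for ci, props in enumerate(self.proportions):
            p = {fid: float(props.get(fid, 0.0)) for fid in self.father_ids}
            if any(v < 0 for v in p.values()):
                raise ValueError(f"clutch {ci + 1}: negative siring proportion")
            total = sum(p.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"clutch {ci + 1}: siring proportions sum to {total}, not 1"
                )
            norm.append(p)
        object.__setattr__(self, "proportions", tuple(norm))

    @property
    def n_clutches(self) -> int:
        return len(self.proportions)

    def entry_clutch(self, father_id: str) -> int | None:
        """0-based index of the first clutch a father sires, or None."""
        for ci, props in enumerate(self.proportions):
            if props.get(father_id, 0.0) > 0:
                return ci
        return None

    @property
    def remating_events(self) -> dict[str, int]:
        """Fathers entering after the first clutch (father id -> clutch index)."""
        events = {}
        for fid in self.father_ids:
            entry = self.entry_clutch(fid)
            if entry is not None and entry > 0:
                events[fid] = entry
        return events


@dataclass(frozen=True)
class SimClutch:
    """A simulated clutch plus the truth label of each sampled hatchling."""

    clutch: Clutch
    true_fathers: Mapping[str, str]  # hatchling id -> father id

    @property
    def true_father_count(self) -> int:
        return len(set(self.true_fathers.values()))


def gen_allele_freqs(
    n_loci: int,
    alleles_per_locus: int | tuple[int, int],
    concentration: float = 1.0,
    seed: int = 0,
) -> PopulationFrequencies:
    """Draw per-locus allele frequencies from a symmetric Dirichlet.

    ``alleles_per_locus`` is either a fixed count or an inclusive
    ``(low, high)`` range sampled uniformly per locus.  Allele labels are
    integer fragment sizes in steps of :data:`REPEAT_UNIT`.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if concentration <= 0:
        raise ValueError("Dirichlet concentration must be positive")
    if isinstance(alleles_per_locus, int):
        lo = hi = alleles_per_locus
    else:
        lo, hi = alleles_per_locus
    if lo < 2:
        raise ValueError("each locus needs at least 2 alleles")
    if hi < lo:
        raise ValueError("allele count range is inverted")
    rng = np.random.default_rng(seed)
    loci = [f"L{i + 1:02d}" for i in range(n_loci)]
    freqs = {}
    for i, locus in enumerate(loci):
        k = int(rng.integers(lo, hi + 1))
        base = 100 + 200 * i
        labels = [base + REPEAT_UNIT * j for j in range(k)]
        p = rng.dirichlet(np.full(k, concentration))
        # renormalise away float drift so the invariant holds exactly
        p = p / p.sum()
        freqs[locus] = dict(zip(labels, p.tolist()))
    return PopulationFrequencies(loci=loci, freqs=freqs)


def _draw_genotype(freqs: PopulationFrequencies, rng: np.random.Generator, ind_id: str) -> Genotype:
    calls = {}
    for locus in freqs.loci:
        alleles = np.array(freqs.alleles(locus))
        p = np.array([freqs.freqs[locus][a] for a in alleles])
        pair = rng.choice(alleles, size=2, p=p)
        calls[locus] = (int(pair[0]), int(pair[1]))
    return Genotype(ind_id, calls)


def sim_adults(
    freqs: PopulationFrequencies, n_females: int, n_males: int, seed: int = 0
) -> tuple[list[Genotype], list[Genotype]]:
    """Simulate adult genotypes under Hardy-Weinberg equilibrium.

    Each individual's two alleles per locus are independent draws from the
    population frequencies (random union of gametes).
    """
    if n_females < 0 or n_males < 0:
        raise ValueError("adult counts must be non-negative")
    rng = np.random.default_rng(seed)
    females = [_draw_genotype(freqs, rng, f"F{i + 1:03d}") for i in range(n_females)]
    males = [_draw_genotype(freqs, rng, f"M{i + 1:03d}") for i in range(n_males)]
    return females, males


def _transmit(allele: int, rng: np.random.Generator, mutation_rate: float) -> int:
    if mutation_rate > 0 and rng.random() < mutation_rate:
        return allele + REPEAT_UNIT * (1 if rng.random() < 0.5 else -1)
    return allele


def _record(
    allele: int,
    locus_alleles: Sequence[int],
    rng: np.random.Generator,
    error_rate: float,
) -> int:
    if error_rate > 0 and rng.random() < error_rate:
        return int(locus_alleles[rng.integers(len(locus_alleles))])
    return allele


def sim_clutches(
    plan: MatingPlan,
    mother: Genotype,
    fathers: Mapping[str, Genotype],
    clutch_sizes: Sequence[int],
    sample_n: int,
    mutation_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
    freqs: PopulationFrequencies | None = None,
    hatch_success: float = 0.65,
) -> list[SimClutch]:
    """Simulate a female's clutches under her mating plan.

    Each sampled hatchling receives one maternal allele (a uniform pick of
    the mother's two) and one paternal allele from a father drawn by the
    clutch's siring proportions.  Mutation perturbs a transmitted allele by
    one size class; genotyping error replaces a recorded call by a uniform
    draw from the locus's population allele set (``freqs`` required when
    ``error_rate > 0``).  Nest-inventory counts are drawn so emergence
    success is realistic for a hot season (~0.6).
    """
    if len(clutch_sizes) != plan.n_clutches:
        raise ValueError("clutch_sizes length must match the plan's clutch count")
    for fid in plan.father_ids:
        if fid not in fathers:
            raise KeyError(f"father {fid} in mating plan has no genotype")
    if error_rate > 0 and freqs is None:
        raise ValueError("freqs is required when error_rate > 0")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(plan.n_clutches)]
    out = []
    for ci, (size, rng) in enumerate(zip(clutch_sizes, streams)):
        if sample_n > size:
            raise ValueError(f"sample_n ({sample_n}) exceeds clutch size ({size})")
        props = plan.proportions[ci]
        sires = [fid for fid in plan.father_ids if props[fid] > 0]
        weights = np.array([props[fid] for fid in sires])
        hatchlings = []
        truth = {}
        for j in range(sample_n):
            hid = f"{plan.female_id}-c{ci + 1}-h{j + 1:02d}"
            sire = sires[int(rng.choice(len(sires), p=weights))]
            father = fathers[sire]
            calls = {}
            for locus in mother.loci:
                mat = _transmit(
                    mother.alleles(locus)[int(rng.integers(2))], rng, mutation_rate
                )
                pat = _transmit(
                    father.alleles(locus)[int(rng.integers(2))], rng, mutation_rate
                )
                if error_rate > 0:
                    locus_alleles = freqs.alleles(locus)
                    mat = _record(mat, locus_alleles, rng, error_rate)
                    pat = _record(pat, locus_alleles, rng, error_rate)
                calls[locus] = (mat, pat)
            hatchlings.append(Genotype(hid, calls))
            truth[hid] = sire
        hatched = int(rng.binomial(size, hatch_success))
        live = int(rng.binomial(hatched, 0.02)) if hatched else 0
        dead = int(rng.binomial(hatched - live, 0.02)) if hatched - live else 0
        inv = NestInventory(hatched=hatched, total=size, live_in_nest=live, dead_in_nest=dead)
        clutch = Clutch(
            mother_id=plan.female_id,
            order=ci + 1,
            hatchlings=tuple(hatchlings),
            inventory=inv,
            incubation_days=int(rng.integers(48, 58)),
        )
        out.append(SimClutch(clutch=clutch, true_fathers=truth))
    return out


#: default distribution of fathers per female: 75% of females mate singly,
#: the rest carry 2-5 fathers (polyandry is the minority pattern)
DEFAULT_FATHER_COUNT_PROBS: dict[int, float] = {1: 0.75, 2: 0.10, 3: 0.10, 4: 0.025, 5: 0.025}


@dataclass(frozen=True)
class StudyData:
    """A complete simulated season: population, adults, plans and clutches."""

    freqs: PopulationFrequencies
    mothers: Mapping[str, Genotype]
    fathers: Mapping[str, Genotype]
    plans: tuple[MatingPlan, ...]
    sim_clutches: tuple[SimClutch, ...] = field(default_factory=tuple)

    @property
    def clutches(self) -> list[Clutch]:
        return [sc.clutch for sc in self.sim_clutches]

    def truth_labels(self) -> dict[str, str]:
        labels: dict[str, str] = {}
        for sc in self.sim_clutches:
            labels.update(sc.true_fathers)
        return labels


def sim_study(
    n_females: int = 16,
    n_loci: int = 7,
    alleles_per_locus: tuple[int, int] = (14, 25),
    concentration: float = 1.0,
    n_clutches_choices: Sequence[int] = (2, 2, 2, 3),
    father_count_probs: Mapping[int, float] = DEFAULT_FATHER_COUNT_PROBS,
    proportion_concentration: float = 2.0,
    remating_prob: float = 0.0,
    remating_fraction: tuple[float, float] = (0.3, 0.7),
    clutch_size: int = 100,
    sample_n: int = 20,
    mutation_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> StudyData:
    """Simulate a full nesting season with study-scale defaults.

    Defaults mirror the assemblage the analysis is designed for: 16 females
    each laying 2-3 clutches of ~100 eggs with 20 hatchlings sampled, seven
    loci of 14-25 alleles, three quarters of females singly mated, siring
    proportions from a moderately even symmetric Dirichlet, and no mutation
    or genotyping error unless requested.  With ``remating_prob > 0`` a
    female may acquire a new father between her first and second clutch,
    entering at a fraction drawn uniformly from ``remating_fraction``.
    """
    ss = np.random.SeedSequence(seed)
    s_freq, s_adults, s_plan, s_clutch = ss.spawn(4)
    freqs = gen_allele_freqs(n_loci, alleles_per_locus, concentration, seed=s_freq)
    rng = np.random.default_rng(s_plan)
    # generous male pool: every father unique unless plans reuse ids
    max_fathers = 5 * n_females
    females, males = sim_adults(freqs, n_females, max_fathers, seed=s_adults)
    mothers = {g.individual_id: g for g in females}
    male_pool = {g.individual_id: g for g in males}
    male_ids = list(male_pool)
    counts = sorted(father_count_probs)
    probs = np.array([father_count_probs[k] for k in counts], dtype=float)
    probs = probs / probs.sum()
    plans = []
    used = 0
    sim = []
    clutch_streams = s_clutch.spawn(n_females)
    for i, (fid_mother, mother) in enumerate(sorted(mothers.items())):
        n_clutches = int(n_clutches_choices[i % len(n_clutches_choices)])
        k = int(counts[int(rng.choice(len(counts), p=probs))])
        father_ids = male_ids[used : used + k]
        used += k
        base = rng.dirichlet(np.full(k, proportion_concentration))
        base = base / base.sum()
        props_per_clutch: list[dict[str, float]] = []
        remates = n_clutches > 1 and rng.random() < remating_prob
        new_father = None
        if remates:
            new_father = male_ids[used]
            used += 1
            father_ids = father_ids + [new_father]
        for ci in range(n_clutches):
            props = {fid: float(b) for fid, b in zip(father_ids, list(base) + [0.0])}
            if remates and ci >= 1:
                frac = float(rng.uniform(*remating_fraction))
                props = {fid: float(b) * (1 - frac) for fid, b in zip(father_ids[:-1], base)}
                props[new_father] = frac
            elif remates:
                props = {fid: float(b) for fid, b in zip(father_ids[:-1], base)}
                props[new_father] = 0.0
            props_per_clutch.append(props)
        plan = MatingPlan(
            female_id=fid_mother,
            father_ids=tuple(father_ids),
            proportions=tuple(props_per_clutch),
        )
        plans.append(plan)
        sim.extend(
            sim_clutches(
                plan,
                mother,
                male_pool,
                clutch_sizes=[clutch_size] * n_clutches,
                sample_n=sample_n,
                mutation_rate=mutation_rate,
                error_rate=error_rate,
                seed=clutch_streams[i],
                freqs=freqs,
            )
        )
    father_ids_used = {fid for p in plans for fid in p.father_ids}
    return StudyData(
        freqs=freqs,
        mothers=mothers,
        fathers={fid: male_pool[fid] for fid in sorted(father_ids_used)},
        plans=tuple(plans),
        sim_clutches=tuple(sim),
    )


def write_truth_labels(path, sim_clutches: Sequence[SimClutch]) -> None:
    """Sidecar CSV mapping hatchling id to its true father id."""
    rows = []
    for sc in sim_clutches:
        for hid, fid in sc.true_fathers.items():
            rows.append({"hatchling_id": hid, "father_id": fid})
    pd.DataFrame(rows, columns=["hatchling_id", "father_id"]).to_csv(path, index=False)


def read_truth_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df["hatchling_id"], df["father_id"]))
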