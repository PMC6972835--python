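"""Genotype and clutch-metadata I/O plus allele-frequency estimation.

The on-disk genotype dialect is a GenAlEx-style CSV: an ``individual_id``
column followed by two integer columns per locus (``<locus>_1``,
``<locus>_2``), with 0 encoding a missing allele call.  Clutch metadata and
morphometrics are plain CSVs with documented, stable column orders so that
written files diff bit-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clutchmetrics import NestInventory

__all__ = [
    "Genotype",
    "Clutch",
    "GenotypeFormatError",
    "read_genotypes",
    "write_genotypes",
    "read_clutch_table",
    "write_clutch_table",
    "estimate_allele_freqs",
]

MISSING = 0


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype tables (bad columns, non-integer calls)."""


@dataclass(frozen=True)
class Genotype:
    """A multilocus microsatellite genotype.

    ``calls`` maps locus name to an unordered pair of integer allele sizes;
    pairs are stored sorted so equality is order-insensitive.  0 encodes a
    missing allele call; one allele of a pair may be missing (flagged via
    :meth:`partially_missing_loci`) — the record is kept, not dropped.
    """

    individual_id: str
    calls: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {}
        for locus, pair in self.calls.items():
            a, b = int(pair[0]), int(pair[1])
            if a < 0 or b < 0:
                raise GenotypeFormatError(
                    f"{self.individual_id}/{locus}: negative allele size"
                )
            norm[locus] = (a, b) if a <= b else (b, a)
        object.__setattr__(self, "calls", norm)

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.calls)

    def alleles(self, locus: str) -> tuple[int, int]:
        return self.calls[locus]

    def is_missing(self, locus: str) -> bool:
        """True when no allele at the locus was called."""
        pair = self.calls[locus]
        return pair == (MISSING, MISSING)

    def partially_missing_loci(self) -> tuple[str, ...]:
        """Loci where exactly one of the two allele calls is missing."""
        return tuple(
            locus
            for locus, (a, b) in self.calls.items()
            if (a == MISSING) != (b == MISSING)
        )


@dataclass(frozen=True)
class Clutch:
    """One nesting event: the mother's id, order in her season, and samples.

    ``order`` is 1 for the primary clutch, 2 for the secondary, 3 for a
    tertiary.  ``hatchlings`` are the sampled (not total) offspring.
    """

    mother_id: str
    order: int
    hatchlings: tuple[Genotype, ...]
    lay_date: str | None = None
    inventory: NestInventory | None = None
    incubation_days: int | None = None

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("clutch order starts at 1")
        object.__setattr__(self, "hatchlings", tuple(self.hatchlings))
        if self.inventory is not None and self.n > self.inventory.total:
            raise ValueError(
                f"sampled hatchlings ({self.n}) exceed clutch size "
                f"({self.inventory.total})"
            )

    @property
    def n(self) -> int:
        """Number of sampled hatchlings."""
        return len(self.hatchlings)


def _locus_columns(locus_names: Sequence[str]) -> list[str]:
    cols = []
    for locus in locus_names:
        cols.extend([f"{locus}_1", f"{locus}_2"])
    return cols


def read_genotypes(path, locus_names: Sequence[str]) -> list[Genotype]:
    """Read a two-columns-per-locus genotype CSV.

    Malformed rows are reported with their (1-based, header-inclusive) line
    numbers in the raised :class:`GenotypeFormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    expected = ["individual_id"] + _locus_columns(locus_names)
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise GenotypeFormatError(
            f"{path.name}: missing columns {missing_cols}; each locus needs "
            "exactly two columns (<locus>_1, <locus>_2)"
        )
    genotypes: list[Genotype] = []
    bad_rows: list[str] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        calls = {}
        ok = True
        for locus in locus_names:
            try:
                a = int(row[f"{locus}_1"])
                b = int(row[f"{locus}_2"])
            except (TypeError, ValueError):
                bad_rows.append(f"line {line_no}: non-integer allele at {locus}")
                ok = False
                break
            calls[locus] = (a, b)
        if ok:
            genotypes.append(Genotype(str(row["individual_id"]), calls))
    if bad_rows:
        raise GenotypeFormatError("; ".join(bad_rows))
    return genotypes


def write_genotypes(path, genotypes: Iterable[Genotype], locus_names: Sequence[str]) -> None:
    """Write genotypes in the same dialect :func:`read_genotypes` accepts."""
    rows = []
    for g in genotypes:
        row = {"individual_id": g.individual_id}
        for locus in locus_names:
            a, b = g.calls.get(locus, (MISSING, MISSING))
            row[f"{locus}_1"] = a
            row[f"{locus}_2"] = b
        rows.append(row)
    df = pd.DataFrame(rows, columns=["individual_id"] + _locus_columns(locus_names))
    df.to_csv(path, index=False)


_CLUTCH_COLUMNS = [
    "mother_id",
    "clutch_order",
    "lay_date",
    "n_sampled",
    "eggs_hatched",
    "eggs_total",
    "live_in_nest",
    "dead_in_nest",
    "incubation_days",
]


def write_clutch_table(path, clutches: Iterable[Clutch]) -> None:
    """Write clutch metadata (one row per clutch; hatchlings stored separately)."""
    rows = []
    for c in clutches:
        inv = c.inventory
        rows.append(
            {
                "mother_id": c.mother_id,
                "clutch_order": c.order,
                "lay_date": c.lay_date if c.lay_date is not None else "",
                "n_sampled": c.n,
                "eggs_hatched": inv.hatched if inv else "",
                "eggs_total": inv.total if inv else "",
                "live_in_nest": inv.live_in_nest if inv else "",
                "dead_in_nest": inv.dead_in_nest if inv else "",
                "incubation_days": c.incubation_days
                if c.incubation_days is not None
                else "",
            }
        )
    pd.DataFrame(rows, columns=_CLUTCH_COLUMNS).to_csv(path, index=False)


def read_clutch_table(path, hatchlings_by_clutch: Mapping[tuple[str, int], Sequence[Genotype]] | None = None) -> list[Clutch]:
    """Read clutch metadata; optionally attach hatchling genotypes.

    ``hatchlings_by_clutch`` maps ``(mother_id, clutch_order)`` to the sampled
    genotypes (e.g. grouped from a genotype CSV whose ids encode the clutch).
    When ``clutch_order`` is blank it is inferred from lay-date order within
    each mother.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    records = df.to_dict("records")
    # infer missing clutch order from lay dates (ISO-8601 strings sort correctly)
    by_mother: dict[str, list[dict]] = {}
    for rec in records:
        by_mother.setdefault(str(rec["mother_id"]), []).append(rec)
    for mother, recs in by_mother.items():
        if any(str(r.get("clutch_order", "")).strip() == "" for r in recs):
            recs.sort(key=lambda r: str(r.get("lay_date", "")))
            for i, r in enumerate(recs, start=1):
                r["clutch_order"] = i
    clutches = []
    for rec in records:
        mother = str(rec["mother_id"])
        order = int(rec["clutch_order"])
        inv = None
        if str(rec.get("eggs_total", "")).strip() != "":
            inv = NestInventory(
                hatched=int(rec["eggs_hatched"]),
                total=int(rec["eggs_total"]),
                live_in_nest=int(rec["live_in_nest"]),
                dead_in_nest=int(rec["dead_in_nest"]),
            )
        incubation = (
            int(rec["incubation_days"])
            if str(rec.get("incubation_days", "")).strip() != ""
            else None
        )
        hatchlings: Sequence[Genotype] = ()
        if hatchlings_by_clutch is not None:
            hatchlings = hatchlings_by_clutch.get((mother, order), ())
        clutches.append(
            Clutch(
                mother_id=mother,
                order=order,
                hatchlings=tuple(hatchlings),
                lay_date=str(rec.get("lay_date", "")) or None,
                inventory=inv,
                incubation_days=incubation,
            )
        )
    return clutches


def estimate_allele_freqs(genotypes: Sequence[Genotype]):
    """Estimate population allele frequencies by direct allele counting.

    Each non-missing allele call contributes one count; the frequency at a
    locus is count / total non-missing calls there.  Loci with zero calls
    are excluded with a warning.  Returns a
    :class:`~clutchkin.simdata.PopulationFrequencies`.
    """
    from .simdata import PopulationFrequencies  # avoid import cycle

    if not genotypes:
        raise ValueError("no genotypes supplied")
    loci = list(genotypes[0].loci)
    freqs: dict[str, dict[int, float]] = {}
    kept = []
    for locus in loci:
        counts: dict[int, int] = {}
        for g in genotypes:
            if locus not in g.calls:
                continue
            for allele in g.calls[locus]:
                if allele != MISSING:
                    counts[allele] = counts.get(allele, 0) + 1
        total = sum(counts.values())
        if total == 0:
            warnings.warn(f"locus {locus}: no non-missing calls, excluded")
            continue
        kept.append(locus)
        freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
    return PopulationFrequencies(loci=kept, freqs=freqs)
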