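"""End-to-end orchestration: simulate or load data, analyse, write reports.

A run is described by a :class:`RunConfig` holding either a simulation
block (parameters forwarded to :func:`clutchkin.simdata.sim_study`) or
input file paths, plus the analysis knobs (significance level, siring
fraction estimation mode, breeding-sex-ratio scope) and the root seed.
Every output table carries the seed and a hash of the configuration in a
comment header, and a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
import sys
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import clutchmetrics, genotype_io, matingsys, paternity, popgen, simdata

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

_HATCHLING_ID = re.compile(r"^(?P<mother>.+)-c(?P<order>\d+)-")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulate`` (keyword arguments for
    :func:`~clutchkin.simdata.sim_study`) or ``inputs`` must be given.
    ``inputs`` is a mapping with keys ``mothers`` (genotype CSV),
    ``hatchlings`` (genotype CSV whose ids follow
    ``<mother_id>-c<order>-...``), ``clutches`` (metadata CSV, optional)
    and ``locus_names``.
    """

    out_dir: str
    seed: int = 0
    simulate: Mapping[str, Any] | None = None
    inputs: Mapping[str, Any] | None = None
    alpha: float = 0.05
    f_mode: str = "first-clutch"
    scope: str = "all-clutches"
    total_nests: int | None = None
    clutch_freq: tuple[float, float] | None = None
    partition_method: str = "exact"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'simulate' or 'inputs' must be configured"
            )

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # where outputs land does not change what they are
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(path: Path, df: pd.DataFrame, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def _load_inputs(inputs: Mapping[str, Any]):
    locus_names = list(inputs["locus_names"])
    mothers = genotype_io.read_genotypes(inputs["mothers"], locus_names)
    hatchlings = genotype_io.read_genotypes(inputs["hatchlings"], locus_names)
    grouped: dict[tuple[str, int], list[genotype_io.Genotype]] = {}
    for h in hatchlings:
        m = _HATCHLING_ID.match(h.individual_id)
        if not m:
            raise genotype_io.GenotypeFormatError(
                f"hatchling id {h.individual_id!r} does not encode its clutch "
                "(<mother_id>-c<order>-...)"
            )
        grouped.setdefault((m.group("mother"), int(m.group("order"))), []).append(h)
    if inputs.get("clutches"):
        clutches = genotype_io.read_clutch_table(inputs["clutches"], grouped)
    else:
        clutches = [
            genotype_io.Clutch(mother_id=m, order=o, hatchlings=tuple(hs))
            for (m, o), hs in sorted(grouped.items())
        ]
    return {g.individual_id: g for g in mothers}, clutches


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis and write the report bundle.

    Stages: data acquisition -> population-genetic panel summary ->
    per-clutch exclusion paternity -> mating-system inference ->
    clutch-quality metrics.  Returns the combined summary (also written to
    ``summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# clutchkin seed={config.seed} config={config.config_hash()}\n"
    summary: dict[str, Any] = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }

    t0 = time.perf_counter()
    stage = "data"
    try:
        if config.simulate is not None:
            study = simdata.sim_study(seed=config.seed, **dict(config.simulate))
            mothers = dict(study.mothers)
            clutches = study.clutches
            simdata.write_truth_labels(out / "truth_labels.csv", study.sim_clutches)
            genotype_io.write_genotypes(
                out / "mothers.csv", mothers.values(), study.freqs.loci
            )
            genotype_io.write_genotypes(
                out / "hatchlings.csv",
                [h for c in clutches for h in c.hatchlings],
                study.freqs.loci,
            )
            genotype_io.write_clutch_table(out / "clutches.csv", clutches)
        else:
            mothers, clutches = _load_inputs(config.inputs)
        _log(f"[data] {len(mothers)} mothers, {len(clutches)} clutches "
             f"({time.perf_counter() - t0:.2f}s)")
    except Exception as e:  # noqa: BLE001 - rewrapped with stage context
        raise PipelineStageError(stage, e) from e

    stage = "popgen"
    try:
        t = time.perf_counter()
        pg = popgen.summarize(list(mothers.values()), seed=config.seed)
        _write_tsv(out / "popgen_summary.tsv", pg.table, header)
        comb = pg.table[pg.table["locus"] == "combined"].iloc[0]
        summary["popgen"] = {
            "combined_PI": float(comb["PI"]),
            "combined_PE2": float(comb["PE2"]),
            "combined_PE3": float(comb["PE3"]),
        }
        _log(f"[popgen] combined PI={comb['PI']:.3g} ({time.perf_counter() - t:.2f}s)")
    except Exception as e:
        raise PipelineStageError(stage, e) from e

    stage = "paternity"
    try:
        t = time.perf_counter()
        assignments: dict[str, list[paternity.FatherAssignment]] = {}
        rows = []
        for clutch in clutches:
            mother = mothers[clutch.mother_id]
            table = paternity.paternal_allele_sets(mother, list(clutch.hatchlings))
            assign = paternity.min_father_partition(
                table, method=config.partition_method
            )
            assign = dataclasses.replace(assign, clutch_order=clutch.order)
            assignments.setdefault(clutch.mother_id, []).append(assign)
            rows.append(
                {
                    "mother_id": clutch.mother_id,
                    "clutch_order": clutch.order,
                    "n": assign.n,
                    "father_count": assign.father_count,
                    "multiple_paternity": assign.mp.is_mp,
                    "mutation_locus": assign.mutation_locus or "",
                    "siring_proportions": ";".join(
                        f"{p:.3f}" for p in assign.proportions
                    ),
                }
            )
        pat_df = pd.DataFrame(rows)
        _write_tsv(out / "paternity_report.tsv", pat_df, header)
        summary["paternity"] = {
            "n_clutches": len(rows),
            "mp_rate": matingsys.multiple_paternity_rate(pat_df["father_count"]),
        }
        _log(f"[paternity] MP rate={summary['paternity']['mp_rate']:.2f} "
             f"({time.perf_counter() - t:.2f}s)")
    except Exception as e:
        raise PipelineStageError(stage, e) from e

    stage = "matingsystem"
    try:
        t = time.perf_counter()
        pair_rows = []
        transition_rows = []
        for female in sorted(assignments):
            ordered = sorted(assignments[female], key=lambda a: a.clutch_order or 0)
            for a1, a2 in zip(ordered, ordered[1:]):
                match = paternity.match_fathers(a1, a2)
                qs = matingsys.sorensen_qs(match.a_count, match.b_count, match.shared)
                pair_rows.append(
                    {
                        "mother_id": female,
                        "clutch_pair": f"{a1.clutch_order}-{a2.clutch_order}",
                        "A": match.a_count,
                        "B": match.b_count,
                        "C": match.shared,
                        "QS_percent": qs,
                    }
                )
                for rec in matingsys.classify_transitions(
                    a1, a2, alpha=config.alpha, f_mode=config.f_mode, match=match
                ):
                    transition_rows.append(
                        {
                            "mother_id": female,
                            "clutch_pair": f"{a1.clutch_order}-{a2.clutch_order}",
                            "father": rec.father,
                            "status": rec.status,
                            "f": "" if rec.f is None else f"{rec.f:.4f}",
                            "n": "" if rec.n is None else rec.n,
                            "p_f": "" if rec.p_f is None else f"{rec.p_f:.4g}",
                            "classification": rec.classification,
                        }
                    )
        bsr_all = matingsys.breeding_sex_ratio(assignments, scope="all-clutches")
        bsr_first = matingsys.breeding_sex_ratio(assignments, scope="first-clutch-only")
        ms_df = pd.DataFrame(
            pair_rows, columns=["mother_id", "clutch_pair", "A", "B", "C", "QS_percent"]
        )
        _write_tsv(out / "matingsystem_report.tsv", ms_df, header)
        tr_df = pd.DataFrame(
            transition_rows,
            columns=["mother_id", "clutch_pair", "father", "status", "f", "n",
                     "p_f", "classification"],
        )
        _write_tsv(out / "transitions_report.tsv", tr_df, header)
        summary["matingsystem"] = {
            "bsr": bsr_all if config.scope == "all-clutches" else bsr_first,
            "bsr_all_clutches": bsr_all,
            "bsr_first_clutch_only": bsr_first,
            "n_females": len(assignments),
            "remating_consistent_transitions": sum(
                1
                for r in transition_rows
                if r["classification"] == matingsys.UNLIKELY_BY_CHANCE
            ),
        }
        if config.total_nests is not None and config.clutch_freq is not None:
            females, males = matingsys.extrapolate_population(
                config.total_nests,
                config.clutch_freq[0],
                config.clutch_freq[1],
                bsr_all,
            )
            summary["matingsystem"]["extrapolation"] = {
                "total_nests": config.total_nests,
                "females": list(females),
                "males": list(males),
            }
        _log(f"[matingsystem] BSR={bsr_all:.2f} (first-clutch {bsr_first:.2f}) "
             f"({time.perf_counter() - t:.2f}s)")
    except Exception as e:
        raise PipelineStageError(stage, e) from e

    stage = "clutchmetrics"
    try:
        t = time.perf_counter()
        cm_rows = []
        for clutch in clutches:
            e = (
                clutchmetrics.emergence_success(clutch.inventory)
                if clutch.inventory is not None
                else float("nan")
            )
            cm_rows.append(
                {
                    "mother_id": clutch.mother_id,
                    "clutch_order": clutch.order,
                    "n_sampled": clutch.n,
                    "emergence_success": e,
                    "incubation_days": clutch.incubation_days
                    if clutch.incubation_days is not None
                    else "",
                }
            )
        cm_df = pd.DataFrame(cm_rows)
        _write_tsv(out / "clutchmetrics_report.tsv", cm_df, header)
        primary = cm_df[cm_df["clutch_order"] == 1]["emergence_success"].dropna()
        secondary = cm_df[cm_df["clutch_order"] == 2]["emergence_success"].dropna()
        cm_summary: dict[str, Any] = {
            "mean_emergence_primary": float(primary.mean()) if len(primary) else None,
            "mean_emergence_secondary": float(secondary.mean()) if len(secondary) else None,
        }
        if len(primary) >= 2 and len(secondary) >= 2:
            rep = clutchmetrics.group_comparisons(primary, secondary)
            cm_summary["primary_vs_secondary_t_p"] = rep.t_p_two_tailed
        summary["clutchmetrics"] = cm_summary
        _log(f"[clutchmetrics] ({time.perf_counter() - t:.2f}s)")
    except Exception as e:
        raise PipelineStageError(stage, e) from e

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _log(f"[done] total {time.perf_counter() - t0:.2f}s -> {out}")
    return summary
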