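import numpy as np
import pytest

from clutchkin import simdata
from clutchkin.paternity import PaternalAlleleTable


@pytest.fixture(scope="session")
def study():
    """One simulated season at study-scale defaults, shared across tests."""
    return simdata.sim_study(seed=11)


@pytest.fixture(scope="session")
def panel_freqs():
    """A 7-locus, 14-25-alleles-per-locus frequency panel."""
    return simdata.gen_allele_freqs(7, (14, 25), 1.0, seed=5)


def random_candidate_table(rng: np.random.Generator, n: int, n_loci: int = 3,
                           n_alleles: int = 4, p_none: float = 0.15,
                           p_ambiguous: float = 0.35) -> PaternalAlleleTable:
    """A random paternal-candidate table for partition stress tests.

    Candidate sets are drawn directly (certain singleton, ambiguous pair,
    or uninformative None), bypassing genotype simulation, so the partition
    search is exercised on arbitrary constraint structures.
    """
    loci = tuple(f"L{i}" for i in range(n_loci))
    ids = tuple(f"h{i:02d}" for i in range(n))
    candidates = {}
    for hid in ids:
        row = {}
        for locus in loci:
            u = rng.random()
            if u < p_none:
                row[locus] = None
            elif u < p_none + p_ambiguous:
                pair = rng.choice(n_alleles, size=2, replace=False)
                row[locus] = frozenset(int(a) for a in pair)
            else:
                row[locus] = frozenset({int(rng.integers(n_alleles))})
        candidates[hid] = row
    return PaternalAlleleTable(
        mother_id="M",
        loci=loci,
        hatchling_ids=ids,
        candidates=candidates,
        mismatches={hid: () for hid in ids},
    )
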