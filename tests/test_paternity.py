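"""Exclusion analysis: paternal allele subtraction, sibship partitioning,
multiple-paternity calls and father matching."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clutchkin import paternity, simdata
from clutchkin.genotype_io import Genotype
from clutchkin.paternity import (
    call_multiple_paternity,
    match_fathers,
    min_father_partition,
    paternal_allele_sets,
    pigeonhole_lower_bound,
)

from conftest import random_candidate_table
from oracles import min_fathers_oracle, pigeonhole_oracle


def _mother(alleles=(1, 2)):
    return Genotype("mom", {"L": alleles})


class TestPaternalAlleleSets:
    @pytest.mark.parametrize(
        "mother, hatchling, expected",
        [
            ((1, 2), (1, 3), frozenset({3})),  # one maternal match: other is paternal
            ((1, 2), (1, 2), frozenset({1, 2})),  # both match: ambiguous
            ((1, 1), (1, 3), frozenset({3})),  # homozygous mother resolves
            ((1, 2), (1, 1), frozenset({1})),  # homozygous hatchling: paternal = 1
        ],
    )
    def test_subtraction_cases(self, mother, hatchling, expected):
        table = paternal_allele_sets(
            Genotype("mom", {"L": mother}), [Genotype("h", {"L": hatchling})]
        )
        assert table.candidates["h"]["L"] == expected

    def test_incompatible_locus_flagged_not_dropped(self):
        table = paternal_allele_sets(
            _mother(), [Genotype("h", {"L": (3, 4)})]
        )
        assert table.mismatches["h"] == ("L",)
        assert table.candidates["h"]["L"] is None
        assert table.hatchling_ids == ("h",)

    def test_foreign_hatchling_excluded_with_warning(self):
        mom = Genotype("mom", {f"L{i}": (1, 2) for i in range(5)})
        alien = Genotype("alien", {f"L{i}": (8, 9) for i in range(5)})
        own = Genotype("own", {f"L{i}": (1, 5) for i in range(5)})
        with pytest.warns(UserWarning, match="alien"):
            table = paternal_allele_sets(mom, [alien, own])
        assert table.foreign == ("alien",)
        assert table.hatchling_ids == ("own",)

    def test_partial_missing_call(self):
        # observed allele absent from the mother must be paternal
        table = paternal_allele_sets(_mother(), [Genotype("h", {"L": (0, 7)})])
        assert table.candidates["h"]["L"] == frozenset({7})
        # observed allele present in the mother: uninformative
        table = paternal_allele_sets(_mother(), [Genotype("h2", {"L": (0, 1)})])
        assert table.candidates["h2"]["L"] is None


class TestMultiplePaternityRule:
    def _table(self, paternal_allele_lists):
        """Build a table whose certain paternal alleles per locus are given."""
        loci = [f"L{i}" for i in range(len(paternal_allele_lists))]
        mom = Genotype("mom", {l: (90, 91) for l in loci})
        hatchlings = []
        n = max(len(v) for v in paternal_allele_lists)
        for j in range(n):
            calls = {}
            for l, alleles in zip(loci, paternal_allele_lists):
                calls[l] = (90, alleles[j % len(alleles)])
            hatchlings.append(Genotype(f"h{j}", calls))
        return paternal_allele_sets(mom, hatchlings)

    def test_three_alleles_at_one_locus_is_mutation_not_mp(self):
        table = self._table([[1, 2, 3], [1, 2], [1, 2]])
        call = call_multiple_paternity(table)
        assert not call.is_mp and "mutation" in call.note

    def test_three_alleles_at_two_loci_is_mp(self):
        table = self._table([[1, 2, 3], [4, 5, 6], [1, 2]])
        call = call_multiple_paternity(table)
        assert call.is_mp and set(call.supporting_loci) == {"L0", "L1"}

    def test_two_alleles_everywhere_is_single_father(self):
        table = self._table([[1, 2], [3, 4], [5, 6]])
        assert not call_multiple_paternity(table).is_mp


class TestPartition:
    def test_shared_allele_yields_single_father(self):
        table = self._shared_table()
        assign = min_father_partition(table)
        assert assign.father_count == 1
        assert assign.proportions == (1.0,)

    @staticmethod
    def _shared_table():
        mom = Genotype("mom", {"L1": (1, 2), "L2": (1, 2)})
        hs = [Genotype(f"h{i}", {"L1": (1, 5), "L2": (2, 6)}) for i in range(6)]
        return paternal_allele_sets(mom, hs)

    def test_pigeonhole_five_alleles_needs_three_fathers(self):
        mom = Genotype("mom", {"L": (90, 91)})
        hs = [Genotype(f"h{i}", {"L": (90, 10 + i)}) for i in range(5)]
        table = paternal_allele_sets(mom, hs)
        assert pigeonhole_lower_bound(table) == 3
        assign = min_father_partition(table, max_mutation_loci=0)
        assert assign.father_count >= 3

    def test_exact_matches_set_partition_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(3, 9))
            table = random_candidate_table(rng, n)
            assign = min_father_partition(table, method="exact", max_mutation_loci=0)
            expected = min_fathers_oracle(
                table.hatchling_ids, table.candidates, table.loci
            )
            assert assign.father_count == expected

    def test_exact_never_exceeds_greedy_and_respects_lower_bound(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(3, 12))
            table = random_candidate_table(rng, n)
            exact = min_father_partition(table, "exact", max_mutation_loci=0)
            greedy = min_father_partition(table, "greedy", max_mutation_loci=0)
            lb = pigeonhole_lower_bound(table)
            assert lb == pigeonhole_oracle(table.hatchling_ids, table.candidates, table.loci)
            assert lb <= exact.father_count <= greedy.father_count

    def test_exact_partition_invariant_to_input_order(self, study):
        sc = next(s for s in study.sim_clutches if s.true_father_count > 1)
        mom = study.mothers[sc.clutch.mother_id]
        fwd = paternal_allele_sets(mom, list(sc.clutch.hatchlings))
        rev = paternal_allele_sets(mom, list(sc.clutch.hatchlings)[::-1])
        a = min_father_partition(fwd, "exact")
        b = min_father_partition(rev, "exact")
        assert sorted(a.groups) == sorted(b.groups)

    def test_groups_cover_all_hatchlings_disjointly(self, study):
        for sc in study.sim_clutches[:8]:
            mom = study.mothers[sc.clutch.mother_id]
            table = paternal_allele_sets(mom, list(sc.clutch.hatchlings))
            assign = min_father_partition(table)
            flat = [h for g in assign.groups for h in g]
            assert sorted(flat) == sorted(table.hatchling_ids)
            assert len(flat) == len(set(flat))
            assert sum(assign.proportions) == pytest.approx(1.0)

    def test_mutation_allowance_collapses_single_bad_locus(self):
        # one locus showing 3 paternal alleles, all others consistent with
        # a single father: the conservative rule designates it a mutation
        mom = Genotype("mom", {"L1": (90, 91), "L2": (90, 91), "L3": (90, 91)})
        hs = []
        for i in range(6):
            mut = 3 if i == 5 else (1 if i % 2 else 2)
            hs.append(Genotype(f"h{i}", {"L1": (90, mut), "L2": (90, 7), "L3": (90, 8)}))
        table = paternal_allele_sets(mom, hs)
        strict = min_father_partition(table, max_mutation_loci=0)
        relaxed = min_father_partition(table, max_mutation_loci=1)
        assert strict.father_count == 2
        assert relaxed.father_count == 1
        assert relaxed.mutation_locus == "L1"
        assert not relaxed.mp.is_mp

    def test_recovery_on_error_free_clutches(self, study):
        hits = eligible = 0
        for sc in study.sim_clutches:
            mom = study.mothers[sc.clutch.mother_id]
            table = paternal_allele_sets(mom, list(sc.clutch.hatchlings))
            assign = min_father_partition(table)
            sired = Counter(sc.true_fathers.values())
            if min(sired.values()) >= 2:
                eligible += 1
                hits += assign.father_count == sc.true_father_count
        assert eligible > 10
        assert hits / eligible >= 0.95


class TestMatchFathers:
    @staticmethod
    def _assign(genotypes, n_each=5):
        groups = tuple(
            tuple(f"g{i}h{j}" for j in range(n_each)) for i in range(len(genotypes))
        )
        return paternity.FatherAssignment(
            mother_id="mom",
            groups=groups,
            father_genotypes=tuple(genotypes),
            proportions=tuple(n_each / (n_each * len(genotypes)) for _ in genotypes),
            mp=paternity.MPCall(len(genotypes) > 1, ()),
            method="exact",
        )

    def test_identical_reconstructions_match(self):
        g = {"L1": frozenset({1, 2}), "L2": frozenset({3})}
        res = match_fathers(self._assign([g]), self._assign([g]))
        assert res.pairs == ((0, 0),) and res.shared == 1

    def test_contradictory_fathers_do_not_match(self):
        ga = {"L1": frozenset({1, 2})}
        gb = {"L1": frozenset({3, 4})}
        res = match_fathers(self._assign([ga]), self._assign([gb]))
        assert res.shared == 0

    def test_incomplete_attribution_is_compatible(self):
        ga = {"L1": frozenset({1}), "L2": frozenset()}
        gb = {"L1": frozenset({1, 2}), "L2": frozenset({9, 10})}
        res = match_fathers(self._assign([ga]), self._assign([gb]))
        assert res.shared == 1

    def test_matching_is_one_to_one(self):
        loose = {"L1": frozenset()}
        res = match_fathers(self._assign([loose, loose]), self._assign([loose]))
        assert res.shared == 1  # both of A's fathers are compatible, only one pairs

    def test_true_shared_fathers_recovered_across_clutches(self):
        # simulate females with two clutches from the same sperm store and
        # check matched father counts against truth
        ok = total = 0
        study = simdata.sim_study(seed=23)
        for plan in study.plans:
            scs = [sc for sc in study.sim_clutches if sc.clutch.mother_id == plan.female_id]
            if len(scs) < 2:
                continue
            mom = study.mothers[plan.female_id]
            a1 = min_father_partition(
                paternal_allele_sets(mom, list(scs[0].clutch.hatchlings))
            )
            a2 = min_father_partition(
                paternal_allele_sets(mom, list(scs[1].clutch.hatchlings))
            )
            truth_shared = len(
                set(scs[0].true_fathers.values()) & set(scs[1].true_fathers.values())
            )
            total += 1
            ok += match_fathers(a1, a2).shared == truth_shared
        assert total >= 10
        assert ok / total >= 0.95


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(2, 9), st.integers(0, 2**31 - 1))
def test_partition_bounds_property(n, seed):
    """exact <= greedy and both >= pigeonhole bound, on random tables."""
    rng = np.random.default_rng(seed)
    table = random_candidate_table(rng, n)
    exact = min_father_partition(table, "exact", max_mutation_loci=0)
    greedy = min_father_partition(table, "greedy", max_mutation_loci=0)
    assert (
        pigeonhole_lower_bound(table)
        <= exact.father_count
        <= greedy.father_count
        <= n
    )
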