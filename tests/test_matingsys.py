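"""Clutch-pair similarity, chance-vs-remating tests, detection power, BSR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clutchkin import matingsys, paternity, simdata
from clutchkin.matingsys import (
    CHANCE_OR_DEPLETION,
    RETAINED,
    UNLIKELY_BY_CHANCE,
    breeding_sex_ratio,
    breeding_sex_ratio_from_counts,
    classify_transitions,
    detection_power,
    extrapolate_population,
    multiple_paternity_rate,
    prob_nonappearance,
    sorensen_qs,
)
from clutchkin.paternity import min_father_partition, paternal_allele_sets


class TestSorensenQS:
    def test_half_overlap_father_sets(self):
        # father sets {N, O} then {O, P}: two fathers each, one shared
        assert sorensen_qs(2, 2, 1) == pytest.approx(50.0)

    def test_identical_sets(self):
        assert sorensen_qs(3, 3, 3) == pytest.approx(100.0)

    def test_disjoint_sets(self):
        assert sorensen_qs(2, 4, 0) == pytest.approx(0.0)

    def test_shared_cannot_exceed_smaller_set(self):
        with pytest.raises(ValueError):
            sorensen_qs(2, 3, 3)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(1, 10), st.integers(1, 10), st.data())
    def test_symmetry_and_bounds(self, a, b, data):
        c = data.draw(st.integers(0, min(a, b)))
        qs = sorensen_qs(a, b, c)
        assert qs == sorensen_qs(b, a, c)
        assert 0.0 <= qs <= 100.0


class TestProbNonappearance:
    @pytest.mark.parametrize(
        "f, n, expected",
        [(1.0, 20, 0.0), (0.0, 20, 1.0), (0.5, 2, 0.25), (0.5, 20, 0.5**20)],
    )
    def test_values(self, f, n, expected):
        assert prob_nonappearance(f, n) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.floats(0.01, 0.98),
        st.floats(0.01, 0.98),
        st.integers(1, 50),
        st.integers(1, 50),
    )
    def test_strictly_decreasing_in_f_and_n(self, f1, df, n1, dn):
        f2 = min(f1 + df, 0.99)
        assert prob_nonappearance(f2, n1) < prob_nonappearance(f1, n1)
        assert prob_nonappearance(f1, n1 + dn) < prob_nonappearance(f1, n1)


def _assign(sizes, genotypes, order=1):
    groups = []
    start = 0
    for i, s in enumerate(sizes):
        groups.append(tuple(f"c{order}h{start + j}" for j in range(s)))
        start += s
    n = sum(sizes)
    return paternity.FatherAssignment(
        mother_id="mom",
        groups=tuple(groups),
        father_genotypes=tuple(genotypes),
        proportions=tuple(s / n for s in sizes),
        mp=paternity.MPCall(len(sizes) > 1, ()),
        method="exact",
        clutch_order=order,
    )


def _geno(*alleles):
    return {"L1": frozenset(alleles)}


class TestClassifyTransitions:
    def test_half_sired_father_absent_from_twenty_is_remating_consistent(self):
        a1 = _assign([10, 10], [_geno(1, 2), _geno(3, 4)], order=1)
        a2 = _assign([20], [_geno(3, 4)], order=2)
        recs = classify_transitions(a1, a2, f_mode="first-clutch")
        gone = [r for r in recs if r.status == "disappeared"]
        assert len(gone) == 1
        assert gone[0].p_f == pytest.approx(0.5**20)
        assert gone[0].classification == UNLIKELY_BY_CHANCE

    def test_minor_father_absent_from_ten_is_chance(self):
        a1 = _assign([19, 1], [_geno(1, 2), _geno(3, 4)], order=1)
        a2 = _assign([10], [_geno(1, 2)], order=2)
        recs = classify_transitions(a1, a2, f_mode="first-clutch")
        gone = [r for r in recs if r.status == "disappeared"]
        assert gone[0].f == pytest.approx(0.05)
        assert gone[0].p_f == pytest.approx(0.95**10)
        assert gone[0].classification == CHANCE_OR_DEPLETION

    def test_retained_father_gets_no_test(self):
        a1 = _assign([20], [_geno(1, 2)], order=1)
        a2 = _assign([20], [_geno(1, 2)], order=2)
        (rec,) = classify_transitions(a1, a2)
        assert rec.classification == RETAINED and rec.p_f is None

    def test_new_father_uses_combined_f_and_first_clutch_n(self):
        a1 = _assign([20], [_geno(1, 2)], order=1)
        a2 = _assign([8, 12], [_geno(1, 2), _geno(7, 8)], order=2)
        recs = classify_transitions(a1, a2, f_mode="first-clutch")
        new = [r for r in recs if r.status == "appeared"]
        assert len(new) == 1
        assert new[0].f == pytest.approx(12 / 40)
        assert new[0].n == 20
        assert new[0].classification == UNLIKELY_BY_CHANCE

    def test_empty_clutch_flagged(self):
        a1 = _assign([20], [_geno(1, 2)], order=1)
        a2 = paternity.FatherAssignment(
            mother_id="mom", groups=(), father_genotypes=(), proportions=(),
            mp=paternity.MPCall(False, ()), method="exact", clutch_order=2,
        )
        with pytest.raises(ValueError):
            classify_transitions(a1, a2)


class TestDetectionPower:
    def test_even_two_father_clutch_nearly_always_detected(self):
        power = detection_power([0.5, 0.5], 20)
        assert power == pytest.approx(1 - 2 * 0.5**20, abs=1e-12)

    def test_skewed_fathers_power(self):
        power = detection_power([0.9, 0.1], 20)
        assert power == pytest.approx(1 - 0.9**20 - 0.1**20, abs=1e-12)

    def test_single_hatchling_sample_has_no_power(self):
        assert detection_power([0.3, 0.3, 0.4], 1) == 0.0

    def test_single_father_returns_zero(self):
        assert detection_power([1.0], 20) == 0.0

    @pytest.mark.parametrize("props", [(0.5, 0.5), (0.9, 0.1), (0.6, 0.3, 0.1)])
    def test_simulation_agrees_with_analytic(self, props):
        reps = 10_000
        analytic = detection_power(props, 10, mode="analytic")
        sim = detection_power(props, 10, mode="simulation", reps=reps, seed=4)
        se = math.sqrt(max(analytic * (1 - analytic), 1e-9) / reps)
        assert abs(sim - analytic) <= 3 * se + 1e-12


class TestBreedingSexRatio:
    def test_counts_form(self):
        assert breeding_sex_ratio_from_counts([1, 1, 2]) == pytest.approx(4 / 3)

    def test_every_female_singly_mated_gives_one(self):
        per_female = {
            f"F{i}": [_assign([20], [_geno(10 * i, 10 * i + 1)], order=1)]
            for i in range(4)
        }
        assert breeding_sex_ratio(per_female) == pytest.approx(1.0)

    def test_stored_sperm_father_counted_once_across_clutches(self):
        g = _geno(1, 2)
        per_female = {"F1": [_assign([20], [g], 1), _assign([20], [g], 2)]}
        assert breeding_sex_ratio(per_female, scope="all-clutches") == 1.0

    def test_first_clutch_scope_ignores_later_clutches(self):
        per_female = {
            "F1": [
                _assign([20], [_geno(1, 2)], 1),
                _assign([10, 10], [_geno(1, 2), _geno(5, 6)], 2),
            ]
        }
        assert breeding_sex_ratio(per_female, "first-clutch-only") == 1.0
        assert breeding_sex_ratio(per_female, "all-clutches") == 2.0

    def test_recovers_true_ratio_on_simulation(self):
        study = simdata.sim_study(seed=31)
        per_female = {}
        for sc in study.sim_clutches:
            mom = study.mothers[sc.clutch.mother_id]
            table = paternal_allele_sets(mom, list(sc.clutch.hatchlings))
            assign = min_father_partition(table)
            import dataclasses

            assign = dataclasses.replace(assign, clutch_order=sc.clutch.order)
            per_female.setdefault(sc.clutch.mother_id, []).append(assign)
        est = breeding_sex_ratio(per_female, "all-clutches")
        true_bsr = sum(len(p.father_ids) for p in study.plans) / len(study.plans)
        # sampling may miss a rare father, never invent one (fathers unique
        # across females by construction here)
        assert est <= true_bsr + 1e-9
        assert est >= true_bsr - 0.2

    def test_mp_rate(self):
        assert multiple_paternity_rate([1, 1, 3, 2]) == pytest.approx(0.5)


class TestExtrapolation:
    def test_beach_wide_season_arithmetic(self):
        females, males = extrapolate_population(634, 3.9, 5.4, 1.46)
        assert females == (117, 163)
        assert males == (171, 238)

    def test_unit_frequency(self):
        assert extrapolate_population(100, 1, 1, 1.0) == ((100, 100), (100, 100))

    def test_males_increase_with_bsr(self):
        _, males_lo = extrapolate_population(500, 3.0, 5.0, 1.2)
        _, males_hi = extrapolate_population(500, 3.0, 5.0, 1.8)
        assert males_hi[0] >= males_lo[0] and males_hi[1] >= males_lo[1]

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_population(500, 0, 5.0, 1.2)


def test_fisher_comparison_returns_two_sided_p():
    p = matingsys.compare_bsr_fisher(25, 16, 23, 16)
    assert 0.0 <= p <= 1.0
    assert matingsys.compare_bsr_fisher(10, 10, 10, 10) == pytest.approx(1.0)
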