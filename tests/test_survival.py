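"""Survival-curve construction and the Gehan-Breslow curve comparison."""

import numpy as np
import pandas as pd
import pytest

from circafly import (SurvivalCohort, build_survival_curve, event_times,
                      gehan_wilcoxon_test)
from circafly.survival import DataIntegrityError
from circafly.synthetic import SurvivalSimSpec, simulate_survival


def cohort_from_counts(counts, days=None, n0=None, horizon=None, geno="g"):
    days = list(range(len(counts))) if days is None else days
    n0 = counts[0] if n0 is None else n0
    horizon = max(days) if horizon is None else horizon
    return SurvivalCohort(geno, [pd.Series(counts, index=days)], n0, horizon)


def test_curve_all_die_on_day_six():
    cohort = cohort_from_counts([20, 20, 20, 20, 20, 20, 0])
    c = build_survival_curve(cohort)
    np.testing.assert_allclose(c.surviving_fraction,
                               [1, 1, 1, 1, 1, 1, 0])
    assert c.median_lifespan_d == 6


def test_curve_fractions_and_median_from_direct_arithmetic():
    c = build_survival_curve(cohort_from_counts([20, 18, 12, 9, 4, 0]))
    np.testing.assert_allclose(c.surviving_fraction,
                               [1.0, 0.9, 0.6, 0.45, 0.2, 0.0])
    assert c.median_lifespan_d == 3   # first day with fraction <= 0.5


def test_curve_without_deaths_flags_median_absent():
    c = build_survival_curve(cohort_from_counts([20, 20, 20]))
    assert c.median_lifespan_d is None and not c.median_reached


def test_sparse_observations_carried_forward():
    cohort = cohort_from_counts([20, 14, 10], days=[0, 2, 4])
    c = build_survival_curve(cohort)
    np.testing.assert_allclose(c.surviving_fraction,
                               [1.0, 1.0, 0.7, 0.7, 0.5])
    # deaths land on the observation day closing each counting gap
    np.testing.assert_array_equal(c.deaths, [0, 0, 6, 0, 4])


def test_increasing_counts_rejected_with_location():
    with pytest.raises(DataIntegrityError, match="vial 0.*day 2"):
        cohort_from_counts([20, 15, 17, 10])


def test_death_reconstruction_conserves_flies():
    cohort, _ = simulate_survival(SurvivalSimSpec(seed=14), "x")
    c = build_survival_curve(cohort)
    final_alive = int(cohort.daily_alive().sum(axis=1).iloc[-1])
    assert int(c.deaths.sum()) == cohort.n_flies - final_alive
    t, e = event_times(cohort)
    assert t.size == cohort.n_flies
    assert int(e.sum()) == cohort.n_flies - final_alive


def gehan_pairwise_oracle(ta, ea, tb, eb):
    """Classic pairwise Gehan score sum: +1 when the A fly definitely
    outlives the B fly, -1 for the reverse, 0 when indeterminate."""
    total = 0
    for ti, ei in zip(ta, ea):
        for tj, ej in zip(tb, eb):
            if (tj < ti and ej == 1) or (tj == ti and ej == 1 and ei == 0):
                total += 1
            elif (ti < tj and ei == 1) or (ti == tj and ei == 1 and ej == 0):
                total -= 1
    return total


def test_gehan_u_matches_pairwise_oracle():
    for seed, med_a, med_b in [(1, 5, 8), (2, 6, 6), (3, 3, 12)]:
        a, _ = simulate_survival(
            SurvivalSimSpec(n_vials=1, flies_per_vial=12, horizon_d=15,
                            median_lifespan_d=med_a, seed=seed), "a")
        b, _ = simulate_survival(
            SurvivalSimSpec(n_vials=1, flies_per_vial=12, horizon_d=15,
                            median_lifespan_d=med_b, seed=seed + 50), "b")
        res = gehan_wilcoxon_test(a, b)
        ta, ea = event_times(a)
        tb, eb = event_times(b)
        assert res.statistic_u == pytest.approx(
            -gehan_pairwise_oracle(ta, ea, tb, eb))


def test_identical_cohorts_give_zero_statistic_and_p_one():
    cohort, _ = simulate_survival(SurvivalSimSpec(seed=4), "x")
    res = gehan_wilcoxon_test(cohort, cohort, mode="permutation",
                              n_perm=2000, seed=0)
    assert res.statistic_u == 0.0
    assert res.p_value == 1.0


def test_separated_cohorts_are_significant_in_both_modes():
    a = SurvivalCohort("a", [pd.Series({0: 20, 1: 0})] * 3, 20, 10)
    b = SurvivalCohort("b", [pd.Series({0: 20, 10: 0})] * 3, 20, 10)
    asym = gehan_wilcoxon_test(a, b)
    perm = gehan_wilcoxon_test(a, b, mode="permutation", n_perm=20000, seed=1)
    assert asym.p_value < 0.001
    assert perm.p_value < 0.001


def test_swapping_cohorts_negates_u_and_keeps_p():
    a, _ = simulate_survival(SurvivalSimSpec(median_lifespan_d=5, seed=6), "a")
    b, _ = simulate_survival(SurvivalSimSpec(median_lifespan_d=9, seed=7), "b")
    ab = gehan_wilcoxon_test(a, b)
    ba = gehan_wilcoxon_test(b, a)
    assert ab.statistic_u == pytest.approx(-ba.statistic_u)
    assert ab.p_value == pytest.approx(ba.p_value)


def test_permutation_agrees_with_asymptotic_at_small_n():
    a, _ = simulate_survival(
        SurvivalSimSpec(n_vials=1, flies_per_vial=15, median_lifespan_d=5,
                        horizon_d=20, seed=8), "a")
    b, _ = simulate_survival(
        SurvivalSimSpec(n_vials=1, flies_per_vial=15, median_lifespan_d=8,
                        horizon_d=20, seed=9), "b")
    asym = gehan_wilcoxon_test(a, b)
    perm = gehan_wilcoxon_test(a, b, mode="permutation", n_perm=20000, seed=2)
    assert perm.p_value == pytest.approx(asym.p_value, abs=0.03)


def test_matches_lifelines_generalized_wilcoxon():
    from lifelines.statistics import logrank_test

    a, _ = simulate_survival(SurvivalSimSpec(median_lifespan_d=6, seed=10), "a")
    b, _ = simulate_survival(SurvivalSimSpec(median_lifespan_d=9, seed=11), "b")
    res = gehan_wilcoxon_test(a, b)
    ta, ea = event_times(a)
    tb, eb = event_times(b)
    ref = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb,
                       weightings="wilcoxon")
    assert res.z ** 2 == pytest.approx(ref.test_statistic, rel=1e-9)
    assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)


def test_fully_censored_cohorts_warn_and_flag_p():
    a = cohort_from_counts([20, 20, 20])
    with pytest.warns(UserWarning, match="no deaths"):
        res = gehan_wilcoxon_test(a, a)
    assert np.isnan(res.p_value)


def test_heavy_censoring_warns():
    with pytest.warns(UserWarning, match="censored"):
        _, truth = simulate_survival(
            SurvivalSimSpec(median_lifespan_d=50, horizon_d=20, seed=1), "x")
    assert truth["heavy_censoring"]


def test_median_recovery_on_simulated_cohorts():
    hits = 0
    for seed in range(40):
        cohort, _ = simulate_survival(
            SurvivalSimSpec(median_lifespan_d=6, seed=seed), "x")
        med = build_survival_curve(cohort).median_lifespan_d
        hits += abs(med - 6) <= 1
    assert hits >= 36
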