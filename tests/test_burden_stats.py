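"""Burden point statistics (frozen against the printed cohort tables),
permutation and bootstrap behaviour, and group aggregation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trioburden.burden_stats import (
    BurdenInput,
    NormalizationMode,
    aggregate_burden,
    aggregate_from_totals,
    ascertainment_differential,
    bootstrap_ci,
    burden_from_totals,
    burden_test,
    compare_affected_groups,
    expected_count,
    percent_contributory,
    permutation_p,
)

NM = NormalizationMode


class TestPointStatistics:
    @pytest.mark.parametrize(
        "S_u, N_a, N_u, expected",
        [
            (157, 499, 484, 161.9),  # simplex LGD expectation, SYN-normalized
            (0, 123, 456, 0.0),
            (86, 1869, 1874, 85.8),  # all-CNV expectation, child-count-normalized
        ],
    )
    def test_expected_count(self, S_u, N_a, N_u, expected):
        assert round(expected_count(S_u, N_a, N_u), 1) == expected

    @pytest.mark.parametrize(
        "S_a, ES_a, C_a, expected",
        [
            (283, 157 * 499 / 484, 1869, 6.48),
            (100, 100.0, 50, 0.0),
            (116, 157 * 309 / 484, 1107, 1.42),
        ],
    )
    def test_ascertainment_differential(self, S_a, ES_a, C_a, expected):
        assert round(ascertainment_differential(S_a, ES_a, C_a), 2) == expected

    @pytest.mark.parametrize(
        "S_a, ES_a, expected",
        [
            (283, 157 * 499 / 484, 42.8),
            (50, 50.0, 0.0),
            (26, 11 * 1869 / 1874, 57.8),
        ],
    )
    def test_percent_contributory(self, S_a, ES_a, expected):
        assert round(percent_contributory(S_a, ES_a), 1) == expected

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            expected_count(1, 1, 0)
        with pytest.raises(ValueError):
            ascertainment_differential(1, 1.0, 0)
        with pytest.raises(ValueError):
            percent_contributory(0, 1.0)

    @given(scale=st.integers(min_value=1, max_value=50))
    @settings(max_examples=20, derandomize=True)
    def test_scale_invariance_of_ad(self, scale):
        """Multiplying every child's normalization count by a constant leaves
        the AD unchanged."""
        rng = np.random.default_rng(0)
        sa, su = rng.poisson(0.2, 100), rng.poisson(0.2, 100)
        na, nu = rng.poisson(2.0, 100) + 1, rng.poisson(2.0, 100) + 1
        r1 = burden_from_totals(su.sum(), sa.sum(), nu.sum(), na.sum(), 100)
        r2 = burden_from_totals(su.sum(), sa.sum(), scale * nu.sum(), scale * na.sum(), 100)
        assert r1.AD == pytest.approx(r2.AD)

    def test_monotone_in_subject_count(self):
        prev = burden_from_totals(100, 100, 500, 500, 200)
        for s_a in (120, 150, 200):
            cur = burden_from_totals(100, s_a, 500, 500, 200)
            assert cur.AD > prev.AD and cur.PC > prev.PC
            prev = cur


def _random_input(rng, n_a=300, n_u=300, s_rate=0.1, n_rate=0.3, planted=0.0):
    sa = rng.poisson(s_rate, n_a)
    if planted:
        sa = sa + (rng.random(n_a) < planted / 100.0)
    return BurdenInput(
        sa,
        rng.poisson(s_rate, n_u),
        rng.poisson(n_rate, n_a),
        rng.poisson(n_rate, n_u),
    )


def exhaustive_permutation_p(inp: BurdenInput) -> float:
    """Oracle: the exact label-permutation distribution of the AD (no normal
    fit), feasible for <= 8 children."""
    S = np.concatenate([inp.subject_a, inp.subject_u]).astype(float)
    N = np.concatenate([inp.norm_a, inp.norm_u]).astype(float)
    n, C_a = len(S), inp.C_a
    obs = 100.0 * (inp.subject_a.sum()
                   - inp.subject_u.sum() * inp.norm_a.sum() / inp.norm_u.sum()) / C_a
    ads = []
    for comb in itertools.combinations(range(n), C_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        N_u = N[~mask].sum()
        if N_u == 0:
            continue
        ads.append(100.0 * (S[mask].sum() - S[~mask].sum() * N[mask].sum() / N_u) / C_a)
    ads = np.array(ads)
    return float(np.mean(ads >= obs - 1e-12))


class TestPermutation:
    def test_fitted_normal_brackets_exhaustive_oracle(self):
        """On 8-child cohorts the fitted-normal p stays within 0.1 of the
        exact permutation p."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            sa = rng.poisson(2.0, 4)
            su = rng.poisson(1.0, 4)
            na = rng.poisson(3.0, 4) + 1
            nu = rng.poisson(3.0, 4) + 1
            inp = BurdenInput(sa, su, na, nu)
            p_norm = permutation_p(inp, n_perm=4000, seed=1)
            p_exact = exhaustive_permutation_p(inp)
            assert abs(p_norm - p_exact) <= 0.1

    def test_observed_at_permutation_mean_gives_half(self):
        """Symmetry of the fitted normal: an observation at the null mean has
        one-sided p of exactly 1/2."""
        from trioburden.burden_stats import _normal_upper_tail, _permuted_ads

        rng = np.random.default_rng(21)
        inp = _random_input(rng, n_a=500, n_u=500)
        null = _permuted_ads(inp, 2000, np.random.default_rng(3))
        assert _normal_upper_tail(float(null.mean()), null) == pytest.approx(0.5)

    def test_null_p_is_roughly_uniform(self):
        """Under exchangeable groups the one-sided p is uniform: the median
        over replicate null cohorts sits centrally."""
        ps = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            inp = _random_input(rng, n_a=400, n_u=400)
            ps.append(permutation_p(inp, n_perm=500, seed=rep))
        assert 0.25 < float(np.median(ps)) < 0.75

    def test_degenerate_distribution_warns_p_one(self):
        inp = BurdenInput(np.zeros(10, int), np.zeros(10, int),
                          np.ones(10, int), np.ones(10, int))
        with pytest.warns(UserWarning, match="degenerate"):
            assert permutation_p(inp, n_perm=200, seed=0) == 1.0

    def test_planted_signal_is_detected(self, rng):
        inp = _random_input(rng, n_a=1869, n_u=1874, s_rate=0.084, n_rate=0.26, planted=6.0)
        assert permutation_p(inp, n_perm=1000, seed=4) < 1e-3


class TestBootstrap:
    def test_identical_children_give_zero_width_ci(self):
        inp = BurdenInput(np.ones(50, int), np.ones(60, int),
                          np.full(50, 2), np.full(60, 2))
        ad_ci, pc_ci = bootstrap_ci(inp, n_boot=500, seed=0)
        point = burden_from_totals(60, 50, 120, 100, 50).AD
        assert ad_ci[0] == pytest.approx(ad_ci[1]) == pytest.approx(point)
        assert pc_ci[0] == pytest.approx(pc_ci[1])

    def test_bootstrap_does_not_perturb_permutation_p(self, rng):
        inp = _random_input(rng)
        r1 = burden_test(inp, n_perm=500, n_boot=10, seed=9)
        r2 = burden_test(inp, n_perm=500, n_boot=1000, seed=9)
        assert r1.p_value == r2.p_value


class TestGroupComparison:
    def test_identically_distributed_groups_give_central_p(self):
        ps = []
        for rep in range(15):
            rng = np.random.default_rng(500 + rep)
            i1 = _random_input(rng, n_a=400)
            i2 = _random_input(rng, n_a=400)
            ps.append(compare_affected_groups(i1, i2, n_perm=500, seed=rep))
        assert 0.25 < float(np.median(ps)) < 0.75

    def test_label_swap_flips_p(self, rng):
        i1 = _random_input(rng, n_a=400, planted=5.0)
        i2 = _random_input(rng, n_a=400)
        p12 = compare_affected_groups(i1, i2, n_perm=4000, seed=6)
        p21 = compare_affected_groups(i2, i1, n_perm=4000, seed=6)
        assert p12 + p21 == pytest.approx(1.0, abs=0.05)


class TestAggregation:
    def test_single_class_aggregate_reduces_to_plain_result(self, rng):
        inp = _random_input(rng)
        agg = aggregate_burden([inp], n_perm=300, n_boot=300, seed=7)
        plain = burden_from_totals(*(lambda t: (t[1], t[0], t[3], t[2]))(inp.totals()),
                                   C_a=inp.C_a)
        assert agg.AD == pytest.approx(plain.AD)
        assert agg.ES_a == pytest.approx(plain.ES_a)

    def test_mixed_normalization_totals_match_published_aggregates(self):
        """LGD (event-class) plus coding CNVs (child-count) reproduce the
        printed simplex 9.80% and multiplex 2.15% aggregated differentials
        from full-precision expectations."""
        ssc = aggregate_from_totals(
            [(157, 283, 484, 499, NM.EVENT_CLASS), (44, 106, 0, 0, NM.CHILD_COUNT)],
            C_a=1869, C_u=1874,
        )
        assert round(ssc.ES_a, 1) == 205.7 and round(ssc.AD, 2) == 9.80
        agre = aggregate_from_totals(
            [(157, 116, 484, 309, NM.EVENT_CLASS), (44, 34, 0, 0, NM.CHILD_COUNT)],
            C_a=1107, C_u=1874,
        )
        assert round(agre.AD, 2) == 2.15

    def test_mismatched_cohorts_rejected(self, rng):
        with pytest.raises(ValueError, match="same cohorts"):
            aggregate_burden([_random_input(rng, n_a=10), _random_input(rng, n_a=12)])

    def test_joint_permutation_runs_on_two_classes(self, rng):
        i1 = _random_input(rng, planted=4.0)
        i2 = BurdenInput(rng.poisson(0.05, 300), rng.poisson(0.05, 300),
                         np.ones(300), np.ones(300), mode=NM.CHILD_COUNT)
        res = aggregate_burden([i1, i2], n_perm=500, n_boot=500, seed=8)
        assert res.S_a == i1.subject_a.sum() + i2.subject_a.sum()
        assert 0.0 <= res.p_value <= 1.0
        assert res.AD_ci95[0] <= res.AD <= res.AD_ci95[1]
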