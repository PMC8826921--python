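"""Univariate statistics against independent oracles and their invariances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metabofp as m
from metabofp.synthetic import CohortConfig, simulate_cohort
from metabofp.univariate import (
    bh_adjust,
    cliffs_delta,
    log2_fold_change,
    univariate_profile,
    wilcoxon_rank_sum,
    FoldChangeError,
)


# -- independent oracles ------------------------------------------------------

def cliffs_delta_bruteforce(a, b):
    gt = sum(1 for x in a for y in b if x > y)
    lt = sum(1 for x in a for y in b if x < y)
    return (gt - lt) / (len(a) * len(b))


def wilcoxon_exact_bruteforce(a, b):
    """Full enumeration over label assignments of the pooled sample: two-sided
    p = fraction of assignments with |U - n1*n2/2| at least as extreme."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(idx_a):
        xs = [pooled[i] for i in idx_a]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx_a]
        return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in xs for y in ys)

    center = na * (len(b)) / 2.0
    obs = abs(u_stat(tuple(range(na))) - center)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        total += 1
        if abs(u_stat(comb) - center) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_small_exact_example(self):
        # a={1,2}, b={3,4}: 2 of the 6 label assignments are as extreme
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_samples_give_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_agrees_with_permutation_oracle(self, rng):
        for _ in range(100):
            na, nb = rng.integers(2, 5, size=2)
            a = rng.normal(size=na).round(3)
            b = rng.normal(size=nb).round(3)
            if np.unique(np.concatenate([a, b])).size < na + nb:
                continue  # oracle and exact rule both assume no ties
            assert wilcoxon_rank_sum(a, b) == pytest.approx(
                wilcoxon_exact_bruteforce(a, b), abs=1e-12
            )

    def test_monotone_transform_invariance(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=15) + 0.5
        assert wilcoxon_rank_sum(a, b) == pytest.approx(
            wilcoxon_rank_sum(np.exp(a), np.exp(b))
        )

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBhAdjust:
    def test_step_up_worked_example(self):
        # hand application of the step-up rule: all adjusted to 0.04
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_output_dominates_input_and_capped(self, p):
        out = bh_adjust(p)
        assert np.all(out >= np.asarray(p) - 1e-12)
        assert np.all(out <= 1.0)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.random(25)
        out = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(out[order]) >= -1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "case,control,expected",
        [([2, 2, 2], [8, 8, 8], -2.0), ([5, 5], [5, 5], 0.0), ([3, 3], [1, 1], np.log2(3))],
    )
    def test_worked_examples(self, case, control, expected):
        assert log2_fold_change(case, control) == pytest.approx(expected)

    def test_nonpositive_median_raises(self):
        with pytest.raises(FoldChangeError):
            log2_fold_change([0.0, 0.0, 0.0], [1.0, 2.0])


class TestCliffsDelta:
    def test_complete_dominance(self):
        d, mag = cliffs_delta([5, 6, 7], [1, 2, 3])
        assert d == 1.0 and mag == "large"

    def test_identical_multisets(self):
        d, mag = cliffs_delta([1, 2, 2], [1, 2, 2])
        assert d == 0.0 and mag == "negligible"

    def test_worked_example_with_ties(self):
        # pairs: 1 greater, 6 less, 2 ties -> delta = -5/9
        d, mag = cliffs_delta([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(-5 / 9)
        assert mag == "large"

    def test_agrees_with_bruteforce_on_random_instances(self, rng):
        for _ in range(200):
            na, nb = rng.integers(1, 16, size=2)
            a = rng.integers(0, 8, size=na).astype(float)
            b = rng.integers(0, 8, size=nb).astype(float)
            d, _ = cliffs_delta(a, b)
            assert d == pytest.approx(cliffs_delta_bruteforce(a, b), abs=1e-12)

    def test_antisymmetry_and_monotone_invariance(self, rng):
        a, b = rng.normal(size=9), rng.normal(size=11)
        d_ab, _ = cliffs_delta(a, b)
        d_ba, _ = cliffs_delta(b, a)
        assert d_ab == pytest.approx(-d_ba)
        d_t, _ = cliffs_delta(np.exp(a), np.exp(b))
        assert d_t == pytest.approx(d_ab)

    @pytest.mark.parametrize(
        "delta,expected",
        [(0.10, "negligible"), (0.2, "small"), (0.4, "medium"), (0.6, "large")],
    )
    def test_romano_magnitude_thresholds(self, delta, expected):
        # construct two-point samples realizing the requested delta
        n = 100
        k = int(round(n * (1 + delta) / 2))
        a = [1.0] * k + [-1.0] * (n - k)
        b = [0.0] * n
        d, mag = cliffs_delta(a, b)
        assert d == pytest.approx(delta, abs=1e-9)
        assert mag == expected


class TestUnivariateProfile:
    def test_planted_male_signature_recovered_at_study_sizes(self):
        # 26 planted analytes at the study's male stratum (40 vs 36):
        # high recovery, few false flags, directions match the planting
        recovered, false_flags = [], []
        for seed in range(6):
            table, _ = simulate_cohort(m.study_config("training", seed=300 + seed))
            res = univariate_profile(table, "dn2PD", "CTR", sex_filter="M")
            sig = set(res.significant["analyte"])
            planted = set(m.analytes.MALE_SIGNATURE)
            recovered.append(len(sig & planted))
            false_flags.append(len(sig - planted - set(m.analytes.PROGRESSION_DOWN)
                                   - set(m.analytes.DN2PD_SPECIFIC_UP)))
            fc = res.table.set_index("analyte")["log2fc"]
            assert all(fc[n] > 0 for n in m.analytes.MALE_SIGNATURE_UP)
            assert all(fc[n] < 0 for n in m.analytes.MALE_SIGNATURE_DOWN)
        assert np.mean(recovered) >= 20
        assert np.mean(false_flags) <= 2

    def test_null_female_stratum_is_quiet(self):
        # zero-effect stratum: BH keeps false findings near zero
        counts = []
        for seed in range(5):
            cfg = CohortConfig(
                n_per_group_per_sex={("dn2PD", "F"): 32, ("CTR", "F"): 23},
                effect_table={},
                seed=400 + seed,
            )
            table, _ = simulate_cohort(cfg)
            res = univariate_profile(table, "dn2PD", "CTR", sex_filter="F")
            counts.append(len(res.significant))
        assert np.mean(counts) <= 1.0

    def test_fdr_family_is_all_analytes(self, small_cohort):
        table, _ = small_cohort
        res = univariate_profile(table, "dn2PD", "CTR", sex_filter="M")
        assert len(res.table) == 138
        assert np.allclose(
            res.table["fdr"].to_numpy(), bh_adjust(res.table["p_value"].to_numpy())
        )

    def test_empty_stratum_raises(self, small_cohort):
        table, _ = small_cohort
        with pytest.raises(ValueError):
            univariate_profile(table, "advPD", "CTR", sex_filter="M")
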