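"""Feature ranking and Ward/Pearson clustering, checked against a naive
agglomeration oracle."""

import numpy as np
import pytest

import metabofp as m
from metabofp.profiling import (
    HeatmapResult,
    ZeroVarianceProfileError,
    heatmap_summary,
    linkage_to_newick,
    pearson_distance_matrix,
    rank_top_features,
    ward_cluster,
)
from metabofp.synthetic import CohortConfig, simulate_cohort


def ward_oracle(d0: np.ndarray) -> np.ndarray:
    """Naive O(n^3) Ward agglomeration by the Lance-Williams recurrence."""
    n = d0.shape[0]
    d = d0.astype(float).copy()
    active = {i: (i, 1) for i in range(n)}  # slot -> (cluster id, size)
    merges = []
    next_id = n
    for step in range(n - 1):
        slots = sorted(active)
        best = None
        for ii, a in enumerate(slots):
            for b in slots[ii + 1:]:
                if best is None or d[a, b] < best[0]:
                    best = (d[a, b], a, b)
        h, a, b = best
        (ida, na), (idb, nb) = active[a], active[b]
        merges.append([min(ida, idb), max(ida, idb), h, na + nb])
        # Lance-Williams Ward update against every other active slot
        for c in slots:
            if c in (a, b):
                continue
            nc = active[c][1]
            tot = na + nb + nc
            new = np.sqrt(
                ((na + nc) * d[a, c] ** 2 + (nb + nc) * d[b, c] ** 2 - nc * d[a, b] ** 2)
                / tot
            )
            d[a, c] = d[c, a] = new
        active[a] = (next_id, na + nb)
        del active[b]
        next_id += 1
    return np.array(merges)


class TestRankTopFeatures:
    def _three_group_table(self, seed=0, planted_sd=5.0):
        cfg = CohortConfig(
            n_per_group_per_sex={("CTR", "M"): 20, ("dn2PD", "M"): 20, ("advPD", "M"): 20},
            effect_table={("dn2PD", "M"): {"Acetone": planted_sd * 0.25 / np.log(2)}},
            seed=seed,
        )
        return simulate_cohort(cfg)[0]

    def test_planted_five_sd_shift_ranks_first(self):
        firsts = 0
        for seed in range(5):
            table = self._three_group_table(seed=seed)
            df = rank_top_features(table, ["CTR", "dn2PD", "advPD"], k=10)
            firsts += int(df.iloc[0].analyte == "Acetone")
        assert firsts == 5

    def test_fewer_analytes_than_k_returns_all_ranked(self):
        table = self._three_group_table()
        df = rank_top_features(table, ["CTR", "dn2PD"], k=10_000)
        assert len(df) == 138
        assert np.all(np.diff(df["min_pairwise_p"].to_numpy()) >= 0)

    def test_default_k_is_30(self, small_cohort):
        table, _ = small_cohort
        assert len(rank_top_features(table, ["CTR", "dn2PD"])) == 30

    def test_ranking_invariant_to_analyte_order(self):
        table = self._three_group_table(seed=3)
        perm = np.random.default_rng(0).permutation(len(table.analyte_names))
        shuffled = m.ConcentrationTable(
            table.values[:, perm], [table.analyte_names[i] for i in perm], table.meta
        )
        a = rank_top_features(table, ["CTR", "dn2PD", "advPD"], k=15)
        b = rank_top_features(shuffled, ["CTR", "dn2PD", "advPD"], k=15)
        assert a["analyte"].tolist() == b["analyte"].tolist()

    def test_bad_k_raises(self, small_cohort):
        with pytest.raises(ValueError):
            rank_top_features(small_cohort[0], ["CTR", "dn2PD"], k=0)


class TestWardCluster:
    def test_identical_profiles_merge_first_at_height_zero(self, rng):
        base = rng.random(8)
        mat = np.vstack([base, base, rng.random(8) + 5 * np.arange(8), rng.random(8)])
        link = ward_cluster(mat, axis=0)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}
        assert link[0, 2] == pytest.approx(0.0, abs=1e-8)

    def test_anticorrelated_profiles_at_distance_two(self):
        x = np.linspace(0, 1, 10)
        d = pearson_distance_matrix(np.vstack([x, -x]))
        assert d[0, 1] == pytest.approx(2.0)

    def test_merge_tree_matches_naive_oracle(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            mat = r.standard_normal((10, 12))
            d = pearson_distance_matrix(mat)
            ours = ward_cluster(mat, axis=0)
            ref = ward_oracle(d)
            assert np.allclose(ours[:, 2], ref[:, 2], atol=1e-8)  # heights
            assert np.array_equal(ours[:, 3], ref[:, 3])  # sizes
            # same partition sequence: compare merged leaf sets at each step
            assert _partition_trace(ours, 10) == _partition_trace(ref, 10)

    def test_heights_nondecreasing(self, rng):
        mat = rng.standard_normal((15, 9))
        link = ward_cluster(mat, axis=0)
        assert np.all(np.diff(link[:, 2]) >= -1e-10)

    def test_zero_variance_profile_flagged(self):
        mat = np.vstack([np.ones(6), np.arange(6.0), np.arange(6.0) ** 2])
        with pytest.raises(ZeroVarianceProfileError):
            ward_cluster(mat, axis=0)


def _partition_trace(link, n):
    """Frozenset-of-leafsets after each merge, for tree comparison."""
    members = {i: frozenset([i]) for i in range(n)}
    trace = []
    for i, (a, b, _, _) in enumerate(link):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        trace.append(merged)
    return trace


class TestHeatmapSummary:
    @pytest.fixture(scope="class")
    def progression_cohort(self):
        cfg = m.study_config("validation", seed=77)
        return simulate_cohort(cfg)[0]

    def test_progression_block_monotone_across_groups(self, progression_cohort):
        hm = heatmap_summary(progression_cohort, ["CTR", "dn2PD", "advPD"], k=30)
        gm = hm.group_means
        present = [n for n in m.analytes.PROGRESSION_DOWN if n in gm.index]
        assert len(present) >= 3
        mono = sum(gm.loc[n, "CTR"] > gm.loc[n, "dn2PD"] > gm.loc[n, "advPD"]
                   for n in present)
        assert mono >= 0.7 * len(present)

    def test_planted_pd_split_joins_pd_groups_first(self):
        # planted CTR-vs-PD split: both PD groups carry (nearly) the same
        # shift pattern, so the column dendrogram should pair them before CTR
        joins = 0
        for seed in range(5):
            effects = m.synthetic.study_effect_table(dn2pd_specific_up=0.0)
            male = effects[("dn2PD", "M")]
            effects[("advPD", "M")] = {k: 1.1 * v for k, v in male.items()}
            effects[("advPD", "F")] = dict(effects[("advPD", "M")])
            cfg = simulate_cohort(
                m.CohortConfig(
                    n_per_group_per_sex={(g, "M"): 30 for g in
                                         ("CTR", "dn2PD", "advPD")},
                    effect_table=effects,
                    seed=500 + seed,
                )
            )[0]
            hm = heatmap_summary(cfg, ["CTR", "dn2PD", "advPD"], k=30)
            first = {int(hm.col_linkage[0, 0]), int(hm.col_linkage[0, 1])}
            joins += int(first == {1, 2})  # columns ordered CTR, dn2PD, advPD
        assert joins >= 4

    def test_deterministic_and_shapes(self, progression_cohort):
        h1 = heatmap_summary(progression_cohort, ["CTR", "dn2PD", "advPD"], k=12)
        h2 = heatmap_summary(progression_cohort, ["CTR", "dn2PD", "advPD"], k=12)
        assert isinstance(h1, HeatmapResult)
        assert h1.analytes == h2.analytes
        assert np.array_equal(h1.row_linkage, h2.row_linkage)
        assert h1.group_means.shape == (12, 3)

    def test_newick_serialization_roundtrips_labels(self, progression_cohort):
        hm = heatmap_summary(progression_cohort, ["CTR", "dn2PD", "advPD"], k=5)
        nwk = linkage_to_newick(hm.col_linkage, list(hm.group_means.columns))
        assert nwk.endswith(";")
        for g in ("CTR", "dn2PD", "advPD"):
            assert g in nwk
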