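"""Coalescent simulator: closed-form expectations, structure, serialization."""

import math

import numpy as np
import pytest

from genomesim.coalescent import (
    CoalescentError,
    Demography,
    Epoch,
    Genealogy,
    PopulationStructure,
    RecombinationMap,
    SampleConfig,
    load_user_tree,
    simulate_arg,
    simulate_genealogy,
    tmrca,
    total_branch_length,
)

N = 1000.0
DEM = Demography.constant(N)


def mean_tmrca(n, reps, seed, demography=DEM, structure=None, sample=None):
    rng = np.random.default_rng(seed)
    sc = sample or SampleConfig.contemporaneous(n)
    vals = [
        tmrca(simulate_genealogy(sc, demography, structure, rng=rng))
        for _ in range(reps)
    ]
    return np.mean(vals), np.std(vals, ddof=1) / math.sqrt(reps)


class TestClosedForms:
    def test_pairwise_tmrca_is_2N(self):
        m, se = mean_tmrca(2, 3000, seed=1)
        assert abs(m - 2 * N) < 4 * se

    def test_n15_tmrca(self):
        # E[TMRCA] = 4N(1 - 1/n)
        m, se = mean_tmrca(15, 3000, seed=2)
        assert abs(m - 4 * N * (1 - 1 / 15)) < 4 * se

    def test_n15_total_length(self):
        rng = np.random.default_rng(3)
        sc = SampleConfig.contemporaneous(15)
        vals = [
            total_branch_length(simulate_genealogy(sc, DEM, rng=rng))
            for _ in range(3000)
        ]
        expect = 4 * N * sum(1 / k for k in range(1, 15))
        assert abs(np.mean(vals) - expect) < 4 * np.std(vals, ddof=1) / math.sqrt(len(vals))

    def test_single_sample_degenerates(self, rng):
        g = simulate_genealogy(SampleConfig.contemporaneous(1), DEM, rng=rng)
        assert g.n_leaves == 1
        assert tmrca(g) == 0.0


class TestDemography:
    def test_growth_shrinks_tmrca(self):
        grown = Demography((Epoch(0.0, math.inf, {"pop": N}, {"pop": 0.005}),))
        m_g, se_g = mean_tmrca(10, 1500, seed=4, demography=grown)
        m_c, se_c = mean_tmrca(10, 1500, seed=5)
        assert m_g + 4 * se_g < m_c  # strong growth: stochastically smaller

    def test_epoch_bottleneck_accelerates_coalescence(self):
        # recent small epoch then large ancestral size
        dem = Demography(
            (
                Epoch(0.0, 500.0, {"pop": 50.0}),
                Epoch(500.0, math.inf, {"pop": N}),
            )
        )
        m, _ = mean_tmrca(2, 1500, seed=6, demography=dem)
        # P(coalesce in epoch) = 1 - exp(-500/(2*50)); afterwards mean 500 + 2N
        p = 1 - math.exp(-500 / 100.0)
        expect = p * 100.0 * (1 - (1 + 5.0) * math.exp(-5.0)) / p if False else None
        # direct numeric expectation by integration
        ts = np.linspace(0, 500, 20001)
        dens = np.exp(-ts / 100.0) / 100.0
        expect = float(np.trapezoid(ts * dens, ts)) + (1 - p) * (500.0 + 2 * N)
        assert abs(m - expect) < 0.1 * expect

    def test_invalid_epochs_rejected(self):
        with pytest.raises(ValueError):
            Demography((Epoch(0.0, 100.0, {"pop": N}),))  # does not reach inf
        with pytest.raises(ValueError):
            Demography((Epoch(0.0, math.inf, {"pop": -5.0}),))


class TestStructure:
    def test_island_model_matches_first_step_analysis(self):
        # 2 demes, one lineage each, per-lineage emigration rate m.
        m_rate = 1e-3
        struct = PopulationStructure.island(2, m_rate)
        sample = SampleConfig(groups=(("deme0", 0.0, 1), ("deme1", 0.0, 1)))
        dem = Demography.constant(N, demes=("deme0", "deme1"))
        # first-step equations: E[T_diff] = 1/(2m) + E[T_same];
        # E[T_same] = (1 + 2m E[T_diff]) / (c + 2m), c = 1/(2N)
        c = 1 / (2 * N)
        A = np.array([[1.0, -1.0], [-2 * m_rate / (c + 2 * m_rate), 1.0]])
        b = np.array([1 / (2 * m_rate), 1 / (c + 2 * m_rate)])
        t_diff, _t_same = np.linalg.solve(A, b)
        rng = np.random.default_rng(7)
        vals = [
            tmrca(simulate_genealogy(sample, dem, struct, rng=rng))
            for _ in range(2000)
        ]
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert abs(np.mean(vals) - t_diff) < 4 * se

    def test_disconnected_demes_fail_fast(self):
        # zero migration, no splits: cannot guarantee one final deme
        with pytest.raises(ValueError):
            PopulationStructure(demes=("a", "b"))

    def test_population_split_merges_lineages(self):
        from genomesim.coalescent import SplitEvent

        struct = PopulationStructure(
            demes=("a", "b"),
            splits=(SplitEvent(500.0, ("a", "b"), "anc"),),
        )
        dem = Demography.constant(N, demes=("a", "b", "anc"))
        sample = SampleConfig(groups=(("a", 0.0, 2), ("b", 0.0, 2)))
        rng = np.random.default_rng(8)
        g = simulate_genealogy(sample, dem, struct, rng=rng)
        assert g.n_leaves == 4
        assert tmrca(g) > 0


class TestSerialSampling:
    def test_leaf_times_match_configuration(self, rng):
        sc = SampleConfig(groups=(("pop", 0.0, 3), ("pop", 500.0, 2)))
        g = simulate_genealogy(sc, DEM, rng=rng)
        assert sorted(g.time[g.leaf_indices]) == [0.0, 0.0, 0.0, 500.0, 500.0]

    def test_serial_leaf_branch_shortened(self, rng):
        # ancient leaf's branch is its parent time minus 500, not minus 0
        sc = SampleConfig(groups=(("pop", 0.0, 1), ("pop", 500.0, 1)))
        g = simulate_genealogy(sc, DEM, rng=rng)
        old = [i for i in g.leaf_indices if g.time[i] == 500.0][0]
        new = [i for i in g.leaf_indices if g.time[i] == 0.0][0]
        assert g.branch_lengths[new] - g.branch_lengths[old] == pytest.approx(500.0)

    def test_serial_pair_mean_tmrca(self):
        # lineages can only coalesce after the older sample activates:
        # E[TMRCA] = 500 + 2N
        sc = SampleConfig(groups=(("pop", 0.0, 1), ("pop", 500.0, 1)))
        m, se = mean_tmrca(2, 2000, seed=11, sample=sc)
        assert abs(m - (500 + 2 * N)) < 4 * se


class TestNewick:
    def test_arithmetic_example(self):
        g = load_user_tree("((A:0.1,B:0.1):0.05,C:0.15);")
        assert g.n_leaves == 3
        assert tmrca(g) == pytest.approx(0.15)
        assert total_branch_length(g) == pytest.approx(0.4)

    def test_two_leaf_tmrca_and_length(self):
        g = load_user_tree("(a:1500,b:1500);", units="generations")
        assert tmrca(g) == pytest.approx(1500)
        assert total_branch_length(g) == pytest.approx(3000)

    def test_roundtrip_identity(self, small_tree):
        text = small_tree.newick()
        again = load_user_tree(text, units="generations")
        assert again.newick() == text

    def test_internal_names_preserved(self):
        g = load_user_tree("((A:0.1,B:0.1)AB:0.05,C:0.15)root;")
        assert "AB" in g.labels and "root" in g.labels

    def test_malformed_raises(self):
        with pytest.raises(ValueError):
            load_user_tree("((A:0.1,B:0.1:0.05,C;")


class TestRecombination:
    def test_zero_rate_single_interval(self, rng):
        mts = simulate_arg(
            SampleConfig.contemporaneous(5), DEM, recmap=None, L=300, rng=rng
        )
        assert mts.intervals == [(0, 300)]
        assert mts.n_recombination_events == 0

    def test_rate_requires_two_sites(self, rng):
        rm = RecombinationMap(rate=1e-5, length=1)
        with pytest.raises(ValueError):
            simulate_arg(SampleConfig.contemporaneous(2), DEM, recmap=rm, L=1, rng=rng)

    def test_intervals_tile_and_trees_valid(self, rng):
        rm = RecombinationMap(rate=2e-5, length=400)
        mts = simulate_arg(
            SampleConfig.contemporaneous(6), DEM, recmap=rm, L=400, rng=rng
        )
        assert mts.intervals[0][0] == 0 and mts.intervals[-1][1] == 400
        for (a, b), (c, _) in zip(mts.intervals, mts.intervals[1:]):
            assert b == c
        for t in mts.trees:
            assert t.n_leaves == 6
            assert sorted(t.leaf_labels) == [f"s{i}" for i in range(6)]

    def test_hotspot_attracts_breakpoints(self):
        # multiplier 10 over 10% of the region: a breakpoint lands in the
        # hotspot with probability 10*0.1 / (10*0.1 + 0.9). The first event
        # of each replicate is the clean oracle (the ancestral span is still
        # the whole region then; later events see fragmented spans).
        rng = np.random.default_rng(13)
        L = 1000
        rm = RecombinationMap(rate=2e-6, length=L, hotspots=((450, 550, 10.0),))
        firsts = []
        for _ in range(400):
            mts = simulate_arg(
                SampleConfig.contemporaneous(4), DEM, recmap=rm, L=L, rng=rng
            )
            if mts.breakpoint_positions:
                firsts.append(mts.breakpoint_positions[0])
        expect = 1.0 / (1.0 + 0.9)
        frac = np.mean([450 <= b < 550 for b in firsts])
        se = math.sqrt(expect * (1 - expect) / len(firsts))
        assert abs(frac - expect) < 4 * se

    def test_marginal_tmrca_correlation_decays_with_distance(self):
        rng = np.random.default_rng(14)
        L = 2000
        rm = RecombinationMap(rate=5e-6, length=L)
        t_near, t_far, t_ref = [], [], []
        for _ in range(150):
            mts = simulate_arg(
                SampleConfig.contemporaneous(4), DEM, recmap=rm, L=L, rng=rng
            )
            t_ref.append(tmrca(mts.tree_at(0)))
            t_near.append(tmrca(mts.tree_at(50)))
            t_far.append(tmrca(mts.tree_at(L - 1)))
        r_near = np.corrcoef(t_ref, t_near)[0, 1]
        r_far = np.corrcoef(t_ref, t_far)[0, 1]
        assert r_near > r_far

    def test_same_point_identical_tree(self, rng):
        rm = RecombinationMap(rate=1e-5, length=300)
        mts = simulate_arg(
            SampleConfig.contemporaneous(4), DEM, recmap=rm, L=300, rng=rng
        )
        a, b = mts.intervals[0]
        assert mts.tree_at(a) is mts.tree_at(b - 1)
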