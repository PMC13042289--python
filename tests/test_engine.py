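"""Breeding-cycle operations and full-simulation behavior."""

import numpy as np
import pytest

from enksim.engine import (
    CycleRecord,
    SimulationConfig,
    StructureConfig,
    add_entry_mean_noise,
    effective_parent_number,
    evaluate_gca,
    external_proportions,
    individual_contributions,
    predict_and_select_hybrids,
    rank_programs,
    run_replicate,
    sample_breeding_crosses,
    simulate_effective_parents,
    structure_preset,
)
from enksim.environment import tpe_performance_batch
from enksim.exceptions import ConfigurationError
from enksim.landscape import build_enk_model


def small_structure(name="iso", exchange=frozenset(), p_max=0.25):
    return StructureConfig(name, 5, 20, 5, 5, p_max, exchange)


def small_sim(**kw):
    kw.setdefault("k_target", 1)
    kw.setdefault("n_cycles", 3)
    kw.setdefault("n_reps", 1)
    kw.setdefault("master_seed", 404)
    return SimulationConfig(**kw)


class TestStructurePresets:
    @pytest.mark.parametrize(
        "name,n_programs,subpop,selected",
        [
            ("distributed", 5, 100, 25),
            ("centralized", 1, 500, 125),
            ("iso", 5, 100, 25),
            ("iso7", 5, 100, 25),
            ("iso21", 5, 100, 25),
        ],
    )
    def test_group_totals_constant_across_structures(
        self, name, n_programs, subpop, selected
    ):
        s = structure_preset(name)
        assert (s.n_programs, s.subpop_size, s.n_selected_parents) == (
            n_programs, subpop, selected,
        )
        assert s.n_programs * s.subpop_size == 500
        assert s.n_programs * s.n_selected_parents == 125
        assert s.n_programs * s.n_experimental_hybrids == 125

    def test_exchange_schedules(self):
        assert structure_preset("iso7").exchange_cycles == frozenset({7, 14, 21, 28})
        assert structure_preset("iso21").exchange_cycles == frozenset({21})
        assert structure_preset("distributed").exchange_cycles is None
        assert not structure_preset("iso").exchanges_in(5)
        assert structure_preset("distributed").exchanges_in(5)

    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigurationError):
            structure_preset("federated")


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(5)
    model = build_enk_model(1, master_seed=12)
    lines = rng.integers(0, 2, size=(8, 500), dtype=np.uint8)
    partner = rng.integers(0, 2, size=(8, 500), dtype=np.uint8)
    b = np.full(12, 1 / 12)
    return model, lines, partner, b


class TestEvaluateGCA:

    def test_complete_factorial_limit(self, setup, rng):
        """n_testers = partner size: the mean over all partner hybrids."""
        model, lines, partner, b = setup
        res = evaluate_gca(lines, partner, model, b, partner.shape[0], rng)
        for i in range(lines.shape[0]):
            hyb = lines[i][None, :].astype(int) + partner.astype(int)
            expected = tpe_performance_batch(model, hyb, b).mean()
            assert res.true_means[i] == pytest.approx(expected, abs=1e-12)

    def test_identical_lines_equal_means(self, setup, rng):
        model, lines, partner, b = setup
        same = np.tile(lines[0], (6, 1))
        res = evaluate_gca(same, partner, model, b, partner.shape[0], rng)
        assert np.ptp(res.true_means) < 1e-12

    def test_additive_gca_differences_half_own_difference(self, setup):
        """At K=1 the complete-factorial testcross mean difference of two
        lines is exactly half their per-se (line dosage) difference; random
        tester sets recover it in expectation."""
        model, lines, partner, b = setup
        own = tpe_performance_batch(model, 2 * lines.astype(int), b)
        d12_true = (own[0] - own[1]) / 2
        full = evaluate_gca(
            lines, partner, model, b, partner.shape[0], np.random.default_rng(1)
        )
        assert full.true_means[0] - full.true_means[1] == pytest.approx(
            d12_true, abs=1e-12
        )
        diffs = [
            np.diff(
                evaluate_gca(
                    lines, partner, model, b, 4, np.random.default_rng(s)
                ).true_means[:2]
            )[0]
            for s in range(100)
        ]
        se = np.std(diffs) / 10
        assert -np.mean(diffs) == pytest.approx(d12_true, abs=max(3 * se, 1e-12))

    def test_too_many_testers_rejected(self, setup, rng):
        model, lines, partner, b = setup
        with pytest.raises(ConfigurationError):
            evaluate_gca(lines, partner, model, b, 9, rng)


class TestEntryMeanNoise:
    def test_h2_one_is_noiseless(self, rng):
        t = rng.normal(size=30)
        assert np.array_equal(add_entry_mean_noise(t, 1.0, rng), t)

    def test_reliability_identity(self):
        """Squared correlation between observed and true approximates h2."""
        r2 = []
        for seed in range(300):
            r = np.random.default_rng(seed)
            t = r.normal(size=100)
            o = add_entry_mean_noise(t, 0.75, r)
            r2.append(np.corrcoef(t, o)[0, 1] ** 2)
        assert np.mean(r2) == pytest.approx(0.75, abs=0.02)

    def test_variance_inflation(self):
        r = np.random.default_rng(0)
        t = r.normal(size=20000)
        o = add_entry_mean_noise(t, 0.75, r)
        assert o.var() / t.var() == pytest.approx(1 / 0.75, rel=0.05)

    def test_zero_variance_means_no_noise(self, rng):
        t = np.full(10, 0.3)
        assert np.array_equal(add_entry_mean_noise(t, 0.75, rng), t)


class TestHybridSelection:
    def test_select_all_is_identity(self, rng):
        g1, g2 = rng.normal(size=4), rng.normal(size=3)
        i1, i2 = predict_and_select_hybrids(g1, g2, 12)
        assert sorted(zip(i1, i2)) == [(i, j) for i in range(4) for j in range(3)]

    def test_rank_invariant_to_group_constant(self, rng):
        g1, g2 = rng.normal(size=6), rng.normal(size=6)
        a = predict_and_select_hybrids(g1, g2, 5)
        b = predict_and_select_hybrids(g1 + 10.0, g2, 5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_brute_force_top_set(self, rng):
        """Selection matches exhaustive enumeration of GCA sums on a 6x6 toy."""
        g1, g2 = rng.normal(size=6), rng.normal(size=6)
        i1, i2 = predict_and_select_hybrids(g1, g2, 7)
        sums = sorted(
            ((g1[i] + g2[j], i, j) for i in range(6) for j in range(6)),
            reverse=True,
        )
        expected = {(i, j) for _, i, j in sums[:7]}
        assert set(zip(i1.tolist(), i2.tolist())) == expected
        # with truthful GCAs the selected set maximizes the attainable mean
        best_mean = np.mean([s for s, _, _ in sums[:7]])
        assert np.mean(g1[i1] + g2[i2]) == pytest.approx(best_mean)

    def test_tie_break_lexicographic(self):
        i1, i2 = predict_and_select_hybrids(np.zeros(3), np.zeros(3), 4)
        assert list(zip(i1, i2)) == [(0, 0), (0, 1), (0, 2), (1, 0)]

    def test_oversized_selection_rejected(self):
        with pytest.raises(ConfigurationError):
            predict_and_select_hybrids(np.ones(2), np.ones(2), 5)


class TestRankingAndExchange:
    def test_rank_programs_cases(self):
        assert np.array_equal(rank_programs([3.0, 2.0, 1.0]), [0, 1, 2])
        assert np.array_equal(rank_programs([1.0, 3.0, 2.0]), [1, 2, 0])
        assert np.array_equal(rank_programs([1.0, 1.0, 1.0]), [0, 1, 2])

    def test_worked_three_program_example(self):
        """Pmax=25%, gap to A twice the gap to B: totals 0/12.5/25, split 2:1."""
        perf = np.array([0.6, 0.55, 0.5])  # A - C = 0.10 = 2 x (B - C)
        x, shares = external_proportions(perf, 0.25)
        assert np.allclose(x, [0.0, 0.125, 0.25])
        assert shares[2, 0] == pytest.approx(0.25 * 2 / 3)
        assert shares[2, 1] == pytest.approx(0.25 * 1 / 3)
        assert round(100 * shares[2, 0]) == 17 and round(100 * shares[2, 1]) == 8

    def test_single_program_no_exchange(self):
        x, shares = external_proportions([0.5], 0.25)
        assert x[0] == 0.0 and not shares.any()

    def test_equal_performance_split_equally(self):
        x, shares = external_proportions([0.5, 0.5, 0.5], 0.25)
        assert shares[2, 0] == pytest.approx(shares[2, 1]) == pytest.approx(0.125)

    def test_flow_strictly_downward(self, rng):
        perf = np.sort(rng.random(5))[::-1]
        x, shares = external_proportions(perf, 0.25)
        assert np.allclose(np.triu(shares), 0.0)  # no donor of equal/lower rank
        assert np.allclose(shares.sum(axis=1), x)


class TestContributions:
    def test_unselected_get_zero_and_sum_is_one(self, rng):
        c = individual_contributions(np.arange(1, 101), 25, 600.0, rng)
        assert (c[25:] == 0).all() and (c[:25] > 0).all()
        assert c.sum() == pytest.approx(1.0)

    def test_halving_per_quintile_in_expectation(self):
        """Mean contribution ratio rank 1 : rank 6 = 2 with 25 selected."""
        draws = np.stack([
            individual_contributions(
                np.arange(1, 26), 25, 600.0, np.random.default_rng(s)
            )
            for s in range(3000)
        ])
        m = draws.mean(axis=0)
        assert m[0] / m[5] == pytest.approx(2.0, rel=0.05)
        assert m[0] / m[9] == pytest.approx(2 ** (9 / 5), rel=0.05)


class TestCrossSampling:
    def test_no_selfing_and_all_internal_at_x_zero(self, rng):
        contrib = individual_contributions(np.arange(1, 21), 5, 600.0, rng)
        pa, ia, pb, ib = sample_breeding_crosses(
            contrib, 0.0, [], np.zeros(0), [], 500, rng
        )
        assert (pa == -1).all() and (pb == -1).all()
        assert not np.any(ia == ib)

    def test_external_fraction_matches_designation_probability(self, rng):
        contrib = individual_contributions(np.arange(1, 21), 5, 600.0, rng)
        donor = individual_contributions(np.arange(1, 21), 5, 600.0, rng)
        _, _, pb, _ = sample_breeding_crosses(
            contrib, 0.2, [3], np.array([0.2]), [donor], 20000, rng
        )
        assert (pb == 3).mean() == pytest.approx(0.2, abs=0.01)

    def test_single_usable_parent_rejected(self, rng):
        contrib = np.zeros(10)
        contrib[0] = 1.0
        with pytest.raises(ConfigurationError):
            sample_breeding_crosses(contrib, 0.0, [], np.zeros(0), [], 5, rng)


class TestEffectiveParents:
    def test_equal_usage(self):
        assert effective_parent_number(np.ones(125)) == pytest.approx(125.0)

    def test_single_parent(self):
        c = np.zeros(50)
        c[3] = 10
        assert effective_parent_number(c) == pytest.approx(1.0)

    def test_standalone_iso_simulation_near_reference(self):
        """Cycle-averaged effective parent number ~65 at default concentration."""
        vals = [
            simulate_effective_parents(np.random.default_rng(s), n_cycles=10)
            for s in range(3)
        ]
        assert np.mean(vals) == pytest.approx(65.0, rel=0.08)


class TestFullSimulation:
    def test_reproducibility_bit_identical(self):
        sim = small_sim()
        a = run_replicate(small_structure(), sim, 0)
        b = run_replicate(small_structure(), sim, 0)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.program_performance, rb.program_performance)
            assert ra.top_hybrid == rb.top_hybrid
            assert np.array_equal(ra.true_tpe, rb.true_tpe)

    def test_distributed_pmax_zero_identical_to_iso(self):
        sim = small_sim()
        iso = run_replicate(small_structure("iso", frozenset()), sim, 0)
        dist = run_replicate(small_structure("distributed", None, p_max=0.0), sim, 0)
        for ra, rb in zip(iso, dist):
            assert np.array_equal(ra.program_performance, rb.program_performance)
            assert ra.top_hybrid == rb.top_hybrid
            assert ra.effective_parents == rb.effective_parents

    def test_iso21_identical_to_iso_before_exchange(self):
        sim = small_sim(n_cycles=7)
        iso = run_replicate(small_structure("iso", frozenset()), sim, 0)
        iso5 = run_replicate(small_structure("iso5", frozenset({5})), sim, 0)
        for c in range(4):  # identical before the exchange cycle
            assert iso[c].top_hybrid == iso5[c].top_hybrid
            assert np.array_equal(
                iso[c].program_performance, iso5[c].program_performance
            )
        assert iso5[4].external_total.max() > 0.0
        assert any(
            iso[c].top_hybrid != iso5[c].top_hybrid for c in range(5, 7)
        )

    def test_additive_selection_gains_in_early_cycles(self):
        """Sign test: mean top-hybrid performance rises over the first cycles
        of a purely additive landscape."""
        gains = []
        sim = small_sim(n_cycles=5, master_seed=77)
        for rep in range(10):
            recs = run_replicate(structure_preset("iso"), sim, rep)
            tops = [r.top_hybrid for r in recs]
            gains.append(np.mean(tops[3:]) - np.mean(tops[:2]))
        assert sum(g > 0 for g in gains) >= 8

    def test_record_invariants(self):
        sim = small_sim(k_target=3)
        recs = run_replicate(small_structure(exchange=None), sim, 0)
        assert len(recs) == sim.n_cycles
        for r in recs:
            assert isinstance(r, CycleRecord)
            assert 0 <= r.pct_gca <= 1
            assert np.isnan(r.fst) or 0 <= r.fst <= 1
            assert 0 <= r.uw <= 1
            assert r.effective_parents > 0
            assert r.top_hybrid >= r.program_performance.max()
            assert np.all(r.external_total >= 0)
            assert np.all(r.external_total <= 0.25 + 1e-12)
            ranked = r.program_performance[r.rank_order]
            assert np.all(np.diff(ranked) <= 1e-15)
            # the top-ranked program never uses external parents
            assert r.external_total[r.rank_order[0]] == 0.0

    def test_homozygosity_and_sizes_preserved(self):
        from enksim.engine import _ReplicateState, run_cycle

        sim = small_sim(n_cycles=2)
        state = _ReplicateState(small_structure(), sim, 0)
        for cycle in (1, 2):
            run_cycle(state, cycle)
        for (p, g), haps in state.pops.items():
            assert haps.shape == (20, 500)
            assert set(np.unique(haps)) <= {0, 1}
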