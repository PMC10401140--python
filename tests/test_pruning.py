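import numpy as np
import pytest

from depf.objectives import ObjectivePair
from depf.pruning import (
    Fly,
    balance_factor,
    dominates,
    exchange_information,
    init_population,
    olfactory_step,
    prune,
    pruning_code,
    smell,
    vision_update,
    Subswarm,
)


class TestSmell:
    def test_pole_guard_at_origin(self):
        s = smell(np.zeros(1), np.zeros(1), eps_smell=1e-6)
        assert s[0] == pytest.approx(1e6)

    def test_closed_form(self):
        s = smell(np.array([2.0]), np.array([0.0]))
        assert s[0] == pytest.approx(1.0 / (2.0 + 1e-6))
        assert s[0] < 0.5

    def test_matches_scalar_recomputation(self):
        rng = np.random.default_rng(0)
        X, Y = rng.uniform(0, 2, 8), rng.uniform(0, 2, 8)
        s = smell(X, Y)
        for m in range(8):
            assert s[m] == pytest.approx(1.0 / (np.hypot(X[m], Y[m]) + 1e-6))

    def test_inverse_square_form(self):
        s = smell(np.array([1.0]), np.array([1.0]), form="inverse_square")
        assert s[0] == pytest.approx(1.0 / (2.0 + 1e-6))


class TestPruningCode:
    def test_threshold_rule(self):
        np.testing.assert_array_equal(
            pruning_code(np.array([0.9, 0.4, 0.51])), [True, False, True]
        )

    def test_boundary_is_off(self):
        # a single 0.5 smell maps to 0, which then triggers the repair
        assert pruning_code(np.array([0.5, 0.9])).tolist() == [False, True]

    def test_all_zero_repaired_to_full_ensemble(self):
        np.testing.assert_array_equal(
            pruning_code(np.array([0.1, 0.2, 0.5])), [True, True, True]
        )


class TestBalanceFactor:
    def test_first_iteration_is_one(self):
        for alpha in (0.5, 1.0, 13.0):
            assert balance_factor(1, 20, alpha) == pytest.approx(1.0)

    def test_full_exponent_reaches_alpha(self):
        assert balance_factor(21, 20, 13.0) == pytest.approx(13.0)

    def test_strictly_increasing_for_alpha_13(self):
        vals = [balance_factor(f, 20, 13.0) for f in range(1, 21)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            balance_factor(1, 20, 0.0)


class TestInitPopulation:
    def test_population_size_and_origin_fly(self):
        subs = init_population(D=3, G=3, M=5, seed=0)
        assert sum(len(s.flies) for s in subs) == 9
        for s in subs:
            assert s.flies[0].mask.all()  # origin fly selects everything
            for f in s.flies:
                assert (f.X >= 0).all() and (f.X <= 2).all()

    def test_deterministic(self):
        a = init_population(3, 3, 5, seed=9)
        b = init_population(3, 3, 5, seed=9)
        for sa, sb in zip(a, b):
            for fa, fb in zip(sa.flies, sb.flies):
                np.testing.assert_array_equal(fa.X, fb.X)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            init_population(2, 0, 5)


class TestOlfactoryStep:
    def test_zero_omega_keeps_position(self):
        best = Fly(np.full(4, 1.0), np.full(4, 1.0))
        child = olfactory_step(best, omega=0.0, seed=1)
        np.testing.assert_array_equal(child.X, best.X)

    def test_reproducible(self):
        best = Fly(np.full(4, 1.0), np.full(4, 1.0))
        c1 = olfactory_step(best, omega=1.0, seed=5)
        c2 = olfactory_step(best, omega=1.0, seed=5)
        np.testing.assert_array_equal(c1.X, c2.X)

    def test_step_magnitude_scales_with_omega(self):
        best = Fly(np.full(1, 1.0), np.full(1, 1.0))
        rng1, rng2 = np.random.default_rng(0), np.random.default_rng(0)
        bounds = (-100.0, 100.0)  # wide bounds so clamping cannot bite
        small = [abs(olfactory_step(best, 0.5, bounds, rng=rng1).X[0] - 1.0)
                 for _ in range(1000)]
        large = [abs(olfactory_step(best, 5.0, bounds, rng=rng2).X[0] - 1.0)
                 for _ in range(1000)]
        assert np.mean(large) == pytest.approx(10 * np.mean(small), rel=1e-9)


class TestDominance:
    def test_cases(self):
        p = lambda d, c: ObjectivePair(d, c, direction=1)
        assert dominates(p(1, 1), p(2, 2))
        assert not dominates(p(1, 3), p(3, 1))
        assert not dominates(p(3, 1), p(1, 3))
        assert not dominates(p(1, 2), p(1, 2))
        assert dominates(p(1, 2), p(1, 3))

    def test_direction_flips_ordering(self):
        a = ObjectivePair(1.0, 1.0, direction=-1)
        b = ObjectivePair(2.0, 2.0, direction=-1)
        assert dominates(b, a)  # maximization under "-"

    def test_mixed_directions_rejected(self):
        with pytest.raises(ValueError):
            dominates(ObjectivePair(1, 1, 1), ObjectivePair(1, 1, -1))


def make_fly(dev, cp, M=3):
    f = Fly(np.full(M, 0.1), np.full(M, 0.1))
    f.objectives = ObjectivePair(dev, cp, direction=1)
    return f


class TestVisionUpdate:
    def test_no_improvement_keeps_swarm(self):
        flies = [make_fly(1, 1), make_fly(2, 2)]
        sub = Subswarm(flies, 0, best=flies[0])
        out = vision_update(sub, [make_fly(5, 5), make_fly(5, 5)])
        assert out.flies[0] is flies[0]
        assert out.best is flies[0]

    def test_dominating_offspring_replaces_fly_and_best(self):
        flies = [make_fly(2, 2), make_fly(3, 3)]
        sub = Subswarm(flies, 0, best=flies[0])
        child = make_fly(1, 1)
        out = vision_update(sub, [child, make_fly(9, 9)])
        assert out.flies[0] is child
        assert out.best is child

    def test_best_tie_break_prefers_smaller_dev(self):
        flies = [make_fly(2, 5), make_fly(1, 5), make_fly(1, 5)]
        sub = Subswarm(flies, 0, best=None)
        out = vision_update(sub, flies)
        assert out.best is flies[1]  # smaller dev, then lower index


class TestExchange:
    def test_single_subswarm_noop(self):
        flies = [make_fly(1, 1)]
        subs = [Subswarm(flies, 0, best=flies[0])]
        assert exchange_information(subs) is subs

    def test_ring_pattern_and_mask_preservation(self):
        subs = []
        for d in range(3):
            f = make_fly(d + 1.0, d + 1.0)
            subs.append(Subswarm([f, make_fly(9, 9)], d, best=f))
        masks = [s.best.mask.copy() for s in subs]
        out = exchange_information(subs)
        for i in range(3):
            # donor is subswarm (i-1) mod 3; its best's mask arrives intact
            np.testing.assert_array_equal(out[i].flies[-1].mask, masks[(i - 1) % 3])

    def test_elite_never_worsens_on_exchange(self):
        subs = []
        for d in range(2):
            f = make_fly(1.0, 1.0)
            subs.append(Subswarm([f], d, best=f))
        evaluator = lambda s, m: ObjectivePair(50.0, 50.0, direction=1)
        out = exchange_information(subs, evaluator)
        for s in out:
            assert s.best.objectives.dev == 1.0


@pytest.fixture(scope="module")
def pruned(blob_ensemble):
    ens, Z, labels = blob_ensemble
    return prune(ens, Z, direction=1, max_fes=8, flies=9, seed=5), ens


class TestPrune:
    def test_trace_length_matches_iterations(self, pruned):
        res, _ = pruned
        assert len(res.trace) == 8

    def test_pruned_is_nonempty_subset_per_subspace(self, pruned):
        res, ens = pruned
        groups = res.pruned_ensemble.by_subspace()
        full = ens.by_subspace()
        for d, parts in groups.items():
            assert 1 <= len(parts) <= len(full[d])
            ids = {(p.subspace_index, p.run_index) for p in parts}
            assert ids <= {(p.subspace_index, p.run_index) for p in full[d]}

    def test_elitism_trace_never_worsens(self, pruned):
        res, _ = pruned
        for d in range(len(res.trace[0])):
            seq = [row[d] for row in res.trace]
            for (d0, c0), (d1, c1) in zip(seq, seq[1:]):
                assert d1 <= d0 + 1e-12 and c1 <= c0 + 1e-12

    def test_bitwise_reproducible(self, blob_ensemble):
        ens, Z, _ = blob_ensemble
        r1 = prune(ens, Z, direction=1, max_fes=5, seed=3)
        r2 = prune(ens, Z, direction=1, max_fes=5, seed=3)
        for d in r1.selected:
            np.testing.assert_array_equal(r1.selected[d], r2.selected[d])
        assert r1.trace == r2.trace

    def test_archive_is_mutually_nondominated(self, pruned):
        res, _ = pruned
        for i, (_, _, a) in enumerate(res.archive):
            for j, (_, _, b) in enumerate(res.archive):
                if i != j:
                    assert not dominates(a, b)
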