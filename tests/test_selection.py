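"""Reserve-selection objective, annealing optimizer and Marxan-dialect I/O."""

import itertools

import numpy as np
import pytest

import reefconnect as rc
from reefconnect.selection import (
    Feature,
    ParseError,
    PlanningProblem,
    build_connectivity_boundary,
    build_distance_boundary,
    build_problem,
    calibrate_blm,
    crossing_value,
    iterative_improvement,
    objective_score,
    read_problem,
    run_scenario,
    simulated_annealing,
    stratify_features,
    write_problem,
)

from conftest import make_unit


def two_unit_problem(costs=(1.0, 3.0), amounts=((5.0,), (5.0,)), target=4.0,
                     blm=0.0, bounds=None):
    b1, b2, bv = bounds if bounds else ([], [], [])
    return PlanningProblem(
        unit_ids=np.array([1, 2]),
        cost=np.array(costs),
        status=np.zeros(2, dtype=int),
        features=[Feature(feature_id=1, name="f", target=target, spf=10.0)],
        amounts=np.array(amounts),
        bound_id1=np.array(b1, dtype=np.int64),
        bound_id2=np.array(b2, dtype=np.int64),
        bound_value=np.array(bv, dtype=float),
        blm=blm,
    )


def random_problem(rng, n):
    nf = int(rng.integers(2, 4))
    amounts = rng.random((n, nf)) * 10
    amounts[rng.random((n, nf)) < 0.3] = 0.0
    feats = [
        Feature(feature_id=k + 1, name=f"f{k}", target=0.3 * amounts[:, k].sum(), spf=10.0)
        for k in range(nf)
    ]
    m = int(rng.integers(0, n * 2))
    b1 = rng.integers(1, n + 1, size=m)
    b2 = rng.integers(1, n + 1, size=m)
    keep = b1 != b2
    return PlanningProblem(
        unit_ids=np.arange(1, n + 1),
        cost=rng.random(n) * 5,
        status=np.zeros(n, dtype=int),
        features=feats,
        amounts=amounts,
        bound_id1=b1[keep],
        bound_id2=b2[keep],
        bound_value=rng.random(int(keep.sum())),
        blm=float(rng.random() * 0.5),
    )


class TestDistanceBoundary:
    def test_scaled_and_reversed(self):
        # collinear units: pair distances {50, 50, 100} -> values {1, 1, 0}
        units = [
            make_unit(1, [(0, 0)], [4.0]),
            make_unit(2, [(0, 50)], [4.0]),
            make_unit(3, [(0, 100)], [4.0]),
        ]
        i1, i2, v = build_distance_boundary(units, cell_size_km=1.0)
        vals = dict(zip(zip(i1.tolist(), i2.tolist()), v.tolist()))
        assert vals[(1, 2)] == pytest.approx(1.0)
        assert vals[(2, 3)] == pytest.approx(1.0)
        assert vals[(1, 3)] == pytest.approx(0.0)

    def test_nearest_pair_has_largest_value(self):
        rng = np.random.default_rng(1)
        units = [
            make_unit(i + 1, [(int(r), int(c))], [4.0])
            for i, (r, c) in enumerate(rng.integers(0, 40, (8, 2)))
        ]
        i1, i2, v = build_distance_boundary(units)
        pts = {u.unit_id: np.array(u.centroid) for u in units}
        d = np.array([np.linalg.norm(pts[a] - pts[b]) for a, b in zip(i1, i2)])
        assert v[np.argmin(d)] == v.max()

    def test_two_units_degenerate(self):
        units = [make_unit(1, [(0, 0)], [4.0]), make_unit(2, [(0, 5)], [4.0])]
        with pytest.warns(UserWarning):
            _, _, v = build_distance_boundary(units)
        np.testing.assert_allclose(v, [1.0])


class TestConnectivityBoundary:
    def test_max_scaling_keeps_asymmetry(self):
        settled = np.array([[0.0, 4.0], [1.0, 0.0]])
        m = rc.ConnectivityMatrix(settled=settled, released=np.full(2, 10.0), unit_ids=[1, 2])
        i1, i2, v = build_connectivity_boundary(m)
        vals = dict(zip(zip(i1.tolist(), i2.tolist()), v.tolist()))
        assert vals[(1, 2)] == pytest.approx(1.0)
        assert vals[(2, 1)] == pytest.approx(0.25)

    def test_diagonal_never_emitted(self):
        settled = np.array([[9.0, 1.0], [0.0, 5.0]])
        m = rc.ConnectivityMatrix(settled=settled, released=np.full(2, 10.0), unit_ids=[1, 2])
        i1, i2, _ = build_connectivity_boundary(m)
        assert all(a != b for a, b in zip(i1, i2))

    def test_all_zero_offdiagonal_warns_empty(self):
        m = rc.ConnectivityMatrix(
            settled=np.diag([1.0, 2.0]), released=np.full(2, 10.0), unit_ids=[1, 2]
        )
        with pytest.warns(UserWarning):
            i1, i2, v = build_connectivity_boundary(m)
        assert len(v) == 0


class TestObjective:
    def test_cost_only_when_targets_met_blm_zero(self):
        p = two_unit_problem()
        s = objective_score(p, [1])
        assert s.total == pytest.approx(1.0)
        assert s.boundary_term == 0.0 and s.penalty_term == 0.0 and s.threshold_term == 0.0

    def test_target_met_exactly_no_penalty(self):
        p = two_unit_problem(amounts=((4.0,), (5.0,)), target=4.0)
        s = objective_score(p, [1])
        assert s.penalty_term == 0.0
        assert s.feature_met[1]

    def test_penalty_positive_iff_target_unmet(self):
        p = two_unit_problem(target=8.0)
        assert objective_score(p, []).penalty_term > 0.0
        assert objective_score(p, [1]).penalty_term > 0.0
        assert objective_score(p, [1, 2]).penalty_term == 0.0

    def test_asymmetric_crossing_edges_counted_once_each(self):
        p = two_unit_problem(blm=1.0, bounds=([1, 2], [2, 1], [0.6, 0.2]))
        s = objective_score(p, [1])
        assert s.boundary_term == pytest.approx(0.8)
        # verified against all four subsets of {1, 2}
        assert objective_score(p, []).boundary_term == 0.0
        assert objective_score(p, [2]).boundary_term == pytest.approx(0.8)
        assert objective_score(p, [1, 2]).boundary_term == 0.0

    def test_threshold_ramp(self):
        p = two_unit_problem(costs=(2.0, 2.0))
        p.cost_threshold = (1.0, 1.0, 1.4)
        s = objective_score(p, [1, 2], progress=1.0)
        assert s.threshold_term == pytest.approx(1.4 * (4.0 - 1.0))
        s0 = objective_score(p, [1, 2], progress=0.0)
        assert s0.threshold_term == pytest.approx(1.0 * 3.0)

    def test_locked_status_enforced(self):
        p = two_unit_problem()
        p.status[0] = 2  # locked in
        with pytest.raises(ValueError):
            objective_score(p, [2])
        p.status[0] = 3  # locked out
        with pytest.raises(ValueError):
            objective_score(p, [1])

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError):
            objective_score(two_unit_problem(), [99])


class TestAnnealing:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        p = random_problem(rng, 12)
        a = simulated_annealing(p, iterations=10_000, seed=7)
        b = simulated_annealing(p, iterations=10_000, seed=7)
        assert a == b

    def test_two_unit_problem_picks_cheaper_cover(self):
        # either unit meets the target alone; unit 1 is cheaper
        p = two_unit_problem(costs=(1.0, 3.0))
        best = min(
            (simulated_annealing(p, iterations=2_000, seed=s) for s in range(5)),
            key=lambda s: s.total,
        )
        assert best.selected == (1,)
        # matches exhaustive enumeration of the four subsets
        totals = {
            sel: objective_score(p, sel).total for sel in [(), (1,), (2,), (1, 2)]
        }
        assert best.total == pytest.approx(min(totals.values()))

    def test_never_worse_than_initial_random_selection(self):
        from reefconnect.selection import _initial_selection

        rng = np.random.default_rng(3)
        for seed in range(5):
            p = random_problem(rng, 14)
            sol = simulated_annealing(p, iterations=5_000, seed=seed)
            init = _initial_selection(p, np.random.default_rng(seed))
            init_total = objective_score(p, p.unit_ids[init.astype(bool)]).total
            assert sol.total <= init_total + 1e-9

    def test_breakdown_sums_to_total(self):
        rng = np.random.default_rng(8)
        p = random_problem(rng, 10)
        s = simulated_annealing(p, iterations=5_000, seed=1)
        assert s.total == pytest.approx(
            s.cost_term + s.boundary_term + s.penalty_term + s.threshold_term
        )


class TestIterativeImprovement:
    def test_local_optimum_returned_unchanged(self):
        p = two_unit_problem()
        s = objective_score(p, [1])
        assert iterative_improvement(p, s) == s

    def test_useless_unit_removed(self):
        # unit 2 has cost but contributes nothing
        p = two_unit_problem(amounts=((5.0,), (0.0,)), target=4.0)
        s = objective_score(p, [1, 2])
        out = iterative_improvement(p, s)
        assert out.selected == (1,)

    def test_never_increases_objective(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            p = random_problem(rng, 12)
            sel = p.unit_ids[rng.random(12) < 0.5]
            s = objective_score(p, sel)
            out = iterative_improvement(p, s)
            assert out.total <= s.total + 1e-9

    def test_result_is_one_flip_optimal(self):
        rng = np.random.default_rng(22)
        p = random_problem(rng, 10)
        out = iterative_improvement(p, objective_score(p, p.unit_ids[:4]))
        sel = set(out.selected)
        for u in p.unit_ids.tolist():
            flipped = sel ^ {u}
            assert objective_score(p, flipped).total >= out.total - 1e-9


class TestFlipDeltaConsistency:
    def test_kernel_delta_matches_objective_difference(self):
        from reefconnect.selection import _flip_delta, _kernel_arrays

        rng = np.random.default_rng(13)
        for _ in range(20):
            p = random_problem(rng, 10)
            p.cost_threshold = (2.0, 1.0, 1.4) if rng.random() < 0.5 else None
            arrays = _kernel_arrays(p)
            inc_ptr, inc_other, inc_val, targets, pen_scale, thr_on, thr, p0, p1 = arrays
            sel = (rng.random(10) < 0.5).astype(np.int8)
            sel_ids = p.unit_ids[sel.astype(bool)]
            base = objective_score(p, sel_ids)
            cost_tot = float(p.cost[sel.astype(bool)].sum())
            held = p.amounts[sel.astype(bool)].sum(axis=0)
            u = int(rng.integers(10))
            new_val = 1 - int(sel[u])
            d = _flip_delta(
                u, new_val, sel, p.cost, p.amounts, targets, pen_scale, p.blm,
                inc_ptr, inc_other, inc_val, cost_tot, held, thr_on, thr, p1,
            )
            flipped = set(sel_ids.tolist()) ^ {int(p.unit_ids[u])}
            want = objective_score(p, flipped).total - base.total
            assert d == pytest.approx(want, abs=1e-9)


class TestRunScenario:
    def test_frequency_bounds_and_best(self):
        rng = np.random.default_rng(5)
        p = random_problem(rng, 12)
        best, freq = run_scenario(p, n_reps=8, iterations=3_000, seed=4)
        assert (freq.counts >= 0).all() and (freq.counts <= 8).all()
        assert freq.n_repetitions == 8
        # best is no worse than each individual repetition
        for s in np.random.SeedSequence(4).generate_state(8):
            rep = simulated_annealing(p, iterations=3_000, seed=int(s))
            assert best.total <= rep.total + 1e-9

    def test_single_rep_frequency_binary(self):
        rng = np.random.default_rng(6)
        p = random_problem(rng, 10)
        _, freq = run_scenario(p, n_reps=1, iterations=2_000, seed=0)
        assert set(freq.counts.tolist()) <= {0, 1}


class TestStratify:
    def _units_and_problem(self):
        units = [
            make_unit(1, [(0, 0)], [10.0], eco=0, cost=1.0),
            make_unit(2, [(0, 2)], [20.0], eco=0, cost=1.0),
            make_unit(3, [(5, 0)], [30.0], eco=1, cost=1.0),
            make_unit(4, [(5, 2)], [40.0], eco=1, cost=1.0),
        ]
        areas = np.array([u.total_reef_area_km2 for u in units])
        problem = build_problem(units, {"reef_area": areas}, target_fraction=0.30)
        return units, problem, areas

    def test_amounts_partition(self):
        units, problem, areas = self._units_and_problem()
        strat = stratify_features(problem, units)
        assert len(strat.features) == 2
        np.testing.assert_allclose(strat.amounts.sum(axis=1), areas)

    def test_targets_are_thirty_percent_of_stratum(self):
        units, problem, _ = self._units_and_problem()
        strat = stratify_features(problem, units)
        targets = {f.name: f.target for f in strat.features}
        assert targets["reef_area_eco0"] == pytest.approx(0.3 * 30.0)
        assert targets["reef_area_eco1"] == pytest.approx(0.3 * 70.0)
        assert sum(targets.values()) == pytest.approx(0.3 * 100.0)

    def test_single_ecoregion_equivalent_to_unstratified(self):
        units = [make_unit(i, [(0, i)], [10.0], eco=0) for i in (1, 2)]
        problem = build_problem(units, {"reef_area": np.array([10.0, 10.0])})
        strat = stratify_features(problem, units)
        assert len(strat.features) == 1
        assert strat.features[0].target == pytest.approx(problem.features[0].target)

    def test_empty_stratum_omitted_with_warning(self):
        units, problem, _ = self._units_and_problem()
        # a feature present only in ecoregion 0
        problem2 = build_problem(
            units, {"sparse": np.array([1.0, 1.0, 0.0, 0.0])}
        )
        with pytest.warns(UserWarning):
            strat = stratify_features(problem2, units)
        assert len(strat.features) == 1


class TestCalibrateBlm:
    def test_table_shape(self):
        rng = np.random.default_rng(10)
        p = random_problem(rng, 12)
        table = calibrate_blm(p, [0.0, 0.17, 1.0], n_reps=3, iterations=2_000, seed=0)
        assert len(table) == 3
        assert list(table["blm"]) == [0.0, 0.17, 1.0]

    def test_single_candidate(self):
        rng = np.random.default_rng(10)
        p = random_problem(rng, 10)
        table = calibrate_blm(p, [0.5], n_reps=2, iterations=1_000, seed=0)
        assert len(table) == 1

    def test_empty_candidates_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError):
            calibrate_blm(random_problem(rng, 8), [], n_reps=1)


class TestMarxanIO:
    def test_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(30)
        p = random_problem(rng, 9)
        p.cost_threshold = (5.0, 1.0, 1.4)
        write_problem(p, tmp_path)
        q = read_problem(tmp_path)
        np.testing.assert_array_equal(p.unit_ids, q.unit_ids)
        np.testing.assert_allclose(p.cost, q.cost)
        np.testing.assert_array_equal(p.status, q.status)
        np.testing.assert_allclose(p.amounts, q.amounts)
        assert p.features == q.features
        assert p.blm == q.blm
        assert p.cost_threshold == q.cost_threshold
        # boundary entries preserved as an (id1, id2) -> value multiset
        pb = sorted(zip(p.bound_id1, p.bound_id2, p.bound_value))
        qb = sorted(zip(q.bound_id1, q.bound_id2, q.bound_value))
        np.testing.assert_allclose(np.array(pb, dtype=float), np.array(qb, dtype=float))

    def test_dangling_boundary_id_names_file_and_line(self, tmp_path):
        rng = np.random.default_rng(31)
        p = random_problem(rng, 6)
        write_problem(p, tmp_path)
        with open(tmp_path / "bound.csv", "a") as fh:
            fh.write("1,999,0.5\n")
        with pytest.raises(ParseError, match="bound.csv line"):
            read_problem(tmp_path)

    def test_missing_column_rejected(self, tmp_path):
        rng = np.random.default_rng(32)
        p = random_problem(rng, 6)
        write_problem(p, tmp_path)
        pu = (tmp_path / "pu.csv").read_text().splitlines()
        (tmp_path / "pu.csv").write_text(
            "\n".join(ln.replace("cost", "price") for ln in pu)
        )
        with pytest.raises(ParseError, match="pu.csv"):
            read_problem(tmp_path)

    def test_empty_boundary_file(self, tmp_path):
        rng = np.random.default_rng(33)
        p = random_problem(rng, 6)
        p.bound_id1 = np.empty(0, dtype=np.int64)
        p.bound_id2 = np.empty(0, dtype=np.int64)
        p.bound_value = np.empty(0)
        write_problem(p, tmp_path)
        q = read_problem(tmp_path)
        assert len(q.bound_value) == 0
        assert crossing_value(q, q.unit_ids[:3]) == 0.0


class TestProblemValidation:
    def test_boundary_to_unknown_unit_rejected(self):
        with pytest.raises(ValueError):
            two_unit_problem(bounds=([1], [99], [0.5]))

    def test_unachievable_target_warns(self):
        with pytest.warns(UserWarning):
            two_unit_problem(target=1000.0)

    def test_no_free_units_returns_locked_configuration(self):
        p = two_unit_problem()
        p.status[:] = [2, 3]
        s = simulated_annealing(p, iterations=100, seed=0)
        assert s.selected == (1,)
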