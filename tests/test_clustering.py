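"""Shape distance and the modified K-means: quadrature accuracy,
pseudometric properties, assignment/update steps, recovery and labels."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

import wbtraj as w
from wbtraj.clustering import ClusterSolution, Prototype, _quad_nodes
from wbtraj.trajectories import PolyTrajectory, Trajectory3D


def proto(k, ls_coef, ab_coef, center=7, window=(0, 97)):
    return Prototype(
        k=k,
        ls_poly=PolyTrajectory(tuple(ls_coef), center=center, window=window),
        ab_poly=PolyTrajectory(tuple(ab_coef), center=center, window=window),
    )


coef = st.lists(st.floats(-2, 2, allow_nan=False), min_size=2, max_size=5)


@st.composite
def trajectory(draw):
    return Trajectory3D(
        participant_id="p",
        sample_id="s1",
        ls_poly=PolyTrajectory(tuple(draw(coef)), center=7, window=(0, 97)),
        ab_poly=PolyTrajectory(tuple(draw(coef)), center=7, window=(0, 97)),
    )


class TestShapeDistance:
    def test_identical_trajectories_have_zero_distance(self, make_traj):
        a = make_traj((1, 2, -0.01), (3, 0.5))
        assert w.shape_distance(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_intercept_shifts_do_not_change_distance(self, make_traj):
        a = make_traj((1, 2, -0.01), (3, 0.5))
        b = make_traj((1 + 5, 2, -0.01), (3 - 3, 0.5))
        assert w.shape_distance(a, b) == pytest.approx(0.0, abs=1e-10)

    def test_constant_derivative_gap_is_pythagorean(self, make_traj):
        # LS' differs by 3, AB' by 4 over a length-10 window: 5 * 10 = 50
        a = make_traj((0, 3), (0, 4), center=0, window=(0, 10))
        b = make_traj((0, 0), (0, 0), center=0, window=(0, 10))
        assert w.shape_distance(a, b) == pytest.approx(50.0, abs=1e-10)

    def test_quadratic_against_closed_form_integral(self, make_traj):
        # LS u^2 vs flat on [0,1] (center 0): int_0^1 2u du = 1
        a = make_traj((0, 0, 1), (0, 0), center=0, window=(0, 1))
        b = make_traj((0, 0), (0, 0), center=0, window=(0, 1))
        assert w.shape_distance(a, b) == pytest.approx(1.0, abs=1e-10)

    def test_normalized_distance_is_windowwise_mean(self, make_traj):
        a = make_traj((0, 3), (0, 4), center=0, window=(0, 10))
        b = make_traj((0, 0), (0, 0), center=0, window=(0, 10))
        assert w.shape_distance(a, b, normalize=True) == pytest.approx(5.0, abs=1e-10)

    def test_window_mismatch_rejected(self, make_traj):
        a = make_traj((0, 1), (0, 1), window=(0, 97))
        b = make_traj((0, 1), (0, 1), sample="s2", center=42, window=(0, 132))
        with pytest.raises(w.ConfigError):
            w.shape_distance(a, b)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(trajectory(), trajectory(), trajectory())
    def test_pseudometric_properties(self, a, b, c):
        dab = w.shape_distance(a, b)
        dba = w.shape_distance(b, a)
        dac = w.shape_distance(a, c)
        dcb = w.shape_distance(c, b)
        assert dab >= 0
        assert dab == pytest.approx(dba, abs=1e-8)
        assert w.shape_distance(a, a) == pytest.approx(0.0, abs=1e-8)
        assert dab <= dac + dcb + 1e-8

    def test_gauss_legendre_matches_riemann_oracle(self, make_traj):
        rng = np.random.default_rng(8)
        t = np.linspace(0, 97, 200_001)
        dt = t[1] - t[0]
        tm = 0.5 * (t[1:] + t[:-1])
        for _ in range(10):
            a = make_traj(rng.normal(0, 1, 4), rng.normal(0, 1, 4))
            b = make_traj(rng.normal(0, 1, 4), rng.normal(0, 1, 4))
            def dvals(p):
                dp = w.derivative(p)
                return np.polynomial.polynomial.polyval(tm - dp.center, dp.coefficients)
            integrand = np.hypot(dvals(a.ls_poly) - dvals(b.ls_poly),
                                 dvals(a.ab_poly) - dvals(b.ab_poly))
            riemann = float(np.sum(integrand) * dt)
            gl = w.shape_distance(a, b)
            assert gl == pytest.approx(riemann, rel=1e-5)


class TestSteps:
    def test_single_prototype_takes_everyone(self, make_traj):
        trajs = [make_traj((0, s), (0, 0), pid=f"p{s}") for s in (1, 2, 3)]
        assert w.assign_step(trajs, [proto(0, (0, 1), (0, 0))]).tolist() == [0, 0, 0]

    def test_matching_shape_assigned_to_its_prototype(self, make_traj):
        protos = [proto(k, (0, s), (0, 0)) for k, s in enumerate((-1.0, 0.0, 1.0))]
        t = make_traj((12.0, 1.0), (4.0, 0.0))  # slope 1 -> prototype 2
        assert w.assign_step([t], protos)[0] == 2

    def test_ties_break_to_lowest_index(self, make_traj):
        protos = [proto(0, (0, 1), (0, 0)), proto(1, (0, 1), (0, 0))]
        t = make_traj((0, 5), (0, 0))
        assert w.assign_step([t], protos)[0] == 0

    def test_single_member_prototype_is_that_shape(self, make_traj):
        t = make_traj((12, 1.5, 0.01), (4, -0.5))
        (p,) = w.update_step([t], np.array([0]), K=1)
        assert p.ls_poly.coefficients[0] == 0.0
        assert p.ls_poly.coefficients[1:] == pytest.approx((1.5, 0.01))
        assert p.ab_poly.coefficients[1] == pytest.approx(-0.5)

    def test_prototype_is_coefficient_mean(self, make_traj):
        a = make_traj((10, 1.0), (0, 0), pid="a")
        b = make_traj((20, 3.0), (0, 0), pid="b")
        (p,) = w.update_step([a, b], np.array([0, 0]), K=1)
        assert p.ls_poly.coefficients[1] == pytest.approx(2.0)

    def test_empty_cluster_reseeded_to_farthest_trajectory(self, make_traj):
        trajs = [
            make_traj((0, 0.0), (0, 0), pid="near0"),
            make_traj((0, 0.1), (0, 0), pid="near1"),
            make_traj((0, 9.0), (0, 0), pid="far"),
        ]
        protos = w.update_step(trajs, np.array([0, 0, 0]), K=2)
        # cluster 1 was empty: reseeded to the trajectory farthest from
        # prototype 0 (the mean shape), i.e. the slope-9 outlier
        assert protos[1].ls_poly.coefficients[1] == pytest.approx(9.0)


class TestKmeans:
    def test_identical_trajectories_give_zero_objective(self, make_traj):
        trajs = [make_traj((10, 1, 0.02), (5, -1), pid=f"p{i}") for i in range(6)]
        sol = w.kmeans_shape(trajs, K=1, seed=0, restarts=2)
        assert sol.objective == pytest.approx(0.0, abs=1e-10)

    def test_k_equals_n_distinct_shapes_gives_zero_objective(self, make_traj):
        trajs = [make_traj((0, s), (0, -s), pid=f"p{s}") for s in (1.0, 2.0, 3.0)]
        sol = w.kmeans_shape(trajs, K=3, seed=0, restarts=5)
        assert sol.objective == pytest.approx(0.0, abs=1e-8)

    def test_two_separated_slope_groups_recovered_exactly(self, make_traj):
        trajs = [make_traj((20, 1.0), (10, 0), pid=f"a{i}") for i in range(20)]
        trajs += [make_traj((20, -1.0), (10, 0), pid=f"b{i}") for i in range(20)]
        truth = [0] * 20 + [1] * 20
        sol = w.kmeans_shape(trajs, K=2, seed=1, restarts=5)
        assert adjusted_rand_score(truth, sol.labels_array()) == 1.0

    def test_objective_matches_recomputed_assignment_distances(self, make_traj):
        rng = np.random.default_rng(3)
        trajs = [
            make_traj(rng.normal(0, 1, 3), rng.normal(0, 1, 3), pid=f"p{i}")
            for i in range(15)
        ]
        sol = w.kmeans_shape(trajs, K=3, seed=2, restarts=5)
        recomputed = sum(
            w.shape_distance(t, sol.prototypes[sol.assignments[t.participant_id]])
            for t in trajs
        )
        assert sol.objective == pytest.approx(recomputed, abs=1e-8)

    def test_objective_trace_is_monotone_nonincreasing(self, make_traj):
        rng = np.random.default_rng(4)
        trajs = [
            make_traj(rng.normal(0, 1, 3), rng.normal(0, 1, 3), pid=f"p{i}")
            for i in range(30)
        ]
        sol = w.kmeans_shape(trajs, K=4, seed=3, restarts=3)
        trace = np.array(sol.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9)
        assert sol.converged and sol.n_iter <= 100

    def test_k_larger_than_n_rejected(self, make_traj):
        trajs = [make_traj((0, 1), (0, 1), pid="p0")]
        with pytest.raises(w.ConfigError):
            w.kmeans_shape(trajs, K=2, seed=0)

    def test_same_seed_reproduces_solution(self, make_traj):
        rng = np.random.default_rng(5)
        trajs = [
            make_traj(rng.normal(0, 1, 3), rng.normal(0, 1, 3), pid=f"p{i}")
            for i in range(20)
        ]
        s1 = w.kmeans_shape(trajs, K=3, seed=7, restarts=4)
        s2 = w.kmeans_shape(trajs, K=3, seed=7, restarts=4)
        assert s1.assignments == s2.assignments
        assert s1.objective == s2.objective


class TestScree:
    def test_zero_shape_variance_elbows_at_minimum_interior_k(self, make_traj):
        trajs = [make_traj((10 + i, 1.0), (5, 0.5), pid=f"p{i}") for i in range(12)]
        scree = w.scree_select(trajs, range(1, 6), seed=0, restarts=2)
        assert scree.selected_K == 2
        assert scree.table["objective"].max() < 1e-8

    def test_k_range_beyond_n_rejected(self, make_traj):
        trajs = [make_traj((0, i), (0, 0), pid=f"p{i}") for i in range(3)]
        with pytest.raises(w.ConfigError):
            w.scree_select(trajs, range(1, 11), seed=0, restarts=2)

    def test_too_few_k_values_leave_selection_undefined(self, make_traj):
        trajs = [make_traj((0, float(i)), (0, 0), pid=f"p{i}") for i in range(6)]
        scree = w.scree_select(trajs, [2, 3], seed=0, restarts=2)
        assert scree.selected_K is None
        assert set(scree.table["K"]) == {2, 3}


class TestLabelsAndAnchors:
    SHAPES = {
        "flat_high": (27, 27, 27, 27),
        "rise_hold": (17, 19, 25, 25),
        "rise_return": (17, 19, 25, 17),
        "dip": (18, 16, 13, 16),
    }

    @pytest.fixture
    def labeled_setup(self, make_cohort):
        rows = []
        assignments = {}
        days = (0, 7, 37, 97)
        for k, (name, vals) in enumerate(self.SHAPES.items()):
            for i in range(3):
                pid = f"{name}{i}"
                assignments[pid] = k
                for d, v in zip(days, vals):
                    rows.append((pid, "s1", d, v, (v - 20) * 2, 10))
        cohort = make_cohort(rows)
        solution = ClusterSolution(
            K=4,
            participant_ids=sorted(assignments),
            assignments=assignments,
            prototypes=[proto(k, (0, 0), (0, 0)) for k in range(4)],
            objective=0.0, n_iter=1, seed=0, restarts=1, converged=True,
            objective_trace=[0.0],
        )
        return cohort, solution

    def test_shape_rules_name_the_four_archetypes(self, labeled_setup, designs):
        cohort, solution = labeled_setup
        by_p, by_k = w.label_clusters(solution, cohort, designs["s1"])
        assert by_k == {0: "nondistressed", 1: "lasting_benefit",
                        2: "hedonic_adaptation", 3: "residual"}
        assert by_p["flat_high0"] == "nondistressed"

    def test_other_k_suppresses_names(self, labeled_setup, designs):
        cohort, solution = labeled_setup
        solution.K = 3
        solution.prototypes = solution.prototypes[:3]
        assignments = {p: min(k, 2) for p, k in solution.assignments.items()}
        solution.assignments = assignments
        _, by_k = w.label_clusters(solution, cohort, designs["s1"])
        assert set(by_k.values()) == {"cluster_0", "cluster_1", "cluster_2"}

    def test_display_intercept_anchors_at_member_mean(self, labeled_setup, designs):
        cohort, solution = labeled_setup
        members = [p for p, k in solution.assignments.items() if k == 0]
        anchored = w.apply_display_intercept(solution.prototypes[0], members, cohort)
        ls_anchor, ab_anchor = anchored.display_intercepts
        assert ls_anchor == pytest.approx(27.0)
        # anchoring never changes any distance
        t = Trajectory3D("t", "s1",
                         PolyTrajectory((1, 1), 7, (0, 97)),
                         PolyTrajectory((1, 1), 7, (0, 97)))
        assert w.shape_distance(t, anchored) == pytest.approx(
            w.shape_distance(t, solution.prototypes[0]), abs=1e-12
        )

    def test_empty_member_set_anchors_at_zero(self, labeled_setup, designs):
        cohort, solution = labeled_setup
        anchored = w.apply_display_intercept(solution.prototypes[0], [], cohort)
        assert anchored.display_intercepts == (0.0, 0.0)
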