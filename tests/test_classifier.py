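"""Linear max-margin boundary, amplitude ranking, accuracy grid, SVD baseline."""

import numpy as np
import pytest
from scipy import stats

from supercells import (
    SupercellConfig,
    SyntheticSpec,
    accuracy_grid,
    boundary_distances,
    build_supercell_cohort,
    expected_accuracy_1d,
    generate_cohort,
    stack_supercells,
    svd_project,
    train_linear,
)
from supercells.exceptions import DegenerateLabelsError, SchemaError
from oracles import brute_force_max_margin_2d


def fit_clouds(cohort, n, k=100, seed=0, **kw):
    clouds = build_supercell_cohort(cohort, SupercellConfig(n, k, seed=seed))
    X, y, _ = stack_supercells(clouds)
    clf = train_linear(X, y, cohort.class_names[0],
                       feature_names=cohort.measurement_names, **kw)
    return clf, X, y


class TestBoundaryGeometry:
    def test_two_point_1d_symmetry(self):
        clf = train_linear([[2.0], [0.0]], ["pos", "neg"], "pos")
        d = boundary_distances(clf, [[2.0], [0.0]])
        assert d[0] == pytest.approx(-d[1], abs=1e-9)
        assert d[0] > 0
        # midpoint of the standardized pair lies on the boundary
        assert boundary_distances(clf, [[1.0]])[0] == pytest.approx(0.0, abs=1e-6)

    def test_four_point_axis_aligned_set(self):
        X = [[0, 0], [0, 1], [2, 0], [2, 1]]
        y = ["neg", "neg", "pos", "pos"]
        clf = train_linear(X, y, "pos")
        # the second measurement carries no class signal
        assert abs(clf.amplitudes_[1]) < 1e-6
        assert clf.amplitudes_[0] == pytest.approx(1.0, abs=1e-6)
        # all four points are support vectors at +-1 margin unit
        d = boundary_distances(clf, X)
        assert np.allclose(np.abs(d), clf.margin_, atol=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_margin_matches_brute_force_on_random_separable_sets(self, seed):
        rng = np.random.default_rng(seed)
        while True:  # rejection-sample a strictly separable 6-point set
            X = rng.uniform(-1, 1, (6, 2))
            proj = X @ [1.0, 0.6]
            y = np.where(proj > np.median(proj), "a", "b")
            if len(set(y)) == 2:
                gap = X[y == "a"] @ [1.0, 0.6]
                if gap.min() - (X[y == "b"] @ [1.0, 0.6]).max() > 0.15:
                    break
        clf = train_linear(X, y, "a", margin_cost=1e8, standardize=False)
        oracle = brute_force_max_margin_2d(X, y)
        assert clf.margin_ == pytest.approx(oracle, abs=1e-6)

    def test_reflection_negates_distance(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(2, 1, (30, 3)), rng.normal(-2, 1, (30, 3))])
        y = ["p"] * 30 + ["q"] * 30
        clf = train_linear(X, y, "p")
        pt = np.array([[0.7, -0.4, 1.2]])
        d = boundary_distances(clf, pt)[0]
        z = (pt - clf.mean_) / clf.scale_
        reflected_z = z - 2 * d * clf.amplitudes_
        reflected = reflected_z * clf.scale_ + clf.mean_
        assert boundary_distances(clf, reflected)[0] == pytest.approx(-d, abs=1e-9)

    def test_point_on_hyperplane_has_zero_distance(self):
        clf = train_linear([[0.0, 0], [2.0, 1], [0.0, 1], [2.0, 0]],
                           ["n", "p", "n", "p"], "p")
        # boundary point: midway along the normal in raw space
        assert boundary_distances(clf, [[1.0, 0.5]])[0] == pytest.approx(0, abs=1e-6)

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateLabelsError):
            train_linear([[1.0], [2.0]], ["a", "a"], "a")

    def test_measurement_count_mismatch(self):
        clf = train_linear([[1.0, 0], [0, 1.0]], ["a", "b"], "a")
        with pytest.raises(SchemaError):
            boundary_distances(clf, [[1.0]])

    def test_zero_variance_measurement_dropped_with_warning(self):
        X = [[0.0, 5.0], [1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]
        with pytest.warns(UserWarning, match="zero-variance"):
            clf = train_linear(X, ["a", "a", "b", "b"], "a",
                               feature_names=["sig", "flat"])
        assert clf.dropped_features_ == ["flat"]
        assert clf.amplitudes_[1] == 0.0


class TestInvariances:
    def test_scale_invariance_of_amplitudes_and_ranking(self, overlap_cohort):
        clf, X, y = fit_clouds(overlap_cohort, n=50, k=40)
        X2 = X.copy()
        X2[:, 0] *= 731.0  # positive rescaling of one raw measurement
        clf2 = train_linear(X2, y, overlap_cohort.class_names[0],
                            feature_names=overlap_cohort.measurement_names)
        assert np.allclose(clf.amplitudes_, clf2.amplitudes_, atol=1e-7)
        assert (clf.rank_measurements().ordered_measurements
                == clf2.rank_measurements().ordered_measurements)
        Xq = X[::7]
        Xq2 = Xq.copy()
        Xq2[:, 0] *= 731.0
        assert np.allclose(boundary_distances(clf, Xq),
                           boundary_distances(clf2, Xq2), atol=1e-7)

    def test_label_swap_antisymmetry(self, overlap_cohort):
        clf_a, X, y = fit_clouds(overlap_cohort, n=50, k=40)
        clf_b = train_linear(X, y, overlap_cohort.class_names[1],
                             feature_names=overlap_cohort.measurement_names)
        assert np.allclose(clf_a.amplitudes_, -clf_b.amplitudes_, atol=1e-7)
        assert clf_a.intercept_ == pytest.approx(-clf_b.intercept_, abs=1e-7)
        Xq = X[::11]
        assert np.allclose(boundary_distances(clf_a, Xq),
                           -boundary_distances(clf_b, Xq), atol=1e-7)
        assert (np.mean(clf_a.predict(X) == y)
                == pytest.approx(np.mean(clf_b.predict(X) == y)))


class TestRanking:
    def test_rank_order_by_absolute_amplitude(self):
        clf = train_linear(np.eye(3) + 1.0, ["a", "a", "b"], "a",
                           feature_names=["m1", "m2", "m3"])
        clf.amplitudes_ = np.array([0.1, -0.9, 0.3])  # exercise sorting alone
        r = clf.rank_measurements()
        assert r.ordered_measurements == ["m2", "m3", "m1"]
        assert np.allclose(r.abs_amplitudes, [0.9, 0.3, 0.1])
        assert list(r.order) == [1, 2, 0]

    def test_shifted_measurement_ranks_first_and_dominates(self):
        spec = SyntheticSpec(
            n_patients_per_class=(3, 3), cells_per_patient=1500,
            n_measurements=5, class_shift=[1, 0, 0, 0, 0],
            patient_effect_sd=0.0, seed=13,
        )
        cohort = generate_cohort(spec)
        clf, _, _ = fit_clouds(cohort, n=200, k=60, seed=13)
        r = clf.rank_measurements()
        assert r.ordered_measurements[0] == "m01"
        assert r.abs_amplitudes[0] > 0.9  # |amplitude| -> 1 as N grows

    def test_rank_order_stabilizes_for_large_supercells(self, overlap_cohort):
        def ranks_at(n):
            clf, _, _ = fit_clouds(overlap_cohort, n=n, k=60, seed=2)
            order = clf.rank_measurements().order
            pos = np.empty(len(order), dtype=int)
            pos[order] = np.arange(len(order))
            return pos

        r1, r200, r500 = ranks_at(1), ranks_at(200), ranks_at(500)
        rho_large = stats.spearmanr(r200, r500).statistic
        rho_small = stats.spearmanr(r1, r500).statistic
        assert rho_large > rho_small


class TestAccuracyGrid:
    def test_identical_classes_stay_at_chance(self, gauss1d_cohort):
        cohort = gauss1d_cohort(delta=0.0, n_patients=3, cells=1000)
        grid = accuracy_grid(
            cohort, [25], [1], SupercellConfig(25, 80, seed=5),
            evaluation="held_out", margin_cost=1.0,
        )
        assert 0.4 < grid.accuracy[0, 0] < 0.6

    def test_matches_gaussian_closed_form(self, gauss1d_cohort):
        cohort = gauss1d_cohort(delta=1.0, n_patients=2, cells=2500, seed=23)
        cfg = SupercellConfig(size_n=10, count_k=250, seed=23)
        grid = accuracy_grid(cohort, [10], [1], cfg,
                             evaluation="held_out", margin_cost=1.0)
        expected = expected_accuracy_1d(1.0, 1.0, 10)
        n_eval = 4 * cfg.count_k
        se = np.sqrt(expected * (1 - expected) / n_eval)
        assert abs(grid.accuracy[0, 0] - expected) < 3 * se + 0.01

    def test_accuracy_nondecreasing_in_n_and_m(self, overlap_cohort):
        grid = accuracy_grid(
            overlap_cohort, [1, 10, 100], [1, 3, 10],
            SupercellConfig(1, 60, seed=4), evaluation="held_out",
            margin_cost=1.0,
        )
        a = grid.accuracy
        assert (np.diff(a, axis=0) > -0.05).all()  # along N
        assert (np.diff(a, axis=1) > -0.05).all()  # along M

    def test_insufficient_cells_names_the_sample(self, small_cohort):
        from supercells.exceptions import InsufficientCellsError
        with pytest.raises(InsufficientCellsError):
            accuracy_grid(small_cohort, [40], [1],
                          SupercellConfig(40, 10, seed=0), evaluation="held_out")


class TestSVDBaseline:
    def test_rank_one_input_second_component_vanishes(self):
        u = np.linspace(0, 1, 40)[:, None]
        X = u @ np.array([[2.0, -1.0, 0.5]])
        proj = svd_project(X, 2)
        assert proj[:, 1].std() < 1e-10

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3)) @ np.diag([3.0, 1.0, 0.2])
        proj = svd_project(X, 3)
        evals = np.sort(np.linalg.eigvalsh(np.cov(X.T, ddof=0)))[::-1]
        proj_var = proj.var(axis=0, ddof=0)
        assert np.allclose(proj_var, evals, rtol=1e-8)
        # scores are uncorrelated
        off = np.cov(proj.T) - np.diag(np.diag(np.cov(proj.T)))
        assert np.abs(off).max() < 1e-8

    def test_unsupervised_projection_fails_where_supercells_succeed(
        self, overlap_cohort
    ):
        # single cells: top-2 SVD projection stays non-separable
        X = np.vstack([s.values for s in overlap_cohort])
        y = np.concatenate(
            [np.repeat(s.class_label, s.n_cells) for s in overlap_cohort]
        )
        sub = np.random.default_rng(0).choice(len(X), 3000, replace=False)
        proj = svd_project(X[sub], 2)
        clf = train_linear(proj, y[sub], overlap_cohort.class_names[0],
                           margin_cost=1.0)
        svd_acc = np.mean(clf.predict(proj) == y[sub])
        grid = accuracy_grid(
            overlap_cohort, [100], [10], SupercellConfig(100, 50, seed=1),
            evaluation="held_out", margin_cost=1.0,
        )
        assert svd_acc < 0.65
        assert grid.accuracy[0, 0] > 0.95

    def test_single_cell_training_fails_but_supercells_classify(
        self, overlap_cohort
    ):
        grid = accuracy_grid(
            overlap_cohort, [1, 100], [10], SupercellConfig(1, 60, seed=3),
            evaluation="training", margin_cost=1.0,
        )
        assert grid.at(1, 10) < 0.7
        assert grid.at(100, 10) > 0.95
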