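import numpy as np
import pytest
from scipy import optimize

from inspire.core import (
    LatentFeatures,
    ModuleAssignment,
    assign_leftover,
    coordinate_sweep_latents,
    fit,
    objective,
    update_assignments,
    update_latents,
    update_precision,
)
from inspire.datamodel import ExpressionDataset, build_collection, zscore_genes
from inspire.evaluate import rand_index
from inspire.simulate import SimulationConfig, make_instantiation

from conftest import make_dataset


def _collection_from(values, prefix="a"):
    ds = make_dataset(values, prefix=prefix)
    ds.standardized = True  # raw values on purpose for algebraic checks
    return build_collection([ds])


def _random_problem(rng, p=12, n=6, k=3, q=2):
    datasets = []
    for qi in range(q):
        ds = make_dataset(rng.standard_normal((p, n)), prefix=f"d{qi}")
        ds.standardized = True
        datasets.append(ds)
    coll = build_collection(datasets)
    assignment = ModuleAssignment(coll.universe, rng.integers(0, k, p), k)
    A = rng.standard_normal((k, k))
    theta = A @ A.T + k * np.eye(k)
    return coll, assignment, theta


class TestLatentStep:
    def test_single_module_closed_form(self):
        """One module, two genes with one sample each valued 1 and 3:
        (m + sigma^2 theta) L = sum x -> 3 L = 4."""
        coll = _collection_from([[1.0], [3.0]])
        assignment = ModuleAssignment(coll.universe, [0, 0], 1)
        latents = update_latents(coll, assignment, np.array([[1.0]]), 1.0)
        np.testing.assert_allclose(latents.per_dataset[0], [[4.0 / 3.0]])

    def test_matches_generic_optimizer(self, rng):
        coll, assignment, theta = _random_problem(rng, p=8, n=4, k=3, q=2)
        sigma = 0.7
        latents = update_latents(coll, assignment, theta, sigma)

        def negobj(flat):
            total = 0.0
            off = 0
            for q, ds in enumerate(coll.datasets):
                L = flat[off : off + 3 * ds.n_samples].reshape(3, ds.n_samples)
                off += 3 * ds.n_samples
                labels = assignment.labels[coll.dataset_rows[q]]
                total += np.trace(L @ L.T @ theta)
                total += ((ds.values - L[labels]) ** 2).sum() / sigma**2
            return total

        x0 = np.zeros(sum(3 * ds.n_samples for ds in coll.datasets))
        res = optimize.minimize(negobj, x0, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-14})
        ours = np.concatenate([m.ravel() for m in latents.per_dataset])
        np.testing.assert_allclose(ours, res.x, atol=1e-4)

    def test_decoupled_limit_is_module_mean(self, rng):
        """With diagonal Theta and sigma^2 Theta_cc -> 0, each latent is the
        plain mean of its member genes."""
        X = rng.standard_normal((9, 5))
        coll = _collection_from(X)
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        assignment = ModuleAssignment(coll.universe, labels, 3)
        latents = update_latents(coll, assignment, np.eye(3), sigma=1e-6)
        for c in range(3):
            np.testing.assert_allclose(
                latents.per_dataset[0][c], X[labels == c].mean(axis=0), atol=1e-9
            )

    def test_zero_data_zero_latents(self):
        coll = _collection_from(np.zeros((4, 3)))
        assignment = ModuleAssignment(coll.universe, [0, 1, 0, 1], 2)
        latents = update_latents(coll, assignment, np.eye(2), 1.0)
        np.testing.assert_array_equal(latents.per_dataset[0], np.zeros((2, 3)))

    def test_linear_solve_matches_coordinate_sweeps(self, rng):
        """The one-shot linear solve equals 500 cyclic per-module sweeps."""
        coll, assignment, theta = _random_problem(rng, p=15, n=7, k=4, q=2)
        direct = update_latents(coll, assignment, theta, 0.8)
        swept = coordinate_sweep_latents(coll, assignment, theta, 0.8, n_sweeps=500)
        for a, b in zip(direct.per_dataset, swept.per_dataset):
            np.testing.assert_allclose(a, b, atol=1e-8)


class TestAssignmentStep:
    def test_exact_match_gets_zero_distance_module(self, rng):
        L = rng.standard_normal((3, 6))
        X = np.vstack([L[2], L[0], L[1] + 0.01])
        coll = _collection_from(X)
        latents = LatentFeatures([L])
        assignment = update_assignments(coll, latents)
        np.testing.assert_array_equal(assignment.labels, [2, 0, 1])

    def test_tie_breaks_to_lowest_index(self):
        L = np.array([[1.0, 1.0], [1.0, 1.0], [0.0, 0.0]])
        coll = _collection_from([[1.0, 1.0]])
        assignment = update_assignments(coll, LatentFeatures([L]))
        assert assignment.labels[0] == 0

    def test_shared_gene_scored_on_concatenated_samples(self, rng):
        """A gene in both datasets is assigned by the summed distance, which
        can differ from either dataset's individual preference."""
        # module 0 wins in dataset A, module 1 wins (by more) in dataset B
        LA = np.array([[1.0, 1.0], [0.0, 0.0]])
        LB = np.array([[4.0, 4.0], [0.0, 0.0]])
        dsA = make_dataset([[0.9, 0.9]], prefix="a")
        dsB = make_dataset([[0.5, 0.5]], prefix="b")
        dsA.standardized = dsB.standardized = True
        coll = build_collection([dsA, dsB])
        assignment = update_assignments(coll, LatentFeatures([LA, LB]))
        # dataset A alone prefers module 0 (0.01+0.01 < 0.81+0.81) but the
        # summed distance over both datasets prefers module 1
        dist0 = 2 * 0.01 + 2 * 3.5**2
        dist1 = 2 * 0.81 + 2 * 0.25
        assert dist1 < dist0
        assert assignment.labels[0] == 1


class TestPrecisionStep:
    @staticmethod
    def _latents(rng, k=3, n=40):
        A = rng.standard_normal((k, k))
        cov = A @ A.T / k + np.eye(k)
        L = np.linalg.cholesky(cov) @ rng.standard_normal((k, n))
        return LatentFeatures([L])

    def test_large_lambda_gives_diagonal(self, rng):
        lat = self._latents(rng)
        S = lat.empirical_covariance()
        big = np.abs(S - np.diag(np.diag(S))).max() * 1.5 + 0.1
        prec = update_precision(lat, big)
        off = prec.theta[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-10)
        np.testing.assert_allclose(np.diag(prec.theta), 1.0 / np.diag(S), rtol=1e-6)

    def test_tiny_lambda_matches_inverse(self, rng):
        lat = self._latents(rng, k=3, n=200)
        S = lat.empirical_covariance()
        prec = update_precision(lat, 1e-8)
        np.testing.assert_allclose(prec.theta, np.linalg.inv(S), atol=1e-4)

    def test_offdiagonals_shrink_with_lambda(self, rng):
        lat = self._latents(rng, k=4, n=60)
        lams = [0.01, 0.05, 0.1, 0.3]
        maxes = []
        for lam in lams:
            theta = update_precision(lat, lam).theta
            off = np.abs(theta[~np.eye(4, dtype=bool)])
            maxes.append(off)
        for a, b in zip(maxes, maxes[1:]):
            assert np.all(b <= a + 1e-6)

    def test_nonpositive_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            update_precision(self._latents(rng), 0.0)


class TestObjective:
    def test_perfect_reconstruction_drops_data_term(self, rng):
        k, p, n = 2, 6, 5
        L = rng.standard_normal((k, n))
        labels = np.array([0, 1, 0, 1, 0, 1])
        coll = _collection_from(L[labels])
        assignment = ModuleAssignment(coll.universe, labels, k)
        latents = LatentFeatures([L])
        theta = np.eye(k)
        val = objective(coll, assignment, latents, theta, sigma=0.31, lam=0.1)
        # equal to the pure Theta part: reconstruction contributes nothing
        S = latents.empirical_covariance()
        expected = 0.5 * n * (0.0 - np.trace(S))
        np.testing.assert_allclose(val, expected, atol=1e-10)

    def test_identity_theta_reduces_to_trace_term(self, rng):
        coll, assignment, _ = _random_problem(rng, p=5, n=4, k=1, q=1)
        latents = update_latents(coll, assignment, np.eye(1), 1.0)
        val = objective(coll, assignment, latents, np.eye(1), 1.0, 0.2)
        S = latents.empirical_covariance()
        recon = sum(
            ((ds.values - latents.per_dataset[q][assignment.labels[coll.dataset_rows[q]]]) ** 2).sum()
            for q, ds in enumerate(coll.datasets)
        )
        expected = -0.5 * coll.n_total * np.trace(S) - 0.5 * recon
        np.testing.assert_allclose(val, expected)

    def test_non_pd_theta_rejected(self, rng):
        coll, assignment, theta = _random_problem(rng)
        latents = update_latents(coll, assignment, theta, 1.0)
        with pytest.raises(ValueError):
            objective(coll, assignment, latents, -np.eye(3), 1.0, 0.1)


class TestFit:
    @staticmethod
    def _synthetic_collection(seed, setting=(150, 100, 0), sigma_obs=1.0):
        truth = make_instantiation(
            SimulationConfig(setting=setting, sigma_obs=sigma_obs), seed
        )
        coll = build_collection(
            [zscore_genes(truth.dataset1), zscore_genes(truth.dataset2)]
        )
        return truth, coll

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_ascent(self, seed):
        """The tracked objective never decreases along the trace."""
        _, coll = self._synthetic_collection(seed)
        model = fit(coll, 10, 0.05, seed=seed)
        trace = np.asarray(model.objective_trace)
        assert np.all(np.diff(trace) >= -1e-8)
        assert not model.degenerate

    def test_single_dataset_equals_joint_on_one_dataset(self, rng):
        ds = make_dataset(rng.standard_normal((30, 12)), standardize=True)
        coll = build_collection([ds])
        init = ModuleAssignment(coll.universe, rng.integers(0, 4, 30), 4)
        a = fit(coll, 4, 0.1, init=init, mode="joint")
        b = fit(coll, 4, 0.1, init=init, mode="single_dataset")
        np.testing.assert_array_equal(a.assignment.labels, b.assignment.labels)
        np.testing.assert_allclose(a.precision.theta, b.precision.theta, atol=1e-12)

    def test_duplicate_dataset_joint_equals_single(self, rng):
        """Presenting the same data twice (fresh sample IDs) changes nothing
        relative to fitting dataset 1 alone."""
        X = rng.standard_normal((30, 12))
        ds1 = make_dataset(X, prefix="a", standardize=True)
        ds2 = make_dataset(X, prefix="b", standardize=True)
        coll = build_collection([ds1, ds2])
        init = ModuleAssignment(coll.universe, rng.integers(0, 4, 30), 4)
        a = fit(coll, 4, 0.1, init=init, mode="joint")
        b = fit(coll, 4, 0.1, init=init, mode="single_dataset")
        np.testing.assert_array_equal(a.assignment.labels, b.assignment.labels)
        np.testing.assert_allclose(a.precision.theta, b.precision.theta, atol=1e-8)
        np.testing.assert_allclose(
            a.latents.per_dataset[0], b.latents.per_dataset[0], atol=1e-8
        )

    def test_noiseless_recovery_is_exact(self):
        """With no observation noise the true partition is recovered."""
        for seed in (0, 1, 2):
            truth, coll = self._synthetic_collection(
                seed, setting=(250, 0, 0), sigma_obs=0.0
            )
            model = fit(coll, 10, 0.1, seed=seed)
            assert rand_index(truth.Z_true.labels, model.assignment.labels) == 1.0

    def test_deterministic_under_seed(self):
        _, coll = self._synthetic_collection(5)
        a = fit(coll, 10, 0.1, seed=7)
        b = fit(coll, 10, 0.1, seed=7)
        np.testing.assert_array_equal(a.assignment.labels, b.assignment.labels)
        np.testing.assert_array_equal(a.precision.theta, b.precision.theta)

    def test_more_samples_recover_better(self):
        """Average module recovery on full overlap improves from n=20-only
        to all 50 samples."""
        r_small, r_big = [], []
        for seed in range(8):
            truth, coll = self._synthetic_collection(
                seed, setting=(250, 0, 0), sigma_obs=1.0
            )
            single = fit(coll, 10, 0.1, seed=seed, mode="single_dataset")
            joint = fit(coll, 10, 0.1, seed=seed, mode="joint")
            r_small.append(rand_index(truth.Z_true.labels, single.assignment.labels))
            r_big.append(rand_index(truth.Z_true.labels, joint.assignment.labels))
        assert np.mean(r_big) > np.mean(r_small)


class TestAssignLeftover:
    def test_empty_leftover_unchanged(self, rng):
        _, coll = TestFit._synthetic_collection(0, setting=(250, 0, 0))
        model = fit(coll, 10, 0.1, seed=0)
        out = assign_leftover(model, coll, [])
        np.testing.assert_array_equal(out.labels, model.assignment.labels)

    def test_duplicated_gene_gets_nearest_latent_module(self, rng):
        X = rng.standard_normal((20, 10))
        ds = make_dataset(X, standardize=True)
        coll = build_collection([ds])
        model = fit(coll, 3, 0.1, seed=1)
        # a "new" universe where one extra gene copies gene 0's row
        X2 = np.vstack([X, X[0]])
        ds2 = ExpressionDataset(
            [f"g{i:03d}" for i in range(20)] + ["zz_copy"],
            ds.sample_ids,
            X2,
            standardized=False,
        )
        ds2.standardized = True
        coll2 = build_collection([ds2])
        out = assign_leftover(model, coll2, ["zz_copy"])
        idx = {g: i for i, g in enumerate(out.gene_ids)}
        # the copy lands in whichever module's latent is nearest to the row
        L = model.latents.per_dataset[0]
        d = ((X[0] - L) ** 2).sum(axis=1)
        assert out.labels[idx["zz_copy"]] == int(np.argmin(d))

    def test_unknown_gene_rejected(self):
        _, coll = TestFit._synthetic_collection(0, setting=(250, 0, 0))
        model = fit(coll, 10, 0.1, seed=0)
        with pytest.raises(KeyError):
            assign_leftover(model, coll, ["not_a_gene"])

    def test_leftover_recovery_beats_chance(self):
        """On partial overlap, nearest-latent assignment of the unshared
        genes recovers their true module far above the 1/k chance rate."""
        truth, coll = TestFit._synthetic_collection(
            3, setting=(150, 100, 0), sigma_obs=0.5
        )
        model = fit(coll, 10, 0.1, seed=3, mode="intersection_knn")
        overlap = set(truth.dataset2.gene_ids)
        leftover = [g for g in coll.universe if g not in overlap]
        idx = {g: i for i, g in enumerate(model.assignment.gene_ids)}
        tidx = {g: i for i, g in enumerate(truth.Z_true.gene_ids)}
        est = np.array([model.assignment.labels[idx[g]] for g in leftover])
        tru = np.array([truth.Z_true.labels[tidx[g]] for g in leftover])
        # module IDs are not aligned between fit and truth, so score by
        # pair agreement restricted to leftover genes
        assert rand_index(tru, est) > 0.9
        # and by the best label matching: far above 1/k
        from scipy.optimize import linear_sum_assignment

        C = np.zeros((10, 10))
        for t, e in zip(tru, est):
            C[t, e] += 1
        r, c = linear_sum_assignment(-C)
        accuracy = C[r, c].sum() / len(leftover)
        assert accuracy > 3.0 / 10.0
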