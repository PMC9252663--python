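"""OMP sparse coding and K-SVD dictionary training."""

import numpy as np
import pytest

from helpers import (
    exact_recovery_condition,
    exhaustive_sparse_fit,
    greedy_path_margin,
    planted_sparse_signals,
    simplex_frame,
)
from segdict import (
    KSVD,
    Dictionary,
    SparseCodes,
    ksvd_train,
    omp_encode,
    representation_error,
)


def random_dictionary(rng, x=8, d=16):
    atoms = rng.standard_normal((x, d))
    return Dictionary(atoms / np.linalg.norm(atoms, axis=0))


class TestOmp:
    def test_exact_single_atom_signal(self, rng):
        dic = random_dictionary(rng)
        j = 5
        codes = omp_encode(dic, 3.0 * dic.atoms[:, [j]], sparsity=1)
        assert codes.coeffs[j, 0] == pytest.approx(3.0)
        assert np.count_nonzero(codes.coeffs) == 1
        assert codes.residual_norms[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_sparsity_gives_zero_codes(self, rng):
        dic = random_dictionary(rng)
        signals = rng.standard_normal((8, 5))
        codes = omp_encode(dic, signals, sparsity=0)
        assert not codes.coeffs.any()
        np.testing.assert_allclose(
            codes.residual_norms, np.linalg.norm(signals, axis=0)
        )

    def test_matches_exhaustive_support_search(self):
        """Where greedy selection is provably safe (exact-recovery
        condition, unambiguous path) the solution equals the global
        optimum over all supports (the l0 oracle)."""
        rng = np.random.default_rng(77)
        checked = 0
        for trial in range(300):
            if checked >= 40:
                break
            dic = random_dictionary(rng)
            sparsity = int(rng.integers(1, 3))
            support = rng.choice(16, size=sparsity, replace=False)
            coeffs = rng.uniform(1.0, 2.0, sparsity) * rng.choice([-1, 1], sparsity)
            signal = dic.atoms[:, support] @ coeffs
            if not exact_recovery_condition(dic.atoms, support):
                continue
            if greedy_path_margin(dic.atoms, signal, sparsity) < 1e-6:
                continue
            best_support, best_coef, _ = exhaustive_sparse_fit(
                dic.atoms, signal, sparsity
            )
            codes = omp_encode(dic, signal, sparsity)
            got_support = tuple(int(j) for j in np.flatnonzero(codes.coeffs[:, 0]))
            assert set(got_support) == set(best_support)
            np.testing.assert_allclose(
                codes.coeffs[list(best_support), 0], best_coef, atol=1e-9
            )
            checked += 1
        assert checked >= 40

    def test_residual_tolerance_stops_early(self, rng):
        dic = random_dictionary(rng)
        signal = dic.atoms[:, [2]] * 4.0
        codes = omp_encode(dic, signal, sparsity=5, residual_tol=1e-6)
        assert np.count_nonzero(codes.coeffs) == 1

    def test_invalid_inputs(self, rng):
        dic = random_dictionary(rng)
        with pytest.raises(ValueError):
            omp_encode(dic, rng.standard_normal((8, 2)), sparsity=17)
        with pytest.raises(ValueError):
            omp_encode(dic, rng.standard_normal((7, 2)), sparsity=2)


class TestKsvd:
    def test_planted_dictionary_is_recovered(self):
        """Noiseless signals from a minimal-coherence planted frame are
        represented to numerical precision after training."""
        rng = np.random.default_rng(5)
        D0 = simplex_frame(16, rng)
        X, _ = planted_sparse_signals(D0, 500, 3, rng)
        _, _, errors = ksvd_train(X, 16, 3, n_iter=30, seed=5)
        assert errors[-1] / (X**2).sum() <= 1e-6

    def test_error_history_non_increasing(self):
        rng = np.random.default_rng(9)
        D0 = simplex_frame(16, rng)
        X, _ = planted_sparse_signals(D0, 300, 3, rng)
        _, _, errors = ksvd_train(X, 16, 3, n_iter=12, seed=9)
        assert all(b <= a + 1e-9 for a, b in zip(errors, errors[1:]))

    def test_atoms_stay_unit_norm(self, rng):
        X = rng.standard_normal((8, 60))
        dic, _, _ = ksvd_train(X, 16, 3, n_iter=4, seed=1)
        np.testing.assert_allclose(np.linalg.norm(dic.atoms, axis=0), 1.0, atol=1e-9)

    def test_zero_iterations_returns_initialization_with_codes(self, rng):
        X = rng.standard_normal((8, 40))
        dic, codes, errors = ksvd_train(X, 16, 2, n_iter=0, seed=3)
        assert errors == []
        recomputed = omp_encode(dic, X, 2)
        np.testing.assert_array_equal(codes.coeffs, recomputed.coeffs)

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((8, 50))
        d1, c1, e1 = ksvd_train(X, 16, 3, n_iter=3, seed=21)
        d2, c2, e2 = ksvd_train(X, 16, 3, n_iter=3, seed=21)
        np.testing.assert_array_equal(d1.atoms, d2.atoms)
        np.testing.assert_array_equal(c1.coeffs, c2.coeffs)
        assert e1 == e2

    def test_underdetermined_and_degenerate_inputs(self, rng):
        with pytest.raises(ValueError, match="y >= d"):
            ksvd_train(rng.standard_normal((8, 10)), 16, 3)
        with pytest.raises(ValueError, match="zero"):
            ksvd_train(np.zeros((8, 40)), 16, 3)
        with pytest.raises(ValueError, match="overcomplete"):
            ksvd_train(rng.standard_normal((16, 40)), 16, 3)


class TestContainers:
    def test_dictionary_invariants(self, rng):
        with pytest.raises(ValueError, match="overcomplete"):
            Dictionary(np.eye(4))
        atoms = rng.standard_normal((4, 8))
        with pytest.raises(ValueError, match="unit"):
            Dictionary(atoms)

    def test_sparse_codes_sparsity_bound(self):
        with pytest.raises(ValueError, match="sparsity"):
            SparseCodes(np.ones((4, 2)), sparsity=2, residual_norms=np.zeros(2))

    def test_representation_error_matches_brute_force(self, rng):
        atoms = rng.standard_normal((4, 6))
        dic = Dictionary(atoms / np.linalg.norm(atoms, axis=0))
        X = rng.standard_normal((4, 5))
        coeffs = np.zeros((6, 5))
        coeffs[rng.integers(0, 6, 5), np.arange(5)] = rng.standard_normal(5)
        codes = SparseCodes(coeffs, 1, np.linalg.norm(X - dic.atoms @ coeffs, axis=0))
        expected = sum(
            np.linalg.norm(X[:, j] - dic.atoms @ coeffs[:, j]) ** 2 for j in range(5)
        )
        assert representation_error(X, dic, codes) == pytest.approx(expected)

    def test_representation_error_identities(self, rng):
        dic = random_dictionary(rng, 4, 6)
        X = dic.atoms[:, :5] * 2.0
        codes = omp_encode(dic, X, 1)
        assert representation_error(X, dic, codes) == pytest.approx(0.0, abs=1e-18)
        zero = SparseCodes(np.zeros((6, 5)), 0, np.linalg.norm(X, axis=0))
        assert representation_error(X, dic, zero) == pytest.approx((X**2).sum())

    def test_dictionary_save_load(self, tmp_path, rng):
        dic = random_dictionary(rng, 6, 9)
        path = tmp_path / "dict.txt"
        dic.save(path, metadata={"sparsity": 3, "seed": 0})
        back = Dictionary.load(path)
        np.testing.assert_array_equal(back.atoms, dic.atoms)
        assert (tmp_path / "dict.txt.json").exists()


class TestEstimator:
    def test_sklearn_protocol(self, rng):
        from sklearn.base import clone

        est = KSVD(n_atoms=16, sparsity=2, n_iter=2, random_state=0)
        clone(est)  # get_params/set_params round trip
        X = rng.standard_normal((50, 8))
        codes = est.fit(X).transform(X)
        assert est.components_.shape == (16, 8)
        assert codes.shape == (50, 16)
        assert (np.count_nonzero(codes, axis=1) <= 2).all()

    def test_transform_matches_functional_api(self, rng):
        X = rng.standard_normal((40, 8))
        est = KSVD(n_atoms=16, sparsity=3, n_iter=2, random_state=4).fit(X)
        codes = omp_encode(Dictionary(est.components_.T), X.T, 3)
        np.testing.assert_array_equal(est.transform(X), codes.coeffs.T)
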