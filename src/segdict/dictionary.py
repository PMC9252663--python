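"""Sparse coding with OMP and overcomplete dictionary training with K-SVD.

The sparse model: a signal m (a vectorized patch) is approximated as
``m ≈ K α`` with an overcomplete dictionary K of unit-norm atoms
(more atoms than signal dimensions) and a coefficient vector α with at
most ``sparsity`` nonzeros.  Exact l0 minimization is NP-hard; the
greedy orthogonal matching pursuit is the normative solver here, and
K-SVD alternates it with rank-1 singular-value atom updates.

Implementation notes
--------------------
* :func:`omp_encode` is fully batched: atom selection tracks an
  orthonormal basis of each signal's selected atoms (batched
  Gram-Schmidt), and the final coefficients come from stacked
  normal-equation solves grouped by support size.  No per-signal Python
  loop is needed, which is what makes image-scale encoding cheap.
* :func:`ksvd_train` guards monotonicity: after each OMP pass any
  column whose new code fits worse than the previous one keeps the old
  code, so the representation error is non-increasing by construction
  (greedy OMP alone does not guarantee this).
* The SVD sign is fixed so each atom's largest-magnitude entry is
  positive, making repeated runs bit-identical for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .raster import read_matrix, write_matrix

__all__ = [
    "Dictionary",
    "SparseCodes",
    "omp_encode",
    "ksvd_train",
    "representation_error",
    "KSVD",
]



@dataclass
class Dictionary:
    """An overcomplete dictionary: ``atoms`` of shape (x, d) with x < d,
    every column unit l2-norm."""

    atoms: np.ndarray

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 2:
            raise ValueError("atoms must be a 2-D matrix")
        x, d = self.atoms.shape
        if not x < d:
            raise ValueError(f"dictionary must be overcomplete (x={x} >= d={d})")
        norms = np.linalg.norm(self.atoms, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("every atom must have unit l2 norm")

    @property
    def x(self) -> int:
        return self.atoms.shape[0]

    @property
    def d(self) -> int:
        return self.atoms.shape[1]

    def save(self, path, metadata: dict | None = None) -> None:
        """Write atoms as a plain-matrix file plus a JSON sidecar."""
        path = Path(path)
        write_matrix(self.atoms, path)
        sidecar = {"x": self.x, "d": self.d}
        if metadata:
            sidecar.update(metadata)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "Dictionary":
        return cls(read_matrix(path))


@dataclass
class SparseCodes:
    """Coefficients α for a batch of signals: ``coeffs`` of shape (d, y),
    each column with at most ``sparsity`` nonzeros; ``residual_norms[j]``
    is ``||m_j - K α_j||_2``."""

    coeffs: np.ndarray
    sparsity: int
    residual_norms: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.residual_norms = np.asarray(self.residual_norms, dtype=float)
        if self.coeffs.ndim != 2:
            raise ValueError("coeffs must be 2-D (atoms x signals)")
        if self.residual_norms.shape != (self.coeffs.shape[1],):
            raise ValueError("one residual norm per signal required")
        if np.count_nonzero(self.coeffs, axis=0).max(initial=0) > self.sparsity:
            raise ValueError("a column exceeds the sparsity bound")


def _check_signals(signals, x: int) -> np.ndarray:
    arr = np.asarray(signals, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[0] != x:
        raise ValueError(
            f"signals must be (x={x}, y); got shape {np.asarray(signals).shape}"
        )
    return arr


def omp_encode(
    dictionary: Dictionary | np.ndarray,
    signals,
    sparsity: int,
    residual_tol: float = 1e-9,
) -> SparseCodes:
    """Greedy orthogonal matching pursuit, batched over signal columns.

    Per column: repeatedly select the atom with the largest absolute
    correlation with the current residual (ties to the lowest atom
    index), re-solve least squares on the selected support, and stop
    after ``sparsity`` atoms or once the residual norm is at most
    ``residual_tol``.  Off-support coefficients are exactly zero.
    """
    D = dictionary.atoms if isinstance(dictionary, Dictionary) else np.asarray(dictionary, float)
    x, d = D.shape
    X = _check_signals(signals, x)
    y = X.shape[1]
    if sparsity < 0 or sparsity > d:
        raise ValueError(f"sparsity must be in [0, {d}], got {sparsity}")
    coeffs = np.zeros((d, y))
    if sparsity == 0:
        return SparseCodes(coeffs, 0, np.linalg.norm(X, axis=0))

    R = X.copy()
    res_norm = np.linalg.norm(R, axis=0)
    Q = np.zeros((y, x, sparsity))
    support = np.full((y, sparsity), -1, dtype=int)
    n_sel = np.zeros(y, dtype=int)
    active = res_norm > max(residual_tol, 0.0)
    for t in range(sparsity):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        corr = np.abs(D.T @ R[:, idx])  # (d, m)
        for tt in range(t):
            corr[support[idx, tt], np.arange(idx.size)] = -1.0
        chosen = np.argmax(corr, axis=0)
        atoms = D[:, chosen].T  # (m, x)
        if t > 0:
            Qa = Q[idx, :, :t]
            proj = np.einsum("mxk,mx->mk", Qa, atoms)
            atoms = atoms - np.einsum("mxk,mk->mx", Qa, proj)
        norms = np.linalg.norm(atoms, axis=1)
        good = norms > 1e-12
        # An atom (numerically) inside the current span cannot improve the
        # fit along the greedy path; such signals stop here.
        keep = idx[good]
        if keep.size:
            q = atoms[good] / norms[good, None]
            Q[keep, :, t] = q
            support[keep, t] = chosen[good]
            n_sel[keep] = t + 1
            dots = np.einsum("mx,xm->m", q, R[:, keep])
            R[:, keep] -= (q * dots[:, None]).T
            res_norm[keep] = np.linalg.norm(R[:, keep], axis=0)
        active[idx[~good]] = False
        active[keep] = res_norm[keep] > max(residual_tol, 0.0)

    # Final coefficients: stacked least squares on each signal's support,
    # grouped by support size so every solve is one batched call.
    for k in np.unique(n_sel):
        if k == 0:
            continue
        cols = np.flatnonzero(n_sel == k)
        S = support[cols, :k]  # (m, k)
        A = np.transpose(D[:, S], (1, 0, 2))  # (m, x, k)
        G = np.einsum("mxi,mxj->mij", A, A)
        b = np.einsum("mxi,xm->mi", A, X[:, cols])
        sol = np.linalg.solve(G, b[..., None])[..., 0]
        coeffs[S, cols[:, None]] = sol
    residuals = np.linalg.norm(X - D @ coeffs, axis=0)
    return SparseCodes(coeffs, sparsity, residuals)


def representation_error(signals, dictionary: Dictionary | np.ndarray, codes: SparseCodes) -> float:
    """Total squared coding error ``sum_j ||m_j - K α_j||_2**2``."""
    D = dictionary.atoms if isinstance(dictionary, Dictionary) else np.asarray(dictionary, float)
    X = _check_signals(signals, D.shape[0])
    if codes.coeffs.shape != (D.shape[1], X.shape[1]):
        raise ValueError(
            f"codes have shape {codes.coeffs.shape}, expected {(D.shape[1], X.shape[1])}"
        )
    return float(((X - D @ codes.coeffs) ** 2).sum())


def _sign_fix(vec: np.ndarray) -> float:
    """Sign making the largest-magnitude entry of ``vec`` positive."""
    return 1.0 if vec[np.argmax(np.abs(vec))] >= 0 else -1.0


def _init_dictionary(X: np.ndarray, d: int, rng: np.random.Generator) -> np.ndarray:
    norms = np.linalg.norm(X, axis=0)
    candidates = np.flatnonzero(norms > 1e-12)
    if candidates.size < d:
        raise ValueError(
            f"need at least {d} nonzero training signals, got {candidates.size}"
        )
    idx = rng.choice(candidates, size=d, replace=False)
    D = X[:, np.sort(idx)] / norms[np.sort(idx)]
    for j in range(d):
        D[:, j] *= _sign_fix(D[:, j])
    return D.copy()


def _attempt_reseed(
    X: np.ndarray,
    D: np.ndarray,
    A: np.ndarray,
    sparsity: int,
    residual_tol: float,
    prev_err: float,
    n_candidates: int,
):
    """Try to escape a dictionary-learning local minimum.

    The worst-represented column's residual points (up to the span of
    its correctly coded atoms) along whatever structure the dictionary
    is missing, so that direction is offered as a replacement for each
    of the ``n_candidates`` lowest-energy atoms in turn; a full
    re-coding follows, keeping any still-valid old code that fits
    better.  The replacement is accepted only if the total error
    strictly decreases — rollback otherwise — so the per-iteration
    error stays non-increasing by construction.
    """
    residual = X - D @ A
    wcol = int(np.argmax(np.linalg.norm(residual, axis=0)))
    vec = residual[:, wcol]
    if np.linalg.norm(vec) <= 1e-10 * np.linalg.norm(X):
        return None
    vec = vec / np.linalg.norm(vec) * _sign_fix(vec)
    for j in np.argsort((A**2).sum(axis=1))[:n_candidates]:
        D_try = D.copy()
        D_try[:, j] = vec
        new = omp_encode(D_try, X, sparsity, residual_tol)
        A_try = new.coeffs
        # Old codes remain valid for columns that never used atom j.
        valid = A[j, :] == 0
        old_res = np.linalg.norm(X - D_try @ A, axis=0)
        keep = valid & (old_res < new.residual_norms)
        A_try[:, keep] = A[:, keep]
        err_try = float(((X - D_try @ A_try) ** 2).sum())
        if err_try < prev_err - 1e-12:
            return D_try, A_try
    return None


def ksvd_train(
    signals,
    n_atoms: int,
    sparsity: int,
    n_iter: int = 10,
    seed: int = 0,
    residual_tol: float = 1e-9,
    reseed_candidates: int = 4,
):
    """Train an overcomplete dictionary with K-SVD.

    Alternates a full OMP coding pass with sequential atom updates: for
    each atom, the residual of the signals using it (with that atom's
    own contribution restored) is reduced by its best rank-1
    approximation, which simultaneously replaces the atom (left singular
    vector, unit norm) and its coefficient row (singular value times
    right singular vector).  Atoms used by no signal are replaced by the
    currently worst-represented residual direction, normalized.

    Two safeguards keep the reported error non-increasing while still
    escaping the local minima this alternation is prone to: (a) after
    each coding pass, any column whose fresh OMP code fits worse than
    its previous code keeps the previous one; (b) each iteration first
    offers the worst column's residual direction as a replacement for a
    low-energy atom and keeps it only if the total error strictly drops
    (see :func:`_attempt_reseed`; disable with ``reseed_candidates=0``).

    Returns
    -------
    (Dictionary, SparseCodes, errors)
        The trained dictionary, codes consistent with it, and the
        representation error after each full iteration (non-increasing).
    """
    X = np.asarray(signals, dtype=float)
    if X.ndim != 2:
        raise ValueError("signals must be a 2-D matrix (x, y)")
    x, y = X.shape
    if y < n_atoms:
        raise ValueError(f"training needs y >= d signals (y={y}, d={n_atoms})")
    if not x < n_atoms:
        raise ValueError(f"dictionary must be overcomplete (x={x} >= d={n_atoms})")
    if not np.any(np.linalg.norm(X, axis=0) > 1e-12):
        raise ValueError("all training signals are (numerically) zero")
    rng = np.random.default_rng(seed)
    D = _init_dictionary(X, n_atoms, rng)
    codes = omp_encode(D, X, sparsity, residual_tol)
    prev_err = float((codes.residual_norms**2).sum())
    errors: list[float] = []
    A = codes.coeffs.copy()
    for iteration in range(n_iter):
        reseeded = None
        if iteration >= 1 and reseed_candidates > 0:
            reseeded = _attempt_reseed(
                X, D, A, sparsity, residual_tol, prev_err, reseed_candidates
            )
        if reseeded is not None:
            D, A = reseeded
        else:
            new = omp_encode(D, X, sparsity, residual_tol)
            # Monotone safeguard: keep previous codes wherever OMP regressed.
            old_res = np.linalg.norm(X - D @ A, axis=0)
            worse = new.residual_norms > old_res + 1e-12
            A_new = new.coeffs
            A_new[:, worse] = A[:, worse]
            A = A_new

        residual_cols = np.linalg.norm(X - D @ A, axis=0)
        for j in range(n_atoms):
            using = np.flatnonzero(A[j] != 0)
            if using.size == 0:
                worst = int(np.argmax(residual_cols))
                col = (X - D @ A)[:, worst]
                if np.linalg.norm(col) < 1e-12:
                    col = X[:, worst]
                nrm = np.linalg.norm(col)
                if nrm > 1e-12:
                    D[:, j] = col / nrm * _sign_fix(col)
                continue
            E = X[:, using] - D @ A[:, using] + np.outer(D[:, j], A[j, using])
            U, s, Vt = np.linalg.svd(E, full_matrices=False)
            sign = _sign_fix(U[:, 0])
            D[:, j] = U[:, 0] * sign
            A[j, using] = s[0] * Vt[0] * sign
            residual_cols[using] = np.linalg.norm(
                X[:, using] - D @ A[:, using], axis=0
            )
        codes = SparseCodes(A, sparsity, np.linalg.norm(X - D @ A, axis=0))
        err = float((codes.residual_norms**2).sum())
        errors.append(err)
        prev_err = err
    return Dictionary(D), codes, errors


class KSVD(TransformerMixin, BaseEstimator):
    """K-SVD dictionary learning as a scikit-learn transformer.

    ``fit(X)`` learns the dictionary from signals given as rows of X
    (sklearn convention); ``transform(X)`` returns OMP sparse codes,
    one row per signal.

    Attributes
    ----------
    components_ : ndarray of shape (n_atoms, n_features)
        Learned unit-norm atoms, one per row.
    error_history_ : list of float
        Representation error after each K-SVD iteration.
    """

    def __init__(
        self,
        n_atoms: int = 64,
        sparsity: int = 4,
        n_iter: int = 10,
        residual_tol: float = 1e-9,
        random_state: int = 0,
    ):
        self.n_atoms = n_atoms
        self.sparsity = sparsity
        self.n_iter = n_iter
        self.residual_tol = residual_tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        dictionary, codes, errors = ksvd_train(
            X.T,
            self.n_atoms,
            self.sparsity,
            n_iter=self.n_iter,
            seed=self.random_state,
            residual_tol=self.residual_tol,
        )
        self.components_ = dictionary.atoms.T
        self.error_history_ = errors
        self.n_iter_ = self.n_iter
        self._codes_ = codes
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        codes = omp_encode(
            Dictionary(self.components_.T), X.T, self.sparsity, self.residual_tol
        )
        return codes.coeffs.T
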