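"""Shared oracles and generators for the test suite.

Everything here is deliberately naive — brute force, exhaustive
enumeration, direct double loops — and independent of the library code
paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def simplex_frame(n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """The simplex equiangular tight frame: ``n_atoms`` unit vectors in
    dimension ``n_atoms - 1`` with pairwise inner products exactly
    ``-1/(n_atoms-1)`` (minimal possible coherence), randomly rotated.
    At this coherence greedy pursuit recovers 3-sparse supports exactly,
    which makes it the natural planted dictionary for noiseless
    recovery experiments."""
    from scipy.stats import ortho_group

    d = n_atoms
    V = np.eye(d) - np.ones((d, d)) / d
    Q, _ = np.linalg.qr(V[:, : d - 1])
    frame = Q.T @ V
    frame /= np.linalg.norm(frame, axis=0)
    rotation = ortho_group.rvs(d - 1, random_state=rng)
    return rotation @ frame


def planted_sparse_signals(
    dictionary: np.ndarray,
    n_signals: int,
    sparsity: int,
    rng: np.random.Generator,
    coeff_range: tuple[float, float] = (1.0, 2.0),
):
    """Noiseless signals synthesized from random supports of the planted
    dictionary with coefficients of magnitude in ``coeff_range`` (bounded
    away from zero so supports are identifiable)."""
    d = dictionary.shape[1]
    codes = np.zeros((d, n_signals))
    for j in range(n_signals):
        support = rng.choice(d, size=sparsity, replace=False)
        codes[support, j] = rng.uniform(*coeff_range, size=sparsity) * rng.choice(
            [-1.0, 1.0], size=sparsity
        )
    return dictionary @ codes, codes


def exhaustive_sparse_fit(D: np.ndarray, signal: np.ndarray, sparsity: int):
    """Best least-squares fit over *all* supports of size <= sparsity.

    Returns (support tuple, coefficients, residual norm) of the global
    optimum of the l0-constrained problem — the oracle OMP is checked
    against.
    """
    d = D.shape[1]
    best = ((), np.zeros(0), float(np.linalg.norm(signal)))
    for k in range(1, sparsity + 1):
        for support in combinations(range(d), k):
            sub = D[:, support]
            coef, *_ = np.linalg.lstsq(sub, signal, rcond=None)
            res = float(np.linalg.norm(signal - sub @ coef))
            if res < best[2] - 1e-12:
                best = (support, coef, res)
    return best


def exact_recovery_condition(D: np.ndarray, support) -> bool:
    """Tropp's exact recovery condition: ``max_{j not in S} ||D_S^+ d_j||_1 < 1``.

    When it holds, greedy pursuit provably selects only atoms of S and
    therefore coincides with the exhaustive least-squares oracle; when
    it fails, greedy may legitimately pick a wrong atom even with a
    clear selection margin.
    """
    support = list(support)
    pinv = np.linalg.pinv(D[:, support])
    others = [j for j in range(D.shape[1]) if j not in support]
    return float(np.abs(pinv @ D[:, others]).sum(axis=0).max()) < 1.0 - 1e-9


def greedy_path_margin(D: np.ndarray, signal: np.ndarray, sparsity: int) -> float:
    """Smallest relative gap between the winning and runner-up atom
    correlations along the greedy selection path (small margin means the
    greedy choice is ambiguous and implementations may legally differ)."""
    residual = signal.astype(float).copy()
    chosen: list[int] = []
    margin = np.inf
    for _ in range(sparsity):
        corr = np.abs(D.T @ residual)
        corr[chosen] = -np.inf
        order = np.argsort(corr)[::-1]
        top, second = corr[order[0]], corr[order[1]]
        if top <= 0:
            break
        margin = min(margin, (top - second) / max(top, 1e-300))
        chosen.append(int(order[0]))
        sub = D[:, chosen]
        coef, *_ = np.linalg.lstsq(sub, signal, rcond=None)
        residual = signal - sub @ coef
    return margin


def brute_force_ssim(
    a: np.ndarray, b: np.ndarray, window: int, c1: float, c2: float
) -> float:
    """Direct per-window evaluation of the structural-similarity mean."""
    h, w = a.shape
    values = []
    for r in range(h - window + 1):
        for c in range(w - window + 1):
            wa = a[r : r + window, c : c + window].ravel()
            wb = b[r : r + window, c : c + window].ravel()
            mu_a, mu_b = wa.mean(), wb.mean()
            var_a, var_b = wa.var(), wb.var()
            cov = np.mean(wa * wb) - mu_a * mu_b
            values.append(
                ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
            )
    return float(np.mean(values))


def brute_force_assemble(patches) -> np.ndarray:
    """Pixel-wise accumulation oracle for overlap-averaged reassembly."""
    p = patches.patch_size
    h, w = patches.source_shape
    total = np.zeros((h, w))
    count = np.zeros((h, w))
    for idx, (r, c) in enumerate(patches.origins):
        block = patches.data[:, idx].reshape(p, p)
        total[r : r + p, c : c + p] += block
        count[r : r + p, c : c + p] += 1
    return total / count


def kmeans_objective(X: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squared distances to cluster means."""
    total = 0.0
    for k in np.unique(labels):
        member = X[labels == k]
        total += float(((member - member.mean(axis=0)) ** 2).sum())
    return total


def best_two_partition(X: np.ndarray) -> float:
    """Global minimum of the K=2 clustering objective by exhausting all
    2-partitions (feasible for ~10 points)."""
    n = len(X)
    best = np.inf
    for mask_bits in range(1, 2 ** (n - 1)):  # fix point 0 in cluster 0
        labels = np.array([(mask_bits >> i) & 1 for i in range(n)])
        best = min(best, kmeans_objective(X, labels))
    return best
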