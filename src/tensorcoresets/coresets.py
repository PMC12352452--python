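"""Per-mode coreset machinery.

A mode of an unfolded tensor ``X (D x Dt)`` is summarized by embedding each
row ``x_i`` as the outer product ``x_i^T x_i`` (a ``Dt x Dt`` matrix, never
materialized).  A *coreset* is a weighted subset of rows whose summed
embeddings approximate the full-mode embedding ``X^T X``.  The squared
Frobenius distance between the two — the *discrepancy* — is a quadratic form
in the weights that only involves kernels between embeddings,

    k(i, j) = <x_i^T x_i, x_j^T x_j> = (x_i . x_j)^2,

so everything here is computed from ``D x D`` Gram-type matrices.

Selection is either randomized (squared-norm row sampling without
replacement) or deterministic (weighted kernel herding: greedily add the row
whose embedding best aligns with the current residual, re-solving nonnegative
least-squares weights after each addition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .tensor_ops import ModeUnfolding, _check_index_set

__all__ = [
    "KernelBundle",
    "Coreset",
    "build_kernel_bundle",
    "discrepancy",
    "nnls_weights",
    "norm_sample",
    "wkh_select",
    "norm_rescaled_weights",
    "as_generator",
]

# Relative ridge applied only when the embedding kernel is numerically singular.
_RIDGE_SCALE = 1e-12
# Floor (relative to max weight) applied to exact-zero weights where W^-1 is needed.
WEIGHT_FLOOR_SCALE = 1e-12


def as_generator(seed) -> np.random.Generator:
    """Coerce ``None``/int/SeedSequence/Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class KernelBundle:
    """Kernel-space summary of one mode subset.

    ``P = Xs @ X.T`` holds inner products between subset rows and all rows;
    ``P_II`` is its subset-internal block; ``K = P_II**2`` is the embedding
    kernel; ``c = (P**2) @ 1`` collects each subset embedding's inner product
    with the full-mode embedding.  ``full_embedding_normsq = ||X^T X||_F^2``
    is optional and only needed for absolute discrepancy values.
    """

    P: np.ndarray
    P_II: np.ndarray
    K: np.ndarray
    c: np.ndarray
    indices: np.ndarray
    full_embedding_normsq: float | None = None

    @property
    def size(self) -> int:
        return len(self.indices)


@dataclass
class Coreset:
    """Ordered index set with nonnegative weights for one mode."""

    indices: np.ndarray
    weights: np.ndarray
    mode: int | None = None
    discrepancy_value: float | None = None
    selector: str | None = None
    trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("coreset indices must be distinct")
        if np.any(self.weights < 0):
            raise ValueError("coreset weights must be nonnegative")


def _as_matrix(unfolding) -> np.ndarray:
    if isinstance(unfolding, ModeUnfolding):
        return unfolding.matrix
    return np.atleast_2d(np.asarray(unfolding, dtype=float))


def build_kernel_bundle(
    unfolding, indices, *, with_full_normsq: bool = True
) -> KernelBundle:
    """Assemble the kernel quantities for a row subset of an unfolding.

    ``P = X[I] @ X.T``, ``P_II = P[:, I]``, ``K = P_II**2`` entrywise,
    ``c = row sums of P**2``.  The full-embedding norm is computed as
    ``||X @ X.T||_F**2`` (equal to ``||X.T @ X||_F**2``) when requested.
    """
    X = _as_matrix(unfolding)
    idx = _check_index_set(indices, X.shape[0], mode=-1)
    P = X[idx] @ X.T
    P_II = P[:, idx]
    K = P_II**2
    c = (P**2).sum(axis=1)
    full = None
    if with_full_normsq:
        gram = X @ X.T
        full = float((gram**2).sum())
    return KernelBundle(P=P, P_II=P_II, K=K, c=c, indices=idx, full_embedding_normsq=full)


def discrepancy(bundle: KernelBundle, weights) -> float:
    """Squared distance between weighted subset embeddings and the full mode.

    Evaluates ``w^T K w - 2 w^T c + ||X^T X||_F^2`` and clamps round-off
    negatives at zero.
    """
    if bundle.full_embedding_normsq is None:
        raise ValueError("bundle lacks full_embedding_normsq; rebuild with "
                         "with_full_normsq=True")
    w = np.asarray(weights, dtype=float)
    if w.shape != (bundle.size,):
        raise ValueError(f"expected {bundle.size} weights, got shape {w.shape}")
    val = float(w @ bundle.K @ w - 2.0 * (w @ bundle.c) + bundle.full_embedding_normsq)
    return max(val, 0.0)


def _nnls_kernel(K: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, bool]:
    """Minimize ``w^T K w - 2 w^T c`` over ``w >= 0`` given only kernels.

    Tries the unconstrained normal-equation solution first (it is usually
    already nonnegative); otherwise runs active-set NNLS on a square-root
    factorization ``A^T A = K``, ``A^T b = c``.  Returns ``(w, ridged)``.
    """
    r = K.shape[0]
    scale = float(np.trace(K)) / max(r, 1)
    ridged = False
    K_work = K
    try:
        w_ols = np.linalg.solve(K_work, c)
    except np.linalg.LinAlgError:
        ridged = True
        K_work = K + _RIDGE_SCALE * scale * np.eye(r)
        w_ols = np.linalg.solve(K_work, c)
    resid_ok = np.linalg.norm(K_work @ w_ols - c) <= 1e-8 * max(
        np.linalg.norm(c), scale
    )
    wmax = float(np.abs(w_ols).max(initial=0.0))
    if resid_ok and np.all(w_ols >= -1e-10 * max(wmax, 1.0)):
        return np.clip(w_ols, 0.0, None), ridged
    # Square-root factorization via eigendecomposition (K is PSD).
    lam, V = np.linalg.eigh(K_work)
    lam = np.clip(lam, 0.0, None)
    keep = lam > lam.max(initial=0.0) * r * np.finfo(float).eps
    sq = np.sqrt(lam[keep])
    A = sq[:, None] * V[:, keep].T            # A^T A = K (on its range)
    b = (V[:, keep].T @ c) / sq               # A^T b = c (projected)
    w, _ = _scipy_nnls(A, b)
    return w, ridged


def nnls_weights(bundle: KernelBundle) -> np.ndarray:
    """Discrepancy-minimizing nonnegative weights for a fixed subset.

    If the ordinary least-squares solution ``K^{-1} c`` is already
    nonnegative it is returned directly; otherwise an active-set NNLS on the
    kernel normal equations is solved.
    """
    w, ridged = _nnls_kernel(bundle.K, bundle.c)
    if ridged:
        warnings.warn("embedding kernel numerically singular; ridge applied",
                      RuntimeWarning, stacklevel=2)
    return w


def norm_rescaled_weights(matrix, indices) -> np.ndarray:
    """Embedding weights implied by classical squared-norm column rescaling.

    Rescaling subset row i by ``||X||_F / (sqrt(Ns) ||x_i||)`` corresponds to
    embedding weight ``||X||_F^2 / (Ns ||x_i||^2)``.  Used as the baseline the
    optimized weights are compared against.
    """
    X = _as_matrix(matrix)
    idx = np.asarray(indices, dtype=int)
    row_sq = (X[idx] ** 2).sum(axis=1)
    if np.any(row_sq == 0):
        raise ValueError("norm-rescaled weights undefined for zero-norm rows")
    total = (X**2).sum()
    return total / (len(idx) * row_sq)


def norm_sample(unfolding, size: int, rng_seed=None) -> np.ndarray:
    """Draw distinct row indices with probability proportional to squared norms.

    Sampling is sequential without replacement, renormalizing after each draw;
    zero-norm rows are never selected.
    """
    X = _as_matrix(unfolding)
    size = int(size)
    sq_norms = (X**2).sum(axis=1)
    n_nonzero = int(np.count_nonzero(sq_norms))
    if not 1 <= size <= n_nonzero:
        raise ValueError(
            f"size must be in [1, {n_nonzero}] (rows with nonzero norm), got {size}"
        )
    rng = as_generator(rng_seed)
    probs = sq_norms.astype(float).copy()
    chosen = np.empty(size, dtype=int)
    for t in range(size):
        p = probs / probs.sum()
        i = int(rng.choice(len(p), p=p))
        chosen[t] = i
        probs[i] = 0.0
    return chosen


def wkh_select(
    gram: np.ndarray,
    size: int,
    full_embedding_normsq: float | None = None,
) -> Coreset:
    """Deterministic coreset by weighted kernel herding on a mode Gram matrix.

    Maintaining a coreset ``S`` with NNLS weights ``w``, each step adds the
    unselected index maximizing the residual alignment
    ``(c_i - sum_j w_j K(i,j)) / sqrt(K(i,i))`` where ``K = gram**2`` and
    ``c = K @ 1``, then re-solves the weights over the enlarged set.  Ties
    break to the smallest index; rows with zero Gram diagonal are skipped.
    """
    G = np.atleast_2d(np.asarray(gram, dtype=float))
    D = G.shape[0]
    if G.shape != (D, D):
        raise ValueError("gram must be square")
    if not np.allclose(G, G.T, atol=1e-8 * max(1.0, np.abs(G).max())):
        raise ValueError("gram must be symmetric")
    K = G**2
    c = K.sum(axis=1)
    diag = np.diag(K).copy()
    usable = diag > 0
    size = int(size)
    if not 1 <= size <= int(usable.sum()):
        raise ValueError(
            f"size must be in [1, {int(usable.sum())}] (rows with nonzero "
            f"Gram diagonal), got {size}"
        )
    if full_embedding_normsq is None:
        full_embedding_normsq = float(K.sum())
    inv_root = np.zeros(D)
    inv_root[usable] = 1.0 / np.sqrt(diag[usable])

    selected: list[int] = []
    w = np.empty(0)
    trace: list[float] = []
    for _ in range(size):
        resid_align = c - (K[:, selected] @ w if selected else 0.0)
        score = resid_align * inv_root
        score[~usable] = -np.inf
        score[selected] = -np.inf
        i = int(np.argmax(score))  # argmax returns the first (smallest) maximizer
        selected.append(i)
        sub = np.asarray(selected)
        w, _ = _nnls_kernel(K[np.ix_(sub, sub)], c[sub])
        val = float(w @ K[np.ix_(sub, sub)] @ w - 2.0 * (w @ c[sub])
                    + full_embedding_normsq)
        trace.append(max(val, 0.0))
    return Coreset(
        indices=np.asarray(selected),
        weights=w,
        discrepancy_value=trace[-1],
        selector="wkh",
        trace=trace,
    )
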