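"""Reference and comparison Tucker decompositions.

Implements the higher-order SVD (HOSVD), its sequentially truncated variant
(ST-HOSVD), conversion of an arbitrary Tucker model into HOSVD form, and two
subset-based baselines: the Chidori CUR (row-subset core with beam-local
mapping matrices) and the randomized-sampling Tucker CUR (uniformly sampled
fiber columns as factors).

All singular vectors follow one sign convention — the entry of largest
magnitude in each vector is made positive — so repeated runs are
bit-reproducible.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import scipy.linalg

from .coresets import Coreset, norm_sample
from .models import CoresetModel, TuckerModel
from .tensor_ops import (
    as_tensor,
    mode_product,
    multi_mode_product,
    subtensor,
    unfold,
)

__all__ = ["hosvd", "st_hosvd", "tucker_to_hosvd", "chidori_cur", "rst_cur"]

# Use the D x D Gram eigen-decomposition instead of a direct SVD once the
# unfolding is this many times wider than tall (cheaper, agrees to < 1e-8).
_GRAM_WIDTH_FACTOR = 8


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive."""
    if U.size == 0:
        return U
    peaks = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[peaks, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def _left_singular_vectors(matrix: np.ndarray, rank: int) -> np.ndarray:
    """Top ``rank`` left singular vectors with the fixed sign convention."""
    m, n = matrix.shape
    if n >= _GRAM_WIDTH_FACTOR * m:
        lam, V = np.linalg.eigh(matrix @ matrix.T)
        U = V[:, ::-1][:, :rank]
    else:
        U, _, _ = np.linalg.svd(matrix, full_matrices=False)
        U = U[:, :rank]
    return _fix_signs(U)


def _check_ranks(shape: Sequence[int], ranks: Sequence[int]) -> tuple[int, ...]:
    ranks = tuple(int(r) for r in ranks)
    if len(ranks) != len(shape):
        raise ValueError(f"need {len(shape)} ranks, got {len(ranks)}")
    for n, (r, d) in enumerate(zip(ranks, shape)):
        if not 1 <= r <= d:
            raise ValueError(f"rank {r} for mode {n} outside [1, {d}]")
    return ranks


def _pinv(matrix: np.ndarray) -> np.ndarray:
    """Pseudo-inverse with the standard numerical-rank cutoff."""
    rcond = max(matrix.shape) * np.finfo(float).eps
    return np.linalg.pinv(matrix, rcond=rcond)


def hosvd(tensor, ranks) -> TuckerModel:
    """Higher-order SVD: per-mode left singular vectors + projected core."""
    tensor = as_tensor(tensor)
    ranks = _check_ranks(tensor.shape, ranks)
    factors = [
        _left_singular_vectors(unfold(tensor, n).matrix, r)
        for n, r in enumerate(ranks)
    ]
    core = multi_mode_product(tensor, factors, transpose=True)
    return TuckerModel(
        core=core,
        factors=factors,
        orthonormal=(True,) * tensor.ndim,
        provenance={"method": "hosvd", "ranks": ranks},
    )


def st_hosvd(tensor, ranks, order: Sequence[int] | None = None) -> TuckerModel:
    """Sequentially truncated HOSVD.

    After each mode's SVD the working tensor is replaced by its projection
    (``A_n^T`` applied to the mode) before the next mode is processed, so
    later SVDs act on progressively smaller arrays.
    """
    tensor = as_tensor(tensor)
    ranks = _check_ranks(tensor.shape, ranks)
    N = tensor.ndim
    if order is None:
        order = tuple(range(N))
    else:
        order = tuple(int(n) for n in order)
        if sorted(order) != list(range(N)):
            raise ValueError(f"order must be a permutation of 0..{N - 1}")
    factors: list[np.ndarray | None] = [None] * N
    working = tensor
    for n in order:
        X = unfold(working, n).matrix
        A = _left_singular_vectors(X, ranks[n])
        factors[n] = A
        working = mode_product(working, A.T, n)
    return TuckerModel(
        core=working,
        factors=factors,  # type: ignore[arg-type]
        orthonormal=(True,) * N,
        provenance={"method": "st_hosvd", "ranks": ranks, "order": order},
    )


def tucker_to_hosvd(model) -> TuckerModel:
    """Re-express any Tucker-form model in HOSVD form.

    QR-factorizes each factor, absorbs the triangular parts into the core,
    runs a full HOSVD on the (small) core, and composes the orthonormal parts
    with the small HOSVD factors.  The represented tensor is unchanged.
    Rank-deficient factors trigger a warning and a column-pivoted QR.
    """
    core = np.asarray(model.core, dtype=float)
    qs: list[np.ndarray] = []
    for n, A in enumerate(model.factors):
        A = np.asarray(A, dtype=float)
        Q, R = np.linalg.qr(A)
        r_diag = np.abs(np.diag(R))
        rank_cut = max(A.shape) * np.finfo(float).eps * r_diag.max()
        if r_diag.min() <= rank_cut:
            warnings.warn(
                f"factor {n} is numerically rank-deficient; using pivoted QR",
                RuntimeWarning,
                stacklevel=2,
            )
            Q, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
            inv_piv = np.argsort(piv)
            R = R[:, inv_piv]
        qs.append(Q)
        core = mode_product(core, R, n)
    small = hosvd(core, core.shape)
    factors = [q @ a for q, a in zip(qs, small.factors)]
    return TuckerModel(
        core=small.core,
        factors=factors,
        orthonormal=(True,) * core.ndim,
        provenance={"method": "tucker_to_hosvd",
                    "source": dict(getattr(model, "provenance", {}))},
    )


def chidori_cur(tensor, ranks, sampler: str = "norm", rng_seed=None) -> CoresetModel:
    """Chidori CUR: subtensor core with beam-local mapping matrices.

    Index sets are drawn per mode from the full tensor (squared-norm sampling
    by default).  The mode-n mapping matrix is the least-squares row mapping
    computed from the n-th Chidori beam only — the subtensor free in mode n
    and restricted to the chosen indices elsewhere — so the decomposition
    depends on the beams alone.
    """
    tensor = as_tensor(tensor)
    ranks = _check_ranks(tensor.shape, ranks)
    if sampler not in ("norm", "uniform"):
        raise ValueError(f"sampler must be 'norm' or 'uniform', got {sampler!r}")
    N = tensor.ndim
    streams = np.random.SeedSequence(rng_seed).spawn(N)
    index_sets: list[np.ndarray] = []
    for n in range(N):
        rng = np.random.default_rng(streams[n])
        if sampler == "norm":
            idx = norm_sample(unfold(tensor, n), ranks[n], rng)
        else:
            idx = rng.choice(tensor.shape[n], size=ranks[n], replace=False)
        index_sets.append(np.asarray(idx, dtype=int))

    core = subtensor(tensor, index_sets)
    mappings: list[np.ndarray] = []
    for n in range(N):
        beam_sel: list = [index_sets[m] for m in range(N)]
        beam_sel[n] = ":"
        beam = subtensor(tensor, beam_sel)
        Xb = unfold(beam, n).matrix          # D_n x prod(R_m, m != n)
        Xs = Xb[index_sets[n]]               # R_n x same
        mappings.append(Xb @ Xs.T @ _pinv(Xs @ Xs.T))

    coresets = {
        n: Coreset(indices=index_sets[n], weights=np.ones(ranks[n]), mode=n,
                   selector=sampler)
        for n in range(N)
    }
    return CoresetModel(
        core=core,
        mappings=mappings,
        coresets=coresets,
        symmetry_groups=[(n,) for n in range(N)],
        selector=sampler,
        truncation_order=tuple(range(N)),
        weight_power=1.0,
        seed=rng_seed,
        provenance={"method": "chidori_cur", "ranks": ranks, "sampler": sampler,
                    "seed": rng_seed},
    )


def rst_cur(tensor, ranks, rng_seed=None) -> TuckerModel:
    """Randomized-sampling Tucker CUR: uniformly sampled fibers as factors.

    Factor n holds ``R_n`` uniformly sampled (without replacement) columns of
    the mode-n unfolding; the core contracts the tensor with each factor's
    pseudo-inverse.  Reduces to the matrix CUR ``C C^+ X R^+ R`` when N = 2.
    """
    tensor = as_tensor(tensor)
    ranks = _check_ranks(tensor.shape, ranks)
    N = tensor.ndim
    streams = np.random.SeedSequence(rng_seed).spawn(N)
    factors: list[np.ndarray] = []
    column_sets: list[np.ndarray] = []
    for n in range(N):
        X = unfold(tensor, n).matrix
        if ranks[n] > X.shape[1]:
            raise ValueError(
                f"rank {ranks[n]} exceeds the {X.shape[1]} fibers of mode {n}"
            )
        rng = np.random.default_rng(streams[n])
        cols = np.sort(rng.choice(X.shape[1], size=ranks[n], replace=False))
        column_sets.append(cols)
        factors.append(X[:, cols])
    core = tensor
    for n in range(N):
        core = mode_product(core, _pinv(factors[n]), n)
    return TuckerModel(
        core=core,
        factors=factors,
        orthonormal=(False,) * N,
        provenance={"method": "rst_cur", "ranks": ranks, "seed": rng_seed,
                    "columns": [c.tolist() for c in column_sets]},
    )
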