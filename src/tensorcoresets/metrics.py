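"""Evaluation measures for Tucker-form decompositions.

* relative approximation error ``||X - Xhat||_F / ||X||_F``;
* the inter-symbol-interference (ISI) index of a square matrix, 0 iff the
  matrix is a scaled (signed) permutation — the standard blind-source-
  separation measure, evaluated on entrywise absolute values so it is
  invariant to the sign and permutation ambiguities of orthonormal factors;
* the HOSVD distance between two factor sets: the sum over modes of
  ``ISI(A_n^T B_n)``;
* the cross-distance of a collection of repeated runs: the average HOSVD
  distance over all ordered pairs (zero diagonal included, normalized by
  M^2 — note this differs from cross-ISI conventions that divide by M(M-1)).

Factor sets are plain lists of per-mode matrices.  Models that are not
already in HOSVD form must be converted (see
:func:`tensorcoresets.baselines.tucker_to_hosvd` and :func:`factor_set`).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .baselines import tucker_to_hosvd
from .models import TuckerModel
from .tensor_ops import frobenius_norm

__all__ = [
    "relative_error",
    "isi",
    "hosvd_distance",
    "cross_distance",
    "most_representative_run",
    "factor_set",
]

FactorSet = Sequence[np.ndarray]


def relative_error(truth, approx) -> float:
    """``||truth - approx||_F / ||truth||_F``."""
    truth = np.asarray(truth, dtype=float)
    approx = np.asarray(approx, dtype=float)
    if truth.shape != approx.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {approx.shape}")
    denom = frobenius_norm(truth)
    if denom == 0.0:
        raise ValueError("relative error undefined for a zero tensor")
    return frobenius_norm(truth - approx) / denom


def isi(U) -> float:
    """Inter-symbol-interference index of a square matrix, in [0, 1].

    Zero iff ``|U|`` is a scaled permutation matrix.  Rows and columns must
    not be entirely zero.
    """
    A = np.abs(np.atleast_2d(np.asarray(U, dtype=float)))
    n = A.shape[0]
    if A.shape != (n, n) or n < 2:
        raise ValueError(f"isi requires a square matrix of size >= 2, got {A.shape}")
    row_max = A.max(axis=1)
    col_max = A.max(axis=0)
    if np.any(row_max == 0) or np.any(col_max == 0):
        raise ValueError("isi undefined for a matrix with an all-zero row or column")
    row_term = (A / row_max[:, None]).sum(axis=1) - 1.0
    col_term = (A / col_max[None, :]).sum(axis=0) - 1.0
    return float((row_term.sum() + col_term.sum()) / (2.0 * n * (n - 1)))


def _check_comparable(a: FactorSet, b: FactorSet) -> None:
    if len(a) != len(b):
        raise ValueError("factor sets have different mode counts")
    for n, (fa, fb) in enumerate(zip(a, b)):
        if fa.shape[1] != fb.shape[1] or fa.shape[0] != fb.shape[0]:
            raise ValueError(
                f"mode {n} factors not comparable: {fa.shape} vs {fb.shape}"
            )


def hosvd_distance(a: FactorSet, b: FactorSet) -> float:
    """Sum over modes of ``ISI(A_n^T B_n)``."""
    _check_comparable(a, b)
    return float(sum(isi(fa.T @ fb) for fa, fb in zip(a, b)))


def cross_distance(runs: Sequence[FactorSet]) -> float:
    """Average pairwise HOSVD distance over repeated runs.

    All ``M^2`` ordered pairs are averaged, including the zero diagonal.
    """
    M = len(runs)
    if M < 1:
        raise ValueError("need at least one run")
    total = 0.0
    for i in range(M):
        for j in range(i + 1, M):
            total += 2.0 * hosvd_distance(runs[i], runs[j])
    return total / (M * M)


def most_representative_run(runs: Sequence[FactorSet]) -> int:
    """Index of the run minimizing its mean HOSVD distance to all runs.

    Ties break to the smallest index.
    """
    M = len(runs)
    if M < 1:
        raise ValueError("need at least one run")
    means = np.zeros(M)
    for i in range(M):
        means[i] = sum(hosvd_distance(runs[i], runs[j]) for j in range(M)) / M
    return int(np.argmin(means))


def factor_set(model) -> list[np.ndarray]:
    """Orthonormal HOSVD-form factors of any Tucker-form model.

    Models whose factors are not all orthonormal (coreset models, CUR-type
    baselines) are converted first, as required before any distance
    computation.
    """
    if isinstance(model, TuckerModel) and all(model.orthonormal):
        return list(model.factors)
    return list(tucker_to_hosvd(model).factors)
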