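"""Dense multilinear algebra with a single fixed index convention.

A dense tensor is an N-dimensional :class:`numpy.ndarray` (N >= 2) of real,
finite values.  All public functions in this package use the same mode-n
unfolding convention: row *i* of the mode-n unfolding is the vectorization of
element *i* of mode n, and the column index enumerates the remaining modes
(1, ..., n-1, n+1, ..., N) with the lowest-numbered remaining mode varying
fastest (the standard Kolda--Bader convention).

Modes are 0-based throughout the Python API; serialized index sets carry an
explicit ``index_base`` field (see :mod:`tensorcoresets.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ModeUnfolding",
    "as_tensor",
    "unfold",
    "fold",
    "mode_product",
    "multi_mode_product",
    "frobenius_norm",
    "subtensor",
]


def as_tensor(values, min_order: int = 2) -> np.ndarray:
    """Validate and return ``values`` as a dense real tensor.

    Raises ``ValueError`` if the array has order below ``min_order`` or
    contains non-finite entries.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim < min_order:
        raise ValueError(f"tensor must have order >= {min_order}, got {arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("tensor entries must all be finite")
    return arr


@dataclass(frozen=True)
class ModeUnfolding:
    """A mode-n matricization together with the metadata needed to invert it.

    Attributes
    ----------
    matrix:
        Array of shape ``(D_n, prod of the other mode sizes)``.
    mode:
        The unfolded mode (0-based).
    origin_shape:
        Shape of the source tensor.
    """

    matrix: np.ndarray
    mode: int
    origin_shape: tuple[int, ...]

    def __post_init__(self) -> None:
        shape = tuple(int(d) for d in self.origin_shape)
        object.__setattr__(self, "origin_shape", shape)
        n_cols = int(np.prod(shape)) // shape[self.mode]
        if self.matrix.shape != (shape[self.mode], n_cols):
            raise ValueError(
                f"unfolding matrix shape {self.matrix.shape} inconsistent with "
                f"mode {self.mode} of origin shape {shape}"
            )


def _check_mode(tensor: np.ndarray, mode: int) -> int:
    mode = int(mode)
    if not 0 <= mode < tensor.ndim:
        raise ValueError(f"mode {mode} out of range for order-{tensor.ndim} tensor")
    return mode


def unfold(tensor: np.ndarray, mode: int) -> ModeUnfolding:
    """Matricize ``tensor`` with respect to ``mode`` (0-based).

    Row *i* of the result is ``vec`` of the *i*-th element of the mode; columns
    enumerate the remaining modes with the lowest remaining mode fastest.
    """
    tensor = as_tensor(tensor)
    mode = _check_mode(tensor, mode)
    matrix = np.reshape(
        np.moveaxis(tensor, mode, 0), (tensor.shape[mode], -1), order="F"
    )
    return ModeUnfolding(matrix=matrix, mode=mode, origin_shape=tensor.shape)


def fold(unfolding: ModeUnfolding) -> np.ndarray:
    """Exact inverse of :func:`unfold`."""
    shape = unfolding.origin_shape
    mode = unfolding.mode
    moved = (shape[mode],) + shape[:mode] + shape[mode + 1 :]
    tensor = np.reshape(unfolding.matrix, moved, order="F")
    return np.moveaxis(tensor, 0, mode)


def mode_product(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n product ``tensor x_n matrix``.

    ``matrix`` has shape ``(J, D_mode)``; the result replaces the mode's size
    by ``J`` and equals folding ``matrix @ unfold(tensor, mode)``.
    """
    tensor = as_tensor(tensor)
    mode = _check_mode(tensor, mode)
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[1] != tensor.shape[mode]:
        raise ValueError(
            f"matrix has {matrix.shape[1]} columns but mode {mode} has size "
            f"{tensor.shape[mode]}"
        )
    unf = unfold(tensor, mode)
    new_shape = list(tensor.shape)
    new_shape[mode] = matrix.shape[0]
    return fold(
        ModeUnfolding(matrix @ unf.matrix, mode=mode, origin_shape=tuple(new_shape))
    )


def multi_mode_product(
    tensor: np.ndarray,
    matrices: Sequence[np.ndarray],
    modes: Sequence[int] | None = None,
    transpose: bool = False,
) -> np.ndarray:
    """Apply one mode product per entry of ``matrices``.

    ``modes`` defaults to ``range(len(matrices))``.  With ``transpose=True``
    each matrix is transposed first (the usual core-projection contraction).
    """
    if modes is None:
        modes = range(len(matrices))
    out = tensor
    for matrix, mode in zip(matrices, modes):
        out = mode_product(out, matrix.T if transpose else matrix, mode)
    return out


def frobenius_norm(tensor: np.ndarray) -> float:
    """Square root of the sum of squared entries."""
    return float(np.linalg.norm(np.asarray(tensor, dtype=float).ravel()))


def _check_index_set(indices, size: int, mode: int) -> np.ndarray:
    idx = np.asarray(indices, dtype=int).ravel()
    if idx.size == 0:
        raise ValueError(f"empty index set for mode {mode}")
    if idx.min(initial=0) < 0 or (idx.size and idx.max() >= size):
        raise ValueError(f"index out of range [0, {size}) for mode {mode}: {idx}")
    if len(np.unique(idx)) != len(idx):
        raise ValueError(f"duplicate index in set for mode {mode}: {idx}")
    return idx


def subtensor(tensor: np.ndarray, index_sets: Sequence) -> np.ndarray:
    """Extract the subtensor at one index set per mode.

    Each entry of ``index_sets`` is either a sequence of distinct 0-based
    indices or the string ``":"`` / ``slice(None)`` meaning the full range.
    """
    tensor = as_tensor(tensor)
    if len(index_sets) != tensor.ndim:
        raise ValueError(
            f"need {tensor.ndim} index sets, got {len(index_sets)}"
        )
    out = tensor
    for mode, sel in enumerate(index_sets):
        if isinstance(sel, str):
            if sel != ":":
                raise ValueError(f"unrecognized selector {sel!r} for mode {mode}")
            continue
        if isinstance(sel, slice):
            if sel != slice(None):
                raise ValueError("only the full slice ':' is supported")
            continue
        idx = _check_index_set(sel, tensor.shape[mode], mode)
        out = np.take(out, idx, axis=mode)
    return out
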