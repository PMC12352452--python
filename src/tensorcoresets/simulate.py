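"""Synthetic tensor generators.

Two study conditions are emulated:

* a low-rank signal-plus-noise tensor ``X = S + noise`` where the signal is a
  Tucker product of standard-Gaussian factors with either a fully Gaussian
  core ("tucker") or a superdiagonal Gaussian core ("cpd"), and the additive
  Gaussian noise is rescaled so that ``||S||_F / ||X - S||_F`` equals the
  requested signal-to-noise ratio;
* a functional-network-connectivity-like tensor: per-subject symmetric
  correlation matrices with unit diagonal, values in [-1, 1], and two dense
  diagonal blocks of elevated correlation mimicking motor/visual network
  groups.  Positive semidefiniteness per slice is *not* enforced — none of
  the decompositions use it — so slices are correlation-like, not guaranteed
  correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tensor_ops import frobenius_norm, multi_mode_product

__all__ = [
    "SimulationSpec",
    "SimulatedTensor",
    "generate_tensor",
    "generate_fnc_like",
    "elementwise_square",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Description of one signal-plus-noise experiment.

    ``dims`` is a common mode size (int) or a per-mode tuple; ``rank`` is the
    true core size R; ``snr`` is the Frobenius signal-to-noise ratio
    (``numpy.inf`` for noiseless); ``core_model`` is ``"cpd"`` or
    ``"tucker"``.
    """

    order: int = 3
    dims: int | tuple[int, ...] = 200
    rank: int = 4
    core_model: str = "cpd"
    snr: float = 10.0
    seed: int | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        if isinstance(self.dims, int):
            return (self.dims,) * self.order
        return tuple(self.dims)

    def __post_init__(self) -> None:
        if self.core_model not in ("cpd", "tucker"):
            raise ValueError(
                f"core_model must be 'cpd' or 'tucker', got {self.core_model!r}"
            )
        if not self.snr > 0:
            raise ValueError("snr must be positive (numpy.inf for noiseless)")
        if self.rank > min(self.shape):
            raise ValueError(
                f"rank {self.rank} exceeds smallest mode size {min(self.shape)}"
            )


@dataclass
class SimulatedTensor:
    """Generated tensor with full ground truth."""

    tensor: np.ndarray
    signal: np.ndarray
    true_core: np.ndarray
    true_factors: list[np.ndarray]
    spec: SimulationSpec = field(repr=False, default=None)  # type: ignore[assignment]


def generate_tensor(
    spec: SimulationSpec, snr_convention: str = "ratio"
) -> SimulatedTensor:
    """Draw one signal-plus-noise tensor from ``spec``.

    ``snr_convention="ratio"`` (default) scales the noise so that
    ``||signal||_F / ||noise||_F = snr`` — larger values mean cleaner data.
    ``"literal"`` instead multiplies the normalized noise by ``snr``, the
    opposite convention.
    """
    if snr_convention not in ("ratio", "literal"):
        raise ValueError("snr_convention must be 'ratio' or 'literal'")
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    R = spec.rank
    if spec.core_model == "tucker":
        core = rng.standard_normal((R,) * spec.order)
    else:
        core = np.zeros((R,) * spec.order)
        diag = rng.standard_normal(R)
        core[tuple(np.arange(R) for _ in range(spec.order))] = diag
    factors = [rng.standard_normal((d, R)) for d in shape]
    signal = multi_mode_product(core, factors)
    if np.isinf(spec.snr):
        tensor = signal.copy()
    else:
        noise = rng.standard_normal(shape)
        base = frobenius_norm(signal) / frobenius_norm(noise)
        scale = base / spec.snr if snr_convention == "ratio" else base * spec.snr
        tensor = signal + scale * noise
    return SimulatedTensor(
        tensor=tensor,
        signal=signal,
        true_core=core,
        true_factors=factors,
        spec=spec,
    )


def _default_partition(n_nodes: int) -> list[list[int]]:
    # Two dense diagonal blocks (motor- and visual-like groups, ~17% of the
    # nodes each, matching 9-of-53); remaining nodes stay unblocked.
    b1 = max(2, round(0.17 * n_nodes))
    start = min(n_nodes // 6, n_nodes - 2 * b1)
    blocks = [
        list(range(start, start + b1)),
        list(range(start + b1, start + 2 * b1)),
    ]
    covered = {i for b in blocks for i in b}
    singles = [[i] for i in range(n_nodes) if i not in covered]
    return blocks + singles


def generate_fnc_like(
    n_nodes: int = 53,
    n_subjects: int = 352,
    block_partition: Sequence[Sequence[int]] | None = None,
    within_block_strength: float = 0.6,
    noise_sd: float = 0.15,
    seed: int | None = None,
) -> np.ndarray:
    """Subject-stacked symmetric correlation-like tensor with block structure.

    Returns an array of shape ``(n_nodes, n_nodes, n_subjects)``.  Every
    subject slice is symmetric with unit diagonal and entries clipped to
    [-1, 1]; node pairs inside a declared multi-node block have mean
    correlation ``within_block_strength`` while all other pairs are pure
    noise, producing the two dense diagonal blocks of the default partition.
    """
    if block_partition is None:
        block_partition = _default_partition(n_nodes)
    seen: set[int] = set()
    for block in block_partition:
        b = {int(i) for i in block}
        if not b or min(b) < 0 or max(b) >= n_nodes:
            raise ValueError(f"block {sorted(b)} outside 0..{n_nodes - 1}")
        if seen & b:
            raise ValueError("block partition has overlapping blocks")
        seen |= b
    if seen != set(range(n_nodes)):
        raise ValueError("block partition must cover every node")

    mean = np.zeros((n_nodes, n_nodes))
    for block in block_partition:
        idx = np.asarray(sorted(int(i) for i in block))
        if len(idx) > 1:
            mean[np.ix_(idx, idx)] = within_block_strength
    np.fill_diagonal(mean, 0.0)

    rng = np.random.default_rng(seed)
    out = np.empty((n_nodes, n_nodes, n_subjects))
    for k in range(n_subjects):
        noise = rng.standard_normal((n_nodes, n_nodes)) * noise_sd
        noise = (noise + noise.T) / np.sqrt(2.0)
        slice_k = np.clip(mean + noise, -1.0, 1.0)
        np.fill_diagonal(slice_k, 1.0)
        out[:, :, k] = slice_k
    return out


def elementwise_square(tensor) -> np.ndarray:
    """Entrywise square (correlations become R-squared values)."""
    return np.square(np.asarray(tensor, dtype=float))
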