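"""Model containers shared by the decomposition routines.

Two kinds of factorization circulate in this package:

* :class:`TuckerModel` — a core tensor plus one factor matrix per mode
  (HOSVD, ST-HOSVD, RST-CUR, and converted models).
* :class:`CoresetModel` — a Tucker-form model whose core is a (weighted)
  subtensor of the data and whose factors are mapping matrices, together with
  the per-mode index sets and weights that produced it (TCD, Chidori CUR).

Both reconstruct through the same multilinear contraction
``core x_1 F_1 x_2 ... x_N F_N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .tensor_ops import multi_mode_product

__all__ = ["TuckerModel", "CoresetModel", "reconstruct"]

_ORTHO_TOL = 1e-10


@dataclass
class TuckerModel:
    """Core tensor + per-mode factor matrices.

    ``orthonormal[n]`` declares that ``factors[n].T @ factors[n] == I`` to
    1e-10; this is checked on construction.
    """

    core: np.ndarray
    factors: list[np.ndarray]
    orthonormal: tuple[bool, ...] = ()
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.core = np.asarray(self.core, dtype=float)
        self.factors = [np.asarray(f, dtype=float) for f in self.factors]
        if len(self.factors) != self.core.ndim:
            raise ValueError("one factor matrix required per core mode")
        if not self.orthonormal:
            self.orthonormal = (False,) * len(self.factors)
        for n, (f, r) in enumerate(zip(self.factors, self.core.shape)):
            if f.shape[1] != r:
                raise ValueError(
                    f"factor {n} has {f.shape[1]} columns, core mode has size {r}"
                )
            if self.orthonormal[n]:
                gram = f.T @ f
                if not np.allclose(gram, np.eye(f.shape[1]), atol=_ORTHO_TOL):
                    raise ValueError(f"factor {n} declared orthonormal but is not")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(f.shape[0] for f in self.factors)

    @property
    def ranks(self) -> tuple[int, ...]:
        return self.core.shape


@dataclass
class CoresetModel:
    """Weighted-subtensor Tucker model with per-mode index sets and weights.

    ``mappings`` play the role of factor matrices; ``coresets`` maps each mode
    to the :class:`~tensorcoresets.coresets.Coreset` that truncated it.  Modes
    in one symmetry group share identical indices, weights, and mapping.
    """

    core: np.ndarray
    mappings: list[np.ndarray]
    coresets: dict[int, Any]
    symmetry_groups: list[tuple[int, ...]]
    selector: str
    truncation_order: tuple[int, ...]
    weight_power: float = 0.5
    seed: int | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def factors(self) -> list[np.ndarray]:
        return self.mappings

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(m.shape[0] for m in self.mappings)

    @property
    def ranks(self) -> tuple[int, ...]:
        return self.core.shape


def reconstruct(model: TuckerModel | CoresetModel) -> np.ndarray:
    """Contract ``core x_1 F_1 ... x_N F_N`` back to a full tensor."""
    core = np.asarray(model.core, dtype=float)
    factors = model.factors
    if len(factors) != core.ndim:
        raise ValueError("factor count does not match core order")
    for n, f in enumerate(factors):
        if f.shape[1] != core.shape[n]:
            raise ValueError(f"factor {n} shape {f.shape} mismatches core {core.shape}")
    return multi_mode_product(core, factors)
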