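"""Sequentially truncated tensor coreset decomposition (TCD).

The algorithm walks the modes in a truncation order.  For each mode it
unfolds the current working tensor, selects a row subset — by squared-norm
sampling (TCD-R) or deterministic weighted kernel herding (TCD-D) — solves
nonnegative least-squares coreset weights, forms the mapping matrix

    M = P^T P_II^{-1} W^{-1},

and replaces the unfolding by the weighted coreset ``W X[I]`` before moving
on, so every later mode works on a tensor whose processed modes have shrunk
to their subset sizes.  The final working tensor is the core: a weighted
subtensor of the original data.

Weights enter through ``W = diag(w ** weight_power)``.  The default power is
1/2: the discrepancy weights multiply the rank-one *embeddings*
``x_i^T x_i``, so the rows themselves carry the square roots, and only
sqrt-scaling makes the truncated mode's Gram match the full-mode Gram the
weights were optimized for.  ``weight_power=1.0`` applies the weights to the
rows literally.  The per-mode product ``M @ (W X[I])`` is identical either
way, so the choice only affects how error propagates to later modes.

Modes declared symmetric (e.g. the two network modes of a subject-stacked
connectivity tensor) share one selection: the group's representative (lowest
mode index) is processed normally and its indices, weights, and mapping are
reused to truncate every other member immediately afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coresets import (
    WEIGHT_FLOOR_SCALE,
    Coreset,
    build_kernel_bundle,
    discrepancy,
    nnls_weights,
    norm_sample,
    wkh_select,
)
from .models import CoresetModel, TuckerModel, reconstruct
from .tensor_ops import ModeUnfolding, as_tensor, fold, unfold

__all__ = ["tcd", "reconstruct", "selected_features", "FeatureReport",
           "shared_features"]

_SELECTORS = ("random", "deterministic")


def _normalize_groups(
    groups: Sequence[Sequence[int]] | None, N: int
) -> list[tuple[int, ...]]:
    if groups is None:
        return [(n,) for n in range(N)]
    seen: set[int] = set()
    out: list[tuple[int, ...]] = []
    for g in groups:
        tup = tuple(sorted(int(m) for m in g))
        if any(not 0 <= m < N for m in tup):
            raise ValueError(f"symmetry group {tup} has modes outside 0..{N - 1}")
        if seen & set(tup):
            raise ValueError("symmetry groups must be disjoint")
        seen |= set(tup)
        out.append(tup)
    if seen != set(range(N)):
        raise ValueError("symmetry groups must cover every mode")
    return out


def tcd(
    tensor,
    ranks,
    selector: str = "deterministic",
    truncation_order: Sequence[int] | None = None,
    symmetry_groups: Sequence[Sequence[int]] | None = None,
    rng_seed=None,
    weight_power: float = 0.5,
    weights: str = "nnls",
) -> CoresetModel:
    """Decompose ``tensor`` into a weighted-coreset Tucker model.

    Parameters
    ----------
    tensor:
        Dense real array of order >= 2.
    ranks:
        Per-mode subset sizes, ``1 <= R_n <= D_n``.  Modes in one symmetry
        group must share the same rank.
    selector:
        ``"random"`` (squared-norm sampling, TCD-R) or ``"deterministic"``
        (weighted kernel herding, TCD-D).
    truncation_order:
        Permutation of the modes; defaults to ascending.  Members of a
        symmetry group are truncated consecutively after their representative.
    symmetry_groups:
        Partition of the modes; modes in one group reuse the representative's
        indices, weights, and mapping matrix.
    rng_seed:
        Seed for the random selector.  One seed expands to independent
        per-mode substreams, so the draw for a mode does not depend on how
        many modes precede it.
    weight_power:
        Exponent applied to the NNLS weights in ``W`` (0.5 default, 1.0
        literal).
    weights:
        ``"nnls"`` (optimized) or ``"unit"`` (ablation: all-ones weights with
        the same index selection).
    """
    tensor = as_tensor(tensor)
    N = tensor.ndim
    ranks = tuple(int(r) for r in ranks)
    if len(ranks) != N:
        raise ValueError(f"need {N} ranks, got {len(ranks)}")
    for n, (r, d) in enumerate(zip(ranks, tensor.shape)):
        if not 1 <= r <= d:
            raise ValueError(f"rank {r} for mode {n} outside [1, {d}]")
    if selector not in _SELECTORS:
        raise ValueError(f"selector must be one of {_SELECTORS}, got {selector!r}")
    if weights not in ("nnls", "unit"):
        raise ValueError(f"weights must be 'nnls' or 'unit', got {weights!r}")
    groups = _normalize_groups(symmetry_groups, N)
    group_of = {m: g for g in groups for m in g}
    for g in groups:
        if len({ranks[m] for m in g}) != 1:
            raise ValueError(f"symmetry group {g} mixes ranks")
        if len({tensor.shape[m] for m in g}) != 1:
            raise ValueError(f"symmetry group {g} mixes mode sizes")
    if truncation_order is None:
        truncation_order = tuple(range(N))
    else:
        truncation_order = tuple(int(n) for n in truncation_order)
        if sorted(truncation_order) != list(range(N)):
            raise ValueError(f"truncation_order must be a permutation of 0..{N - 1}")

    streams = np.random.SeedSequence(rng_seed).spawn(N)
    working = tensor
    mappings: list[np.ndarray | None] = [None] * N
    coresets: dict[int, Coreset] = {}
    flags: list[str] = []
    done: set[int] = set()
    processed_order: list[int] = []

    for lead in truncation_order:
        if lead in done:
            continue
        group = group_of[lead]
        rep = group[0]
        r = ranks[rep]
        unf = unfold(working, rep)
        X = unf.matrix

        if selector == "random":
            idx = norm_sample(X, r, np.random.default_rng(streams[rep]))
            bundle = build_kernel_bundle(X, idx)
            w = nnls_weights(bundle) if weights == "nnls" else np.ones(r)
            disc = discrepancy(bundle, w)
            cs = Coreset(indices=idx, weights=w, mode=rep,
                         discrepancy_value=disc, selector="norm")
        else:
            gram = X @ X.T
            cs = wkh_select(gram, r)
            idx = cs.indices
            bundle = build_kernel_bundle(X, idx)
            if weights == "unit":
                w = np.ones(r)
                cs = Coreset(indices=idx, weights=w, mode=rep,
                             discrepancy_value=discrepancy(bundle, w),
                             selector="wkh", trace=cs.trace)
            else:
                w = cs.weights
                cs.mode = rep

        # Mapping matrix M = P^T P_II^{-1} W^{-1}; exact-zero weights are
        # floored so W^{-1} exists, and the event is recorded.
        w_eff = w.copy()
        floor = WEIGHT_FLOOR_SCALE * w_eff.max(initial=0.0)
        if np.any(w_eff <= floor):
            w_eff = np.maximum(w_eff, floor if floor > 0 else WEIGHT_FLOOR_SCALE)
            flags.append(f"mode {rep}: zero weight floored")
        w_scale = w_eff**weight_power
        P_II = bundle.P_II
        sv = np.linalg.svd(P_II, compute_uv=False)
        if sv[-1] <= sv[0] * max(P_II.shape) * np.finfo(float).eps:
            rcond = max(P_II.shape) * np.finfo(float).eps
            P_inv_P = np.linalg.pinv(P_II, rcond=rcond) @ bundle.P
            flags.append(f"mode {rep}: singular subset Gram, pseudo-inverse used")
        else:
            P_inv_P = np.linalg.solve(P_II, bundle.P)
        mapping = P_inv_P.T / w_scale[None, :]

        # Truncate every member of the group with the representative's coreset.
        for member in group:
            m_unf = unfold(working, member)
            new_shape = list(m_unf.origin_shape)
            new_shape[member] = r
            truncated = w_scale[:, None] * m_unf.matrix[cs.indices]
            working = fold(ModeUnfolding(truncated, mode=member,
                                         origin_shape=tuple(new_shape)))
            mappings[member] = mapping
            coresets[member] = cs
            done.add(member)
            processed_order.append(member)

    return CoresetModel(
        core=working,
        mappings=mappings,  # type: ignore[arg-type]
        coresets=coresets,
        symmetry_groups=groups,
        selector=selector,
        truncation_order=tuple(processed_order),
        weight_power=weight_power,
        seed=rng_seed,
        provenance={
            "method": "tcd",
            "ranks": ranks,
            "selector": selector,
            "weights": weights,
            "weight_power": weight_power,
            "seed": rng_seed,
            "flags": flags,
        },
    )


@dataclass
class FeatureReport:
    """Selected elements of one mode, in selection order."""

    mode: int
    indices: np.ndarray
    weights: np.ndarray
    labels: list[str] | None = None


def selected_features(
    model: CoresetModel, mode: int, labels: Sequence[str] | None = None
) -> FeatureReport:
    """Report the mode's selected indices, weights, and optional labels.

    Selection order is meaningful for the deterministic selector (earlier
    picks explain more of the tensor); a warning is issued for models built
    with the random selector.
    """
    if mode not in model.coresets:
        raise ValueError(f"model has no coreset for mode {mode}")
    if model.selector != "deterministic":
        warnings.warn(
            "feature report from a non-deterministic model; selection order "
            "reflects random sampling",
            RuntimeWarning,
            stacklevel=2,
        )
    cs = model.coresets[mode]
    attached = None
    if labels is not None:
        labels = list(labels)
        attached = [labels[i] for i in cs.indices]
    return FeatureReport(
        mode=mode,
        indices=cs.indices.copy(),
        weights=cs.weights.copy(),
        labels=attached,
    )


def shared_features(a: FeatureReport, b: FeatureReport) -> np.ndarray:
    """Sorted indices selected in both reports."""
    return np.intersect1d(a.indices, b.indices)
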