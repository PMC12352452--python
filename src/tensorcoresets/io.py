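"""Serialization: HDF5 tensors/models, JSON coresets and feature reports.

Tensors are stored one per HDF5 file (or group) under a ``values`` dataset
whose shape is self-describing.  Models are stored as a group holding the
core, the factor/mapping arrays, and a JSON ``provenance`` attribute.  Index
sets always serialize with an explicit ``index_base`` field (this package
writes base 0; the loader honors whatever base the file declares).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .coresets import Coreset
from .models import CoresetModel, TuckerModel

__all__ = [
    "save_tensor",
    "load_tensor",
    "save_model",
    "load_model",
    "coreset_to_json",
    "coreset_from_json",
    "save_ground_truth",
]


def save_tensor(path, tensor, name: str = "tensor") -> None:
    with h5py.File(path, "a") as f:
        grp = f.require_group(name)
        if "values" in grp:
            del grp["values"]
        grp.create_dataset("values", data=np.asarray(tensor, dtype=float))


def load_tensor(path, name: str = "tensor") -> np.ndarray:
    with h5py.File(path, "r") as f:
        return np.asarray(f[name]["values"])


def save_ground_truth(path, sim, name: str = "truth") -> None:
    """Store a SimulatedTensor's signal, core, and factors alongside the data."""
    with h5py.File(path, "a") as f:
        grp = f.require_group(name)
        for key in list(grp):
            del grp[key]
        grp.create_dataset("signal", data=sim.signal)
        grp.create_dataset("core", data=sim.true_core)
        for n, fac in enumerate(sim.true_factors):
            grp.create_dataset(f"factor_{n}", data=fac)


def _coreset_dict(cs: Coreset) -> dict:
    return {
        "mode": cs.mode,
        "index_base": 0,
        "indices": cs.indices.tolist(),
        "weights": cs.weights.tolist(),
        "discrepancy": cs.discrepancy_value,
        "selector": cs.selector,
    }


def coreset_to_json(cs: Coreset, path=None) -> str:
    """Serialize a coreset (selection order preserved) to JSON."""
    text = json.dumps(_coreset_dict(cs), indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def coreset_from_json(source) -> Coreset:
    """Load a coreset from a JSON string or file path."""
    text = source
    p = Path(str(source))
    if p.exists():
        text = p.read_text()
    data = json.loads(text)
    base = int(data.get("index_base", 0))
    return Coreset(
        indices=np.asarray(data["indices"], dtype=int) - base,
        weights=np.asarray(data["weights"], dtype=float),
        mode=data.get("mode"),
        discrepancy_value=data.get("discrepancy"),
        selector=data.get("selector"),
    )


def save_model(path, model, name: str = "model") -> None:
    """Store a Tucker or coreset model as an HDF5 group."""
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        grp = f.create_group(name)
        grp.create_dataset("core", data=model.core)
        for n, fac in enumerate(model.factors):
            grp.create_dataset(f"factor_{n}", data=fac)
        grp.attrs["provenance"] = json.dumps(model.provenance, default=str)
        if isinstance(model, CoresetModel):
            grp.attrs["kind"] = "coreset"
            grp.attrs["selector"] = model.selector
            grp.attrs["weight_power"] = model.weight_power
            grp.attrs["truncation_order"] = list(model.truncation_order)
            grp.attrs["symmetry_groups"] = json.dumps(
                [list(g) for g in model.symmetry_groups]
            )
            grp.attrs["coresets"] = json.dumps(
                {str(m): _coreset_dict(cs) for m, cs in model.coresets.items()}
            )
        else:
            grp.attrs["kind"] = "tucker"
            grp.attrs["orthonormal"] = list(model.orthonormal)


def load_model(path, name: str = "model"):
    with h5py.File(path, "r") as f:
        grp = f[name]
        core = np.asarray(grp["core"])
        factors = [np.asarray(grp[f"factor_{n}"]) for n in range(core.ndim)]
        provenance = json.loads(grp.attrs.get("provenance", "{}"))
        if grp.attrs.get("kind") == "coreset":
            raw = json.loads(grp.attrs["coresets"])
            coresets = {}
            for m, d in raw.items():
                base = int(d.get("index_base", 0))
                coresets[int(m)] = Coreset(
                    indices=np.asarray(d["indices"], dtype=int) - base,
                    weights=np.asarray(d["weights"], dtype=float),
                    mode=d.get("mode"),
                    discrepancy_value=d.get("discrepancy"),
                    selector=d.get("selector"),
                )
            return CoresetModel(
                core=core,
                mappings=factors,
                coresets=coresets,
                symmetry_groups=[
                    tuple(g) for g in json.loads(grp.attrs["symmetry_groups"])
                ],
                selector=str(grp.attrs["selector"]),
                truncation_order=tuple(int(x) for x in grp.attrs["truncation_order"]),
                weight_power=float(grp.attrs["weight_power"]),
                provenance=provenance,
            )
        return TuckerModel(
            core=core,
            factors=factors,
            orthonormal=tuple(bool(x) for x in grp.attrs.get("orthonormal", [])),
            provenance=provenance,
        )
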