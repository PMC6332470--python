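"""On-disk container for network descriptions and CSV dataset helpers.

A network is stored as a single ``.npz`` archive holding a JSON manifest
(layer kinds, shapes, strides/padding, pooling sizes, BN epsilon, neuron
parameters, metadata, format version) plus one array entry per weight/bias/
batch-norm statistic.  The manifest makes conversion bit-faithful: nothing
about a layer is implicit.

Datasets travel as CSV with feature columns and a ``label`` column.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .asn_core import ASNParams
from .network import LayerSpec, NetworkSpec

__all__ = ["save_network", "load_network", "save_dataset_csv", "load_dataset_csv"]

FORMAT_VERSION = 1

_ARRAY_FIELDS = ("weights", "bias", "bn_mean", "bn_var", "bn_scale", "bn_offset")
_SCALAR_FIELDS = ("kind", "pool_size", "stride", "padding", "bn_eps")


def save_network(spec: NetworkSpec, path: Union[str, Path]) -> None:
    """Write a :class:`NetworkSpec` to a ``.npz`` container."""
    arrays = {}
    manifest_layers = []
    for i, layer in enumerate(spec.layers):
        entry = {name: getattr(layer, name) for name in _SCALAR_FIELDS}
        for name in _ARRAY_FIELDS:
            value = getattr(layer, name)
            if value is not None:
                key = f"layer{i}_{name}"
                arrays[key] = np.asarray(value)
                entry[name] = key
        manifest_layers.append(entry)
    manifest = {
        "version": FORMAT_VERSION,
        "layers": manifest_layers,
        "params": asdict(spec.params),
        "metadata": spec.metadata,
    }
    np.savez(path, manifest=np.array(json.dumps(manifest)), **arrays)


def load_network(path: Union[str, Path]) -> NetworkSpec:
    """Read a network container written by :func:`save_network`."""
    with np.load(path, allow_pickle=False) as archive:
        manifest = json.loads(str(archive["manifest"]))
        if manifest.get("version") != FORMAT_VERSION:
            raise ValueError(
                f"unsupported container version {manifest.get('version')!r}"
            )
        layers = []
        for entry in manifest["layers"]:
            kwargs = {name: entry[name] for name in _SCALAR_FIELDS}
            for name in _ARRAY_FIELDS:
                if name in entry:
                    kwargs[name] = archive[entry[name]]
            layers.append(LayerSpec(**kwargs))
    return NetworkSpec(
        layers=layers,
        params=ASNParams(**manifest["params"]),
        metadata=manifest.get("metadata", {}),
    )


def save_dataset_csv(
    X: np.ndarray, y: np.ndarray, path: Union[str, Path]
) -> None:
    frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    frame["label"] = np.asarray(y, dtype=int)
    frame.to_csv(path, index=False)


def load_dataset_csv(path: Union[str, Path]) -> Tuple[np.ndarray, np.ndarray]:
    frame = pd.read_csv(path)
    if "label" not in frame.columns:
        raise ValueError("dataset CSV needs a 'label' column")
    y = frame.pop("label").to_numpy(dtype=int)
    return frame.to_numpy(dtype=float), y
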