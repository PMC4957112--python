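"""Model persistence: a single self-describing container file.

Layout: an 10-byte magic, an 8-byte little-endian header length, a JSON
header (sorted keys), then the raw array payload.  All arrays are written
little-endian in a declared order with dtype and shape recorded in the
header manifest, and the header carries a SHA-256 of the payload, so a
truncated or corrupted file fails loudly instead of mispredicting.  Bit
conventions follow :mod:`rbforest.bitstore` (LSB-first within 64-bit
words); the training bit matrix is not persisted — a saved model predicts
but does not resume training.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict

import numpy as np

from .boost import BoostConfig
from .estimators import (
    FeatureScaler,
    RandomBitsForestClassifier,
    RandomBitsForestRegressor,
)
from .forest import BitForest, ForestConfig, Tree
from .random_bits import NetworkBatch

__all__ = ["ModelFormatError", "save_model", "load_model", "FORMAT_VERSION"]

MAGIC = b"RBFOREST\x01\n"
FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """Raised when a model file is unreadable, truncated, or corrupted."""


def _model_arrays(model) -> dict[str, np.ndarray]:
    trees = model.forest_.trees
    offsets = np.cumsum([0] + [t.n_nodes for t in trees])
    return {
        "scaler_means": model.scaler_.means,
        "scaler_sds": model.scaler_.sds,
        "pool_feature_indices": model.pool_.feature_indices,
        "pool_weights": model.pool_.weights,
        "pool_hidden_thresholds": model.pool_.hidden_thresholds,
        "pool_top_weights": model.pool_.top_weights,
        "pool_top_thresholds": model.pool_.top_thresholds,
        "tree_offsets": offsets,
        "tree_split_bit": np.concatenate([t.split_bit for t in trees]),
        "tree_left": np.concatenate([t.left for t in trees]),
        "tree_right": np.concatenate([t.right for t in trees]),
        "tree_value": np.concatenate([t.value for t in trees]),
    }


_LE = {"int64": "<i8", "float64": "<f8"}


def save_model(model, path) -> None:
    """Serialize a fitted estimator to ``path`` (deterministic bytes)."""
    if not hasattr(model, "forest_"):
        raise ValueError("model is not fitted")
    arrays = _model_arrays(model)
    manifest = []
    chunks = []
    for name, arr in arrays.items():
        dt = _LE[str(arr.dtype)]
        chunks.append(np.ascontiguousarray(arr).astype(dt).tobytes())
        manifest.append([name, dt, list(arr.shape)])
    payload = b"".join(chunks)

    classes = getattr(model, "classes_", None)
    header = {
        "format_version": FORMAT_VERSION,
        "task": model._task,
        "params": model.get_params(),
        "n_features_in": int(model.n_features_in_),
        "classes": None if classes is None else np.asarray(classes).tolist(),
        "boost_config": asdict(model.boost_config_),
        "forest_config": asdict(model.forest_config_),
        "n_pool_bits": int(model.forest_.n_pool_bits),
        "arrays": manifest,
        "payload_sha256": hashlib.sha256(payload).hexdigest(),
        "payload_size": len(payload),
    }
    header_bytes = json.dumps(header, sort_keys=True).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(len(header_bytes).to_bytes(8, "little"))
        fh.write(header_bytes)
        fh.write(payload)


def load_model(path):
    """Load a model saved by :func:`save_model`.

    Returns a fitted :class:`RandomBitsForestClassifier` or
    :class:`RandomBitsForestRegressor` whose predictions reproduce the
    saved model's bit-for-bit.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if not blob.startswith(MAGIC):
        raise ModelFormatError("not a rbforest model file (bad magic)")
    pos = len(MAGIC)
    if len(blob) < pos + 8:
        raise ModelFormatError("truncated file: missing header length")
    hlen = int.from_bytes(blob[pos : pos + 8], "little")
    pos += 8
    if len(blob) < pos + hlen:
        raise ModelFormatError("truncated file: incomplete header")
    try:
        header = json.loads(blob[pos : pos + hlen].decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"unreadable header: {exc}") from exc
    pos += hlen

    if header.get("format_version") != FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported format version {header.get('format_version')!r}"
        )
    payload = blob[pos:]
    if len(payload) != header["payload_size"]:
        raise ModelFormatError(
            f"truncated payload: expected {header['payload_size']} bytes, "
            f"got {len(payload)}"
        )
    if hashlib.sha256(payload).hexdigest() != header["payload_sha256"]:
        raise ModelFormatError("payload checksum mismatch (corrupted file)")

    arrays = {}
    off = 0
    for name, dt, shape in header["arrays"]:
        nbytes = int(np.dtype(dt).itemsize * np.prod(shape)) if shape else np.dtype(dt).itemsize
        arrays[name] = np.frombuffer(payload[off : off + nbytes], dtype=dt).reshape(shape).copy()
        off += nbytes

    cls = (
        RandomBitsForestClassifier
        if header["task"] == "classification"
        else RandomBitsForestRegressor
    )
    model = cls(**header["params"])
    model.n_features_in_ = header["n_features_in"]
    model.scaler_ = FeatureScaler(arrays["scaler_means"], arrays["scaler_sds"])
    model.pool_ = NetworkBatch(
        arrays["pool_feature_indices"],
        arrays["pool_weights"],
        arrays["pool_hidden_thresholds"],
        arrays["pool_top_weights"],
        arrays["pool_top_thresholds"],
    )
    model.boost_config_ = BoostConfig(**header["boost_config"])
    model.forest_config_ = ForestConfig(**header["forest_config"])
    offsets = arrays["tree_offsets"]
    trees = [
        Tree(
            arrays["tree_split_bit"][a:b],
            arrays["tree_left"][a:b],
            arrays["tree_right"][a:b],
            arrays["tree_value"][a:b],
        )
        for a, b in zip(offsets[:-1], offsets[1:])
    ]
    model.forest_ = BitForest(trees, model.forest_config_, header["n_pool_bits"])
    if header["classes"] is not None:
        model.classes_ = np.asarray(header["classes"])
    return model
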