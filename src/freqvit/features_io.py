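"""Feature table I/O shared by the encoder export and the handcrafted
baselines: one row per image with an id, an optional label, and the feature
columns ``f0000 .. f{D-1}``."""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["write_features", "read_features", "write_features_npz", "read_features_npz"]


def write_features(
    path: str,
    features: np.ndarray,
    image_ids: Sequence[str] | None = None,
    labels: Sequence[int] | None = None,
    source: str = "",
) -> None:
    features = np.asarray(features)
    n, d = features.shape
    if image_ids is None:
        image_ids = [f"img_{i:05d}" for i in range(n)]
    cols = {"image_id": list(image_ids)}
    if labels is not None:
        cols["label"] = list(np.asarray(labels, dtype=int))
    if source:
        cols["source"] = [source] * n
    frame = pd.DataFrame(cols)
    feat = pd.DataFrame(features, columns=[f"f{i:04d}" for i in range(d)])
    sep = "\t" if path.endswith(".tsv") else ","
    pd.concat([frame, feat], axis=1).to_csv(path, index=False, sep=sep)


def read_features(path: str) -> Tuple[np.ndarray, np.ndarray | None, list]:
    """Returns (features, labels-or-None, image_ids)."""
    sep = "\t" if path.endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep)
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    features = df[feat_cols].to_numpy(dtype=np.float64)
    labels = df["label"].to_numpy(dtype=np.int64) if "label" in df.columns else None
    ids = df["image_id"].tolist() if "image_id" in df.columns else list(range(len(df)))
    return features, labels, ids


def write_features_npz(path: str, features: np.ndarray,
                       image_ids: Sequence[str] | None = None,
                       labels: Sequence[int] | None = None) -> None:
    """Binary array container with an id manifest (runtime artifact only)."""
    features = np.asarray(features)
    n = features.shape[0]
    if image_ids is None:
        image_ids = [f"img_{i:05d}" for i in range(n)]
    payload = {"features": features, "image_ids": np.asarray(image_ids)}
    if labels is not None:
        payload["labels"] = np.asarray(labels, dtype=np.int64)
    np.savez(path, **payload)


def read_features_npz(path: str) -> Tuple[np.ndarray, np.ndarray | None, list]:
    npz = np.load(path, allow_pickle=False)
    labels = npz["labels"] if "labels" in npz.files else None
    return npz["features"], labels, [str(s) for s in npz["image_ids"]]
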