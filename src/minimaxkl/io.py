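"""Delimited-text readers/writers and JSON report helpers."""

from __future__ import annotations

import json
from typing import Tuple

import numpy as np
import pandas as pd

from .large_alphabet import CountVector

__all__ = ["read_counts", "read_samples", "write_probs", "write_json"]


def read_counts(path: str, m: int | None = None) -> Tuple[CountVector, list]:
    """Read a two-column (symbol, count) delimited table.

    Symbols may be arbitrary labels; rows are kept in file order.  If
    ``m`` exceeds the number of rows, the alphabet is padded with unseen
    symbols labelled ``unseen_<i>``.
    """
    df = pd.read_csv(path, sep=r"[,;\t ]+", engine="python", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("counts file must have two columns: symbol, count")
    if isinstance(df.iloc[0, 1], str):  # header row
        df = df.iloc[1:]
    labels = [str(v) for v in df.iloc[:, 0]]
    counts = df.iloc[:, 1].astype(float).to_numpy()
    if np.any(counts < 0) or np.any(counts % 1 != 0):
        raise ValueError("counts must be nonnegative integers")
    counts = counts.astype(np.int64)
    if m is not None:
        if m < counts.size:
            raise ValueError("m smaller than number of listed symbols")
        pad = m - counts.size
        labels = labels + [f"unseen_{i}" for i in range(pad)]
        counts = np.concatenate([counts, np.zeros(pad, dtype=np.int64)])
    return CountVector(counts), labels


def read_samples(path: str) -> np.ndarray:
    """Read a whitespace/comma-delimited numeric sample matrix (n rows)."""
    df = pd.read_csv(path, sep=r"[,;\t ]+", engine="python", header=None, comment="#")
    arr = df.to_numpy(dtype=float)
    return arr if arr.shape[1] > 1 else arr.ravel()[:, None]


def write_probs(path: str, labels, probs: np.ndarray) -> None:
    pd.DataFrame({"symbol": labels, "probability": probs}).to_csv(path, sep="\t", index=False)


def write_json(path: str, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
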