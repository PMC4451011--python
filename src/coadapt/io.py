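"""Serialization helpers: whitespace matrix text, JSON with nested lists."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .encoding import Encoder
from .sskf import SSKFDecoder

__all__ = [
    "save_matrix",
    "load_matrix",
    "save_json",
    "load_json",
    "save_decoder",
    "load_decoder",
    "save_encoder",
    "load_encoder",
]


def save_matrix(path: str | Path, M: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(np.asarray(M, dtype=float)), fmt="%.17g")


def load_matrix(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, dtype=float))


def save_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_decoder(path: str | Path, dec: SSKFDecoder) -> None:
    save_json(path, dec.to_dict())


def load_decoder(path: str | Path) -> SSKFDecoder:
    return SSKFDecoder.from_dict(load_json(path))


def save_encoder(path: str | Path, enc: Encoder) -> None:
    save_json(path, enc.to_dict())


def load_encoder(path: str | Path) -> Encoder:
    return Encoder.from_dict(load_json(path))
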