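"""Shared helpers: seeded substreams and small validation utilities."""

from __future__ import annotations

import numpy as np

# Fixed tags so that adding a new consumer never perturbs existing streams.
_STREAM_TAGS = {
    "universe": 0,
    "latent": 1,
    "text_map": 2,
    "graph_map": 3,
    "text_noise": 4,
    "graph_noise": 5,
    "jitter": 6,
    "fasta": 7,
    "pdb": 8,
    "split": 9,
    "multilabel": 10,
    "init": 11,
    "shuffle": 12,
    "misc": 13,
}


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named sub-operation of one master seed."""
    if name not in _STREAM_TAGS:
        raise KeyError(f"unknown stream name: {name!r}")
    seq = np.random.SeedSequence(int(master_seed), spawn_key=(_STREAM_TAGS[name],))
    return np.random.default_rng(seq)


def as_2d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got ndim={arr.ndim}")
    return arr


def check_unit_rows(x: np.ndarray, name: str, atol: float = 1e-6) -> None:
    norms = np.linalg.norm(x, axis=1)
    if not np.allclose(norms, 1.0, atol=atol):
        raise ValueError(f"{name} rows must be unit-normalized")
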