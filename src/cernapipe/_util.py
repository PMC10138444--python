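"""Small shared helpers: sequence ops, seeding, checksums."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returns DNA letters)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def spawn_rng(seed: int, *key: object) -> np.random.Generator:
    """Deterministic per-component generator derived from a global seed.

    The key (e.g. a stage name) is hashed into the seed sequence so each
    pipeline stage gets an independent but reproducible stream.
    """
    digest = hashlib.sha256(repr(key).encode()).digest()
    salt = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, salt]))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
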