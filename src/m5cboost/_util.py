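"""Small shared helpers."""

from __future__ import annotations

import hashlib

ALPHABET = "ACGU"
NT_TO_CODE = {nt: i for i, nt in enumerate(ALPHABET)}


def derive_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from one top-level run seed.

    Every stochastic stage (embedding training, ranking model, CV folds,
    simulation) draws its seed through this function so that a single run seed
    reproduces the whole pipeline while stages stay decorrelated.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def encode_nt(sequence: str):
    """Map an A/C/G/U string to an integer code vector (A=0,C=1,G=2,U=3)."""
    import numpy as np

    try:
        return np.array([NT_TO_CODE[c] for c in sequence], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"invalid nucleotide {exc} in {sequence!r}") from exc
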