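"""Byte-level sequence helpers shared across the pipeline.

Sequences are held as ``numpy.uint8`` arrays of ASCII codes, which keeps
conversion, reverse-complement and mismatch counting vectorised.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = (np.uint8(ord(b)) for b in "ACGTN")

_COMPLEMENT = np.zeros(256, dtype=np.uint8)
_COMPLEMENT[:] = ord("N")
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_x] = _y

_CT = np.arange(256, dtype=np.uint8)
_CT[ord("C")] = ord("T")

_GA = np.arange(256, dtype=np.uint8)
_GA[ord("G")] = ord("A")


def encode(seq: str) -> np.ndarray:
    """ASCII-encode a sequence string (upper-cased) as a uint8 array."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr][::-1]


def convert_ct(arr: np.ndarray) -> np.ndarray:
    """Three-letter conversion C->T (plus-strand bisulfite template)."""
    return _CT[arr]


def convert_ga(arr: np.ndarray) -> np.ndarray:
    """Three-letter conversion G->A (minus-strand bisulfite template)."""
    return _GA[arr]
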