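"""DNA alphabet helpers shared across the package.

The canonical base order everywhere in :mod:`selexscan` is ``A, C, G, T``
(indices 0..3); the complement of index ``i`` is ``3 - i``.
"""
from __future__ import annotations

from collections.abc import Iterable

import numpy as np
from Bio.Seq import Seq

DNA = "ACGT"

_ENCODE_TABLE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(DNA):
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(DNA.encode(), dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes handled by Biopython)."""
    return str(Seq(seq).reverse_complement())


def encode(seq: str, strict: bool = True) -> np.ndarray:
    """Encode a DNA string to an int8 array (A=0, C=1, G=2, T=3).

    Non-ACGT characters become -1 when ``strict`` is False, otherwise raise.
    """
    arr = _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if strict and (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def encode_many(seqs: Iterable[str], strict: bool = True) -> np.ndarray:
    """Encode equal-length DNA strings into a (n, L) int8 array."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.int8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
    return encode("".join(seqs), strict=strict).reshape(len(seqs), lengths.pop())


def decode(arr: np.ndarray) -> str:
    """Inverse of :func:`encode` for a 1-D index array."""
    return _DECODE[np.asarray(arr, dtype=np.intp)].tobytes().decode("ascii")


def decode_many(arr: np.ndarray) -> list[str]:
    return [decode(row) for row in np.asarray(arr)]


def composition(seqs: Iterable[str]) -> np.ndarray:
    """0-order base frequencies over a collection of sequences (ACGT order)."""
    counts = np.zeros(4, dtype=float)
    for s in seqs:
        arr = encode(s, strict=False)
        counts += np.bincount(arr[arr >= 0], minlength=4)[:4]
    total = counts.sum()
    if total == 0:
        raise ValueError("no ACGT characters in input")
    return counts / total
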