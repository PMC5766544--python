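"""Vectorized 2-bit k-mer encoding used by depletion and recruitment.

A k-mer of length <= 31 fits a uint64 with two bits per base (A=0, C=1,
G=2, T=3).  N is encoded as 4 and invalidates any window containing it.
"""

from __future__ import annotations

import numpy as np

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_CODE_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Base string -> uint8 codes (A=0 C=1 G=2 T=3, anything else 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def decode(code: int, k: int) -> str:
    digits = np.empty(k, dtype=np.uint8)
    for i in range(k - 1, -1, -1):
        digits[i] = code & 3
        code >>= 2
    return _CODE_BASE[digits].tobytes().decode("ascii")


def _window_codes(arr2d: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward, reverse-complement codes and validity for each k-window.

    ``arr2d`` is an (n, L) uint8 matrix of base codes; returns three
    (n, L - k + 1) arrays.  Shift-accumulate formulation avoids the
    (n, W, k) intermediate a windowed dot product would allocate.
    """
    n, length = arr2d.shape
    w = length - k + 1
    fwd = np.zeros((n, w), dtype=np.uint64)
    rc = np.zeros((n, w), dtype=np.uint64)
    for i in range(k):
        col = arr2d[:, i : i + w].astype(np.uint64)
        fwd = (fwd << np.uint64(2)) | (col & np.uint64(3))
        # reverse complement reads columns back to front
        col_rc = arr2d[:, k - 1 - i : k - 1 - i + w].astype(np.uint64)
        rc = (rc << np.uint64(2)) | ((np.uint64(3) - col_rc) & np.uint64(3))
    # window is valid iff it contains no N (code 4); prefix-sum trick
    is_n = (arr2d == 4).astype(np.int32)
    cs = np.zeros((n, length + 1), dtype=np.int32)
    np.cumsum(is_n, axis=1, out=cs[:, 1:])
    valid = (cs[:, k:] - cs[:, :-k]) == 0
    return fwd, rc, valid


def canonical_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes for every window of ``seq``.

    Returns (codes, valid) of length ``len(seq) - k + 1``; windows containing
    N are marked invalid (their code value is meaningless).
    """
    arr = encode(seq)
    if len(arr) < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    fwd, rc, valid = _window_codes(arr[None, :], k)
    return np.minimum(fwd[0], rc[0]), valid[0]


def canonical_codes_batch(seqs: list[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes for a batch of equal-length sequences.

    Returns (codes, valid) with shape (n, L - k + 1).
    """
    n = len(seqs)
    length = len(seqs[0])
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    arr = _BASE_CODE[buf].reshape(n, length)
    fwd, rc, valid = _window_codes(arr, k)
    return np.minimum(fwd, rc), valid


def forward_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-canonical forward codes for every window of ``seq``."""
    arr = encode(seq)
    if len(arr) < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (win < 4).all(axis=-1)
    pows = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    return (win.astype(np.uint64) * pows).sum(axis=-1), valid
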