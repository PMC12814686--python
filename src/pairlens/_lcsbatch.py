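"""Batched bit-parallel longest-common-subsequence lengths.

Screening many sequence pairs against an identity threshold (cluster
closure, leakage audits) needs tens of thousands of LCS computations; the
numba kernel here runs the classic bit-vector LCS recurrence
``V <- (V + (V & M)) | (V - (V & M))`` over multi-word bitsets at about a
microsecond per pair.  Sequences up to ``MAX_LEN`` residues are supported
(8 x 64-bit words); callers fall back to the pure-Python implementation in
:mod:`pairlens.align` beyond that.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numba
import numpy as np

MAX_WORDS = 8
MAX_LEN = MAX_WORDS * 64

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CODE = np.full(128, 20, dtype=np.uint8)
for _i, _c in enumerate(_ALPHABET):
    _CODE[ord(_c)] = _i


def encode_sequences(seqs: Sequence[str]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate sequences into (codes, offsets, lengths) arrays."""
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)])[:-1].astype(np.int64)
    codes = np.empty(int(lens.sum()), dtype=np.uint8)
    for s, off in zip(seqs, offsets):
        codes[off : off + len(s)] = _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    return codes, offsets, lens


@numba.njit(cache=True, inline="always")
def _popcount64(x: np.uint64) -> np.int64:
    x = x - ((x >> np.uint64(1)) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + (
        (x >> np.uint64(2)) & np.uint64(0x3333333333333333)
    )
    x = (x + (x >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return np.int64((x * np.uint64(0x0101010101010101)) >> np.uint64(56))


@numba.njit(cache=True)
def _lcs_batch(codes, offsets, lens, ii, jj, out):  # pragma: no cover - jitted
    one = np.uint64(1)
    full = np.uint64(0xFFFFFFFFFFFFFFFF)
    mask = np.zeros((21, MAX_WORDS), dtype=np.uint64)
    v = np.zeros(MAX_WORDS, dtype=np.uint64)
    for p in range(ii.shape[0]):
        a = ii[p]
        b = jj[p]
        a0, la = offsets[a], lens[a]
        b0, lb = offsets[b], lens[b]
        if la == 0 or lb == 0:
            out[p] = 0
            continue
        nw = (la + 63) // 64
        for c in range(21):
            for w in range(nw):
                mask[c, w] = np.uint64(0)
        for i in range(la):
            c = codes[a0 + i]
            mask[c, i >> 6] |= one << np.uint64(i & 63)
        for w in range(nw):
            v[w] = full
        rem = la & 63
        if rem != 0:
            v[nw - 1] = (one << np.uint64(rem)) - one
        top = v[nw - 1]
        for j in range(lb):
            c = codes[b0 + j]
            carry = np.uint64(0)
            borrow = np.uint64(0)
            for w in range(nw):
                u = v[w] & mask[c, w]
                t1 = v[w] + u
                c1 = np.uint64(1) if t1 < v[w] else np.uint64(0)
                s = t1 + carry
                c2 = np.uint64(1) if s < t1 else np.uint64(0)
                carry = c1 | c2
                b1 = np.uint64(1) if v[w] < u else np.uint64(0)
                t2 = v[w] - u
                b2 = np.uint64(1) if t2 < borrow else np.uint64(0)
                d = t2 - borrow
                borrow = b1 | b2
                v[w] = s | d
            v[nw - 1] &= top
        ones = 0
        for w in range(nw):
            ones += _popcount64(v[w])
        out[p] = la - ones


def lcs_lengths(
    seqs: Sequence[str],
    pairs: np.ndarray,
    encoded: Tuple[np.ndarray, np.ndarray, np.ndarray] = None,
) -> np.ndarray:
    """LCS length for each (i, j) row of ``pairs`` over ``seqs``.

    ``encoded`` may carry a precomputed :func:`encode_sequences` result.
    """
    if encoded is None:
        encoded = encode_sequences(seqs)
    codes, offsets, lens = encoded
    if lens.size and lens.max() > MAX_LEN:
        raise ValueError(f"sequences longer than {MAX_LEN} not supported by the batch kernel")
    pairs = np.ascontiguousarray(pairs, dtype=np.int64)
    out = np.empty(len(pairs), dtype=np.int64)
    if len(pairs):
        _lcs_batch(codes, offsets, lens, pairs[:, 0].copy(), pairs[:, 1].copy(), out)
    return out
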