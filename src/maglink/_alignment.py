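"""Seeded banded local alignment used by the ANI module.

The aligner is a banded affine-gap Smith-Waterman restricted to a
diagonal band around a shared-k-mer seed.  Among co-optimal local
alignments it deterministically prefers, in order: higher score, more
matched columns, more alignment columns, larger query span.  The four
quantities are packed into a single int64 "composite" so the whole
lexicographic optimisation is one max() per DP cell:

    composite = score * 2**39 + matches * 2**26 + columns * 2**13 + qspan

Bounds: fragments are <= 2**13 bp, so every term fits its slot and the
packing is exact.  A composite of 0 is the empty alignment, which is the
local-alignment floor.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MASK13 = (np.int64(1) << 13) - 1

# base encoding A=0 C=1 G=2 T=3
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0 C=1 G=2 T=3)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 255).any():
        bad = chr(raw[codes == 255][0])
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    return codes.tobytes().translate(bytes.maketrans(bytes(range(4)), b"ACGT")).decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """All forward k-mer integer codes of a coded sequence (base-4 packing)."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    powers = (np.int64(4) ** np.arange(k - 1, -1, -1)).astype(np.int64)
    return windows @ powers


def canonical_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Strand-independent k-mer codes: min(forward, reverse-complement)."""
    fwd = kmer_codes(codes, k)
    rc = kmer_codes(revcomp_codes(codes), k)[::-1]
    return np.minimum(fwd, rc)


def _kmer_codes_2d(codes: np.ndarray, k: int) -> np.ndarray:
    """Row-wise forward k-mer codes of a (n_seqs, seq_len) int matrix,
    accumulated from k shifted views (no 3D window materialisation)."""
    n_k = codes.shape[1] - k + 1
    out = np.zeros((codes.shape[0], n_k), dtype=np.int64)
    for j in range(k):
        out += codes[:, j:j + n_k].astype(np.int64) * (np.int64(4) ** (k - 1 - j))
    return out


def canonical_kmer_codes_2d(codes: np.ndarray, k: int) -> np.ndarray:
    """Row-wise canonical k-mer codes of a (n_seqs, seq_len) code matrix."""
    fwd = _kmer_codes_2d(codes, k)
    rc = _kmer_codes_2d((3 - codes.astype(np.int64))[:, ::-1], k)[:, ::-1]
    return np.minimum(fwd, rc)


def unpack_composite(comp: int) -> tuple[int, int, int, int]:
    """Return (score, matches, columns, query_span) from a packed composite."""
    comp = int(comp)
    qspan = comp & int(_MASK13)
    cols = (comp >> 13) & int(_MASK13)
    matches = (comp >> 26) & int(_MASK13)
    score = comp >> 39
    return score, matches, cols, qspan


@njit(cache=False)
def banded_sw(q, r, diag, band, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Banded affine local alignment; returns the packed best composite.

    q, r: uint8 code arrays.  diag: reference offset such that q[i]
    pairs near r[i + diag].  Penalties are positive; a gap of length g
    costs gap_open + g * gap_extend.
    """
    W_SCORE = np.int64(1) << 39
    W_MATCH = np.int64(1) << 26
    W_COLS = np.int64(1) << 13
    NEG = -(np.int64(1) << 60)

    qlen = q.shape[0]
    rlen = r.shape[0]
    width = 2 * band + 1

    d_match = match * W_SCORE + W_MATCH + W_COLS + 1
    d_mismatch = -mismatch * W_SCORE + W_COLS + 1
    d_gq_open = -(gap_open + gap_extend) * W_SCORE + W_COLS + 1  # consumes query
    d_gq_ext = -gap_extend * W_SCORE + W_COLS + 1
    d_gr_open = -(gap_open + gap_extend) * W_SCORE + W_COLS  # consumes reference
    d_gr_ext = -gap_extend * W_SCORE + W_COLS

    m_prev = np.full(width, NEG, dtype=np.int64)
    ix_prev = np.full(width, NEG, dtype=np.int64)
    iy_prev = np.full(width, NEG, dtype=np.int64)
    m_cur = np.full(width, NEG, dtype=np.int64)
    ix_cur = np.full(width, NEG, dtype=np.int64)
    iy_cur = np.full(width, NEG, dtype=np.int64)

    best = np.int64(0)
    for i in range(qlen):
        base_j = i + diag - band
        for b in range(width):
            m_cur[b] = NEG
            ix_cur[b] = NEG
            iy_cur[b] = NEG
            j = base_j + b
            if j < 0 or j >= rlen:
                continue
            # substitution state: predecessor is (i-1, j-1) = previous row, same b
            prev = np.int64(0)  # fresh local start
            if i > 0 and j > 0:
                p = m_prev[b]
                if ix_prev[b] > p:
                    p = ix_prev[b]
                if iy_prev[b] > p:
                    p = iy_prev[b]
                if p > prev:
                    prev = p
            if q[i] == r[j]:
                m_cur[b] = prev + d_match
            else:
                m_cur[b] = prev + d_mismatch
            # gap in reference (query consumed): predecessor (i-1, j) = prev row, b+1
            if i > 0 and b + 1 < width:
                o = m_prev[b + 1] + d_gq_open
                e = ix_prev[b + 1] + d_gq_ext
                ix_cur[b] = o if o > e else e
            # gap in query (reference consumed): predecessor (i, j-1) = this row, b-1
            if b > 0:
                o = m_cur[b - 1] + d_gr_open
                e = iy_cur[b - 1] + d_gr_ext
                iy_cur[b] = o if o > e else e
            if m_cur[b] > best:
                best = m_cur[b]
        m_prev, m_cur = m_cur, m_prev
        ix_prev, ix_cur = ix_cur, ix_prev
        iy_prev, iy_cur = iy_cur, iy_prev
    return best


class ReferenceIndex:
    """Forward-strand k-mer position index of one reference sequence."""

    def __init__(self, codes: np.ndarray, k: int):
        self.codes = codes
        self.k = k
        kms = kmer_codes(codes, k)
        order = np.argsort(kms, kind="stable")
        self._sorted = kms[order]
        self._positions = order.astype(np.int64)

    def positions(self, kmer: int) -> np.ndarray:
        lo = np.searchsorted(self._sorted, kmer, side="left")
        hi = np.searchsorted(self._sorted, kmer, side="right")
        return self._positions[lo:hi]

    def seed_diagonals(self, frag_kmers: np.ndarray) -> np.ndarray:
        """All (ref_pos - frag_pos) diagonals of shared k-mers."""
        lo = np.searchsorted(self._sorted, frag_kmers, side="left")
        hi = np.searchsorted(self._sorted, frag_kmers, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64)
        offsets = np.cumsum(counts) - counts
        flat = np.repeat(lo - offsets, counts) + np.arange(total)
        ref_pos = self._positions[flat]
        frag_pos = np.repeat(np.arange(len(frag_kmers)), counts)
        return ref_pos - frag_pos


def _candidate_diagonals(frag: np.ndarray, index: ReferenceIndex, band: int,
                         max_candidates: int = 3) -> list[int]:
    """Diagonals (ref_pos - frag_pos) supported by shared k-mers, most
    votes first, keeping at most max_candidates separated by > band."""
    diags = index.seed_diagonals(kmer_codes(frag, index.k))
    if diags.size == 0:
        return []
    uniq, votes = np.unique(diags, return_counts=True)
    order = np.lexsort((uniq, -votes))
    chosen: list[int] = []
    for d in uniq[order]:
        d = int(d)
        if all(abs(d - c) > band for c in chosen):
            chosen.append(d)
        if len(chosen) >= max_candidates:
            break
    return chosen


def align_fragment(frag: np.ndarray, index: ReferenceIndex, rc_index: ReferenceIndex,
                   band: int = 32, match: int = 1, mismatch: int = 1,
                   gap_open: int = 5, gap_extend: int = 2):
    """Best seeded banded local alignment of a fragment against a
    reference, trying both strands.

    Returns (score, matches, columns, query_span) or None when no
    seed is found on either strand.
    """
    best = 0
    for idx in (index, rc_index):
        for diag in _candidate_diagonals(frag, idx, band):
            comp = banded_sw(frag, idx.codes, np.int64(diag), np.int64(band),
                             np.int64(match), np.int64(mismatch),
                             np.int64(gap_open), np.int64(gap_extend))
            if comp > best:
                best = comp
    if best == 0:
        return None
    return unpack_composite(best)
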