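"""Independent full-matrix Smith-Waterman oracle for alignment tests.

Pure-Python dynamic programming over the complete (not banded) matrix
with affine gaps.  Among co-optimal local alignments it prefers, in
lexicographic order: higher score, more matches, more columns, larger
query span — the same deterministic tie-break convention the package
defines, encoded the same way (one packed integer), but computed
without seeding, banding or compilation.
"""

W_SCORE = 1 << 39
W_MATCH = 1 << 26
W_COLS = 1 << 13
NEG = -(1 << 60)


def sw_local(q: str, r: str, match=1, mismatch=1, gap_open=5, gap_extend=2):
    """Return (score, matches, columns, query_span) of the optimal
    local alignment of q against r."""
    n, m = len(q), len(r)
    d_match = match * W_SCORE + W_MATCH + W_COLS + 1
    d_mismatch = -mismatch * W_SCORE + W_COLS + 1
    d_gq_open = -(gap_open + gap_extend) * W_SCORE + W_COLS + 1
    d_gq_ext = -gap_extend * W_SCORE + W_COLS + 1
    d_gr_open = -(gap_open + gap_extend) * W_SCORE + W_COLS
    d_gr_ext = -gap_extend * W_SCORE + W_COLS

    M_prev = [NEG] * (m + 1)
    Ix_prev = [NEG] * (m + 1)
    Iy_prev = [NEG] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        M_cur = [NEG] * (m + 1)
        Ix_cur = [NEG] * (m + 1)
        Iy_cur = [NEG] * (m + 1)
        qi = q[i - 1]
        for j in range(1, m + 1):
            prev = max(M_prev[j - 1], Ix_prev[j - 1], Iy_prev[j - 1], 0)
            M_cur[j] = prev + (d_match if qi == r[j - 1] else d_mismatch)
            Ix_cur[j] = max(M_prev[j] + d_gq_open, Ix_prev[j] + d_gq_ext)
            Iy_cur[j] = max(M_cur[j - 1] + d_gr_open, Iy_cur[j - 1] + d_gr_ext)
            if M_cur[j] > best:
                best = M_cur[j]
        M_prev, Ix_prev, Iy_prev = M_cur, Ix_cur, Iy_cur

    qspan = best & (W_COLS - 1)
    cols = (best >> 13) & (W_COLS - 1)
    matches = (best >> 26) & (W_COLS - 1)
    score = best >> 39
    return score, matches, cols, qspan


def sw_identity_percent(q: str, r: str, **kwargs) -> float:
    """Identity (percent) of the optimal local alignment, or None when
    nothing aligns."""
    score, matches, cols, _ = sw_local(q, r, **kwargs)
    if cols == 0:
        return None
    return 100.0 * (matches / cols)
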