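"""Numba kernels for affine-gap Smith-Waterman alignment.

Gap convention follows the classic protein-search tools: a gap of length L
costs ``gap_open + L * gap_extend`` (existence 11, extension 1 by default),
i.e. opening a gap from the match state costs ``gap_open + gap_extend``.

Scoring matrices are dense int64 tables over an integer-coded alphabet;
sequences are int64 code arrays.  The traceback kernel resolves ties in a
fixed operator order (diagonal, then gap-in-subject, then gap-in-query) and
anchors the alignment at the first maximal cell in row-major order, so the
reported alignment is deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NEG = -(10**8)


@njit(cache=True)
def sw_score(q, s, sub, gap_open, gap_extend):
    """Optimal local alignment score (score only, linear memory)."""
    n = q.shape[0]
    m = s.shape[0]
    H = np.zeros(m, np.int64)
    F = np.full(m, _NEG, np.int64)
    goe = gap_open + gap_extend
    best = 0
    for i in range(n):
        prev_diag = 0
        e = _NEG
        h_left = 0
        prof = sub[q[i]]
        for j in range(m):
            hj = H[j]
            f = F[j] - gap_extend
            f2 = hj - goe
            if f2 > f:
                f = f2
            e -= gap_extend
            e2 = h_left - goe
            if e2 > e:
                e = e2
            h = prev_diag + prof[s[j]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            prev_diag = hj
            H[j] = h
            F[j] = f
            h_left = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def sw_score_many(q, db_flat, db_start, db_len, sub, gap_open, gap_extend):
    """Local-alignment scores of one query against a packed subject set."""
    k = db_start.shape[0]
    out = np.empty(k, np.int64)
    for t in range(k):
        s = db_flat[db_start[t] : db_start[t] + db_len[t]]
        out[t] = sw_score(q, s, sub, gap_open, gap_extend)
    return out


@njit(cache=True)
def sw_traceback(q, s, sub, gap_open, gap_extend):
    """Full local alignment with deterministic traceback.

    Returns (score, qstart, qend, sstart, send, length, identical, mismatch,
    gapopen, qcols, scols) where coordinates are 1-based inclusive and
    qcols/scols hold per-column 0-based residue indices (-1 for a gap).
    """
    n = q.shape[0]
    m = s.shape[0]
    goe = gap_open + gap_extend
    H = np.zeros((n + 1, m + 1), np.int64)
    E = np.full((n + 1, m + 1), _NEG, np.int64)
    F = np.full((n + 1, m + 1), _NEG, np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        prof = sub[q[i - 1]]
        for j in range(1, m + 1):
            e = E[i, j - 1] - gap_extend
            e2 = H[i, j - 1] - goe
            if e2 > e:
                e = e2
            E[i, j] = e
            f = F[i - 1, j] - gap_extend
            f2 = H[i - 1, j] - goe
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + prof[s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    qcols = np.empty(n + m, np.int64)
    scols = np.empty(n + m, np.int64)
    ncols = 0
    identical = 0
    mismatch = 0
    gapopen_count = 0
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = E (gap in query), 2 = F (gap in subject)
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            # tie order: diagonal, then gap-in-subject (up), then gap-in-query
            if h == H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]:
                qcols[ncols] = i - 1
                scols[ncols] = j - 1
                ncols += 1
                if q[i - 1] == s[j - 1]:
                    identical += 1
                else:
                    mismatch += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 2
            else:
                state = 1
        elif state == 2:
            qcols[ncols] = i - 1
            scols[ncols] = -1
            ncols += 1
            if F[i, j] == H[i - 1, j] - goe:
                gapopen_count += 1
                state = 0
            i -= 1
        else:
            qcols[ncols] = -1
            scols[ncols] = j - 1
            ncols += 1
            if E[i, j] == H[i, j - 1] - goe:
                gapopen_count += 1
                state = 0
            j -= 1
    qcols = qcols[:ncols][::-1].copy()
    scols = scols[:ncols][::-1].copy()
    qstart = i + 1
    sstart = j + 1
    return (
        int(best),
        int(qstart),
        int(bi),
        int(sstart),
        int(bj),
        int(ncols),
        int(identical),
        int(mismatch),
        int(gapopen_count),
        qcols,
        scols,
    )
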