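"""Global affine-gap alignment identity for LTR pair comparison.

Identity between two LTR copies is defined as matches / alignment columns of
a global alignment under match +1, mismatch -1, gap open -2, gap extend -1
(opening a gap costs open + extend for its first column).  Among co-optimal
alignments the one with the most matches, then the fewest columns, is used,
which makes the reported identity a deterministic, symmetric function of the
two sequences.

The three-state (match / gap-in-a / gap-in-b) Gotoh recursion is run on a
single int64 value per cell that encodes (score, matches, columns) in a mixed
radix so that ordinary ``max`` realises the lexicographic objective.  Rows
are vectorised with numpy; the horizontal-gap state uses the classic
prefix-maximum trick, so the whole DP is O(n*m) with O(m) python overhead.
"""

from __future__ import annotations

import numpy as np

__all__ = ["global_identity", "align_stats"]

_GAP_OPEN = 2
_GAP_EXTEND = 1


def _encode_params(la: int, lb: int) -> tuple[int, int, int, int]:
    """Radix constants for the (score, matches, columns) encoding."""
    colmax = la + lb
    k2 = colmax + 1                      # weight of the matches digit
    k1 = k2 * (min(la, lb) + 1)          # weight of the score digit
    soff = 3 * colmax + 1                # shift making the score digit >= 0
    return colmax, k2, k1, soff


def align_stats(a: str, b: str) -> tuple[int, int, int]:
    """Return (score, matches, columns) of the optimal global alignment.

    The optimum is lexicographic: maximal score, then maximal matches, then
    minimal columns.  Raises ValueError on empty input.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    # symmetric by construction, but order canonically so that float
    # identity is bit-identical either way
    if len(a) > len(b) or (len(a) == len(b) and a > b):
        a, b = b, a
    la, lb = len(a), len(b)
    colmax, k2, k1, soff = _encode_params(la, lb)

    neg = np.int64(np.iinfo(np.int64).min // 4)
    ext = -(_GAP_EXTEND * k1) - 1                       # extend: score-1, col+1
    opn = -((_GAP_OPEN + _GAP_EXTEND) * k1) - 1        # open:   score-3, col+1
    diag_match = k1 + k2 - 1                            # score+1, match+1, col+1
    diag_mismatch = -k1 - 1                             # score-1, col+1

    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)

    jj = np.arange(lb + 1, dtype=np.int64)
    base = np.int64(soff * k1 + colmax)                 # (score 0, 0 matches, 0 cols)

    m_prev = np.full(lb + 1, neg, dtype=np.int64)
    p_prev = np.full(lb + 1, neg, dtype=np.int64)
    q_prev = np.full(lb + 1, neg, dtype=np.int64)
    m_prev[0] = base
    # first row: only horizontal gaps
    if lb:
        q_prev[1:] = base + opn + ext * (jj[1:] - 1)

    for i in range(1, la + 1):
        best_prev = np.maximum(np.maximum(m_prev, p_prev), q_prev)
        m_cur = np.full(lb + 1, neg, dtype=np.int64)
        if lb:
            sub = np.where(bv == av[i - 1], diag_match, diag_mismatch)
            m_cur[1:] = best_prev[:-1] + sub
        # vertical gap (consumes a[i-1])
        p_cur = np.maximum(
            np.maximum(m_prev, q_prev) + opn,
            p_prev + ext,
        )
        # horizontal gap via prefix maximum:
        #   q[j] = max_{k<j} max(m[k], p[k]) + opn + (j-1-k)*ext
        q_cur = np.full(lb + 1, neg, dtype=np.int64)
        if lb:
            cand = np.maximum(m_cur, p_cur) + opn - ext * (jj + 1)
            run = np.maximum.accumulate(cand)[:-1]
            q_cur[1:] = run + ext * jj[1:]
        m_prev, p_prev, q_prev = m_cur, p_cur, q_cur

    best = int(max(m_prev[lb], p_prev[lb], q_prev[lb]))
    sprime, rem = divmod(best, k1)
    matches, colcode = divmod(rem, k2)
    score = sprime - soff
    columns = colmax - colcode
    return score, int(matches), int(columns)


def global_identity(a: str, b: str) -> float:
    """Fraction of matching columns in the optimal global alignment of a, b."""
    _, matches, columns = align_stats(a, b)
    return matches / columns
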