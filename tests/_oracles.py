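"""Independent brute-force oracles used to cross-check the package.

These deliberately share no code with the implementation: the local
alignment oracle is a numpy Gotoh recurrence (with a pure-Python
reference for grounding it), and the ORF oracle is an exhaustive
enumeration over all frames and codon spans.
"""

from __future__ import annotations

import numpy as np

MATCH = 1.0
MISMATCH = -2.0
GAP_OPEN = 5.0   # charged once per gap
GAP_EXTEND = 2.0  # charged per gap column
NEG = -1e9


def sw_score(query: str, target: str) -> float:
    """Optimal local (Smith-Waterman) alignment score under the package's
    scoring scheme: match +1, mismatch -2, a gap of length L costs 5+2L.
    N is a mismatch to everything. Row-wise vectorised Gotoh; horizontal
    gaps are closed with a running-max prefix scan (a gap restarting from
    another horizontal gap is never better than the merged single gap, so
    the scan over diagonal/vertical entries is exact)."""
    n, m = len(query), len(target)
    if n == 0 or m == 0:
        return 0.0
    qa = np.frombuffer(query.encode(), dtype="S1")
    ta = np.frombuffer(target.encode(), dtype="S1")
    t_ok = ta != b"N"
    cols = np.arange(1, m + 1, dtype=float)
    H_prev = np.zeros(m + 1)
    F = np.full(m + 1, NEG)
    best = 0.0
    for i in range(n):
        match_mask = (ta == qa[i]) & t_ok & (qa[i] != b"N")
        sub = np.where(match_mask, MATCH, MISMATCH)
        F = np.concatenate(([NEG], np.maximum(H_prev[1:] - (GAP_OPEN + GAP_EXTEND), F[1:] - GAP_EXTEND)))
        tmp = np.maximum(H_prev[:-1] + sub, F[1:])
        gain = np.maximum.accumulate(tmp + GAP_EXTEND * cols)
        E = np.full(m, NEG)
        if m > 1:
            E[1:] = gain[:-1] - GAP_OPEN - GAP_EXTEND * cols[1:]
        H = np.concatenate(([0.0], np.maximum(np.maximum(tmp, E), 0.0)))
        best = max(best, float(H.max()))
        H_prev = H
    return best


def sw_score_reference(query: str, target: str) -> float:
    """Plain three-matrix Gotoh in pure Python; grounds :func:`sw_score`
    on tiny inputs."""
    n, m = len(query), len(target)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            qc, tc = query[i - 1], target[j - 1]
            s = MATCH if (qc == tc and qc != "N") else MISMATCH
            E[i][j] = max(H[i][j - 1] - (GAP_OPEN + GAP_EXTEND), E[i][j - 1] - GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] - (GAP_OPEN + GAP_EXTEND), F[i - 1][j] - GAP_EXTEND)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def score_from_hit(hit) -> float:
    """Raw alignment score recomputed purely from the reported statistics
    (matching columns, mismatches, gap openings and gap columns)."""
    return (
        MATCH * hit.identities
        + MISMATCH * hit.mismatches
        - GAP_OPEN * hit.gap_opens
        - GAP_EXTEND * hit.gap_columns
    )


# ---------------------------------------------------------------------------
# ORF enumeration

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def brute_force_orf(seq: str):
    """Exhaustive six-frame scan. Returns (length, frame, start, end,
    has_start, has_stop) of the winning stretch under the same preference
    rule the package documents (full-length ORFs first, then longest open
    stretch; ties to lowest frame index then smallest start), or None.

    Enumerates every ATG..stop span and every maximal open stretch
    directly rather than reusing the implementation's segment walk.
    """
    length = len(seq)
    full_candidates = []
    open_candidates = []
    for rank, frame in enumerate([1, 2, 3, -1, -2, -3]):
        oriented = seq if frame > 0 else _rc(seq)
        off = abs(frame) - 1
        codons = [oriented[i : i + 3] for i in range(off, length - 2, 3)]
        n = len(codons)
        stops = [i for i, c in enumerate(codons) if c in _STOPS]
        # regions between stops: (exclusive lower stop, upper stop or n)
        bounds = [-1] + stops + [n]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            a = lo + 1
            has_stop = hi < n
            atgs = [j for j in range(a, hi) if codons[j] == "ATG"]
            if has_stop and atgs:
                # the maximal ATG..stop stretch of this region
                full_candidates.append(
                    _as_candidate(rank, frame, off, atgs[0], hi, length, True, True)
                )
                continue
            b = hi if has_stop else n - 1  # include the trailing stop codon
            if b < a:
                continue
            open_candidates.append(
                _as_candidate(rank, frame, off, a, b, length, codons[a] == "ATG", has_stop)
            )
    pool = full_candidates if full_candidates else open_candidates
    if not pool:
        return None
    return min(pool, key=lambda c: (-c[0], c[6], c[2]))


def _as_candidate(rank, frame, off, a, b, length, has_start, has_stop):
    o_start = off + a * 3
    o_end = off + (b + 1) * 3
    if frame > 0:
        start, end = o_start + 1, o_end
    else:
        start, end = length - o_end + 1, length - o_start
    return (o_end - o_start, frame, start, end, has_start, has_stop, rank)
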