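"""Low-level alignment kernels.

Two primitives back the whole package:

* :func:`edit_distance` — unit-cost edit distance via the greedy
  furthest-reaching-path algorithm, wrapped in a band-doubling driver so the
  cost is O((n+m)·D) for distance-D pairs instead of O(nm).
* :func:`fit_align` — "fitting" alignment of a query (aligned end to end)
  against a longer segment (free end gaps), with a traceback that reports
  matches and alignment columns so callers can compute identities.

Kernels are numba-compiled when numba is importable and fall back to the
same pure-Python code otherwise (slower, identical results).

Sequences are passed as ``uint8`` arrays of ASCII codes.  ``N`` (0x4E) never
counts as a match.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


_N = 0x4E  # ord("N")


def encode(seq: str) -> np.ndarray:
    """ASCII-encode a nucleotide string for the kernels."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@njit(cache=False)
def _banded_levenshtein(a, b, t):  # pragma: no cover - numba kernel
    """Unit-cost edit distance restricted to diagonals |i - j| <= t.

    Any alignment of cost <= t stays inside that band, so a result <= t is
    the true distance; returns -1 when the banded distance exceeds t.
    """
    n = a.shape[0]
    m = b.shape[0]
    if n - m > t or m - n > t:
        return -1
    INF = np.int64(1) << 40
    prev = np.full(m + 1, INF, dtype=np.int64)
    cur = np.full(m + 1, INF, dtype=np.int64)
    for j in range(min(m, t) + 1):
        prev[j] = j
    for i in range(1, n + 1):
        jlo = i - t
        if jlo < 0:
            jlo = 0
        jhi = i + t
        if jhi > m:
            jhi = m
        if jlo > 0:
            cur[jlo - 1] = INF
        if jhi < m:
            cur[jhi + 1] = INF
        for j in range(jlo, jhi + 1):
            if j == 0:
                cur[0] = i
                continue
            sub = prev[j - 1]
            if a[i - 1] != b[j - 1] or a[i - 1] == _N:
                sub += 1
            best = sub
            if prev[j] + 1 < best:
                best = prev[j] + 1
            if cur[j - 1] + 1 < best:
                best = cur[j - 1] + 1
            cur[j] = best
        tmp = prev
        prev = cur
        cur = tmp
    if prev[m] <= t:
        return prev[m]
    return -1


def edit_distance(a: np.ndarray, b: np.ndarray, limit: int | None = None) -> int:
    """Minimal unit-cost edit distance between two encoded sequences.

    The explored band starts narrow and doubles until the distance fits
    inside it, so near-identical pairs cost O(n) while the worst case stays
    O((n+m)·D).  If ``limit`` is given and the distance exceeds it, returns
    ``limit + 1``.
    """
    n, m = int(a.shape[0]), int(b.shape[0])
    if n == 0:
        return m
    if m == 0:
        return n
    cap = max(n, m) if limit is None else min(limit, max(n, m))
    t = max(8, abs(n - m))
    while True:
        if t > cap:
            t = cap
        d = _banded_levenshtein(a, b, t)
        if d >= 0:
            return int(d)
        if t >= cap:
            return cap + 1
        t *= 2


@njit(cache=False)
def _fit_align_kernel(q, s):  # pragma: no cover - numba kernel
    """Align q end-to-end inside s (free end gaps on s); match +1, mismatch/gap -1.

    Returns (score, seg_start, seg_end, matches, columns).
    """
    m = q.shape[0]
    n = s.shape[0]
    score = np.empty((m + 1, n + 1), dtype=np.int32)
    tb = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 diag, 1 up (gap in s), 2 left (gap in q)
    for j in range(n + 1):
        score[0, j] = 0
    for i in range(1, m + 1):
        score[i, 0] = score[i - 1, 0] - 1
        tb[i, 0] = 1
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            diag = score[i - 1, j - 1]
            if qi == s[j - 1] and qi != _N:
                diag += 1
            else:
                diag -= 1
            up = score[i - 1, j] - 1
            left = score[i, j - 1] - 1
            best = diag
            t = np.int8(0)
            if up > best:
                best = up
                t = np.int8(1)
            if left > best:
                best = left
                t = np.int8(2)
            score[i, j] = best
            tb[i, j] = t
    jend = 0
    best = score[m, 0]
    for j in range(1, n + 1):
        if score[m, j] > best:
            best = score[m, j]
            jend = j
    i = m
    j = jend
    matches = 0
    cols = 0
    while i > 0:
        t = tb[i, j]
        if t == 0:
            cols += 1
            if q[i - 1] == s[j - 1] and q[i - 1] != _N:
                matches += 1
            i -= 1
            j -= 1
        elif t == 1:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return best, j, jend, matches, cols


def fit_align(query: np.ndarray, segment: np.ndarray) -> tuple[int, int, int, int, int]:
    """Fitting alignment of ``query`` within ``segment``.

    Returns ``(score, start, end, matches, columns)`` where ``[start, end)``
    is the aligned span on ``segment`` and ``matches / columns`` is the
    alignment identity.
    """
    if query.shape[0] == 0 or segment.shape[0] == 0:
        raise ValueError("fit_align requires non-empty sequences")
    score, start, end, matches, cols = _fit_align_kernel(query, segment)
    return int(score), int(start), int(end), int(matches), int(cols)


@njit(cache=False)
def _global_tb_kernel(a, b):  # pragma: no cover - numba kernel
    """Needleman-Wunsch direction matrix; match +1, mismatch/gap -1."""
    m = a.shape[0]
    n = b.shape[0]
    score = np.empty((m + 1, n + 1), dtype=np.int32)
    tb = np.zeros((m + 1, n + 1), dtype=np.int8)
    score[0, 0] = 0
    for j in range(1, n + 1):
        score[0, j] = score[0, j - 1] - 1
        tb[0, j] = 2
    for i in range(1, m + 1):
        score[i, 0] = score[i - 1, 0] - 1
        tb[i, 0] = 1
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            diag = score[i - 1, j - 1]
            if ai == b[j - 1] and ai != _N:
                diag += 1
            else:
                diag -= 1
            up = score[i - 1, j] - 1
            left = score[i, j - 1] - 1
            best = diag
            t = np.int8(0)
            if up > best:
                best = up
                t = np.int8(1)
            if left > best:
                best = left
                t = np.int8(2)
            score[i, j] = best
            tb[i, j] = t
    return tb


def global_align_columns(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    """Global alignment column list: pairs of (index in a | -1, index in b | -1)."""
    tb = _global_tb_kernel(a, b)
    i, j = int(a.shape[0]), int(b.shape[0])
    cols: list[tuple[int, int]] = []
    while i > 0 or j > 0:
        t = tb[i, j]
        if i > 0 and j > 0 and t == 0:
            cols.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif i > 0 and (t == 1 or j == 0):
            cols.append((i - 1, -1))
            i -= 1
        else:
            cols.append((-1, j - 1))
            j -= 1
    cols.reverse()
    return cols


def warmup() -> None:
    """Trigger JIT compilation of all kernels (a few seconds, once per process)."""
    a = encode("ACGTACGT")
    b = encode("ACGTTCGT")
    edit_distance(a, b)
    fit_align(a, b)
    global_align_columns(a, b)
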