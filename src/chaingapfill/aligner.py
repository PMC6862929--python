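"""Seed-and-extend local alignment of two sequence fragments.

Three stages, mirroring the classic genome-aligner pipeline:

1. *Seeding* — exact k-mer matches (default k = 12) between the fragments.
   N never participates in a seed; optionally, soft-masked (lowercase)
   positions are excluded too, which is how a first-pass genome alignment
   avoids seeding inside repeats.
2. *Ungapped extension* — each seed is extended along its diagonal in both
   directions under an X-drop bound; the maximal-scoring ungapped segment
   containing the seed is kept as an HSP if it scores at least the
   ungapped threshold K.
3. *Gapped extension* — each HSP is extended left and right from its
   best-scoring anchor point by banded affine-gap dynamic programming that
   abandons cells falling more than Y below the best score seen (Y-drop);
   the traceback yields a gapped local alignment, reported if it scores at
   least the gapped threshold L.

Scoring is case-insensitive (unmasking changes seeding, never scoring);
any column involving N receives the worst matrix entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .scoring import N_CODE, ScoringScheme, encode

__all__ = [
    "SeedMatch",
    "HSP",
    "Segment",
    "LocalAlignment",
    "find_seeds",
    "extend_ungapped",
    "extend_gapped",
    "find_hsps",
    "align_region",
]

logger = logging.getLogger(__name__)

_NEG = -(1 << 40)


@dataclass(frozen=True)
class SeedMatch:
    """An exact k-mer match at (t_pos, q_pos) of the two fragments."""

    t_pos: int
    q_pos: int
    length: int


@dataclass(frozen=True)
class HSP:
    """Ungapped high-scoring segment pair (half-open fragment offsets)."""

    t_start: int
    t_end: int
    q_start: int
    q_end: int
    score: int

    @property
    def diagonal(self) -> int:
        return self.t_start - self.q_start


@dataclass(frozen=True)
class Segment:
    """One ungapped run of aligned columns within a gapped alignment."""

    t_start: int
    q_start: int
    length: int

    @property
    def t_end(self) -> int:
        return self.t_start + self.length

    @property
    def q_end(self) -> int:
        return self.q_start + self.length


@dataclass(frozen=True)
class LocalAlignment:
    """A gapped local alignment: co-linear ungapped segments plus score."""

    segments: tuple[Segment, ...]
    score: int

    @property
    def t_start(self) -> int:
        return self.segments[0].t_start

    @property
    def t_end(self) -> int:
        return self.segments[-1].t_end

    @property
    def q_start(self) -> int:
        return self.segments[0].q_start

    @property
    def q_end(self) -> int:
        return self.segments[-1].q_end

    @property
    def aligned_columns(self) -> int:
        return sum(s.length for s in self.segments)


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def _window_codes(seq: str, k: int, respect_mask: bool) -> tuple[np.ndarray, np.ndarray]:
    """Return (packed k-mer codes, window start positions) for valid windows.

    A window is valid when it contains no N and, with ``respect_mask``,
    no lowercase base.
    """
    codes = encode(seq)
    n = len(codes)
    if n < k:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy()
    bad = codes == N_CODE
    if respect_mask:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        bad = bad | ((raw >= 97) & (raw <= 122))
    csum = np.concatenate(([0], np.cumsum(bad)))
    starts = np.arange(n - k + 1)
    valid = (csum[k:] - csum[:-k]) == 0
    packed = np.zeros(n - k + 1, dtype=np.int64)
    c64 = codes.astype(np.int64)
    for j in range(k):
        packed += c64[j:j + n - k + 1] << (2 * (k - 1 - j))
    return packed[valid], starts[valid]


def _seed_pairs(ref: str, query: str, k: int, respect_mask: bool = False) -> np.ndarray:
    """All (t_pos, q_pos) exact k-mer match pairs, sorted by (t, q)."""
    if k < 4:
        raise ValueError(f"seed length must be >= 4, got {k}")
    t_vals, t_pos = _window_codes(ref, k, respect_mask)
    q_vals, q_pos = _window_codes(query, k, respect_mask)
    if len(t_vals) == 0 or len(q_vals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.argsort(q_vals, kind="stable")
    q_sorted = q_vals[order]
    left = np.searchsorted(q_sorted, t_vals, side="left")
    right = np.searchsorted(q_sorted, t_vals, side="right")
    counts = right - left
    hit = counts > 0
    if not np.any(hit):
        return np.empty((0, 2), dtype=np.int64)
    t_rep = np.repeat(t_pos[hit], counts[hit])
    offsets = np.concatenate(
        [np.arange(lo, hi) for lo, hi in zip(left[hit], right[hit])]
    )
    q_rep = q_pos[order[offsets]]
    pairs = np.column_stack([t_rep, q_rep])
    idx = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[idx]


def find_seeds(
    ref: str, query: str, k: int = 12, *, respect_mask: bool = False
) -> list[SeedMatch]:
    """Exact N-free k-mer matches between two fragments, sorted (t, q).

    Matching is case-insensitive; with ``respect_mask=True``, windows that
    touch a lowercase (soft-masked) base on either side never seed.
    """
    pairs = _seed_pairs(ref, query, k, respect_mask)
    return [SeedMatch(int(t), int(q), k) for t, q in pairs]


# ---------------------------------------------------------------------------
# Ungapped X-drop extension
# ---------------------------------------------------------------------------

def _extend_ungapped_codes(
    ct: np.ndarray,
    cq: np.ndarray,
    t_pos: int,
    q_pos: int,
    length: int,
    matrix: np.ndarray,
    x_drop: int,
) -> tuple[int, int, int, int]:
    """Diagonal X-drop extension; returns (t_start, t_end, q_start, score)."""
    mat = matrix
    score = int(mat[ct[t_pos:t_pos + length], cq[q_pos:q_pos + length]].sum())
    n, m = len(ct), len(cq)
    # rightward from the seed end
    best_gain, cur, ext = 0, 0, 0
    ti, qi = t_pos + length, q_pos + length
    step = 0
    while ti + step < n and qi + step < m:
        cur += int(mat[ct[ti + step], cq[qi + step]])
        step += 1
        if cur > best_gain:
            best_gain, ext = cur, step
        elif cur < best_gain - x_drop:
            break
    right_gain, right_ext = best_gain, ext
    # leftward from the seed start
    best_gain, cur, ext = 0, 0, 0
    step = 0
    while t_pos - step - 1 >= 0 and q_pos - step - 1 >= 0:
        cur += int(mat[ct[t_pos - step - 1], cq[q_pos - step - 1]])
        step += 1
        if cur > best_gain:
            best_gain, ext = cur, step
        elif cur < best_gain - x_drop:
            break
    left_gain, left_ext = best_gain, ext
    t_start = t_pos - left_ext
    t_end = t_pos + length + right_ext
    return t_start, t_end, q_pos - left_ext, score + left_gain + right_gain


def extend_ungapped(
    seed: SeedMatch, ref: str, query: str, scheme: ScoringScheme
) -> HSP | None:
    """Extend a seed along its diagonal; emit an HSP if score >= K."""
    ct, cq = encode(ref), encode(query)
    t_start, t_end, q_start, score = _extend_ungapped_codes(
        ct, cq, seed.t_pos, seed.q_pos, seed.length,
        scheme.matrix, scheme.effective_x_drop,
    )
    if score < scheme.hsp_threshold:
        return None
    size = t_end - t_start
    return HSP(t_start, t_end, q_start, q_start + size, score)


# ---------------------------------------------------------------------------
# Gapped Y-drop extension
# ---------------------------------------------------------------------------

def _ydrop_extend(
    ct: np.ndarray,
    cq: np.ndarray,
    matrix: np.ndarray,
    gap_open: int,
    gap_extend: int,
    y_drop: int,
) -> tuple[int, list[tuple[int, int]]]:
    """Affine-gap extension from the origin of (ct, cq) under Y-drop.

    Returns the best extension score (>= 0; 0 means "do not extend") and
    the aligned columns (t_index, q_index) of the best path, ascending.
    The alignment is anchored: it must start at cell (0, 0).
    """
    n, m = len(ct), len(cq)
    go, ge = gap_open, gap_extend
    oe = go + ge
    # rows[i] = (lo, M, I, D) arrays over band columns [lo, lo+len)
    rows: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] = []

    width0 = m + 1
    M = np.full(width0, _NEG, dtype=np.int64)
    I = np.full(width0, _NEG, dtype=np.int64)
    D = np.full(width0, _NEG, dtype=np.int64)
    M[0] = 0
    if m > 0:
        js = np.arange(1, m + 1, dtype=np.int64)
        I[1:] = -(go + js * ge)
    best, best_cell = 0, (0, 0)
    H = np.maximum(np.maximum(M, I), D)
    alive = H >= best - y_drop
    lo0, M, I, D = _trim_row(0, M, I, D, alive)
    rows.append((lo0, M, I, D))

    for i in range(1, n + 1):
        lo_p, Mp, Ip, Dp = rows[i - 1]
        hi_p = lo_p + len(Mp)
        if len(Mp) == 0:
            break
        Hp = np.maximum(np.maximum(Mp, Ip), Dp)
        lo = lo_p
        hi = min(hi_p + 1, m + 1)
        if lo >= hi:
            break
        width = hi - lo
        js = np.arange(lo, hi, dtype=np.int64)
        M = np.full(width, _NEG, dtype=np.int64)
        D = np.full(width, _NEG, dtype=np.int64)
        # M[j] = Hp[j-1] + s(t[i-1], q[j-1]), j in [lo_p+1, hi_p+1)
        j_lo = max(lo, lo_p + 1, 1)
        j_hi = min(hi, hi_p + 1)
        if j_lo < j_hi:
            sub = matrix[ct[i - 1], cq[j_lo - 1:j_hi - 1]]
            M[j_lo - lo:j_hi - lo] = Hp[j_lo - 1 - lo_p:j_hi - 1 - lo_p] + sub
        # D[j] = max(Hp[j] - (go+ge), Dp[j] - ge), j in [lo_p, hi_p)
        d_hi = min(hi, hi_p)
        if lo < d_hi:
            D[:d_hi - lo] = np.maximum(
                Hp[lo - lo_p:d_hi - lo_p] - oe,
                Dp[lo - lo_p:d_hi - lo_p] - ge,
            )
        H0 = np.maximum(M, D)
        # I[j] = max_{k in [lo, j-1]} H0[k] - go - (j-k)*ge, via prefix max
        I = np.full(width, _NEG, dtype=np.int64)
        P = np.maximum.accumulate(H0 + js * ge)
        if width > 1:
            I[1:] = P[:-1] - go - js[1:] * ge
        H = np.maximum(np.maximum(M, I), D)
        row_best = int(H.max())
        if row_best > best:
            best = row_best
            best_cell = (i, lo + int(np.argmax(H)))
        # extend the band rightward along pure horizontal gaps still above Y-drop
        top = int(P[-1])
        if hi <= m and top > _NEG // 2:
            j_tail_max = (top - go - (best - y_drop)) // ge
            tail_hi = min(m + 1, int(j_tail_max) + 1)
            if tail_hi > hi:
                tj = np.arange(hi, tail_hi, dtype=np.int64)
                I_tail = top - go - tj * ge
                pad = len(tj)
                M = np.concatenate([M, np.full(pad, _NEG, dtype=np.int64)])
                D = np.concatenate([D, np.full(pad, _NEG, dtype=np.int64)])
                I = np.concatenate([I, I_tail])
                H = np.concatenate([H, I_tail])
        alive = H >= best - y_drop
        lo_t, M, I, D = _trim_row(lo, M, I, D, alive)
        rows.append((lo_t, M, I, D))
        if len(M) == 0:
            break

    if best == 0:
        return 0, []
    columns = _traceback(rows, best_cell, ct, cq, matrix, go, ge)
    return best, columns


def _trim_row(lo, M, I, D, alive):
    idx = np.flatnonzero(alive)
    if len(idx) == 0:
        empty = np.empty(0, dtype=np.int64)
        return lo, empty, empty.copy(), empty.copy()
    dead = ~alive
    M[dead] = _NEG
    I[dead] = _NEG
    D[dead] = _NEG
    sl = slice(idx[0], idx[-1] + 1)
    return lo + int(idx[0]), M[sl], I[sl], D[sl]


def _traceback(rows, best_cell, ct, cq, matrix, go, ge):
    oe = go + ge

    def cell(i: int, j: int) -> tuple[int, int, int]:
        if i < 0 or i >= len(rows):
            return _NEG, _NEG, _NEG
        lo, M, I, D = rows[i]
        if lo <= j < lo + len(M):
            idx = j - lo
            return int(M[idx]), int(I[idx]), int(D[idx])
        return _NEG, _NEG, _NEG

    def h_state(m_, i_, d_) -> str:
        # tie order: diagonal (M) over up (D) over left (I)
        if m_ >= d_ and m_ >= i_:
            return "M"
        if d_ >= i_:
            return "D"
        return "I"

    i, j = best_cell
    m_, i_, d_ = cell(i, j)
    state = h_state(m_, i_, d_)
    columns: list[tuple[int, int]] = []
    while (i, j) != (0, 0):
        m_, i_, d_ = cell(i, j)
        if state == "M":
            columns.append((i - 1, j - 1))
            pm, pi, pd = cell(i - 1, j - 1)
            state = h_state(pm, pi, pd)
            i, j = i - 1, j - 1
        elif state == "D":
            pm, pi, pd = cell(i - 1, j)
            if d_ == pd - ge:
                state = "D"
            else:
                state = h_state(pm, pi, pd)
            i = i - 1
        else:  # I
            pm, pi, pd = cell(i, j - 1)
            if i_ == pi - ge:
                state = "I"
            else:
                state = "M" if pm >= pd else "D"
            j = j - 1
    columns.reverse()
    return columns


def _columns_to_segments(columns: list[tuple[int, int]]) -> tuple[Segment, ...]:
    segments: list[Segment] = []
    for t, q in columns:
        if segments and t == segments[-1].t_end and q == segments[-1].q_end:
            last = segments[-1]
            segments[-1] = Segment(last.t_start, last.q_start, last.length + 1)
        else:
            segments.append(Segment(t, q, 1))
    return tuple(segments)


def extend_gapped(
    hsp: HSP, ref: str, query: str, scheme: ScoringScheme
) -> LocalAlignment | None:
    """Y-drop gapped extension of an HSP; emit the alignment if score >= L.

    The extension is anchored at the HSP's maximum-scoring point and run
    independently leftward and rightward; the two tracebacks are joined.
    """
    ct, cq = encode(ref), encode(query)
    mat = scheme.matrix
    length = hsp.t_end - hsp.t_start
    diag = mat[ct[hsp.t_start:hsp.t_end], cq[hsp.q_start:hsp.q_end]]
    prefix = np.cumsum(diag)
    p = int(np.argmax(prefix))
    ta, qa = hsp.t_start + p + 1, hsp.q_start + p + 1

    l_score, l_cols = _ydrop_extend(
        ct[:ta][::-1].copy(), cq[:qa][::-1].copy(),
        mat, scheme.gap_open, scheme.gap_extend, scheme.y_drop,
    )
    r_score, r_cols = _ydrop_extend(
        ct[ta:], cq[qa:],
        mat, scheme.gap_open, scheme.gap_extend, scheme.y_drop,
    )
    score = l_score + r_score
    if score < scheme.gapped_threshold:
        return None
    columns = [(ta - 1 - t, qa - 1 - q) for t, q in reversed(l_cols)]
    columns.extend((ta + t, qa + q) for t, q in r_cols)
    segments = _columns_to_segments(columns)
    if not segments:
        return None
    return LocalAlignment(segments, int(score))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def find_hsps(
    ref: str,
    query: str,
    scheme: ScoringScheme,
    *,
    k: int = 12,
    respect_mask: bool = False,
    seed_cap: int = 50_000,
    cap_seed: int = 0,
) -> list[HSP]:
    """Seed and ungapped-extend: all distinct HSPs scoring >= K.

    Seeds already covered by an HSP on the same diagonal are skipped.  If
    more than ``seed_cap`` seeds arise, a deterministic uniform subsample
    (seeded by ``cap_seed``) is kept and a warning logged.
    """
    pairs = _seed_pairs(ref, query, k, respect_mask)
    if len(pairs) > seed_cap:
        logger.warning(
            "seed cap: %d seeds reduced to %d (cap_seed=%d)",
            len(pairs), seed_cap, cap_seed,
        )
        rng = np.random.default_rng(cap_seed)
        keep = rng.choice(len(pairs), size=seed_cap, replace=False)
        pairs = pairs[np.sort(keep)]
    if len(pairs) == 0:
        return []
    ct, cq = encode(ref), encode(query)
    mat = scheme.matrix
    x_drop = scheme.effective_x_drop
    K = scheme.hsp_threshold
    diag = pairs[:, 0] - pairs[:, 1]
    order = np.lexsort((pairs[:, 0], diag))
    covered_until: dict[int, int] = {}
    out: dict[tuple[int, int, int], HSP] = {}
    for idx in order:
        t_pos, q_pos = int(pairs[idx, 0]), int(pairs[idx, 1])
        d = t_pos - q_pos
        if t_pos + k <= covered_until.get(d, -1):
            continue
        t_start, t_end, q_start, score = _extend_ungapped_codes(
            ct, cq, t_pos, q_pos, k, mat, x_drop
        )
        if score < K:
            continue
        covered_until[d] = max(covered_until.get(d, -1), t_end)
        key = (t_start, t_end, q_start)
        if key not in out:
            out[key] = HSP(t_start, t_end, q_start, q_start + (t_end - t_start), score)
    return sorted(out.values(), key=lambda h: (-h.score, h.t_start, h.q_start))


def align_region(
    ref: str,
    query: str,
    scheme: ScoringScheme,
    *,
    k: int = 12,
    seed_cap: int = 50_000,
    cap_seed: int = 0,
) -> list[LocalAlignment]:
    """Full pipeline: seeds -> HSPs -> gapped alignments scoring >= L.

    HSPs whose diagonal span is already covered by a previously extended
    gapped alignment are not re-extended.  Results are sorted by
    descending score, then (t_start, q_start); duplicates are removed.
    """
    if not ref or not query:
        return []
    hsps = find_hsps(
        ref, query, scheme, k=k, seed_cap=seed_cap, cap_seed=cap_seed
    )
    covered: dict[int, list[tuple[int, int]]] = {}
    seen: set[tuple] = set()
    alignments: list[LocalAlignment] = []
    for hsp in hsps:
        if _diag_covered(covered, hsp.diagonal, hsp.t_start, hsp.t_end):
            continue
        aln = extend_gapped(hsp, ref, query, scheme)
        if aln is None:
            continue
        key = tuple((s.t_start, s.q_start, s.length) for s in aln.segments)
        if key not in seen:
            seen.add(key)
            alignments.append(aln)
        for seg in aln.segments:
            _diag_add(covered, seg.t_start - seg.q_start, seg.t_start, seg.t_end)
    alignments.sort(key=lambda a: (-a.score, a.t_start, a.q_start))
    return alignments


def _diag_covered(cov, d, start, end) -> bool:
    for s, e in cov.get(d, ()):
        if s <= start and end <= e:
            return True
    return False


def _diag_add(cov, d, start, end) -> None:
    ivs = cov.setdefault(d, [])
    ivs.append((start, end))
    if len(ivs) > 1:
        ivs.sort()
        merged = [ivs[0]]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        cov[d] = merged
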