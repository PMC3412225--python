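"""Local alignment support for amplicon annotation.

Scoring scheme (fixed for determinism): match +1, mismatch -1, gap open -2,
gap extension -1, where "open" is the score of the first gap base (a gap of
length L scores -(L + 1)).

Small problems are solved exactly with Smith-Waterman dynamic programming
(Biopython's PairwiseAligner under this scheme).  Above a size cutoff the
quadratic DP is impractical, so hits are localized by exact k-mer seeding
and chained on a consistent diagonal band, boundaries are refined by greedy
exact extension, and the aligned slices are scored via an edit-distance path
(edlib).  This is the standard seed-and-extend design of read mappers; the
scoring scheme applied to the final path is the same in both branches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import edlib
from Bio import Align

from .seq import revcomp

__all__ = ["LocalHit", "dp_local", "seeded_local", "locate"]

MATCH = 1
MISMATCH = -1
GAP_OPEN = -2  # score of the first base of a gap
GAP_EXTEND = -1

# query*ref size above which seeding replaces exact DP
DP_LIMIT = 1_000_000
SEED_K = 16
SEED_MAX_OCC = 8
DIAG_BAND = 32


@dataclass(frozen=True)
class LocalHit:
    """A local alignment: 0-based half-open intervals on query and reference
    (both on the plus strand of the query; ``strand`` refers to the
    reference orientation)."""

    q_start: int
    q_end: int
    r_start: int
    r_end: int
    strand: str
    score: float
    identity: float
    aligned_length: int

    @property
    def q_span(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def r_span(self) -> tuple[int, int]:
        return (self.r_start, self.r_end)


_aligner = Align.PairwiseAligner(
    mode="local",
    match_score=MATCH,
    mismatch_score=MISMATCH,
    open_gap_score=GAP_OPEN,
    extend_gap_score=GAP_EXTEND,
)


def dp_local(query: str, ref: str) -> LocalHit | None:
    """Exact Smith-Waterman local alignment (best hit), or None if no
    positive-scoring alignment exists."""
    if not query or not ref:
        return None
    query, ref = query.upper(), ref.upper()
    if _aligner.score(query, ref) <= 0:
        return None
    a = _aligner.align(query, ref)[0]
    qblocks, rblocks = a.aligned
    if len(qblocks) == 0:
        return None
    counts = a.counts()
    aligned = counts.identities + counts.mismatches + counts.internal_gaps
    identity = counts.identities / aligned if aligned else 0.0
    return LocalHit(
        q_start=int(qblocks[0][0]),
        q_end=int(qblocks[-1][1]),
        r_start=int(rblocks[0][0]),
        r_end=int(rblocks[-1][1]),
        strand="+",
        score=float(a.score),
        identity=identity,
        aligned_length=int(aligned),
    )


def _cigar_columns(cigar: str) -> list[tuple[str, int]]:
    """Expand an edlib extended cigar into (op, run_length) tuples."""
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


def _best_local_window(cigar: str) -> tuple[int, int, int, int, float, int, int]:
    """Best-scoring contiguous sub-path of a global alignment path.

    A global (NW) path can carry negative-scoring ends (e.g. unrelated
    sequence dragged in by a spurious seed); trimming to the maximum-scoring
    window restores local-alignment semantics.  Returns (q_trim_left,
    q_trim_right, r_trim_left, r_trim_right, score, matches, columns).
    """
    # per-column scores with query/ref advances
    scores: list[float] = []
    dq: list[int] = []
    dr: list[int] = []
    for op, n in _cigar_columns(cigar):
        if op == "=":
            scores.extend([MATCH] * n)
            dq.extend([1] * n)
            dr.extend([1] * n)
        elif op == "X":
            scores.extend([MISMATCH] * n)
            dq.extend([1] * n)
            dr.extend([1] * n)
        elif op in "ID":
            scores.extend([GAP_OPEN] + [GAP_EXTEND] * (n - 1))
            adv_q = 1 if op == "I" else 0
            dq.extend([adv_q] * n)
            dr.extend([1 - adv_q] * n)
        else:
            raise ValueError(f"unexpected cigar op {op!r}")
    # Kadane over columns
    best_sum = cur_sum = 0.0
    best = (0, 0)
    start = 0
    for i, s in enumerate(scores):
        if cur_sum <= 0:
            cur_sum = 0.0
            start = i
        cur_sum += s
        if cur_sum > best_sum:
            best_sum = cur_sum
            best = (start, i + 1)
    lo, hi = best
    q_left, r_left = sum(dq[:lo]), sum(dr[:lo])
    q_right, r_right = sum(dq[hi:]), sum(dr[hi:])
    matches = sum(1 for i in range(lo, hi) if scores[i] == MATCH and dq[i] and dr[i])
    return q_left, q_right, r_left, r_right, best_sum, matches, hi - lo


def _seed_chain(query: str, ref: str) -> tuple[int, int, int, int] | None:
    """Approximate hit extents from exact k-mer seeds chained on a diagonal
    band.  High-multiplicity reference k-mers (low-complexity tracts) are
    skipped, minimizer-style."""
    k = SEED_K
    if len(query) < k or len(ref) < k:
        return None
    index: dict[str, list[int]] = {}
    for i in range(len(ref) - k + 1):
        index.setdefault(ref[i:i + k], []).append(i)
    # diagonal -> list of (qpos, rpos)
    buckets: dict[int, list[tuple[int, int]]] = {}
    step = 4  # sampling query k-mers is enough to find kb-scale hits
    for q in range(0, len(query) - k + 1, step):
        positions = index.get(query[q:q + k])
        if not positions or len(positions) > SEED_MAX_OCC:
            continue
        for r in positions:
            buckets.setdefault((q - r) // DIAG_BAND, []).append((q, r))
    if not buckets:
        return None
    # merge adjacent bands and pick the band group with most seeds
    best_key = max(
        buckets,
        key=lambda d: len(buckets[d])
        + len(buckets.get(d - 1, ())) + len(buckets.get(d + 1, ())),
    )
    seeds = sorted(
        buckets.get(best_key - 1, []) + buckets[best_key]
        + buckets.get(best_key + 1, [])
    )
    # longest run of seeds with co-increasing reference positions
    runs: list[list[tuple[int, int]]] = [[seeds[0]]]
    for s in seeds[1:]:
        if s[1] >= runs[-1][-1][1]:
            runs[-1].append(s)
        else:
            runs.append([s])
    run = max(runs, key=len)
    qs, rs = run[0]
    qe, re_ = run[-1]
    return qs, qe + k, rs, re_ + k


def seeded_local(query: str, ref: str) -> LocalHit | None:
    """Seed-and-extend local hit for large query/reference pairs."""
    query = query.upper()
    ref = ref.upper()
    chain = _seed_chain(query, ref)
    if chain is None:
        return None
    qs, qe, rs, re_ = chain
    # greedy exact extension outward
    while qs > 0 and rs > 0 and query[qs - 1] == ref[rs - 1]:
        qs -= 1
        rs -= 1
    while qe < len(query) and re_ < len(ref) and query[qe] == ref[re_]:
        qe += 1
        re_ += 1
    result = edlib.align(query[qs:qe], ref[rs:re_], mode="NW", task="path")
    ql, qr, rl, rr, score, matches, columns = _best_local_window(result["cigar"])
    if columns == 0:
        return None
    identity = matches / columns
    return LocalHit(
        q_start=qs + ql, q_end=qe - qr, r_start=rs + rl, r_end=re_ - rr,
        strand="+", score=score, identity=identity, aligned_length=columns,
    )


def locate(
    query: str,
    ref: str,
    min_len: int = 50,
    min_identity: float = 0.9,
    both_strands: bool = False,
) -> LocalHit | None:
    """Best local hit of ``query`` against ``ref`` (optionally both strands)
    passing the length and identity thresholds.

    Reference coordinates of minus-strand hits are reported on the
    reference's plus strand; query coordinates always refer to the query as
    given.
    """
    exact = len(query) * len(ref) <= DP_LIMIT
    hits: list[LocalHit] = []
    plus = dp_local(query, ref) if exact else seeded_local(query, ref)
    if plus is not None:
        hits.append(plus)
    if both_strands:
        rc = revcomp(ref)
        minus = dp_local(query, rc) if exact else seeded_local(query, rc)
        if minus is not None:
            L = len(ref)
            hits.append(
                replace(minus, strand="-",
                        r_start=L - minus.r_end, r_end=L - minus.r_start)
            )
    hits = [
        h for h in hits
        if h.aligned_length >= min_len and h.identity >= min_identity
    ]
    if not hits:
        return None
    # ties broken toward the smaller query start coordinate
    return max(hits, key=lambda h: (h.score, -h.q_start))
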