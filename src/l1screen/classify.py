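"""Annotation and classification of candidate insertion amplicons.

A genuine target-primed (TPRT) insertion amplicon contains, in order along
the target's plus strand: a 5' target flank, the element (possibly
5'-truncated, either orientation), the element's poly-A tail (a T-tract 5'
of the element when it inserted in minus orientation), and a 3' target
flank that resumes the target a short distance *before* where the 5' flank
ended — the overlap being the target site duplication (TSD).  PCR chimeras,
by contrast, join a target flank to sequence from another locus, with the
breakdown of target identity occurring at an A/T-rich tract and with no TSD
and no second target flank.  The classifier aligns a candidate against its
target reference and the element reference and applies those structural
criteria.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np

from .align import LocalHit, locate
from .seq import at_fraction, revcomp, validate_alphabet

__all__ = [
    "CandidateAmplicon",
    "Thresholds",
    "InsertionAnnotation",
    "align_flanks",
    "locate_l1",
    "find_polyA",
    "find_tsd",
    "junction_composition",
    "classify",
]


@dataclass(frozen=True)
class CandidateAmplicon:
    """A candidate insertion amplicon to be annotated against its target."""

    id: str
    sequence: str
    target_id: str = ""

    def __post_init__(self) -> None:
        validate_alphabet(self.sequence)
        if len(self.sequence) < 100:
            raise ValueError("amplicon must be >= 100 nt")


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds (all configurable; defaults chosen for the
    canonical TPRT hallmarks)."""

    flank_min_identity: float = 0.90
    flank_min_len: int = 50
    l1_min_identity: float = 0.85
    l1_min_len: int = 100
    polyA_min_len: int = 10
    polyA_min_purity: float = 0.8
    polyA_anchor_slop: int = 10
    tsd_min_len: int = 4
    tsd_max_len: int = 30
    junction_window: int = 20
    junction_at_threshold: float = 0.7
    flank_pad: int = 100
    collinear_max_gap: int = 50


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class L1Segment:
    """Element hit on the amplicon: interval, orientation relative to the
    target plus strand, and the 5'-truncation offset on the element."""

    q_start: int
    q_end: int
    orientation: str
    truncation_offset: int
    identity: float

    @property
    def q_span(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)


@dataclass(frozen=True)
class InsertionAnnotation:
    """Structured verdict for one amplicon.

    All intervals are 0-based half-open in amplicon coordinates;
    ``junction_at_fraction`` maps each internal junction position to the
    A+T fraction of the window around it.
    """

    amplicon_id: str
    verdict: str  # genuine | chimera | no_insertion | unresolved
    flank5: LocalHit | None
    flank3: LocalHit | None
    l1_segment: L1Segment | None
    polyA: tuple[tuple[int, int], float] | None
    tsd: str | None
    junction_at_fraction: dict[int, float]
    evidence: list[str]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["junction_at_fraction"] = {
            str(k): v for k, v in self.junction_at_fraction.items()
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def align_flanks(
    amplicon: str, target_ref: str, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[LocalHit | None, LocalHit | None]:
    """Best local hits of the amplicon's prefix and suffix on the target.

    The prefix/suffix windows are one target length (plus padding) deep —
    a flank cannot be longer than the target.  Hits below the identity or
    length thresholds are reported absent.  For an amplicon that is just a
    copy of the target the two hits coincide.
    """
    if len(target_ref) < 500:
        raise ValueError("target reference must be >= 500 nt")
    amplicon = amplicon.upper()
    w = min(len(amplicon), len(target_ref) + thresholds.flank_pad)
    flank5 = _terminal_flank(amplicon[:w], target_ref, "5", thresholds)
    suffix_start = len(amplicon) - w
    flank3 = _terminal_flank(amplicon[suffix_start:], target_ref, "3", thresholds)
    if flank3 is not None:
        flank3 = replace(
            flank3,
            q_start=flank3.q_start + suffix_start,
            q_end=flank3.q_end + suffix_start,
        )
    return flank5, flank3


_ANCHOR_TOL = 25  # a flank must reach this close to its amplicon terminus


def _terminal_flank(
    seq_slice: str, ref: str, end: str, thresholds: Thresholds
) -> LocalHit | None:
    """Best target hit anchored at the slice's 5' or 3' terminus.

    The amplicon is primed from its termini, so a true flank reaches the
    corresponding end of the amplicon.  When the globally best local hit
    lies in the interior (e.g. the other, longer flank within the search
    window), the search is repeated on the region between it and the
    terminus until an anchored hit (or nothing) remains.
    """
    lo, hi = 0, len(seq_slice)
    for _ in range(5):
        if hi - lo < thresholds.flank_min_len:
            return None
        hit = locate(
            seq_slice[lo:hi], ref,
            min_len=thresholds.flank_min_len,
            min_identity=thresholds.flank_min_identity,
        )
        if hit is None:
            return None
        if end == "5":
            if hit.q_start + lo <= _ANCHOR_TOL:
                return replace(hit, q_start=hit.q_start + lo,
                               q_end=hit.q_end + lo)
            hi = lo + hit.q_start
        else:
            if hit.q_end + lo >= len(seq_slice) - _ANCHOR_TOL:
                return replace(hit, q_start=hit.q_start + lo,
                               q_end=hit.q_end + lo)
            lo = lo + hit.q_end
    return None


def locate_l1(
    amplicon: str, l1_ref: str, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> L1Segment | None:
    """Best element hit on either strand, with 5'-truncation offset
    (distance from the element's 5' end to the alignment start)."""
    if len(l1_ref) < 2000:
        raise ValueError("element reference must be >= 2000 nt")
    hit = locate(
        amplicon.upper(), l1_ref.upper(),
        min_len=thresholds.l1_min_len,
        min_identity=thresholds.l1_min_identity,
        both_strands=True,
    )
    if hit is None:
        return None
    return L1Segment(
        q_start=hit.q_start,
        q_end=hit.q_end,
        orientation="plus" if hit.strand == "+" else "minus",
        truncation_offset=hit.r_start,
        identity=hit.identity,
    )


def find_polyA(
    amplicon: str,
    anchor: int,
    direction: str = "right",
    base: str = "A",
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    limit: int | None = None,
) -> tuple[tuple[int, int], float] | None:
    """Longest homopolymer-rich window adjacent to ``anchor``.

    ``direction`` "right": the window starts within ``polyA_anchor_slop`` of
    the anchor and extends rightward (plus-orientation poly-A after the
    element 3' end).  "left": the window ends near the anchor and extends
    leftward (minus-orientation T-tract 5' of the element).  ``limit`` caps
    the far end (e.g. at the start of the 3' flank).  Returns the interval
    and its base purity, or None if no window reaches the minimum length at
    the purity threshold.
    """
    if not 0 <= anchor <= len(amplicon):
        raise ValueError("anchor outside amplicon")
    s = amplicon.upper()
    if direction == "left":
        # mirror the problem: search rightward in the reversed string
        mirrored = find_polyA(
            s[::-1], len(s) - anchor, "right", base, thresholds,
            limit=None if limit is None else len(s) - limit,
        )
        if mirrored is None:
            return None
        (a, b), purity = mirrored
        return (len(s) - b, len(s) - a), purity
    lo = max(0, anchor - thresholds.polyA_anchor_slop)
    hi = min(len(s), anchor + thresholds.polyA_anchor_slop)
    far = len(s) if limit is None else min(limit, len(s))
    is_base = np.frombuffer(s.encode(), dtype=np.uint8) == ord(base)
    cum = np.concatenate([[0], np.cumsum(is_base)])
    best: tuple[tuple[int, int], float] | None = None
    for start in range(lo, hi + 1):
        if start >= far or not is_base[start]:
            continue
        # extend with +1 per tail base, -2 per other base; the argmax end
        # stops the tract at the tail instead of absorbing flanking sequence
        run_score = 0
        best_score = 0
        end = start
        for e in range(start, far):
            run_score += 1 if is_base[e] else -2
            if run_score > best_score:
                best_score = run_score
                end = e + 1
            elif run_score < -6:
                break
        length = end - start
        if length < thresholds.polyA_min_len:
            continue
        purity = (cum[end] - cum[start]) / length
        if purity < thresholds.polyA_min_purity:
            continue
        if best is None or length > best[0][1] - best[0][0]:
            best = ((start, end), purity)
    return best


def find_tsd(
    target_ref: str,
    left_break: int,
    right_break: int,
    min_len: int = DEFAULT_THRESHOLDS.tsd_min_len,
    max_len: int = DEFAULT_THRESHOLDS.tsd_max_len,
) -> str | None:
    """Target site duplication between the two flank breakpoints.

    ``left_break`` is the target coordinate where the 5' flank ends,
    ``right_break`` where the 3' flank begins.  TPRT duplicates the target
    bases between the two nicks, so the duplicated motif is simultaneously a
    suffix of the target before ``left_break`` and a prefix from
    ``right_break``.  Returns the longest such exact repeat within
    ``max_len``, or None below ``min_len`` (blunt insertion or discordant
    breaks)."""
    t = target_ref.upper()
    if not (0 <= right_break <= len(t) and 0 <= left_break <= len(t)):
        return None
    for L in range(max_len, min_len - 1, -1):
        if left_break - L < 0 or right_break + L > len(t):
            continue
        if t[left_break - L:left_break] == t[right_break:right_break + L]:
            return t[left_break - L:left_break]
    return None


def junction_composition(sequence: str, position: int, window: int = 20) -> float:
    """A+T fraction of the window centred at ``position`` (clipped at the
    sequence ends)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    half = window // 2
    lo = max(0, position - half)
    hi = min(len(sequence), position + (window - half))
    return at_fraction(sequence[lo:hi])


def classify(
    amplicon: CandidateAmplicon | str,
    target_ref: str,
    l1_ref: str,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> InsertionAnnotation:
    """Apply the structural criteria for a genuine TPRT insertion.

    Verdicts:

    * ``genuine`` — both flanks present and collinear on the target, an
      element segment between them, and a poly-A tail on the element's 3'
      side (TSD recorded when detectable, but not required).
    * ``no_insertion`` — no element segment (evidence notes whether the
      flanks reconstruct the bare target).
    * ``chimera`` — an element segment with a missing or discordant flank;
      the A+T fraction at the discordance junction is recorded.
    * ``unresolved`` — an element segment with flanks that fit neither
      pattern (e.g. missing poly-A).
    """
    if isinstance(amplicon, str):
        amplicon = CandidateAmplicon(id="amplicon", sequence=amplicon)
    seq = amplicon.sequence.upper()
    evidence: list[str] = []
    junctions: dict[int, float] = {}

    flank5, flank3 = align_flanks(seq, target_ref, thresholds)
    l1 = locate_l1(seq, l1_ref, thresholds)

    def _annotation(verdict: str, polyA=None, tsd=None) -> InsertionAnnotation:
        return InsertionAnnotation(
            amplicon_id=amplicon.id, verdict=verdict,
            flank5=flank5, flank3=flank3, l1_segment=l1,
            polyA=polyA, tsd=tsd, junction_at_fraction=junctions,
            evidence=evidence,
        )

    if l1 is None:
        evidence.append("no element segment above threshold")
        covered = _target_coverage(flank5, flank3, len(target_ref))
        if covered >= 0.9:
            evidence.append(
                f"flanks reconstruct {covered:.0%} of the empty target"
            )
        else:
            evidence.append(
                f"flanks cover only {covered:.0%} of the target"
            )
        return _annotation("no_insertion")

    evidence.append(
        f"element segment {l1.q_span} orientation {l1.orientation}, "
        f"5'-truncated by {l1.truncation_offset} bp, "
        f"identity {l1.identity:.3f}"
    )

    # keep flank/element intervals disjoint: the element interval wins
    if flank5 is not None and flank5.q_end > l1.q_start:
        if flank5.q_start >= l1.q_start:
            flank5 = None
        else:
            flank5 = replace(flank5, q_end=min(flank5.q_end, l1.q_start))
    if flank3 is not None and flank3.q_start < l1.q_end:
        if flank3.q_end <= l1.q_end:
            flank3 = None
        else:
            flank3 = replace(flank3, q_start=max(flank3.q_start, l1.q_end))

    if flank5 is None and flank3 is None:
        evidence.append("no target flank on either side")
        return _annotation("unresolved")

    # poly-A on the element's 3' side, bounded by the neighbouring flank
    if l1.orientation == "plus":
        polyA = find_polyA(
            seq, l1.q_end, "right", "A", thresholds,
            limit=flank3.q_start if flank3 else None,
        )
    else:
        polyA = find_polyA(
            seq, l1.q_start, "left", "T", thresholds,
            limit=flank5.q_end if flank5 else None,
        )
    if polyA is not None:
        evidence.append(
            f"poly-A tract {polyA[0]} purity {polyA[1]:.2f} "
            f"({'A' if l1.orientation == 'plus' else 'T on plus strand'})"
        )
    else:
        evidence.append("no poly-A tract at the element 3' end")

    collinear = (
        flank5 is not None
        and flank3 is not None
        and flank5.r_start < flank3.r_start
        and flank3.r_end > flank5.r_end
        and flank3.r_start - flank5.r_end <= thresholds.collinear_max_gap
    )

    if flank5 is not None and flank3 is not None and collinear and polyA:
        tsd = find_tsd(
            target_ref, flank5.r_end, flank3.r_start,
            thresholds.tsd_min_len, thresholds.tsd_max_len,
        )
        evidence.append("flanks collinear on target; structure matches TPRT")
        evidence.append(
            f"TSD {tsd!r}" if tsd else "no TSD >= minimum length (blunt?)"
        )
        for pos in (flank5.q_end, flank3.q_start):
            junctions[pos] = junction_composition(
                seq, pos, thresholds.junction_window
            )
        return _annotation("genuine", polyA=polyA, tsd=tsd)

    if flank5 is not None and flank3 is not None and not collinear:
        evidence.append("both flanks present but discordant on the target")
        pos = flank5.q_end
        junctions[pos] = junction_composition(seq, pos, thresholds.junction_window)
        evidence.append(
            f"junction at {pos}: A+T fraction {junctions[pos]:.2f}"
        )
        return _annotation("chimera", polyA=polyA)

    if flank5 is None or flank3 is None:
        side = "5'" if flank5 is None else "3'"
        pos = flank3.q_start if flank5 is None else flank5.q_end
        junctions[pos] = junction_composition(seq, pos, thresholds.junction_window)
        evidence.append(
            f"{side} target flank absent; discordance junction at {pos} "
            f"with A+T fraction {junctions[pos]:.2f}"
        )
        return _annotation("chimera", polyA=polyA)

    evidence.append("element present but structure matches no pattern")
    return _annotation("unresolved", polyA=polyA)


def _target_coverage(
    flank5: LocalHit | None, flank3: LocalHit | None, target_len: int
) -> float:
    intervals = [
        h.r_span for h in (flank5, flank3) if h is not None
    ]
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0
    cursor = 0
    for s, e in intervals:
        s = max(s, cursor)
        if e > s:
            covered += e - s
            cursor = e
    return covered / target_len
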