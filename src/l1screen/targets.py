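"""Suitability screening of candidate insertion-trap loci.

A usable target locus must (i) contain no close match to any of the
biotinylated capture oligos (otherwise the empty site itself is recovered by
hybridization), (ii) offer integration sites for the element's endonuclease
(loose consensus 5'-TTAAAA-3'), and (iii) contain repeat-free stretches long
enough for nested PCR primer design.  Repeat intervals are consumed as BED
input; computing them is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .seq import revcomp

__all__ = [
    "OligoHit",
    "ScreenReport",
    "scan_oligos",
    "count_en_sites",
    "en_density",
    "primer_windows",
    "merge_intervals",
    "screen_target",
]

EN_MOTIF = "TTAAAA"


@dataclass(frozen=True)
class OligoHit:
    """A window of the target within ``mismatches`` substitutions of an oligo
    (strand '+') or of its reverse complement (strand '-')."""

    oligo_id: str
    position: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class ScreenReport:
    """Outcome of the three-criterion locus screen."""

    target_id: str
    oligo_hits: list
    passes_oligo_screen: bool
    en_sites: list
    en_density: float
    primer_windows: list

    def to_json(self) -> str:
        d = asdict(self)
        d["oligo_hits"] = [asdict(h) for h in self.oligo_hits]
        return json.dumps(d, indent=2)


def _encode(seq: str, sentinel: int) -> np.ndarray:
    """Bytes of ``seq`` uppercased, with any non-ACGT byte replaced by
    ``sentinel`` so ambiguous bases never match anything."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    acgt = (arr == 65) | (arr == 67) | (arr == 71) | (arr == 84)
    arr[~acgt] = sentinel
    return arr


def scan_oligos(
    target: str, oligos: dict[str, str], max_mismatch: int = 3
) -> list[OligoHit]:
    """All gapless windows of ``target`` within Hamming distance
    ``max_mismatch`` of any oligo, on either strand.

    Ambiguous bases count as mismatches.  Hits are sorted by position, then
    oligo id, then strand.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    hits: list[OligoHit] = []
    # distinct sentinels: an N in the target never equals an N in the oligo
    tgt = _encode(target, sentinel=0)
    for oligo_id, oligo in oligos.items():
        L = len(oligo)
        if L > len(target):
            raise ValueError(f"oligo {oligo_id!r} longer than target")
        windows = np.lib.stride_tricks.sliding_window_view(tgt, L)
        for strand, probe in (("+", oligo), ("-", revcomp(oligo))):
            arr = _encode(probe, sentinel=1)
            mm = (windows != arr).sum(axis=1)
            for pos in np.nonzero(mm <= max_mismatch)[0]:
                hits.append(OligoHit(oligo_id, int(pos), strand, int(mm[pos])))
    hits.sort(key=lambda h: (h.position, h.oligo_id, h.strand))
    return hits


def count_en_sites(target: str, motif: str = EN_MOTIF) -> list[tuple[int, str]]:
    """Exact occurrences of the endonuclease nick motif.

    Plus-strand sites are occurrences of ``motif``; minus-strand sites are
    occurrences of its reverse complement (a nickable motif on the bottom
    strand).  Overlapping occurrences are all reported; positions are 0-based
    starts of the matched window on the plus strand.
    """
    if len(motif) < 4:
        raise ValueError("motif length must be >= 4")
    target = target.upper()
    sites: list[tuple[int, str]] = []
    for strand, probe in (("+", motif.upper()), ("-", revcomp(motif))):
        start = target.find(probe)
        while start != -1:
            sites.append((start, strand))
            start = target.find(probe, start + 1)
    if revcomp(motif) == motif.upper():  # palindromic motif: one site per window
        sites = [(p, s) for p, s in sites if s == "+"]
    sites.sort()
    return sites


def en_density(target: str, motif: str = EN_MOTIF) -> float:
    """Endonuclease sites per kb of target."""
    return len(count_en_sites(target, motif)) / (len(target) / 1000.0)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 0-based half-open intervals as a sorted disjoint list."""
    merged: list[list[int]] = []
    for s, e in sorted((int(s), int(e)) for s, e in intervals):
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def primer_windows(
    target_length: int,
    repeat_intervals: list[tuple[int, int]],
    min_window: int = 100,
) -> list[tuple[int, int]]:
    """Maximal repeat-free intervals of length >= ``min_window``.

    ``repeat_intervals`` are 0-based half-open and must lie within the
    target; overlapping repeats are merged.
    """
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    merged = merge_intervals(repeat_intervals)
    if merged and (merged[0][0] < 0 or merged[-1][1] > target_length):
        raise ValueError("repeat intervals outside target bounds")
    windows: list[tuple[int, int]] = []
    cursor = 0
    for s, e in merged + [(target_length, target_length)]:
        if s - cursor >= min_window:
            windows.append((cursor, s))
        cursor = max(cursor, e)
    return windows


def screen_target(
    target_id: str,
    target: str,
    oligos: dict[str, str],
    repeat_intervals: list[tuple[int, int]] | None = None,
    max_mismatch: int = 3,
    motif: str = EN_MOTIF,
    min_window: int = 100,
) -> ScreenReport:
    """Run all three suitability criteria on one locus."""
    hits = scan_oligos(target, oligos, max_mismatch)
    sites = count_en_sites(target, motif)
    return ScreenReport(
        target_id=target_id,
        oligo_hits=hits,
        passes_oligo_screen=not hits,
        en_sites=sites,
        en_density=en_density(target, motif),
        primer_windows=primer_windows(
            len(target), repeat_intervals or [], min_window
        ),
    )
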