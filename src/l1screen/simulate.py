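"""Synthetic data for every stage of the insertion screen, with ground truth.

The study's raw material (sperm DNA, trace files) is not available, so this
module generates structurally faithful stand-ins: an L1-like element
reference with capture oligos complementary to its 3'-terminal 1.5 kb;
target loci with planted endonuclease nick motifs and no close oligo
matches; genuine insertion amplicons built by the target-primed reverse
transcription (TPRT) convention (target site duplication, optionally
5'-truncated element, 3' poly-A tail, either orientation); PCR-chimera
amplicons fused at A-rich linker tracts shared between two loci; and
limiting-dilution well tables drawn from the Poisson zero-class model.

Every generator is a pure function of its seed: identical seeds give
byte-identical output.  Seeds for sub-streams are derived as
``default_rng([seed, stream])`` with a fixed stream id per generator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict

import numpy as np

from .dilution import DilutionSeries
from .seq import random_seq, revcomp
from .targets import EN_MOTIF, count_en_sites, scan_oligos

__all__ = [
    "SimConfig",
    "TruthRecord",
    "DonorLocus",
    "GenerationError",
    "gen_l1_reference",
    "gen_bio_oligos",
    "gen_target_locus",
    "gen_insertion_amplicon",
    "gen_empty_amplicon",
    "gen_donor_locus",
    "gen_chimeric_amplicon",
    "gen_dilution_series",
    "find_a_rich_tract",
    "simulate_bundle",
]

# sub-stream ids for seed derivation
_S_L1, _S_TARGET, _S_AMPLICON, _S_CHIMERA, _S_DILUTION, _S_BUNDLE = range(6)

OLIGO_REGION = 1500  # 3'-terminal span of the element carrying capture sites


class GenerationError(RuntimeError):
    """Constraint-satisfying generation failed within the retry budget."""


@dataclass(frozen=True)
class SimConfig:
    """Structural parameters of a simulated insertion.

    ``truncation_offset`` is the number of element bases missing from the 5'
    end (incomplete reverse transcription); ``tsd_length`` the target site
    duplication; ``orientation`` the element strand relative to the target.
    ``polyA_error_rate`` degrades poly-A purity for robustness experiments.
    """

    seed: int
    l1_length: int = 6000
    target_length: int = 5000
    gc_fraction: float = 0.42
    polyA_length: int = 20
    tsd_length: int = 15
    truncation_offset: int = 0
    orientation: str = "plus"
    polyA_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.tsd_length < 0:
            raise ValueError("tsd_length must be >= 0")
        if not 0 <= self.truncation_offset < self.l1_length:
            raise ValueError("require 0 <= truncation_offset < l1_length")
        if self.orientation not in ("plus", "minus"):
            raise ValueError("orientation must be 'plus' or 'minus'")
        if self.polyA_length < 0:
            raise ValueError("polyA_length must be >= 0")
        if not 0.0 <= self.polyA_error_rate < 1.0:
            raise ValueError("polyA_error_rate must be in [0, 1)")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated amplicon (0-based half-open spans in
    amplicon coordinates)."""

    kind: str  # genuine | chimera | empty
    insertion_point: int | None = None
    tsd_sequence: str | None = None
    polyA_span: tuple[int, int] | None = None
    l1_span: tuple[int, int] | None = None
    orientation: str | None = None
    truncation_offset: int | None = None
    donor_locus_id: str | None = None
    junction_position: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("genuine", "chimera", "empty"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "genuine" and self.donor_locus_id is not None:
            raise ValueError("genuine records carry no donor locus")
        if self.kind == "chimera" and self.junction_position is None:
            raise ValueError("chimera records require a junction position")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DonorLocus:
    """A locus harboring a known element insertion, used as the partner of a
    PCR chimera.  Spans are 0-based half-open on ``sequence``."""

    locus_id: str
    sequence: str
    l1_span: tuple[int, int] | None
    polyA_span: tuple[int, int] | None
    a_tract: tuple[int, int]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def gen_l1_reference(config: SimConfig) -> str:
    """Synthetic element reference (stand-in for a full-length L1 sequence).

    The 3'-terminal 1.5 kb is the region from which capture oligos are
    drawn; being i.i.d. random it is unique within the element, so oligos
    taken from it have no close match elsewhere.
    """
    if config.l1_length < 2000:
        raise ValueError("l1_length must be >= 2000")
    return random_seq(_rng(config.seed, _S_L1), config.l1_length,
                      config.gc_fraction)


def gen_bio_oligos(l1_ref: str, n: int = 4, length: int = 30) -> dict[str, str]:
    """Capture oligos: exact reverse complements of ``n`` evenly spaced
    windows inside the element's 3'-terminal 1.5 kb."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if length > OLIGO_REGION:
        raise ValueError(f"oligo length must be <= {OLIGO_REGION}")
    region_start = max(0, len(l1_ref) - OLIGO_REGION)
    last_start = len(l1_ref) - length
    if last_start < region_start:
        raise ValueError("oligo windows do not fit in the 3' region")
    starts = np.unique(
        np.linspace(region_start, last_start, n).round().astype(int)
    )
    if len(starts) < n:
        raise ValueError("3' region too small for n distinct windows")
    return {
        f"bio{i + 1}": revcomp(l1_ref[s:s + length])
        for i, s in enumerate(starts)
    }


def _scrub_motifs(seq: list[str], motif: str, rng: np.random.Generator,
                  protected: set[int]) -> None:
    """Destroy all occurrences of ``motif`` (both strands) in place by
    writing G/C at an unprotected window position.  For A/T-only motifs this
    cannot create new occurrences, so a bounded loop converges."""
    probes = {motif.upper(), revcomp(motif)}
    for _ in range(50):
        s = "".join(seq)
        occurrences = [
            i
            for probe in probes
            for i in _find_all(s, probe)
        ]
        if not occurrences:
            return
        changed = False
        for start in occurrences:
            free = [j for j in range(start, start + len(motif))
                    if j not in protected]
            if free:
                j = free[len(free) // 2]
                seq[j] = rng.choice(["G", "C"])
                changed = True
        if not changed:
            return  # every occurrence protected: leave them
    raise GenerationError("motif scrubbing did not converge")


def _find_all(s: str, probe: str) -> list[int]:
    out, i = [], s.find(probe)
    while i != -1:
        out.append(i)
        i = s.find(probe, i + 1)
    return out


def gen_target_locus(
    length: int = 5000,
    gc: float = 0.42,
    planted_en_sites: int = 5,
    seed: int = 0,
    motif: str = EN_MOTIF,
    motif_free_background: bool = True,
    plant_a_tract: bool = False,
    a_tract_length: int = 25,
    avoid_oligos: dict[str, str] | None = None,
    margin: int = 600,
    max_retries: int = 20,
) -> tuple[str, dict]:
    """Target locus with a controlled complement of endonuclease nick sites.

    Returns (sequence, info) where ``info`` records planted motif positions
    and, if requested, the planted A-rich linker interval.  The background is
    i.i.d. at the requested GC; with ``motif_free_background`` all incidental
    motif occurrences (either strand) are destroyed before planting, so the
    planted sites are the only interior ones.  If ``avoid_oligos`` is given,
    candidates with any window within 3 mismatches of an oligo are rejected
    and regenerated (bounded retries).
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if planted_en_sites < 0:
        raise ValueError("planted_en_sites must be >= 0")
    rng = _rng(seed, _S_TARGET)
    for _ in range(max_retries):
        seq = list(random_seq(rng, length, gc))
        protected: set[int] = set()
        info: dict = {"en_positions": [], "a_tract": None}

        if plant_a_tract:
            a_start = (length - a_tract_length) // 2
            seq[a_start:a_start + a_tract_length] = ["A"] * a_tract_length
            protected |= set(range(a_start, a_start + a_tract_length))
            info["a_tract"] = (a_start, a_start + a_tract_length)

        if motif_free_background:
            _scrub_motifs(seq, motif, rng, protected)

        if planted_en_sites:
            lo, hi = margin, length - margin - len(motif)
            if hi - lo < planted_en_sites * 50:
                raise ValueError("target too short for requested motif count")
            positions = _spaced_positions(
                rng, lo, hi, planted_en_sites, min_gap=50,
                forbidden=info["a_tract"],
            )
            for p in positions:
                seq[p:p + len(motif)] = list(motif)
                protected |= set(range(p, p + len(motif)))
            info["en_positions"] = sorted(int(p) for p in positions)
            if motif_free_background:
                # planting can create straddle occurrences at motif edges
                _scrub_motifs(seq, motif, rng, protected)

        out = "".join(seq)
        if avoid_oligos and scan_oligos(out, avoid_oligos, 3):
            continue
        return out, info
    raise GenerationError(
        "could not generate a target satisfying the oligo screen"
    )


def _spaced_positions(
    rng: np.random.Generator, lo: int, hi: int, n: int, min_gap: int,
    forbidden: tuple[int, int] | None,
) -> list[int]:
    positions: list[int] = []
    for _ in range(200 * n):
        p = int(rng.integers(lo, hi))
        if forbidden and forbidden[0] - min_gap <= p <= forbidden[1] + min_gap:
            continue
        if all(abs(p - q) >= min_gap for q in positions):
            positions.append(p)
            if len(positions) == n:
                return positions
    raise GenerationError("could not place spaced motif positions")


def gen_insertion_amplicon(
    target: str,
    l1_ref: str,
    config: SimConfig,
    insertion_point: int | None = None,
) -> tuple[str, TruthRecord]:
    """Genuine TPRT-style insertion amplicon.

    The element (5'-truncated by ``truncation_offset``) plus its poly-A tail
    is inserted at an endonuclease motif position ``p``, duplicating the
    ``tsd_length`` target bases 5' of the nick around the insert:

        target[:p+tsd] + element(+polyA, oriented) + target[p:]

    In minus orientation the element appears reverse-complemented, so its
    poly-A tail reads as a T-tract 5' of the element segment.
    """
    if config.truncation_offset >= len(l1_ref):
        raise ValueError("truncation_offset must be < element length")
    rng = _rng(config.seed, _S_AMPLICON)
    if insertion_point is None:
        sites = [p for p, s in count_en_sites(target) if s == "+"]
        sites = [p for p in sites if 200 <= p <= len(target) - 200]
        if not sites:
            raise GenerationError("target has no usable endonuclease motif")
        insertion_point = int(sites[rng.integers(len(sites))])
    p, t = insertion_point, config.tsd_length
    if not 0 <= p <= len(target) - t:
        raise ValueError("insertion point outside target")

    segment = l1_ref[config.truncation_offset:]
    tail = _polyA(rng, config.polyA_length, config.polyA_error_rate)
    left = target[:p + t]
    if config.orientation == "plus":
        insert = segment + tail
        l1_span = (len(left), len(left) + len(segment))
        polyA_span = (l1_span[1], l1_span[1] + len(tail))
    else:
        insert = revcomp(segment + tail)
        polyA_span = (len(left), len(left) + len(tail))
        l1_span = (polyA_span[1], polyA_span[1] + len(segment))
    amplicon = left + insert + target[p:]
    truth = TruthRecord(
        kind="genuine",
        insertion_point=p,
        tsd_sequence=target[p:p + t],
        polyA_span=polyA_span,
        l1_span=l1_span,
        orientation=config.orientation,
        truncation_offset=config.truncation_offset,
    )
    return amplicon, truth


def _polyA(rng: np.random.Generator, length: int, error_rate: float) -> str:
    if length == 0:
        return ""
    tail = np.full(length, "A")
    if error_rate > 0:
        bad = rng.random(length) < error_rate
        tail[bad] = rng.choice(["C", "G", "T"], size=int(bad.sum()))
    return "".join(tail)


def gen_empty_amplicon(target: str) -> tuple[str, TruthRecord]:
    """Empty-site amplicon: the target itself, no insertion."""
    return target, TruthRecord(kind="empty")


def gen_donor_locus(
    l1_ref: str,
    seed: int,
    locus_id: str = "donor",
    gc: float = 0.42,
    flank: int = 800,
    spacer: int = 200,
    l1_tail: int = 1500,
    polyA_length: int = 20,
    a_tract_length: int = 25,
    include_l1: bool = True,
) -> DonorLocus:
    """A locus carrying a known element 3' end downstream of an A-rich
    linker, as the donor partner of a PCR chimera."""
    rng = _rng(seed, _S_CHIMERA)
    parts = [random_seq(rng, flank, gc)]
    a_start = len(parts[0])
    parts.append("A" * a_tract_length)
    parts.append(random_seq(rng, spacer, gc))
    l1_span = polyA_span = None
    if include_l1:
        start = sum(len(x) for x in parts)
        parts.append(l1_ref[-l1_tail:])
        l1_span = (start, start + l1_tail)
        parts.append("A" * polyA_length)
        polyA_span = (l1_span[1], l1_span[1] + polyA_length)
    parts.append(random_seq(rng, flank, gc))
    return DonorLocus(
        locus_id=locus_id,
        sequence="".join(parts),
        l1_span=l1_span,
        polyA_span=polyA_span,
        a_tract=(a_start, a_start + a_tract_length),
    )


def find_a_rich_tract(
    seq: str, min_len: int = 20, min_a: float = 0.9
) -> tuple[int, int] | None:
    """First A-rich tract suitable as a template-switch fusion point.

    Primary definition: the first pure-A run of length >= ``min_len`` (the
    planted chimera linkers are A-homopolymers).  If none exists and
    ``min_a`` < 1, falls back to the first ``min_len`` window whose A
    fraction reaches ``min_a``.
    """
    s = seq.upper()
    m = re.search("A{%d,}" % min_len, s)
    if m:
        return (m.start(), m.end())
    if min_a < 1.0:
        counts = np.frombuffer(s.encode(), dtype=np.uint8) == ord("A")
        if len(counts) >= min_len:
            window = np.convolve(counts, np.ones(min_len, dtype=int), "valid")
            idx = np.nonzero(window >= min_a * min_len)[0]
            if idx.size:
                return (int(idx[0]), int(idx[0]) + min_len)
    return None


def gen_chimeric_amplicon(
    target: str,
    donor: DonorLocus | str,
    seed: int,
) -> tuple[str, TruthRecord]:
    """Template-switch chimera fused inside shared A-rich tracts.

    The product is the target prefix through its A-rich tract joined to the
    donor suffix from its own A-rich tract onward (which carries the donor's
    element 3' end, when present).  There is no target site duplication and
    no 5' element/target junction — the hallmarks that let the classifier
    separate chimeras from genuine insertions.
    """
    donor_seq = donor.sequence if isinstance(donor, DonorLocus) else donor
    t_tract = find_a_rich_tract(target)
    d_tract = donor.a_tract if isinstance(donor, DonorLocus) else \
        find_a_rich_tract(donor_seq)
    if t_tract is None or d_tract is None:
        raise GenerationError("both fusion partners need an A-rich tract")
    te = t_tract[1]  # fuse at the end of the target's tract
    ds = d_tract[0]  # resume at the start of the donor's tract
    amplicon = target[:te] + donor_seq[ds:]
    shift = te - ds
    l1_span = None
    if isinstance(donor, DonorLocus) and donor.l1_span is not None:
        l1_span = (donor.l1_span[0] + shift, donor.l1_span[1] + shift)
    truth = TruthRecord(
        kind="chimera",
        junction_position=te,
        l1_span=l1_span,
        donor_locus_id=donor.locus_id if isinstance(donor, DonorLocus) else None,
    )
    return amplicon, truth


def gen_dilution_series(
    true_lambda: float,
    inputs_pg: list[float],
    replicates: int = 8,
    seed: int = 0,
) -> DilutionSeries:
    """Bernoulli well outcomes under the Poisson zero-class model:
    P(positive well) = 1 - exp(-lambda * m)."""
    if true_lambda < 0:
        raise ValueError("true_lambda must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    m = np.asarray(inputs_pg, dtype=float)
    if np.any(m <= 0):
        raise ValueError("inputs_pg must be positive")
    rng = _rng(seed, _S_DILUTION)
    p = -np.expm1(-true_lambda * m)
    k = rng.binomial(replicates, p)
    return DilutionSeries(m, k, np.full(m.shape, replicates, dtype=int))


def simulate_bundle(
    seed: int,
    n_targets: int = 3,
    n_genuine: int = 5,
    n_chimera: int = 5,
    n_empty: int = 2,
    l1_length: int = 6000,
    target_length: int = 5000,
    gc_fraction: float = 0.42,
    true_lambda: float = 1.0 / 12.0,
    dilution_inputs_pg: tuple[float, ...] = (1.0, 3.0, 10.0, 30.0, 100.0),
    replicates: int = 8,
) -> dict:
    """Everything the pipeline consumes, in one deterministic bundle.

    Genuine amplicons vary truncation offset, orientation, TSD length
    (7-20 nt) and poly-A length (15-30 nt) across cases; chimeras fuse each
    target (with planted A-linker) to a fresh donor locus.
    """
    base = SimConfig(seed=seed, l1_length=l1_length,
                     target_length=target_length, gc_fraction=gc_fraction)
    l1_ref = gen_l1_reference(base)
    oligos = gen_bio_oligos(l1_ref)
    rng = _rng(seed, _S_BUNDLE)

    targets = []
    for i in range(n_targets):
        tseq, info = gen_target_locus(
            length=target_length, gc=gc_fraction, planted_en_sites=5,
            seed=int(rng.integers(2**31)), plant_a_tract=True,
            avoid_oligos=oligos,
        )
        targets.append({"id": f"T{i + 1}", "sequence": tseq, "info": info})

    amplicons = []
    for j in range(n_genuine):
        tgt = targets[j % n_targets]
        cfg = SimConfig(
            seed=int(rng.integers(2**31)),
            l1_length=l1_length,
            target_length=target_length,
            gc_fraction=gc_fraction,
            polyA_length=int(rng.integers(15, 31)),
            tsd_length=int(rng.integers(7, 21)),
            truncation_offset=int(rng.integers(0, l1_length - 2000)),
            orientation="plus" if rng.random() < 0.5 else "minus",
        )
        seq, truth = gen_insertion_amplicon(tgt["sequence"], l1_ref, cfg)
        amplicons.append(
            {"id": f"amp_genuine_{j + 1}", "target_id": tgt["id"],
             "sequence": seq, "truth": truth}
        )
    for j in range(n_chimera):
        tgt = targets[j % n_targets]
        donor = gen_donor_locus(
            l1_ref, seed=int(rng.integers(2**31)), locus_id=f"donor_{j + 1}",
            gc=gc_fraction,
        )
        seq, truth = gen_chimeric_amplicon(
            tgt["sequence"], donor, seed=int(rng.integers(2**31))
        )
        amplicons.append(
            {"id": f"amp_chimera_{j + 1}", "target_id": tgt["id"],
             "sequence": seq, "truth": truth}
        )
    for j in range(n_empty):
        tgt = targets[j % n_targets]
        seq, truth = gen_empty_amplicon(tgt["sequence"])
        amplicons.append(
            {"id": f"amp_empty_{j + 1}", "target_id": tgt["id"],
             "sequence": seq, "truth": truth}
        )

    series = gen_dilution_series(
        true_lambda, list(dilution_inputs_pg), replicates,
        seed=int(rng.integers(2**31)),
    )
    return {
        "l1_ref": l1_ref,
        "oligos": oligos,
        "targets": targets,
        "amplicons": amplicons,
        "dilution": series,
    }
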