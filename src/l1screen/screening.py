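"""Screening depth and zero-event frequency bounds for the insertion trap.

A multiplex single-molecule screen interrogates a panel of target loci in a
known mass of sperm DNA.  Observing no (or few) genuine insertions converts,
via an exact one-sided Poisson bound, into an upper bound on the germline
retrotransposition rate per kilobase and per haploid genome.  This module
implements that design arithmetic: panel target size (with X-linked loci
present in only half of sperm), sperm and amplifiable-molecule counts, total
kilobases screened, the exact Poisson upper bound, and the incidence-format
conversions used to compare with population estimates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import pandas as pd
from scipy.optimize import brentq
from scipy.stats import poisson

__all__ = [
    "TargetLocus",
    "ScreeningDesign",
    "FrequencyBound",
    "load_target_loci",
    "default_target_loci",
    "effective_target_size",
    "sperm_count",
    "amplifiable_per_target",
    "kb_screened",
    "poisson_upper_bound",
    "rate_bound",
    "incidence_to_mass",
    "per_sperm_rate",
    "ejaculate_expectation",
    "to_sig_figs",
    "floor_to_nearest",
    "nearest_power_of_ten",
    "screen_depth_report",
]


@dataclass(frozen=True)
class TargetLocus:
    """One locus of the insertion-trap panel.

    ``amplicon_length`` is the target amplicon length in bp; ``x_linked``
    loci are hemizygous in sperm, i.e. present in only 50% of gametes.
    """

    name: str
    chromosome: str
    amplicon_length: int
    x_linked: bool

    def __post_init__(self) -> None:
        if self.amplicon_length <= 0:
            raise ValueError("amplicon_length must be positive")


@dataclass(frozen=True)
class ScreeningDesign:
    """Experimental design constants for the sperm screen.

    Defaults are the published screen: 576 µg sperm DNA, 3 pg per haploid
    genome, 50% single-molecule PCR efficiency for filled (insertion-bearing,
    ~12 kb) sites, a 3x10^6 kb haploid genome and 6 pg per diploid genome.
    """

    loci: tuple[TargetLocus, ...]
    dna_mass_ug: float = 576.0
    pg_per_haploid: float = 3.0
    filled_site_efficiency: float = 0.5
    haploid_genome_kb: float = 3.0e6
    diploid_genome_pg: float = 6.0

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("at least one target locus is required")
        if not 0.0 < self.filled_site_efficiency <= 1.0:
            raise ValueError("filled_site_efficiency must be in (0, 1]")
        for name, value in (
            ("dna_mass_ug", self.dna_mass_ug),
            ("pg_per_haploid", self.pg_per_haploid),
            ("haploid_genome_kb", self.haploid_genome_kb),
            ("diploid_genome_pg", self.diploid_genome_pg),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FrequencyBound:
    """Upper bound on the insertion rate implied by ``observed`` events.

    ``events_ub`` is the one-sided Poisson upper bound on the expected event
    count at level ``alpha``; ``rate_per_kb`` divides it by the kilobases
    screened; ``genomes_per_event`` is the reciprocal rate in haploid genomes
    (how many haploid genomes carry, at most, one insertion).
    """

    events_ub: float
    alpha: float
    kb_screened: float
    rate_per_kb: float
    genomes_per_event: float

    def summary(self) -> str:
        rounded = floor_to_nearest(self.genomes_per_event, 100.0)
        return (
            f"<1 insertion per {rounded:.0f} haploid genomes "
            f"({self.events_ub:.3f} events in {self.kb_screened:.3e} kb, "
            f"P = {self.alpha:g})"
        )

    def to_json(self) -> str:
        d = asdict(self)
        d["genomes_per_event_floor100"] = floor_to_nearest(
            self.genomes_per_event, 100.0
        )
        return json.dumps(d, indent=2)


def load_target_loci(path: str | Path) -> list[TargetLocus]:
    """Read a target-locus table (TSV: name, chromosome, amplicon_length_bp,
    x_linked; ``#`` comment lines ignored)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "chromosome", "amplicon_length_bp", "x_linked"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"locus table missing columns: {sorted(missing)}")
    return [
        TargetLocus(
            name=str(r["name"]),
            chromosome=str(r["chromosome"]),
            amplicon_length=int(r["amplicon_length_bp"]),
            x_linked=bool(int(r["x_linked"])),
        )
        for _, r in df.iterrows()
    ]


def default_target_loci() -> list[TargetLocus]:
    """The packaged ten-locus panel (eight disease-insertion loci plus HoxD
    and an MHC class II interval)."""
    ref = resources.files("l1screen.data").joinpath("target_loci.tsv")
    with resources.as_file(ref) as path:
        return load_target_loci(path)


def effective_target_size(loci: list[TargetLocus] | tuple[TargetLocus, ...]) -> tuple[float, float]:
    """Total and sperm-effective panel size in bp.

    X-linked loci are present in only half of sperm, so they contribute half
    their length to the effective per-sperm target.
    """
    if not loci:
        raise ValueError("empty locus list")
    total = float(sum(l.amplicon_length for l in loci))
    effective = float(
        sum(l.amplicon_length * (0.5 if l.x_linked else 1.0) for l in loci)
    )
    return total, effective


def sperm_count(mass_ug: float, pg_per_haploid: float) -> float:
    """Number of (haploid) sperm genomes in ``mass_ug`` µg of sperm DNA."""
    if mass_ug <= 0 or pg_per_haploid <= 0:
        raise ValueError("mass and pg per haploid genome must be positive")
    return mass_ug * 1.0e6 / pg_per_haploid


def amplifiable_per_target(sperm: float, efficiency: float) -> float:
    """Amplifiable molecules of each (autosomal) target given single-molecule
    PCR efficiency; X-linked presence is handled by effective_target_size."""
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must be in (0, 1]")
    return sperm * efficiency


def kb_screened(effective_bp: float, molecules: float) -> float:
    """Kilobases of genomic DNA interrogated: effective panel kb times
    amplifiable molecules per target."""
    if effective_bp <= 0 or molecules <= 0:
        raise ValueError("effective_bp and molecules must be positive")
    return (effective_bp / 1000.0) * molecules


def poisson_upper_bound(observed: int, alpha: float) -> float:
    """Exact one-sided Poisson upper bound: the smallest mean ``lam`` with
    P(X <= observed; lam) <= alpha.

    For ``observed`` = 0 this is -ln(alpha).  Found by root-finding on the
    Poisson CDF, which is continuous and strictly decreasing in ``lam``.
    """
    if observed < 0:
        raise ValueError("observed must be >= 0")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if observed == 0:
        return -math.log(alpha)

    def f(lam: float) -> float:
        return poisson.cdf(observed, lam) - alpha

    lo, hi = 1e-12, float(observed) + 1.0
    while f(hi) > 0:
        hi *= 2.0
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def rate_bound(
    events_ub: float, kb: float, haploid_genome_kb: float, alpha: float = 0.05
) -> FrequencyBound:
    """Convert an event-count upper bound over ``kb`` screened kilobases into
    a per-kb rate and its reciprocal in haploid genomes."""
    if events_ub <= 0 or kb <= 0 or haploid_genome_kb <= 0:
        raise ValueError("all arguments must be positive")
    rate_per_kb = events_ub / kb
    genomes_per_event = 1.0 / (rate_per_kb * haploid_genome_kb)
    return FrequencyBound(
        events_ub=events_ub,
        alpha=alpha,
        kb_screened=kb,
        rate_per_kb=rate_per_kb,
        genomes_per_event=genomes_per_event,
    )


def incidence_to_mass(one_in_n_individuals: float, diploid_pg: float = 6.0) -> float:
    """Picograms of germline DNA containing one de novo insertion when one in
    ``n`` individuals carries an insertion (one event per n diploid genomes)."""
    if one_in_n_individuals < 1:
        raise ValueError("incidence denominator must be >= 1")
    return one_in_n_individuals * diploid_pg


def per_sperm_rate(
    one_in_n_individuals: float, diploid_bp: float, target_bp: float
) -> tuple[float, float]:
    """Insertion rate into a target region per sperm, and its reciprocal.

    An incidence of one insertion per ``n`` individuals anywhere in a diploid
    genome of ``diploid_bp`` corresponds to a per-bp, per-gamete rate of
    1/(n * diploid_bp); a target of ``target_bp`` then traps insertions at
    that rate times its size.
    """
    if one_in_n_individuals <= 0 or diploid_bp <= 0 or target_bp <= 0:
        raise ValueError("all arguments must be positive")
    rate = (1.0 / one_in_n_individuals) / diploid_bp * target_bp
    return rate, 1.0 / rate


def ejaculate_expectation(sperm_per_insertion: float, ejaculate_sperm: float) -> float:
    """Expected number of trapped insertions among ``ejaculate_sperm`` sperm."""
    if sperm_per_insertion <= 0 or ejaculate_sperm <= 0:
        raise ValueError("all arguments must be positive")
    return ejaculate_sperm / sperm_per_insertion


def to_sig_figs(x: float, n: int) -> float:
    """Round ``x`` to ``n`` significant figures (0 stays 0)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if x == 0:
        return 0.0
    digits = n - 1 - int(math.floor(math.log10(abs(x))))
    return round(x, digits)


def floor_to_nearest(x: float, step: float) -> float:
    """Floor ``x`` to a multiple of ``step``."""
    if step <= 0:
        raise ValueError("step must be positive")
    return math.floor(x / step) * step


def nearest_power_of_ten(x: float) -> float:
    """The power of ten nearest to ``x`` on a log scale."""
    if x <= 0:
        raise ValueError("x must be positive")
    return 10.0 ** round(math.log10(x))


def screen_depth_report(
    design: ScreeningDesign, observed: int = 0, alpha: float = 0.05
) -> dict:
    """Full design chain: panel size, sperm and molecule counts, kb screened,
    Poisson bound and reciprocal rate.  Raw values plus the conventional
    rounded headline figures."""
    total_bp, effective_bp = effective_target_size(list(design.loci))
    sperm = sperm_count(design.dna_mass_ug, design.pg_per_haploid)
    molecules = amplifiable_per_target(sperm, design.filled_site_efficiency)
    kb = kb_screened(effective_bp, molecules)
    lam_ub = poisson_upper_bound(observed, alpha)
    bound = rate_bound(lam_ub, kb, design.haploid_genome_kb, alpha)
    return {
        "total_target_bp": total_bp,
        "effective_target_bp": effective_bp,
        "total_target_kb_rounded": round(total_bp / 1000.0),
        "effective_target_kb_rounded": round(effective_bp / 1000.0),
        "sperm": sperm,
        "amplifiable_molecules_per_target": molecules,
        "kb_screened": kb,
        "events_upper_bound": lam_ub,
        "rate_per_kb": bound.rate_per_kb,
        "genomes_per_event": bound.genomes_per_event,
        "genomes_per_event_floor100": floor_to_nearest(
            bound.genomes_per_event, 100.0
        ),
        "alpha": alpha,
        "observed": observed,
        "summary": bound.summary(),
    }
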