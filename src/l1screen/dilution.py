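"""Limiting-dilution Poisson quantification of amplifiable molecules.

Serial dilutions of genomic DNA are PCR-amplified in replicate wells; a well
is positive when it received at least one amplifiable molecule.  If lambda is
the concentration in molecules per pg and a well receives m pg, the number of
molecules per well is Poisson(lambda * m) and

    P(positive) = 1 - exp(-lambda * m).

The concentration is estimated by maximum likelihood over all dilutions, and
its 95% confidence interval by profile likelihood at the chi-squared(1 df)
cutoff.  On a single dilution the MLE reduces to the zero-class closed form
-ln(negatives/total)/m.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2

__all__ = [
    "DilutionSeries",
    "MoleculeEstimate",
    "BoundaryError",
    "lambda_from_single_dilution",
    "estimate_molecules",
    "pcr_efficiency",
]

# chi-squared(1 df) 95% quantile: profile cutoff for a 95% CI
_CHI2_95 = 3.8414588206941245


class BoundaryError(ValueError):
    """Raised when well counts pin the estimate to a boundary (no finite or
    nonzero MLE)."""


@dataclass(frozen=True)
class DilutionSeries:
    """Replicate well outcomes at known per-well DNA inputs.

    Row i: ``input_pg[i]`` pg of genomic DNA per well, ``wells_positive[i]``
    of ``wells_total[i]`` wells gave product.
    """

    input_pg: np.ndarray
    wells_positive: np.ndarray
    wells_total: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.input_pg, dtype=float)
        k = np.asarray(self.wells_positive, dtype=int)
        n = np.asarray(self.wells_total, dtype=int)
        if not (m.shape == k.shape == n.shape) or m.ndim != 1 or m.size == 0:
            raise ValueError("series columns must be equal-length, non-empty 1-D")
        if np.any(m <= 0):
            raise ValueError("input_pg must be positive")
        if np.any(k < 0) or np.any(k > n) or np.any(n < 1):
            raise ValueError("require 0 <= wells_positive <= wells_total, total >= 1")
        object.__setattr__(self, "input_pg", m)
        object.__setattr__(self, "wells_positive", k)
        object.__setattr__(self, "wells_total", n)

    @classmethod
    def from_rows(cls, rows: list[tuple[float, int, int]]) -> "DilutionSeries":
        m, k, n = zip(*rows)
        return cls(np.array(m, float), np.array(k, int), np.array(n, int))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DilutionSeries":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"input_pg", "wells_positive", "wells_total"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dilution table missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("dilution table has no data rows")
        return cls(
            df["input_pg"].to_numpy(float),
            df["wells_positive"].to_numpy(int),
            df["wells_total"].to_numpy(int),
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "input_pg": self.input_pg,
                "wells_positive": self.wells_positive,
                "wells_total": self.wells_total,
            }
        ).to_csv(path, sep="\t", index=False)

    def log_likelihood(self, lam: float) -> float:
        """Binomial log-likelihood of the well counts at concentration
        ``lam`` (molecules/pg), up to the constant binomial coefficients."""
        if lam < 0:
            return -math.inf
        m, k, n = self.input_pg, self.wells_positive, self.wells_total
        with np.errstate(divide="ignore"):
            p = -np.expm1(-lam * m)  # P(positive), accurate for small lam*m
            pos = np.where(k > 0, k * np.log(np.where(p > 0, p, 1.0)), 0.0)
            if np.any((k > 0) & (p == 0)):
                return -math.inf
        neg = -(n - k) * lam * m
        return float(np.sum(pos + neg))


@dataclass(frozen=True)
class MoleculeEstimate:
    """MLE of amplifiable-molecule concentration with profile 95% CI.

    ``lambda_hat`` is molecules per pg; ``pg_per_molecule`` its reciprocal;
    ``boundary_flag`` marks the degenerate all-negative / all-positive cases.
    """

    lambda_hat: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    boundary_flag: str = "none"  # none | all_negative | all_positive

    @property
    def pg_per_molecule(self) -> float:
        return math.inf if self.lambda_hat == 0 else 1.0 / self.lambda_hat

    def summary(self) -> str:
        if self.boundary_flag == "all_positive":
            return "all wells positive: concentration unbounded above"
        if self.lambda_hat == 0:
            return (
                "no positive wells: 0 molecules/pg "
                f"(95% upper bound {self.ci_high:.4g} molecules/pg)"
            )
        lo = math.inf if self.ci_high == 0 else 1.0 / self.ci_high
        hi = math.inf if self.ci_low == 0 else 1.0 / self.ci_low
        return (
            f"1 molecule per {self.pg_per_molecule:.3g} pg "
            f"(95% CI {lo:.3g}–{hi:.3g} pg)"
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "lambda_hat_per_pg": self.lambda_hat,
                "ci_low_per_pg": self.ci_low,
                "ci_high_per_pg": self.ci_high,
                "pg_per_molecule": self.pg_per_molecule,
                "alpha": self.alpha,
                "boundary_flag": self.boundary_flag,
                "summary": self.summary(),
            },
            indent=2,
        )


def lambda_from_single_dilution(
    wells_negative: int, wells_total: int, input_pg: float
) -> float:
    """Zero-class closed form: -ln(negatives/total) / input_pg."""
    if wells_total < 1 or wells_negative > wells_total:
        raise ValueError("require 0 <= wells_negative <= wells_total")
    if input_pg <= 0:
        raise ValueError("input_pg must be positive")
    if wells_negative == 0:
        raise BoundaryError("no negative wells: estimate unbounded")
    return -math.log(wells_negative / wells_total) / input_pg


def estimate_molecules(series: DilutionSeries, alpha: float = 0.05) -> MoleculeEstimate:
    """Multi-dilution MLE with profile-likelihood CI.

    Maximizes the product-binomial likelihood over lambda (bounded search on
    log lambda); the CI is the set of lambda whose likelihood-ratio statistic
    stays below the chi-squared(1) quantile at ``alpha``.  All-negative data
    give a zero estimate with a one-sided upper limit; all-positive data have
    no finite MLE and are flagged.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    cutoff = _CHI2_95 if alpha == 0.05 else float(chi2.ppf(1 - alpha, 1))
    k, n, m = series.wells_positive, series.wells_total, series.input_pg

    if np.all(k == n):
        # likelihood increases without bound in lambda; lower limit only
        ll_sup = 0.0  # limit of the log-likelihood as lambda -> infinity

        def g(lam: float) -> float:
            return 2.0 * (ll_sup - series.log_likelihood(lam)) - cutoff

        lo = brentq(g, 1e-12, 1e9, xtol=1e-12)
        return MoleculeEstimate(
            lambda_hat=math.inf, ci_low=float(lo), ci_high=math.inf,
            alpha=alpha, boundary_flag="all_positive",
        )

    if np.all(k == 0):
        # ll(lam) = -lam * sum(n m); exact one-sided upper limit
        ll_hat = 0.0

        def g(lam: float) -> float:
            return 2.0 * (ll_hat - series.log_likelihood(lam)) - cutoff

        hi = brentq(g, 1e-12, 1e9, xtol=1e-12)
        return MoleculeEstimate(
            lambda_hat=0.0, ci_low=0.0, ci_high=float(hi),
            alpha=alpha, boundary_flag="all_negative",
        )

    # The score (d log-likelihood / d lambda) is strictly decreasing with a
    # unique root when the data are off the boundaries, so the MLE is found
    # by root-finding to machine precision.
    def score(lam: float) -> float:
        em = np.exp(-lam * m)
        return float(np.sum(k * m * em / (1.0 - em)) - np.sum((n - k) * m))

    lo, hi = 1e-9, 1.0
    while score(hi) > 0 and hi < 1e9:
        hi *= 4.0
    lam_hat = float(brentq(score, lo, hi, xtol=1e-15, rtol=1e-15))
    ll_hat = series.log_likelihood(lam_hat)

    def g(lam: float) -> float:
        return 2.0 * (ll_hat - series.log_likelihood(lam)) - cutoff

    # lower bound: g(0+) > 0 because some wells are positive
    ci_low = brentq(g, 1e-15, lam_hat, xtol=1e-14) if g(1e-15) > 0 else 0.0
    hi = lam_hat if lam_hat > 0 else 1.0
    while g(hi) <= 0:
        hi *= 2.0
        if hi > 1e12:
            break
    ci_high = float(brentq(g, lam_hat, hi, xtol=1e-12)) if g(hi) > 0 else math.inf
    return MoleculeEstimate(
        lambda_hat=float(lam_hat), ci_low=float(ci_low), ci_high=ci_high,
        alpha=alpha, boundary_flag="none",
    )


def pcr_efficiency(
    estimate: MoleculeEstimate,
    genome_pg: float,
    amplifiable_copies_per_genome: int = 1,
) -> float:
    """Observed molecules per pg relative to the physical copy density.

    A locus present in ``amplifiable_copies_per_genome`` copies per genome of
    ``genome_pg`` pg has copies/genome_pg molecules per pg; the ratio of the
    estimated concentration to that density is the single-molecule PCR
    efficiency.  Values above 1 (an inconsistent copy-number assumption or
    sampling noise) are returned as computed but flagged with a warning.
    """
    if genome_pg <= 0:
        raise ValueError("genome_pg must be positive")
    if amplifiable_copies_per_genome < 1:
        raise ValueError("copies per genome must be >= 1")
    expected = amplifiable_copies_per_genome / genome_pg
    eff = estimate.lambda_hat / expected
    if eff > 1.0:
        warnings.warn(
            f"efficiency {eff:.3f} exceeds 1: more molecules observed than the "
            "assumed copy number provides",
            stacklevel=2,
        )
    return eff
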