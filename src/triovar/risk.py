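"""Risk attribution: odds-ratio to relative-risk conversion, population
attributable risk (PAR) with heterozygote and homozygote terms, a
multiplicative locus-wide PAR with Monte-Carlo confidence interval, and
liability-scale heritability explained.

The exposure proportion Pe is the risk-allele frequency, entering the
PAR formula through the Hardy-Weinberg genotype terms 2Pe(1-Pe) and
Pe^2. Homozygote relative risk follows the multiplicative model
RR_BB = RR_Bb^2, and per-variant PARs combine multiplicatively across a
locus (1 - prod(1 - PAR_i)), which is conservative relative to the sum.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

__all__ = [
    "RiskVariantEstimate",
    "LocusAttribution",
    "or_to_rr",
    "genotype_relative_risks",
    "variant_par",
    "locus_par",
    "locus_par_ci",
    "liability_heritability",
    "locus_heritability",
    "attribute_risk",
]


def or_to_rr(or_value: float, p0: float) -> float:
    """Convert an odds ratio to a relative risk at disease prevalence p0.

    RR = OR / (1 - P0 + P0 x OR). For a rare disease RR ~ OR; RR <= OR
    whenever OR >= 1.
    """
    if or_value <= 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    if not 0 <= p0 < 1:
        raise ValueError(f"prevalence must be in [0, 1), got {p0}")
    return or_value / (1.0 - p0 + p0 * or_value)


def genotype_relative_risks(rr_het: float) -> tuple[float, float]:
    """(RR_Bb, RR_BB) under the multiplicative model: RR_BB = RR_Bb^2."""
    if rr_het <= 0:
        raise ValueError(f"rr_het must be positive, got {rr_het}")
    return rr_het, rr_het ** 2


def variant_par(pe: float, rr_het: float, rr_hom: float) -> float:
    """Population attributable risk of one variant.

    PAR = [2Pe(1-Pe)(RR_Bb - 1) + Pe^2 (RR_BB - 1)]
        / [1 + 2Pe(1-Pe)(RR_Bb - 1) + Pe^2 (RR_BB - 1)].
    """
    if not 0 <= pe <= 1:
        raise ValueError(f"pe must be in [0, 1], got {pe}")
    if min(rr_het, rr_hom) <= 0:
        raise ValueError("relative risks must be positive")
    excess = 2 * pe * (1 - pe) * (rr_het - 1) + pe ** 2 * (rr_hom - 1)
    return excess / (1.0 + excess)


def locus_par(pars) -> float:
    """Locus-wide PAR combined multiplicatively: 1 - prod(1 - PAR_i)."""
    pars = list(pars)
    if any(not 0 <= p < 1 for p in pars):
        raise ValueError("each PAR must be in [0, 1)")
    prod = 1.0
    for p in pars:
        prod *= 1.0 - p
    return 1.0 - prod


@dataclasses.dataclass(frozen=True)
class RiskVariantEstimate:
    variant_id: str
    pe: float                 # risk-allele frequency (exposure proportion)
    or_per_allele: float
    p0: float                 # disease prevalence
    se_log_or: float | None = None
    source: str = "cohort"    # cohort | meta | reference

    @property
    def rr_het(self) -> float:
        return or_to_rr(self.or_per_allele, self.p0)

    @property
    def rr_hom(self) -> float:
        return self.rr_het ** 2

    @property
    def par(self) -> float:
        return variant_par(self.pe, self.rr_het, self.rr_hom)

    @property
    def h2(self) -> float:
        return liability_heritability(self.pe, self.rr_het, self.rr_hom, self.p0)


@dataclasses.dataclass(frozen=True)
class LocusAttribution:
    estimates: tuple
    locus_par: float
    locus_par_ci: tuple[float, float] | None
    locus_h2: float


def locus_par_ci(estimates: list[RiskVariantEstimate], n_sim: int = 10_000,
                 seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo 95% CI for the locus-wide PAR.

    Each per-allele log OR is drawn Normal(log OR, SE^2); the locus PAR
    is recomputed per draw and the 2.5/97.5 percentiles reported.
    Deterministic given the seed.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000 for stable percentiles")
    for e in estimates:
        if e.se_log_or is None:
            raise ValueError(f"estimate {e.variant_id!r} has no SE(log OR)")
    rng = np.random.default_rng(seed)
    log_or = np.array([math.log(e.or_per_allele) for e in estimates])
    se = np.array([e.se_log_or for e in estimates])
    pe = np.array([e.pe for e in estimates])
    p0 = np.array([e.p0 for e in estimates])
    draws = rng.normal(log_or, se, size=(n_sim, len(estimates)))
    ors = np.exp(draws)
    rr = ors / (1.0 - p0 + p0 * ors)
    excess = 2 * pe * (1 - pe) * (rr - 1) + pe ** 2 * (rr ** 2 - 1)
    pars = np.clip(excess / (1.0 + excess), 0.0, 1.0 - 1e-12)
    locus = 1.0 - np.prod(1.0 - pars, axis=1)
    lo, hi = np.percentile(locus, [2.5, 97.5])
    return float(lo), float(hi)


def liability_heritability(pe: float, rr_het: float, rr_hom: float,
                           p0: float) -> float:
    """Liability-scale variance explained by one variant.

    Under the liability threshold model disease occurs when a
    standard-normal liability exceeds T = Phi^{-1}(1 - p0). Genotype
    frequencies follow HWE from pe; genotype penetrances are the
    relative risks normalised so the population risk equals p0. Each
    genotype's mean liability is T - Phi^{-1}(1 - K_g), and the variance
    of these means (total liability variance 1) is the heritability
    explained. This follows the liability-scale single-locus framework
    behind web calculators of variance explained; exact parity with any
    particular implementation is not claimed.
    """
    if not 0 <= pe <= 1:
        raise ValueError(f"pe must be in [0, 1], got {pe}")
    if not 0 < p0 < 1:
        raise ValueError(f"prevalence must be in (0, 1), got {p0}")
    if min(rr_het, rr_hom) <= 0:
        raise ValueError("relative risks must be positive")
    freqs = np.array([(1 - pe) ** 2, 2 * pe * (1 - pe), pe ** 2])
    rel = np.array([1.0, rr_het, rr_hom])
    baseline = p0 / float(freqs @ rel)
    penetrance = baseline * rel
    if np.any(penetrance >= 1):
        raise ValueError("a genotype risk reaches 1; threshold model undefined")
    T = stats.norm.isf(p0)
    mean_liab = T - stats.norm.isf(penetrance)
    mbar = float(freqs @ mean_liab)
    return float(freqs @ (mean_liab - mbar) ** 2)


def locus_heritability(h2_list) -> float:
    """Additive combination of per-variant heritabilities."""
    return float(sum(h2_list))


def attribute_risk(estimates: list[RiskVariantEstimate], n_sim: int = 10_000,
                   seed: int = 0, ci: bool = True) -> LocusAttribution:
    """Per-variant and locus-wide PAR and heritability for a set of estimates."""
    pars = [e.par for e in estimates]
    h2 = locus_heritability(e.h2 for e in estimates)
    interval = None
    if ci and estimates and all(e.se_log_or is not None for e in estimates):
        interval = locus_par_ci(estimates, n_sim=n_sim, seed=seed)
    return LocusAttribution(estimates=tuple(estimates), locus_par=locus_par(pars),
                            locus_par_ci=interval, locus_h2=h2)
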