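"""Association statistics: 2x2 odds ratios, Fisher exact tests,
reference-augmented single-marker tests, a carrier-collapsing burden
test, maximum-likelihood and Firth-penalized logistic regression, the
Tjur coefficient of discrimination, and Bonferroni correction.

The Firth fit maximises the Jeffreys-penalized binomial likelihood by
Newton-Raphson with the hat-value score correction, which keeps
estimates finite under complete or quasi-complete separation - the
situation rare risk variants routinely create in case-control data.
"""

from __future__ import annotations

import dataclasses
import enum
import math

import numpy as np
from scipy import stats

from .cohort import (MISSING, ConfigurationError, GenotypeMatrix,
                     PedigreeTable, ReferenceCountTable, VariantRecord)

__all__ = [
    "TwoByTwo",
    "Continuity",
    "AssociationResult",
    "RegressionFit",
    "odds_ratio_2x2",
    "fisher_exact",
    "single_marker_test",
    "min_allele_copies",
    "min_allele_copy_filter",
    "carrier_burden_test",
    "bonferroni",
    "logistic_fit",
    "tjur_r2",
]

Z95 = float(stats.norm.ppf(0.975))


@dataclasses.dataclass(frozen=True)
class TwoByTwo:
    """Counts: a = exposed cases, b = unexposed cases,
    c = exposed controls, d = unexposed controls."""

    a: float
    b: float
    c: float
    d: float
    allele_based: bool = False

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


class Continuity(str, enum.Enum):
    NONE = "none"
    HALDANE = "haldane"          # add 0.5 to every cell when any cell is 0
    HALDANE_ALWAYS = "haldane_always"


@dataclasses.dataclass(frozen=True)
class AssociationResult:
    estimate: float
    ci_low: float
    ci_high: float
    p: float | None
    method: str
    sided: str = "two_sided"
    flags: tuple = ()


def _apply_continuity(t: TwoByTwo, continuity: Continuity) -> tuple[TwoByTwo, tuple]:
    cells = t.cells()
    if continuity is Continuity.HALDANE_ALWAYS or (
            continuity is Continuity.HALDANE and 0 in cells):
        return (TwoByTwo(*(x + 0.5 for x in cells), allele_based=t.allele_based),
                ("haldane_corrected",))
    return t, ()


def odds_ratio_2x2(t: TwoByTwo,
                   continuity: Continuity = Continuity.NONE) -> AssociationResult:
    """Cross-product odds ratio with Woolf log-scale 95% CI.

    A zero cell without continuity correction yields an infinite or zero
    estimate flagged ``degenerate`` rather than an exception.
    """
    continuity = Continuity(continuity)
    t, flags = _apply_continuity(t, continuity)
    a, b, c, d = t.cells()
    if 0 in (a, b, c, d):
        est = math.inf if (b == 0 or c == 0) and a > 0 and d > 0 else (
            0.0 if (a == 0 or d == 0) else math.nan)
        return AssociationResult(est, math.nan, math.nan, None, "odds_ratio",
                                 flags=flags + ("degenerate",))
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return AssociationResult(est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se),
                             None, "odds_ratio", flags=flags)


def fisher_exact(t: TwoByTwo, sided: str = "two_sided") -> float:
    """Hypergeometric exact p-value for a 2x2 table.

    ``greater`` tests enrichment of exposure in cases; ``two_sided``
    sums the probabilities of all tables no more probable than the
    observed one.
    """
    alternative = {"greater": "greater", "two_sided": "two-sided"}[sided]
    cells = [[int(t.a), int(t.b)], [int(t.c), int(t.d)]]
    if cells != [[t.a, t.b], [t.c, t.d]]:
        raise ValueError("fisher_exact requires integer counts")
    return float(stats.fisher_exact(cells, alternative=alternative)[1])


def single_marker_test(variant: VariantRecord, gm: GenotypeMatrix,
                       ped: PedigreeTable, ref: ReferenceCountTable,
                       population: str = "NFE",
                       internal_maf_cap: float = 0.01) -> AssociationResult:
    """Allele-count single-marker test with reference-augmented controls.

    For a rare variant (internal-control MAF below ``internal_maf_cap``),
    case alt-allele copies are compared against internal control alleles
    pooled with the reference population's allele counts: one-sided
    Fisher exact p (case enrichment) and a Haldane-corrected odds ratio.
    """
    j = gm.variant_index(variant.key)
    cases = [s for s in ped.cases if gm.has_individual(s)]
    controls = [s for s in ped.controls if gm.has_individual(s)]
    case_calls = gm.rows(cases)[:, j]
    ctrl_calls = gm.rows(controls)[:, j]
    case_called = case_calls[case_calls != MISSING]
    ctrl_called = ctrl_calls[ctrl_calls != MISSING]
    if len(ctrl_called) == 0:
        raise ConfigurationError("no called control genotypes for single-marker test")
    internal_f = float(ctrl_called.sum() / (2 * len(ctrl_called)))
    if min(internal_f, 1 - internal_f) >= internal_maf_cap:
        raise ConfigurationError(
            f"single-marker test is restricted to variants with internal-control "
            f"MAF < {internal_maf_cap:.0%}; observed {internal_f:.3%}")
    ref_ac, ref_an = ref.counts(variant.key, population)
    a = int(case_called.sum())
    b = 2 * len(case_called) - a
    c = int(ctrl_called.sum()) + ref_ac
    d = (2 * len(ctrl_called) + ref_an) - c
    t = TwoByTwo(a, b, c, d, allele_based=True)
    flags: tuple = ("reference_augmented",)
    if a + c == 0:
        flags += ("degenerate",)
    p = fisher_exact(t, sided="greater")
    orr = odds_ratio_2x2(t, continuity=Continuity.HALDANE)
    return AssociationResult(orr.estimate, orr.ci_low, orr.ci_high, p,
                             "fisher", sided="greater", flags=flags + orr.flags)


def min_allele_copies(n_cases: int, n_controls: int, alpha: float = 0.05) -> int:
    """Smallest alt-copy count that can reach one-sided Fisher p < alpha.

    The most extreme configuration places all m copies in cases (allele
    denominators 2 x n_cases vs 2 x n_controls); m* is the least m whose
    p-value beats alpha.
    """
    if not 0 < alpha < 1:
        if alpha == 1.0:
            return 1
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    m = 1
    while True:
        p = fisher_exact(TwoByTwo(m, 2 * n_cases - m, 0, 2 * n_controls,
                                  allele_based=True), sided="greater")
        if p < alpha:
            return m
        m += 1
        if m > 2 * n_cases:
            raise ValueError("no copy count can reach the requested alpha")


def min_allele_copy_filter(gene_allele_counts: dict[str, int], n_cases: int,
                           n_controls: int, alpha: float = 0.05) -> set[str]:
    """Genes with enough alt-allele copies to potentially reach p < alpha."""
    m_star = min_allele_copies(n_cases, n_controls, alpha)
    return {g for g, copies in gene_allele_counts.items() if copies >= m_star}


def carrier_burden_test(gene: str, gm: GenotypeMatrix, ped: PedigreeTable,
                        maf_cap: float = 0.05) -> AssociationResult:
    """Carrier-collapsing burden stand-in for a gene.

    Variants of the gene with combined case+control MAF <= ``maf_cap``
    are collapsed to a per-individual carrier indicator, tested by
    one-sided Fisher exact (case enrichment). This is a simple burden
    test; it does not weight variants by functional priors the way
    composite-likelihood tools (VAAST) do, and all outputs carry a
    ``burden_stand_in`` flag to keep the two uncomfusable.
    """
    cases = [s for s in ped.cases if gm.has_individual(s)]
    controls = [s for s in ped.controls if gm.has_individual(s)]
    subjects = cases + controls
    sub = gm.rows(subjects)
    qual = []
    for j, v in enumerate(gm.variants):
        if v.gene != gene:
            continue
        col = sub[:, j]
        called = col[col != MISSING]
        if len(called) == 0 or called.sum() == 0:
            continue  # monomorphic among subjects: not a variant in this cohort
        f = called.sum() / (2 * len(called))
        if min(f, 1 - f) <= maf_cap:
            qual.append(j)
    if not qual:
        return AssociationResult(math.nan, math.nan, math.nan, None,
                                 "fisher", sided="greater",
                                 flags=("burden_stand_in", "untestable"))
    carrier = (sub[:, qual] >= 1).any(axis=1)
    n_cases = len(cases)
    a = int(carrier[:n_cases].sum())
    c = int(carrier[n_cases:].sum())
    t = TwoByTwo(a, n_cases - a, c, len(controls) - c)
    p = fisher_exact(t, sided="greater")
    orr = odds_ratio_2x2(t, continuity=Continuity.HALDANE)
    return AssociationResult(orr.estimate, orr.ci_low, orr.ci_high, p,
                             "fisher", sided="greater",
                             flags=("burden_stand_in",) + orr.flags)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p x m)."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return min(1.0, p * m)


@dataclasses.dataclass
class RegressionFit:
    coefficients: np.ndarray      # log-odds scale, one per column of X
    standard_errors: np.ndarray
    fitted: np.ndarray            # per-individual probabilities, in (0,1)
    converged: bool
    penalized: bool
    names: list[str]

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def wald_ci(self, z: float = Z95) -> np.ndarray:
        lo = np.exp(self.coefficients - z * self.standard_errors)
        hi = np.exp(self.coefficients + z * self.standard_errors)
        return np.stack([lo, hi], axis=1)


def logistic_fit(y, X, method: str = "ml", names: list[str] | None = None,
                 tol: float = 1e-8, max_iter: int = 50) -> RegressionFit:
    """Logistic regression by Newton-Raphson: plain ML or Firth-penalized.

    ``firth`` maximises the Jeffreys-penalized log-likelihood
    l(b) + 0.5 log det I(b); its modified score adds h_i (0.5 - p_i) to
    each residual, with h_i the hat values of the weighted design. Wald
    standard errors come from the inverse (penalized) information.
    Convergence requires max |score| < tol within ``max_iter``
    iterations; a non-converged fit is returned flagged, never silently.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (n, p) aligned with y")
    if not np.any(np.all(X == 1.0, axis=0)):
        raise ValueError("X must include an intercept column of ones")
    if method not in ("ml", "firth"):
        raise ValueError(f"unknown method {method!r}")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("X has collinear columns")
    beta = np.zeros(p)

    def inv(matrix):
        try:
            return np.linalg.inv(matrix)
        except np.linalg.LinAlgError:  # transiently singular far from optimum
            return np.linalg.pinv(matrix)

    def state(b):
        """(mu, w, info, penalized-or-plain log-likelihood) at coefficients b."""
        eta = np.clip(X @ b, -700, 700)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-300, None)
        info = (X * w[:, None]).T @ X
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        if method == "firth":
            ll += 0.5 * float(np.linalg.slogdet(info)[1])
        return mu, w, info, ll

    def score_at(mu_, w_, info_):
        resid = y - mu_
        if method == "firth":
            # hat values of W^(1/2) X (X' W X)^(-1) X' W^(1/2)
            xw = X * np.sqrt(w_)[:, None]
            h = np.einsum("ij,ij->i", xw @ inv(info_), xw)
            resid = resid + h * (0.5 - mu_)
        return X.T @ resid

    mu, w, info, ll = state(beta)
    score = score_at(mu, w, info)
    converged = False
    for _ in range(max_iter):
        snorm = np.max(np.abs(score))
        if snorm < tol:
            converged = True
            break
        step = inv(info) @ score
        # step-halving: require the objective to improve, or - once it has
        # plateaued at float precision - the score to shrink
        for _half in range(30):
            cand = beta + step
            mu_c, w_c, info_c, ll_c = state(cand)
            if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                score_c = score_at(mu_c, w_c, info_c)
                if ll_c > ll + 1e-13 or np.max(np.abs(score_c)) < snorm:
                    beta, mu, w, info, ll = cand, mu_c, w_c, info_c, ll_c
                    score = score_c
                    break
            step *= 0.5
        else:  # no acceptable step; give up and report non-convergence
            break
    se = np.sqrt(np.diag(inv(info)))
    return RegressionFit(coefficients=beta, standard_errors=se, fitted=mu,
                         converged=converged, penalized=(method == "firth"),
                         names=names or [f"x{j}" for j in range(p)])


def tjur_r2(fitted, y) -> float:
    """Tjur's coefficient of discrimination.

    Mean fitted probability among cases minus mean fitted probability
    among controls; 0 for a non-discriminating model, 1 for perfect
    separation of fitted values.
    """
    fitted = np.asarray(fitted, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("tjur_r2 needs both outcome classes present")
    return float(fitted[y == 1].mean() - fitted[y == 0].mean())
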