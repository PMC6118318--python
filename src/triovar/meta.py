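"""DerSimonian-Laird random-effects meta-analysis of 2x2 study tables."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .assoc import TwoByTwo, Z95

__all__ = ["MetaStudy", "MetaResult", "study_effect", "dersimonian_laird",
           "read_study_table", "forest_table"]


@dataclasses.dataclass(frozen=True)
class MetaStudy:
    label: str
    y: float            # log odds ratio
    v: float            # variance of y
    table: TwoByTwo | None = None
    haldane_corrected: bool = False

    def __post_init__(self):
        if self.v <= 0:
            raise ValueError(f"study {self.label!r}: variance must be positive")


@dataclasses.dataclass(frozen=True)
class MetaResult:
    pooled_or: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    k: int


def study_effect(t: TwoByTwo) -> tuple[float, float]:
    """Woolf log-odds-ratio effect and variance, Haldane-corrected on zero cells.

    y = log(ad/bc), v = 1/a + 1/b + 1/c + 1/d on the (possibly
    corrected) counts.
    """
    a, b, c, d = t.cells()
    if 0 in (a, b, c, d):
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    y = math.log((a * d) / (b * c))
    v = 1 / a + 1 / b + 1 / c + 1 / d
    return y, v


def make_study(label: str, t: TwoByTwo) -> MetaStudy:
    y, v = study_effect(t)
    return MetaStudy(label=label, y=y, v=v, table=t,
                     haldane_corrected=0 in t.cells())


def dersimonian_laird(studies: list[MetaStudy]) -> MetaResult:
    """Moment-based random-effects pooling of log odds ratios.

    Fixed-effect weights w = 1/v give the heterogeneity statistic
    Q = sum w (y - ybar_FE)^2; the between-study variance is
    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); random-effects
    weights 1/(v + tau2) produce the pooled log OR and its Wald 95% CI.
    A single study is returned unchanged with tau2 = 0.
    """
    k = len(studies)
    if k == 0:
        raise ValueError("meta-analysis needs at least one study")
    y = np.array([s.y for s in studies])
    v = np.array([s.v for s in studies])
    w = 1.0 / v
    ybar = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - ybar) ** 2))
    if k == 1:
        tau2 = 0.0
    else:
        denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
        tau2 = max(0.0, (Q - (k - 1)) / denom)
    wstar = 1.0 / (v + tau2)
    mu = float(np.sum(wstar * y) / np.sum(wstar))
    se = 1.0 / math.sqrt(float(np.sum(wstar)))
    return MetaResult(pooled_or=math.exp(mu),
                      ci_low=math.exp(mu - Z95 * se),
                      ci_high=math.exp(mu + Z95 * se),
                      tau2=tau2, Q=Q, k=k)


def read_study_table(path) -> list[MetaStudy]:
    """Read studies from a TSV: label, a, b, c, d (or precomputed y, v)."""
    df = pd.read_csv(path, sep="\t")
    studies = []
    for _, row in df.iterrows():
        label = str(row["label"])
        if {"y", "v"}.issubset(df.columns) and not (
                pd.isna(row.get("y")) or pd.isna(row.get("v"))):
            studies.append(MetaStudy(label=label, y=float(row["y"]), v=float(row["v"])))
        else:
            t = TwoByTwo(float(row["a"]), float(row["b"]),
                         float(row["c"]), float(row["d"]))
            studies.append(make_study(label, t))
    return studies


def forest_table(studies: list[MetaStudy], result: MetaResult) -> pd.DataFrame:
    """Per-study forest-plot rows: label, OR, 95% CI, random-effects weight %."""
    wstar = np.array([1.0 / (s.v + result.tau2) for s in studies])
    weight_pct = 100.0 * wstar / wstar.sum()
    rows = [{
        "label": s.label,
        "or": math.exp(s.y),
        "ci_low": math.exp(s.y - Z95 * math.sqrt(s.v)),
        "ci_high": math.exp(s.y + Z95 * math.sqrt(s.v)),
        "weight_pct": float(wp),
        "haldane_corrected": s.haldane_corrected,
    } for s, wp in zip(studies, weight_pct)]
    return pd.DataFrame(rows)
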