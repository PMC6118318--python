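"""Synthetic trio-cohort generator.

Emulates a case-parent trio sequencing study of a single risk locus:
parents are drawn at Hardy-Weinberg/linkage equilibrium, children by
Mendelian transmission, and disease status under a multiplicative
genotype-relative-risk model whose baseline is calibrated so the
population prevalence matches the configured value. Affected children
(with or without genotyped parents) are ascertained by rejection
sampling; controls are sampled conditional on being unaffected. De novo
events are injected per trio child at the configured per-haploid-base
mutation rates, and genotypes are masked completely at random at the
configured missingness rate.

Default panel and cohort sizes mirror a pediatric Crohn's disease
NOD2 study design: 205 affected children (179 with both parents
sequenced), 200 unaffected adult controls, three common risk alleles
(MAF 1.4-3.5%, per-allele relative risk 2.2-3.8), eight rare risk
alleles (MAF < 0.5%, relative risk 3-15), neutral variants, prevalence
34.7 per 100,000.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (MISSING, FunctionalClass, GenotypeMatrix, PedigreeTable,
                     Status, VariantRecord, write_ped, write_vcf)

__all__ = [
    "PanelVariant",
    "SimulationConfig",
    "TruthTable",
    "SimulatedCohort",
    "default_panel",
    "simulate_cohort",
    "simulate_meta_studies",
    "sample_case_control_genotypes",
]


@dataclasses.dataclass(frozen=True)
class PanelVariant:
    """Generating parameters for one locus variant."""

    allele_frequency: float
    rr: float  # per-allele genotype relative risk (multiplicative)
    functional_class: FunctionalClass = FunctionalClass.MISSENSE
    gene: str = "GENE1"
    variant_id: str = ""

    def __post_init__(self):
        if not 0 <= self.allele_frequency <= 1:
            raise ValueError(f"allele_frequency {self.allele_frequency} outside [0,1]")
        if self.rr <= 0:
            raise ValueError(f"per-allele RR must be positive, got {self.rr}")


def _clipping_excess(variants: list["PanelVariant"], baseline: float) -> float:
    """Expected prevalence lost to clipping genotype risks at 1.

    Enumerates the exact HWE distribution of the multiplicative risk
    product over variants with RR != 1 (3^k genotype combinations) and
    returns sum p * max(0, baseline * product - 1). Falls back to a
    conservative max-risk check when the risk-variant count makes
    enumeration unreasonable.
    """
    risky = [(v.allele_frequency, v.rr) for v in variants if v.rr != 1.0]
    if len(risky) > 13:
        max_risk = baseline * float(np.prod([max(r, 1.0) ** 2 for _, r in risky]))
        return max(0.0, max_risk - 1.0)
    values = np.array([1.0])
    probs = np.array([1.0])
    for f, rr in risky:
        g_p = np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
        g_v = np.array([1.0, rr, rr ** 2])
        values = np.multiply.outer(values, g_v).ravel()
        probs = np.multiply.outer(probs, g_p).ravel()
    risk = baseline * values
    return float(probs @ np.maximum(0.0, risk - 1.0))


def default_panel() -> list[PanelVariant]:
    """NOD2-like panel: 3 common risk, 8 rare risk, 3 neutral variants.

    Common-variant frequencies are reference (ExAC NFE) frequencies of
    R702W/G908R/L1007fs; their relative risks are the meta-analytic
    per-allele odds ratios. Rare risk variants span MAF 0.01-0.12% with
    relative risks 3-15.
    """
    mis, fs, syn = (FunctionalClass.MISSENSE, FunctionalClass.FRAMESHIFT,
                    FunctionalClass.SYNONYMOUS)
    common = [
        PanelVariant(0.035, 2.23, mis, "GENE1", "common_R702W_like"),
        PanelVariant(0.014, 2.58, mis, "GENE1", "common_G908R_like"),
        PanelVariant(0.020, 3.83, fs, "GENE1", "common_L1007fs_like"),
    ]
    rare_freqs = [0.0012, 0.0006, 0.0004, 0.0004, 0.0003, 0.0002, 0.0001, 0.0001]
    rare_rrs = [3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0, 15.0]
    rare = [PanelVariant(f, r, fs if i == 5 else mis, "GENE1", f"rare{i + 1}")
            for i, (f, r) in enumerate(zip(rare_freqs, rare_rrs))]
    neutral = [
        PanelVariant(0.05, 1.0, syn, "GENE1", "neutral1"),
        PanelVariant(0.01, 1.0, syn, "GENE1", "neutral2"),
        PanelVariant(0.002, 1.0, mis, "GENE1", "neutral3"),
    ]
    return common + rare + neutral


@dataclasses.dataclass
class SimulationConfig:
    n_trios: int = 179
    n_case_only: int = 26
    n_controls: int = 200
    prevalence: float = 34.7e-5
    variants: list[PanelVariant] = dataclasses.field(default_factory=default_panel)
    de_novo_rate_snv: float = 1.2e-8  # per haploid base per generation
    de_novo_rate_indel: float = 4e-10
    gene_length: int = 3040  # coding bases exposed to de novo mutation
    missing_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        for name in ("prevalence", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.prevalence > 0 and self.variants:
            # Genotype risks above 1 are clipped when sampling; require the
            # clipped probability mass to leave the calibrated prevalence
            # essentially untouched (relative error < 0.1%).
            baseline = self.baseline_risk
            excess = _clipping_excess(self.variants, baseline)
            if excess > 1e-3 * self.prevalence:
                raise ValueError(
                    f"prevalence {self.prevalence} with this panel implies "
                    f"genotype risks above 1 with non-negligible probability "
                    f"(prevalence distortion {excess:.3g})")

    @property
    def baseline_risk(self) -> float:
        """Risk of the zero-alt genotype, calibrated to the prevalence."""
        f = np.array([v.allele_frequency for v in self.variants])
        rr = np.array([v.rr for v in self.variants])
        return self.prevalence / float(np.prod(((1 - f) + f * rr) ** 2))


@dataclasses.dataclass
class TruthTable:
    """Generating truth for a simulated cohort.

    ``diplotypes`` maps individual -> (2, n_panel_variants) haplotype
    array (maternal row first for children). ``risk`` is the generating
    disease probability of each individual. De novo events list
    (child_id, VariantRecord) pairs; the injected variants sit after the
    panel block in the emitted VCF and have generating frequency 0.
    """

    diplotypes: dict[str, np.ndarray]
    risk: dict[str, float]
    de_novo_events: list[tuple[str, VariantRecord]]
    panel: list[PanelVariant]

    def genotype(self, individual: str) -> np.ndarray:
        return self.diplotypes[individual].sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind, hap in self.diplotypes.items():
            rows.append({
                "individual": ind,
                "haplotype_1": "".join(map(str, hap[0])),
                "haplotype_2": "".join(map(str, hap[1])),
                "risk": self.risk[ind],
            })
        return pd.DataFrame(rows)


@dataclasses.dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    pedigree: PedigreeTable
    truth: TruthTable
    config: SimulationConfig


def _panel_records(panel: list[PanelVariant], chrom: str = "16",
                   start: int = 50_700_000) -> list[VariantRecord]:
    records = []
    for i, v in enumerate(panel):
        pos = start + 50 * i
        if v.functional_class is FunctionalClass.FRAMESHIFT:
            ref, alt = "AT", "A"
        else:
            ref, alt = "A", "G"
        records.append(VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                     gene=v.gene, variant_id=v.variant_id or f"v{i + 1}",
                                     functional_class=v.functional_class))
    return records


def _sample_affected_children(rng: np.random.Generator, n: int, freqs: np.ndarray,
                              rrs: np.ndarray, baseline: float,
                              batch: int = 250_000, max_draws: int = 500_000_000):
    """Rejection-sample affected children with their parents' haplotypes.

    Returns maternal haplotype pairs, paternal haplotype pairs, the
    transmitted maternal/paternal gametes and the children's risks, each
    with n rows. Vectorised over batches; acceptance probability equals
    the population prevalence by construction.
    """
    m = len(freqs)
    if n == 0:
        empty = np.empty((0, m), dtype=bool)
        return (empty,) * 6 + (np.empty(0),)
    out_m1, out_m2, out_f1, out_f2, out_cm, out_cf, out_risk = ([] for _ in range(7))
    drawn = got = 0
    while got < n:
        if drawn >= max_draws:
            raise RuntimeError("ascertainment did not converge; prevalence too low "
                               "for the requested cohort size")
        b = batch
        m1 = rng.random((b, m)) < freqs
        m2 = rng.random((b, m)) < freqs
        f1 = rng.random((b, m)) < freqs
        f2 = rng.random((b, m)) < freqs
        pick_m = rng.random((b, m)) < 0.5
        pick_f = rng.random((b, m)) < 0.5
        cm = np.where(pick_m, m1, m2)
        cf = np.where(pick_f, f1, f2)
        g = cm.astype(np.int8) + cf.astype(np.int8)
        risk = np.minimum(1.0, baseline * np.prod(rrs[None, :] ** g, axis=1))
        affected = rng.random(b) < risk
        drawn += b
        for src, dst in ((m1, out_m1), (m2, out_m2), (f1, out_f1), (f2, out_f2),
                         (cm, out_cm), (cf, out_cf)):
            dst.append(src[affected])
        out_risk.append(risk[affected])
        got += int(affected.sum())
    cat = lambda parts: np.concatenate(parts, axis=0)[:n]
    return (cat(out_m1), cat(out_m2), cat(out_f1), cat(out_f2),
            cat(out_cm), cat(out_cf), cat(out_risk))


def _sample_unaffected(rng: np.random.Generator, n: int, freqs: np.ndarray,
                       rrs: np.ndarray, baseline: float):
    """Sample adults conditional on being unaffected (acceptance ~ 1)."""
    m = len(freqs)
    if n == 0:
        empty = np.empty((0, m), dtype=bool)
        return empty, empty, np.empty(0)
    h1_parts, h2_parts, risk_parts = [], [], []
    got = 0
    while got < n:
        b = max(n - got + 16, 64)
        h1 = rng.random((b, m)) < freqs
        h2 = rng.random((b, m)) < freqs
        g = h1.astype(np.int8) + h2.astype(np.int8)
        risk = np.minimum(1.0, baseline * np.prod(rrs[None, :] ** g, axis=1))
        keep = rng.random(b) >= risk
        h1_parts.append(h1[keep])
        h2_parts.append(h2[keep])
        risk_parts.append(risk[keep])
        got += int(keep.sum())
    cat = lambda parts: np.concatenate(parts, axis=0)[:n]
    return cat(h1_parts), cat(h2_parts), cat(risk_parts)


def _de_novo_counts(rng: np.random.Generator, n_children: int, gene_length: int,
                    rate: float) -> np.ndarray:
    """Events per child: Poisson with mean 2 x gene_length x rate.

    Rates are per haploid base per generation, hence the factor 2 for a
    diploid genome.
    """
    return rng.poisson(2.0 * gene_length * rate, size=n_children)


def simulate_cohort(config: SimulationConfig, out_dir=None) -> SimulatedCohort:
    """Simulate a trio cohort; optionally emit VCF/PED/truth files.

    Deterministic given ``config.seed``. When ``out_dir`` is given,
    writes ``cohort.vcf``, ``cohort.ped`` and ``truth.tsv`` there.
    """
    if config.prevalence < 1e-8:
        raise ValueError(f"expected ascertainment acceptance probability "
                         f"{config.prevalence:.2g} < 1e-8 is unattainable")
    rng = np.random.default_rng(config.seed)
    panel = config.variants
    freqs = np.array([v.allele_frequency for v in panel])
    rrs = np.array([v.rr for v in panel])
    baseline = config.baseline_risk

    n_children = config.n_trios + config.n_case_only
    m1, m2, f1, f2, cm, cf, child_risk = _sample_affected_children(
        rng, n_children, freqs, rrs, baseline)
    ctrl1, ctrl2, ctrl_risk = _sample_unaffected(
        rng, config.n_controls, freqs, rrs, baseline)

    width = max(3, len(str(max(n_children, config.n_controls))))
    child_ids = [f"case{i + 1:0{width}d}" for i in range(n_children)]
    ctrl_ids = [f"ctrl{i + 1:0{width}d}" for i in range(config.n_controls)]

    diplotypes: dict[str, np.ndarray] = {}
    risk: dict[str, float] = {}
    individuals: list[str] = []
    rows_hap: list[np.ndarray] = []  # (2, m) per individual
    ped_rows = []

    for i, cid in enumerate(child_ids):
        is_trio = i < config.n_trios
        sex = "1" if rng.random() < 0.5 else "2"
        child_hap = np.stack([cm[i], cf[i]]).astype(np.int8)
        individuals.append(cid)
        rows_hap.append(child_hap)
        diplotypes[cid] = child_hap
        risk[cid] = float(child_risk[i])
        if is_trio:
            mo, fa = f"{cid}_mo", f"{cid}_fa"
            for pid, h1, h2 in ((mo, m1[i], m2[i]), (fa, f1[i], f2[i])):
                hap = np.stack([h1, h2]).astype(np.int8)
                individuals.append(pid)
                rows_hap.append(hap)
                diplotypes[pid] = hap
                g = hap.sum(axis=0)
                risk[pid] = float(min(1.0, baseline * np.prod(rrs ** g)))
            ped_rows.append((cid, cid, fa, mo, sex, Status.CASE))
            ped_rows.append((cid, fa, "0", "0", "1", Status.PARENT))
            ped_rows.append((cid, mo, "0", "0", "2", Status.PARENT))
        else:
            ped_rows.append((cid, cid, "0", "0", sex, Status.CASE))
    for i, sid in enumerate(ctrl_ids):
        sex = "1" if rng.random() < 0.5 else "2"
        hap = np.stack([ctrl1[i], ctrl2[i]]).astype(np.int8)
        individuals.append(sid)
        rows_hap.append(hap)
        diplotypes[sid] = hap
        risk[sid] = float(ctrl_risk[i])
        ped_rows.append((sid, sid, "0", "0", sex, Status.CONTROL))

    records = _panel_records(panel)
    calls = np.stack([h.sum(axis=0) for h in rows_hap]).astype(np.int8)

    # De novo injection: per trio child, per mutation class.
    de_novo_events: list[tuple[str, VariantRecord]] = []
    dn_cols: list[np.ndarray] = []
    trio_children = child_ids[:config.n_trios]
    n_snv = _de_novo_counts(rng, len(trio_children), config.gene_length,
                            config.de_novo_rate_snv)
    n_indel = _de_novo_counts(rng, len(trio_children), config.gene_length,
                              config.de_novo_rate_indel)
    next_pos = records[-1].pos + 50 if records else 50_700_000
    gene = panel[0].gene if panel else "GENE1"
    ind_index = {s: i for i, s in enumerate(individuals)}
    for i, cid in enumerate(trio_children):
        for count, fclass, ref, alt in (
                (int(n_snv[i]), FunctionalClass.MISSENSE, "C", "T"),
                (int(n_indel[i]), FunctionalClass.FRAMESHIFT, "CA", "C")):
            for _ in range(count):
                rec = VariantRecord(chrom="16", pos=next_pos, ref=ref, alt=alt,
                                    gene=gene, variant_id=f"dn_{cid}_{next_pos}",
                                    functional_class=fclass)
                next_pos += 50
                col = np.zeros(len(individuals), dtype=np.int8)
                col[ind_index[cid]] = 1
                dn_cols.append(col)
                de_novo_events.append((cid, rec))
                records.append(rec)
    if dn_cols:
        calls = np.concatenate([calls, np.stack(dn_cols, axis=1)], axis=1)

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)

    gm = GenotypeMatrix(individuals, records, calls)
    ped = PedigreeTable(pd.DataFrame(
        ped_rows, columns=["family", "individual", "father", "mother", "sex", "status"]))
    truth = TruthTable(diplotypes=diplotypes, risk=risk,
                       de_novo_events=de_novo_events, panel=panel)
    cohort = SimulatedCohort(gm, ped, truth, config)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_vcf(gm, out_dir / "cohort.vcf")
        write_ped(ped, out_dir / "cohort.ped")
        truth.to_frame().to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return cohort


def sample_case_control_genotypes(rng: np.random.Generator, n_cases: int,
                                  n_controls: int, freqs, rrs,
                                  prevalence: float = 34.7e-5
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Draw case and control genotype matrices from the exact conditional law.

    Under linkage equilibrium and a multiplicative model the genotype
    distribution conditional on affection factorises per variant:
    P(g | case) ~ HWE(g) x RR^g, and controls follow HWE weighted by
    (1 - risk) which at low prevalence is HWE to first order. This is the
    same law the rejection sampler targets, drawn directly; used for
    large power/calibration studies where rejection at a realistic
    prevalence would be wasteful.
    """
    freqs = np.asarray(freqs, float)
    rrs = np.asarray(rrs, float)
    hwe = np.stack([(1 - freqs) ** 2, 2 * freqs * (1 - freqs), freqs ** 2])
    tilt = np.stack([np.ones_like(rrs), rrs, rrs ** 2])
    case_p = hwe * tilt
    case_p /= case_p.sum(axis=0, keepdims=True)
    cases = np.stack([rng.choice(3, size=n_cases, p=case_p[:, j])
                      for j in range(len(freqs))], axis=1).astype(np.int8)
    # controls: unaffected ~ HWE x (1 - baseline*RR^g); at low prevalence ~ HWE
    base = prevalence / np.prod(((1 - freqs) + freqs * rrs) ** 2)
    ctrl_p = hwe * (1 - np.minimum(base * tilt, 1.0))
    ctrl_p /= ctrl_p.sum(axis=0, keepdims=True)
    controls = np.stack([rng.choice(3, size=n_controls, p=ctrl_p[:, j])
                         for j in range(len(freqs))], axis=1).astype(np.int8)
    return cases, controls


def simulate_meta_studies(k: int, true_log_or: float, tau2: float,
                          study_sizes, seed: int) -> list[tuple[int, int, int, int]]:
    """Simulate per-study 2x2 tables with between-study heterogeneity.

    Each study's log odds ratio is drawn Normal(true_log_or, tau2); case
    and control exposure counts are binomial at the implied odds around a
    baseline exposure of 0.3. Returns (a, b, c, d) tuples: exposed cases,
    unexposed cases, exposed controls, unexposed controls.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    sizes = list(study_sizes)
    if len(sizes) == 1:
        sizes = sizes * k
    if len(sizes) != k:
        raise ValueError(f"study_sizes has {len(sizes)} entries for k={k}")
    rng = np.random.default_rng(seed)
    p0 = 0.3
    odds0 = p0 / (1 - p0)
    tables = []
    for n in sizes:
        theta = true_log_or + (np.sqrt(tau2) * rng.standard_normal() if tau2 > 0 else 0.0)
        p1 = odds0 * np.exp(theta) / (1 + odds0 * np.exp(theta))
        a = int(rng.binomial(n, p1))
        c = int(rng.binomial(n, p0))
        tables.append((a, n - a, c, n - c))
    return tables
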