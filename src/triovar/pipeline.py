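"""End-to-end pipeline: filter -> trio genetics -> association ->
meta-analysis -> risk attribution, driven by a single YAML config.

Every stage communicates through TSV files in the output directory, so
stages can be re-run individually; a run log records the seed and every
threshold actually applied. Outputs are deterministic for a fixed
config and seed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, meta, risk, trio
from .cohort import (ConfigurationError, GenotypeMatrix, PedigreeTable,
                     ReferenceCountTable, apply_missingness_filter, read_ped,
                     read_reference_counts, read_vcf)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("triovar")


@dataclasses.dataclass
class PipelineConfig:
    vcf: str
    ped: str
    out_dir: str
    reference_counts: str | None = None
    panel: str | None = None
    meta_studies: str | None = None
    missingness_threshold: float = 0.10
    maf_cap: float = 0.05
    rare_maf: float = 0.01
    de_novo_maf: float = 0.005
    alpha: float = 0.05
    prevalence: float = 34.7e-5
    reference_population: str = "NFE"
    method: str = "firth"
    par_n_sim: int = 10_000
    seed: int = 0

    def __post_init__(self):
        bounds = {"missingness_threshold": (0, 1), "maf_cap": (0, 0.5),
                  "rare_maf": (0, 0.5), "de_novo_maf": (0, 0.5),
                  "alpha": (0, 1), "prevalence": (0, 1)}
        for name, (lo, hi) in bounds.items():
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ConfigurationError(f"{name}={v} outside ({lo}, {hi}]")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _read_panel(path, gm: GenotypeMatrix) -> trio.Panel:
    """Panel TSV: variant (chrom:pos:ref:alt), label, class (common|rare)."""
    df = pd.read_csv(path, sep="\t")
    common, rare, labels = [], [], []
    from .cohort import _parse_variant_key
    for _, row in df.iterrows():
        key = _parse_variant_key(str(row["variant"]))
        labels.append((key, str(row.get("label", row["variant"]))))
        cls = str(row["class"]).lower()
        if cls == "common":
            common.append(key)
        elif cls == "rare":
            rare.append(key)
        else:
            raise ConfigurationError(f"panel class must be common|rare, got {cls!r}")
    return trio.Panel(common=tuple(common), rare=tuple(rare), labels=tuple(labels))


def _derive_panel(gm: GenotypeMatrix, ped: PedigreeTable,
                  rare_maf: float, maf_cap: float) -> trio.Panel:
    """Fallback panel from observed frequencies when none is configured:
    non-synonymous variants split at the rare-MAF threshold."""
    subjects = [s for s in ped.cases + ped.controls if gm.has_individual(s)]
    sub = gm.rows(subjects)
    common, rare, labels = [], [], []
    for j, v in enumerate(gm.variants):
        if v.functional_class.value == "synonymous":
            continue
        col = sub[:, j]
        called = col[col != -1]
        if len(called) == 0 or called.sum() == 0:
            continue
        f = called.sum() / (2 * len(called))
        maf = min(f, 1 - f)
        labels.append(((v.chrom, v.pos, v.ref, v.alt), v.variant_id or f"{v.chrom}:{v.pos}"))
        if maf >= rare_maf:
            if maf <= maf_cap:
                common.append((v.chrom, v.pos, v.ref, v.alt))
            else:
                labels.pop()
        else:
            rare.append((v.chrom, v.pos, v.ref, v.alt))
    return trio.Panel(common=tuple(common), rare=tuple(rare), labels=tuple(labels))


def _fit_model(encoding_df: pd.DataFrame, method: str):
    y = (encoding_df["status"] == "case").to_numpy(dtype=float)
    # constant indicator columns (no carriers in the cohort) carry no
    # information and would make the design rank-deficient
    cols = [c for c in encoding_df.columns
            if c != "status" and encoding_df[c].nunique() > 1]
    X = np.column_stack([np.ones(len(encoding_df)),
                         encoding_df[cols].to_numpy(dtype=float)])
    fit = assoc.logistic_fit(y, X, method=method, names=["intercept"] + cols)
    return fit, y


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: list[str] = []
    try:
        log.info("seed=%d thresholds: missingness=%g maf_cap=%g rare_maf=%g "
                 "de_novo_maf=%g alpha=%g prevalence=%g method=%s",
                 config.seed, config.missingness_threshold, config.maf_cap,
                 config.rare_maf, config.de_novo_maf, config.alpha,
                 config.prevalence, config.method)

        # --- stage: input + missingness filter -------------------------------
        try:
            gm, _ = read_vcf(config.vcf)
            ped = read_ped(config.ped)
            n_before = gm.n_variants
            gm = apply_missingness_filter(gm, ped, config.missingness_threshold)
            log.info("missingness filter: %d -> %d variants", n_before, gm.n_variants)
        except Exception as exc:
            raise RuntimeError(f"stage 'filter' failed: {exc}") from exc
        summary.append(f"variants after missingness filter: {gm.n_variants}")

        ref = None
        if config.reference_counts:
            ref = read_reference_counts(config.reference_counts)
        else:
            log.warning("no reference count table; single-marker and de novo "
                        "frequency filters run without external frequencies")

        # --- stage: trio genetics -------------------------------------------
        try:
            panel = (_read_panel(config.panel, gm) if config.panel
                     else _derive_panel(gm, ped, config.rare_maf, config.maf_cap))
            log.info("panel: %d common, %d rare variants", len(panel.common),
                     len(panel.rare))
            trios = ped.complete_trios(gm.individuals)
            if trios:
                dn_calls = trio.detect_de_novo(gm, ped, ref,
                                               max_maf=config.de_novo_maf)
                pd.DataFrame([{
                    "trio": c.trio_id, "chrom": c.variant.chrom,
                    "pos": c.variant.pos, "ref": c.variant.ref,
                    "alt": c.variant.alt, "gene": c.variant.gene,
                    "cohort_occurrence": c.cohort_occurrence,
                    "max_reference_maf": c.max_reference_maf,
                } for c in dn_calls]).to_csv(out / "de_novo_calls.tsv",
                                             sep="\t", index=False)
                genes = sorted({v.gene for v in gm.variants if v.gene})
                dn_rows = []
                for gene in genes:
                    obs = sum(1 for c in dn_calls if c.variant.gene == gene)
                    p = trio.de_novo_burden_test(obs, gene_length=3040,
                                                 n_trios=len(trios))
                    dn_rows.append({"gene": gene, "observed": obs, "p": p,
                                    "method": "poisson_burden_stand_in"})
                pd.DataFrame(dn_rows).to_csv(out / "de_novo_burden.tsv",
                                             sep="\t", index=False)
                summary.append(f"de novo calls passing filters: {len(dn_calls)}")
            else:
                log.warning("no complete trios; de novo stage skipped")
            encoding = trio.build_carrier_encoding(gm, ped, panel)
            encoding.model1.to_csv(out / "encoding_model1.tsv", sep="\t")
            encoding.model2.to_csv(out / "encoding_model2.tsv", sep="\t")
            encoding.provenance.to_csv(out / "encoding_categories.tsv",
                                       sep="\t", index=False)
        except Exception as exc:
            raise RuntimeError(f"stage 'trio' failed: {exc}") from exc

        # --- stage: association ---------------------------------------------
        try:
            genes = sorted({v.gene for v in gm.variants if v.gene})
            burden_rows = []
            for gene in genes:
                r = assoc.carrier_burden_test(gene, gm, ped, maf_cap=config.maf_cap)
                burden_rows.append({
                    "gene": gene, "or": r.estimate, "ci_low": r.ci_low,
                    "ci_high": r.ci_high, "p": r.p, "sided": r.sided,
                    "p_bonferroni": (assoc.bonferroni(r.p, len(genes))
                                     if r.p is not None else None),
                    "flags": ",".join(r.flags)})
            pd.DataFrame(burden_rows).to_csv(out / "burden.tsv", sep="\t", index=False)

            if ref is not None:
                sm_rows = []
                for key in panel.rare:
                    v = gm.variants[gm.variant_index(key)]
                    try:
                        r = assoc.single_marker_test(
                            v, gm, ped, ref, population=config.reference_population,
                            internal_maf_cap=config.rare_maf)
                    except ConfigurationError as exc:
                        log.warning("single-marker skipped for %s: %s",
                                    panel.label(key), exc)
                        continue
                    sm_rows.append({"variant": panel.label(key), "or": r.estimate,
                                    "ci_low": r.ci_low, "ci_high": r.ci_high,
                                    "p": r.p, "sided": r.sided,
                                    "flags": ",".join(r.flags)})
                pd.DataFrame(sm_rows).to_csv(out / "single_marker.tsv",
                                             sep="\t", index=False)
            model_rows = []
            for model_no, df in ((1, encoding.model1), (2, encoding.model2)):
                fit, y = _fit_model(df, config.method)
                r2 = assoc.tjur_r2(fit.fitted, y)
                ci = fit.wald_ci()
                for name, coef, se, (lo, hi) in zip(
                        fit.names, fit.coefficients, fit.standard_errors, ci):
                    model_rows.append({
                        "model": model_no, "covariate": name,
                        "log_or": coef, "se": se, "or": float(np.exp(coef)),
                        "ci_low": lo, "ci_high": hi, "method": config.method,
                        "converged": fit.converged, "tjur_r2": r2})
                summary.append(f"model {model_no} Tjur R2 = {r2:.4f}")
            pd.DataFrame(model_rows).to_csv(out / "effect_models.tsv",
                                            sep="\t", index=False)
        except Exception as exc:
            raise RuntimeError(f"stage 'assoc' failed: {exc}") from exc

        # --- stage: meta-analysis -------------------------------------------
        meta_or = {}
        if config.meta_studies:
            try:
                studies = meta.read_study_table(config.meta_studies)
                result = meta.dersimonian_laird(studies)
                pd.DataFrame([{
                    "pooled_or": result.pooled_or, "ci_low": result.ci_low,
                    "ci_high": result.ci_high, "tau2": result.tau2,
                    "Q": result.Q, "k": result.k,
                }]).to_csv(out / "meta.tsv", sep="\t", index=False)
                meta.forest_table(studies, result).to_csv(
                    out / "meta_forest.tsv", sep="\t", index=False)
                summary.append(f"meta-analysis pooled OR = {result.pooled_or:.3f} "
                               f"(k={result.k}, tau2={result.tau2:.4f})")
            except Exception as exc:
                raise RuntimeError(f"stage 'meta' failed: {exc}") from exc
        else:
            log.warning("no meta-analysis study table; meta stage skipped")

        # --- stage: risk attribution ----------------------------------------
        try:
            estimates = []
            subjects = [s for s in ped.cases + ped.controls if gm.has_individual(s)]
            controls = [s for s in ped.controls if gm.has_individual(s)]
            for key in (*panel.common, *panel.rare):
                j = gm.variant_index(key)
                col = gm.rows(controls)[:, j]
                called = col[col != -1]
                pe = (ref.frequency(key, config.reference_population)
                      if ref is not None else
                      float(called.sum() / (2 * len(called))) if len(called) else 0.0)
                if pe <= 0:
                    continue
                sub = gm.rows(subjects)[:, j]
                cases_idx = len([s for s in ped.cases if gm.has_individual(s)])
                cc = sub[:cases_idx]
                ct = sub[cases_idx:]
                a = int(cc[cc != -1].sum())
                b = 2 * len(cc[cc != -1]) - a
                c = int(ct[ct != -1].sum())
                d = 2 * len(ct[ct != -1]) - c
                orr = assoc.odds_ratio_2x2(assoc.TwoByTwo(a, b, c, d, allele_based=True),
                                           continuity=assoc.Continuity.HALDANE)
                se = ((np.log(orr.ci_high) - np.log(orr.ci_low)) / (2 * assoc.Z95)
                      if np.isfinite(orr.ci_high) else None)
                # locus attribution covers putative risk variants only;
                # chance-protective estimates would contribute negative PAR
                if orr.estimate <= 1 or not np.isfinite(orr.estimate):
                    continue
                estimates.append(risk.RiskVariantEstimate(
                    variant_id=panel.label(key), pe=pe, or_per_allele=orr.estimate,
                    p0=config.prevalence, se_log_or=se, source="cohort"))
            attribution = risk.attribute_risk(estimates, n_sim=config.par_n_sim,
                                              seed=config.seed)
            rows = [{
                "variant": e.variant_id, "pe": e.pe, "or": e.or_per_allele,
                "rr_het": e.rr_het, "rr_hom": e.rr_hom, "par": e.par,
                "h2": e.h2, "source": e.source,
            } for e in attribution.estimates]
            rows.append({"variant": "LOCUS", "par": attribution.locus_par,
                         "h2": attribution.locus_h2,
                         "pe": None, "or": None, "rr_het": None, "rr_hom": None,
                         "source": "combined"})
            df = pd.DataFrame(rows)
            if attribution.locus_par_ci is not None:
                df.loc[df["variant"] == "LOCUS", "par_ci_low"] = attribution.locus_par_ci[0]
                df.loc[df["variant"] == "LOCUS", "par_ci_high"] = attribution.locus_par_ci[1]
            df.to_csv(out / "risk_attribution.tsv", sep="\t", index=False)
            summary.append(f"locus PAR = {attribution.locus_par:.4f}, "
                           f"locus h2 = {attribution.locus_h2:.5f}")
        except Exception as exc:
            raise RuntimeError(f"stage 'par' failed: {exc}") from exc

        (out / "summary.txt").write_text("\n".join(summary) + "\n")
        log.info("pipeline complete")
        return out
    finally:
        log.removeHandler(handler)
        handler.close()
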